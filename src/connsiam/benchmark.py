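"""End-to-end synthetic benchmarks: simulate -> features -> train -> evaluate.

The default benchmark is a desk-scale stand-in for a multi-site cohort:
7 sites at R=20 regions and T=150 timepoints, 20 subjects per class per
site; 4 sites train the similarity model, 1 serves as the baseline (its
class-mean embeddings are the prototypes), and 2 held-out sites play the
role of unseen target sites.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluate import (
    EvalProtocol,
    evaluate_target_sites,
    nearest_class_mean,
)
from .features import WindowSpec, cohort_features
from .io import RunConfig
from .simulate import SimConfig, simulate_cohort_arrays
from .training import SiteDataset, sites_from_features, train

TRAINING_SITES = ("SITE00", "SITE01", "SITE02", "SITE03")
BASELINE_SITE = "SITE04"
TARGET_SITES = ("SITE05", "SITE06")


def default_sim_config(seed: int, **overrides) -> SimConfig:
    return replace(SimConfig(rng_seed=seed), **overrides) if overrides else SimConfig(rng_seed=seed)


def default_run_config(seed: int, **overrides) -> RunConfig:
    """Run parameters scaled to the R=20 benchmark (input dim 190)."""
    config = RunConfig(
        n_regions=20,
        encoder_widths=(64, 32),
        head_widths=(32,),
        embedding_dim=16,
        n_iterations=500,
        rng_seed=seed,
        baseline_site=BASELINE_SITE,
        training_sites=TRAINING_SITES,
    )
    for key, value in overrides.items():
        setattr(config, key, value)
    return config


def benchmark_features(
    sim: SimConfig,
    window: WindowSpec,
    *,
    site_effect_sd_by_site: dict[str, float] | None = None,
) -> dict[str, SiteDataset]:
    cohort = simulate_cohort_arrays(sim, site_effect_sd_by_site=site_effect_sd_by_site)
    table = cohort_features(cohort, window)
    return sites_from_features(table)


def run_benchmark(
    seed: int,
    *,
    sim_overrides: dict | None = None,
    run_overrides: dict | None = None,
    target_site_effect_sd: float | None = None,
    protocol: EvalProtocol | None = None,
    with_ncm_baseline: bool = False,
    with_zero_shot: bool = False,
) -> dict:
    """One full benchmark run at the given seed.

    Returns a dict with the trained model, loss history, final meta-test
    accuracies per training site, the target-site metrics report, and
    optionally a pooled nearest-class-mean comparison and a zero-shot
    (no fine-tuning) arm scored on the same queries.
    """
    sim = default_sim_config(seed, **(sim_overrides or {}))
    run = default_run_config(seed, **(run_overrides or {}))
    window = WindowSpec(run.window_length, run.window_stride)
    overrides_by_site = None
    if target_site_effect_sd is not None:
        overrides_by_site = {s: target_site_effect_sd for s in TARGET_SITES}
    sites = benchmark_features(sim, window, site_effect_sd_by_site=overrides_by_site)

    training = [sites[s] for s in TRAINING_SITES]
    baseline = sites[BASELINE_SITE]
    targets = [sites[s] for s in TARGET_SITES]

    model, history, splits = train(run, training, baseline)

    final_meta = history[-1].meta_test_accuracy or {}
    mean_meta_accuracy = 100.0 * float(np.mean(list(final_meta.values()))) if final_meta else float("nan")

    protocol = protocol or EvalProtocol(
        fine_tune_shots_per_class=run.fine_tune_shots_per_class,
        fine_tune_steps=run.fine_tune_steps,
        learning_rate=run.learning_rate,
        optimizer=run.optimizer,
        rng_seed=run.rng_seed,
    )
    report, predictions = evaluate_target_sites(
        model,
        targets,
        baseline,
        protocol,
        training_site_ids=TRAINING_SITES,
    )
    out = {
        "model": model,
        "history": history,
        "splits": splits,
        "meta_test_accuracy_per_site": {k: 100.0 * v for k, v in final_meta.items()},
        "mean_meta_test_accuracy": mean_meta_accuracy,
        "target_report": report,
        "mean_target_accuracy": report["MACRO"]["accuracy"],
        "predictions": predictions,
    }
    if with_zero_shot:
        zs_protocol = replace(protocol, fine_tune_steps=0)
        zs_report, _ = evaluate_target_sites(
            model, targets, baseline, zs_protocol, training_site_ids=TRAINING_SITES
        )
        out["zero_shot_report"] = zs_report
        out["mean_zero_shot_accuracy"] = zs_report["MACRO"]["accuracy"]
    if with_ncm_baseline:  # pooled comparison, ignoring site structure
        pooled_x = np.vstack([sites[s].features for s in (*TRAINING_SITES, BASELINE_SITE)])
        pooled_y = [
            label
            for s in (*TRAINING_SITES, BASELINE_SITE)
            for label in sites[s].labels
        ]
        accs = []
        for target in targets:
            preds = nearest_class_mean(pooled_x, pooled_y, target.features)
            accs.append(
                100.0 * float(np.mean([p == t for p, t in zip(preds, target.labels)]))
            )
        out["ncm_mean_target_accuracy"] = float(np.mean(accs))
    return out


def run_pipeline(
    workdir,
    sim: SimConfig,
    run: RunConfig,
    protocol: EvalProtocol,
    *,
    training_site_ids: tuple[str, ...] = TRAINING_SITES,
    baseline_site: str = BASELINE_SITE,
    target_site_ids: tuple[str, ...] = TARGET_SITES,
) -> dict:
    """File-based end-to-end run: simulate -> features -> train -> evaluate.

    Every intermediate artifact is written under ``workdir`` (time-series
    CSVs + manifest, feature CSV, model checkpoint, loss history CSV,
    metrics JSON), exercising the same format round-trips a user's shell
    run would.  Returns the paths and the metrics report.
    """
    from pathlib import Path

    from .io import load_cohort, read_features, read_manifest, write_features, write_metrics
    from .simulate import simulate_cohort
    from .training import run_config_hash

    workdir = Path(workdir)
    data_dir = workdir / "data"
    manifest = simulate_cohort(sim, data_dir)
    manifest = read_manifest(data_dir / "manifest.csv")
    cohort = load_cohort(manifest, sim.n_regions)
    window = WindowSpec(run.window_length, run.window_stride)
    table = cohort_features(cohort, window, fisher_z=run.fisher_z)
    features_path = workdir / "features.csv"
    write_features(table, features_path)

    sites = sites_from_features(read_features(features_path))
    training = [sites[s] for s in training_site_ids]
    baseline = sites[baseline_site]
    targets = [sites[s] for s in target_site_ids]
    model, history, _ = train(run, training, baseline)
    checkpoint_path = workdir / "model.npz"
    model.save(checkpoint_path, config_hash=run_config_hash(run))
    history_rows = []
    for report in history:
        for site_id, value in sorted(report.per_site.items()):
            history_rows.append(
                {"step": report.step, "site_id": site_id, "loss": value, "total": report.total}
            )
    pd.DataFrame(history_rows).to_csv(workdir / "loss_history.csv", index=False)

    report, predictions = evaluate_target_sites(
        model, targets, baseline, protocol, training_site_ids=tuple(training_site_ids)
    )
    metrics_path = workdir / "metrics.json"
    write_metrics(report, metrics_path)
    predictions.to_csv(workdir / "predictions.csv", index=False)
    return {
        "metrics_path": metrics_path,
        "features_path": features_path,
        "checkpoint_path": checkpoint_path,
        "report": report,
    }
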