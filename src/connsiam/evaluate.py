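"""Target-site evaluation: balancing, fine-tuning, prototype matching, metrics.

The protocol for an unseen site: equalize the class counts by random
removal, draw a small seeded support set (N shots per class) to briefly
continue training against the baseline prototypes, then classify every
remaining query subject by comparing its similarity output against the NC
and ASD prototypes -- the class with the smaller sigmoid-of-distance output
wins, with exact ties going to ASD.  Support subjects are never scored.

ASD is treated as the positive class for precision/recall/F1.  Zero
denominators follow the conventions: precision := 0 when no positive
predictions exist; F1 := 0 when precision + recall = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .io import ASD, NC, RunConfig
from .model import SiameseNet, l1_distance, similarity_output
from .training import (
    Adam,
    PrototypePair,
    SiteDataset,
    _check_fresh,
    _losses_and_grads,
    compute_prototypes,
    make_optimizer,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalProtocol:
    """Two-way (NC vs ASD) target-site protocol parameters."""

    fine_tune_shots_per_class: int = 5
    fine_tune_steps: int = 50
    balance: bool = True
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fine_tune_shots_per_class < 0:
            raise ValueError("fine_tune_shots_per_class must be >= 0")
        if self.fine_tune_steps < 0:
            raise ValueError("fine_tune_steps must be >= 0")


def balance_classes(site: SiteDataset, rng: np.random.Generator) -> SiteDataset:
    """Equalize class counts by uniform random removal from the larger class."""
    nc_idx = site.class_indices(NC)
    asd_idx = site.class_indices(ASD)
    if len(nc_idx) == 0 or len(asd_idx) == 0:
        missing = NC if len(nc_idx) == 0 else ASD
        raise ValueError(f"site {site.site_id}: class {missing} absent, cannot balance")
    keep = min(len(nc_idx), len(asd_idx))
    kept = []
    for idx in (nc_idx, asd_idx):
        if len(idx) > keep:
            chosen = rng.choice(len(idx), size=keep, replace=False)
            kept.extend(idx[np.sort(chosen)])
        else:
            kept.extend(idx)
    return site.subset(np.sort(kept))


def fine_tune(
    model: SiameseNet,
    target_support: SiteDataset,
    baseline: SiteDataset,
    protocol: EvalProtocol,
    *,
    raw_distance: bool = False,
    reconstruction_weight: float = 0.0,
) -> SiameseNet:
    """Continue gradient descent on the support-vs-prototypes loss.

    Operates on a copy; the input model is never mutated.  All parameters
    are updated (no layer freezing).
    """
    tuned = model.copy()
    if protocol.fine_tune_steps == 0 or target_support.n_samples == 0:
        return tuned
    if protocol.optimizer == "adam":
        optimizer = Adam(protocol.learning_rate)
    else:
        from .training import SGD

        optimizer = SGD(protocol.learning_rate)
    for _ in range(protocol.fine_tune_steps):
        _, total, grads = _losses_and_grads(
            tuned,
            [target_support],
            baseline,
            raw_distance=raw_distance,
            reconstruction_weight=reconstruction_weight,
        )
        if not np.isfinite(total):
            raise FloatingPointError("fine-tuning diverged (non-finite loss)")
        tuned.set_params(optimizer.step(tuned.params, grads))
    return tuned


def classify(
    model: SiameseNet, query: np.ndarray, protos: PrototypePair
) -> tuple[str, float, float]:
    """Predict NC iff the similarity output against the NC prototype is
    strictly smaller; ties go to ASD.  Returns (label, out_nc, out_asd)."""
    _check_fresh(model, protos)
    emb = model.embed(query)
    out_nc = similarity_output(
        l1_distance(emb, protos.proto_nc),
        affine_a=model.affine_a,
        affine_b=model.affine_b,
    )
    out_asd = similarity_output(
        l1_distance(emb, protos.proto_asd),
        affine_a=model.affine_a,
        affine_b=model.affine_b,
    )
    label = NC if out_nc < out_asd else ASD
    return label, out_nc, out_asd


def compute_metrics(preds: list[str], truth: list[str]) -> dict:
    """Accuracy/precision/F1 (percent) with ASD as the positive class."""
    if len(preds) != len(truth):
        raise ValueError(f"length mismatch: {len(preds)} preds vs {len(truth)} truths")
    if len(preds) == 0:
        raise ValueError("empty prediction list")
    tp = sum(1 for p, t in zip(preds, truth) if p == ASD and t == ASD)
    fp = sum(1 for p, t in zip(preds, truth) if p == ASD and t == NC)
    fn = sum(1 for p, t in zip(preds, truth) if p == NC and t == ASD)
    tn = sum(1 for p, t in zip(preds, truth) if p == NC and t == NC)
    n = len(preds)
    accuracy = (tp + tn) / n
    if tp + fp == 0:
        logger.warning("no positive (ASD) predictions; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        logger.warning("precision + recall = 0; F1 set to 0")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": 100.0 * accuracy,
        "precision": 100.0 * precision,
        "f1": 100.0 * f1,
        "n": n,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def evaluate_target_sites(
    model: SiameseNet,
    targets: list[SiteDataset],
    baseline: SiteDataset,
    protocol: EvalProtocol,
    *,
    training_site_ids: tuple[str, ...] = (),
    raw_distance: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Run the full target-site protocol per site.

    Per site: balance -> draw support (shots per class) -> fine-tune a fresh
    copy of the model -> classify the remaining queries against recomputed
    baseline prototypes -> metrics.  Returns (metrics report keyed by site
    plus a MACRO average row, per-subject prediction table).
    """
    forbidden = set(training_site_ids) | {baseline.site_id}
    overlap = sorted({t.site_id for t in targets} & forbidden)
    if overlap:
        raise ValueError(
            f"target site(s) overlap training/baseline sites: {', '.join(overlap)}"
        )
    report: dict = {}
    rows = []
    site_accs, site_precs, site_f1s = [], [], []
    for target in targets:
        rng = substream(protocol.rng_seed, f"eval:{target.site_id}")
        working = balance_classes(target, rng) if protocol.balance else target
        shots = protocol.fine_tune_shots_per_class
        support_idx: list[int] = []
        if shots > 0:
            for label in (NC, ASD):
                idx = working.class_indices(label)
                if shots > len(idx):
                    raise ValueError(
                        f"site {working.site_id}: {shots} shots requested but only "
                        f"{len(idx)} {label} samples available"
                    )
                chosen = rng.choice(len(idx), size=shots, replace=False)
                support_idx.extend(idx[np.sort(chosen)])
        support_idx = sorted(support_idx)
        query_idx = [i for i in range(working.n_samples) if i not in set(support_idx)]
        support = working.subset(np.array(support_idx, dtype=int))
        queries = working.subset(np.array(query_idx, dtype=int))
        # support/query disjointness audit
        shared = set(support.subject_ids) & set(queries.subject_ids)
        assert not shared, f"support leaked into queries: {shared}"
        if shots > 0 and protocol.fine_tune_steps > 0:
            site_model = fine_tune(
                model, support, baseline, protocol, raw_distance=raw_distance
            )
        else:
            site_model = model.copy()
        protos = compute_prototypes(site_model, baseline)
        preds = []
        for sid, q, truth in zip(queries.subject_ids, queries.features, queries.labels):
            label, out_nc, out_asd = classify(site_model, q, protos)
            preds.append(label)
            rows.append(
                {
                    "subject_id": sid,
                    "site_id": queries.site_id,
                    "truth": truth,
                    "pred": label,
                    "output_nc": out_nc,
                    "output_asd": out_asd,
                }
            )
        metrics = compute_metrics(preds, list(queries.labels))
        report[target.site_id] = metrics
        site_accs.append(metrics["accuracy"])
        site_precs.append(metrics["precision"])
        site_f1s.append(metrics["f1"])
    if site_accs:
        report["MACRO"] = {
            "accuracy": float(np.mean(site_accs)),
            "precision": float(np.mean(site_precs)),
            "f1": float(np.mean(site_f1s)),
            "n": int(sum(report[t.site_id]["n"] for t in targets)),
            "confusion": None,
        }
    return report, pd.DataFrame(rows)


def nearest_class_mean(
    train_features: np.ndarray,
    train_labels: list[str],
    query_features: np.ndarray,
) -> list[str]:
    """Pooled nearest-class-mean classifier in raw feature space.

    The comparison baseline for the multi-site pooling failure mode: class
    means are computed over all pooled training subjects, ignoring sites.
    """
    train_features = np.atleast_2d(train_features)
    labels = np.asarray(train_labels)
    means = {}
    for label in (NC, ASD):
        mask = labels == label
        if not mask.any():
            raise ValueError(f"pooled training set has no {label} samples")
        means[label] = train_features[mask].mean(axis=0)
    preds = []
    for q in np.atleast_2d(query_features):
        d_nc = float(np.linalg.norm(q - means[NC]))
        d_asd = float(np.linalg.norm(q - means[ASD]))
        preds.append(NC if d_nc < d_asd else ASD)
    return preds
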