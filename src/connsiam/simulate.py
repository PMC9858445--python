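"""Synthetic multi-site ROI BOLD cohorts with a controllable group effect.

The generator emulates the two phenomena the pipeline must cope with:

* a shared latent correlation structure across sites (a low-rank factor
  model), on top of which the ASD group differs by an additive shift
  ``group_effect`` on a fixed, seed-chosen set of connectivity edges;
* site heterogeneity, modelled as additive Gaussian edge offsets
  (SD ``site_effect_sd``) applied identically to both classes within a
  site -- the scanner/protocol shift that moves both groups together.

Each subject's series is T independent draws from a zero-mean multivariate
normal with the (PSD-repaired) target correlation as covariance, plus
independent Gaussian observation noise.  No hemodynamics, temporal
autocorrelation, or motion artifacts are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rng import substream
from .io import ASD, NC, CohortManifest, ManifestRecord, ROITimeSeries, write_manifest, write_timeseries

CLASSES = (NC, ASD)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults are the package's standard synthetic benchmark: 7 sites of
    20 subjects per class at R=20 regions, T=150 timepoints, a group effect
    of 0.4 (correlation scale) on 20 edges, site offsets of SD 0.1, and
    observation noise of SD 0.3 relative to unit-variance signals.
    """

    n_sites: int = 7
    subjects_per_site_per_class: int = 20
    n_regions: int = 20
    n_timepoints: int = 150
    group_effect: float = 0.4
    n_affected_edges: int = 20
    site_effect_sd: float = 0.1
    noise_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.group_effect) >= 1.0:
            raise ValueError("|group_effect| must be < 1")
        max_edges = self.n_regions * (self.n_regions - 1) // 2
        if self.n_affected_edges > max_edges:
            raise ValueError(
                f"n_affected_edges={self.n_affected_edges} exceeds edge count {max_edges}"
            )
        if self.n_sites < 1 or self.n_regions < 2 or self.n_timepoints < 2:
            raise ValueError("need n_sites >= 1, n_regions >= 2, n_timepoints >= 2")

    def site_ids(self) -> list[str]:
        return [f"SITE{i:02d}" for i in range(self.n_sites)]


def _base_correlation(config: SimConfig) -> np.ndarray:
    """Shared latent correlation matrix from a rank-3 factor model."""
    rng = substream(config.rng_seed, "sim:structure")
    loadings = rng.normal(scale=0.6, size=(config.n_regions, 3))
    cov = loadings @ loadings.T + np.diag(rng.uniform(0.5, 1.5, config.n_regions))
    d = 1.0 / np.sqrt(np.diag(cov))
    return cov * np.outer(d, d)


def affected_edges(config: SimConfig) -> list[tuple[int, int]]:
    """The fixed (i < j) edge set carrying the group effect, chosen by seed."""
    rng = substream(config.rng_seed, "sim:edges")
    iu = np.column_stack(np.triu_indices(config.n_regions, k=1))
    picks = rng.choice(len(iu), size=config.n_affected_edges, replace=False)
    return [tuple(iu[p]) for p in sorted(picks)]


def repair_psd(mat: np.ndarray, *, max_rounds: int = 5) -> np.ndarray:
    """Clip negative eigenvalues to 1e-6, reconstruct, re-normalize diagonal.

    Re-normalization can reintroduce tiny negative eigenvalues, so the
    clip/renormalize cycle runs up to ``max_rounds`` times.
    """
    out = mat.copy()
    for _ in range(max_rounds):
        eigvals = np.linalg.eigvalsh(out)
        if eigvals.min() >= 0.0:
            return out
        vals, vecs = np.linalg.eigh(out)
        vals = np.clip(vals, 1e-6, None)
        out = (vecs * vals) @ vecs.T
        d = 1.0 / np.sqrt(np.diag(out))
        out = out * np.outer(d, d)
        out = np.clip((out + out.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(out, 1.0)
    raise ValueError(
        "correlation target not positive semi-definite after repair; "
        "reduce group_effect or site_effect_sd"
    )


def make_target_correlation(
    config: SimConfig,
    site: int,
    klass: str,
    *,
    repair: bool = True,
    site_effect_sd: float | None = None,
) -> np.ndarray:
    """Target correlation matrix for one (site, class) cell.

    base + group shift (ASD only, on the fixed affected-edge set) + per-site
    Gaussian edge offsets shared by both classes.  ``repair=False`` returns
    the raw target before the PSD repair (useful for inspecting the
    construction).
    """
    if klass not in CLASSES:
        raise ValueError(f"klass must be one of {CLASSES}, got {klass!r}")
    sd = config.site_effect_sd if site_effect_sd is None else site_effect_sd
    target = _base_correlation(config)
    if klass == ASD and config.group_effect != 0.0:
        for i, j in affected_edges(config):
            target[i, j] += config.group_effect
            target[j, i] = target[i, j]
    if sd > 0.0:
        rng = substream(config.rng_seed, f"sim:site:{site}")
        iu = np.triu_indices(config.n_regions, k=1)
        offsets = rng.normal(scale=sd, size=len(iu[0]))
        target[iu] += offsets
        target[(iu[1], iu[0])] = target[iu]
    np.clip(target, -0.99, 0.99, out=target)
    np.fill_diagonal(target, 1.0)
    if repair:
        target = repair_psd(target)
    return target


def simulate_subject(
    target: np.ndarray,
    n_timepoints: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """T x R series: multivariate-normal draws from ``target`` plus iid noise."""
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    n_regions = target.shape[0]
    chol = np.linalg.cholesky(target + 1e-9 * np.eye(n_regions))
    latent = rng.standard_normal((n_timepoints, n_regions)) @ chol.T
    if noise_sd > 0.0:
        latent = latent + rng.normal(scale=noise_sd, size=latent.shape)
    return latent


def simulate_cohort_arrays(
    config: SimConfig,
    *,
    site_effect_sd_by_site: dict[str, float] | None = None,
) -> list[ROITimeSeries]:
    """Generate the full cohort in memory (deterministic in the seed).

    ``site_effect_sd_by_site`` overrides the heterogeneity SD for selected
    site ids, e.g. to give held-out target sites a larger shift than the
    training sites.
    """
    if config.subjects_per_site_per_class < 1:
        raise ValueError("empty cohort: subjects_per_site_per_class must be >= 1")
    overrides = site_effect_sd_by_site or {}
    cohort: list[ROITimeSeries] = []
    for site in range(config.n_sites):
        site_id = f"SITE{site:02d}"
        for klass in CLASSES:
            target = make_target_correlation(
                config, site, klass, site_effect_sd=overrides.get(site_id)
            )
            for idx in range(config.subjects_per_site_per_class):
                rng = substream(config.rng_seed, f"sim:subject:{site_id}:{klass}:{idx}")
                data = simulate_subject(target, config.n_timepoints, config.noise_sd, rng)
                cohort.append(
                    ROITimeSeries(
                        subject_id=f"{site_id}_{klass}_{idx:03d}",
                        site_id=site_id,
                        label=klass,
                        data=data,
                    )
                )
    return cohort


def simulate_cohort(
    config: SimConfig,
    out_dir: str | Path,
    *,
    site_effect_sd_by_site: dict[str, float] | None = None,
) -> CohortManifest:
    """Write per-subject time-series CSVs plus a manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort_arrays(
        config, site_effect_sd_by_site=site_effect_sd_by_site
    )
    records = []
    for ts in cohort:
        ts_path = out_dir / f"{ts.subject_id}.csv"
        write_timeseries(ts, ts_path)
        records.append(
            ManifestRecord(
                subject_id=ts.subject_id,
                site_id=ts.site_id,
                label=ts.label,
                path=ts_path,
            )
        )
    manifest = CohortManifest(records=tuple(records))
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
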