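"""Few-shot training against baseline-site class prototypes.

Each training site contributes an independent loss: every meta-training
sample is paired with the baseline site's NC and ASD prototypes (the
class-mean embeddings, recomputed under the current parameters at every
step), as a same-class pair (y = 0) and a different-class pair (y = 1).
The per-site loss is the mean over those 2n pairs, and the total objective
is the plain sum over the K training sites -- summing rather than averaging
keeps each site's contribution explicit and discourages overfitting any one
site.

Within each site, 70% of subjects (stratified by class) form the
meta-training set used for gradient updates; the remaining 30% form the
meta-test set, which is only ever scored, never differentiated through.

Gradients are derived by hand: the loss chain is
sigmoid'(u) = out(1-out), d||e-p||_1/de = sign(e-p), and the prototype,
being a class mean of baseline embeddings, routes its gradient back to every
baseline sample's encoder pass divided by the class count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .io import ASD, NC, RunConfig
from .model import EncoderSpec, SiameseNet, config_hash, l1_distance, pair_loss, similarity_output
from .io import config_to_dict


@dataclass(frozen=True)
class SiteDataset:
    """Labelled feature collection for one imaging site."""

    site_id: str
    features: np.ndarray
    labels: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        feats = np.atleast_2d(np.asarray(self.features, dtype=float))
        if feats.shape[0] != len(self.labels) or feats.shape[0] != len(self.subject_ids):
            raise ValueError("features, labels and subject_ids must align")
        object.__setattr__(self, "features", feats)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    def class_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == label], dtype=int)

    def class_count(self, label: str) -> int:
        return len(self.class_indices(label))

    def subset(self, indices: np.ndarray) -> "SiteDataset":
        indices = np.asarray(indices, dtype=int)
        return SiteDataset(
            site_id=self.site_id,
            features=self.features[indices],
            labels=tuple(self.labels[i] for i in indices),
            subject_ids=tuple(self.subject_ids[i] for i in indices),
        )


def sites_from_features(frame: pd.DataFrame) -> dict[str, SiteDataset]:
    """Split a feature table (subject_id,site_id,label,f1..fP) by site."""
    feature_cols = [c for c in frame.columns if c.startswith("f")]
    out = {}
    for site_id, group in frame.groupby("site_id", sort=True):
        out[str(site_id)] = SiteDataset(
            site_id=str(site_id),
            features=group[feature_cols].to_numpy(dtype=float),
            labels=tuple(group["label"]),
            subject_ids=tuple(group["subject_id"]),
        )
    return out


@dataclass(frozen=True)
class MetaSplit:
    meta_train: SiteDataset
    meta_test: SiteDataset


def split_meta(site: SiteDataset, fraction: float, rng: np.random.Generator) -> MetaSplit:
    """Stratified within-site split; round(fraction * n_class) to meta-train,
    remainder to meta-test."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if site.n_samples == 0:
        raise ValueError(f"site {site.site_id} is empty")
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in (NC, ASD):
        idx = site.class_indices(label)
        if len(idx) == 0:
            continue
        if len(idx) < 2:
            raise ValueError(
                f"site {site.site_id}: class {label} has fewer than 2 samples, "
                "cannot stratify"
            )
        n_train = int(np.floor(fraction * len(idx) + 0.5))
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return MetaSplit(
        meta_train=site.subset(np.sort(train_idx)),
        meta_test=site.subset(np.sort(test_idx)),
    )


@dataclass(frozen=True)
class PrototypePair:
    """Class-mean embeddings of the baseline site under specific parameters."""

    proto_nc: np.ndarray
    proto_asd: np.ndarray
    source_site: str
    model_version: int


def compute_prototypes(model: SiameseNet, baseline: SiteDataset) -> PrototypePair:
    nc_idx = baseline.class_indices(NC)
    asd_idx = baseline.class_indices(ASD)
    if len(nc_idx) == 0 or len(asd_idx) == 0:
        missing = NC if len(nc_idx) == 0 else ASD
        raise ValueError(f"baseline site {baseline.site_id} has no {missing} samples")
    emb = model.embed_batch(baseline.features)
    return PrototypePair(
        proto_nc=emb[nc_idx].mean(axis=0),
        proto_asd=emb[asd_idx].mean(axis=0),
        source_site=baseline.site_id,
        model_version=model.version,
    )


def _check_fresh(model: SiameseNet, protos: PrototypePair) -> None:
    if protos.model_version != model.version:
        raise ValueError(
            "stale prototypes: computed under model version "
            f"{protos.model_version}, current is {model.version}"
        )


def site_loss(
    model: SiameseNet,
    meta_train: SiteDataset,
    protos: PrototypePair,
    *,
    raw_distance: bool = False,
) -> float:
    """Mean pair loss of a site's meta-training samples against the prototypes.

    Each sample forms two pairs: with its own class prototype (y = 0) and
    with the other class prototype (y = 1).
    """
    _check_fresh(model, protos)
    if meta_train.n_samples == 0:
        raise ValueError(f"site {meta_train.site_id}: empty meta-training set")
    emb = model.embed_batch(meta_train.features)
    total = 0.0
    for row, label in zip(emb, meta_train.labels):
        own = protos.proto_nc if label == NC else protos.proto_asd
        other = protos.proto_asd if label == NC else protos.proto_nc
        for proto, y in ((own, 0), (other, 1)):
            dist = l1_distance(row, proto)
            if raw_distance:
                total += 0.5 * (dist - y) ** 2
            else:
                out = similarity_output(
                    dist, affine_a=model.affine_a, affine_b=model.affine_b
                )
                total += pair_loss(out, y)
    return total / (2 * meta_train.n_samples)


def total_loss(per_site: list[float]) -> float:
    """Plain unweighted sum of the per-site losses."""
    if len(per_site) == 0:
        raise ValueError("no per-site losses")
    return float(np.sum(per_site))


@dataclass(frozen=True)
class LossReport:
    step: int
    per_site: dict[str, float]
    total: float
    meta_test_accuracy: dict[str, float] | None = None


class Adam:
    """Standard Adam updates; state is allocated lazily on the first step."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> list[np.ndarray]:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            out.append(p - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))
        return out


class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> list[np.ndarray]:
        return [p - self.lr * g for p, g in zip(params, grads)]


def _losses_and_grads(
    model: SiameseNet,
    site_sets: list[SiteDataset],
    baseline: SiteDataset,
    *,
    raw_distance: bool = False,
    reconstruction_weight: float = 0.0,
) -> tuple[dict[str, float], float, list[np.ndarray]]:
    """One full-batch forward/backward pass.

    Returns per-site losses, the total loss, and gradients aligned with
    ``model.params``.  Prototypes are recomputed inside the pass (they are
    part of the computation graph, so gradient flows through the baseline
    branch of the twin network as well).
    """
    a_aff, b_aff = model.affine_a, model.affine_b
    emb_b, cache_b = model.forward(baseline.features)
    nc_idx = baseline.class_indices(NC)
    asd_idx = baseline.class_indices(ASD)
    if len(nc_idx) == 0 or len(asd_idx) == 0:
        raise ValueError(f"baseline site {baseline.site_id} is missing a class")
    p_nc = emb_b[nc_idx].mean(axis=0)
    p_asd = emb_b[asd_idx].mean(axis=0)

    g_enc_w = [np.zeros_like(w) for w in model.ae_encoder.weights]
    g_enc_b = [np.zeros_like(b) for b in model.ae_encoder.biases]
    g_head_w = [np.zeros_like(w) for w in model.head.weights]
    g_head_b = [np.zeros_like(b) for b in model.head.biases]
    g_dec_w = g_dec_b = None
    if model.decoder is not None:
        g_dec_w = [np.zeros_like(w) for w in model.decoder.weights]
        g_dec_b = [np.zeros_like(b) for b in model.decoder.biases]
    g_affine = np.zeros(2)
    g_p_nc = np.zeros_like(p_nc)
    g_p_asd = np.zeros_like(p_asd)

    def backprop_batch(cache: dict, g_emb: np.ndarray) -> float:
        """Backprop one forwarded batch; returns its reconstruction loss."""
        recon_loss = 0.0
        gw_h, gb_h, g_bot = model.head.backward(cache["head"], g_emb)
        for acc, g in zip(g_head_w, gw_h):
            acc += g
        for acc, g in zip(g_head_b, gb_h):
            acc += g
        if model.decoder is not None and reconstruction_weight > 0.0:
            recon, dec_cache = model.reconstruct(cache)
            x = cache["x"]
            recon_loss = reconstruction_weight * 0.5 * float(np.mean((recon - x) ** 2))
            g_recon = reconstruction_weight * (recon - x) / recon.size
            gw_d, gb_d, g_bot_dec = model.decoder.backward(dec_cache, g_recon)
            for acc, g in zip(g_dec_w, gw_d):
                acc += g
            for acc, g in zip(g_dec_b, gb_d):
                acc += g
            g_bot = g_bot + g_bot_dec
        gw_e, gb_e, _ = model.ae_encoder.backward(cache["enc"], g_bot)
        for acc, g in zip(g_enc_w, gw_e):
            acc += g
        for acc, g in zip(g_enc_b, gb_e):
            acc += g
        return recon_loss

    per_site: dict[str, float] = {}
    recon_total = 0.0
    for site in site_sets:
        if site.n_samples == 0:
            raise ValueError(f"site {site.site_id}: empty meta-training set")
        emb, cache = model.forward(site.features)
        n = site.n_samples
        is_nc = np.array([l == NC for l in site.labels])
        own = np.where(is_nc[:, None], p_nc, p_asd)
        other = np.where(is_nc[:, None], p_asd, p_nc)
        site_total = 0.0
        g_emb = np.zeros_like(emb)
        for proto, y in ((own, 0.0), (other, 1.0)):
            diff = emb - proto
            dist = np.abs(diff).sum(axis=1)
            sign = np.sign(diff)
            if raw_distance:
                site_total += float(np.sum(0.5 * (dist - y) ** 2))
                g_dist = (dist - y) / (2 * n)
            else:
                u = a_aff * dist + b_aff
                out = 1.0 / (1.0 + np.exp(-u))
                site_total += float(np.sum(0.5 * (out - y) ** 2))
                g_u = (out - y) / (2 * n) * out * (1.0 - out)
                g_affine[0] += float(np.sum(g_u * dist))
                g_affine[1] += float(np.sum(g_u))
                g_dist = g_u * a_aff
            g_pair = g_dist[:, None] * sign
            g_emb += g_pair
            g_proto = -g_pair
            if y == 0.0:
                g_p_nc += g_proto[is_nc].sum(axis=0)
                g_p_asd += g_proto[~is_nc].sum(axis=0)
            else:
                g_p_asd += g_proto[is_nc].sum(axis=0)
                g_p_nc += g_proto[~is_nc].sum(axis=0)
        per_site[site.site_id] = site_total / (2 * n)
        recon_total += backprop_batch(cache, g_emb)

    # route prototype gradients back through the baseline branch
    g_emb_b = np.zeros_like(emb_b)
    g_emb_b[nc_idx] = g_p_nc / len(nc_idx)
    g_emb_b[asd_idx] = g_p_asd / len(asd_idx)
    recon_total += backprop_batch(cache_b, g_emb_b)

    grads = [*g_enc_w, *g_enc_b, *g_head_w, *g_head_b]
    if model.decoder is not None:
        grads.extend([*g_dec_w, *g_dec_b])
    if model.spec.affine_head:
        grads.append(g_affine)
    total = total_loss(list(per_site.values())) + recon_total
    return per_site, total, grads


def _prototype_predictions(
    model: SiameseNet, dataset: SiteDataset, protos: PrototypePair
) -> list[str]:
    """Argmin-output classification: NC iff output vs the NC prototype is the
    smaller of the two; exact ties go to ASD."""
    _check_fresh(model, protos)
    emb = model.embed_batch(dataset.features)
    d_nc = np.abs(emb - protos.proto_nc).sum(axis=1)
    d_asd = np.abs(emb - protos.proto_asd).sum(axis=1)
    return [NC if dn < da else ASD for dn, da in zip(d_nc, d_asd)]


def make_model(config: RunConfig, input_dim: int) -> SiameseNet:
    spec = EncoderSpec(
        input_dim=input_dim,
        encoder_widths=tuple(config.encoder_widths),
        head_widths=tuple(config.head_widths),
        embedding_dim=config.embedding_dim,
        activation=config.activation,
        affine_head=config.affine_head,
    )
    return SiameseNet(spec, reconstruction=config.reconstruction_weight > 0.0)


def make_optimizer(config: RunConfig):
    if config.optimizer == "adam":
        return Adam(config.learning_rate)
    if config.optimizer == "sgd":
        return SGD(config.learning_rate)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def train(
    config: RunConfig,
    sites: list[SiteDataset],
    baseline: SiteDataset,
    *,
    eval_interval: int = 50,
) -> tuple[SiameseNet, list[LossReport], dict[str, MetaSplit]]:
    """Train the similarity model on K training sites against the baseline.

    Returns the trained model, the per-step loss history, and the per-site
    meta splits (meta-test portions are scored during training but never
    used for gradient updates).
    """
    if not sites:
        raise ValueError("need at least one training site")
    if any(s.site_id == baseline.site_id for s in sites):
        raise ValueError(
            f"baseline site {baseline.site_id} must not be among the training sites"
        )
    splits = {
        s.site_id: split_meta(
            s,
            config.meta_train_fraction,
            substream(config.rng_seed, f"split:{s.site_id}"),
        )
        for s in sites
    }
    meta_trains = [splits[s.site_id].meta_train for s in sites]

    input_dim = baseline.features.shape[1]
    model = make_model(config, input_dim)
    train_stack = np.vstack([m.features for m in meta_trains] + [baseline.features])
    model.fit_scaler(train_stack)
    model.init_params(substream(config.rng_seed, "init"))
    optimizer = make_optimizer(config)

    history: list[LossReport] = []
    for step in range(config.n_iterations):
        per_site, total, grads = _losses_and_grads(
            model,
            meta_trains,
            baseline,
            raw_distance=config.loss_on_raw_distance,
            reconstruction_weight=config.reconstruction_weight,
        )
        if not np.isfinite(total):
            raise FloatingPointError(
                f"training diverged at step {step}: total loss {total!r}"
            )
        meta_acc = None
        if eval_interval and (step % eval_interval == 0 or step == config.n_iterations - 1):
            protos = compute_prototypes(model, baseline)
            meta_acc = {}
            for s in sites:
                mt = splits[s.site_id].meta_test
                if mt.n_samples:
                    preds = _prototype_predictions(model, mt, protos)
                    meta_acc[s.site_id] = float(
                        np.mean([p == t for p, t in zip(preds, mt.labels)])
                    )
        history.append(
            LossReport(step=step, per_site=per_site, total=total, meta_test_accuracy=meta_acc)
        )
        model.set_params(optimizer.step(model.params, grads))
    return model, history, splits


def run_config_hash(config: RunConfig) -> str:
    return config_hash(config_to_dict(config))
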