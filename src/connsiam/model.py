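"""The twin-encoder similarity model.

A Siamese network is two copies of the same encoder applied to the two
members of a pair; sharing parameters is an invariant, not an option, so the
implementation keeps a single encoder and simply applies it twice.  The
encoder is an autoencoder-style MLP (encoder half + fully connected head)
producing an embedding; pair similarity is scored as

    dist(e1, e2) = ||e1 - e2||_1,      out = sigmoid(dist),

and trained with the squared-error pair loss  L = 1/2 (out - y)^2, where
y = 0 for a same-category pair and y = 1 otherwise.

Note on the sigmoid range: over nonnegative distances sigmoid(d) spans
[0.5, 1), so the y = 0 target is unreachable in the literal formulation.
Training still drives same-class distances toward 0 (output toward 0.5) and
classification uses the argmin of the output, so the offset is harmless.  An
optional affine head sigmoid(a*d + b) with learnable a, b restores the full
(0, 1) range.

Everything is plain numpy with hand-derived reverse-mode gradients; the
networks involved are small MLPs and need no framework.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_ACTIVATIONS = ("relu", "tanh")


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of the shared encoder.

    ``encoder_widths`` is the autoencoder's encoder half; ``head_widths``
    the fully connected layers between the bottleneck and the embedding.
    """

    input_dim: int
    encoder_widths: tuple[int, ...] = (512, 128)
    head_widths: tuple[int, ...] = (64,)
    embedding_dim: int = 64
    activation: str = "relu"
    affine_head: bool = False

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        widths = (*self.encoder_widths, *self.head_widths, self.embedding_dim)
        if any(w < 1 for w in widths):
            raise ValueError("all layer widths must be >= 1")
        if not self.encoder_widths:
            raise ValueError("encoder_widths must contain at least one layer")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "encoder_widths": list(self.encoder_widths),
            "head_widths": list(self.head_widths),
            "embedding_dim": self.embedding_dim,
            "activation": self.activation,
            "affine_head": self.affine_head,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "EncoderSpec":
        return cls(
            input_dim=int(raw["input_dim"]),
            encoder_widths=tuple(raw["encoder_widths"]),
            head_widths=tuple(raw["head_widths"]),
            embedding_dim=int(raw["embedding_dim"]),
            activation=raw["activation"],
            affine_head=bool(raw["affine_head"]),
        )


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _act_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    return (z > 0).astype(float) if kind == "relu" else 1.0 - a * a


class _MLP:
    """Dense stack with activation on every layer except (optionally) the last."""

    def __init__(self, widths: list[int], activation: str, final_activation: bool):
        self.widths = widths
        self.activation = activation
        self.final_activation = final_activation
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []

    def init(self, rng: np.random.Generator, *, output_scale: float = 1.0) -> None:
        self.weights, self.biases = [], []
        n_layers = len(self.widths) - 1
        for i in range(n_layers):
            fan_in = self.widths[i]
            limit = np.sqrt(1.0 / fan_in)
            w = rng.uniform(-limit, limit, size=(fan_in, self.widths[i + 1]))
            if i == n_layers - 1:
                w = w * output_scale
            self.weights.append(w)
            self.biases.append(np.zeros(self.widths[i + 1]))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        acts = [x]
        zs = []
        a = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            zs.append(z)
            if i < n_layers - 1 or self.final_activation:
                a = _act(z, self.activation)
            else:
                a = z
            acts.append(a)
        return a, {"acts": acts, "zs": zs}

    def backward(
        self, cache: dict, grad_out: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Return (weight grads, bias grads, gradient w.r.t. the input)."""
        acts, zs = cache["acts"], cache["zs"]
        n_layers = len(self.weights)
        gw = [np.zeros_like(w) for w in self.weights]
        gb = [np.zeros_like(b) for b in self.biases]
        g = grad_out
        for i in range(n_layers - 1, -1, -1):
            if i < n_layers - 1 or self.final_activation:
                g = g * _act_grad(zs[i], acts[i + 1], self.activation)
            gw[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        return gw, gb, g

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    @property
    def n_layers(self) -> int:
        return len(self.widths) - 1

    def set_params(self, flat: list[np.ndarray]) -> None:
        n = self.n_layers
        if len(flat) != 2 * n:
            raise ValueError(f"expected {2 * n} parameter arrays, got {len(flat)}")
        self.weights = [np.asarray(p, dtype=float).copy() for p in flat[:n]]
        self.biases = [np.asarray(p, dtype=float).copy() for p in flat[n:]]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (self.widths[i], self.widths[i + 1]) or b.shape != (self.widths[i + 1],):
                raise ValueError(f"parameter shape mismatch at layer {i}")


class SiameseNet:
    """Shared-parameter encoder with L1/sigmoid similarity head.

    ``version`` is an opaque token bumped on every parameter update; class
    prototypes record the version they were computed under so that stale
    prototypes are rejected rather than silently reused.
    """

    def __init__(self, spec: EncoderSpec, *, reconstruction: bool = False):
        self.spec = spec
        self.reconstruction = reconstruction
        act = spec.activation
        # autoencoder encoder half (activation on its bottleneck output)
        self.ae_encoder = _MLP([spec.input_dim, *spec.encoder_widths], act, True)
        # fully connected head down to the (linear) embedding
        self.head = _MLP(
            [spec.encoder_widths[-1], *spec.head_widths, spec.embedding_dim], act, False
        )
        self.decoder: _MLP | None = None
        if reconstruction:
            dec_widths = [
                *reversed(spec.encoder_widths),
                spec.input_dim,
            ]
            self.decoder = _MLP(dec_widths, act, False)
        self.affine_a = 1.0
        self.affine_b = 0.0
        self.scaler_mean: np.ndarray | None = None
        self.scaler_std: np.ndarray | None = None
        self.version = 0

    # -- lifecycle ---------------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> None:
        # The final embedding layer starts small so that initial pair
        # distances fall in the responsive region of the sigmoid.
        self.ae_encoder.init(rng)
        self.head.init(rng, output_scale=0.1)
        if self.decoder is not None:
            self.decoder.init(rng)
        if self.spec.affine_head:
            self.affine_a = 1.0
            self.affine_b = 0.0
        self.version += 1

    def fit_scaler(self, features: np.ndarray) -> None:
        """Per-feature z-scoring statistics; fit on training-site data only."""
        mean = features.mean(axis=0)
        std = features.std(axis=0)
        self.scaler_mean = mean
        self.scaler_std = np.where(std < 1e-8, 1.0, std)
        self.version += 1

    def standardize(self, features: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None or self.scaler_std is None:
            return np.asarray(features, dtype=float)
        return (np.asarray(features, dtype=float) - self.scaler_mean) / self.scaler_std

    # -- forward -----------------------------------------------------------
    def forward(self, features: np.ndarray) -> tuple[np.ndarray, dict]:
        """Embeddings plus caches for backprop; input is raw feature rows."""
        x = np.atleast_2d(self.standardize(features))
        if x.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"feature dimension {x.shape[1]} != input_dim {self.spec.input_dim}"
            )
        bottleneck, enc_cache = self.ae_encoder.forward(x)
        emb, head_cache = self.head.forward(bottleneck)
        return emb, {"x": x, "enc": enc_cache, "head": head_cache}

    def embed_batch(self, features: np.ndarray) -> np.ndarray:
        emb, _ = self.forward(features)
        return emb

    def embed(self, feature_vector: np.ndarray) -> np.ndarray:
        """Embed one feature vector (either branch of the twin network)."""
        return self.embed_batch(np.atleast_2d(feature_vector))[0]

    def reconstruct(self, cache: dict) -> tuple[np.ndarray, dict]:
        if self.decoder is None:
            raise ValueError("reconstruction decoder not enabled")
        bottleneck = cache["enc"]["acts"][-1]
        return self.decoder.forward(bottleneck)

    # -- parameters --------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out = [*self.ae_encoder.params, *self.head.params]
        if self.decoder is not None:
            out.extend(self.decoder.params)
        if self.spec.affine_head:
            out.append(np.array([self.affine_a, self.affine_b]))
        return out

    def set_params(self, flat: list[np.ndarray]) -> None:
        n_enc = 2 * self.ae_encoder.n_layers
        n_head = 2 * self.head.n_layers
        self.ae_encoder.set_params(flat[:n_enc])
        self.head.set_params(flat[n_enc : n_enc + n_head])
        pos = n_enc + n_head
        if self.decoder is not None:
            n_dec = 2 * self.decoder.n_layers
            self.decoder.set_params(flat[pos : pos + n_dec])
            pos += n_dec
        if self.spec.affine_head:
            self.affine_a = float(flat[pos][0])
            self.affine_b = float(flat[pos][1])
        self.version += 1

    def copy(self) -> "SiameseNet":
        clone = SiameseNet(self.spec, reconstruction=self.reconstruction)
        clone.set_params(self.params)
        if self.scaler_mean is not None:
            clone.scaler_mean = self.scaler_mean.copy()
            clone.scaler_std = self.scaler_std.copy()
        clone.version = self.version
        return clone

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path, *, config_hash: str = "") -> None:
        """Single-file checkpoint: spec, parameters, scaler stats, hash."""
        path = Path(path)
        meta = {
            "format_version": 1,
            "spec": self.spec.to_dict(),
            "reconstruction": self.reconstruction,
            "config_hash": config_hash,
            "version": self.version,
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.params)}
        if self.scaler_mean is not None:
            arrays["scaler_mean"] = self.scaler_mean
            arrays["scaler_std"] = self.scaler_std
        np.savez(path, meta=json.dumps(meta, sort_keys=True), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SiameseNet":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            spec = EncoderSpec.from_dict(meta["spec"])
            model = cls(spec, reconstruction=meta["reconstruction"])
            n_params = len([k for k in data.files if k.startswith("param_")])
            model.set_params([data[f"param_{i}"] for i in range(n_params)])
            if "scaler_mean" in data.files:
                model.scaler_mean = data["scaler_mean"]
                model.scaler_std = data["scaler_std"]
            model.version = int(meta["version"])
        return model


# -- functional similarity primitives --------------------------------------

def l1_distance(e1: np.ndarray, e2: np.ndarray) -> float:
    """Manhattan distance between two embeddings."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError(f"embedding shapes differ: {e1.shape} vs {e2.shape}")
    return float(np.abs(e1 - e2).sum())


def similarity_output(
    dist: float, *, affine_a: float = 1.0, affine_b: float = 0.0
) -> float:
    """Sigmoid-mapped distance in (0, 1); monotone increasing in the distance,
    so a LOWER output means a MORE similar pair."""
    if dist < 0:
        raise ValueError("distance must be nonnegative")
    return float(1.0 / (1.0 + np.exp(-(affine_a * dist + affine_b))))


def pair_loss(output: float, y: int) -> float:
    """Squared-error pair loss 1/2 (output - y)^2 with y in {0, 1}."""
    if y not in (0, 1):
        raise ValueError(f"pair label must be 0 or 1, got {y!r}")
    return 0.5 * (output - y) ** 2


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
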