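"""The usage-prediction network family.

A model is a per-site base network (shared across all sites of a gene)
followed by an interaction layer over the ordered site list:

* base networks — ``feature_net`` (fully connected layers over
  hand-engineered features), ``single_conv`` (one convolution block:
  1-D convolution, ReLU, max pooling), ``multi_conv`` (two convolution
  blocks) — each maps one site to a fixed-length feature vector;
* interaction — ``bilstm`` (a bidirectional LSTM whose time steps are
  the sites in transcription order; per-step outputs of both directions
  are concatenated and mapped to a scalar logit), ``dense_only`` (the
  same scalar head without recurrence), or ``none_pairwise`` (raw
  per-site scores for comparison-based training, no joint
  normalization).

For the first two interactions the logits pass through a joint softmax,
so predicted usages of a gene's sites always sum to one, for any number
of sites; no padding is ever used. Site usage is mutually exclusive and
competitive, which is exactly what the joint softmax over an ordered,
variable-length site list encodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import DataError, one_hot

BASE_NETS = ("feature_net", "single_conv", "multi_conv")
INTERACTIONS = ("bilstm", "dense_only", "none_pairwise")

STATE_FORMAT_VERSION = 1
LOG_EPS = 1e-12


@dataclass
class ModelSpec:
    base_net: str = "multi_conv"
    interaction: str = "bilstm"
    W: int = 455
    n_features: int = 0            # feature_net input width (set from the motif table)
    conv1_filters: int = 40
    conv1_width: int = 12
    pool_width: int = 3
    pool_stride: int = 3
    conv2_filters: int = 40
    conv2_width: int = 10
    base_out_dim: int = 64
    lstm_hidden: int = 64          # per direction
    fc_sizes: tuple = (64,)
    dropout_p: float = 0.2
    weight_decay: float = 1e-4

    def __post_init__(self):
        if self.base_net not in BASE_NETS:
            raise DataError(f"unknown base_net {self.base_net!r}")
        if self.interaction not in INTERACTIONS:
            raise DataError(f"unknown interaction {self.interaction!r}")
        if not 0 <= self.dropout_p < 1:
            raise DataError("dropout_p must be in [0, 1)")
        self.fc_sizes = tuple(self.fc_sizes)

    # geometry ---------------------------------------------------------

    def conv1_positions(self) -> int:
        return self.W - self.conv1_width + 1

    def pooled1_positions(self) -> int:
        return (self.conv1_positions() - self.pool_width) // self.pool_stride + 1

    def conv2_positions(self) -> int:
        return self.pooled1_positions() - self.conv2_width + 1

    def pooled2_positions(self) -> int:
        return (self.conv2_positions() - self.pool_width) // self.pool_stride + 1

    def flatten_dim(self) -> int:
        if self.base_net == "single_conv":
            return self.pooled1_positions() * self.conv1_filters
        if self.base_net == "multi_conv":
            return self.pooled2_positions() * self.conv2_filters
        return self.n_features

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        d["fc_sizes"] = tuple(d["fc_sizes"])
        return cls(**d)


def receptive_field(spec: ModelSpec) -> int:
    """Input-window span (nt) seen by one layer-2 convolution neuron.

    A layer-2 neuron reads `conv2_width` pooled positions; consecutive
    pooled positions are `pool_stride` apart and each covers
    `pool_width + conv1_width - 1` input bases.
    """
    if spec.base_net != "multi_conv":
        raise DataError("receptive_field is defined for multi_conv only")
    return ((spec.conv2_width - 1) * spec.pool_stride
            + spec.pool_width + spec.conv1_width - 1)


def layer2_field_start(spec: ModelSpec, position: int) -> int:
    """First input index of the receptive field of layer-2 position `position`."""
    return position * spec.pool_stride


# ---------------------------------------------------------------------
# parameters


@dataclass
class ModelState:
    params: dict                      # name -> Tensor (requires_grad=True)
    spec_json: str = ""
    format_version: int = STATE_FORMAT_VERSION
    aux: dict = field(default_factory=dict)   # e.g., z-score stats arrays

    def copy_arrays(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_arrays(self, arrays: dict):
        for k, v in self.params.items():
            v.data = arrays[k].copy()

    def save(self, path):
        meta = {"format_version": self.format_version, "spec": self.spec_json,
                "aux_keys": sorted(self.aux)}
        arrays = {f"param::{k}": v.data for k, v in self.params.items()}
        arrays.update({f"aux::{k}": np.asarray(v) for k, v in self.aux.items()})
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> tuple:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta["format_version"] != STATE_FORMAT_VERSION:
                raise DataError(f"unsupported state format {meta['format_version']}")
            params = {k[len("param::"):]: Tensor(z[k], requires_grad=True)
                      for k in z.files if k.startswith("param::")}
            aux = {k[len("aux::"):]: z[k] for k in z.files if k.startswith("aux::")}
        spec = ModelSpec.from_json(meta["spec"])
        return spec, cls(params, spec_json=meta["spec"], aux=aux)


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_state(spec: ModelSpec, rng: np.random.Generator) -> ModelState:
    p = {}

    def add_fc(prefix, dims):
        for i, (a, b) in enumerate(zip(dims, dims[1:])):
            p[f"{prefix}{i}_W"] = _glorot(rng, (a, b))
            p[f"{prefix}{i}_b"] = np.zeros(b)

    if spec.base_net in ("single_conv", "multi_conv"):
        p["conv1_W"] = _glorot(rng, (4 * spec.conv1_width, spec.conv1_filters))
        p["conv1_b"] = np.zeros(spec.conv1_filters)
        if spec.base_net == "multi_conv":
            p["conv2_W"] = _glorot(rng, (spec.conv1_filters * spec.conv2_width,
                                         spec.conv2_filters))
            p["conv2_b"] = np.zeros(spec.conv2_filters)
    else:
        if spec.n_features <= 0:
            raise DataError("feature_net requires spec.n_features > 0")
    add_fc("base_fc", (spec.flatten_dim(),) + spec.fc_sizes + (spec.base_out_dim,))

    if spec.interaction == "bilstm":
        D, H = spec.base_out_dim, spec.lstm_hidden
        for d in ("fwd", "bwd"):
            p[f"lstm_{d}_Wih"] = _glorot(rng, (D, 4 * H))
            p[f"lstm_{d}_Whh"] = _glorot(rng, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias
            p[f"lstm_{d}_b"] = b
        p["head_W"] = _glorot(rng, (2 * H, 1))
    else:
        p["head_W"] = _glorot(rng, (spec.base_out_dim, 1))
    p["head_b"] = np.zeros(1)

    params = {k: Tensor(v, requires_grad=True) for k, v in p.items()}
    return ModelState(params, spec_json=spec.to_json())


def decayed_param_names(state: ModelState) -> list:
    """Convolution and fully-connected weight matrices (weight decay applies
    to these; biases and LSTM matrices are exempt)."""
    return [k for k in state.params
            if k.endswith("_W") and not k.startswith("lstm_")]


# ---------------------------------------------------------------------
# forward passes


def _im2col(x: np.ndarray, width: int) -> np.ndarray:
    """(B, P, C) -> (B, P-width+1, width*C) sliding windows, contiguous."""
    B, P, C = x.shape
    v = np.lib.stride_tricks.sliding_window_view(x, width, axis=1)  # (B, P', C, width)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(B, P - width + 1, width * C)


def _conv_block(x: Tensor, W: Tensor, b: Tensor, width: int,
                pool_width: int, pool_stride: int, pool: bool = True) -> Tensor:
    # x is the one-hot input (a constant leaf), so im2col can stay in numpy
    cols = Tensor(_im2col(x.data, width))
    act = ad.relu(ad.matmul(cols, W) + b)
    return ad.maxpool1d(act, pool_width, pool_stride) if pool else act


def encode_windows(spec: ModelSpec, windows: Sequence[str],
                   features: np.ndarray | None = None) -> np.ndarray:
    """One-hot stack (B, W, 4) for conv nets, feature matrix for feature_net."""
    if spec.base_net == "feature_net":
        if features is None:
            raise DataError("feature_net input requires a feature matrix")
        return np.asarray(features, dtype=float)
    for w in windows:
        if len(w) != spec.W:
            raise DataError(f"window length {len(w)} != spec.W {spec.W}")
    return np.stack([one_hot(w) for w in windows])


def base_forward(spec: ModelSpec, state: ModelState, encoded: np.ndarray) -> Tensor:
    """Per-site feature vectors: (B, ...) encoded input -> (B, base_out_dim)."""
    p = state.params
    if spec.base_net == "feature_net":
        if encoded.ndim != 2 or encoded.shape[1] != spec.n_features:
            raise DataError("feature_net expects (B, n_features) input")
        h = Tensor(encoded)
    else:
        if encoded.ndim != 3 or encoded.shape[1] != spec.W or encoded.shape[2] != 4:
            raise DataError(f"conv base-net expects (B, {spec.W}, 4) one-hot input")
        x = Tensor(encoded)
        h = _conv_block(x, p["conv1_W"], p["conv1_b"], spec.conv1_width,
                        spec.pool_width, spec.pool_stride)
        if spec.base_net == "multi_conv":
            h = _conv_block_t(h, p, spec)
        B = h.data.shape[0]
        h = ad.reshape(h, (B, -1))
    n_fc = sum(1 for k in p if k.startswith("base_fc") and k.endswith("_W"))
    for i in range(n_fc):
        h = ad.matmul(h, p[f"base_fc{i}_W"]) + p[f"base_fc{i}_b"]
        if i < n_fc - 1:
            h = ad.relu(h)
    return h


def _conv_block_t(h: Tensor, p: dict, spec: ModelSpec) -> Tensor:
    """Second conv block over a differentiable (B, P, F) activation."""
    B, P, F = h.data.shape
    w = spec.conv2_width
    n_out = P - w + 1
    idx = np.arange(n_out)[:, None] + np.arange(w)[None, :]
    cols = ad.getitem(h, (slice(None), idx, slice(None)))       # (B, n_out, w, F)
    cols = ad.reshape(cols, (B, n_out, w * F))
    act = ad.relu(ad.matmul(cols, p["conv2_W"]) + p["conv2_b"])
    return ad.maxpool1d(act, spec.pool_width, spec.pool_stride)


def _lstm_direction(p: dict, prefix: str, steps: list, H: int) -> list:
    """Run one LSTM direction over a list of (B, D) tensors; returns hidden states."""
    B = steps[0].data.shape[0]
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    out = []
    Wih, Whh, b = p[f"{prefix}_Wih"], p[f"{prefix}_Whh"], p[f"{prefix}_b"]
    for x in steps:
        gates = ad.matmul(x, Wih) + ad.matmul(h, Whh) + b
        i = ad.sigmoid(gates[:, 0 * H:1 * H])
        f = ad.sigmoid(gates[:, 1 * H:2 * H])
        g = ad.tanh(gates[:, 2 * H:3 * H])
        o = ad.sigmoid(gates[:, 3 * H:4 * H])
        c = ad.add(ad.mul(f, c), ad.mul(i, g))
        h = ad.mul(o, ad.tanh(c))
        out.append(h)
    return out


def interaction_forward(spec: ModelSpec, state: ModelState, base_vectors: Tensor,
                        dropout_rng: np.random.Generator | None = None) -> Tensor:
    """(B, n, D) per-site vectors -> (B, n) logits (or raw scores).

    Sites must be fed in transcription order. `dropout_rng` enables
    dropout on the BiLSTM outputs (training mode); None disables it.
    """
    B, n, D = base_vectors.data.shape
    if n == 0:
        raise DataError("a gene must have at least one PAS")
    p = state.params
    if spec.interaction == "bilstm":
        H = spec.lstm_hidden
        steps = [base_vectors[:, t, :] for t in range(n)]
        h_f = _lstm_direction(p, "lstm_fwd", steps, H)
        h_b = _lstm_direction(p, "lstm_bwd", steps[::-1], H)[::-1]
        logits = []
        for t in range(n):
            ht = ad.concat([h_f[t], h_b[t]], axis=1)  # (B, 2H)
            if dropout_rng is not None and spec.dropout_p > 0:
                keep = 1.0 - spec.dropout_p
                mask = (dropout_rng.random(ht.data.shape) < keep) / keep
                ht = ad.mul(ht, Tensor(mask))
            logits.append(ad.matmul(ht, p["head_W"]) + p["head_b"])  # (B, 1)
        return ad.concat(logits, axis=1)
    # dense_only / none_pairwise: per-site scalar head, no recurrence
    scores = ad.matmul(base_vectors, p["head_W"]) + p["head_b"]      # (B, n, 1)
    return ad.reshape(scores, (B, n))


@dataclass
class Prediction:
    usage: np.ndarray | None   # sums to 1; None for comparison-trained models
    logits: np.ndarray

    def __post_init__(self):
        if self.usage is not None:
            assert abs(self.usage.sum() - 1.0) < 1e-6


def forward_logits(spec: ModelSpec, state: ModelState, genes_windows: list,
                   features: list | None = None,
                   dropout_rng: np.random.Generator | None = None) -> Tensor:
    """Batched forward for genes sharing one PAS count. Returns (B, n) logits."""
    B = len(genes_windows)
    n = len(genes_windows[0])
    if any(len(w) != n for w in genes_windows):
        raise DataError("forward_logits: all genes in a batch must share the PAS count")
    flat_windows = [w for g in genes_windows for w in g]
    if spec.base_net == "feature_net":
        enc = np.concatenate(features, axis=0)
    else:
        enc = encode_windows(spec, flat_windows)
    base = base_forward(spec, state, enc)                 # (B*n, D)
    base = ad.reshape(base, (B, n, spec.base_out_dim))
    return interaction_forward(spec, state, base, dropout_rng=dropout_rng)


def predict_windows(spec: ModelSpec, state: ModelState, windows: list,
                    features: np.ndarray | None = None) -> Prediction:
    """Inference for a single gene given its ordered site windows."""
    with ad.no_grad():
        logits = forward_logits(spec, state, [list(windows)],
                                features=[features] if features is not None else None)
    z = logits.data[0]
    if spec.interaction == "none_pairwise":
        return Prediction(usage=None, logits=z)
    return Prediction(usage=ad.softmax(z), logits=z)


# ---------------------------------------------------------------------
# losses


def gene_loss(pred_usage: np.ndarray, truth: np.ndarray) -> float:
    """Cross entropy -sum(t * ln p) between predicted and true usage."""
    p = np.asarray(pred_usage, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise DataError("gene_loss: shape mismatch")
    return float(-(t * np.log(np.clip(p, LOG_EPS, None))).sum())


def batch_cross_entropy(logits: Tensor, truth: np.ndarray) -> Tensor:
    """Mean over genes of -sum(t * log_softmax(logits)); differentiable."""
    logp = ad.log_softmax(logits, axis=1)
    per_gene = ad.sum_(ad.mul(logp, Tensor(-truth)), axis=1)
    return ad.mean(per_gene)


def pairwise_loss(score_hi: Tensor, score_lo: Tensor) -> Tensor:
    """Logistic comparison loss -ln sigmoid(s_hi - s_lo) (mean over pairs)."""
    diff = ad.add(score_hi, -score_lo)
    # -ln sigmoid(d) = softplus(-d), computed stably
    val = np.log1p(np.exp(-np.abs(diff.data))) + np.maximum(0.0, -diff.data)
    s = 0.5 * (np.tanh(0.5 * diff.data) + 1.0)  # sigmoid(diff)

    def ga(g):
        return -g * (1.0 - s)

    out = ad._result(val, [(diff, ga)])
    return ad.mean(out)


def eligible_pairs(truth: np.ndarray, threshold: float = 0.05) -> list:
    """Within-gene index pairs (hi, lo) with usage difference strictly > threshold."""
    pairs = []
    n = len(truth)
    for i in range(n):
        for j in range(i + 1, n):
            d = truth[i] - truth[j]
            if abs(d) > threshold:
                pairs.append((i, j) if d > 0 else (j, i))
    return pairs
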