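"""Model interpretation: mutation maps, in-silico reporters, filter PFMs.

* A *mutation map* scores every single-nucleotide substitution in one
  site's window by the change it induces in that site's predicted usage,
  holding the gene's other sites fixed — an in-silico saturation
  mutagenesis (3L mutants for a window of length L).
* A *reporter experiment* predicts usage for explicitly edited window
  variants (e.g. the two parental alleles plus swap constructs), the
  computational analogue of a reporter assay.
* *Filter visualization* accumulates, for each convolutional filter, the
  maximally activating subsequence of every dataset window into a
  position frequency matrix (PFM); layer-2 filters use a partial forward
  pass and the receptive field of the maximally activated neuron, which
  is wider than the filter itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import DataError, Gene, one_hot
from .network import (ModelSpec, ModelState, _im2col, layer2_field_start,
                      predict_windows, receptive_field)

_BASES = "ACGT"


@dataclass
class MutationMap:
    gene_id: str
    pas_index: int
    window: str
    deltas: np.ndarray          # 4 x L; rows A,C,G,T; reference entries exactly 0
    missing: np.ndarray         # 4 x L bool; True where entry could not be computed
    original_usage: np.ndarray  # per-site usage of the unedited gene

    @property
    def reference_row_mask(self) -> np.ndarray:
        return np.stack([np.frombuffer(self.window.encode(), dtype="S1") == b.encode()
                         for b in _BASES])

    def to_frame(self):
        import pandas as pd
        rows = []
        for j, ref in enumerate(self.window):
            for i, alt in enumerate(_BASES):
                if alt == ref:
                    continue
                rows.append((j, ref, alt, self.deltas[i, j], bool(self.missing[i, j])))
        return pd.DataFrame(rows, columns=["position", "ref", "alt", "delta", "missing"])


def _model_parts(model):
    """Accept either a fitted estimator or a (spec, state) pair."""
    if hasattr(model, "spec_"):
        return model.spec_, model.state_
    return model


def mutation_map(model, gene: Gene, target_pas: int) -> MutationMap:
    """Saturation mutagenesis of one site's window within its gene context.

    Every mutant is pushed through the full model alongside the gene's
    other (unchanged) site windows; the delta is the mutant's predicted
    usage at the target site minus the original prediction. Substituting
    a base with itself is by convention 0; positions holding N are
    flagged missing.
    """
    spec, state = _model_parts(model)
    idx = [r.pas_index for r in gene.pas_list]
    if target_pas not in idx:
        raise DataError(f"gene {gene.gene_id} has no PAS {target_pas}")
    k = idx.index(target_pas)
    windows = list(gene.windows)
    orig = predict_windows(spec, state, windows)
    L = len(windows[k])
    deltas = np.zeros((4, L))
    missing = np.zeros((4, L), dtype=bool)
    target = windows[k]
    for j, ref in enumerate(target):
        if ref == "N":
            missing[:, j] = True
            continue
        for i, alt in enumerate(_BASES):
            if alt == ref:
                continue
            mutated = windows.copy()
            mutated[k] = target[:j] + alt + target[j + 1:]
            pred = predict_windows(spec, state, mutated)
            deltas[i, j] = pred.usage[k] - orig.usage[k]
    return MutationMap(gene.gene_id, target_pas, target, deltas, missing, orig.usage)


def apply_indel(window: str, offset: int, insertion: str = "",
                deletion: int = 0) -> str:
    """Edit a window at `offset` (relative to the cleavage-site center) and
    re-extract a fixed-width window centered on the cleavage site — as if
    re-extracting from an edited genome. Bases shifted in from beyond the
    original window boundary are unknown and filled with N.
    """
    W = len(window)
    center = (W - 1) // 2
    pos = center + offset
    if not 0 <= pos <= W:
        raise DataError("edit offset outside the window")
    edited = window[:pos] + insertion + window[pos + deletion:]
    # cleavage site stays at the same sequence position unless the edit
    # is strictly upstream of it
    c = center + (len(insertion) - deletion if pos <= center else 0)
    u = (W - 1) // 2
    lo, hi = c - u, c + u + 1
    pad_l = max(0, -lo)
    pad_r = max(0, hi - len(edited))
    out = "N" * pad_l + edited[max(lo, 0):min(hi, len(edited))] + "N" * pad_r
    return out


def reporter_experiment(model, gene: Gene, variants: dict) -> dict:
    """Predict usage for named variants of a gene.

    `variants` maps a variant name to {pas_index: replacement window};
    an empty edit dict reproduces the unedited prediction. All edited
    windows must already have the model's window length (use
    :func:`apply_indel` for insertions/deletions).
    """
    spec, state = _model_parts(model)
    idx = {r.pas_index: i for i, r in enumerate(gene.pas_list)}
    out = {}
    for name, edits in variants.items():
        windows = list(gene.windows)
        for pas_index, seq in edits.items():
            if pas_index not in idx:
                raise DataError(f"gene {gene.gene_id} has no PAS {pas_index}")
            if len(seq) != spec.W:
                raise DataError(f"variant {name!r}: edited window length "
                                f"{len(seq)} != {spec.W} (re-center indels first)")
            windows[idx[pas_index]] = seq
        out[name] = predict_windows(spec, state, windows)
    return out


# ---------------------------------------------------------------------
# convolutional filter visualization


@dataclass
class PFM:
    counts: np.ndarray   # K x 4 integer counts; rows are positions
    n_sequences: int
    layer: int
    filter_index: int

    def consensus(self) -> str:
        return "".join(_BASES[int(i)] for i in self.counts.argmax(axis=1))


def _conv1_activation(spec: ModelSpec, state: ModelState, onehot: np.ndarray):
    cols = _im2col(onehot, spec.conv1_width)
    return np.maximum(cols @ state.params["conv1_W"].data
                      + state.params["conv1_b"].data, 0.0)


def _conv2_activation(spec: ModelSpec, state: ModelState, onehot: np.ndarray):
    a1 = _conv1_activation(spec, state, onehot)
    with ad.no_grad():
        pooled = ad.maxpool1d(Tensor(a1), spec.pool_width, spec.pool_stride).data
    cols = _im2col(pooled, spec.conv2_width)
    return np.maximum(cols @ state.params["conv2_W"].data
                      + state.params["conv2_b"].data, 0.0)


def _accumulate(windows, act, width, start_of, layer, n_filters):
    pfms = []
    for f in range(n_filters):
        counts = np.zeros((width, 4), dtype=np.int64)
        n_used = 0
        # ties: np.argmax takes the lowest position
        best = act[:, :, f].argmax(axis=1)
        for s, w in enumerate(windows):
            lo = start_of(int(best[s]))
            sub = w[lo:lo + width]
            if len(sub) < width or "N" in sub:
                continue  # overhanging or ambiguous subsequence: skip, keep row sums exact
            counts += one_hot(sub).astype(np.int64)
            n_used += 1
        pfms.append(PFM(counts, n_used, layer, f))
    return pfms


def visualize_layer1_filters(model, windows) -> list:
    """One PFM (width = filter width) per layer-1 filter over all windows."""
    spec, state = _model_parts(model)
    if spec.base_net not in ("single_conv", "multi_conv"):
        raise DataError("filter visualization requires a convolutional base net")
    onehot = np.stack([one_hot(w) for w in windows])
    act = _conv1_activation(spec, state, onehot)
    return _accumulate(windows, act, spec.conv1_width, lambda p: p, 1,
                       spec.conv1_filters)


def visualize_layer2_filters(model, windows) -> list:
    """One PFM (width = layer-2 receptive field) per layer-2 filter.

    Activations come from a partial forward pass; the accumulated
    subsequence is the receptive field of the maximally activated neuron.
    """
    spec, state = _model_parts(model)
    if spec.base_net != "multi_conv":
        raise DataError("layer-2 visualization requires multi_conv")
    rf = receptive_field(spec)
    if rf > spec.W:
        raise DataError(f"receptive field {rf} exceeds window length {spec.W}")
    onehot = np.stack([one_hot(w) for w in windows])
    act = _conv2_activation(spec, state, onehot)
    return _accumulate(windows, act, rf,
                       lambda p: layer2_field_start(spec, p), 2,
                       spec.conv2_filters)


# ---------------------------------------------------------------------
# output formats


def write_meme(pfms, path, alphabet: str = "ACGT"):
    """MEME minimal motif format (probabilities from the count matrices)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pfm in pfms:
            name = f"layer{pfm.layer}_filter{pfm.filter_index}"
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pfm.counts.shape[0]} "
                     f"nsites= {pfm.n_sequences}\n")
            denom = max(pfm.n_sequences, 1)
            for row in pfm.counts:
                fh.write(" ".join(f"{v / denom:.6f}" for v in row) + "\n")
            fh.write("\n")


def write_transfac(pfms, path):
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f"ID layer{pfm.layer}_filter{pfm.filter_index}\nBF synthetic\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(pfm.counts, start=1):
                fh.write(f"{i:02d} " + " ".join(f"{int(v):6d}" for v in row)
                         + f"  {pfm.consensus()[i - 1]}\n")
            fh.write("XX\n//\n")


def plot_mutation_map(mmap: MutationMap, path, region: tuple | None = None):
    """Heatmap of the 4 x L delta matrix (blue = usage loss, red = gain)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    deltas = mmap.deltas
    lo, hi = region if region else (0, deltas.shape[1])
    fig, axis = plt.subplots(figsize=(max(6, (hi - lo) / 8), 2.4))
    v = np.nanmax(np.abs(deltas[:, lo:hi])) or 1.0
    im = axis.imshow(deltas[:, lo:hi], cmap="RdBu_r", vmin=-v, vmax=v,
                     aspect="auto", interpolation="nearest")
    axis.set_yticks(range(4), list(_BASES))
    axis.set_xlabel(f"window position ({lo}..{hi})")
    axis.set_title(f"{mmap.gene_id} PAS {mmap.pas_index}: predicted usage change")
    fig.colorbar(im, ax=axis, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pfm(pfm: PFM, path):
    """Positionwise base-frequency heatmap of a PFM."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freq = pfm.counts.T / max(pfm.n_sequences, 1)
    fig, axis = plt.subplots(figsize=(max(4, pfm.counts.shape[0] / 4), 2))
    im = axis.imshow(freq, cmap="viridis", vmin=0, vmax=1, aspect="auto",
                     interpolation="nearest")
    axis.set_yticks(range(4), list(_BASES))
    axis.set_title(f"layer {pfm.layer} filter {pfm.filter_index} "
                   f"({pfm.n_sequences} seqs) {pfm.consensus()}")
    fig.colorbar(im, ax=axis, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
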