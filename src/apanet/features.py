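"""Hand-engineered sequence features for the fully-connected base network.

Features are occurrence counts of named regulatory motifs (IUPAC
patterns, each restricted to a region relative to the cleavage site)
plus global 1- to 4-mer counts, z-score normalized with statistics
estimated on the training split only.

The motif list is data, not code: a default table ships with the
canonical poly(A) signal hexamer variants and the well-known flanking
elements (UGUA upstream, U-rich/GU-rich downstream), and users may
supply their own TSV. Overlapping matches are counted; N never matches
any IUPAC code.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

CATEGORIES = ("PAS_signal", "aux_upstream", "core_upstream",
              "core_downstream", "aux_downstream", "RBP")

#: The 12 most common poly(A) signal hexamer variants plus 6 rarer ones.
PAS_HEXAMERS = [
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AAGAAA", "AATATA",
    "AATACA", "CATAAA", "GATAAA", "AATGAA", "TTTAAA", "ACTAAA",
    "AATAGA", "AATAAT", "AACAAA", "ATTACA", "ATTATA", "AACAAG",
]


@dataclass(frozen=True)
class MotifEntry:
    name: str
    category: str
    pattern: str
    region_start: int  # relative to cleavage site, negative = upstream
    region_end: int    # inclusive

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise DataError(f"unknown motif category {self.category!r}")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise DataError(f"invalid IUPAC code(s) {sorted(bad)} in {self.pattern!r}")


@dataclass
class MotifTable:
    entries: list

    def __len__(self):
        return len(self.entries)

    @classmethod
    def default(cls) -> "MotifTable":
        entries = [MotifEntry(f"PAS_{h}", "PAS_signal", h, -40, -10) for h in PAS_HEXAMERS]
        entries += [
            MotifEntry("UGUA_upstream", "core_upstream", "TGTA", -100, -40),
            MotifEntry("AUE_TATA", "aux_upstream", "TATA", -150, -41),
            MotifEntry("CDE_U_rich", "core_downstream", "TTTT", 5, 45),
            MotifEntry("CDE_GU_rich", "core_downstream", "GTGT", 5, 45),
            MotifEntry("ADE_U_rich", "aux_downstream", "TTTTT", 46, 120),
            MotifEntry("RBP_GGGG", "RBP", "GGGG", -150, 150),
        ]
        return cls(entries)

    @classmethod
    def from_tsv(cls, path) -> "MotifTable":
        df = pd.read_csv(path, sep="\t")
        return cls([MotifEntry(r["name"], r["category"], r["pattern"],
                               int(r["region_start"]), int(r["region_end"]))
                    for _, r in df.iterrows()])

    def to_tsv(self, path):
        pd.DataFrame([e.__dict__ for e in self.entries]).to_csv(path, sep="\t", index=False)


def _iupac_regex(pattern: str) -> re.Pattern:
    # N rows of the window must not match, so character classes never include N
    return re.compile("".join(f"[{IUPAC[c]}]" for c in pattern))


def count_motif(window: str, pattern: str, region: tuple) -> int:
    """Number of (possibly overlapping) match starts of `pattern` in `region`.

    `region` is (start, end), inclusive, relative to the cleavage site at
    the window center; matches must lie entirely within the window.
    """
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise DataError(f"invalid IUPAC code(s) {sorted(bad)}")
    W = len(window)
    center = (W - 1) // 2
    lo = max(0, center + region[0])
    hi = min(W - len(pattern), center + region[1])
    if hi < lo:
        return 0
    rx = _iupac_regex(pattern)
    return sum(1 for i in range(lo, hi + 1) if rx.match(window, i, i + len(pattern)))


_KMER_NAMES = {k: ["".join(p) for p in itertools.product("ACGT", repeat=k)]
               for k in range(1, 5)}


def kmer_counts(window: str, k: int) -> np.ndarray:
    """Counts of all 4^k k-mers (lexicographic ACGT order); k-mers touching N are skipped."""
    if not 1 <= k <= 4:
        raise DataError("k must be in 1..4")
    codes = np.frombuffer(window.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    enc = lut[codes]
    if len(enc) < k:
        return np.zeros(4 ** k, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = (np.where(win < 0, 0, win) * powers).sum(axis=1)
    return np.bincount(idx[valid], minlength=4 ** k).astype(np.int64)


def feature_names(motif_table: MotifTable) -> list:
    names = [e.name for e in motif_table.entries]
    for k in range(1, 5):
        names.extend(f"{k}mer_{m}" for m in _KMER_NAMES[k])
    return names


def featurize(window: str, motif_table: MotifTable) -> np.ndarray:
    """Motif-count block followed by k-mer blocks for k = 1..4."""
    motif = [count_motif(window, e.pattern, (e.region_start, e.region_end))
             for e in motif_table.entries]
    kmers = [kmer_counts(window, k) for k in range(1, 5)]
    return np.concatenate([np.asarray(motif, dtype=float)] + [b.astype(float) for b in kmers])


def featurize_many(windows, motif_table: MotifTable) -> np.ndarray:
    return np.stack([featurize(w, motif_table) for w in windows])


@dataclass
class ZScoreStats:
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if (self.sd < 0).any():
            raise DataError("negative sd")


def fit_zscore(train_matrix: np.ndarray) -> ZScoreStats:
    m = np.asarray(train_matrix, dtype=float)
    return ZScoreStats(m.mean(axis=0), m.std(axis=0))


def apply_zscore(values: np.ndarray, stats: ZScoreStats) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != stats.mean.shape[0]:
        raise DataError(f"feature length {v.shape[-1]} != stats length {stats.mean.shape[0]}")
    # constant features (sd == 0) carry no information -> mapped to 0
    sd = np.where(stats.sd == 0, 1.0, stats.sd)
    out = (v - stats.mean) / sd
    return np.where(stats.sd == 0, 0.0, out)
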