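"""Generator of multi-PAS genes with known competitive usage.

Each gene carries 2-8 sites. A site's latent strength is the sum of a
planted poly(A)-signal hexamer term (canonical AATAAA strongest, then
ATTAAA and TTTAAA, mirroring the known affinity ordering), a positional
advantage for proximal sites (sites transcribed first get first shot at
the cleavage machinery), contributions from auxiliary enhancer/silencer
motifs (a UGUA-like upstream enhancer and a U-rich downstream silencer),
and Gaussian noise standing in for unmodeled trans effects. True usage
is the softmax of the strengths; observed read counts are multinomial.

Crucially the hexamer and auxiliary-motif terms are recomputed from the
*realized* window sequence (`true_score`), so any edit to a window —
allelic substitutions, in-silico mutagenesis — has a well-defined
ground-truth effect, which the interpretation tests score against.

What this emulates: competition among co-transcribed sites driven by
local sequence elements. What it does not: sequencing artifacts,
isoform-length effects, inter-site distances, chromatin or kinetic
context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import softmax
from .data import Dataset, Gene, PASRecord
from Bio.Seq import reverse_complement

DEFAULT_HEXAMER_STRENGTHS = {"AATAAA": 1.0, "ATTAAA": 0.7, "TTTAAA": 0.4, "": 0.0}
DEFAULT_HEXAMER_PROBS = {"AATAAA": 0.45, "ATTAAA": 0.25, "TTTAAA": 0.15, "": 0.15}
DEFAULT_PAS_COUNT_PROBS = {2: 0.35, 3: 0.25, 4: 0.15, 5: 0.10, 6: 0.07, 7: 0.05, 8: 0.03}
#: (pattern, region relative to cleavage site, per-occurrence strength effect)
DEFAULT_AUX_MOTIFS = (("TGTA", (-100, -40), 0.15), ("TTTT", (10, 80), -0.15))


@dataclass
class GeneratorConfig:
    n_genes: int = 500
    pas_count_probs: dict = field(default_factory=lambda: dict(DEFAULT_PAS_COUNT_PROBS))
    W: int = 455
    hexamer_strengths: dict = field(default_factory=lambda: dict(DEFAULT_HEXAMER_STRENGTHS))
    hexamer_probs: dict = field(default_factory=lambda: dict(DEFAULT_HEXAMER_PROBS))
    hexamer_offset_range: tuple = (-30, -15)   # planted hexamer start, nt upstream
    beta_position: float = 0.25                # proximal advantage per index step
    aux_motifs: tuple = DEFAULT_AUX_MOTIFS
    aux_plant_prob: float = 0.3                # chance to plant each aux motif per site
    noise_sd: float = 0.15
    read_depth: int = 2000
    gc_content: float = 0.5
    minus_strand_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.W % 2 == 0:
            raise ValueError("W must be odd")
        s = sum(self.pas_count_probs.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError("pas_count_probs must sum to 1")
        if abs(sum(self.hexamer_probs.values()) - 1.0) > 1e-9:
            raise ValueError("hexamer_probs must sum to 1")


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _plant(seq: np.ndarray, center: int, offset: int, motif: str):
    start = center + offset
    if start < 0 or start + len(motif) > len(seq):
        return
    seq[start:start + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")


def sequence_strength(window: str, config: GeneratorConfig) -> float:
    """Sequence-derived part of the latent strength of a site window.

    Hexamer term: strongest known hexamer whose start lies in the signal
    region. Auxiliary terms: per-occurrence effects in their regions.
    Recomputable on any (possibly edited) window.
    """
    from .features import count_motif

    center = (len(window) - 1) // 2
    lo, hi = config.hexamer_offset_range
    region = window[max(0, center + lo):center + hi + 6]
    hex_term = 0.0
    for hexamer, strength in config.hexamer_strengths.items():
        if hexamer and hexamer in region:
            hex_term = max(hex_term, strength)
    aux_term = sum(eff * count_motif(window, pat, reg)
                   for pat, reg, eff in config.aux_motifs)
    return hex_term + aux_term


def true_score(window: str, pas_index: int, n_pas: int, config: GeneratorConfig,
               noise: float = 0.0) -> float:
    """Full latent strength: sequence term + proximal positional advantage + noise."""
    return (sequence_strength(window, config)
            + config.beta_position * (n_pas - pas_index)
            + noise)


def simulate_gene(config: GeneratorConfig, rng: np.random.Generator,
                  gene_id: str = "g0", allele: str = "A",
                  n_pas: int | None = None) -> tuple:
    """One gene plus its truth record (scores, noise, planted hexamers)."""
    if n_pas is None:
        ks = sorted(config.pas_count_probs)
        n_pas = int(rng.choice(ks, p=[config.pas_count_probs[k] for k in ks]))
    W = config.W
    center = (W - 1) // 2
    windows, hexamers, offsets = [], [], []
    for _ in range(n_pas):
        seq = _random_background(rng, W, config.gc_content)
        hexes = sorted(config.hexamer_probs)
        hexamer = str(rng.choice(hexes, p=[config.hexamer_probs[h] for h in hexes]))
        off = int(rng.integers(config.hexamer_offset_range[0],
                               config.hexamer_offset_range[1] + 1))
        if hexamer:
            _plant(seq, center, off, hexamer)
        for pat, (rlo, rhi), _eff in config.aux_motifs:
            if rng.random() < config.aux_plant_prob:
                _plant(seq, center, int(rng.integers(rlo, rhi - len(pat) + 2)), pat)
        windows.append(seq.tobytes().decode())
        hexamers.append(hexamer)
        offsets.append(off)
    noise = rng.normal(0.0, config.noise_sd, size=n_pas)
    scores = np.array([true_score(w, k + 1, n_pas, config, noise[k])
                       for k, w in enumerate(windows)])
    usage_exact = softmax(scores)
    counts = rng.multinomial(config.read_depth, usage_exact)
    usage = counts / counts.sum() if counts.sum() else usage_exact

    strand = "-" if rng.random() < config.minus_strand_prob else "+"
    chrom = f"chr_{gene_id}_{allele}"
    # genome contig = windows laid back-to-back in genomic order; cleavage
    # positions are the window centers, so extraction round-trips exactly
    if strand == "+":
        contig = "".join(windows)
        positions = [i * W + center for i in range(n_pas)]
    else:
        contig = reverse_complement("".join(windows))
        positions = [len(contig) - 1 - (i * W + center) for i in range(n_pas)]
    records = [PASRecord(gene_id, k + 1, chrom, strand, positions[k], windows[k],
                         float(usage[k]), int(counts[k]))
               for k in range(n_pas)]
    gene = Gene(gene_id, allele, records)
    truth = pd.DataFrame({
        "gene_id": gene_id, "allele": allele,
        "pas_index": np.arange(1, n_pas + 1),
        "planted_hexamer": hexamers, "hexamer_offset": offsets,
        "noise": noise, "true_score": scores, "usage_exact": usage_exact,
    })
    return gene, truth, contig


def simulate_dataset(config: GeneratorConfig, out_dir=None,
                     allele: str = "A") -> tuple:
    """Simulate `config.n_genes` genes; optionally write the on-disk formats.

    Returns (Dataset, truth DataFrame). With `out_dir`, writes genome.fa,
    pas.tsv, usage.tsv and truth.tsv — the exact formats `load_dataset`
    reads.
    """
    rng = np.random.default_rng(config.seed)
    genes, truths, contigs = [], [], {}
    for i in range(config.n_genes):
        gid = f"g{i:05d}"
        gene, truth, contig = simulate_gene(config, rng, gene_id=gid, allele=allele)
        genes.append(gene)
        truths.append(truth)
        contigs[gene.pas_list[0].chrom] = contig
    dataset = Dataset(genes, config.W, provenance={"generator": "apanet.synthetic",
                                                   "seed": config.seed})
    truth = pd.concat(truths, ignore_index=True)
    if out_dir is not None:
        write_simulated(dataset, truth, contigs, out_dir)
    return dataset, truth


def write_simulated(dataset: Dataset, truth: pd.DataFrame, contigs: dict, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    pas_rows, usage_rows = [], []
    for g in dataset.genes:
        for r in g.pas_list:
            pas_rows.append((r.gene_id, r.chrom, r.strand, r.cleavage_pos,
                             r.pas_index, g.allele))
            usage_rows.append((r.gene_id, g.allele, r.pas_index, r.read_count, r.usage))
    pd.DataFrame(pas_rows, columns=["gene_id", "chrom", "strand", "cleavage_pos",
                                    "pas_index", "allele"]) \
        .to_csv(out / "pas.tsv", sep="\t", index=False)
    pd.DataFrame(usage_rows, columns=["gene_id", "allele", "pas_index",
                                      "read_count", "usage"]) \
        .to_csv(out / "usage.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _disrupt_hexamer(window: str, offset: int, hexamer: str) -> str:
    """Point substitution in the planted hexamer (first A -> C) killing the signal."""
    center = (len(window) - 1) // 2
    start = center + offset
    sub = "C" if window[start] != "C" else "G"
    return window[:start] + sub + window[start + 1:]


def simulate_allele_pair(config: GeneratorConfig, n_variants: int) -> tuple:
    """Two alleles of each gene; allele B carries hexamer-disrupting substitutions.

    `n_variants` PASs with planted hexamers are chosen across the dataset
    and disrupted in allele B. Noise realizations are shared between
    alleles (same trans environment, as in an F1 hybrid), so the true
    usage difference is purely due to the sequence edits. Returns
    (dataset_A, dataset_B, truth table with per-PAS true allelic diffs).
    """
    ds_a, truth_a = simulate_dataset(config, allele="A")
    rng = np.random.default_rng(config.seed + 1)
    planted = truth_a[truth_a.planted_hexamer != ""].reset_index(drop=True)
    n_variants = min(n_variants, len(planted))
    chosen = planted.iloc[rng.choice(len(planted), size=n_variants, replace=False)]
    edited = {(r.gene_id, r.pas_index): (r.hexamer_offset, r.planted_hexamer)
              for r in chosen.itertuples()}

    genes_b, rows = [], []
    for gene in ds_a.genes:
        n = gene.n_pas
        g_truth = truth_a[truth_a.gene_id == gene.gene_id].sort_values("pas_index")
        noise = g_truth["noise"].to_numpy()
        new_windows = []
        for r in gene.pas_list:
            key = (r.gene_id, r.pas_index)
            if key in edited:
                off, hexamer = edited[key]
                new_windows.append(_disrupt_hexamer(r.window_seq, off, hexamer))
            else:
                new_windows.append(r.window_seq)
        scores_b = np.array([true_score(w, k + 1, n, config, noise[k])
                             for k, w in enumerate(new_windows)])
        usage_b_exact = softmax(scores_b)
        counts_b = np.random.default_rng(
            rng.integers(2 ** 31)).multinomial(config.read_depth, usage_b_exact)
        usage_b = counts_b / counts_b.sum()
        recs = [PASRecord(r.gene_id, r.pas_index, r.chrom, r.strand, r.cleavage_pos,
                          w, float(usage_b[k]), int(counts_b[k]))
                for k, (r, w) in enumerate(zip(gene.pas_list, new_windows))]
        genes_b.append(Gene(gene.gene_id, "B", recs))
        ua = g_truth["usage_exact"].to_numpy()
        for k, r in enumerate(gene.pas_list):
            rows.append((r.gene_id, r.pas_index, (r.gene_id, r.pas_index) in edited,
                         ua[k], usage_b_exact[k], usage_b_exact[k] - ua[k]))
    ds_b = Dataset(genes_b, config.W, provenance={"generator": "apanet.synthetic",
                                                  "seed": config.seed, "allele": "B"})
    truth = pd.DataFrame(rows, columns=["gene_id", "pas_index", "disrupted",
                                        "usage_A_exact", "usage_B_exact", "true_diff"])
    return ds_a, ds_b, truth
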