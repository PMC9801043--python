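"""Data model for genes with competing polyadenylation sites.

A gene is an ordered list of PAS records (proximal to distal in
transcription order) whose usage fractions sum to one. Sequences are
fixed-width windows around each cleavage site, always stored 5'->3' on
the transcribed strand, so everything downstream of this module can speak
of "upstream"/"downstream" without caring about genomic strand.

Coordinate conventions: cleavage positions are 0-based genomic
coordinates; windows are closed intervals. An odd window of width W
covers (W-1)/2 bases on each side of the cleavage site. An even window
(the 448-nt dialect) covers W/2 bases up to and including the site and
W/2 bases downstream of it. Out-of-genome positions are filled with N.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = "ACGT"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class DegenerateUsageError(DataError):
    """A gene whose usage cannot be defined (e.g., all-zero read counts)."""


@dataclass
class PASRecord:
    gene_id: str
    pas_index: int          # 1-based, transcription order (proximal -> distal)
    chrom: str
    strand: str             # '+' or '-'
    cleavage_pos: int       # 0-based genomic coordinate
    window_seq: str         # 5'->3' on the transcribed strand
    usage: float = float("nan")
    read_count: int = -1    # -1 when counts were not provided

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pas_index < 1:
            raise DataError("pas_index is 1-based (>= 1)")
        bad = set(self.window_seq) - VALID_BASES
        if bad:
            raise DataError(f"window contains non-ACGTN characters: {sorted(bad)}")


@dataclass
class Gene:
    gene_id: str
    allele: str
    pas_list: list  # of PASRecord, ascending pas_index

    def __post_init__(self):
        self.validate_structure()

    @property
    def n_pas(self) -> int:
        return len(self.pas_list)

    @property
    def usage_vector(self) -> np.ndarray:
        return np.array([r.usage for r in self.pas_list], dtype=float)

    @property
    def windows(self) -> list:
        return [r.window_seq for r in self.pas_list]

    @property
    def W(self) -> int:
        return len(self.pas_list[0].window_seq)

    def validate_structure(self):
        if not self.pas_list:
            raise DataError(f"{self.gene_id}: gene must have at least one PAS")
        idx = [r.pas_index for r in self.pas_list]
        if idx != list(range(1, len(idx) + 1)):
            raise DataError(f"{self.gene_id}: pas_index must be 1..n without gaps, got {idx}")
        W = len(self.pas_list[0].window_seq)
        if any(len(r.window_seq) != W for r in self.pas_list):
            raise DataError(f"{self.gene_id}: inconsistent window lengths")
        strands = {r.strand for r in self.pas_list}
        if len(strands) > 1:
            raise DataError(f"{self.gene_id}: mixed strands")
        pos = [r.cleavage_pos for r in self.pas_list]
        if strands == {"+"} and any(b <= a for a, b in zip(pos, pos[1:])):
            raise DataError(f"{self.gene_id}: '+' strand cleavage positions must increase with pas_index")
        if strands == {"-"} and any(b >= a for a, b in zip(pos, pos[1:])):
            raise DataError(f"{self.gene_id}: '-' strand cleavage positions must decrease with pas_index")

    def validate_usage(self, atol: float = 1e-6):
        u = self.usage_vector
        if np.isnan(u).any():
            raise DataError(f"{self.gene_id}/{self.allele}: usage not set")
        if abs(u.sum() - 1.0) > atol:
            raise DataError(f"{self.gene_id}/{self.allele}: usage sums to {u.sum():.8f}, not 1")


@dataclass
class Dataset:
    genes: list
    W: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [(g.gene_id, g.allele) for g in self.genes]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DataError(f"duplicate (gene_id, allele) pairs: {dupes}")
        for g in self.genes:
            if g.W != self.W:
                raise DataError(f"{g.gene_id}: window length {g.W} != dataset W {self.W}")

    def __len__(self):
        return len(self.genes)

    def multi_pas(self) -> list:
        """Genes with >= 2 sites — the ones training and metrics use."""
        return [g for g in self.genes if g.n_pas >= 2]


# ---------------------------------------------------------------------
# sequence primitives


def extract_window(genome_seq: str, cleavage_pos: int, strand: str, W: int) -> str:
    """Window of width W around a cleavage site, 5'->3' on the transcribed strand.

    Odd W: symmetric, (W-1)/2 each side, site included. Even W (the
    448-nt dialect): W/2 bases ending at the site plus W/2 downstream.
    Flanks outside the sequence are filled with N; minus-strand windows
    are the reverse complement of the plus-strand slice.
    """
    bad = set(genome_seq) - VALID_BASES
    if bad:
        raise DataError(f"genome contains non-ACGTN characters: {sorted(bad)}")
    if W % 2 == 1:
        lo = cleavage_pos - (W - 1) // 2
    else:
        lo = cleavage_pos - W // 2 + 1
    hi = lo + W  # exclusive
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(genome_seq))
    core = genome_seq[max(lo, 0):min(hi, len(genome_seq))]
    window = "N" * left_pad + core + "N" * right_pad
    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise DataError(f"strand must be '+' or '-', got {strand!r}")
    return window


def one_hot(window: str) -> np.ndarray:
    """W x 4 one-hot matrix, channel order A,C,G,T; N rows are all zero."""
    bad = set(window) - VALID_BASES
    if bad:
        raise DataError(f"window contains non-ACGTN characters: {sorted(bad)}")
    mat = np.zeros((len(window), 4), dtype=np.float64)
    for i, b in enumerate(window):
        j = _BASE_INDEX.get(b)
        if j is not None:
            mat[i, j] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    out = []
    for row in mat:
        out.append("N" if row.sum() == 0 else _INDEX_BASE[int(row.argmax())])
    return "".join(out)


def counts_to_usage(read_counts: Sequence[int]) -> np.ndarray:
    counts = np.asarray(read_counts, dtype=float)
    if (counts < 0).any():
        raise DataError("read counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise DegenerateUsageError("all-zero read counts: usage undefined")
    return counts / total


# ---------------------------------------------------------------------
# readers / writers


def _read_fasta(path) -> dict:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def load_dataset(fasta_path, pas_table_path, usage_table_path, W: int,
                 min_total_reads: int = 10) -> Dataset:
    """Assemble a Dataset from a genome FASTA plus PAS and usage tables.

    PAS table: TSV with columns gene_id, chrom, strand, cleavage_pos,
    pas_index, allele. Usage table: TSV with gene_id, allele, pas_index
    and read_count and/or usage. Every PAS row must join to exactly one
    usage row. Genes violating structural invariants, single-PAS genes
    failing nothing but kept aside by consumers, and genes below the
    read-count floor are dropped with a logged reason and counted in
    ``provenance['dropped']``.
    """
    genome = _read_fasta(fasta_path)
    pas = pd.read_csv(pas_table_path, sep="\t", dtype={"gene_id": str, "allele": str})
    usage = pd.read_csv(usage_table_path, sep="\t", dtype={"gene_id": str, "allele": str})

    key = ["gene_id", "allele", "pas_index"]
    for name, df in (("PAS table", pas), ("usage table", usage)):
        dup = df[df.duplicated(key, keep=False)]
        if len(dup):
            offenders = dup[key].to_records(index=False).tolist()
            raise DataError(f"{name}: duplicate (gene, allele, pas_index) rows: {offenders}")

    merged = pas.merge(usage, on=key, how="left", indicator=True)
    missing = merged[merged["_merge"] != "both"]
    if len(missing):
        offenders = missing[key].to_records(index=False).tolist()
        raise DataError(f"PAS rows with no usage entry: {offenders}")

    has_counts = "read_count" in merged.columns
    has_usage = "usage" in merged.columns
    if not (has_counts or has_usage):
        raise DataError("usage table needs a 'read_count' or 'usage' column")

    genes, dropped = [], {}

    def drop(gid, allele, reason):
        logger.info("dropping gene %s/%s: %s", gid, allele, reason)
        dropped[f"{gid}/{allele}"] = reason

    for (gid, allele), grp in merged.groupby(["gene_id", "allele"], sort=True):
        grp = grp.sort_values("pas_index")
        try:
            if has_counts and grp["read_count"].notna().all():
                counts = grp["read_count"].to_numpy(dtype=float)
                if counts.sum() < min_total_reads:
                    drop(gid, allele, f"total reads {counts.sum():.0f} < floor {min_total_reads}")
                    continue
                u = counts_to_usage(counts)
                counts = counts.astype(int)
            else:
                u = grp["usage"].to_numpy(dtype=float)
                counts = np.full(len(grp), -1, dtype=int)
            records = []
            for (_, row), ui, ci in zip(grp.iterrows(), u, counts):
                chrom = str(row["chrom"])
                if chrom not in genome:
                    raise DataError(f"chromosome {chrom!r} not in FASTA")
                win = extract_window(genome[chrom], int(row["cleavage_pos"]), row["strand"], W)
                records.append(PASRecord(gid, int(row["pas_index"]), chrom, row["strand"],
                                         int(row["cleavage_pos"]), win, float(ui), int(ci)))
            gene = Gene(gid, allele, records)
            gene.validate_usage()
            genes.append(gene)
        except DegenerateUsageError as e:
            drop(gid, allele, str(e))
        except DataError as e:
            drop(gid, allele, str(e))

    return Dataset(genes, W, provenance={"dropped": dropped,
                                         "n_loaded": len(genes),
                                         "n_dropped": len(dropped)})


def write_dataset(dataset: Dataset, path):
    """Serialize as JSON lines, one record per gene (lossless round trip)."""
    with open(path, "w") as fh:
        for g in dataset.genes:
            rec = {"gene_id": g.gene_id, "allele": g.allele,
                   "pas_list": [asdict(r) for r in g.pas_list]}
            fh.write(json.dumps(rec) + "\n")


def read_dataset(path, provenance: dict | None = None) -> Dataset:
    genes = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            pas = [PASRecord(**r) for r in rec["pas_list"]]
            genes.append(Gene(rec["gene_id"], rec["allele"], pas))
    if not genes:
        raise DataError("empty dataset file")
    return Dataset(genes, genes[0].W, provenance=provenance or {})


def mix_alleles(gene_a: Gene, gene_b: Gene, take_from_b: Iterable[int]) -> Gene:
    """Hybrid allele: window k from gene_b for k in `take_from_b`, else gene_a.

    Models the in-silico construction of a hypothetical allele carrying
    one parent's sequence at chosen sites; usage is left unset (to be
    predicted).
    """
    if gene_a.gene_id != gene_b.gene_id:
        raise DataError("mix_alleles: gene ids differ")
    if gene_a.n_pas != gene_b.n_pas:
        raise DataError(f"mix_alleles: PAS counts differ ({gene_a.n_pas} vs {gene_b.n_pas})")
    take = set(take_from_b)
    unknown = take - {r.pas_index for r in gene_a.pas_list}
    if unknown:
        raise DataError(f"mix_alleles: unknown pas_index {sorted(unknown)}")
    records = []
    for ra, rb in zip(gene_a.pas_list, gene_b.pas_list):
        src = rb if ra.pas_index in take else ra
        records.append(PASRecord(ra.gene_id, ra.pas_index, ra.chrom, ra.strand,
                                 ra.cleavage_pos, src.window_seq,
                                 float("nan"), -1))
    return Gene(gene_a.gene_id, "mixed", records)
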