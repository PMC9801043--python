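"""Window extraction, encoding, usage normalization, loaders, allele mixing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apanet.data import (DataError, DegenerateUsageError, Dataset, Gene,
                         PASRecord, counts_to_usage, decode_one_hot,
                         extract_window, load_dataset, mix_alleles, one_hot,
                         read_dataset, write_dataset)
from Bio.Seq import reverse_complement

GENOME = "ACGTACGTACGT"


class TestExtractWindow:
    @pytest.mark.parametrize("pos,strand,W,expected", [
        (5, "+", 5, "TACGT"),
        (5, "-", 5, "ACGTA"),          # reverse complement of the plus slice
        (1, "+", 5, GENOME[:4].rjust(5, "N")[:5]),
    ])
    def test_symmetric_window(self, pos, strand, W, expected):
        assert extract_window(GENOME, pos, strand, W) == expected

    def test_left_padding_with_n(self):
        assert extract_window("ACGT", 0, "+", 5) == "NNACG"

    def test_right_padding_with_n(self):
        assert extract_window("ACGT", 3, "+", 5) == "CGTNN"

    def test_even_dialect_covers_site_plus_downstream(self):
        # W=4: two bases ending at the site, two downstream
        assert extract_window(GENOME, 5, "+", 4) == GENOME[4:8]

    def test_rejects_non_acgtn_genome(self):
        with pytest.raises(DataError):
            extract_window("ACGU", 1, "+", 3)

    @given(st.text(alphabet="ACGT", min_size=9, max_size=40),
           st.integers(min_value=0, max_value=39),
           st.sampled_from([3, 5, 7]))
    @settings(max_examples=80, deadline=None)
    def test_minus_strand_is_revcomp_of_plus(self, genome, pos, W):
        pos = pos % len(genome)
        plus = extract_window(genome, pos, "+", W)
        minus = extract_window(genome, pos, "-", W)
        assert minus == reverse_complement(plus)


class TestOneHot:
    def test_acgt_is_identity(self):
        assert np.array_equal(one_hot("ACGT"), np.eye(4))

    def test_n_row_is_all_zeros(self):
        assert np.array_equal(one_hot("N"), np.zeros((1, 4)))

    def test_repeated_base(self):
        assert np.array_equal(one_hot("AA"), [[1, 0, 0, 0], [1, 0, 0, 0]])

    @given(st.text(alphabet="ACGT", min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_decode_recovers_n_free_windows(self, window):
        assert decode_one_hot(one_hot(window)) == window

    def test_rejects_other_characters(self):
        with pytest.raises(DataError):
            one_hot("ACGX")


class TestCountsToUsage:
    def test_simple_fractions(self):
        assert np.allclose(counts_to_usage([30, 70]), [0.3, 0.7])
        assert np.allclose(counts_to_usage([1, 1, 2]), [0.25, 0.25, 0.5])

    def test_all_zero_counts_signal_exclusion(self):
        with pytest.raises(DegenerateUsageError):
            counts_to_usage([0, 0])

    def test_sums_to_one(self, rng):
        c = rng.integers(0, 100, size=6) + 1
        assert np.isclose(counts_to_usage(c).sum(), 1.0)


def _rec(gid, idx, pos, win, usage, strand="+"):
    return PASRecord(gid, idx, "chr1", strand, pos, win, usage)


class TestGeneInvariants:
    def test_gapped_pas_index_rejected(self):
        with pytest.raises(DataError, match="1..n"):
            Gene("g", "A", [_rec("g", 1, 10, "ACG", 0.5), _rec("g", 3, 20, "ACG", 0.5)])

    def test_plus_strand_positions_must_increase(self):
        with pytest.raises(DataError, match="increase"):
            Gene("g", "A", [_rec("g", 1, 30, "ACG", 0.5), _rec("g", 2, 20, "ACG", 0.5)])

    def test_minus_strand_positions_must_decrease(self):
        g = Gene("g", "A", [_rec("g", 1, 30, "ACG", 0.5, "-"),
                            _rec("g", 2, 20, "ACG", 0.5, "-")])
        assert g.n_pas == 2

    def test_usage_must_sum_to_one(self):
        g = Gene("g", "A", [_rec("g", 1, 10, "ACG", 0.5), _rec("g", 2, 20, "ACG", 0.4)])
        with pytest.raises(DataError, match="sums to"):
            g.validate_usage()

    def test_duplicate_gene_allele_rejected_in_dataset(self):
        g1 = Gene("g", "A", [_rec("g", 1, 10, "ACG", 1.0)])
        g2 = Gene("g", "A", [_rec("g", 1, 10, "ACG", 1.0)])
        with pytest.raises(DataError, match="duplicate"):
            Dataset([g1, g2], 3)


@pytest.fixture
def toy_files(tmp_path):
    """Two genes (one on the minus strand) as genome + PAS + usage tables."""
    genome = "".join(np.random.default_rng(0).choice(list("ACGT"), 400))
    (tmp_path / "genome.fa").write_text(f">chr1\n{genome}\n")
    pas = ["gene_id\tchrom\tstrand\tcleavage_pos\tpas_index\tallele",
           "g1\tchr1\t+\t50\t1\tA",
           "g1\tchr1\t+\t150\t2\tA",
           "g2\tchr1\t-\t300\t1\tA",
           "g2\tchr1\t-\t200\t2\tA"]
    usage = ["gene_id\tallele\tpas_index\tread_count",
             "g1\tA\t1\t30", "g1\tA\t2\t70",
             "g2\tA\t1\t10", "g2\tA\t2\t30"]
    (tmp_path / "pas.tsv").write_text("\n".join(pas) + "\n")
    (tmp_path / "usage.tsv").write_text("\n".join(usage) + "\n")
    return tmp_path, genome


class TestLoadDataset:
    def test_toy_fixture_loads_two_genes(self, toy_files):
        d, genome = toy_files
        ds = load_dataset(d / "genome.fa", d / "pas.tsv", d / "usage.tsv", W=21)
        assert len(ds) == 2
        for g in ds.genes:
            assert np.isclose(g.usage_vector.sum(), 1.0)
        g1 = next(g for g in ds.genes if g.gene_id == "g1")
        assert np.allclose(g1.usage_vector, [0.3, 0.7])
        assert g1.pas_list[0].window_seq == extract_window(genome, 50, "+", 21)

    def test_minus_strand_order_matches_descending_coordinates(self, toy_files):
        d, _ = toy_files
        ds = load_dataset(d / "genome.fa", d / "pas.tsv", d / "usage.tsv", W=21)
        g2 = next(g for g in ds.genes if g.gene_id == "g2")
        pos = [r.cleavage_pos for r in g2.pas_list]
        assert pos == sorted(pos, reverse=True)

    def test_pas_without_usage_is_a_hard_error_naming_it(self, toy_files):
        d, _ = toy_files
        usage = (d / "usage.tsv").read_text().splitlines()
        (d / "usage.tsv").write_text("\n".join(usage[:-1]) + "\n")  # drop g2 PAS 2
        with pytest.raises(DataError, match="g2"):
            load_dataset(d / "genome.fa", d / "pas.tsv", d / "usage.tsv", W=21)

    def test_duplicate_rows_are_a_hard_error(self, toy_files):
        d, _ = toy_files
        with open(d / "pas.tsv", "a") as fh:
            fh.write("g1\tchr1\t+\t50\t1\tA\n")
        with pytest.raises(DataError, match="duplicate"):
            load_dataset(d / "genome.fa", d / "pas.tsv", d / "usage.tsv", W=21)

    def test_low_read_genes_dropped_and_counted(self, toy_files):
        d, _ = toy_files
        ds = load_dataset(d / "genome.fa", d / "pas.tsv", d / "usage.tsv", W=21,
                          min_total_reads=50)
        assert len(ds) == 1  # g2 has 40 reads total
        assert "g2/A" in ds.provenance["dropped"]


def test_jsonl_round_trip_is_lossless(small_dataset, tmp_path):
    ds, _ = small_dataset
    path = tmp_path / "genes.jsonl"
    write_dataset(ds, path)
    ds2 = read_dataset(path)
    assert len(ds2) == len(ds)
    for a, b in zip(ds.genes, ds2.genes):
        assert a.gene_id == b.gene_id and a.allele == b.allele
        assert a.windows == b.windows
        assert np.allclose(a.usage_vector, b.usage_vector)
        assert [r.cleavage_pos for r in a.pas_list] == [r.cleavage_pos for r in b.pas_list]


class TestMixAlleles:
    def _pair(self):
        recs_a = [_rec("g", i, i * 100, f"AAAA{'ACGT'[i - 1]}", 0.25) for i in range(1, 5)]
        recs_b = [_rec("g", i, i * 100, f"TTTT{'ACGT'[i - 1]}", 0.25) for i in range(1, 5)]
        return Gene("g", "BL", recs_a), Gene("g", "SP", recs_b)

    def test_empty_set_reproduces_first_allele(self):
        a, b = self._pair()
        assert mix_alleles(a, b, set()).windows == a.windows

    def test_full_set_reproduces_second_allele(self):
        a, b = self._pair()
        assert mix_alleles(a, b, {1, 2, 3, 4}).windows == b.windows

    def test_single_distal_swap_takes_only_that_window(self):
        # the in-silico hybrid: sites 1-3 from one parent, site 4 from the other
        a, b = self._pair()
        mixed = mix_alleles(a, b, {4})
        assert mixed.windows[:3] == a.windows[:3]
        assert mixed.windows[3] == b.windows[3]
        assert mixed.allele == "mixed"
        assert np.isnan(mixed.usage_vector).all()

    def test_mismatched_pas_counts_rejected(self):
        a, b = self._pair()
        short = Gene("g", "SP", b.pas_list[:3])
        with pytest.raises(DataError, match="counts differ"):
            mix_alleles(a, short, {1})
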