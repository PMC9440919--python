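import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isotrunc.exonquant import (
    BedError,
    ExonExpressionMatrix,
    count_reads_per_exon,
    counts_from_coverage,
    read_bed,
    rpkm,
)
from isotrunc.simulate import SimulationConfig, simulate_gene_model


class TestCounting:
    def test_read_inside_exon_counts_once(self, toy_plus):
        reads = [("chr1", ((150, 160),))]
        assert count_reads_per_exon(reads, toy_plus).tolist() == [1, 0]

    def test_read_spanning_two_exons_increments_both(self, toy_plus):
        reads = [("chr1", ((150, 350),))]
        assert count_reads_per_exon(reads, toy_plus).tolist() == [1, 1]

    def test_split_read_blocks_respected(self, toy_plus):
        # a spliced read whose gap covers the intron touches both exons
        reads = [("chr1", ((190, 200), (299, 309)))]
        assert count_reads_per_exon(reads, toy_plus).tolist() == [1, 1]
        # gapped read falling entirely in the intron touches nothing
        reads = [("chr1", ((210, 220), (230, 240)))]
        assert count_reads_per_exon(reads, toy_plus).tolist() == [0, 0]

    def test_empty_read_set(self, toy_plus):
        assert count_reads_per_exon([], toy_plus).tolist() == [0, 0]

    def test_min_overlap_threshold(self, toy_plus):
        reads = [("chr1", ((195, 205),))]  # 5 bp on exon 1
        assert count_reads_per_exon(reads, toy_plus, min_overlap=5).tolist() == [1, 0]
        assert count_reads_per_exon(reads, toy_plus, min_overlap=6).tolist() == [0, 0]

    def test_other_chromosome_ignored(self, toy_plus):
        assert count_reads_per_exon([("chr2", ((150, 160),))], toy_plus).tolist() == [0, 0]

    def test_matches_bruteforce_oracle_on_random_sets(self, toy_plus):
        rng = np.random.default_rng(7)
        exons = [(e.interval.start, e.interval.end) for e in toy_plus.exons]
        for _ in range(500):
            reads = []
            for _ in range(rng.integers(0, 20)):
                s = int(rng.integers(0, 450))
                reads.append(("chr1", ((s, s + int(rng.integers(1, 80))),)))
            expected = [
                sum(
                    1
                    for _, blocks in reads
                    if sum(
                        max(0, min(be, ee) - max(bs, es))
                        for bs, be in blocks
                    )
                    >= 1
                )
                for es, ee in exons
            ]
            assert count_reads_per_exon(reads, toy_plus).tolist() == expected


class TestBedIO:
    def test_twelve_column_blocks(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text(
            "chr1\t190\t309\tr1\t0\t+\t190\t309\t0\t2\t10,10\t0,109\n"
        )
        (chrom, blocks), = read_bed(p)
        assert chrom == "chr1"
        assert blocks == ((190, 200), (299, 309))

    def test_invalid_record_reports_text(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(BedError, match="chr1"):
            read_bed(p)

    def test_reversed_interval_rejected(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(BedError):
            read_bed(p)


class TestRpkm:
    def test_worked_example(self):
        assert rpkm(100, 500, 1_000_000) == 200.0

    def test_zero_count(self):
        assert rpkm(0, 500, 1_000_000) == 0.0

    def test_joint_scaling_is_neutral(self):
        assert rpkm(200, 500, 2_000_000) == 200.0

    @given(
        count=st.integers(0, 10_000),
        length=st.integers(1, 100_000),
        lib=st.integers(1, 10**9),
        scale=st.integers(1, 50),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_homogeneity_and_monotonicity(self, count, length, lib, scale):
        base = rpkm(count, length, lib)
        assert rpkm(count * scale, length, lib * scale) == pytest.approx(base)
        assert rpkm(count + 1, length, lib) > base

    @pytest.mark.parametrize("length,lib", [(0, 1000), (100, 0)])
    def test_degenerate_inputs_rejected(self, length, lib):
        with pytest.raises(ValueError):
            rpkm(10, length, lib)


class TestMatrix:
    def _matrix(self, toy_plus):
        return ExonExpressionMatrix.from_counts(
            toy_plus,
            {"a": [101, 0], "b": [0, 101]},
            {"a": 1_000_000, "b": 2_000_000},
        )

    def test_rpkm_zero_iff_count_zero(self, toy_plus):
        m = self._matrix(toy_plus)
        assert ((m.rpkm.values == 0) == (m.counts.values == 0)).all()

    def test_profile_ordered_by_exon(self, toy_plus):
        m = self._matrix(toy_plus)
        # exon 1 is 101 bp: 101 reads / (0.101 kb * 1 M) = 1000
        assert m.exon_profile("a") == pytest.approx([1000.0, 0.0])

    def test_unknown_sample(self, toy_plus):
        with pytest.raises(KeyError):
            self._matrix(toy_plus).exon_profile("zzz")

    def test_sample_order_irrelevant(self, toy_plus):
        m1 = self._matrix(toy_plus)
        m2 = ExonExpressionMatrix.from_counts(
            toy_plus,
            {"b": [0, 101], "a": [101, 0]},
            {"b": 2_000_000, "a": 1_000_000},
        )
        assert np.allclose(m1.exon_profile("a"), m2.exon_profile("a"))

    def test_truncation_pattern_visible_in_profile(self):
        cfg = SimulationConfig()
        gene = simulate_gene_model(cfg)
        counts = np.zeros(28, dtype=int)
        counts[22:] = 100
        m = ExonExpressionMatrix.from_counts(
            gene.transcript, {"s": counts}, {"s": 10_000_000}
        )
        prof = m.exon_profile("s")
        assert (prof[:22] == 0).all() and (prof[22:] > 0).all()

    def test_zero_library_rejected(self, toy_plus):
        with pytest.raises(ValueError):
            ExonExpressionMatrix.from_counts(toy_plus, {"a": [1, 1]}, {"a": 0})


class TestCoverageCounts:
    def test_uniform_coverage_converts_to_reads(self, toy_plus):
        cov = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500], "value": [10.0]}
        )
        # exon1: mean cov 10 * 101 bp / 50 bp reads = 20.2 -> 20
        out = counts_from_coverage(cov, toy_plus, read_length=50)
        assert out.tolist() == [20, 20]
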