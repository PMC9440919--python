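import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isotrunc.proteomics import (
    infer_isoform_support,
    map_peptides,
    quantify,
    read_peptide_table,
    select_unique_peptides,
    tryptic_digest,
)

proteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


class TestDigest:
    def test_kr_not_before_p_rule(self):
        peps = tryptic_digest("AKRPMK")
        assert [p.sequence for p in peps] == ["AK", "RPMK"]
        assert [(p.start, p.end) for p in peps] == [(1, 2), (3, 6)]

    def test_no_internal_site(self):
        assert [p.sequence for p in tryptic_digest("MK")] == ["MK"]

    def test_one_missed_cleavage(self):
        assert {p.sequence for p in tryptic_digest("AKGR", 1)} == {"AK", "GR", "AKGR"}

    def test_length_filter(self):
        assert [p.sequence for p in tryptic_digest("AKRPMK", min_len=3)] == ["RPMK"]

    def test_bad_length_bounds(self):
        with pytest.raises(ValueError):
            tryptic_digest("AK", min_len=5, max_len=2)

    @given(protein=proteins)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_full_cleavage_reconstructs_protein(self, protein):
        peps = tryptic_digest(protein, missed_cleavages=0)
        assert "".join(p.sequence for p in peps) == protein
        for p in peps:
            assert protein[p.start - 1 : p.end] == p.sequence


class TestCoverage:
    def test_overlapping_peptides_union(self):
        protein = "ACDEFGHIKL"
        rep = map_peptides(["ACDE", "DEFG"], protein)
        assert rep.coverage_pct == pytest.approx(60.0)
        assert rep.n_peptides_mapped == 2

    def test_no_peptides(self):
        assert map_peptides([], "ACDEFGHIKL").coverage_pct == 0.0

    def test_full_length_peptide(self):
        assert map_peptides(["ACDEFGHIKL"], "ACDEFGHIKL").coverage_pct == 100.0

    def test_unmatched_reported_not_raised(self):
        rep = map_peptides(["WWWW"], "ACDEFGHIKL")
        assert rep.unmatched == ["WWWW"] and rep.coverage_pct == 0.0

    def test_monotone_and_order_invariant(self):
        protein = "ACDEFGHIKLMNPQRSTVWY"
        peps = ["ACDE", "GHIK", "STVW", "MNPQ"]
        cov = 0.0
        for i in range(1, len(peps) + 1):
            now = map_peptides(peps[:i], protein).coverage_pct
            assert now >= cov
            cov = now
        rev = map_peptides(peps[::-1], protein).coverage_pct
        assert rev == cov

    def test_every_occurrence_counts(self):
        rep = map_peptides(["ACA"], "ACACA")  # overlapping occurrences at 1 and 3
        assert sorted(rep.covered) == [1, 2, 3, 4, 5]

    def test_il_equivalence_switch(self):
        assert map_peptides(["MIK"], "MLKA").n_peptides_mapped == 0
        assert map_peptides(["MIK"], "MLKA", equate_il=True).n_peptides_mapped == 1


class TestSupport:
    def test_all_shared_supports_short(self):
        assert infer_isoform_support([(6, 9), (10, 12)], delta=5) == "short_supported"

    def test_n_exclusive_hit_implies_full_length(self):
        assert infer_isoform_support([(2, 4)], delta=5) == "full_length_supported"

    def test_straddling_peptide_requires_n_terminus(self):
        assert infer_isoform_support([(4, 9)], delta=5) == "full_length_supported"

    def test_empty_is_ambiguous(self):
        assert infer_isoform_support([], delta=5) == "ambiguous"

    def test_single_shared_below_m_min(self):
        assert infer_isoform_support([(6, 9)], delta=5) == "ambiguous"

    def test_adding_n_exclusive_moves_toward_full_length(self):
        spans = [(6, 9), (10, 12)]
        assert infer_isoform_support(spans, 5) == "short_supported"
        assert infer_isoform_support(spans + [(1, 3)], 5) == "full_length_supported"


def _table(rows):
    return pd.DataFrame(rows, columns=["sequence", "sample", "condition", "auc"])


class TestQuantify:
    def test_worked_fold_change(self):
        rows = []
        for s, v in [("c1", 140.0), ("c2", 160.0)]:
            rows.append(("PEPK", s, "control", v))
        for s, v in [("t1", 290.0), ("t2", 310.0)]:
            rows.append(("PEPK", s, "treated", v))
        q = quantify(_table(rows), {"PEPK"})
        assert q.fold_change == pytest.approx(2.0)
        assert q.p_value < 0.05

    def test_fragment_rows_summed(self):
        rows = [
            ("PEPK", "c1", "control", 70.0),
            ("PEPK", "c1", "control", 70.0),
            ("PEPK", "t1", "treated", 280.0),
        ]
        q = quantify(_table(rows), {"PEPK"})
        assert q.sample_averages["c1"] == pytest.approx(140.0)
        assert q.fold_change == pytest.approx(2.0)
        assert "t-test skipped" in " ".join(q.flags)

    def test_identical_groups(self):
        rows = [
            ("PEPK", s, cond, 100.0)
            for cond, ss in [("control", ["c1", "c2"]), ("treated", ["t1", "t2"])]
            for s in ss
        ]
        q = quantify(_table(rows), {"PEPK"})
        assert q.fold_change == pytest.approx(1.0)
        assert q.t_statistic == 0.0

    def test_all_zero_treated_degenerate(self):
        rows = [
            ("PEPK", "c1", "control", 100.0),
            ("PEPK", "c2", "control", 100.0),
            ("PEPK", "t1", "treated", 0.0),
            ("PEPK", "t2", "treated", 0.0),
        ]
        with pytest.warns(UserWarning, match="skipped"):
            q = quantify(_table(rows), {"PEPK"})
        assert q.fold_change == 0.0
        assert q.p_value is None

    def test_missing_peptide_excluded_and_flagged(self):
        rows = [
            ("AAK", "c1", "control", 100.0),
            ("CCK", "c1", "control", 300.0),
            ("AAK", "c2", "control", 100.0),
            ("AAK", "t1", "treated", 200.0),
            ("CCK", "t1", "treated", 600.0),
            ("AAK", "t2", "treated", 200.0),
        ]
        q = quantify(_table(rows), {"AAK", "CCK"})
        assert q.sample_averages["c1"] == pytest.approx(200.0)
        assert q.sample_averages["c2"] == pytest.approx(100.0)
        assert any("unobserved" in f for f in q.flags)

    def test_empty_unique_set_rejected(self):
        with pytest.raises(ValueError):
            quantify(_table([("A", "s", "control", 1.0)]), set())


class TestUniqueness:
    def test_background_proteome_filters_shared_peptides(self):
        peps = tryptic_digest("AAAKCCCK")
        bg = {"other": "ZZZAAAKZZZ".replace("Z", "G")}
        unique = select_unique_peptides(peps, bg)
        assert [p.sequence for p in unique] == ["CCCK"]

    def test_target_itself_ignored(self):
        peps = tryptic_digest("AAAK")
        bg = {"self": "AAAK"}
        assert select_unique_peptides(peps, bg, target_ids={"self"}) == peps


class TestTableIO:
    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sequence\tsample\tauc\nA\ts\t1\n")
        with pytest.raises(ValueError, match="condition"):
            read_peptide_table(p)
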