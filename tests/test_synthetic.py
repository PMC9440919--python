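import hashlib
from pathlib import Path

import numpy as np
import pytest

from isotrunc.boundary import detect_breakpoint
from isotrunc.genemodel import DomainAnnotation
from isotrunc.orfscan import assess_domains, enumerate_orfs, translate
from isotrunc.promoter import PromoterVerdict, classify_alternative_promoter
from isotrunc.proteomics import quantify
from isotrunc.simulate import (
    SimulationConfig,
    select_signature_peptides,
    simulate_chip_tracks,
    simulate_counts,
    simulate_gene_model,
    simulate_peptides,
    simulate_reads_bed,
    write_fixture_dir,
)


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(k=1)
        with pytest.raises(ValueError):
            SimulationConfig(depth=-1)
        with pytest.raises(ValueError):
            SimulationConfig(detection_prob=0.0)


class TestGeneModel:
    def test_planted_short_orf_at_exon_k(self, default_gene):
        t = default_gene.transcript
        seq = default_gene.transcript_seq
        assert seq[default_gene.short_start_nt : default_gene.short_start_nt + 3] == "ATG"
        assert t.transcript_pos_to_exon_index(default_gene.short_start_nt) == 23
        # canonical ORF translates cleanly and the short protein is its suffix
        canonical = translate(seq[t.cds_start : t.cds_stop])
        short = translate(seq[default_gene.short_start_nt : t.cds_stop])
        assert canonical.endswith(short)
        assert len(short) == 250

    def test_transmembrane_domain_is_lost_in_short_orf(self, default_gene):
        gene = default_gene
        t = gene.transcript
        cands = enumerate_orfs(t, gene.transcript_seq, (gene.short_start_nt, t.cds_stop))
        canonical = translate(gene.transcript_seq[t.cds_start : t.cds_stop])
        c = assess_domains(cands[0], gene.domains, len(canonical), canonical)
        assert "transmembrane" in c.domains_lost
        assert "c_terminal" in c.domains_retained

    def test_k2_with_c_terminal_domain_retained(self):
        cfg = SimulationConfig(k=2, short_orf_aa=1340)
        gene = simulate_gene_model(cfg)
        t = gene.transcript
        cands = enumerate_orfs(t, gene.transcript_seq, (gene.short_start_nt, t.cds_stop))
        canonical = translate(gene.transcript_seq[t.cds_start : t.cds_stop])
        dom = DomainAnnotation("cterm", len(canonical) - 5, len(canonical))
        c = assess_domains(cands[0], [dom], len(canonical), canonical)
        assert c.domains_retained == ["cterm"]

    def test_unsatisfiable_layout_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            simulate_gene_model(SimulationConfig(k=2, short_orf_aa=10))

    def test_minus_strand_locus_consistent(self):
        gene = simulate_gene_model(SimulationConfig(strand="-"))
        t = gene.transcript
        assert t.strand == "-"
        assert t.spliced_sequence(gene.genome) == gene.transcript_seq

    def test_same_seed_is_byte_identical(self, tmp_path):
        def digest(d: Path) -> dict:
            return {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(d.iterdir())
            }

        a = write_fixture_dir(SimulationConfig(seed=5), tmp_path / "a")
        b = write_fixture_dir(SimulationConfig(seed=5), tmp_path / "b")
        assert digest(a) == digest(b)
        c = write_fixture_dir(SimulationConfig(seed=6), tmp_path / "c")
        assert digest(a) != digest(c)


class TestCounts:
    def test_off_state_with_infinite_ratio_is_all_zero(self):
        cfg = SimulationConfig(expression_ratio=float("inf"))
        counts, libs = simulate_counts(cfg, "off")
        assert (counts.values == 0).all()
        assert all(v == cfg.library_background for v in libs.values())

    def test_zero_dispersion_is_poisson(self):
        cfg = SimulationConfig(nb_dispersion=0.0)
        rng = cfg.rng("counts")
        counts, _ = simulate_counts(cfg, "full", n_samples=1000, rng=rng)
        expressed = counts.values.ravel().astype(float)
        ratio = expressed.var() / expressed.mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_short_state_pattern(self):
        cfg = SimulationConfig(seed=1)
        counts, _ = simulate_counts(cfg, "short", n_samples=20)
        mean = counts.mean(axis=1)
        assert mean.iloc[:22].max() < mean.iloc[22:].min()

    def test_overdispersion_exceeds_poisson(self):
        cfg = SimulationConfig(nb_dispersion=0.5)
        counts, _ = simulate_counts(cfg, "full", n_samples=2000, rng=cfg.rng("counts"))
        expressed = counts.values.ravel().astype(float)
        assert expressed.var() / expressed.mean() > 1.2

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(SimulationConfig(), "sideways")

    def test_bed_realizes_exact_counts(self, tmp_path, default_gene):
        from isotrunc.exonquant import count_reads_per_exon, read_bed

        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=28)
        p = tmp_path / "reads.bed"
        simulate_reads_bed(default_gene.transcript, counts, p, rng=rng)
        recounted = count_reads_per_exon(read_bed(p), default_gene.transcript)
        assert recounted.tolist() == counts.tolist()


class TestChip:
    def test_zero_noise_verdict_deterministic(self, default_gene):
        cfg = SimulationConfig(chip_noise_sd=0.0)
        t = default_gene.transcript
        tracks = simulate_chip_tracks(cfg, t, "alternative_promoter")
        ev = classify_alternative_promoter(tracks, t, cfg.k)
        assert ev.verdict is PromoterVerdict.ALTERNATIVE_PROMOTER

    def test_flat_scenario_yields_no_evidence(self, default_gene):
        cfg = SimulationConfig(seed=3)
        tracks = simulate_chip_tracks(cfg, default_gene.transcript, "flat")
        ev = classify_alternative_promoter(tracks, default_gene.transcript, cfg.k)
        assert ev.verdict is PromoterVerdict.NO_EVIDENCE


class TestPeptides:
    def test_signature_set_hits_target_coverage(self, short_protein):
        from isotrunc.proteomics import map_peptides

        sig = select_signature_peptides(short_protein)
        assert len(sig) == 6
        cov = map_peptides([p.sequence for p in sig], short_protein).coverage_pct
        assert cov == pytest.approx(40.0, abs=2.0)

    def test_unit_fold_recovered(self, short_protein):
        cfg = SimulationConfig(peptide_fold=1.0, seed=4)
        obs, sig = simulate_peptides(cfg, short_protein)
        q = quantify(obs, sig)
        assert 0.8 <= q.fold_change <= 1.25

    def test_noiseless_full_detection_recovers_exact_fold(self, short_protein):
        cfg = SimulationConfig(peptide_cv=0.0, detection_prob=1.0)
        obs, sig = simulate_peptides(cfg, short_protein)
        q = quantify(obs, sig)
        assert q.fold_change == pytest.approx(2.0, rel=1e-9)

    def test_n_exclusive_only_under_full_length_scenario(
        self, short_protein, canonical_protein
    ):
        from isotrunc.proteomics import _occurrences, infer_isoform_support

        delta = len(canonical_protein) - len(short_protein)

        def spans(df):
            out = []
            for pep in df["sequence"].unique():
                for h in _occurrences(pep, canonical_protein):
                    out.append((h + 1, h + len(pep)))
            return out

        cfg = SimulationConfig(seed=2)
        obs_short, _ = simulate_peptides(cfg, short_protein)
        assert infer_isoform_support(spans(obs_short), delta) == "short_supported"

        obs_full, _ = simulate_peptides(
            cfg, short_protein, scenario="full_length",
            canonical_protein=canonical_protein,
        )
        assert infer_isoform_support(spans(obs_full), delta) == "full_length_supported"
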