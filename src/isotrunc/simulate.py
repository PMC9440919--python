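"""Synthetic ground-truth data with the statistical structure of the study.

The default configuration emulates a 28-exon receptor transcript whose
treatment-induced short isoform is restricted to exons 23-28: a planted
canonical ORF (ATG in exon 1, stop in exon 28, ~1350 aa, ~150 kDa), a
planted in-frame ATG at the start of exon k encoding a ~250 aa / ~28 kDa
C-terminal fragment, a transmembrane domain entirely within the
fragment-free N-terminal region, negative-binomial exon counts, chromatin
tracks with a repressive 5'-body signal plus a local active-mark peak at
the breakpoint, and condition-dependent peptide intensities confined to the
shared C-terminal region.

All generators are deterministic given the configuration seed; the seed
fans out to per-generator substreams so adding one generator never perturbs
another.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genemodel import (
    DomainAnnotation,
    Exon,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    write_annotation,
)
from .orfscan import STOP_CODONS
from .promoter import ACTIVE_MARKS, REPRESSIVE_MARK, SignalTrack
from .proteomics import tryptic_digest

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

# substream ids for the per-generator RNGs
_STREAMS = {"gene": 0, "counts": 1, "chip": 2, "peptides": 3}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults encode the emulated design."""

    seed: int = 0
    # gene model
    n_exons: int = 28
    exon_length: int = 150
    intron_length: int = 300
    flank: int = 500
    strand: str = "+"
    chrom: str = "chrSim"
    k: int = 23  # first exon of the short isoform
    short_orf_aa: int = 250  # ~28 kDa at 111.9 Da/residue of codon-random sequence
    # exon counts
    depth: float = 100.0  # expected reads per expressed exon
    expression_ratio: float = 50.0  # theta_on / theta_off
    nb_dispersion: float = 0.2
    library_background: int = 200_000_000  # rest-of-transcriptome mapped reads
    n_replicates: int = 3
    # chromatin tracks
    chip_bin: int = 50
    chip_flank: int = 40_000
    chip_peak_fold: float = 5.0
    chip_peak_halfwidth: int = 2000
    chip_noise_sd: float = 0.2  # as a fraction of background
    # peptides
    peptide_fold: float = 2.0
    peptide_cv: float = 0.2
    detection_prob: float = 0.9
    n_signature_peptides: int = 6
    target_coverage: float = 0.4
    base_auc: float = 1.0e5
    peptide_base_spread: float = 0.5  # sd of per-peptide log response

    def __post_init__(self) -> None:
        if not (2 <= self.k <= self.n_exons):
            raise ValueError("k must lie in 2..n_exons")
        for name in (
            "n_exons", "exon_length", "intron_length", "depth",
            "expression_ratio", "library_background", "n_replicates",
            "chip_bin", "chip_peak_fold", "peptide_fold", "base_auc",
            "short_orf_aa",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0 or self.chip_noise_sd < 0 or self.peptide_cv < 0:
            raise ValueError("dispersion/noise parameters must be non-negative")
        if not (0 < self.detection_prob <= 1):
            raise ValueError("detection_prob must be in (0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


@dataclass
class SyntheticGene:
    """Bundle returned by :func:`simulate_gene_model`."""

    transcript: TranscriptModel
    genome: dict[str, str]
    domains: list[DomainAnnotation]
    transcript_seq: str
    short_start_nt: int  # transcript coordinate of the planted short ATG

    @property
    def canonical_protein_length(self) -> int:
        t = self.transcript
        return (t.cds_stop - t.cds_start) // 3


def simulate_gene_model(cfg: SimulationConfig) -> SyntheticGene:
    """Deterministic gene locus with planted canonical and short ORFs."""
    rng = cfg.rng("gene")
    E, L_ex = cfg.n_exons, cfg.exon_length
    tlen = E * L_ex
    short_start = (cfg.k - 1) * L_ex
    cds_stop = short_start + 3 * cfg.short_orf_aa
    if cds_stop < (E - 1) * L_ex or cds_stop + 3 > tlen:
        raise ValueError(
            "short_orf_aa incompatible with exon layout: the canonical stop "
            "codon must fall inside the last exon"
        )
    cds_start = short_start % 3 + 9  # short ATG in frame with the canonical ORF
    n_codons = (cds_stop - cds_start) // 3

    codons = list(rng.choice(_SENSE_CODONS, size=n_codons))
    codons[0] = "ATG"
    codons[(short_start - cds_start) // 3] = "ATG"
    coding = "".join(codons)
    utr5 = "".join(rng.choice(list("ACGT"), size=cds_start))
    tail_len = tlen - cds_stop - 3
    tail = "".join(rng.choice(list("ACGT"), size=tail_len))
    tseq = utr5 + coding + "TAA" + tail
    assert len(tseq) == tlen

    # genomic layout: exons left->right separated by introns, flanked
    glen = 2 * cfg.flank + E * L_ex + (E - 1) * cfg.intron_length
    genome = list(rng.choice(list("ACGT"), size=glen))
    exons = []
    for i in range(E):  # i: genomic order left->right
        gstart = cfg.flank + i * (L_ex + cfg.intron_length)
        index = i + 1 if cfg.strand == "+" else E - i
        segment = tseq[(index - 1) * L_ex : index * L_ex]
        placed = segment if cfg.strand == "+" else reverse_complement(segment)
        genome[gstart : gstart + L_ex] = list(placed)
        exons.append(
            Exon(GenomicInterval(cfg.chrom, gstart, gstart + L_ex, cfg.strand), index)
        )
    exons.sort(key=lambda e: e.index)
    t = TranscriptModel("tx_short_locus", "gene_short_locus", exons, cds_start, cds_stop)

    canonical_aa = n_codons
    delta = canonical_aa - cfg.short_orf_aa
    # transmembrane domain entirely N-terminal of the short ORF's offset,
    # anchored around the exon-17-equivalent position when it fits there
    tm_anchor = max(1, ((16 * L_ex) - cds_start) // 3)
    tm_start = min(tm_anchor, max(1, delta - 25))
    tm_end = min(tm_start + 20, delta)
    domains = [DomainAnnotation("transmembrane", tm_start, tm_end)]
    if canonical_aa > 60:
        domains.append(
            DomainAnnotation("c_terminal", canonical_aa - 50, canonical_aa - 10)
        )

    gene = SyntheticGene(t, {cfg.chrom: "".join(genome)}, domains, tseq, short_start)
    assert gene.transcript.spliced_sequence(gene.genome) == tseq
    return gene


# ---------------------------------------------------------------------------
# Exon counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu * (1 + dispersion).

    ``dispersion`` is the fractional variance excess over Poisson, constant
    across expression levels; dispersion -> 0 recovers the Poisson limit.
    """
    out = np.zeros(mu.shape, dtype=int)
    pos = mu > 0
    if not pos.any():
        return out
    if dispersion == 0:
        out[pos] = rng.poisson(mu[pos])
    else:
        n = mu[pos] / dispersion  # Var = mu + mu^2/n = mu (1 + dispersion)
        p = 1.0 / (1.0 + dispersion)
        out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_counts(
    cfg: SimulationConfig,
    state: str,
    n_samples: int | None = None,
    prefix: str = "sample",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Negative-binomial per-exon counts under an isoform state.

    ``state`` is ``"full"`` (all exons expressed), ``"short"`` (exons k..E
    expressed, 5' exons at the off level) or ``"off"`` (all off).  Returns a
    counts DataFrame (exon index x sample) and per-sample library sizes
    (sum of counts plus the configured transcriptome background).
    """
    if state not in ("full", "short", "off"):
        raise ValueError(f"unknown isoform state {state!r}")
    rng = rng if rng is not None else cfg.rng("counts")
    n_samples = n_samples if n_samples is not None else cfg.n_replicates
    mu_on = cfg.depth
    mu_off = 0.0 if math.isinf(cfg.expression_ratio) else cfg.depth / cfg.expression_ratio
    mu = np.full(cfg.n_exons, mu_off)
    if state == "full":
        mu[:] = mu_on
    elif state == "short":
        mu[cfg.k - 1 :] = mu_on

    counts = {}
    libs = {}
    for i in range(n_samples):
        name = f"{prefix}_{i + 1}"
        c = _nb_draw(rng, mu, cfg.nb_dispersion)
        counts[name] = c
        libs[name] = int(c.sum()) + cfg.library_background
    idx = pd.Index(range(1, cfg.n_exons + 1), name="exon_index")
    return pd.DataFrame(counts, index=idx), libs


def simulate_reads_bed(
    t: TranscriptModel,
    counts: np.ndarray,
    path: str | Path,
    read_length: int = 50,
    rng: np.random.Generator | None = None,
) -> None:
    """Write single-end reads realizing exact per-exon counts as 6-column BED.

    Each read is placed uniformly within its exon, so re-counting the BED
    reproduces ``counts`` for any ``min_overlap <= read_length``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    lines = []
    for e, n in zip(t.exons, counts):
        iv = e.interval
        span = len(e) - read_length
        if span < 0:
            raise ValueError("read_length exceeds exon length")
        for j in range(int(n)):
            s = iv.start + int(rng.integers(0, span + 1))
            lines.append(
                f"{iv.chrom}\t{s}\t{s + read_length}\tread_e{e.index}_{j}\t0\t{iv.strand}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Chromatin tracks
# ---------------------------------------------------------------------------


def simulate_chip_tracks(
    cfg: SimulationConfig,
    t: TranscriptModel,
    scenario: str = "alternative_promoter",
    rng: np.random.Generator | None = None,
) -> dict[str, SignalTrack]:
    """Binned chromatin tracks over the locus with generous flanks.

    Scenarios: ``alternative_promoter`` (active-mark peak at the exon-k
    boundary, H3K27me3 over the 5' body), ``canonical`` (active-mark peak at
    the canonical TSS only), ``flat`` (background everywhere).
    """
    if scenario not in ("alternative_promoter", "canonical", "flat"):
        raise ValueError(f"unknown chip scenario {scenario!r}")
    rng = rng if rng is not None else cfg.rng("chip")
    span = t.genomic_span
    lo = max(0, span.start - cfg.chip_flank)
    # keep the displayed window length constant near a chromosome edge
    deficit = cfg.chip_flank - (span.start - lo)
    hi = span.end + cfg.chip_flank + deficit
    starts = np.arange(lo, hi, cfg.chip_bin)
    ends = np.minimum(starts + cfg.chip_bin, hi)
    mids = (starts + ends) / 2.0

    def noisy_background() -> np.ndarray:
        return np.clip(1.0 + rng.normal(0.0, cfg.chip_noise_sd, size=starts.size), 0.0, None)

    gain = cfg.chip_peak_fold - 1.0
    alt_anchor = t.exon_5prime_genomic(cfg.k)
    tss = t.exon_5prime_genomic(1)
    body_ivs = [e.interval for e in t.exons[: cfg.k - 1]]
    body_lo = min(iv.start for iv in body_ivs)
    body_hi = max(iv.end for iv in body_ivs)

    tracks = {}
    for mark in ACTIVE_MARKS:
        values = noisy_background()
        if scenario == "alternative_promoter":
            in_peak = np.abs(mids - alt_anchor) <= cfg.chip_peak_halfwidth
            values[in_peak] += gain
        elif scenario == "canonical":
            in_peak = np.abs(mids - tss) <= cfg.chip_peak_halfwidth
            values[in_peak] += gain
        tracks[mark] = SignalTrack(mark, scenario, t.chrom, starts, ends, values)

    values = noisy_background()
    if scenario == "alternative_promoter":
        in_body = (mids >= body_lo) & (mids < body_hi)
        values[in_body] += gain
    tracks[REPRESSIVE_MARK] = SignalTrack(
        REPRESSIVE_MARK, scenario, t.chrom, starts, ends, values
    )
    return tracks


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------


def select_signature_peptides(
    protein: str,
    n: int = 6,
    target_coverage: float = 0.4,
    min_len: int = 6,
    max_len: int = 30,
) -> list:
    """Pick ``n`` fully-cleaved tryptic peptides whose combined footprint is
    closest to ``target_coverage`` of the protein.

    Deterministic subset-sum selection over the (non-overlapping, hence
    additive) fully-cleaved peptides; emulates a curated set of signature
    peptides that together cover a stated fraction of the protein.
    """
    peps = tryptic_digest(protein, missed_cleavages=0, min_len=min_len, max_len=max_len)
    if len(peps) <= n:
        return peps
    target = round(target_coverage * len(protein))
    lengths = [len(p.sequence) for p in peps]
    max_sum = sum(sorted(lengths, reverse=True)[:n])
    # dp[j] = set of achievable footprint sums using exactly j peptides
    dp: list[dict[int, int]] = [dict() for _ in range(n + 1)]
    dp[0][0] = -1
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    for i, ln in enumerate(lengths):
        for j in range(min(n, i + 1), 0, -1):
            for s in list(dp[j - 1]):
                s2 = s + ln
                if s2 <= max_sum and s2 not in dp[j]:
                    dp[j][s2] = i
                    parent[(j, s2)] = (j - 1, s)
    best = min(dp[n], key=lambda s: (abs(s - target), s))
    chosen = []
    j, s = n, best
    while j > 0:
        i = dp[j][s]
        chosen.append(peps[i])
        j, s = parent[(j, s)]
    chosen.sort(key=lambda p: p.start)
    return chosen


def simulate_peptides(
    cfg: SimulationConfig,
    short_protein: str,
    scenario: str = "short",
    canonical_protein: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Peptide-observation table for control vs treated samples.

    Signature peptides of the short protein carry a treatment-induced fold
    change with per-peptide lognormal response and per-sample lognormal
    noise; each peptide is observed per sample with ``detection_prob``.
    Under ``scenario="full_length"`` two N-exclusive peptides of the
    canonical protein are additionally emitted (constant across
    conditions), so the support verdict flips to full-length.
    Returns (observations, signature peptide sequences).
    """
    if scenario not in ("short", "full_length"):
        raise ValueError(f"unknown peptide scenario {scenario!r}")
    rng = rng if rng is not None else cfg.rng("peptides")
    signature = select_signature_peptides(
        short_protein, cfg.n_signature_peptides, cfg.target_coverage
    )
    if not signature:
        raise ValueError("short protein yields no usable tryptic peptides")
    sigma = math.sqrt(math.log(1.0 + cfg.peptide_cv**2))
    base = cfg.base_auc * np.exp(
        rng.normal(0.0, cfg.peptide_base_spread, size=len(signature))
    )

    extra = []
    if scenario == "full_length":
        if canonical_protein is None:
            raise ValueError("full_length scenario needs the canonical protein")
        delta = len(canonical_protein) - len(short_protein)
        n_term = [
            p
            for p in tryptic_digest(canonical_protein, 0, min_len=6, max_len=30)
            if p.end <= delta
        ]
        extra = n_term[:2]

    rows = []
    for condition, fold in (("control", 1.0), ("treated", cfg.peptide_fold)):
        for r in range(cfg.n_replicates):
            sample = f"{condition}_{r + 1}"
            detected = rng.random(len(signature)) < cfg.detection_prob
            if not detected.any():
                detected[0] = True
            noise = np.exp(rng.normal(0.0, sigma, size=len(signature))) if sigma else np.ones(
                len(signature)
            )
            for i, pep in enumerate(signature):
                if not detected[i]:
                    continue
                total = base[i] * fold * noise[i]
                for frac in (0.5, 0.3, 0.2):  # three fragment-ion rows
                    rows.append((pep.sequence, sample, condition, total * frac))
            for pep in extra:
                rows.append((pep.sequence, sample, condition, cfg.base_auc))
    df = pd.DataFrame(rows, columns=["sequence", "sample", "condition", "auc"])
    return df, [p.sequence for p in signature]


# ---------------------------------------------------------------------------
# Fixture directory
# ---------------------------------------------------------------------------


def write_fixture_dir(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Write a complete plain-text fixture set for the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene = simulate_gene_model(cfg)
    t = gene.transcript

    chrom = cfg.chrom
    with open(outdir / "genome.fa", "w") as fh:
        seq = gene.genome[chrom]
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    write_annotation([t], outdir / "annotation.gtf")
    with open(outdir / "domains.tsv", "w") as fh:
        fh.write("name\taa_start\taa_end\n")
        for d in gene.domains:
            fh.write(f"{d.name}\t{d.aa_start}\t{d.aa_end}\n")

    rng = cfg.rng("counts")
    treated, lib_t = simulate_counts(cfg, "short", prefix="treated", rng=rng)
    control, lib_c = simulate_counts(cfg, "off", prefix="control", rng=rng)
    counts = pd.concat([control, treated], axis=1)
    counts.to_csv(outdir / "exon_counts.tsv", sep="\t")
    libs = {**lib_c, **lib_t}
    with open(outdir / "library_sizes.tsv", "w") as fh:
        fh.write("sample\tlibrary_size\n")
        for s, v in libs.items():
            fh.write(f"{s}\t{v}\n")

    for mark, track in simulate_chip_tracks(cfg, t, "alternative_promoter").items():
        track.to_bedgraph(outdir / f"chip_{mark}.bedGraph")

    from .orfscan import translate

    short_protein = translate(
        gene.transcript_seq[gene.short_start_nt : t.cds_stop]
    )
    obs, signature = simulate_peptides(cfg, short_protein)
    obs.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
    (outdir / "signature_peptides.txt").write_text("\n".join(signature) + "\n")
    cfg.to_json(outdir / "simulation_config.json")
    return outdir
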