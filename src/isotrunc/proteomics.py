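"""Proteogenomic peptide evidence: digestion, mapping, support, quantification.

The short isoform is a C-terminal suffix of the canonical protein, so
peptide evidence can only discriminate the isoforms through the N-terminal
region unique to the full-length protein: any peptide requiring residues
from that region ("N-exclusive") implies the full-length protein, while a
set of shared peptides with no N-exclusive hit supports the short isoform.
Label-free abundance is the XIC area summed per peptide and averaged over
the isoform-unique peptide set per sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as _pparser
from scipy import stats

log = logging.getLogger(__name__)

#: cleave C-terminal to K/R except before P
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class Peptide:
    """A digestion product with 1-based inclusive coordinates on its protein."""

    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates do not match its length")


def tryptic_digest(
    protein: str,
    missed_cleavages: int = 0,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[Peptide]:
    """In-silico tryptic digestion with positions.

    Returns every product with at most ``missed_cleavages`` internal uncut
    sites, filtered to ``min_len <= length <= max_len``, sorted by start
    position then length.
    """
    if max_len is not None and min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    seen = set()
    peptides = []
    for pos, pep in _pparser.icleave(
        protein, TRYPSIN_RULE, missed_cleavages=missed_cleavages
    ):
        if (pos, pep) in seen:  # icleave may emit terminal duplicates
            continue
        seen.add((pos, pep))
        if len(pep) < min_len or (max_len is not None and len(pep) > max_len):
            continue
        peptides.append(Peptide(pep, pos + 1, pos + len(pep)))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


# ---------------------------------------------------------------------------
# Mapping & coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageReport:
    protein_length: int
    covered: set[int] = field(default_factory=set)  # 1-based residues
    n_peptides_mapped: int = 0
    unmatched: list[str] = field(default_factory=list)

    @property
    def coverage_pct(self) -> float:
        return 100.0 * len(self.covered) / self.protein_length

    def to_dict(self) -> dict:
        return {
            "protein_length": self.protein_length,
            "n_covered_residues": len(self.covered),
            "coverage_pct": self.coverage_pct,
            "n_peptides_mapped": self.n_peptides_mapped,
            "unmatched": list(self.unmatched),
        }


def _occurrences(peptide: str, protein: str) -> list[int]:
    """0-based start offsets of every exact occurrence."""
    hits, i = [], protein.find(peptide)
    while i != -1:
        hits.append(i)
        i = protein.find(peptide, i + 1)
    return hits


def map_peptides(
    observed: Iterable[str], protein: str, equate_il: bool = False
) -> CoverageReport:
    """Map peptides onto a protein by exact string match at every occurrence.

    ``equate_il`` folds isoleucine and leucine together before matching
    (isobaric residues indistinguishable by mass).  Unmatched peptides are
    reported, never raised.
    """
    target = protein.replace("I", "L") if equate_il else protein
    report = CoverageReport(protein_length=len(protein))
    for pep in observed:
        query = pep.replace("I", "L") if equate_il else pep
        hits = _occurrences(query, target)
        if not hits:
            report.unmatched.append(pep)
            continue
        report.n_peptides_mapped += 1
        for h in hits:
            report.covered.update(range(h + 1, h + len(pep) + 1))
    return report


def infer_isoform_support(
    mapped_spans: Sequence[tuple[int, int]], delta: int, m_min: int = 2
) -> str:
    """Infer isoform support from peptide spans on the canonical protein.

    ``mapped_spans`` are 1-based inclusive (start, end) residue spans.  A
    peptide is N-exclusive when it includes any residue at or before
    ``delta`` (a straddling peptide still requires N-terminal sequence).
    Returns ``full_length_supported`` on >= 1 N-exclusive peptide,
    ``short_supported`` on 0 N-exclusive and >= ``m_min`` shared peptides,
    else ``ambiguous``.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    n_exclusive = sum(1 for s, _ in mapped_spans if s <= delta)
    shared = sum(1 for s, _ in mapped_spans if s > delta)
    if n_exclusive >= 1:
        return "full_length_supported"
    if shared >= m_min:
        return "short_supported"
    return "ambiguous"


# ---------------------------------------------------------------------------
# Label-free quantification
# ---------------------------------------------------------------------------


@dataclass
class QuantResult:
    sample_averages: dict[str, float]
    group_means: dict[str, float]
    fold_change: float
    t_statistic: float | None
    p_value: float | None
    control: str
    treated: str
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_averages": self.sample_averages,
            "group_means": self.group_means,
            "fold_change": self.fold_change,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "control": self.control,
            "treated": self.treated,
            "flags": list(self.flags),
        }


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Peptide-evidence TSV: columns sequence, sample, condition, auc.

    Repeated rows per fragment ion are allowed and summed downstream.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sequence", "sample", "condition", "auc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table lacks column(s): {sorted(missing)}")
    if (df["auc"] < 0).any():
        raise ValueError("negative XIC areas in peptide table")
    return df


def quantify(
    observations: pd.DataFrame,
    unique_peptides: Iterable[str],
    control: str = "control",
    treated: str = "treated",
) -> QuantResult:
    """Summed-XIC label-free quantification of isoform-unique peptides.

    Per peptide and sample the fragment-ion areas are summed; per sample the
    summed areas are averaged over the unique-peptide set (peptides missing
    in a sample are excluded from that sample's mean and flagged).  The fold
    change is treated/control on group means of the sample averages; the
    test is a Welch unpaired two-sided t-test on log2 sample averages.
    """
    unique = set(unique_peptides)
    if not unique:
        raise ValueError("empty unique-peptide set")
    df = observations[observations["sequence"].isin(unique)]
    if df.empty:
        raise ValueError("no observations of any unique peptide")

    per_pep = df.groupby(["sample", "sequence"], sort=True)["auc"].sum()
    sample_avgs = per_pep.groupby("sample").mean()

    flags = []
    for sample, grp in per_pep.groupby("sample"):
        missing = unique - set(grp.index.get_level_values("sequence"))
        if missing:
            flags.append(
                f"sample {sample}: {len(missing)} unique peptide(s) unobserved"
            )

    cond = observations.drop_duplicates("sample").set_index("sample")["condition"]
    groups = {
        g: [s for s in sample_avgs.index if cond.get(s) == g]
        for g in (control, treated)
    }
    for g, samples in groups.items():
        if not samples:
            raise ValueError(f"condition {g!r} has no samples with unique-peptide data")

    means = {g: float(sample_avgs[s].mean()) for g, s in groups.items()}
    fold = means[treated] / means[control] if means[control] > 0 else (
        0.0 if means[treated] == 0 else float("inf")
    )

    t_stat = p_val = None
    a = sample_avgs[groups[control]].to_numpy(float)
    b = sample_avgs[groups[treated]].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        flags.append("a condition has <2 samples; t-test skipped")
        warnings.warn("t-test skipped: a condition has <2 samples", stacklevel=2)
    elif np.any(a <= 0) or np.any(b <= 0):
        flags.append("zero sample average; log-scale t-test skipped")
        warnings.warn("t-test skipped: zero sample average on log scale", stacklevel=2)
    else:
        if np.allclose(np.log2(a), np.log2(a).mean()) and np.allclose(
            np.log2(b), np.log2(b).mean()
        ) and np.isclose(np.log2(a).mean(), np.log2(b).mean()):
            t_stat, p_val = 0.0, 1.0
        else:
            res = stats.ttest_ind(np.log2(b), np.log2(a), equal_var=False)
            t_stat, p_val = float(res.statistic), float(res.pvalue)

    return QuantResult(
        sample_averages={s: float(v) for s, v in sample_avgs.items()},
        group_means=means,
        fold_change=float(fold),
        t_statistic=t_stat,
        p_value=p_val,
        control=control,
        treated=treated,
        flags=flags,
    )


def select_unique_peptides(
    peptides: Sequence[Peptide],
    background_proteome: Mapping[str, str] | None = None,
    target_ids: Iterable[str] = (),
) -> list[Peptide]:
    """Filter digestion products to those unique to the target protein.

    A peptide is kept when it occurs in no background-proteome entry other
    than the target itself.  Without a background proteome all peptides are
    kept (uniqueness is then the caller's responsibility).
    """
    if background_proteome is None:
        return list(peptides)
    skip = set(target_ids)
    out = []
    for p in peptides:
        hit = any(
            p.sequence in seq
            for pid, seq in background_proteome.items()
            if pid not in skip
        )
        if not hit:
            out.append(p)
    return out
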