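"""Stop-anchored ORF prediction and domain-loss assessment.

Candidate start codons are ATGs in frame with, and upstream of, the
canonical stop codon, with no intervening in-frame stop — so every
candidate protein is a C-terminal suffix of the canonical protein and all
ORFs terminate at the identical stop.  Masses are average (not
monoisotopic) molecular masses, the scale on which SDS-PAGE band sizes are
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq
from pyteomics import mass as _pmass

from .genemodel import DomainAnnotation, TranscriptModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
WATER_DA = 18.0153
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def find_inframe_starts(
    seq: str, cds_stop: int, search_window: tuple[int, int] | None = None
) -> list[int]:
    """All ATG positions in-frame with ``cds_stop`` and free of internal stops.

    ``search_window`` is a half-open transcript-coordinate interval limited
    to ``[0, cds_stop)``; ``None`` scans the whole upstream sequence.
    Positions are returned in ascending order (longest ORF first).
    """
    seq = seq.upper()
    if seq[cds_stop : cds_stop + 3] not in STOP_CODONS:
        raise ValueError(
            f"cds_stop={cds_stop} is not a stop codon "
            f"({seq[cds_stop:cds_stop + 3]!r})"
        )
    lo, hi = search_window if search_window is not None else (0, cds_stop)
    if lo < 0 or hi > cds_stop:
        raise ValueError("search window must lie within [0, cds_stop)")

    starts = []
    # walk the stop-anchored frame backwards; the first in-frame stop
    # encountered invalidates every position further upstream
    p = cds_stop - 3
    while p >= 0:
        codon = seq[p : p + 3]
        if codon in STOP_CODONS:
            break
        if codon == "ATG" and lo <= p < hi:
            starts.append(p)
        p -= 3
    return starts[::-1]


def translate(seq: str) -> str:
    """Translate an ATG-anchored coding sequence (stop codon excluded)."""
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("coding sequence length must be a multiple of 3")
    bad = next((i for i, c in enumerate(seq) if c not in "ACGT"), None)
    if bad is not None:
        raise ValueError(f"ambiguous/invalid base {seq[bad]!r} at position {bad}")
    protein = str(Seq(seq).translate())
    if "*" in protein:
        raise ValueError(
            f"internal stop codon at codon {protein.index('*') + 1}"
        )
    return protein


def protein_mass(protein: str) -> float:
    """Average molecular mass in Da (residue masses + one water)."""
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")
    return float(_pmass.calculate_mass(sequence=protein, average=True))


@dataclass
class OrfCandidate:
    """A stop-anchored ORF candidate within the short transcript."""

    start_nt: int
    start_exon: int
    protein: str
    mass_da: float
    delta: int | None = None  # N-terminal offset vs the canonical protein
    domains_lost: list[str] = field(default_factory=list)
    domains_retained: list[str] = field(default_factory=list)
    domains_truncated: list[str] = field(default_factory=list)

    @property
    def length_aa(self) -> int:
        return len(self.protein)

    @property
    def mass_kda(self) -> float:
        return round(self.mass_da / 1000.0, 1)


def enumerate_orfs(
    t: TranscriptModel,
    spliced_seq: str,
    search_window: tuple[int, int] | None = None,
) -> list[OrfCandidate]:
    """Stop-anchored ORF candidates for a transcript with a canonical CDS.

    The default ``search_window`` spans the full region upstream of the
    canonical stop; the boundary module's breakpoint is typically used to
    restrict it to the expressed short-transcript region.
    """
    if not t.has_cds:
        raise ValueError(f"transcript {t.transcript_id} has no annotated CDS")
    starts = find_inframe_starts(spliced_seq, t.cds_stop, search_window)
    out = []
    for p in starts:
        protein = translate(spliced_seq[p : t.cds_stop])
        out.append(
            OrfCandidate(
                start_nt=p,
                start_exon=t.transcript_pos_to_exon_index(p),
                protein=protein,
                mass_da=protein_mass(protein),
            )
        )
    return out


def assess_domains(
    c: OrfCandidate,
    domains: Sequence[DomainAnnotation],
    canonical_length: int,
    canonical_protein: str | None = None,
) -> OrfCandidate:
    """Partition canonical domains into lost / retained / truncated.

    With N-terminal offset ``delta = canonical_length - length_aa``, a
    domain is lost when it ends at or before the offset, retained when it
    starts after it, truncated when it straddles it.  When the canonical
    protein sequence is supplied the C-terminal suffix relationship is
    verified first.
    """
    delta = canonical_length - c.length_aa
    if delta < 0:
        raise ValueError("candidate is longer than the canonical protein")
    if canonical_protein is not None and not canonical_protein.endswith(c.protein):
        raise ValueError("short ORF is not a C-terminal fragment of the canonical protein")
    for d in domains:
        if d.aa_end > canonical_length:
            raise ValueError(f"domain {d.name} exceeds canonical protein length")
    c.delta = delta
    c.domains_lost = [d.name for d in domains if d.aa_end <= delta]
    c.domains_retained = [d.name for d in domains if d.aa_start > delta]
    c.domains_truncated = [
        d.name for d in domains if d.aa_start <= delta < d.aa_end
    ]
    return c


def candidates_to_tsv(candidates: Sequence[OrfCandidate], path: str | Path) -> None:
    rows = [
        "start_nt\tstart_exon\tlength_aa\tmass_da\tmass_kda\tdelta\t"
        "domains_lost\tdomains_retained\tdomains_truncated"
    ]
    for c in candidates:
        rows.append(
            f"{c.start_nt}\t{c.start_exon}\t{c.length_aa}\t{c.mass_da:.2f}\t"
            f"{c.mass_kda}\t{'' if c.delta is None else c.delta}\t"
            f"{','.join(c.domains_lost)}\t{','.join(c.domains_retained)}\t"
            f"{','.join(c.domains_truncated)}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def candidates_to_fasta(
    candidates: Sequence[OrfCandidate], path: str | Path, prefix: str = "orf"
) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f">{prefix}_start{c.start_nt}_exon{c.start_exon} "
                f"{c.length_aa}aa {c.mass_kda}kDa\n{c.protein}\n"
            )
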