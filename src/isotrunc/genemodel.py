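"""Gene/transcript data model and coordinate arithmetic.

Internal coordinates are 0-based half-open throughout; GTF/GFF3 input
(1-based inclusive) is converted at the parsing boundary.  Exon indices are
1-based and follow transcript 5'->3' order, i.e. for a minus-strand
transcript exon 1 is the exon with the largest genomic start.  Transcript
("spliced") coordinates are 0-based nucleotide offsets along the
exon-concatenated mRNA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class NotExonicError(ValueError):
    """A genomic position does not fall inside any exon of the transcript."""


class AnnotationError(ValueError):
    """Malformed or unusable annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Exon:
    """An exon with its 1-based position in transcript 5'->3' order."""

    interval: GenomicInterval
    index: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("exon index is 1-based")

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain on the canonical protein, 1-based inclusive."""

    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(f"bad domain coordinates for {self.name}")


@dataclass
class TranscriptModel:
    """Ordered exon structure plus canonical CDS in transcript coordinates.

    ``cds_start`` is the transcript offset of the A of the canonical ATG and
    ``cds_stop`` the offset of the first nucleotide of the canonical stop
    codon; both are ``None`` for non-coding transcripts, which disables the
    ORF stage downstream.
    """

    transcript_id: str
    gene_id: str
    exons: list[Exon] = field(default_factory=list)
    cds_start: int | None = None
    cds_stop: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        idx = [e.index for e in self.exons]
        if idx != list(range(1, len(self.exons) + 1)):
            raise ValueError("exon indices must be consecutive from 1")
        strand = self.strand
        starts = [e.interval.start for e in self.exons]
        ordered = starts == sorted(starts) if strand == "+" else starts == sorted(
            starts, reverse=True
        )
        if not ordered:
            raise ValueError("exon order does not follow strand 5'->3'")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.interval.overlap(b.interval) > 0:
                raise ValueError("exons overlap")
        if self.cds_start is not None and self.cds_stop is not None:
            if not (0 <= self.cds_start < self.cds_stop):
                raise ValueError("cds_start must precede cds_stop")
            if (self.cds_stop - self.cds_start) % 3:
                raise ValueError("CDS length not a multiple of 3")
            if self.cds_stop + 3 > self.length:
                raise ValueError("stop codon extends past transcript end")

    # -- basic geometry ------------------------------------------------

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [len(e) for e in self.exons]

    @property
    def genomic_span(self) -> GenomicInterval:
        starts = [e.interval.start for e in self.exons]
        ends = [e.interval.end for e in self.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.cds_stop is not None

    def exon_5prime_genomic(self, index: int) -> int:
        """Genomic coordinate of the 5' end of exon ``index`` (strand-aware)."""
        e = self.exons[index - 1].interval
        return e.start if self.strand == "+" else e.end

    # -- coordinate conversion -----------------------------------------

    def genomic_to_transcript(self, g: int) -> int:
        offset = 0
        for e in self.exons:
            iv = e.interval
            if iv.start <= g < iv.end:
                within = g - iv.start if self.strand == "+" else iv.end - 1 - g
                return offset + within
            offset += len(e)
        raise NotExonicError(
            f"position {g} is not exonic in transcript {self.transcript_id}"
        )

    def transcript_to_genomic(self, p: int) -> int:
        if p < 0 or p >= self.length:
            raise ValueError(f"transcript position {p} out of range")
        offset = 0
        for e in self.exons:
            if p < offset + len(e):
                within = p - offset
                iv = e.interval
                return iv.start + within if self.strand == "+" else iv.end - 1 - within
            offset += len(e)
        raise AssertionError("unreachable")

    def transcript_pos_to_exon_index(self, p: int) -> int:
        if p < 0 or p >= self.length:
            raise ValueError(f"transcript position {p} out of range")
        offset = 0
        for e in self.exons:
            if p < offset + len(e):
                return e.index
            offset += len(e)
        raise AssertionError("unreachable")

    # -- sequence ------------------------------------------------------

    def spliced_sequence(self, genome: Mapping[str, object]) -> str:
        """Concatenated exon sequence 5'->3' from a FASTA accessor.

        ``genome`` may be a plain dict of chromosome strings or a
        ``pyfaidx.Fasta`` object (anything supporting ``genome[chrom]`` with
        string slicing).
        """
        try:
            contig = genome[self.chrom]
        except KeyError:
            raise KeyError(f"chromosome {self.chrom!r} absent from genome FASTA")
        contig_len = len(contig)
        parts = []
        for e in sorted(self.exons, key=lambda x: x.interval.start):
            iv = e.interval
            if iv.end > contig_len:
                raise ValueError(
                    f"exon {iv.start}-{iv.end} beyond end of contig "
                    f"{self.chrom} (length {contig_len})"
                )
            parts.append(str(contig[iv.start : iv.end]))
        seq = "".join(parts).upper()
        return seq if self.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def _transcript_from_features(
    tid: str, exon_feats: list, cds_feats: list
) -> TranscriptModel:
    strand = exon_feats[0].strand
    if strand not in ("+", "-"):
        raise AnnotationError(f"transcript {tid}: undefined strand {strand!r}")
    gene_id = exon_feats[0].attributes.get("gene_id", [tid])[0]
    # gffutils features are 1-based inclusive -> 0-based half-open
    ivs = sorted(
        (GenomicInterval(f.seqid, f.start - 1, f.end, strand) for f in exon_feats),
        key=lambda iv: iv.start,
        reverse=(strand == "-"),
    )
    exons = [Exon(iv, i + 1) for i, iv in enumerate(ivs)]
    model = TranscriptModel(tid, gene_id, exons)
    if cds_feats:
        cds_len = sum(f.end - f.start + 1 for f in cds_feats)
        # first CDS base in transcript orientation
        if strand == "+":
            g_first = min(f.start for f in cds_feats) - 1
        else:
            g_first = max(f.end for f in cds_feats) - 1
        cds_start = model.genomic_to_transcript(g_first)
        model = TranscriptModel(tid, gene_id, exons, cds_start, cds_start + cds_len)
    else:
        log.warning("transcript %s has no CDS; ORF stage disabled for it", tid)
    return model


def read_annotation(path: str | Path) -> dict[str, TranscriptModel]:
    """Parse a GTF/GFF3 file into transcript models keyed by transcript id.

    The dialect is auto-detected by gffutils from the attribute column.
    Transcripts lacking CDS features are returned with ``cds_start`` /
    ``cds_stop`` set to ``None`` and a warning is logged.
    """
    path = Path(path)
    text = path.read_text()
    body = [
        (i, line)
        for i, line in enumerate(text.splitlines(), start=1)
        if line.strip() and not line.startswith("#")
    ]
    if not body:
        warnings.warn(f"annotation file {path} contains no features", stacklevel=2)
        return {}
    for lineno, line in body:
        if len(line.split("\t")) < 9:
            raise AnnotationError(
                f"{path}:{lineno}: malformed feature line "
                f"(expected 9 tab-separated columns): {line!r}"
            )
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc

    exon_by_tid: dict[str, list] = {}
    cds_by_tid: dict[str, list] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        if not tids:
            raise AnnotationError(
                f"{feat.featuretype} feature without transcript_id/Parent "
                f"at {feat.seqid}:{feat.start}-{feat.end}"
            )
        bucket = exon_by_tid if feat.featuretype == "exon" else cds_by_tid
        for tid in tids:
            bucket.setdefault(tid, []).append(feat)

    models = {}
    for tid, exon_feats in exon_by_tid.items():
        models[tid] = _transcript_from_features(tid, exon_feats, cds_by_tid.get(tid, []))
    return models


def write_annotation(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Serialize transcript models as GTF (exon + CDS features)."""
    lines = []
    for t in models:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        for e in sorted(t.exons, key=lambda x: x.interval.start):
            iv = e.interval
            lines.append(
                f"{iv.chrom}\tisotrunc\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}"
            )
        if t.has_cds:
            # CDS excludes the stop codon, GTF convention
            for gs, ge in _transcript_range_to_genomic_blocks(
                t, t.cds_start, t.cds_stop
            ):
                lines.append(
                    f"{t.chrom}\tisotrunc\tCDS\t{gs + 1}\t{ge}\t.\t"
                    f"{t.strand}\t.\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _transcript_range_to_genomic_blocks(
    t: TranscriptModel, p_start: int, p_end: int
) -> list[tuple[int, int]]:
    """Map a half-open transcript range to sorted genomic (start, end) blocks."""
    positions = [t.transcript_to_genomic(p) for p in range(p_start, p_end)]
    positions.sort()
    blocks: list[tuple[int, int]] = []
    for g in positions:
        if blocks and g == blocks[-1][1]:
            blocks[-1] = (blocks[-1][0], g + 1)
        else:
            blocks.append((g, g + 1))
    return blocks


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """Read a domain TSV with columns name, aa_start, aa_end (header optional)."""
    domains = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "name":
            continue
        name, a, b = fields[0], int(fields[1]), int(fields[2])
        domains.append(DomainAnnotation(name, a, b))
    return domains


def write_exon_table(t: TranscriptModel, path: str | Path) -> None:
    """Flattened per-exon TSV: index, chrom, start, end, strand, length."""
    rows = ["exon_index\tchrom\tstart\tend\tstrand\tlength"]
    for e in t.exons:
        iv = e.interval
        rows.append(
            f"{e.index}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{len(e)}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
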