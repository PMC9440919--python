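"""Per-exon read counting and RPKM computation.

A read increments an exon's count when their genomic overlap reaches
``min_overlap`` base pairs (default 1); a read spanning several exons
increments each of them once.  Spliced reads in 12-column BED contribute
through their aligned blocks; 3-/6-column BED records are treated as
ungapped intervals.  RPKM follows the classic definition
``count / ((exon_length/1e3) * (library_size/1e6))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genemodel import TranscriptModel

#: a read is a list of aligned (start, end) blocks on one chromosome
Read = tuple[str, tuple[tuple[int, int], ...]]


class BedError(ValueError):
    """Invalid BED record."""


def read_bed(path: str | Path) -> list[Read]:
    """Read 3-, 6- or 12-column BED into per-read aligned block lists."""
    reads: list[Read] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise BedError(f"line {ln}: fewer than 3 BED columns: {line!r}")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
        except ValueError as exc:
            raise BedError(f"line {ln}: non-integer coordinates: {line!r}") from exc
        if start < 0 or end <= start:
            raise BedError(f"line {ln}: invalid interval {start}-{end}: {line!r}")
        if len(f) >= 12:
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets):
                raise BedError(f"line {ln}: blockSizes/blockStarts mismatch: {line!r}")
            blocks = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            if blocks[-1][1] > end:
                raise BedError(f"line {ln}: blocks extend past chromEnd: {line!r}")
        else:
            blocks = ((start, end),)
        reads.append((chrom, blocks))
    return reads


def count_reads_per_exon(
    reads: Sequence[Read], t: TranscriptModel, min_overlap: int = 1
) -> np.ndarray:
    """Per-exon read counts for one sample, ordered by exon index."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    starts = np.array([e.interval.start for e in t.exons])
    ends = np.array([e.interval.end for e in t.exons])
    counts = np.zeros(len(t.exons), dtype=int)
    for chrom, blocks in reads:
        if chrom != t.chrom:
            continue
        bs = np.array([b[0] for b in blocks])
        be = np.array([b[1] for b in blocks])
        # overlap of each exon with the union of the read's blocks
        ov = np.maximum(
            0, np.minimum(ends[:, None], be[None, :]) - np.maximum(starts[:, None], bs[None, :])
        ).sum(axis=1)
        counts += ov >= min_overlap
    return counts


def rpkm(count: float, exon_length: int, library_size: int) -> float:
    """Reads per kilobase of exon per million mapped reads."""
    if exon_length <= 0:
        raise ValueError("exon_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / ((exon_length / 1e3) * (library_size / 1e6))


@dataclass
class ExonExpressionMatrix:
    """Exon x sample counts with derived RPKM values.

    Rows are exon indices 1..E of one transcript; columns are samples.
    """

    counts: pd.DataFrame
    exon_lengths: pd.Series
    library_sizes: pd.Series
    rpkm: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if (self.library_sizes <= 0).any():
            raise ValueError("all library sizes must be positive")
        if (self.exon_lengths <= 0).any():
            raise ValueError("all exon lengths must be positive")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.exon_lengths.index.equals(self.counts.index):
            raise ValueError("exon_lengths index must match counts rows")
        if not self.library_sizes.index.equals(self.counts.columns):
            raise ValueError("library_sizes index must match counts columns")
        kb = self.exon_lengths / 1e3
        m = self.library_sizes / 1e6
        self.rpkm = self.counts.div(kb, axis=0).div(m, axis=1)

    @classmethod
    def from_counts(
        cls,
        t: TranscriptModel,
        counts_by_sample: dict[str, Sequence[int]],
        library_sizes: dict[str, int],
    ) -> "ExonExpressionMatrix":
        idx = pd.Index([e.index for e in t.exons], name="exon_index")
        counts = pd.DataFrame(counts_by_sample, index=idx)
        return cls(
            counts,
            pd.Series(t.exon_lengths, index=idx),
            pd.Series(library_sizes)[counts.columns],
        )

    @classmethod
    def from_bed_files(
        cls,
        t: TranscriptModel,
        bed_by_sample: dict[str, str | Path],
        library_sizes: dict[str, int] | None = None,
        min_overlap: int = 1,
    ) -> "ExonExpressionMatrix":
        """Count each sample's BED file; library size defaults to its read count."""
        counts = {}
        libs = {}
        for sample, path in bed_by_sample.items():
            reads = read_bed(path)
            counts[sample] = count_reads_per_exon(reads, t, min_overlap)
            libs[sample] = (
                library_sizes[sample] if library_sizes is not None else len(reads)
            )
        return cls.from_counts(t, counts, libs)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def exon_profile(self, sample: str) -> np.ndarray:
        """RPKM vector for one sample, ordered exon 1 -> E."""
        if sample not in self.rpkm.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.rpkm[sample].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            {"count": self.counts, "rpkm": self.rpkm}, axis=1
        )
        out.columns = [f"{kind}_{sample}" for kind, sample in out.columns]
        out.insert(0, "exon_length", self.exon_lengths)
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# bedGraph coverage alternative
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph file into a DataFrame (chrom, start, end, value)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ValueError(f"bedGraph line {ln}: need 4 columns: {line!r}")
        rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def counts_from_coverage(
    coverage: pd.DataFrame, t: TranscriptModel, read_length: int
) -> np.ndarray:
    """Approximate per-exon counts as round(mean coverage * length / read length)."""
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    cov = coverage[coverage["chrom"] == t.chrom]
    counts = np.zeros(len(t.exons), dtype=int)
    for i, e in enumerate(t.exons):
        iv = e.interval
        ov = np.maximum(
            0,
            np.minimum(cov["end"].values, iv.end)
            - np.maximum(cov["start"].values, iv.start),
        )
        mean_cov = float((ov * cov["value"].values).sum()) / len(e)
        counts[i] = round(mean_cov * len(e) / read_length)
    return counts
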