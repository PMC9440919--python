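"""Truncation-breakpoint calling from per-exon expression profiles.

The target phenomenon is a transcript whose 5' exons are silent while a
contiguous 3' block is expressed, as produced by an internal alternative
promoter.  The caller fits the simplest model of that shape: a single
changepoint k splitting the profile into a 5' block (exons 1..k-1) and a
3' block (exons k..E), scored by the difference of block means on
log2(RPKM + 1).  Exhaustive search over k is exact at transcript-scale E.

Classification thresholds (all configurable):

* ``tau_on``  — mean RPKM at or above which a block counts as expressed
  (default 1 RPKM);
* ``tau_off`` — mean RPKM at or below which a block counts as silent
  (default 0.1 RPKM);
* ``delta``   — minimum block contrast in log2 units (default 1).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class ExpressionClass(str, Enum):
    FULL_LENGTH = "full_length"
    SHORT_3PRIME = "short_3prime"
    NOT_EXPRESSED = "not_expressed"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class IsoformCall:
    """Breakpoint call for one exon profile.

    ``breakpoint_k`` is the 1-based index of the first expressed 3' exon and
    is only set for ``short_3prime`` calls.  ``mean_5prime``/``mean_3prime``
    are the block means of log2(RPKM+1) at the best split and ``score`` their
    difference.
    """

    expression_class: ExpressionClass
    breakpoint_k: int | None
    mean_5prime: float
    mean_3prime: float
    score: float


def detect_breakpoint(
    profile: Sequence[float],
    tau_on: float = 1.0,
    tau_off: float = 0.1,
    delta: float = 1.0,
) -> IsoformCall:
    """Call the truncation breakpoint of a per-exon RPKM profile.

    Evaluates ``score(k) = mean(y[k..E]) - mean(y[1..k-1])`` on
    ``y = log2(RPKM+1)`` for every k in 2..E and takes the maximising k
    (smallest on ties).  The call is ``short_3prime`` when the contrast
    reaches ``delta`` and the raw-RPKM block means clear ``tau_off`` (5')
    and ``tau_on`` (3'); ``full_length`` when every exon is at or above
    ``tau_on``; ``not_expressed`` when every exon is below ``tau_off``;
    otherwise ``ambiguous``.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("profile must be 1-D with at least 3 exons")
    if np.any(x < 0):
        raise ValueError("RPKM values must be non-negative")
    y = np.log2(x + 1.0)
    E = x.size

    # prefix means give every split in O(E)
    csum = np.cumsum(y)
    ks = np.arange(2, E + 1)  # candidate first 3'-block exon (1-based)
    left_mean = csum[ks - 2] / (ks - 1)
    right_mean = (csum[-1] - csum[ks - 2]) / (E - ks + 1)
    scores = right_mean - left_mean
    best = int(np.argmax(scores))  # argmax returns first (= smallest k) on ties
    k_star = int(ks[best])
    m5, m3, score = float(left_mean[best]), float(right_mean[best]), float(scores[best])

    raw5 = float(x[: k_star - 1].mean())
    raw3 = float(x[k_star - 1 :].mean())
    if score >= delta and raw5 <= tau_off and raw3 >= tau_on:
        return IsoformCall(ExpressionClass.SHORT_3PRIME, k_star, m5, m3, score)
    if np.all(x >= tau_on):
        return IsoformCall(ExpressionClass.FULL_LENGTH, None, m5, m3, score)
    if np.all(x < tau_off):
        return IsoformCall(ExpressionClass.NOT_EXPRESSED, None, m5, m3, score)
    return IsoformCall(ExpressionClass.AMBIGUOUS, None, m5, m3, score)


def consensus_call(
    calls: Mapping[str, IsoformCall], groups: Mapping[str, str]
) -> dict[str, IsoformCall]:
    """Per-group consensus: majority class, median breakpoint of short calls.

    ``groups`` maps sample -> group label.  The class is decided by strict
    majority (``ambiguous`` on ties); the consensus breakpoint is the lower
    median of the per-sample breakpoints among ``short_3prime`` calls.
    """
    by_group: dict[str, list[IsoformCall]] = {}
    for sample, call in calls.items():
        if sample not in groups:
            raise KeyError(f"sample {sample!r} has no group label")
        by_group.setdefault(groups[sample], []).append(call)

    out = {}
    for group, members in by_group.items():
        if not members:
            raise ValueError(f"group {group!r} is empty")
        tally: dict[ExpressionClass, int] = {}
        for c in members:
            tally[c.expression_class] = tally.get(c.expression_class, 0) + 1
        best_n = max(tally.values())
        winners = [cls for cls, n in tally.items() if n == best_n]
        cls = winners[0] if len(winners) == 1 else ExpressionClass.AMBIGUOUS

        k = None
        if cls is ExpressionClass.SHORT_3PRIME:
            ks = [c.breakpoint_k for c in members if c.breakpoint_k is not None]
            k = int(statistics.median_low(ks))
        shorts = [c for c in members if c.expression_class is cls] or members
        out[group] = IsoformCall(
            cls,
            k,
            float(np.mean([c.mean_5prime for c in shorts])),
            float(np.mean([c.mean_3prime for c in shorts])),
            float(np.mean([c.score for c in shorts])),
        )
    return out


def calls_to_tsv(calls: Mapping[str, IsoformCall], path: str | Path) -> None:
    rows = ["sample\tclass\tbreakpoint_k\tmean_5prime\tmean_3prime\tscore"]
    for sample, c in calls.items():
        k = "" if c.breakpoint_k is None else str(c.breakpoint_k)
        rows.append(
            f"{sample}\t{c.expression_class.value}\t{k}\t"
            f"{c.mean_5prime:.6g}\t{c.mean_3prime:.6g}\t{c.score:.6g}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
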