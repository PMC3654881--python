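"""Tandem-run detection inside equivalence classes and report emission.

A tandem repeat is a triple (i, f, l): l >= 2 adjacent, non-overlapping
copies of the factor f starting at position i, each copy anchored at
i + j*|f| and each individually meeting the probability threshold.  Since
an equivalence class holds *all* threshold-passing occurrences of its
factor, maximal runs are exactly the maximal arithmetic chains of common
difference |f| inside the class position set.  Only primitive factors are
reported: if f = g^m tandemly repeats, every g-copy weight is at least the
containing f-copy weight (probabilities are <= 1), so the primitive root's
run is always present and nothing is lost by filtering powers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .partition import EquivClass, PartitionState, iterate_partitions
from .wseq import Threshold, WeightedSequence

__all__ = [
    "TandemRepeat",
    "RepeatSet",
    "is_primitive",
    "detect_runs",
    "assemble",
    "find_all_tandem_repeats",
    "write_report",
    "write_gff3",
]


@dataclass(frozen=True)
class TandemRepeat:
    """One maximal run: factor ``factor`` repeated ``copies`` times from
    1-based ``start``; ``copy_probs[j]`` is the cumulative weight of the
    copy anchored at ``start + j*period``."""

    start: int
    factor: str
    copies: int
    copy_probs: tuple[float, ...]

    @property
    def period(self) -> int:
        return len(self.factor)

    @property
    def end(self) -> int:
        """Last covered position, 1-based inclusive."""
        return self.start + self.copies * self.period - 1

    @property
    def triple(self) -> tuple[int, str, int]:
        return (self.start, self.factor, self.copies)

    def sort_key(self) -> tuple[int, int, str]:
        return (self.start, self.period, self.factor)


@dataclass
class RepeatSet:
    """The answer set S: all maximal primitive tandem repeats, sorted by
    (start, factor length, factor)."""

    repeats: list[TandemRepeat]

    def __post_init__(self):
        self.repeats = sorted(self.repeats, key=TandemRepeat.sort_key)

    def triples(self) -> list[tuple[int, str, int]]:
        return [r.triple for r in self.repeats]

    def __len__(self) -> int:
        return len(self.repeats)

    def __iter__(self):
        return iter(self.repeats)

    def __contains__(self, triple: tuple[int, str, int]) -> bool:
        return triple in set(self.triples())


def is_primitive(f: str) -> bool:
    """True iff ``f`` is not a proper power g^m (m >= 2).

    Classic shift test: f is a power iff f occurs inside f+f at an interior
    offset (equivalently, the smallest period of f divides |f| properly).
    """
    if not f:
        raise ValueError("primitivity is undefined for the empty string")
    return (f + f).find(f, 1) == len(f)


def detect_runs(cls: EquivClass) -> list[TandemRepeat]:
    """Maximal arithmetic chains of common difference p in one class.

    The class may interleave occurrences that sit off a chain's p-grid
    (factors can overlap themselves at shifts smaller than p), so the scan
    walks the position *set*: a chain starts at any occurrence i with i - p
    absent and follows i, i+p, i+2p, ... while present.  Chains of length
    one yield nothing.
    """
    p = cls.period
    prob_at = {o.position: o.prob for o in cls.occurrences}
    runs = []
    for occ in cls.occurrences:
        i = occ.position
        if i - p in prob_at:
            continue  # not a chain head
        stops = [i]
        while stops[-1] + p in prob_at:
            stops.append(stops[-1] + p)
        if len(stops) >= 2:
            runs.append(
                TandemRepeat(
                    start=i,
                    factor=cls.factor,
                    copies=len(stops),
                    copy_probs=tuple(prob_at[s] for s in stops),
                )
            )
    return runs


def _drop_covered_rotations(repeats: list[TandemRepeat]) -> list[TandemRepeat]:
    # keep only the leftmost run among same-period runs whose factors are
    # rotations of each other and whose spans nest (e.g. keep (1, AT, 4),
    # drop (2, TA, 3) inside ATATATAT)
    kept: list[TandemRepeat] = []
    by_period: dict[int, list[TandemRepeat]] = {}
    for r in sorted(repeats, key=TandemRepeat.sort_key):
        covered = False
        for q in by_period.get(r.period, []):
            if (
                q.start < r.start
                and q.end >= r.end
                and r.factor in (q.factor + q.factor)
            ):
                covered = True
                break
        if not covered:
            kept.append(r)
            by_period.setdefault(r.period, []).append(r)
    return kept


def assemble(
    states: Iterable[PartitionState], leftmost_only: bool = False
) -> RepeatSet:
    """Union of run detection over every class at every stage, restricted
    to primitive factors, deduplicated and sorted.

    ``leftmost_only`` additionally suppresses runs that are rotations of an
    earlier-starting run covering the same span (the stricter reading in
    which ATATATAT yields only (1, AT, 4) and not also (2, TA, 3))."""
    seen: set[tuple[int, str]] = set()
    out: list[TandemRepeat] = []
    for state in states:
        for cls in state.classes:
            if not is_primitive(cls.factor):
                continue
            for run in detect_runs(cls):
                key = (run.start, run.factor)
                if key not in seen:
                    seen.add(key)
                    out.append(run)
    if leftmost_only:
        out = _drop_covered_rotations(out)
    return RepeatSet(out)


def find_all_tandem_repeats(
    ws: WeightedSequence,
    t: Threshold,
    max_period: Optional[int] = None,
    max_classes: Optional[int] = None,
    leftmost_only: bool = False,
) -> RepeatSet:
    """End-to-end driver: partition stage by stage and collect every
    maximal primitive tandem repeat with factor length up to
    ``min(max_period, floor(n/2))``."""
    return assemble(
        iterate_partitions(ws, t, max_period=max_period, max_classes=max_classes),
        leftmost_only=leftmost_only,
    )


_REPORT_HEADER = "start\tend\tfactor\tperiod\tcopies\tmin_copy_prob\tcopy_probs"


def _fmt(p: float) -> str:
    return repr(round(p, 9))


def write_report(rs: RepeatSet, ws_name: Optional[str] = None) -> str:
    """Tab-separated report, one line per repeat; ``end`` is 1-based
    inclusive (start + copies*period - 1)."""
    lines = []
    if ws_name:
        lines.append(f"# sequence: {ws_name}")
    lines.append(_REPORT_HEADER)
    for r in rs:
        lines.append(
            "\t".join(
                (
                    str(r.start),
                    str(r.end),
                    r.factor,
                    str(r.period),
                    str(r.copies),
                    _fmt(min(r.copy_probs)),
                    ";".join(_fmt(p) for p in r.copy_probs),
                )
            )
        )
    return "\n".join(lines) + "\n"


def write_gff3(rs: RepeatSet, seqid: str = "wseq") -> str:
    """GFF3 emission for genome-browser use: one ``tandem_repeat`` feature
    per run, with the factor, copy count and copy probabilities stowed in
    the attribute column."""
    lines = ["##gff-version 3"]
    for idx, r in enumerate(rs, start=1):
        attrs = (
            f"ID=tr{idx};factor={r.factor};period={r.period};"
            f"copies={r.copies};copy_probs={','.join(_fmt(p) for p in r.copy_probs)}"
        )
        lines.append(
            "\t".join(
                (
                    seqid,
                    "wtandem",
                    "tandem_repeat",
                    str(r.start),
                    str(r.end),
                    _fmt(min(r.copy_probs)),
                    "+",
                    ".",
                    attrs,
                )
            )
        )
    return "\n".join(lines) + "\n"
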