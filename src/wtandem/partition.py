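"""Equivalence-class partitioning over a weighted sequence.

The engine mirrors Crochemore-style iterative partitioning, adapted to the
weighted setting: the stage-p "partition" is the family of classes C_f(p),
one per length-p factor f, each holding the ordered (position, probability)
pairs where f occurs with probability >= min_prob.  Because several
characters may occur at one position, a position can belong to up to
|alphabet| stage-p classes — which is exactly why the classic smaller-half
speed-up does not transfer and every class is refined in full.

Stage p+1 is built from stage p by appending one character: an occurrence
(i, pi) of f extends to (i, pi * w) in C_{f+c}(p+1) for every character c
occurring at position i+p, kept only while the running product stays at or
above the threshold.  Classes that drop below two occurrences can never
host a tandem repeat and are pruned eagerly; refinement only shrinks
classes, so pruning is loss-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .wseq import (
    REAL_FACTOR_EPS,
    Occurrence,
    Threshold,
    WeightedSequence,
)

__all__ = [
    "EquivClass",
    "PartitionState",
    "ClassCapExceeded",
    "build_e1",
    "extend_class",
    "refine",
    "iterate_partitions",
]


class ClassCapExceeded(RuntimeError):
    """Raised when a refinement stage would exceed the configured class cap.

    With an unbounded alphabet and permissive threshold the number of
    distinct real factors can grow exponentially in the sequence length;
    the cap turns that into a loud failure instead of memory exhaustion.
    """


@dataclass
class EquivClass:
    """C_f(p): a factor plus its ordered occurrence list.

    Invariants: occurrences strictly increase by position, each satisfies
    the real-factor threshold, and classes kept between stages have at
    least two occurrences.
    """

    factor: str
    occurrences: list[Occurrence]

    @property
    def period(self) -> int:
        return len(self.factor)

    @property
    def positions(self) -> list[int]:
        return [o.position for o in self.occurrences]


@dataclass
class PartitionState:
    """The family of stage-p classes (all factors of one length p)."""

    p: int
    classes: list[EquivClass] = field(default_factory=list)

    @property
    def total_occurrences(self) -> int:
        return sum(len(c.occurrences) for c in self.classes)

    def __bool__(self) -> bool:
        return bool(self.classes)


def build_e1(ws: WeightedSequence, t: Threshold) -> PartitionState:
    """Stage-1 classes: for each character, the ordered list of positions
    where it occurs with probability >= min_prob.  Classes with fewer than
    two occurrences are dropped — they can never yield a repeat and
    refinement cannot regrow them."""
    cut = t.min_prob - REAL_FACTOR_EPS
    classes = []
    for c in sorted(ws.alphabet):
        occs = []
        for i in range(1, ws.n + 1):
            w = ws.char_weight(i, c)
            if w >= cut:
                occs.append(Occurrence(i, w))
        if len(occs) >= 2:
            classes.append(EquivClass(c, occs))
    return PartitionState(1, classes)


def extend_class(
    ws: WeightedSequence, cls: EquivClass, t: Threshold
) -> list[EquivClass]:
    """Refine one stage-(p-1) class into its stage-p children.

    Each occurrence (i, pi) spawns a candidate (i, pi * w(c)) in the child
    C_{f+c} for every character c occurring at position i + p - 1, kept iff
    the product meets the threshold.  Occurrences whose extended window
    would overrun the sequence end are dropped silently.  Children with
    fewer than two survivors are discarded; children are returned in
    lexicographic order of the appended character for deterministic output.
    """
    p = len(cls.factor) + 1
    cut = t.min_prob - REAL_FACTOR_EPS
    buckets: dict[str, list[Occurrence]] = {}
    for occ in cls.occurrences:
        last = occ.position + p - 1
        if last > ws.n:
            continue
        pos = ws.position(last)
        for c in pos.chars:
            prob = occ.prob * pos.weight(c)
            if prob >= cut:
                buckets.setdefault(c, []).append(Occurrence(occ.position, prob))
    return [
        EquivClass(cls.factor + c, occs)
        for c, occs in sorted(buckets.items())
        if len(occs) >= 2
    ]


def refine(
    ws: WeightedSequence,
    state: PartitionState,
    t: Threshold,
    max_classes: Optional[int] = None,
) -> PartitionState:
    """One refinement step: stage p -> stage p + 1.

    Returns an empty state once no class survives or the factor length
    would exceed floor(n/2) (repeats need two adjacent copies, so longer
    factors cannot tandemly repeat).  Work is proportional to the total
    number of occurrences in ``state``.
    """
    p_next = state.p + 1
    if p_next > ws.n // 2:
        return PartitionState(p_next)
    classes: list[EquivClass] = []
    for cls in state.classes:
        classes.extend(extend_class(ws, cls, t))
        if max_classes is not None and len(classes) > max_classes:
            raise ClassCapExceeded(
                f"stage {p_next} produced more than {max_classes} classes; "
                "raise the cap or the probability threshold"
            )
    return PartitionState(p_next, classes)


def iterate_partitions(
    ws: WeightedSequence,
    t: Threshold,
    max_period: Optional[int] = None,
    max_classes: Optional[int] = None,
) -> Iterator[PartitionState]:
    """Yield the non-empty partition states for p = 1, 2, ... in order.

    Stops when no class survives pruning or p reaches
    ``min(max_period, floor(n/2))``.
    """
    bound = ws.n // 2
    if max_period is not None:
        bound = min(bound, max_period)
    if bound < 1:
        return
    state = build_e1(ws, t)
    while state:
        yield state
        if state.p >= bound:
            break
        state = refine(ws, state, t, max_classes=max_classes)
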