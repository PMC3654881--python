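"""Weighted-sequence data model, probability arithmetic, and I/O.

A *weighted sequence* X[1, n] holds, at every position, a probability
distribution over alphabet characters instead of a single fixed character
(a position probability matrix read as a string).  The probability of a
plain string ``f`` occurring at position ``i`` — its *cumulative weight*
pi_i(f) — is the product of the per-position character probabilities along
``f``; an occurrence is a *real factor* when that product is at least the
user threshold ``min_prob`` (conventionally written 1/k).

All public positions are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "NORMALIZATION_TOL",
    "REAL_FACTOR_EPS",
    "WeightedSequenceError",
    "ParseError",
    "ValidationError",
    "WeightedPosition",
    "WeightedSequence",
    "Threshold",
    "Occurrence",
    "char_weight",
    "factor_weight",
    "is_real_factor",
    "parse_weighted_sequence",
    "write_weighted_sequence",
    "msa_to_weighted",
    "read_msa_fasta",
    "read_weighted_sequence",
]

#: per-position probabilities must sum to 1 within this tolerance
NORMALIZATION_TOL = 1e-6

#: absolute guard on threshold comparisons so exact-boundary products
#: (e.g. 0.5 * 1 * 0.6 vs a threshold of 0.3) are not lost to rounding
REAL_FACTOR_EPS = 1e-12

GAP = "-"


class WeightedSequenceError(ValueError):
    """Base class for weighted-sequence input errors."""


class ParseError(WeightedSequenceError):
    """Malformed .wseq text."""


class ValidationError(WeightedSequenceError):
    """Structurally parseable input that violates the probability model."""


class WeightedPosition:
    """Probability distribution over characters at one sequence position.

    Characters with zero weight are simply absent: a character *occurs* at
    the position iff it is stored, and every stored weight is > 0.  Stored
    weights must sum to 1 within :data:`NORMALIZATION_TOL`; out-of-tolerance
    input is rejected rather than silently renormalized, because downstream
    thresholding depends on absolute probabilities.
    """

    __slots__ = ("_weights",)

    def __init__(self, weights: Mapping[str, float]):
        kept: dict[str, float] = {}
        for c, w in weights.items():
            if len(c) != 1:
                raise ValidationError(f"character {c!r} is not a single symbol")
            w = float(w)
            if w < 0:
                raise ValidationError(f"negative probability {w} for {c!r}")
            if math.isnan(w):
                raise ValidationError(f"NaN probability for {c!r}")
            if w > 0:
                kept[c] = w
        if not kept:
            raise ValidationError("position has no character with positive weight")
        total = math.fsum(kept.values())
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise ValidationError(
                f"position probabilities sum to {total!r}, not 1 "
                f"(tolerance {NORMALIZATION_TOL})"
            )
        self._weights = kept

    @property
    def weights(self) -> Mapping[str, float]:
        return dict(self._weights)

    @property
    def chars(self) -> tuple[str, ...]:
        """Characters occurring here (positive weight), lexicographic."""
        return tuple(sorted(self._weights))

    def weight(self, c: str) -> float:
        """Probability of ``c`` here; 0.0 if ``c`` does not occur."""
        return self._weights.get(c, 0.0)

    def __contains__(self, c: str) -> bool:
        return c in self._weights

    def __eq__(self, other) -> bool:
        return isinstance(other, WeightedPosition) and self._weights == other._weights

    def __hash__(self):
        return hash(frozenset(self._weights.items()))

    def __repr__(self) -> str:
        inner = ",".join(f"{c}:{w:g}" for c, w in sorted(self._weights.items()))
        return f"WeightedPosition({inner})"

    def approx_equal(self, other: "WeightedPosition", tol: float = 1e-9) -> bool:
        if set(self._weights) != set(other._weights):
            return False
        return all(abs(w - other._weights[c]) <= tol for c, w in self._weights.items())


class WeightedSequence:
    """An ordered run of :class:`WeightedPosition`, the model's X[1, n]."""

    __slots__ = ("_positions",)

    def __init__(self, positions: Iterable[WeightedPosition]):
        pos = tuple(positions)
        if not pos:
            raise ValidationError("a weighted sequence needs at least one position")
        for p in pos:
            if not isinstance(p, WeightedPosition):
                raise TypeError(f"expected WeightedPosition, got {type(p).__name__}")
        self._positions = pos

    @classmethod
    def from_string(cls, s: str) -> "WeightedSequence":
        """Deterministic encoding of a plain string (every weight is 1)."""
        return cls(WeightedPosition({c: 1.0}) for c in s)

    @property
    def n(self) -> int:
        return len(self._positions)

    def __len__(self) -> int:
        return self.n

    @property
    def positions(self) -> tuple[WeightedPosition, ...]:
        return self._positions

    @property
    def alphabet(self) -> frozenset[str]:
        """Every character occurring with positive weight anywhere."""
        out: set[str] = set()
        for p in self._positions:
            out.update(p.chars)
        return frozenset(out)

    def position(self, i: int) -> WeightedPosition:
        """1-based position access."""
        if not 1 <= i <= self.n:
            raise IndexError(f"position {i} out of range 1..{self.n}")
        return self._positions[i - 1]

    def char_weight(self, i: int, c: str) -> float:
        return self.position(i).weight(c)

    def factor_weight(self, i: int, f: str) -> float:
        """Cumulative weight pi_i(f) = prod_j pi_{i+j-1}(f[j]).

        The empty factor has weight 1 (empty product); a factor containing
        a character absent at its aligned position has weight 0.
        """
        if i < 1:
            raise IndexError(f"position {i} out of range 1..{self.n}")
        if i + len(f) - 1 > self.n:
            raise IndexError(
                f"factor of length {len(f)} at position {i} overruns "
                f"sequence end (n={self.n})"
            )
        prod = 1.0
        for j, c in enumerate(f):
            w = self._positions[i - 1 + j].weight(c)
            if w == 0.0:
                return 0.0
            prod *= w
        return prod

    def is_real_factor(self, i: int, f: str, t: "Threshold") -> bool:
        return self.factor_weight(i, f) >= t.min_prob - REAL_FACTOR_EPS

    def approx_equal(self, other: "WeightedSequence", tol: float = 1e-9) -> bool:
        return self.n == other.n and all(
            a.approx_equal(b, tol) for a, b in zip(self._positions, other._positions)
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeightedSequence)
            and self._positions == other._positions
        )

    def __hash__(self):
        return hash(self._positions)

    def __repr__(self) -> str:
        return f"WeightedSequence(n={self.n}, alphabet={''.join(sorted(self.alphabet))})"


@dataclass(frozen=True)
class Threshold:
    """Probability cut-off for real factors: ``min_prob`` is the 1/k of the
    real-factor definition, so ``k = 1/min_prob >= 1``."""

    min_prob: float

    def __post_init__(self):
        if not 0.0 < self.min_prob <= 1.0:
            raise ValidationError(
                f"min_prob must lie in (0, 1], got {self.min_prob!r}"
            )

    @property
    def k(self) -> float:
        return 1.0 / self.min_prob

    @classmethod
    def from_k(cls, k: float) -> "Threshold":
        if k < 1.0:
            raise ValidationError(f"k must be >= 1, got {k!r}")
        return cls(1.0 / k)


class Occurrence(NamedTuple):
    """A (1-based position, cumulative weight) pair inside an equivalence
    class — the element the partitioning engine shuffles around."""

    position: int
    prob: float


# -- module-level conveniences mirroring the method surface -------------------

def char_weight(ws: WeightedSequence, i: int, c: str) -> float:
    """Probability of character ``c`` at 1-based position ``i`` (0 if absent)."""
    return ws.char_weight(i, c)


def factor_weight(ws: WeightedSequence, i: int, f: str) -> float:
    """Cumulative weight of factor ``f`` anchored at 1-based position ``i``."""
    return ws.factor_weight(i, f)


def is_real_factor(ws: WeightedSequence, i: int, f: str, t: Threshold) -> bool:
    """True iff ``f`` at ``i`` meets the threshold (>= min_prob, with a tiny
    absolute guard so exact-boundary float products still qualify)."""
    return ws.is_real_factor(i, f, t)


# -- .wseq text format --------------------------------------------------------
#
# One position per line: "<1-based index><TAB><char>:<prob>[,<char>:<prob>...]"
# Lines sorted by index; '#' starts a comment line; blank lines ignored.

def parse_weighted_sequence(text: str | Iterable[str]) -> WeightedSequence:
    """Parse .wseq text into a validated :class:`WeightedSequence`.

    Raises :class:`ParseError` (with the offending line number) for malformed
    lines, and :class:`ValidationError` for probability-model violations
    (negative weights, per-position sums outside tolerance).
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]

    positions: list[WeightedPosition] = []
    expected = 1
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(fields) != 2:
            raise ParseError(f"line {lineno}: expected '<index>\\t<char>:<prob>,...'")
        idx_s, spec = fields
        try:
            idx = int(idx_s)
        except ValueError:
            raise ParseError(f"line {lineno}: bad position index {idx_s!r}") from None
        if idx != expected:
            raise ParseError(
                f"line {lineno}: position index {idx} out of order "
                f"(expected {expected})"
            )
        weights: dict[str, float] = {}
        for item in spec.split(","):
            item = item.strip()
            if ":" not in item:
                raise ParseError(f"line {lineno}: bad entry {item!r}")
            c, _, p_s = item.partition(":")
            if len(c) != 1:
                raise ParseError(f"line {lineno}: bad character {c!r}")
            try:
                p = float(p_s)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: bad probability {p_s!r}"
                ) from None
            if c in weights:
                raise ParseError(f"line {lineno}: duplicate character {c!r}")
            weights[c] = p
        try:
            positions.append(WeightedPosition(weights))
        except ValidationError as e:
            raise ValidationError(f"line {lineno}: {e}") from None
        expected += 1
    if not positions:
        raise ParseError("no positions found")
    return WeightedSequence(positions)


def write_weighted_sequence(ws: WeightedSequence) -> str:
    """Serialize to .wseq text.  Weights are written with ``repr`` so that a
    parse/write round trip reproduces every probability bit-exactly; weight-1
    characters are written explicitly as e.g. ``C:1.0``."""
    out = []
    for i in range(1, ws.n + 1):
        pos = ws.position(i)
        spec = ",".join(f"{c}:{pos.weight(c)!r}" for c in pos.chars)
        out.append(f"{i}\t{spec}")
    return "\n".join(out) + "\n"


def read_weighted_sequence(path) -> WeightedSequence:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_weighted_sequence(fh)


# -- multiple sequence alignment -> weighted sequence -------------------------

def msa_to_weighted(alignment: Sequence[str]) -> WeightedSequence:
    """Collapse a gapped multiple alignment into a weighted sequence.

    Column ``i`` gives character ``c`` the weight (count of ``c`` in the
    column) / (count of non-gap symbols in the column); gaps ('-') never
    enter the alphabet and are excluded from the denominator.  All-gap
    columns are rejected, as are ragged rows.
    """
    rows = [str(r) for r in alignment]
    if not rows:
        raise ValidationError("alignment has no rows")
    width = len(rows[0])
    for r in rows:
        if len(r) != width:
            raise ValidationError(
                f"ragged alignment: row lengths {width} vs {len(r)}"
            )
    if width == 0:
        raise ValidationError("alignment has zero columns")

    positions = []
    for i in range(width):
        counts: dict[str, int] = {}
        for r in rows:
            c = r[i]
            if c == GAP:
                continue
            counts[c] = counts.get(c, 0) + 1
        denom = sum(counts.values())
        if denom == 0:
            raise ValidationError(f"column {i + 1} is all gaps")
        positions.append(
            WeightedPosition({c: k / denom for c, k in counts.items()})
        )
    return WeightedSequence(positions)


def read_msa_fasta(path) -> WeightedSequence:
    """Read a pre-aligned multi-FASTA and collapse it column-wise."""
    from Bio import SeqIO

    rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValidationError(f"no FASTA records in {path}")
    return msa_to_weighted(rows)
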