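"""Synthetic weighted sequences: random generation and repeat planting.

Real weighted sequences typically arise by collapsing a multiple alignment
column-wise (profiles of protein families, binding-site models).  The
generator emulates that kind of input directly: each position carries a
small number of characters with a Dirichlet-distributed probability vector,
so sparsity (characters per position) and peakedness (concentration) are
the two dials that matter.  ``plant_tandem_repeat`` then overwrites a
window so a chosen factor tandemly repeats with an exact per-copy
cumulative weight — the ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wseq import WeightedPosition, WeightedSequence

__all__ = [
    "SynthConfig",
    "example_X",
    "generate_random_weighted_sequence",
    "plant_tandem_repeat",
]


def example_X() -> WeightedSequence:
    """The canonical 5-position worked example:
    (A .5, C .25, G .25) (G 1) (A .6, C .4) (A/C/G/T .25 each) (C 1)."""
    return WeightedSequence(
        [
            WeightedPosition({"A": 0.5, "C": 0.25, "G": 0.25}),
            WeightedPosition({"G": 1.0}),
            WeightedPosition({"A": 0.6, "C": 0.4}),
            WeightedPosition({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}),
            WeightedPosition({"C": 1.0}),
        ]
    )


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for random weighted-sequence generation.

    ``max_chars_per_pos`` bounds how many distinct characters a position may
    carry (1 gives a deterministic plain string); ``dirichlet_conc`` is the
    symmetric Dirichlet concentration of each position's probability vector
    (1.0 = uniform over the simplex, larger = flatter/more even weights).
    """

    n: int
    alphabet: str = "ACGT"
    max_chars_per_pos: int = 2
    dirichlet_conc: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 1 <= self.max_chars_per_pos <= len(self.alphabet):
            raise ValueError(
                "max_chars_per_pos must lie in 1..|alphabet| "
                f"({self.max_chars_per_pos} vs {len(self.alphabet)})"
            )
        if self.dirichlet_conc <= 0:
            raise ValueError("dirichlet_conc must be positive")


def generate_random_weighted_sequence(cfg: SynthConfig) -> WeightedSequence:
    """Reproducible random weighted sequence: per position, draw a number of
    characters in 1..max_chars_per_pos, the characters themselves, and a
    Dirichlet probability vector over them."""
    rng = np.random.default_rng(cfg.seed)
    letters = sorted(set(cfg.alphabet))
    positions = []
    for _ in range(cfg.n):
        m = int(rng.integers(1, cfg.max_chars_per_pos + 1))
        chars = rng.choice(letters, size=m, replace=False)
        if m == 1:
            positions.append(WeightedPosition({str(chars[0]): 1.0}))
            continue
        while True:
            probs = rng.dirichlet([cfg.dirichlet_conc] * m)
            if probs.min() > 0.0:  # all stored weights must be strictly positive
                break
        positions.append(
            WeightedPosition({str(c): float(p) for c, p in zip(chars, probs)})
        )
    return WeightedSequence(positions)


def plant_tandem_repeat(
    ws: WeightedSequence,
    f: str,
    start: int,
    copies: int,
    copy_prob: float,
    seed: int = 0,
) -> WeightedSequence:
    """Overwrite ``copies`` adjacent windows of ``ws`` so that ``f`` tandemly
    repeats from 1-based ``start`` with per-copy cumulative weight exactly
    ``copy_prob``.

    Each planted character gets weight copy_prob**(1/|f|); the residual mass
    is spread over the other alphabet characters in random proportions.  The
    finder is then guaranteed to report a run with factor f (or its primitive
    root), on the planted grid, covering the planted span, whenever
    copy_prob >= min_prob — though a run may extend further if the flanking
    random positions happen to continue it.
    """
    if not f:
        raise ValueError("factor must be nonempty")
    if not 0.0 < copy_prob <= 1.0:
        raise ValueError(f"copy_prob must lie in (0, 1], got {copy_prob!r}")
    if start < 1 or start + copies * len(f) - 1 > ws.n:
        raise IndexError(
            f"planted window [{start}, {start + copies * len(f) - 1}] "
            f"overruns sequence of length {ws.n}"
        )
    rng = np.random.default_rng(seed)
    per_char = copy_prob ** (1.0 / len(f))
    others = sorted(ws.alphabet | set(f))
    positions = list(ws.positions)
    for j in range(copies * len(f)):
        c = f[j % len(f)]
        weights = {c: per_char}
        residual = 1.0 - per_char
        if residual > 0:
            rest = [o for o in others if o != c]
            if not rest:
                raise ValueError(
                    "cannot plant copy_prob < 1 over a single-character "
                    "alphabet: no character can absorb the residual mass"
                )
            shares = rng.dirichlet([1.0] * len(rest)) * residual
            for o, s in zip(rest, shares):
                if s > 0:
                    weights[o] = float(s)
        positions[start - 1 + j] = WeightedPosition(weights)
    return WeightedSequence(positions)
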