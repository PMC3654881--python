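"""Brute-force reference finder for small inputs.

Enumerates every real factor explicitly — depth-first over the characters
present at each position, pruning a branch as soon as its running product
drops below the threshold — then detects maximal runs per factor and
filters non-primitive factors.  Deliberately shares nothing with the
partitioning engine beyond the core weighted-sequence type: run detection
and primitivity are re-derived here (index-walk over occurrence lists,
divisor enumeration) so that agreement between the two routes is evidence,
not tautology.  Intended for n up to a few dozen; the number of real
factors can grow exponentially, so a hard cap aborts pathological runs.
"""

from __future__ import annotations

from typing import Optional

from .repeats import RepeatSet, TandemRepeat
from .wseq import REAL_FACTOR_EPS, Threshold, WeightedSequence

__all__ = ["OracleCapExceeded", "brute_force_tandem_repeats"]

DEFAULT_FACTOR_CAP = 10**6


class OracleCapExceeded(RuntimeError):
    """Real-factor enumeration exceeded the safety cap."""


def _enumerate_real_factors(
    ws: WeightedSequence, cut: float, max_p: int, cap: int
) -> dict[str, dict[int, float]]:
    # factor -> {position -> cumulative weight}; outer loop ascending in i
    # keeps each factor's position map in increasing order
    table: dict[str, dict[int, float]] = {}
    count = 0
    for i in range(1, ws.n + 1):
        stack = [("", 1.0)]
        while stack:
            prefix, prod = stack.pop()
            depth = len(prefix)
            if depth == max_p:
                continue
            pos = ws.position(i + depth)
            for c in reversed(pos.chars):
                p2 = prod * pos.weight(c)
                if p2 < cut:
                    continue
                fac = prefix + c
                table.setdefault(fac, {})[i] = p2
                count += 1
                if count > cap:
                    raise OracleCapExceeded(
                        f"more than {cap} real-factor occurrences enumerated"
                    )
                if i + len(fac) <= ws.n:
                    stack.append((fac, p2))
    return table


def _power_free(f: str) -> bool:
    # divisor enumeration: f is a power iff it equals (f[:d]) * (|f|/d)
    # for some proper divisor d of |f|
    m = len(f)
    for d in range(1, m):
        if m % d == 0 and f[:d] * (m // d) == f:
            return False
    return True


def brute_force_tandem_repeats(
    ws: WeightedSequence,
    t: Threshold,
    max_p: Optional[int] = None,
    cap: int = DEFAULT_FACTOR_CAP,
) -> RepeatSet:
    """Exhaustive tandem-repeat search, same answer shape as the engine.

    For every factor length up to ``min(max_p, floor(n/2))`` and every
    anchor position, enumerate each string whose cumulative weight meets
    the threshold; per factor, walk its occurrence positions for maximal
    same-spaced runs; report runs of >= 2 copies of primitive factors.
    """
    bound = ws.n // 2
    if max_p is not None:
        bound = min(bound, max_p)
    if bound < 1:
        return RepeatSet([])
    cut = t.min_prob - REAL_FACTOR_EPS
    table = _enumerate_real_factors(ws, cut, bound, cap)

    found: list[TandemRepeat] = []
    for fac, occ_map in table.items():
        if len(occ_map) < 2 or not _power_free(fac):
            continue
        p = len(fac)
        anchors = sorted(occ_map)
        consumed: set[int] = set()
        for a in anchors:
            if a in consumed or (a - p) in occ_map:
                continue
            chain = []
            pos = a
            while pos in occ_map:
                chain.append(pos)
                consumed.add(pos)
                pos += p
            if len(chain) >= 2:
                found.append(
                    TandemRepeat(
                        start=a,
                        factor=fac,
                        copies=len(chain),
                        copy_probs=tuple(occ_map[q] for q in chain),
                    )
                )
    return RepeatSet(found)
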