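import random

import pytest

from wtandem import (
    SynthConfig,
    Threshold,
    WeightedSequence,
    example_X,
    generate_random_weighted_sequence,
)


@pytest.fixture
def X():
    """The 5-position worked-example weighted sequence."""
    return example_X()


@pytest.fixture
def t03():
    return Threshold(0.3)


@pytest.fixture
def atatatat():
    return WeightedSequence.from_string("ATATATAT")


def random_ws(seed: int, n: int | None = None, max_chars: int = 2) -> WeightedSequence:
    if n is None:
        n = 5 + seed % 26  # spread lengths over 5..30
    return generate_random_weighted_sequence(
        SynthConfig(n=n, max_chars_per_pos=max_chars, seed=seed)
    )


def random_plain_string(rng: random.Random, max_n: int = 100) -> str:
    n = rng.randint(2, max_n)
    return "".join(rng.choice("ACGT") for _ in range(n))


def naive_primitive(f: str) -> bool:
    m = len(f)
    return not any(m % d == 0 and f[: d] * (m // d) == f for d in range(1, m))


def naive_plain_tandem_repeats(s: str) -> set[tuple[int, str, int]]:
    """Independent maximal-primitive-tandem-run scan on a plain string.

    Quadratic sliding-window comparison; no probabilities, no classes.
    Returns 1-based (start, factor, copies) triples.
    """
    n = len(s)
    out = set()
    for p in range(1, n // 2 + 1):
        for i in range(0, n - 2 * p + 1):
            f = s[i : i + p]
            if not naive_primitive(f):
                continue
            if i >= p and s[i - p : i] == f:
                continue  # not leftmost in its run, hence not maximal
            copies = 1
            while i + (copies + 1) * p <= n and s[i + copies * p : i + (copies + 1) * p] == f:
                copies += 1
            if copies >= 2:
                out.add((i + 1, f, copies))
    return out
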