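"""End-to-end repeat finding on a deterministic string and a weighted one.

The deterministic case shows the reporting contract: ATATATAT yields the
maximal primitive run (1, AT, 4) — never the redundant (1, ATAT, 2) — plus
the rotation (2, TA, 3), which the leftmost_only flag suppresses.
"""

from wtandem import (
    SynthConfig,
    Threshold,
    WeightedSequence,
    find_all_tandem_repeats,
    generate_random_weighted_sequence,
    write_report,
)

ws = WeightedSequence.from_string("ATATATAT")
t = Threshold(0.5)
print("ATATATAT, all runs:      ", find_all_tandem_repeats(ws, t).triples())
print("ATATATAT, leftmost only: ",
      find_all_tandem_repeats(ws, t, leftmost_only=True).triples())

# a random weighted sequence: ~2 characters per position, Dirichlet weights
wws = generate_random_weighted_sequence(SynthConfig(n=60, seed=42))
rs = find_all_tandem_repeats(wws, Threshold(0.2))
print(f"\nrandom weighted sequence (n=60, seed=42), min_prob 0.2: "
      f"{len(rs)} repeats")
print(write_report(rs), end="")
# Columns: start/end are 1-based inclusive; copy_probs lists the cumulative
# weight of each copy (all >= min_prob by construction).
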