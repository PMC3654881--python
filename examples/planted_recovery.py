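"""Plant a tandem repeat in a random weighted sequence and recover it.

plant_tandem_repeat overwrites a window so each copy of the factor has an
exact cumulative weight; the finder must then report a run with that
factor, on the planted grid, covering the planted span.
"""

from wtandem import (
    SynthConfig,
    Threshold,
    brute_force_tandem_repeats,
    find_all_tandem_repeats,
    generate_random_weighted_sequence,
    plant_tandem_repeat,
)

ws = generate_random_weighted_sequence(SynthConfig(n=30, seed=7))
planted = plant_tandem_repeat(ws, "AG", start=5, copies=4, copy_prob=0.49, seed=8)

t = Threshold(0.49)
engine = find_all_tandem_repeats(planted, t)
oracle = brute_force_tandem_repeats(planted, t)

print("engine:", engine.triples())
print("oracle:", oracle.triples())
print("agree: ", engine.triples() == oracle.triples())
hit = [r for r in engine if r.factor == "AG" and r.start <= 5 <= r.end]
print("planted (5, AG, 4) recovered:", bool(hit and hit[0].copies >= 4))
# The brute-force oracle enumerates every real factor explicitly; exact
# agreement with the partitioning engine is the package's core correctness
# check on small inputs.
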