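"""Cumulative weights and real factors on the 5-position worked example.

A weighted sequence stores a probability distribution per position.  The
probability that a plain string f occurs at position i is the product of
the per-position character weights along f; an occurrence is *real* when
that product meets the threshold min_prob (= 1/k).
"""

from wtandem import Threshold, example_X, factor_weight, find_all_tandem_repeats, is_real_factor

X = example_X()
t = Threshold(0.3)

print("X has n =", X.n, "positions over alphabet", "".join(sorted(X.alphabet)))
print("pi_2(GAT) =", factor_weight(X, 2, "GAT"))        # 1 * 0.6 * 0.25 = 0.15
print("pi_1(AGA) =", factor_weight(X, 1, "AGA"))        # 0.5 * 1 * 0.6 = 0.3
print("AGA real at 1 (>= 0.3)?", is_real_factor(X, 1, "AGA", t))
print("pi_3(CAC) =", factor_weight(X, 3, "CAC"))        # 0.4 * 0.25 * 1 = 0.1
print("CAC real at 3 (>= 0.3)?", is_real_factor(X, 3, "CAC", t))

rs = find_all_tandem_repeats(X, t)
print("tandem repeats at min_prob 0.3:", rs.triples() or "none")
# Each triple (i, f, l) means factor f repeats l times back-to-back from
# position i, every copy occurring with probability >= 0.3.
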