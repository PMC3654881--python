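"""Collapse a multiple sequence alignment into a weighted sequence.

Column i gives character c the weight count(c) / count(non-gap); gaps never
enter the alphabet.  The collapsed profile then goes through the same
repeat finder as any other weighted sequence.
"""

from wtandem import Threshold, find_all_tandem_repeats, msa_to_weighted, write_weighted_sequence

alignment = [
    "CAGCAGCAG",
    "CAGCAGCAG",
    "CAGCAACAG",
    "CAGC-GCAG",
]

ws = msa_to_weighted(alignment)
print("collapsed profile (.wseq):")
print(write_weighted_sequence(ws), end="")

for mp in (0.9, 0.5):
    rs = find_all_tandem_repeats(ws, Threshold(mp))
    print(f"min_prob {mp}: {rs.triples()}")
# At the strict threshold only runs supported by near-unanimous columns
# survive; relaxing it admits copies that tolerate the A/G disagreement.
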