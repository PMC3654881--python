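# wtandem

Exact tandem-repeat detection in **weighted biological sequences** — strings
in which each position holds a probability distribution over alphabet
characters rather than one fixed character (a position probability matrix
read as a string, e.g. the column profile of a multiple alignment of a
protein family or a set of binding sites).

## The problem and the method

A weighted sequence X[1, n] assigns every position i a set of characters σ
with weights π_i(σ) ≥ 0, Σ_σ π_i(σ) = 1.  The probability that a plain
string f occurs at position i is its *cumulative weight*

    π_i(f) = ∏_{j=1}^{|f|} π_{i+j−1}(f[j]),

and f is a *real factor* at i when π_i(f) ≥ 1/k for a user threshold k ≥ 1
(exposed here as `min_prob = 1/k`).  A **tandem repeat** is a triple
(i, f, l): l ≥ 2 adjacent, non-overlapping copies of f starting at i, each
copy a real factor.  `wtandem` reports every maximal such triple with a
*primitive* factor (f not itself a power g^m) for every factor length
1 ≤ |f| ≤ n/2.

The engine uses Crochemore-style iterative partitioning adapted to the
weighted setting: the stage-p family of equivalence classes C_f(p) holds,
per length-p factor f, the ordered (position, probability) pairs where f is
a real factor.  Stage p+1 is built by extending each class one character to
the right, multiplying probabilities and discarding occurrences that fall
below threshold; classes with fewer than two occurrences are pruned.
Maximal runs are the maximal arithmetic chains of common difference p in a
class's position set.  Because a position may belong to up to |Σ| classes
per stage, the classic smaller-half speed-up does not apply and the whole
computation is O(n²) for a bounded alphabet — a bound the test suite checks
empirically.

A brute-force oracle (explicit enumeration of every real factor) and a
seeded synthetic generator with repeat planting make the engine falsifiable
without any external data.

## Worked example

The canonical 5-position weighted sequence
(A .5, C .25, G .25)(G)(A .6, C .4)(A/C/G/T .25 each)(C):

```python
from wtandem import Threshold, example_X, factor_weight, is_real_factor

X = example_X()
factor_weight(X, 2, "GAT")              # 0.15   (1 × 0.6 × 0.25)
factor_weight(X, 1, "AGA")              # 0.3    (0.5 × 1 × 0.6)
is_real_factor(X, 1, "AGA", Threshold(0.3))   # True  (0.3 ≥ 0.3)
is_real_factor(X, 3, "CAC", Threshold(0.3))   # False (0.1 < 0.3)
```

Finding repeats — `python examples/find_repeats.py` prints:

```
ATATATAT, all runs:       [(1, 'AT', 4), (2, 'TA', 3)]
ATATATAT, leftmost only:  [(1, 'AT', 4)]
```

`(1, 'AT', 4)` means the factor `AT` repeats four times back-to-back from
position 1.  The non-primitive restatement `(1, 'ATAT', 2)` is never
reported; the rotation `(2, 'TA', 3)` is a genuine distinct triple, and
`leftmost_only=True` suppresses such covered rotations.  See `examples/`
for MSA collapsing and planted-repeat recovery walkthroughs.

## Command line

```sh
wtr find fixtures/example_X.wseq --min-prob 0.3        # TSV report to stdout
wtr find aln.fa --input-format msa-fasta --k 100 -o out.tsv
wtr synth -n 200 --seed 7 --plant AG:5:10:0.4 -o s.wseq
wtr convert aln.fa -o profile.wseq
```

The `.wseq` format is one position per line:
`<1-based index><TAB><char>:<prob>[,<char>:<prob>...]`, `#` comments
allowed.  Exit codes: 2 for parse/validation errors, 3 when the
`--max-classes` cap is hit.

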