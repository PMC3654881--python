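# Methods

## Model

A weighted sequence X[1, n] over alphabet Σ assigns each position i a set
of (character, weight) pairs with π_i(σ) ≥ 0 and Σ_σ π_i(σ) = 1.  A
character *occurs* at i iff its weight is positive; zero-weight characters
are not stored.  The cumulative weight of a plain string f at position i is
the product of per-position character weights, π_i(f) = ∏_j π_{i+j−1}(f[j]);
independence across positions is the modelling assumption, as in any
profile/PWM treatment of alignment columns.  An occurrence is *real* when
π_i(f) ≥ min_prob (= 1/k).  A tandem repeat (i, f, l) is l ≥ 2 adjacent
non-overlapping copies of f from position i, **each copy individually
real**.  The per-copy reading (rather than a whole-run product threshold)
is the one consistent with equivalence classes that only ever hold real
occurrences; it is the package's contract.

Reported repeats are restricted to *maximal* runs of *primitive* factors:

- Maximal: neither (start − p, f) nor (start + l·p, f) is a real
  occurrence, so sub-runs are never restated.
- Primitive: f ≠ g^m for m ≥ 2.  Filtering powers loses nothing: weights
  are ≤ 1, so each g-copy inside an f-copy has weight at least the f-copy's
  weight, and the primitive root's run is always present and at least as
  long.
- Rotations that are genuinely distinct factors (TA inside ATATATAT) are
  reported by default; `leftmost_only` suppresses a run when an
  earlier-starting same-period run whose factor is a rotation covers its
  span, for users who want one representative per repeat tract.
- Length-1 (homopolymer) runs are included — they satisfy the definition
  like any other period.

## Engine

Stage 1 builds, per character, the ordered list of positions where it
occurs with weight ≥ min_prob.  Stage p+1 extends every stage-p class one
character to the right: occurrence (i, π) of f contributes
(i, π·π_{i+p}(σ)) to the class of fσ when the product stays at or above
threshold; occurrences whose window would overrun the sequence end are
dropped.  Classes with fewer than two occurrences are pruned eagerly —
refinement only shrinks position sets, so nothing reportable is lost — and
iteration stops when no class survives or the factor length exceeds
⌊n/2⌋ (two adjacent copies must fit).  Work per stage is proportional to
the surviving occurrence count; with a bounded alphabet this gives the
quadratic overall bound that the scaling test measures empirically.
Characters are extended in lexicographic order so output ordering is
deterministic.  A configurable class cap turns the exponential worst case
(every character at every position, permissive threshold) into a loud
`ClassCapExceeded` instead of memory exhaustion.

Run detection is a post-pass per class: the class holds *all* real
occurrences of its factor, so maximal runs are exactly the maximal
arithmetic chains of common difference p in the position set.  The scan
walks the set (chain heads are occurrences i with i − p absent) rather
than comparing adjacent list entries, because occurrence lists can
interleave positions off a chain's grid — a factor may overlap itself at a
shift d < p with d ∤ p (e.g. AABAA in AABAABAA) — and the adjacent-pair
reading would miss valid runs.

## Numerical choices

- Threshold comparisons use `π ≥ min_prob − 1e-12` (absolute guard) so that
  exact-boundary float products (0.5 × 1 × 0.6 against 0.3) qualify.  The
  guard is shared by engine and oracle, so borderline occurrences are
  classified identically on both routes.
- Per-position weights must sum to 1 within 1e-6; out-of-tolerance input is
  rejected, never silently renormalized, because absolute probabilities
  feed the threshold.
- The `.wseq` writer emits weights via `repr`, so write→parse round trips
  are bit-exact and same-seed outputs are byte-identical.
- Incremental class probabilities multiply left to right, the same
  association as direct cumulative-weight evaluation; the suite asserts
  agreement within 1e-9.

## Inputs

Native input is the `.wseq` text format (one position per line,
`index<TAB>char:prob,...`).  Aligned multi-FASTA is collapsed column-wise:
character weight = column count / non-gap count, all-gap columns rejected,
gaps never entering the alphabet.  That equal-weight column-frequency rule
(no pseudocounts) is a deliberate, simple choice; profiles built with
pseudocounts or sequence weighting should be supplied as `.wseq` directly.
The alphabet is inferred from input rather than fixed to DNA, so protein
profiles work unchanged.

## Synthetic data and what tests show

The generator emulates alignment-profile-like inputs: each position draws
1..`max_chars_per_pos` distinct characters (default 2 of ACGT) and a
symmetric-Dirichlet weight vector (default concentration 1.0, i.e. uniform
on the simplex), seeded and reproducible.  Defaults deliberately produce
moderately uncertain sequences — sparse enough that class counts stay
bounded, uncertain enough to exercise multi-class membership.  It does not
emulate positional dependence, indel structure, or the biased composition
of real satellite DNA; passing tests therefore demonstrate algorithmic
correctness on the stated model, not biological recall on real genomes.

`plant_tandem_repeat` overwrites a window so each planted character has
weight copy_prob^(1/|f|), making every copy's cumulative weight exactly
copy_prob, with residual mass Dirichlet-spread over the other characters.
Recovery is asserted as grid-anchored coverage (a reported run with the
planted factor, start ≡ planted start mod p, span ⊇ planted span, copies ≥
planted copies) because random flanks can legitimately extend a planted run
leftward under the maximality rule.

The brute-force oracle enumerates every real factor by depth-first search
with product pruning and re-derives run detection and primitivity by
independent means (index walk, divisor enumeration); it shares only the
core sequence type and the threshold guard with the engine.  Engine–oracle
equality is checked exactly on 300 seeded corpus runs (n ≤ 30); the
deterministic special case is additionally checked against a naive
plain-string scanner on 50 random strings (n ≤ 100).

Problem sizes in the suite — corpus n ≤ 30 for oracle equivalence, n ≤ 100
for the deterministic reduction, n ∈ {100, 200, 400, 800} at min_prob 0.01
for the scaling fit (median of 3 runs, fitted log–log slope ≤ 2.5) — were
chosen as the smallest scales at which each property is informative; the
whole suite runs in a few seconds.

## Known limitations

- Exact copies only: no mismatch-tolerant or approximate tandem repeats.
- The exponential worst case (dense positions, tiny threshold) is capped,
  not solved; `--max-classes` aborts rather than degrades.
- The oracle is exponential by design and intended for n up to a few dozen.
- No pseudocounts or IUPAC ambiguity handling in MSA collapsing; no
  FASTQ-quality-to-probability conversion.
- Overlapping runs of different factors are all reported (no
  cross-filtering beyond the optional rotation suppression).
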