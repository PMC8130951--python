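# Methods

This note documents the models, rules and numerical choices behind
`recallkit`, in the spirit of a statistical package's methods appendix.

## Scoring model

### Normalization and matching

Written entries are lowercased and stripped of whitespace and hyphens,
so "Angle-Wing" ≡ "anglewing". Entries are matched to targets by a
one-to-one maximum-similarity assignment (Hungarian algorithm on
1 − d/max(|a|,|b|), with d the unit-cost Levenshtein distance computed
by edlib). Two refinements:

* **Morpheme credit.** If entry and target are both two-morpheme
  compounds sharing their modifier or head, similarity is floored at
  0.75. Half the compound is an exact match, so pairs like
  "metalspot"/"metalmark" must survive the assignment floor — such an
  entry was clearly written *in that item's place* and should be scored
  as an insertion against it rather than orphaned.
* **Deterministic tie-breaks.** Equal-similarity alternatives resolve
  toward the lower target index, then the lower entry index, with a
  rearrangement term that pairs duplicate entries in written order.
  Tie-break terms are ≤ 1e-6 in cost, far below the smallest genuine
  similarity difference (~1/L² ≈ 2.5e-3 for tokens of length ≤ 20).

Pairs below the similarity floor (default 0.5) are unmatched: the
target becomes a NULL record, the entry an unassigned insertion.

### Error taxonomy

For an assigned pair with edit distance d and spelling tolerance
s (default 2):

| outcome | condition |
|---|---|
| CORRECT | entry equals target; or d ≤ s and the entry is **not** a meaningful word (a pure spelling slip — the item was clearly retrieved) |
| NEAR_MISS | the entry **is** meaningful and the error is small: d ≤ s, or exactly one compound morpheme changed by ≤ s edits ("angelwing" for "anglewing") |
| INS | anything else — a completely different word in the item's place ("metalspot") |

"Meaningful" is operationalized as lexicon membership: the token is a
known word, or splits into two known morphemes. The morpheme-level
near-miss clause is deliberately bounded by the per-morpheme edit
distance: a wholesale morpheme replacement (mark → spot, distance 4) is
an insertion, not a near miss, even though only one morpheme changed.
s = 2 is the smallest tolerance that accepts the canonical two-edit
spelling slip ("meselmark") while keeping single-morpheme swaps like
mask/mark inside the near-miss net.

Unmatched targets are NULL errors. A **removal** (REM) is a target
correct at the previous timepoint whose slot at the current timepoint
holds no categorized replacement. The detection rule is genuinely
underdetermined — an omission is simultaneously describable as NULL —
so both precedences are implemented: the default `null_first` keeps the
omission as NULL (consistent with removals being vanishingly rare in
practice), while `removal_first` reclassifies every candidate. REM
never double-counts against NULL.

### Sequence Index

Let the *scorable* items be the CORRECT matches (near misses can be
included by configuration, but are excluded by default since a near
miss is an error; the same flag governs the SeqI denominator). Two
positional-distance modes:

* `rank_based` (default): distance = |rank of the entry among written
  scorable entries − rank of its target among recalled targets|. This
  is the Spearman footrule of the recall permutation; it is invariant
  to *which* items were omitted, and its sum is always even (footrule
  parity), so SeqI's numerator (position_sum / 2) is an integer.
* `literal_position`: distance = |sheet position − list position| (the
  "4th item written 6th scores 2" reading). Over-penalizes single
  omissions, which shift every later item; retained because complete
  recalls make the two modes coincide, including the worked example.

SeqI = (position_sum/2)/n_correct. With n_correct = 0 the index is
undefined and reported as missing (never 0, which means perfect order);
such cells are removed listwise from that parameter's repeated-measures
run only.

## Statistical analysis

* **Friedman test** with within-subject midranks and the standard tie
  correction Q = (k−1)·Σ(Rⱼ − N(k+1)/2)² / (Σr²ᵢⱼ − Nk(k+1)²/4),
  p from χ²(k−1). All-constant rows are legal; if every row is tied,
  Q = 0, p = 1. Verified against scipy (tie-free), R's
  `stats::friedman.test` (tied), and an exhaustive enumeration oracle.
* **Kendall's W** = Q/(N(k−1)), clipped to [0,1], labelled weak /
  moderate / strong with bin edges 0.195 and 0.395 (the conventional
  0.19/0.20 and 0.39/0.4 edges leave gaps, closed at midpoints).
* **Nemenyi post-hoc**: qᵢⱼ = |R̄ᵢ − R̄ⱼ| / √(k(k+1)/(12N)) referred to
  the studentized range with infinite df; checked against the published
  5% critical difference for k = 3 (q = 3.314).
* **Improvement ratio**: the default `proportion_ratio` is
  (improved/eligible)/(baseline-perfect/cohort) — the quantity usually
  reported for this design even when labelled an odds ratio — with
  Katz log-Wald CIs; `odds_ratio` gives the cross-product odds ratio
  with the standard log-Wald CI (both validated against statsmodels'
  `Table2x2`). Zero cells get a 0.5 continuity correction and are
  flagged. CIs are reported but not treated as reference values, since
  the CI convention for this ratio varies across published analyses.
* **Group-size equalization**: before each parameter's
  repeated-measures run, oversized arms are trimmed to the smallest
  arm by uniformly random exclusion, re-drawn independently per
  parameter (so no single participant's exclusion drives every
  comparison); exclusions are recorded in the report provenance.
* Five parameters are analyzed per arm: correct count, SeqI, near-miss,
  NULL and insertion counts. Removals are too rare to test and are
  reported only as a raw total.
* The improvement analysis uses the first post-training timepoint only
  (configurable): participants who reach a perfect score there largely
  retain it at the delay, so later timepoints add no information.

## Synthetic cohort generator

What it emulates: the block randomization (a shuffled pool of 26 cards
per suit, drawn without replacement — so realized arm sizes vary
slightly around n_per_group, e.g. 25/26/25 from 76 draws), a ceiling-
limited ability distribution, additive training effects, order noise
and an error mixture.

Per participant, latent ability p ~ Beta(18, 2) (mean 0.9); at each
timepoint every item is recalled independently with probability
logistic(logit(p) + effect). The defaults place baseline recall at
85–90% of the 20-item list with median ≥ 17 and roughly a fifth of the
cohort perfect at baseline — the regime in which a ceiling forces a
nonparametric analysis. Default logit offsets at post-training/delay:
memory palace +1.5, narrative method +2.0, untrained +0.8 (re-exposure
practice effect). These are qualitative calibrations, not fits: no raw
cohort data exist to fit against.

Unrecalled items become NULL / near miss / insertion with probabilities
(0.7, 0.2, 0.1). A near miss swaps the item's head morpheme for a
lexicon neighbour within 2 edits (mark → mask); an insertion swaps it
for an unrelated lexicon morpheme (mark → plume). Because every target
carries a distinct modifier, such errors still identify their target
under morpheme-credit assignment, which is what makes exact
ground-truth recovery possible. Recalled items carry meaningless
spelling slips (1–2 substitutions into rare consonants, verified
non-meaningful) with probability 0.03.

Order noise: entries are sorted by target rank + Gaussian jitter
(baseline SD 0.8; training multiplies it by 0.6 / 0.25 / 1.0 for the
three arms). A single dispersion knob chosen because mean SeqI is
monotone in it; adjacent-transposition models would need a count
parameter coupled to list length.

Randomness: one root seed; materials, card draws and each participant
get independent substreams (`SeedSequence.spawn`), and text rendering
draws from its own substream so ground truth is identical whether or
not entry strings are rendered.

What it does **not** emulate: serial-position (primacy/recency) curves,
semantic confusability beyond shared morphemes, participant dropout,
and real compound-name phonology. Passing recovery tests therefore
shows the *scorer* is exact on in-model errors; it does not certify
performance on handwriting-transcribed real data, where error types
outside the taxonomy (e.g. conjoined entries) would need manual review.

## Calibration choices

The type-I calibration configuration (`SimulationConfig.null()`) zeroes
all group-by-timepoint effects and uses mid-range Beta(2, 2) ability
rather than the ceiling default. Under the ceiling, most subjects are
constant across timepoints; constant rows carry no rank information, so
the Friedman test becomes conservative there by construction and a
nominal-level check would mostly be measuring discreteness. The
calibration run instead probes the test where the null hypothesis
actually exercises it; the suite asserts a rejection rate of 0.05 ±
0.01 over 2,000 simulated studies.

Problem sizes used by the test suite (chosen to keep the checks sharp
at desk scale): exhaustive Friedman enumeration up to N = 4, k = 3
(1,296 orderings per base matrix); 2,000 null studies of 75
participants for calibration; 50-participant mixture recovery within
two binomial standard errors; 10,000 random permutations for the
footrule parity property.

## Known limitations

* The assignment is globally optimal for the similarity it is given; a
  human scorer with semantic context could prefer a different pairing
  when a sheet contains several heavily garbled entries.
* Near-miss detection requires a lexicon; with an empty lexicon every
  small error is treated as a spelling slip (CORRECT).
* The Nemenyi p-values use the asymptotic studentized-range reference;
  for very small N exact permutation post-hocs would be preferable.
* The improvement-ratio CI is a large-sample Wald interval; with the
  small counts typical of this design it should be read as indicative.
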