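# recallkit

Scoring and nonparametric analysis of free-recall list-learning
experiments — the kind of three-arm classroom trial in which
participants study an ordered list of compound words (e.g. common
butterfly names), receive memory-technique training (method-of-loci
variants such as a memory palace or a landscape-narrative technique) or
none, and write down what they recall at several timepoints.

`recallkit` provides, as a library and a small CLI:

* **Fuzzy response scoring.** Written entries are normalized and
  matched one-to-one to the target list by edit-distance similarity
  (with credit for shared compound morphemes), then classified into a
  four-way error taxonomy: *NULL* (nothing written for an item), *near
  miss* (a small error that is still a semantically meaningful word:
  "metalmask" for "metalmark"), *insertion* (a completely different
  word: "metalspot"), and *removal* (a previously correct item that
  disappears without a categorized replacement). Pure spelling slips
  that are not meaningful words ("meselmark") count as correct.
* **Serial-order accuracy.** Each correctly recalled item contributes a
  positional distance (how many places out of sequence it fell); a
  single displaced item necessarily produces two observed position
  errors, so the **Sequence Index** halves the sum before normalizing:

  `SeqI = (Σ positional distances / 2) / (# correct responses)`

  Recalling a 5-item list as 1,3,2,4,5 gives two distance-1 errors and
  SeqI = (2/2)/5 = 0.2.
* **Rank-based repeated-measures analysis.** Recall scores in a
  high-achiever cohort pile up against the 20/20 ceiling, so the
  analysis is nonparametric throughout: a tie-corrected Friedman test
  across timepoints within each arm, Kendall's W = Q/(N(k−1)) as the
  effect size (weak < 0.195 ≤ moderate < 0.395 ≤ strong), and Nemenyi
  all-pairs post-hoc contrasts on the studentized-range distribution.
* **Improvement-to-perfect-recall ratios.** Per arm, the proportion of
  eligible participants (imperfect at baseline) who reach a perfect
  score at the first post-training test, relative to the cohort-wide
  baseline proportion of perfect scores, with log-scale Wald CIs; a
  true odds-ratio variant is available alongside.
* **A synthetic cohort generator.** Card-deck block randomization (two
  decks, clubs removed, 26 cards per remaining suit), Beta-distributed
  latent recall ability with logit-scale training effects, rank-jitter
  sequence noise, and a categorical error mixture for unrecalled items
  — with full ground truth, so the scorer is validated by exact
  recovery of every injected error.

## Worked example

Simulate a study (25 participants per arm, 20-item list, 3 timepoints),
score it and analyze it in one deterministic run:

```sh
recallkit run-all --seed 42 --out demo
```

`demo/` then contains `responses.csv`, `wordlist.txt`, `lexicon.txt`,
`ground_truth.csv`, `scored.csv`, `summary_long.csv`, `report.json` and
`provenance.json`. The head of `scored.csv`:

```
participant_id             group     timepoint  n_correct  n_near  n_ins  n_ins_assigned  n_null  n_rem  position_sum  seq_index
          P001 aboriginal_method      baseline         15       1      1               1       3      0             2   0.066667
          P001 aboriginal_method post_training         18       0      1               1       1      0             0   0.000000
          P001 aboriginal_method       delayed         18       0      1               1       1      0             0   0.000000
```

P001 recalled 15 items correctly at baseline with one near miss, one
insertion and three blanks, and one correct item displaced by one rank
(position_sum 2, SeqI = (2/2)/15 ≈ 0.067); after training they recall
18 in perfect order. From `report.json`, the within-arm Friedman
results for the correct count:

```
aboriginal_method  Q=21.7 df=2 p=2e-05   W=0.45 (strong)
memory_palace      Q=34.4 df=2 p=3.4e-08 W=0.72 (strong)
untrained          Q=16.9 df=2 p=0.00021 W=0.35 (moderate)
```

and the improvement analysis:

```
aboriginal_method  13/21 improved, ratio=5.16 (95% CI 2.57-10.37)
memory_palace      15/24 improved, ratio=5.21 (95% CI 2.62-10.35)
untrained          12/21 improved, ratio=4.76 (95% CI 2.33-9.74)
```

i.e. 13 of the 21 Aboriginal-method participants who were imperfect at
baseline reached 20/20 after training — about five times this cohort's
baseline rate of perfect scores. The same numbers are available
programmatically:

```python
from recallkit import improvement_ratio, kendalls_w_from_q

improvement_ratio(12, 19, 17, 76).ratio   # 2.82
kendalls_w_from_q(21.3, 25, 3)            # 0.426 -> "strong"
```

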