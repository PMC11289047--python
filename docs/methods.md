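# Methods

This note documents the models, conventions, and defaults behind
`cjrank`, in the order a user meets them: the choice model and simulator,
the reliability and preference metrics, the adaptive (AVL) elicitation
design, the text features and the LASSO scorer, and finally numerical
choices and known limitations.

## The choice model and the simulator

Every rationale `i` carries a latent quality θ_i. The simulator's
generative assumptions are the ones the forced-choice method itself
presumes:

1. **Quality grows with team size.** θ_i = a·log₂(s_i) + ε_i with
   ε_i ~ N(0, σ_q²), where s_i is the producing team's size. Defaults:
   slope a = 1 (one latent unit per doubling of team size), σ_q = 0.5.
   The log link reflects the diminishing returns of adding members to a
   problem-solving group.
2. **Accuracy follows quality.** Each of k questions is answered
   correctly with probability logistic(c·(θ_i − θ₀)), defaults c = 1,
   θ₀ = 3.1, k = 3. The offset θ₀ sits just below the corpus-mean quality
   (≈ 3.47 under the default team mixture), anchoring mean proportion
   correct near 0.6 — the level typical of hard group reasoning tasks —
   so that accuracy comparisons between rationales stay informative
   instead of saturating at the ceiling.
3. **Raters are Thurstone Case V choosers.** A rater with
   discriminability β picks rationale a over b with probability
   Φ(β·(θ_a − θ_b)), optionally lapsing to a uniform coin with
   probability `lapse_rate` ≤ 0.5. β = 0 is chance; β = ∞ is an oracle.
   The probit (rather than logistic) form is deliberate: it makes the
   simulator's probability of superiority exactly the quantity that the
   effect-size conversion d = √2·Φ⁻¹(p) inverts, so simulation and
   reporting share one scale.

Default corpus scale mirrors a realistic study: 9 problems × 16
rationales, team sizes {5, 10, 15, 21} mixed 4:6:4:4 (the composition of
the motivating study's teams). β = 1.0 is the package's "moderate noise"
reference rater: three such raters produce ~72% percent agreement on a
full round-robin, the level observed with crowdworker raters in practice.

Synthetic texts are generated from the same θ: token count is
N(150 + 30·(θ − 3.5), 40²) (floored at 20), and each lexicon's planted
rate per 100 tokens is N(2 + λ_f·(θ − 3.5), 1.5²) clipped to [0, 30],
with default links λ = 1.5 for comparison-class, 0.75 for elaboration and
dialectical, 0.5 for first-person pronouns, 0 otherwise. Filler tokens
come from a vocabulary disjoint from every default lexicon, so planted
rates are exact. These links plant the word-count and
comparison-class/quality correlations the automated scorer is supposed to
find; they are a validation harness, not an empirical claim about text.

**What the simulator does not emulate.** Human raters are intransitive in
ways no utility-consistent model reproduces: at matched agreement levels
the simulator's triple-transitivity (~0.93 at β = 1) exceeds what human
panels show (~0.74–0.90). Response times, rater fatigue and learning,
production protocol effects (Delphi vs free is carried as metadata only),
and content-level text structure are all out of scope. Passing tests
therefore demonstrate that the machinery is correct and well calibrated
under the stated model — not that human raters satisfy the model.

## Scores and reliability metrics

- **Winning percentage** = wins / matchups per item, within problem.
  Items never shown to a rater are flagged rather than scored zero.
- **Normalized accuracy**: within each problem, the mean question score
  is z-scored with the sample sd (ddof = 1) and sign-flipped, so lower z
  = more accurate. Zero-variance problems are flagged undefined.
- **Accuracy comparison of a pair**: question-by-question, the higher
  score wins the question; more question-wins = more accurate solution;
  equal counts = tie. **Choice accuracy** is the fraction of judgments
  choosing the strictly more accurate side, with tied pairs excluded from
  both numerator and denominator; SE = √(p(1−p)/N) over untied judgments.
- **Percent agreement**: the unit is a rater-pair on a co-judged unordered
  item pair; the CI half-width is 1.96·√(p(1−p)/N)·100. The rater-pair
  unit was chosen because it reproduces the CI magnitudes reported for
  studies of this design at their N; chance is 50% for binary choice.
- **Transitivity**: per problem, each item triple whose three pairwise
  majorities are all defined (no vote ties) is classified acyclic or
  cyclic; the chance baseline is 6/8 = 0.75 by enumeration of the eight
  equally likely orientation patterns. Tied-majority pairs exclude the
  triples containing them, since a tie has no orientation.
- **Team-size preference**: for each size pair, wins of the larger team
  over n judgments update a Beta(1, 1) prior; p is the posterior mean and
  its sd is closed-form, while the sd of the effect size d = √2·Φ⁻¹(p) is
  estimated from seeded posterior draws. Equal-size pairs are excluded.
  The Φ-based conversion is exactly the probability-of-superiority ↔
  Cohen's d relation and reproduces the printed effect sizes of the
  motivating study's preference table to two decimals.
- **Spearman ρ** between rankings is computed on rank vectors (scipy);
  rankings are permutations by construction so no tie correction applies.

## Adaptive elicitation with an AVL tree

Ranking by exhaustive comparison costs r·n(n−1)/2 ratings. Because
preferences are largely transitive, inserting items into a self-balancing
binary search tree — with each order query answered by the majority of r
independent rater choices — yields a complete ordering in O(n log n)
queries. Conventions:

- "Better" descends right; the in-order traversal is reversed so index 0
  is the best item. Insertion order is a seeded uniform shuffle (order
  affects distortion under intransitive answers; seeding makes runs
  reproducible).
- Majority ties (possible with even r) are resolved by a seeded coin by
  default, or by recruiting extra raters (`tie_policy="extra_rater"`).
- **Two cost figures are reported and never conflated.** The planning
  estimate is round(r·n·log₂n) — the convention under which 100 items at
  r = 3 cost 1993 ratings and 1000 items cost 29,897. The empirical count
  (`AVLTree.n_comparisons`, the sum of descent depths) is smaller,
  ≈ log₂(n!) ≈ n·log₂n − 1.44n. With r = 3 per comparison the estimate
  undercuts the single-rated exhaustive design from n = 31 onward.
- Fidelity is measured as Spearman ρ against the reference ranking built
  from all comparisons and all raters. At the default corpus scale with
  β = 1 raters, the characteristic pattern is: one rater with all
  comparisons ≈ majority-of-three AVL ≫ one-rater AVL — the adaptive
  design trades a modest fidelity loss for an order-of-magnitude cost
  reduction, but only if each comparison is majority-voted.

## Text features and the automated scorer

Features are word count plus per-lexicon rates per 100 tokens (the
standard dictionary-tool convention, making rates length-invariant).
Tokenization lowercases and splits on non-alphanumeric runs; phrases are
matched on the token stream. The shipped lexicons are small, editable
open proxies for proprietary dictionaries: comparison-class terms
("than", "average", "last", "past", "previous", …), elaborative
connectives ("moreover", "in addition", …), dialectical connectives
("however", "on the other hand", …), first-person pronouns, negation, and
spelled numbers. Anything can be replaced via a plain-text config file.

The scorer regresses winning percentage (kept on its [0, 1] scale) on
standardized features with an L1 penalty, solved by cyclic coordinate
descent with soft thresholding under the glmnet-style objective
(1/2n)‖y − Xβ‖² + λ‖β‖₁. λ is chosen at `lambda.min` on a 100-point
log-spaced grid spanning four decades down from λ_max = max|xᵀ(y−ȳ)|/n,
by seeded k = 10-fold cross-validation — the conventional defaults of the
reference LASSO literature. Coefficients are reported on the original
feature scale; predictions are not clipped to [0, 1] because evaluation
uses correlations, which are scale-free.

Two evaluation regimes: `rationale_split` samples training rationales
across problems (within-domain generalization); `problem_split` assigns
whole problems to one side (transfer across domains — the harder test,
which degrades when feature–quality links differ between problems).
Each regime is repeated (default 100×, seeded) and the nonzero count and
both test-set correlations are averaged; degenerate repetitions
(constant test response) are skipped and counted.

## Numerical choices and edge cases

- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; repeated runs with one seed are byte-identical, and
  independent substreams are spawned via `SeedSequence` where a procedure
  has internal replicates.
- Coordinate descent converges when the largest coefficient update in a
  sweep is < 1e-6 (configurable); non-convergence raises with the
  iteration count rather than returning silently.
- Constant features are dropped before standardization and reported as
  exact zeros; λ ≥ λ_max yields the null model identically.
- Win-percentage ties in reference rankings are broken by a seeded
  shuffle; incomplete pair coverage warns and proceeds with available
  matchups.
- Degenerate inputs are flagged, not fudged: empty matchup records,
  zero-variance problems, all-tied accuracy pairs, probabilities of 0 or
  1 in the effect-size map, and empty trees all raise or carry explicit
  undefined flags.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on synthetic data at
sizes chosen to make Monte-Carlo standard errors small relative to the
effects being checked: chance-baseline checks use a 12-problem ×
44-item corpus (≈ 34,000 judgments, ≈ 159,000 triples); the
expertise-ordering and adaptive-design experiments use 20 replicates at
2 × 12 and 9 × 16 items respectively; exhaustive AVL verification covers
every insertion order up to n = 8 and seeded noisy builds at n = 1000.
Monte-Carlo tolerances are ±3 empirical SEs (computed between replicates
or between problems, not from binomial formulas, because triples sharing
a pair are correlated).

## Known limitations

- The simulator's raters are utility-consistent; real panels are less
  transitive than any β setting reproduces at matched agreement.
- Graded ("closeness to truth") question scores are validated to [0, 1]
  but the simulator emits binary scores only.
- The Beta-Binomial preference model pools judgments within a team-size
  pair, ignoring rater and item random effects; its posterior sd is
  therefore optimistic for small rater panels.
- Default lexicons are tiny seed lists meant to be edited, not a
  validated psycholinguistic instrument.
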