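# Methods

## Study design and data model

The analysis assumes a complete block: R raters each assign one of four
posture categories (IDEAL, KL, SB, FB — the Kendall classification)
plus an integer confidence 1–5 to every item, where an item is one
image presented in one variant (S = silhouette, G = grayscale). Each
image also carries a clinical reference label obtained by experienced
physical therapists through visual inspection and palpation. The
reference is treated as ground truth throughout; the question the
statistics answer is how well the image-only panel consensus reproduces
it.

Completeness, duplicate records, confidence range, and per-rater
experience consistency are validated at construction; an incomplete
block is an error, not a warning, because every downstream statistic
(vote entropy, subgroup consensus, stratum totals) silently changes
meaning on ragged data.

## Consensus rule

Each item's label is the category with the most votes. A vote tie is
broken by the highest total confidence *among the vote-tied categories
only* — a category with few votes but enthusiastic voters cannot
overturn the majority. If confidence totals tie as well, the rule is
silent in the source protocol; we fall back to the first tied category
in canonical order (IDEAL < KL < SB < FB) and flag the item
`unresolved_tie=True`, so users can exclude such items rather than
trust an arbitrary (if deterministic) choice. Determinism was the
requirement; the canonical order is the simplest documented total
order.

Subgroup relabeling (experience strata) reuses the identical rule on
the subgroup's votes alone.

## Entropy triage

Item ambiguity is the Shannon entropy of the empirical vote
distribution, in bits: H = −Σ p<sub>c</sub> log₂ p<sub>c</sub> with the
0·log 0 := 0 convention, so H ∈ [0, 2] for four categories. Items are
sorted by ascending entropy and split into LOW (first ⌊n/2⌋) and HIGH
halves per variant. Ties at the boundary are broken by ascending
image id — the split must not depend on input order. For the study's
even n = 28 per variant the halves are exactly 14/14.

## Agreement statistics

All statistics are computed on a K×K cross-tabulation with the clinical
reference on rows and the consensus on columns.

- **P<sub>o</sub>** diagonal proportion; **P<sub>e</sub>** marginal-product
  chance agreement; **Cohen's κ** = (P<sub>o</sub>−P<sub>e</sub>)/(1−P<sub>e</sub>).
- **PABAK.** The default convention is 2·P<sub>o</sub> − 1 for *any* K.
  For K = 2 this is the standard prevalence- and bias-adjusted kappa;
  for K = 4 the common definition is (K·P<sub>o</sub> − 1)/(K − 1), but
  the source study reports the 2·P<sub>o</sub> − 1 value even for its
  4-category tables (−0.14 and −0.29 for S and G), so that form is the
  default and the multi-category form is exposed as
  `pabak(ct, "multicategory")`. A useful identity, asserted in the
  tests: when row marginals are uniform (the study's 7 images per
  category), Cohen's κ equals the multi-category PABAK exactly — which
  is why the study's 4-category "kappa" values (0.2381, 0.1429) are
  also reproduced by that formula.
- **Significance.** z = κ/SE₀ with Fleiss's large-sample null standard
  error; two-sided normal p. This convention reproduces every 2×2
  p-value printed in the source (0.0233, 0.0228, 0.0034, 0.0020,
  0.0001, 0.3927, 0.4805, 0.5148, 0.0011) to four decimals. It does
  *not* reproduce the two 4-category p-values (printed 0.0245 and
  0.3505 vs 0.0259 and 0.1836 here); the software variant behind those
  two numbers could not be identified, and they are excluded from the
  reproduction surface. The z and p are still reported for 4-category
  tables under the stated Fleiss convention.
- **Sensitivity/specificity.** Non-ideal is the positive class:
  sensitivity = tp/(tp+fn) over the clinically non-ideal row,
  specificity = tn/(tn+fp) over the clinically ideal row. A zero row
  makes the measure `None` — degenerate strata must surface as
  undefined, never as silent zeros.
- **Landis–Koch bands.** <0 no; 0–0.20 slight; 0.21–0.40 fair;
  0.41–0.60 moderate; 0.61–0.80 substantial; 0.81–1.00 almost perfect;
  each band inclusive of its upper edge.

One small inconsistency in the source is worth noting: its text gives
the senior-group G-image specificity as 76%, but the corresponding
printed matrix [[5,2],[2,19]] yields 5/7 ≈ 71%. We treat the matrix as
authoritative (every other printed percentage is consistent with its
matrix) and compute 71%.

## Group comparisons

Strata are compared with the **uncorrected** Pearson chi-square on 2×2
tables, computed by the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))
with df = 1. No Yates continuity correction: the uncorrected form
reproduces the source's p-values (0.0497, 0.4319, 0.5770, 1.0000
exactly; 0.0145→0.0146 and 0.0307→0.0308 at the fourth decimal, a
sub-rounding artifact); with the correction none of them match. Counts
in these tables are small, so an exact test would be the textbook
choice — fidelity to the published method wins here, and the tests pin
the convention. Two-sided p-values everywhere; no multiple-testing
adjustment is applied, matching the source analysis.

Paired per-image entropies of the two variants are compared with the
**Wilcoxon signed-rank test**: zero differences dropped, mid-ranks for
tied absolute differences, signed Z from the normal approximation with
tie-corrected variance, no continuity correction (the convention of
the statistical package the source used, and the one consistent with
its printed Z/p pair). The approximation's discreteness error against
exact sign-pattern enumeration is bounded by ≈0.05 at n = 10 and
shrinks with n; the property tests assert that bound, and the
implementation is additionally pinned exactly against
`scipy.stats.wilcoxon(method="approx", correction=False)`.

## Pipeline

`run_full_study` executes: full-panel consensus → 4-category and binary
cross-tabulations per variant → entropy profile and paired Wilcoxon →
median split → entropy-stratum tables → junior/senior relabeling
(threshold 10 years; raters exactly at the threshold go to the junior
group by default, since the source's ">10 / <10" grouping leaves the
boundary undefined; `senior_is_inclusive` flips this) →
experience-stratum tables → agreement statistics and chi-square
comparisons for everything. The pipeline is deterministic in its
inputs; stage counts are logged at INFO level.

`run_from_fixtures` computes the statistics-only portion from the ten
shipped cross-tabulation matrices. The source study's raw 28×56
response matrix is unpublished, so its printed matrices are the only
anchor for the numerical results; rating-level stages are validated on
synthetic data instead. Consequently the study's entropy summary
statistics (medians 1.57/1.59 etc.) and its Wilcoxon Z = 1.345 are not
recomputable and are not asserted anywhere.

## Synthetic data generator

A latent-class model with per-rater confusion — the simplest generative
law consistent with the design. Defaults mirror the study scale and are
fixed once:

| parameter | default | rationale |
|---|---|---|
| n_raters | 28 | study panel size |
| n_images_per_category | 7 | study design (balanced truth) |
| variants | S, G | study design |
| senior_fraction | 12/28 | study's >10-year group size |
| junior/senior years | U(0,10) / U(10.5,25) | study range 0–25 years |
| junior/senior accuracy | 0.6 | mid-range agreement, comparable in magnitude to the observed binary Po |
| confusion | uniform | no published error structure; `within_nonideal` available to emulate panels that identify ideal posture reliably |
| confidence (correct) | (.05,.10,.20,.30,.35) over 1–5 | correct votes stochastically more confident |
| confidence (wrong) | (.25,.30,.25,.15,.05) | mirrored low-confidence profile |

Votes are independent across raters and items given the parameters.
Real panels are not: the study's images vary widely in difficulty, so
its per-item entropies spread from 0.81 to 1.90 bits, while this
generator's entropies cluster by accuracy level. Passing pipeline tests
on synthetic data therefore demonstrate correctness of the *computation*
(labels, strata, statistics, invariants), not that the generator
reproduces the study's response distribution. Parameter-recovery tests
(empirical rater accuracy within a binomial band, chance accuracy
driving entropy to 2 bits, monotone accuracy→PABAK trend, senior-skill
detection in the experience strata) validate the generator's own law.

## Numerical notes

- All agreement statistics are ratios of small integers computed in
  double precision; reproduction of the published values is exact to
  the printed precision (assertions use 5e-5 absolute tolerance on
  4-decimal values).
- Entropy uses `scipy.stats.entropy(base=2)`, which handles zero
  counts by the 0·log 0 convention.
- Degenerate inputs raise typed errors (`UndefinedStatisticError`,
  `UndefinedTestError`) or produce explicit `None` fields; the report
  renderers print them as "undefined".

## Limitations

- Majority vote only; no probabilistic annotator models (Dawid–Skene
  and relatives are out of scope by design).
- The chi-square comparisons use the asymptotic Pearson form on small
  cell counts, for fidelity to the published method, not because the
  asymptotics are trustworthy at n = 7–21 per group.
- PABAK's default 2·P<sub>o</sub> − 1 convention for K > 2 is
  non-standard (it is the source's convention); users comparing against
  other literature should request the multi-category form explicitly.
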