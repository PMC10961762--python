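# postagree

Rater-agreement analysis for posture classification panels.

`postagree` implements the full analysis chain used to decide whether a
panel of clinicians rating images can substitute for hands-on clinical
assessment when labeling training data: majority-vote consensus
labeling with confidence tie-breaking, Shannon-entropy triage of
ambiguous items, and agreement of the consensus labels against clinical
reference labels via PABAK, Cohen's kappa, sensitivity/specificity and
stratified chi-square comparisons.

The concrete setting is standing-posture assessment of older adults
under the four-category Kendall classification — ideal posture,
kyphosis-lordosis (KL), sway back (SB), and flat back (FB) — where a
panel of physical therapists rates sagittal silhouette (S) and
grayscale (G) images of people whose posture was also assessed
face-to-face (visual inspection plus palpation, the *clinical method*).
The machinery is generic: any complete block of raters × items ×
variants with categorical votes, 1–5 confidences, per-rater experience,
and a reference label per item.

## The statistics

For a K×K cross-tabulation with the clinical reference on rows and the
panel consensus on columns (cell counts *n<sub>ij</sub>*, total *n*):

- observed agreement **P<sub>o</sub>** = Σ<sub>i</sub> n<sub>ii</sub>/n,
  chance agreement **P<sub>e</sub>** = Σ<sub>i</sub> p<sub>i·</sub> p<sub>·i</sub>
  from the marginal proportions;
- **Cohen's κ** = (P<sub>o</sub> − P<sub>e</sub>)/(1 − P<sub>e</sub>);
- **PABAK** (prevalence- and bias-adjusted kappa) = 2 P<sub>o</sub> − 1
  by default for any K (the convention under which this study's values
  are reported), with the multi-category form
  (K P<sub>o</sub> − 1)/(K − 1) available as an option;
- κ significance via Fleiss's null standard error,
  SE₀ = √(P<sub>e</sub> + P<sub>e</sub>² − Σ<sub>i</sub> p<sub>i·</sub> p<sub>·i</sub>(p<sub>i·</sub> + p<sub>·i</sub>)) / ((1 − P<sub>e</sub>)√n),
  z = κ/SE₀, two-sided normal p;
- **sensitivity** / **specificity** of the binary ideal vs non-ideal
  collapse, with non-ideal as the positive class;
- verbal strength via the Landis–Koch bands.

Consensus labels are the category with the most votes; vote ties are
broken by the highest total confidence among the tied categories; a
residual double tie falls back to canonical category order and is
flagged. Item ambiguity is the Shannon entropy (bits) of the vote
distribution, 0 for a unanimous panel up to log₂4 = 2 for a uniform
one; items are split into low/high-entropy halves at the median. Strata
are compared with the uncorrected Pearson chi-square, and paired
entropies of the two image variants with the Wilcoxon signed-rank test.

## Worked example

The study's full-panel S-image cross-tabulation, collapsed to ideal vs
non-ideal:

```python
from postagree import (study_crosstab, collapse_binary,
                       agreement_report, sensitivity_specificity)

ct = collapse_binary(study_crosstab("table1", "S", "all"))
print(ct.to_frame())
#            IDEAL  NON_IDEAL
# IDEAL          4          3
# NON_IDEAL      3         18

rep = agreement_report(ct)
d = sensitivity_specificity(ct)
print(f"Po={rep.po:.4f}  Pe={rep.pe:.4f}  kappa={rep.kappa:.4f}")
print(f"PABAK={rep.pabak_binary:.2f} ({rep.landis})  z={rep.z:.3f}  p={rep.p:.4f}")
print(f"sensitivity={d.sensitivity:.2%}  specificity={d.specificity:.2%}")
```

prints

```
Po=0.7857  Pe=0.6250  kappa=0.4286
PABAK=0.57 (moderate agreement)  z=2.268  p=0.0233
sensitivity=85.71%  specificity=57.14%
```

Of the 28 images, 22 receive the same binary label from the clinical
assessment and the 28-rater panel. PABAK 0.57 is moderate agreement;
the panel catches 86% of clinically non-ideal postures (sensitivity)
but confirms only 57% of ideal ones (specificity); the kappa z-test
rejects chance-level agreement at p = 0.0233.

The same machinery runs end-to-end from rating-level data. A synthetic
panel with the study's design (28 raters, 7 images per category, S and
G variants) exercises every stage:

```sh
agree simulate --seed 7 --out-ratings ratings.csv --out-labels labels.csv
agree run --ratings ratings.csv --reference labels.csv --out report/ --format markdown
agree fixtures --out study_report/        # statistics from the published tables
```

`agree run` recomputes consensus labels, the entropy profile and median
split, junior/senior subgroup relabeling (threshold 10 years,
configurable), every stratum's agreement statistics, and all chi-square
comparisons plus the paired entropy Wilcoxon test.

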