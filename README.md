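# metabofe

Metabolite biomarker discovery for broiler feed efficiency.

Direct selection on feed efficiency (FE) requires per-bird feed-intake
recording, which is expensive at breeding-farm scale. An alternative is to
find plasma metabolites whose concentrations are heritable and genetically
correlated with FE, and select on those instead. `metabofe` implements that
analysis as a reusable pipeline for quantitative geneticists and metabolomics
analysts working with divergent-line designs:

1. **Feed-efficiency traits** — from BW4, BW7 and total 4–7-week intake FI:
   BWG = BW7 − BW4, MMBW = ((BW4+BW7)/2)^0.75, FCR = FI/BWG, and
   RFI = FI − (b0 + b1·MMBW + b2·BWG) from the cohort OLS fit.
2. **Metabolome preprocessing** — per-sample total-intensity normalization
   (rows sum to 1) and HMDB annotation filtering of birds × features panels,
   one per LC-MS ion mode.
3. **Screening** — two-class PLS-DA (NIPALS, autoscaled, A = 2 components)
   with R²X/R²Y and sevenfold stratified cross-validated Q²Y; features with
   VIP > 1 and Student's t-test P < 0.05 are differential.
4. **Genetics** — pedigree animal model Y = Xb + Za + e with Var(a) = A·g,
   Var(e) = I·r (line and sex fixed), fitted by average-information REML with
   EM warm-up; per metabolite: h² ± SE and genetic/phenotypic correlations
   with FCR and RFI ± SE, with non-convergence as a first-class outcome.
5. **Biomarker gate** — four criteria: differential; max |r_g| ≥ 0.30 over
   the FE indices (missing-aware); line-mean direction consistent with the
   qualifying r_g's sign; h² ≥ 0.20.

A synthetic-cohort generator (`metabofe.cohort`) produces pedigreed two-line
cohorts with known heritabilities and genetic correlations, so every stage is
testable without any data download, and the published genetic-parameter
tables ship as fixtures for exact gate replay (`metabofe.datasets`).

## Worked example: replaying the biomarker gate

```bash
metabofe replay-tables
```

prints, for the packaged tables (76 metabolites with estimable genetic
parameters, 34 positive- and 42 negative-mode):

```
[overall]
  metabolites:            76
  differential (c1):      76
  |rg| >= threshold (c2): 44 (25 positive, 19 negative)
  h2 pass among c2 (c4):  17
  full-gate passes:       14
    HMDB0000045, HMDB0000225, HMDB0000308, HMDB0000501, HMDB0000670,
    HMDB0001903, HMDB0002226, HMDB0002833, HMDB0003869, HMDB0004983,
    HMDB0011741, HMDB0033338, HMDB0038824, HMDB0062219
```

Reading: all 76 metabolites are differential between the lean and fat lines
(criterion 1); 44 have |r_g| ≥ 0.30 with FCR or RFI, 25 of them positive and
19 negative by the sign of the qualifying (larger-|·|) correlation; 17 of the
44 also have h² ≥ 0.20; and 14 additionally pass the line-mean direction
check — the candidate biomarker panel (e.g. HMDB0000501 is 7-ketocholesterol,
HMDB0002833 testosterone).

The same pipeline runs end to end on synthetic data:

```bash
metabofe simulate --out cohort/          # 441-bird two-line cohort
metabofe run-all --out run/ --seed 7     # traits -> screen -> REML -> gate
```

Library use mirrors scikit-learn: estimators expose `fit` and fitted
attributes with trailing underscores —

```python
from metabofe import PLSDA, q2_sevenfold
model = PLSDA(n_components=2).fit(X, lines)   # X: birds x features
model.vip_, model.r2x_, model.r2y_
q2_sevenfold(X, lines, n_components=2, seed=0)
```

## Layout

```
src/metabofe/
  cohort.py          synthetic pedigreed cohorts (SimulationConfig)
  feed_efficiency.py BWG/MMBW/FCR/RFI (RFIRegression)
  preprocess.py      normalization + HMDB filtering (MetaboliteMatrix)
  plsda.py           PLS-DA, VIP, Q2, t-tests (PLSDA)
  pedigree.py        pedigree container + A matrix (tabular method)
  animal_model.py    univariate/bivariate REML, genetic-parameter tables
  gate.py            four-criterion biomarker gate
  datasets.py        packaged reference tables
  cli.py             `metabofe` command-line interface
docs/methods.md      model details, numerical choices, limitations
```
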