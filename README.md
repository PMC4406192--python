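# sarmatrix

SAR matrices (SARMs) for analog-series analysis and virtual-compound
prediction in medicinal chemistry.

Screening and optimization data sets contain many overlapping analog
series. `sarmatrix` extracts them systematically: every compound is cut
once at each acyclic single bond into a **key** fragment (core) and a
**value** fragment (substituent); the cores are cut again, and cores that
share a second-step scaffold ("core MMPs") are gathered into a matrix whose
rows are cores and columns are substituents. Filled cells are library
compounds; empty cells are **virtual compounds (VCs)** — unexplored
core–substituent combinations that surround the measured series. Two
predictors then score those VCs:

- **Neighborhood (NBH) potency prediction.** For a VC X, any triple of
  measured compounds D (same substituent), G (same core) and E (D's core
  with G's substituent) gives a local Free-Wilson estimate
  `pot(X) = pot(D) + pot(G) − pot(E)`; the final prediction is the mean
  over all such neighborhoods, and its standard deviation flags SAR
  discontinuity (activity cliffs) where additivity cannot be trusted.
- **Conditional-probability activity prediction** for binary screening
  data (hit expansion). Per matrix, class frequencies `P(y|c)` and `P(y|v)`
  are computed per fragment, each compound is re-weighted by the inverse of
  its own-class fragment probability, weighted class contributions
  `C(y) = (α + Σ weights) / (2α + N)` are normalized into fragment class
  probabilities, and a VC's activity probability is the normalized product
  `p_x = P_c(act)P_v(act) / (P_c(act)P_v(act) + P_c(inact)P_v(inact))`.

Matrices with more than 50% row overlap (shared substitution patterns
between series) are considered informative and used for probability
predictions.

## Worked example

The nine-compound demo screen (three cores c1–c3, four substituents
v1–v4, binary labels) is shipped with the package. Scoring its virtual
cell X = (c3, v1):

```python
from sarmatrix import enumerate_virtuals, predict_activity
from sarmatrix.condprob_predictor import explain_probability
from sarmatrix.matrix_builder import build_matrices_from_records
from sarmatrix.synthetic_data import demo_screen

(m,) = build_matrices_from_records(demo_screen())
ex = explain_probability(m, core="c3", value="v1", alpha=0.1)
print(ex.initial.core_probs["c3"])   # {'active': 0.333..., 'inactive': 0.666...}
print(ex.core_contribution.contributions)
print(ex.value_contribution.contributions)
print(ex.core_probs, ex.value_probs)
print(ex.p_x)
```

prints

```
{'active': 0.3333333333333333, 'inactive': 0.6666666666666666}
{'active': 0.34375, 'inactive': 1.125}
{'active': 0.7272727272727273, 'inactive': 1.409090909090909}
(0.23404255319148937, 0.7659574468085106) (0.34042553191489366, 0.6595744680851063)
0.1362229102167183
```

Core c3 appears in one active and two inactive compounds, so its initial
activity probability is 1/3. Re-weighting by substituent evidence barely
changes the picture (normalized activity probability 0.23), value v1 is
split (0.34 after re-weighting), and combining both gives an activity
probability of 0.136 for X — predicted inactive at a 0.5 threshold. The
same pipeline is available from the shell:

```bash
sarm predict-activity demo_screen.csv --format fragment-table -o out/
```

which reports the run summary (9 compounds, 1 matrix, 3 VCs, 2 predicted
active) and writes a ranked `activity_predictions.csv`.

For numeric potency data, `sarm predict-potency library.csv` runs
fragmentation, matrix building and neighborhood prediction from SMILES
input; `sarm make-synthetic` generates combinatorial benchmark libraries
with planted additive potencies, activity cliffs or active fragments.

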