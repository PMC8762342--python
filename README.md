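# vesipred

Identification of **vesicular transport proteins** (VTPs) from evolutionary
sequence profiles with gradient boosting.

Vesicular transport proteins mediate the membrane-bound shuttling of
macromolecules between cellular compartments; their dysfunction underlies
diseases such as Hermansky–Pudlak syndrome and chylomicron retention
disease. Experimental identification is accurate but slow, so sequence-based
classifiers are used to triage candidates. `vesipred` implements a complete
profile-based pipeline for this binary classification problem, aimed at
computational biologists who have PSI-BLAST profiles (or sequences to
profile) and want a trainable, evaluable classifier with honest
cross-validation.

## Method

The input for each protein is its position-specific scoring matrix (PSSM):
an L × 20 matrix *P* of log-odds substitution scores from iterative
PSI-BLAST search (3 iterations against NR; the package consumes the ASCII
`-out_ascii_pssm` output and does not run PSI-BLAST itself). Scores are
mapped through the logistic function 1/(1+e^(−x)) before feature
extraction.

Two feature encoders are fused into a 1,120-dimensional vector:

* **AATP (420)** — amino-acid composition
  x_j = (1/L)·Σᵢ P_ij (20 values) plus transition probability composition,
  the row-normalized matrix of consecutive-position score products
  X_ij = Σₖ P_{k,i}P_{k+1,j} / Σ_j' Σₖ P_{k+1,j'}P_{k,i} (400 values).
* **CSP-SegPseP-SegACP (700)** — segmented pseudo-PSSM (two- and
  three-segment means and mean squared lag-λ differences, 200 + 180),
  segmented autocovariance at lags 1–4 / 1–2 (160 + 120), and
  consensus-sequence composition and composition-moment features (40),
  where the consensus is the per-row argmax residue.

The training set is imbalanced (few VTPs), so **edited nearest neighbours
(ENN)** removes majority-class samples whose neighbourhoods disagree with
their label. Feature dimensionality is reduced by **MRMD**
(Max-Relevance-Max-Distance): features are scored by |Pearson r| with the
label and by mean column distance (non-redundancy), then ranked either by
the score sum or by link-analysis centralities (HITS authority/hub,
PageRank, TrustRank, LeaderRank) on a margin-weighted preference graph. The
classifier is **XGBoost** (1,000 trees, depth 8, η = 0.1, subsample and
colsample 0.8, `scale_pos_weight` 0.6).

Evaluation uses stratified k-fold cross-validation in which resampling,
standardization and feature selection are fitted *inside each training
split only* — synthetic or removed rows can never contaminate a validation
fold. The metric suite reports ACC, Sens, Spec, Precision, MCC, balanced
accuracy (Sens+Spec)/2 and the trapezoidal ROC AUC.

Because the original curated dataset requires PSI-BLAST runs against NR,
the package ships a synthetic profile generator
(`simulate_profiles`) that plants class-dependent structure — a mean shift
on designated profile columns and an elevated probability that consecutive
rows share their argmax — so that every pipeline stage is testable offline.

## Worked example

```python
from vesipred import SyntheticDatasetSpec, simulate_profiles
from vesipred.model import VesicleTransportModel

profiles, labels = simulate_profiles(
    SyntheticDatasetSpec(n_positive=100, n_negative=200, seed=7)
)
model = VesicleTransportModel.from_profiles(
    profiles, labels, select_method="hits_h", select_k=200
)
results = model.fit(k=5, repeats=1, seed=7)
print(results.summary())
```

```
Vesicular transport protein classifier
================================================
samples:            300 (100 positive)
features:           1120 -> 200 used
resampler:          enn_undersample
selection:          hits_h (k=200)
classifier:         XGBoost (1000 trees, depth 8, eta 0.1, scale_pos_weight 0.6)
cross-validation:   5-fold x 1 (seed 7)
------------------------------------------------
mean cross-validation metrics
n = 60  (TP 19.8 | FP 0.6 | TN 39.4 | FN 0.2)
       acc: 0.9867
      sens: 0.9900
      spec: 0.9850
 precision: 0.9727
       mcc: 0.9712
balanced_auc: 0.9875
   roc_auc: 0.9992
```

The per-fold counts are averages over the five validation folds. `sens`
(recall of the vesicular class) and `spec` (recall of the non-vesicular
class) together give the balanced accuracy `balanced_auc`; `roc_auc` is the
threshold-free area under the ROC curve. On this synthetic dataset the
planted class signal is strong, so all metrics are near 1; on real data the
numbers are substantially lower. `results.predict_profiles(...)` scores new
profiles, `results.evaluate(test_table)` reports on a disjoint holdout, and
`results.save(dir)` / `vesipred.load_pipeline(dir)` persist the pipeline.

A `vesipred` console command exposes the same stages
(`simulate`, `extract`, `balance`, `select`, `cv`, `train`, `evaluate`,
`predict`); see `vesipred --help`.

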