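# blockcca

Sparse multiblock canonical correlation analysis for imaging
transcriptomics: linking a blood gene-expression block and a brain-ROI
activity block to a binary clinical phenotype (schizophrenia patient vs.
healthy control), with the full inference chain around it — confound
residualization, univariate differential screening with
Benjamini–Hochberg adjustment, per-block MANCOVA, externally
cross-validated LDA classification on latent components, and
fold-stability signature selection.  A ΔΔCt module produces the
expression block from raw qPCR Ct data, and a synthetic-data generator
emulates the two-block + phenotype structure with a known latent causal
chain for calibration and recovery studies.

## The model

Given J blocks X₁, …, X_J (here: RNA ≈ 33 candidate-gene fold changes,
IMG = 16 ROI mean beta values, DX = the standardized 0/1 diagnosis)
measured on the same n subjects, the engine estimates one weight vector
a_j per block by maximizing

    Σ_{j,k} C_{jk} · g( cov(X_j a_j, X_k a_k) )

subject to either a_jᵀ M_j a_j ≤ 1 with
M_j = τ_j I + (1 − τ_j) X_jᵀX_j / n (regularized mode) or
‖a_j‖₂ ≤ 1, ‖a_j‖₁ ≤ s_j √p_j (sparse mode).  C is a binary symmetric
design matrix encoding the causal hypothesis:

* **sequential** — RNA–IMG, IMG–DX (brain activity mediates between
  peripheral expression and diagnosis);
* **complete** — all three edges;
* **reversed-sequential** — IMG–RNA, RNA–DX (expression mediates).

g is the scheme function (identity, square, or absolute value; default
absolute value).  Optimization is monotone block relaxation; the sparse
update projects the criterion gradient onto the L1∩L2 ball by
soft-thresholding.  The block components y_j = X_j a_j feed a two-class
LDA (RNA and IMG scores only), evaluated by an external stratified
5-fold cross-validation with per-fold residualization and inner-CV
sparsity tuning.  Per-variable fold loadings are aggregated into an
occurrence count and a mean absolute loading ("meanf"); variables
selected in ≥ 3 of 5 folds are flagged robust.

## Worked example

```python
import blockcca as bc

ds = bc.generate_multiblock(bc.SyntheticSpec(n_case=100, n_control=100, seed=0))
report = bc.cross_validate(ds, design="sequential", seed=0)
print(f"mean test error: {report.mean_error:.3f}")
print(report.signature("rna").head(6).round(3).to_string(index=False))
```

prints

```
mean test error: 0.155
variable  meanf  occurrence  robust  fold1  fold2  fold3  fold4  fold5
 gene_01  0.746           5    True  0.882  0.882  0.913  0.500  0.552
 gene_02  0.456           5    True  0.342  0.246  0.376  0.846  0.469
 gene_05  0.202           4    True  0.324  0.000  0.130  0.184  0.371
 gene_03  0.166           2   False  0.000  0.400  0.000  0.000  0.427
 gene_04  0.098           4    True  0.000  0.019  0.077  0.018  0.377
 gene_14  0.018           1   False  0.000  0.000  0.000  0.000  0.088
```

The generator planted genes 1–5 as the RNA support of a sequential
diagnosis → imaging → RNA chain: the five planted genes top the
signature table, four of them selected in ≥ 4 of 5 folds, while the
first pure-noise gene appears once with a small loading.  The 15.5 %
test error reflects the planted path strengths and per-variable noise.
The signature table follows the published convention: mean absolute
loading across folds ("meanf"), occurrence count of nonzero loadings,
robust flag, then the per-fold absolute loadings.

The same analysis runs from the shell:

```bash
blockcca simulate --seed 0 --n-case 100 --n-control 100 --out data/
blockcca crossval --expression data/expression.tsv --imaging data/imaging.tsv \
    --phenotype data/phenotype.tsv --design sequential --seed 0 --out results/
blockcca run-all --config config.yaml   # full pipeline with manifest
```

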