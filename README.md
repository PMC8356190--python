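# tmescore

Tumor-microenvironment (TME) scoring and immune-checkpoint-blockade (ICB)
biomarker evaluation for bulk transcriptomics.

Durable benefit from checkpoint blockade is confined to a minority of
patients, and tumor-intrinsic biomarkers (PD-L1 combined positive score,
tumor mutation burden, microsatellite instability) ignore the immune and
stromal milieu that gates the response. This package implements the
TMEscore methodology — a composite transcriptomic score contrasting
immune-associated against stromal/immune-exclusion-associated gene-set
activity — together with the statistical machinery used to evaluate any
continuous score as an ICB-response and prognosis biomarker. It is a
library first (importable API plus `examples/` scripts) with a thin
`tmescore` CLI for shell pipelines.

## The score

For a gene-expression matrix (RMA/TPM/FPKM- or housekeeping-normalized,
log2 scale), each signature's genes are standardized across samples to mean
0 and SD 1. The signature score is **PC1**: the projection of the z-scored
signature submatrix onto the unit-norm leading eigenvector of its gene-gene
covariance, which concentrates the score on the largest block of co-varying
genes and down-weights genes that do not track the rest. With signatures
split into immune-associated sets *i* (direction +1, "A") and
stromal-associated sets *j* (direction −1, "B"):

```
TMEscore = Σ PC1_i − Σ PC1_j  =  TMEscoreA − TMEscoreB
```

High TMEscore = immune-hot, stroma-poor — the profile that predicts ICB
response. Alternative per-signature scorers (single-sample GSEA with rank
weight `rank^α`, and the mean of z-scored genes) are provided behind the
same interface, as is geometric-mean housekeeping normalization for
NanoString-style linear counts.

Around the score: ROC/AUC with midrank ties and the DeLong test for
comparing correlated AUCs; Mann-Whitney, Kruskal-Wallis, two-sided Fisher
exact, Spearman, Benjamini-Hochberg; Kaplan-Meier, log-rank, univariate Cox
(Efron or Breslow ties); maximally-selected log-rank cutpoints with a
minimum-group-proportion constraint; and genome-/signature-wide association
screens (score vs binary mutations, subtype enrichment, score vs other
signatures). A seeded synthetic-cohort generator with recorded latent truth
makes every stage testable end to end.

## Worked example

```python
import tmescore as tm

expr, panel, clinical = tm.make_fixture_panel()          # linear counts
normalized, report = tm.normalize_housekeeping(expr, tm.HOUSEKEEPING_GENES)
table = tm.compute_signature_scores(normalized, panel, method="pca_pc1")
result = tm.compute_tmescore(table, panel).classify(cutoff=0.0)
print(result.to_frame().head(3).round(3))
```

```
       TMEscoreA  TMEscoreB  TMEscore TMEscore_class
GC001     -1.654     -2.711     1.058           high
GC002     -4.913     -3.257    -1.656            low
GC003     -3.229     -0.468    -2.761            low
```

GC001's immune signature activity exceeds its stromal activity
(TMEscore = −1.654 − (−2.711) = 1.058 > cutoff), so it is classed
TMEscore-high — the group expected to respond to checkpoint blockade and to
show longer survival. On a simulated 120-patient cohort the same pipeline
yields `TMEscore AUC = 0.906` against response versus `0.801` for the
immune arm alone, with a paired DeLong comparison `z = 3.25, p = 0.0012`
(`examples/02_biomarker_evaluation.py`).

The `examples/` scripts cover one capability each: scoring and
normalization, biomarker evaluation, survival cutpoints, mutation/subtype
screens, and cohort simulation. The equivalent CLI:

```sh
tmescore simulate --seed 7 --outdir cohort/
tmescore score --expr cohort/expression.tsv --gmt cohort/signatures.gmt --out scores.tsv
tmescore evaluate --scores scores.tsv --clinical cohort/clinical.tsv --out report.tsv
tmescore survcut  --scores scores.tsv --clinical cohort/clinical.tsv --out cut.tsv
```

Every output begins with `#` header lines carrying the full parameter set
and input MD5 checksums. Exit codes: 0 success, 1 data/validation error,
2 usage error.

Note on gene sets: standard GMT has no field for a sign, so the direction
of each signature in the TMEscore sum is read from the GMT description
field (`+1`/`-1`; anything else defaults to +1 with a warning). The
packaged panel (`tmescore.load_panel()`) is a synthetic stand-in with the
NanoString-panel structure (25 A genes, 19 B genes, 10 housekeeping genes);
substitute your own validated GMT for real analyses.

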