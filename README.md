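# irgpsig

Prognostic risk signatures from **immune-related gene pairs (IRGPs)** —
rank-based, normalization-free survival modelling for tumor transcriptomes,
with a shipped 30-pair bladder-cancer signature.

## The problem and the method

Risk signatures built from absolute expression values transfer poorly
between platforms (RNA-seq FPKM, microarray intensity, targeted panels)
because each platform distorts the expression scale differently.  The
gene-pair approach sidesteps normalization entirely: for an ordered pair of
genes (A, B) and a sample *s*, the feature is the binary indicator

```
x_{(A,B),s} = 1  if  expr(A, s) > expr(B, s),   else 0
```

which depends only on the *within-sample* ranking, and is therefore
invariant under any strictly increasing per-sample transformation of the
data — log-scaling, quantile shifts, platform-specific calibration curves.

The pipeline:

1. **Pair transform** — restrict the expression matrix to an immune gene
   list and binarize every unordered gene combination (canonical
   orientation fixed by gene-list position).
2. **Frequency filter** — drop pairs whose minor state occurs in fewer than
   20% of samples (uninformative, near-constant indicators).
3. **Univariate Cox screen** — keep pairs whose indicator predicts overall
   survival at Wald *P* < 0.05.
4. **LASSO-Cox** — fit an L1-penalized Cox model over the candidates, the
   penalty λ chosen by tenfold cross-validated partial-likelihood deviance
   (lambda.min); pairs with nonzero coefficients form the signature.
5. **Risk score** — score(s) = Σ_p β_p·x_{p,s}; a cutoff chosen by
   time-dependent ROC analysis (Youden's J) splits patients into high- and
   low-risk groups.
6. **Evaluation** — Kaplan–Meier curves, the log-rank test, uni/multivariable
   Cox models, time-dependent AUC at 1/3/5 years, and association of the
   risk score with clinical variables (Fisher's exact test), immune features
   (Pearson correlation, rank-sum comparisons) and tumor mutation burden.

The package also ships `blca_irgp30.json`: a 30-pair, 30-gene signature for
bladder-cancer overall survival trained on the TCGA-BLCA cohort
(classification cutoff 0.538, λ = 0.03253915), usable on any expression
matrix that contains its 30 genes — no normalization required.

A seed-deterministic synthetic-cohort generator (`irgpsig.simulate`)
produces expression, survival and mutation data with the exact structure
the pipeline assumes, so every stage is testable without downloading any
cohort.

## Worked example

```python
import pandas as pd
from irgpsig import (SimulationConfig, simulate_cohort, PipelineConfig,
                     run_full_pipeline, load_packaged_signature, score_samples)

# a synthetic 250-tumor cohort with three implanted prognostic pairs
expr, surv, truth = simulate_cohort(SimulationConfig(
    n_samples=250, n_genes=16, n_signal_pairs=3, betas=(1.0, -1.0, 1.0), seed=11))

result = run_full_pipeline(PipelineConfig(
    expression=expr, clinical=surv, gene_list=list(expr.index),
    seed=11, horizons=(365, 730), cutoff_horizon=730, n_folds=5))

print(len(result["model"].pairs))        # 17  pairs selected by LASSO-Cox
print("%.3g" % result["logrank"]["p"])   # 8.06e-19  high vs low risk log-rank p
print(round(result["auc"][365.0], 3))    # 0.818  1-year time-dependent AUC

# scoring an expression matrix with the shipped bladder-cancer signature
model = load_packaged_signature()
print(len(model.pairs), model.cutoff)    # 30 0.538
```

The log-rank *p* of ~1e-18 says the fitted signature separates the
simulated high- and low-risk groups far beyond chance, and the AUC ≈ 0.82
is the probability that a patient who dies within the first year carries a
higher risk score than one who survives past it.

The same flow is available from the shell:

```bash
irgpsig simulate --n-samples 150 --n-genes 16 --k 3 --seed 3 --outdir sim
irgpsig transform --expression sim/expression.tsv --gene-list sim/gene_list.txt --out pairs.tsv
irgpsig screen    --pairs pairs.tsv --clinical sim/clinical.tsv --out screen.tsv
irgpsig run       --config cfg.json        # end-to-end, writes a result bundle
irgpsig score     --expression sim/expression.tsv --signature out/signature.json --out scores.tsv
```

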