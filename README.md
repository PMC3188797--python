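# chromexpress

Statistical toolkit for relating **positional chromatin-feature signal**
(histone modifications, polymerase and chromatin-factor binding from
ChIP-chip / ChIP-seq) to **gene expression** (RNA-seq RPKM), built for
genome-wide studies of the kind produced for *C. elegans* and other model
organisms.

For each transcript, the regions ±4 kb around the transcription start site
(TSS) and the transcription termination site (TTS) are tiled with 100 bp
bins — 80 bins per anchor, 160 per transcript.  Signal aggregated per bin
yields, for every bin *b*, a predictor matrix **A**<sub>n×m</sub>
(*n* transcripts × *m* features).  On these matrices the toolkit provides:

* **Association** — per-bin Spearman ρ of each feature with expression, and
  two-cluster hierarchical splits whose between-cluster Welch *t*-score
  measures how well a bin (or a single feature's 160-bin profile)
  discriminates highly from lowly expressed genes.
* **Prediction** — support-vector classification (high/low split at the
  median of log₂(RPKM+1)) and regression (SVR on log₂(RPKM+1)) with
  repeated random-half cross-validation; ROC/AUC with ties counted ½
  (equivalently the Mann–Whitney pair statistic), Pearson *r*, and the
  identity R² = r² for variance explained.  Feature subsets, 40-bin joint
  models, and transcript-body coverage features are supported.
* **Combinatorics** — OLS models of log expression with all pairwise
  product terms (`y ~ Σxᵢ + Σᵢ<ⱼ xᵢxⱼ`) versus the main-effects-only
  singleton model, per-pair 3-term models, Gaussian-mixture H/L signal
  categorisation with four-group (HH/HL/LH/LL) expression comparison, and
  the normalised joint mutual information
  I(E;(H₁,H₂)) / max(I(E;H₁), I(E;H₂)).
* **Transfer** — one stage's chromatin evaluated against every
  developmental stage's expression; correlation profiles by operon position
  (first / second / last genes); prediction of microRNA expression from
  pre-miRNA-locus signal with a model trained on protein-coding genes.
* **Synthetic data** — a fully seeded generator (annotation GFF3, bedGraph
  tracks, expression tables, operons, miRNA loci, and a ground-truth JSON)
  whose latent model makes every analysis testable without downloads.

## Worked example

```python
import chromexpress as cx

spec = cx.GeneratorSpec(seed=42, n_transcripts=1000)
ds = cx.generate_tensor(spec)

prof = cx.spearman_profile(ds.tensor, ds.expression, "EEMB")
print("H3K79me2 peak bin:", prof.peak_bin("H3K79me2"),
      f"rho={prof.rho.loc['H3K79me2'].max():.3f}")

design = cx.bin_design(ds.tensor, ds.expression, "EEMB", "TSS:d1")
report = cx.ExpressionModel(design, kind="svm").cross_validate(n_repeats=20, seed=7)
print(report.summary())
svr = cx.ExpressionModel(design, kind="svr").cross_validate(n_repeats=20, seed=7)
print(f"SVR PCC {svr.mean:.3f} -> variance explained {cx.variance_explained(svr.mean):.3f}")
```

prints

```
H3K79me2 peak bin: TSS:u1 rho=0.561
Cross-validation report (svm)
  repeats : 20
  n       : 1000
  AUC    : 0.8861 (sd 0.0093)
  seed    : 7
SVR PCC 0.795 -> variance explained 0.633
```

The K79-methylation signal correlates most strongly with expression in the
bin straddling the TSS (ρ ≈ 0.56); an SVM trained on the 16 features of the
first transcribed bin separates highly from lowly expressed transcripts
with held-out AUC ≈ 0.89, and the corresponding SVR explains ≈ 63 % of the
variance of log expression — the regime expected when marks are strongly
but redundantly coupled to transcription.

The same analyses run from the shell:

```sh
chromexpress simulate --seed 5 --n-transcripts 150 --out fixtures/
chromexpress bin --annotation fixtures/annotation.gff3 --tracks fixtures/tracks.tsv --out tensor/
chromexpress correlate --tensor tensor/ --expr fixtures/expression.tsv --stage EEMB --out profile.tsv
chromexpress train --tensor tensor/ --expr fixtures/expression.tsv --bin TSS:d1 \
    --model svm --repeats 100 --seed 17 --out report.json
```

Every output directory carries a `run_manifest.json` recording the
configuration, seed, and SHA-256 of each input.

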