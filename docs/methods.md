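# Methods

## Coordinates, anchors and bins

All genomic intervals are 0-based half-open internally; GFF3 input
(1-based inclusive) is converted on read, BED input is taken as is.  The
TSS is the 5′-most transcribed base in transcript orientation and the TTS
the 3′-most; in many annotations these coordinates are really the
boundaries of the protein-coding region, and the toolkit deliberately uses
whatever anchors the annotation provides rather than inferring promoters.

Each anchor carries `2·flank/width` bins (default 4 000 / 100 → 80).
Labels are `u40..u1` upstream and `d1..d40` downstream per anchor; `u1` is
the bin covering the 100 nucleotides immediately upstream of the anchor,
`d1` the first transcribed bin.  The flattened 160-vector order is TSS
`u40→d40` then TTS `u40→d40`.  For a `-`-strand transcript upstream bins
lie at higher genomic coordinates, so that bin vectors are strand
symmetric: mirroring all inputs around the anchor leaves the vector
unchanged (a property test asserts this).  Bins are never clipped; a bin
extending below coordinate 0 is wholly masked.  For transcripts shorter
than twice the flank, TSS-downstream and TTS-upstream windows overlap and
are computed independently; the `long` (>8 kb strictly) and `isolated`
(≥4 kb end-to-start gap) filters exist to check that conclusions survive
removing such transcripts.

**Probe aggregation.**  A tiling-array probe contributes to exactly one
bin, the one containing its midpoint; the bin value is the arithmetic mean
of its probes, and a probe-free bin is masked.  The midpoint rule avoids
double counting of typical ~50-mer probes that straddle bin boundaries.

**Read aggregation.**  A sequencing read contributes
`overlap_bp / read_length` to every bin it touches, so a fully contained
read contributes exactly 1 and total read mass is conserved over any
containing window.  Read-free bins score 0, not masked — the absence of
reads is informative.

**Per-bin normalisation.**  Feature columns of a bin matrix are made
comparable by `(x − median)/sd` (sample sd, unmasked entries only);
zero-variance columns raise an error naming the feature.

## Association statistics

Spearman ρ is computed pairwise-complete per (feature, bin) with
average-rank tie handling; cells with fewer than 10 usable transcripts
(configurable) are masked rather than raising.  Because ρ is invariant
under monotone transforms, the expression scale does not matter here; for
everything that is scale-sensitive (t-tests, group means, regression
targets) expression enters as log₂(RPKM+1).

Cluster discrimination scores use agglomerative clustering with Euclidean
distance and complete linkage, cut at the top branch into two clusters,
followed by a Welch unequal-variance t-test of log expression between the
clusters; |t| is the score.  Distance and linkage are not dictated by the
analysis itself; complete linkage was chosen as the long-standing default
of the standard hierarchical-clustering implementations, and the linkage
tie-break (lower leaf index) makes scores independent of input order.
When one feature's 160-bin profile is clustered, masked bins are imputed
to 0 after normalisation (the column median) so no transcript is dropped.
A top-level cluster smaller than 2 yields an undefined (NaN) score rather
than an exception.

## Supervised models

Classification targets the high/low split of log expression at its median,
ties assigned to "low" (deterministic and near-balanced).  Models are
RBF-kernel SVMs (classification) and SVRs (regression) with C = 1,
kernel width γ = 1/p for p predictors, ε = 0.1; predictors are z-scored on
the training half and the transform applied to the test half.  These
hyperparameters are deliberately plain — the toolkit measures how
informative bins and features are, not how far tuning can push a learner —
and all of them are exposed in `RunConfig`.  Rows with any masked
predictor are dropped per design (count logged), not imputed.

Cross-validation repeats random half-splits (default 100); each repeat
reports AUC (classification) or Pearson r (regression) on the held-out
half.  The split sequence is a pure function of the seed and n, so models
for different bins or feature subsets are compared on identical
partitions.  A repeat whose halves lack a class is redrawn and counted.
AUC is computed from average ranks, which is exactly the pair-counting
(Mann–Whitney) statistic with ties ½; the ROC sweeps the distinct score
values plus ±∞.  R² is reported as the square of the held-out Pearson r.

The transcript-body coverage feature is the fraction of body bins whose
signal strictly exceeds a threshold defined as a quantile of that
feature's pooled body-bin signal.  The default is the top decile
(quantile 0.9); "strong signal" has no canonical definition, so the
quantile is a configuration knob and results quoting it should state it.

## Combinatorial effects

The interaction model regresses log expression on standardised feature
signals plus all m(m−1)/2 pairwise products (OLS, intercept always
included); per-term two-sided p-values come from the usual t statistics,
and pairs are called significant at α = 0.001.  Whether such p-values
should additionally be multiplicity-adjusted before counting significant
pairs is a reporting choice; the table carries raw p-values and the
four-group tests carry both raw and Holm-adjusted values.  The singleton
model drops the product terms; both models' predictive power is compared
by the shared cross-validation machinery (PCC).  Rank-deficient designs
raise an error listing the collinear terms.

H/L categorisation of one mark fits a 2-component Gaussian mixture (EM,
k-means initialisation, fixed seed) on standardised values; the mixture is
accepted only when its BIC beats a single Gaussian and both weights are
≥ 0.1, otherwise — the signal is not bimodal — the split falls back to the
median, and the object records which method was used.  Standardising
before EM makes labels invariant to affine rescaling.

Mutual information uses equal-frequency discretisation (ordinal ranks
break ties) into k = 3 levels per variable by default (joint variable:
k² cells) and the plug-in estimator.  The reported ratio
I(E;(H₁,H₂))/max(I(E;H₁),I(E;H₂)) is ≥ 1 wherever defined because the
plug-in empirical distribution obeys the data-processing inequality; a
duplicated mark gives exactly 1, and values well above 1 flag joint
information (e.g. XOR-like structure) that neither mark carries alone.
Plug-in MI is biased upward at small n / large k; k_bins is configurable
and comparisons should hold k fixed.

## Transfer analyses

Cross-stage evaluation retrains a model per target stage — chromatin
predictors from the reference stage, labels from the target stage — under
identical CV partitions, rather than reusing one stage's fitted weights;
this matches the question "how much of stage-s expression is explained by
reference-stage chromatin".  Differentially expressed subsets use
`(max + 1)/(min + 1) ≥ fold` on RPKM (pseudocount 1 keeps the ratio
defined at zero and the rule symmetric).

Operon positions: `first` is the promoter-bearing gene, `last` the final
gene; `second` is defined only for operons with ≥ 3 genes, so a 2-gene
operon contributes first + last and never double-counts its downstream
gene.  Besides per-position correlation profiles the analysis reports
first/second and first/last mean-RPKM ratios, the same ratios of medians
(far more stable under the heavy-tailed RPKM distribution at a few hundred
operons), and the Pearson correlation of first- vs second-gene log
expression.

miRNA prediction averages each feature over the pre-miRNA locus itself
(no flank by default — annotated hairpin starts may lie kilobases from the
true TSS, so flanking windows would be anchored on the wrong point) and
feeds the resulting vector to a model trained on protein-coding designs
with the same feature set; a feature mismatch raises.

## The synthetic-data generator

The generator is the package's study-condition module, not a test helper:
its defaults define the data regime every quantitative claim is measured
under.

Latent model (per transcript t, feature f, stage s):

    a_{t,f}   = sign_f·√r·z_t + √(1−r)·u_{t,f}          coupled features
    g_t       = Σ_f sign_f·β_f·a_{t,f} + Σ_{(i,j)} c_ij·a_i·a_j
    e_t^s     = s_e·(ρ_s·g_t/sd(g) + √(1−ρ_s²)·η) + σ_e·ε
    x_{t,f,b} = w_f(b)·a_{t,f} + N(0, sd_f)             probe features
    RPKM      = max(2^(μ + e) − 1, 0)

The shared factor z (weight r = 0.6) reproduces the strong mutual
correlation and partial functional redundancy of real histone marks:
activating marks correlate positively with one another and negatively with
repressive marks, and no single mark is indispensable for prediction.
Without it, sixteen independent weak predictors would give per-mark
correlations far below what chromatin data show.  Defaults: per-bin noise
sd 0.7; chromatin-explainable expression scale s_e = 2.5 and residual
σ_e = 1.25 log₂ units (so chromatin can explain at most ≈ 80 % of
expression variance, and realised held-out R² lands near 0.6); μ = 3.5
puts RPKM in a realistic 0–100 range with a zero-inflated lower tail from
clipping.  The 16-feature default panel has promoter bumps (K4
methylations, σ ≈ 2 bins, centred at TSS:u1), transcribed-region marks
(K36, flat/decaying), strongly coupled TSS bumps (K79, centred TSS:d1),
flat negatively coupled repressive marks (K9/K27), a read-assay polymerase
peaking after the TTS, and five uncoupled decoys (H3 and four
X-inactivation factors) that calibrate chance-level behaviour.  Stage
coupling ρ = (1, .85, .75, .65, .55, .45) across six stages makes the
chromatin stage strictly the best predicted.  Operon members beyond the
first gene get chromatin decoupled from expression and a variance-matched
expression drop of 2-fold (second) / 3-fold (last) with weak residual
coupling (ρ ≈ 0.3) to the first gene.  miRNA loci reuse the coding
signal→expression law with the locus as a single window.

Serialisation: transcripts are laid out well separated (lengths 8.2–12 kb,
gaps > 2 flanks) so every probe covers exactly one bin of one transcript
and genomic aggregation reproduces the modelled signal exactly; where
operon windows collide, the first writer wins and later bins go unprobed.
Read features emit one bin-aligned read per Poisson count.  All randomness
flows from the single mandatory seed; the same seed yields byte-identical
files.  For large studies the tensor is built directly from the latent
model (`generate_tensor`), skipping track materialisation.

What the generator does **not** emulate: nucleosome-level sequence
structure, spatially correlated measurement noise, mappability and GC
biases, antisense transcription, isoform overlap, or the X-vs-autosome
binding specificities of dosage-compensation factors.  Passing tests
therefore demonstrate that the statistical machinery recovers the
structure it targets under a faithful noise model — not that real
chromatin data will reach the same accuracies.

## Numerical and testing choices

Problem sizes: the reference recovery study uses 2 000 transcripts × 16
features, the operon/miRNA study 881 operons and 162 loci, the null
false-positive sweep 200 seeds at n = 1000, m = 12; oracle equivalence
checks (pair-counting AUC, average-rank Spearman, per-base read counting)
run 1 000 random instances each.  These sizes put Monte-Carlo noise well
inside the asserted tolerances while keeping a full run in minutes on one
CPU.  Degenerate inputs are defined, not improvised: constant expression
cannot be discretised (error); a constant signal column cannot be
normalised (error naming the column); constant predictions give NaN PCC
(masked); both-constant equal-mean groups give t = 0, p = 1; an
undefined MI denominator gives NaN.

Known limitations: the per-bin Spearman loop is quadratic in
(features × bins) and takes a few seconds at n = 2000 — acceptable here,
vectorisable if profiles become a bottleneck; the GMM bimodality decision
(BIC + weight floor) is a heuristic and can prefer the mixture for heavy
tails; plug-in MI bias is not corrected; hierarchical clustering is O(n²)
memory and is not intended for full-genome transcript sets without
subsampling.
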