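# Methods

`inferreg` infers tissue-specific regulons — a transcription factor (TF)
together with the target genes (TGs) it regulates in a given tissue — from
bulk RNA-seq counts, TF binding motifs, and ChIP-seq peaks. This note
documents the model behind each stage, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices that were genuinely open.

## Pipeline model

### Candidate edges from co-expression

Each target gene's expression, as log1p(CPM), is regressed on the
expression of all TFs with a stochastic gradient-boosted tree ensemble
(50 trees, learning rate 0.1, subsample 0.9, depth 3, early stopping on a
10% holdout). The importance (IM) of TF *t* for target *u* is *t*'s share
of the ensemble's split gain, normalized to sum to 1 over TFs per target.
Because IM is normalized per target, the default IM threshold (0.005,
inclusive) has different semantics from pipelines that threshold raw gain;
with 40 TFs a non-informative predictor sits near 1/40 = 0.025, so 0.005
is a permissive floor that mainly removes noise attributions.

Surviving edges must also have pooled-sample Spearman correlation
ρ > 0.03, signed and strict. The signed rule discards repressive
(negative-ρ) edges, consistent with the downstream focus on upregulated
DEGs; `rho_absolute` switches the filter to |ρ|.

### Motif support

Promoters are the 2000 bp upstream of the TSS, strand-aware and clipped at
chromosome bounds: with `tss0` the 0-based TSS base, `[tss0−2000, tss0)`
on the + strand and `[tss0, tss0+2000)` (reverse-complemented at scan
time) on the −.

Two scanners must both confirm a (motif, gene) pair:

1. **Site scanner.** Log2-odds of the PWM against the background, both
   strands, with exact p-values: per-position score contributions are
   discretized at 10⁻³ bits and convolved by dynamic programming into the
   full distribution of a random background word's score; the reported
   p-value is the survival function evaluated at floor(score/granularity),
   i.e. rounded conservatively upward. The default emission threshold is
   p ≤ 10⁻⁴. Because discrete PWMs give lumpy score distributions, the
   exact tail mass at the emission threshold can be well below `p_max`;
   the tables expose both (`score_threshold`, `pvalue`), and calibration
   tests compare empirical hit rates against the table's own tail mass.
2. **Cluster scanner.** Hits with log-odds ≥ 6 (``motif_min``) are kept; a
   200 bp window slides over the promoter and the pair is confirmed when
   the best window's summed score reaches 5 (``cluster_min``). This is a
   deliberately transparent stand-in for HMM-based cis-regulatory-module
   scoring: the pipeline only consumes the confirmation decision, so the
   window-sum semantics are pinned and documented rather than opaque.

Motifs are shared across TFs of the same family before the edge filter
(the union of TFs in all families of a motif's mapped TFs), reflecting
that family members bind near-identical sites and motif databases are
incomplete. An edge keeps motif support only if some motif of its TF is
confirmed by *both* scanners for its target, by default the *same* motif
(`match_level="motif"`; `"tf"` relaxes this).

### ChIP labelling

An edge is a training positive when any peak of its TF overlaps the
target's promoter by ≥ 1 bp (half-open intervals; adjacent regions do not
overlap). Edges of TFs with no peak file stay unlabelled — they remain
prediction candidates but never train the classifier, and "no peak for a
profiled TF" is deliberately *not* treated as a negative: training
negatives come from sampled non-edges instead.

### GCN link prediction

The filtered network becomes an undirected message-passing graph with
self-loops, normalized as D̃^(−1/2)(A+I)D̃^(−1/2). Node inputs are each
gene's expression vector, log1p-scaled, adaptively average-pooled to
`feature_len` values and z-scored per feature; pooling to a fixed length
is what lets a trained model score another expression atlas with a
different sample count (cross-species transfer). Two GCN layers (ReLU and
dropout after the first) produce d-dimensional embeddings; a directed
edge (t, u) is the outer product h_t h_uᵀ — asymmetric, so direction
survives even though propagation is undirected — classified by a small
CNN (two 3×3 same-padding conv layers with 8 and 16 channels, ReLU,
global average pooling, affine, sigmoid).

Training: per-TF balanced negative sampling (|S(t)| = min(|N(t)|,
|V−N(t)−{t}|) non-targets drawn without replacement), a label-stratified
8:1:1 train/val/test split, binary cross-entropy, Adam with learning rate
0.005 and weight decay 10⁻⁴ (decay added to the gradient), dropout 0.5,
and early stopping on validation loss with a 200-epoch patience by
default. Biases are initialized uniform ±1/√fan_in rather than zero: with
the zeroed-features ablation a zero bias makes relu(0) a stationary point
and the ablated model could never train.

The network is implemented on a small in-repo reverse-mode autodiff
engine over numpy arrays (`inferreg.nn`): exactly the operators the model
needs, single-threaded, float32. Gradients are verified against central
finite differences in the test suite.

Threshold post-processing sweeps the decision threshold from 0.5 to 1.0
in steps of 0.01 and picks the largest value with F1 ≥ 0.8, computed on
the validation partition (the test partition is reserved for reporting).
The 0.01 step is deliberate: a coarse 0.1 grid cannot express
intermediate optima.

### Differential expression and regulons

Counts become log2 CPM with a 0.5 count / 1.0 library offset. Library
sizes are TMM-corrected by default (own implementation of the trimmed
mean of M-values, verified against edgeR's `calcNormFactors` in the
suite): a tissue whose regulons upregulate a sizeable slice of the
transcriptome inflates its library and silently shrinks every fold
change, and TMM removes this composition bias as long as a majority of
genes are null. Precision weights follow the voom recipe: per-gene OLS on
the tissue-means design, a lowess trend (span 0.5) of √SD against average
log-count, weights = trend⁻⁴ at each observation's fitted value, clipped
to [10⁻⁶, 10⁶]. Per-gene weighted least squares then gives each tissue's
contrast against the mean of the other tissue means (one-vs-rest; an
all-pairwise mode requiring significance against every other tissue is
available, since the aggregation rule from pairwise contrasts to
per-tissue DEG lists is ambiguous in the underlying description — both
are exposed). Gene variances are moderated with an empirical-Bayes
scaled-F prior fitted by method of moments on log variances (trigamma
inversion by Newton; when the moment estimate of the prior df is
infinite, the prior variance is the mean variance, matching the reference
implementation). DEGs: BH-adjusted within contrast, fdr < 0.01 and
logFC > 1, upregulated only.

A tissue's regulons are the predicted edges whose TF and target are both
DEGs of that tissue; empty regulons are dropped.

### Prioritization

Each tissue's regulons form a directed TF→TG network. Regulons are scored
by out-degree; closeness centrality over *outgoing* paths with the
Wasserman–Faust correction (regulon networks are almost always
disconnected); unnormalized directed betweenness; and GO functional
specificity, pinned as the −log10 one-sided hypergeometric tail of the
overlap between the regulon's target set and a tissue gold-standard gene
set within a stated universe (the notion of "functional specificity" was
otherwise undefined, and hypergeometric enrichment is the standard
choice; the scoring is pluggable). Each metric gives tie-averaged ranks
(1 = best); the Borda score is the geometric mean of the four ranks —
geometric mean of *ranks*, not Borda points — and the final order ascends
in it. Retrieval along a ranking is summarized by R50, the depth at which
half the gold set is recovered. Gold standards are built from gene–term
tables by case-insensitive keyword substring match on term names
restricted to experimental/curated evidence codes
({EXP, IMP, IDA, IPI, IGI, IEP, TAS, NAS, IC}); keyword closure over the
GO graph is intentionally out of scope.

## The synthetic world

The generator builds a ground-truth world from one seed, fanned out into
independent per-stage child streams (GRN, expression, genome, peaks) so a
stage can be regenerated alone.

* **GRN.** TF out-degrees follow a discrete power law with exponent 2
  truncated at n_genes/2; targets are drawn uniformly without
  replacement; no self-edges. Each TF is assigned one *home tissue* and
  all its edges are active exactly there. The home-tissue design is
  deliberate: a TF upregulated in every tissue has a one-vs-rest contrast
  near zero everywhere, can never be called an upregulated DEG, and its
  regulon would be unrecoverable by construction — under edge-wise random
  tissue subsets nearly every multi-edge TF ends up in that state, which
  would make end-to-end recovery meaningless as a test. TFs active in
  several tissues with different target sets are real and are exercised
  by direct fixture construction in the tests instead.
* **Expression.** Gene base means are log-normal (log-mean 4, log-sd 1);
  a tissue-active TF carries a log2 fold change drawn uniform from
  [1.5, 3] (the strong-signal fixture uses [2, 3]) and each active target
  inherits logFC × an edge weight uniform in [0.6, 1], summed over
  regulating TFs; counts are negative binomial with dispersion 0.1
  (variance μ + 0.1μ²), a standard bulk noise level.
* **Genome.** Genes sit in fixed non-overlapping slots, 50 per synthetic
  chromosome, so promoters never collide; background sequence is i.i.d.
  uniform. Each TF gets a random informative PWM (length 8, dominant base
  0.85 per column, total information ≥ 8 bits); for each true edge the
  TF's *consensus* is written into the target promoter with probability
  `motif_plant_rate`, at a position not overlapping previously planted
  sites.
* **Peaks.** Each planted site is covered by a ±30 bp peak with
  probability 1−`peak_fnr`; false peaks appear per (profiled TF,
  promoter) at rate `peak_fpr`.

What the generator does *not* emulate: realistic genome composition (GC
skew, repeats, real promoter architecture), batch effects, library-size
variation beyond composition, secondary motif occurrences, indirect
regulation, and — most importantly — realistic regulon-to-transcriptome
proportions: with 40 TFs and 500 genes, a single tail draw of the degree
law can make one regulon cover ~40% of the transcriptome, a regime in
which one-vs-rest differential expression is genuinely unidentifiable (no
majority-null normalization can tell "half the genome up" from "the other
half down"). Passing tests on this world show the pipeline recovers
planted structure under its assumptions; they do not certify performance
on real atlases, where signals are weaker but regulons are relatively far
smaller.

## Problem sizes and evaluation protocol

Desk-scale runs use the strong-signal fixture family (500 genes, 40 TFs,
3 tissues, 20 samples/tissue, TF logFC in [2, 3], plant rate 0.9, peak
FNR 0.1, FPR 0.05) with reduced model configurations chosen for these
sizes: clean-fixture learning runs use `feature_len` 64, `embed_dim` 16,
patience 40, max 180 epochs; full pipeline runs, whose candidate graphs
are larger and noisier (family-shared motifs admit thousands of false
candidates), use a wider CNN/GCN width (`hidden_dim` 96) and longer
training (patience 60, max 300) — at the narrower width the classifier
demonstrably underfits the candidate graph. The package defaults
(`feature_len` 256, `embed_dim` 64, patience 200) remain the full-scale
configuration.

Because a world's total edge count is dominated by its single largest
degree draw (worlds range from ~80 to ~300 edges across seeds, and a
~2%-tail draw produces a hub regulon covering ~40% of the transcriptome),
no single world is trustworthy in both directions: sparse worlds leave
~13-edge validation/test partitions whose AUC is noise, and hub worlds
break DE identifiability as described above. Evaluation therefore
averages over five complete replicates — a fresh world and model seed
each time. Under this protocol the ablation picture also matches the
full-scale qualitative expectation: rewiring the graph degrades the
model more than zeroing node features on average, with sparse replicate
worlds contributing the strongest structure dependence, and both
ablations sit clearly below the full model.

## Numerical choices

* PFM pseudocount 0.01 per cell on count matrices; probability matrices
  are renormalized untouched. Zero columns are errors.
* PWM p-value granularity 10⁻³ bits; p-values rounded upward; survival
  arrays cover every reachable partial-sum range.
* Spearman ρ is computed as Pearson on tie-averaged ranks (exact for
  ties); constant genes are dropped with a log entry rather than given
  ρ = 0.
* Voom weights clipped to [10⁻⁶, 10⁶]; lowess span 0.5; the trend is
  floored at 10⁻³ before the inverse-fourth power.
* Moderated p-values and FDRs are floored at the smallest positive
  double, keeping them in (0, 1].
* Ranks use average ties throughout; the Borda geometric mean is computed
  in log space.
* The autodiff engine runs in float32; training is deterministic for a
  fixed seed on a single thread (one rng drives init and dropout;
  negative sampling and splits are separately seeded).

## Known limitations

* The GRNBoost2 stand-in pins tree count and learning rate rather than
  matching GRNBoost2's output distribution; absolute IM values are not
  comparable to raw-gain pipelines.
* The cluster scanner is a window sum, not an HMM; it will under-score
  dense clusters of weak sites that an HMM would stitch together.
* One TSS per gene; alternative promoters are not represented.
* TMM assumes a majority of null genes per sample pair; worlds (or
  tissues) violating this retain residual fold-change bias.
* The GCN treats the graph as undirected during propagation; direction
  lives only in the edge embedding.
* R50 is undefined (returned as missing) when the ranking never reaches
  half the gold set.
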