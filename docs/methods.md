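# Methods

## Scope and stance

`nicherx` re-creates a spatial + single-cell immune-niche analysis with a
drug-prioritization stage, at a scale where every statistic can be checked
against ground truth or a brute-force oracle. Where the original analytical
ecosystem uses heavyweight external tools, this package substitutes
deterministic, testable statistics with the same contract, and labels them
by what they are:

* **Compositional testing** is an additive log-ratio (ALR) transform against
  a fixed reference compartment followed by a Welch two-sample t-test and
  Benjamini–Hochberg control (`alr_welch`), in place of a Bayesian
  Dirichlet-multinomial model. Same reference-based contract, no MCMC.
* **Single-sample gene-set scoring** offers two statistics: the
  binned-background control score (set mean minus expression-matched control
  mean) and a rank-AUC score `ES = 2U/(m(n−m)) − 1` (Mann–Whitney U of
  set-gene ranks within one observation, average ranks on ties), a
  deterministic, parameter-free stand-in for kernel-based single-sample
  enrichment. ES is invariant to monotone transforms of the observation's
  expression vector and spans [−1, 1].
* **Deconvolution** is non-negative least squares against a mean-profile
  signature (`nnls`), in place of a neural-network deconvolver. The
  accompanying mixture simulator mirrors the reference tool's
  pseudo-spot construction (n mixtures with counts down-sampled to 10%).
* **Drug scoring** uses two scores on purpose. Differential enrichment uses
  the non-negative target-mean of log-normalized expression, so a log2
  fold-change cutoff of 0.25 is well defined. The final ranking uses the
  binned-background signature score of the targets averaged over CD4⁺/CD8⁺
  effector T cells, which corrects for expression-level background.

## Generative model of the synthetic cohorts

Counts are negative binomial via the gamma–Poisson construction: gene `g`
in observation `i` has mean `λ_g · e_{c(i),g} · s_i` where

* `λ_g` — gene baseline. Background genes draw log-normal
  (mean-log `log 0.4`, sd-log 0.8; ~0.55 expected counts per unit library).
  Cytokine/activation genes are pinned low (`0.1`) — type 1/3 cytokines are
  near-silent outside inflamed tissue, and the drug specificity filter's
  detection contrast rests on exactly this. Structural and lineage marker
  genes draw from the ordinary background distribution: marker genes in real
  data span the abundance spectrum, and pinning them low would starve the
  deconvolution problem of informative counts. Twenty housekeeping genes sit
  at baseline 3.0; a configurable fraction (default 2%) of genes carry the
  `MT-` prefix with ordinary baselines.
* `e_{c,g}` — program effect: `2^effect` for genes in compartment/cluster
  `c`'s program, 1 otherwise. Defaults: structural compartments 3.5 log2
  units, inflamed compartments and T-cell clusters 4.0. These are chosen for
  comfortable recovery at desk scale and are config-exposed, not claims
  about real effect sizes.
* `s_i` — library size, log-normal (0, 0.35), giving ~900 counts per spot
  at 1,500 genes. Two orders below real spot totals, sized for minutes-long
  end-to-end runs.
* Shared NB size parameter 2.0 (over-dispersion typical of UMI counts).

**Spatial layout.** Each sample is a triangular (hex-packed) grid.
Compartment labels are assigned by Voronoi patches: ~`spots/30` random
centers, each drawing a compartment from the group-specific proportions, and
every spot takes its nearest center's label. Contiguity is the point —
neighborhood enrichment is meaningless under per-spot independent labels.
Default cohort: 4 control + 4 case samples × 400 spots. Inflamed
compartments occupy 6% of control and 25% of case tissue in expectation.

**Compartment programs.** The two inflamed compartments express their
structural markers, a 10-gene injury block unique to each (crescentic
glomeruli and inflamed interstitium express damage markers their healthy
counterparts lack), and a shared 26-gene T-cell activation program
containing all 14 type 1/2/3 cytokines plus IL12B/IL23A and pan-T-cell
genes. The injury blocks also make the panel-based annotation well-posed:
with pure superset programs, the mean-z argmax between a normal compartment
and its inflamed counterpart ties in expectation.

**T-cell atlas.** 3,000 kidney + 3,000 blood cells in four clusters
(CD4_Teff, CD8_Teff, CD4_naive, Treg). Effector clusters carry 20 distinct
lineage genes each plus the shared type 1/3 cytokines and IL12B/IL23A, and
are enriched in kidney (35%+35%) versus blood (10%+10%) — naive and
regulatory cells dominate blood. The 20-gene distinct blocks reflect that
effector lineages differ broadly in real atlases; with only a handful of
distinct genes the CD4/CD8 signature columns become nearly collinear and no
deconvolver can separate them.

**Drug dictionary.** One planted record: ATC L04, approved, viable, targets
IL12B/IL23A/IFNG/IL17A/TNF ⊂ activation program. Decoys include a
proximal-tubule-program drug (enriches in the wrong compartment), a
housekeeping-target drug (detected everywhere, trips the specificity cap),
an L03 record, an unapproved and an unviable record (exercise the universe
filter), and random background-target decoys.

**Spot mixtures.** Proportions are symmetric Dirichlet(1); the mixture mean
is the proportion-weighted combination of sum-normalized type profiles
scaled to a log-normal library (median 10,000, Visium-like); NB noise with
size `1/noise`; binomial down-sampling to 10%. The default `noise = 0.05`
derives from the pseudo-spot construction it emulates: pooling ~10 cells of
per-cell NB size 2 yields a pooled size of ~20 = 1/0.05. `noise = 0`
returns the exact noiseless profile so identity checks are machine-precision.

## What the generator does not emulate

No batch effects (an optional per-sample mean-centering flag in clustering
stands in for dedicated integration), no ambient RNA, no doublets, no
antibody-capture counts (CLR normalization is provided regardless), no
spatially varying cell density, no gene–gene correlation beyond the shared
programs. Passing tests therefore demonstrate that the statistics are
implemented correctly and calibrated under a realistic over-dispersed count
model — not that the pipeline is robust to every artifact of real data.

## Parameter defaults that matter

| Parameter | Default | Why |
|---|---|---|
| QC spatial | min_genes 100, min_spots/gene 3, counts in [2000, 35000], inclusive | standard filter-function contract; bounds inclusive |
| QC single-cell | detected genes strictly in (500, 5000); mito ≤ 10% on raw counts over `MT-` symbols | "fewer than / more than" wording makes the gene bounds exclusive |
| Normalization | target 10,000; log2 (spatial) / natural log (cells); base recorded in metadata | downstream fold changes de-log with the recorded base |
| Clustering | HVG 2000, 50 PCs (spatial) / 30 (cells), k = 10, Leiden 1.2 (spatial) / Louvain 0.1 (broad cells) | the two branches' conventional settings; cluster ids relabeled by decreasing size for stability |
| Spot graph | k = 6 nearest neighbors, per sample, symmetrized union | native hex packing of the spot grid; config-exposed |
| Enrichment null | 1,000 permutations, stratified by sample | the merged multi-sample graph makes the sample-stratified null the one that respects per-sample label composition; global permutation available by flag |
| Proximity export | negative z clipped to 0, weights × 0.25, zero-weight edges dropped; undefined z (σ = 0) exported as missing, not 0 | matches the published graph construction |
| Composition | reference CNT/PC, pseudo-count 0.5 (Haldane–Anscombe), FDR 0.05 | reference-based compositional contract |
| Deconvolution | gene space = atlas HVGs (top 300–500 by log-variance) ∩ spatial genes; linear (de-logged) scale | mixing is linear in transcript abundance; HVGs concentrate the informative counts |
| Drug stage | universe L01/L02/L04 minus L03, approved + viable; padj < 0.05 and log2FC > 0.25; specificity threshold 0.75; Teff ranking with 25 bins × 50 controls | the published screen's cutoffs |
| Quantiles | type-6 (`h = p(n+1)`), rounding half away from zero | the unique common convention reproducing all four printed clinical IQR bounds |

## Numerical and procedural choices

* **Wilcoxon DE** uses the tie-corrected normal approximation by default
  (variance `n1·n2/12·((n+1) − Σ(t³−t)/(n(n−1)))`) and an exact
  Mann–Whitney mode for tiny groups; tests pin the exact mode to a full
  enumeration oracle. Fold changes are `log2((m_in+ε)/(m_out+ε))`, ε = 1e-9,
  on de-logged normalized means.
* **Binned-background score**: genes are ranked by mean expression and cut
  into 25 equal bins; each set gene draws up to 50 control genes without
  replacement from its bin, excluding set genes. If a bin cannot supply the
  full quota the available pool is used — callers scoring tiny gene spaces
  should reduce `n_bins`/`ctrl_size` so controls remain expression-matched.
* **Annotation ties** break by panel order with a logged warning; panels
  with no present genes are skipped with a warning; all-absent panels are an
  error.
* **Specificity rule**: "enriched at least 75%" is operationalized as the
  fraction of a compartment's spots with a positive drug score (≥ 1 target
  detected). A drug passes iff the fraction is ≥ 0.75 in *every* interest
  compartment and < 0.75 in *every* other compartment. The threshold and
  interest set are arguments; the stored per-compartment fractions make
  every decision reconstructible.
* **Combined cytokine score** is the background-binned score of the
  14-gene union of the three cytokine families (not the sum of three
  separate scores); the three family sets are also exported for the
  per-family variant.
* **NNLS degenerate spots** (all-zero solution) fall back to uniform
  proportions and are flagged in the result's metadata rather than dropped.
* **Zero-total observations** normalize to all-zero vectors with a warning;
  the CLR pseudo-count (+1) makes zeros harmless there.
* **Determinism**: every stochastic stage derives its generator from
  `(seed, stage-name)` via a CRC-keyed `numpy` SeedSequence, so stage order
  never changes a stage's stream; Leiden takes the seed directly and Louvain
  seeds the `random` module backing igraph.
* **Type-6 quantiles** clamp `h = p(n+1)` to `[1, n]` and interpolate
  linearly; at p = 0.5 this is the ordinary sample median for every n.
  The Tukey summaries of proportions use the same convention — note that
  with type-6 quartiles a single far point in a small sample can fall inside
  the widened fence, so outlier counts differ from type-7-based
  conventions.

## Desk-scale problem sizes

The default study conditions are ~3,200 spots, 6,000 cells, and 1,500 genes
— about two orders of magnitude below the real cohorts — with benchmark and
calibration suites running on further-reduced cohorts (200-spot samples,
1,600 cells, 800 genes; 400-gene zero-effect cohorts for null calibration).
These sizes were chosen so a full end-to-end screen completes in seconds
and the entire verification suite in minutes on a single CPU.

## Known limitations

* The clinical summaries cover only the variables whose per-patient values
  are printed (creatinine, eGFR, ACR at relapse); no testing is attempted at
  n = 4.
* The ALR/Welch compositional test ignores per-sample random effects and
  reports no inclusion probabilities; with few samples per group its power
  profile differs from the Bayesian model it stands in for.
* The rank-AUC score is a monotone-intent stand-in, not a reimplementation
  of kernel-based single-sample GSEA; absolute values are not comparable
  across tools.
* Real drug dictionaries carry many-to-many target relations, versioned
  identifiers, and non-human targets; the TSV format here sidesteps alias
  resolution entirely (gene identity is the bare case-sensitive symbol).
* Spatial spots mix cell types; the drug enrichment stage treats spot-level
  scores as the unit of evidence, as the original screen does, without
  deconvolving the scores themselves.
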