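# Methods

`cpgevo` quantifies the CpG dinucleotide content of the DNA around
transcription start sites (TSS) and transcription termination sites
(TTS), classifies promoters by it, and relates its divergence between
species to the divergence of gene expression. This note documents the
model choices, the tunables and their defaults, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Normalized CpG content

For a window of length L (default 3 kb: 1.5 kb either side of the site),

    nCpG = observed_CpG / (L_eff * (GC/2)^2)

where `observed_CpG` counts positions i with C at i and G at i+1, `GC`
is the fraction of C+G among unambiguous bases, and `L_eff` is the
number of unambiguous bases. Conventions:

- The expected count uses `L_eff` positions, not `L_eff − 1` dinucleotide
  starts; the difference is 0.03% at 3 kb and the convention makes
  `nCpG("CG" * k) = 2` exact.
- Ambiguous bases (N) are excluded from both the CpG count (a
  dinucleotide containing an N never matches CG) and the GC tally.
  Windows with fewer than 500 unambiguous bases (configurable) are
  reported missing with a reason code, as are windows with GC = 0
  (observed is then necessarily 0, and 0/0 has no defined limit).
- Windows are taken on the forward strand only. CG is its own reverse
  complement and GC content is base-pairing symmetric, so nCpG is
  strand-invariant; reverse-complementing minus-strand windows would
  change nothing (property-tested).
- Coordinates are 0-based half-open internally; GTF input is 1-based
  inclusive. The window is `[center − 1500, center + 1500)`. Windows
  clipped at chromosome edges are retained but flagged, and their nCpG
  uses the actual length; silently dropping them would bias the edges.
- Genes with several transcripts get the mean of their transcript-level
  values by default (the maximum is also computed and reported); the two
  aggregations rank genes nearly identically when transcripts share a
  gene-level signal.

## HCP/LCP classification

Promoter nCpG in most amniotes is bimodal: a low mode (CpG eroded by
germline methylation followed by deamination) and a high mode
(CpG-island promoters). The classifier is a fitted model
(`PromoterClassModel(values).fit()`):

1. Gaussian-kernel density on a 512-point grid over [0, max].
   Bandwidth: Silverman's rule by default, or an absolute kernel SD.
   Silverman is adequate at genome scale (tens of thousands of
   promoters) but over-smooths the broad high-CpG mode below a few
   thousand values; pass an explicit bandwidth (≈0.05) there.
2. Peaks: local maxima with prominence ≥ 5% of the density maximum
   (ignores kernel ripples; configurable).
3. Threshold: the grid point of lowest density strictly between the two
   most prominent peaks. Fewer than two peaks — a unimodal
   distribution, as in platypus — yields no threshold and no labels,
   deliberately not an error.
4. Labels: values above the threshold are HCP, values at or below it
   LCP (ties to LCP, for determinism); missing values are unclassified.

The threshold recovery is accurate to well under 0.05 against the
analytic density valley for mixtures with moderately separated,
curved valleys; when components are so far apart that the density
between them is essentially flat at zero, the argmin is ill-conditioned
— any point in the gap separates the classes equally well.

## Expression handling and tissue specificity

Expression tables are RPKM per gene per sample, with a sidecar mapping
samples to tissues. Replicates are combined by averaging on the log
scale: mean over replicates of log2(RPKM + 0.01). The pseudocount
(default 0.01) is recorded in run manifests; a gene is "expressed" in a
tissue when any replicate has RPKM > 0. Missing cells propagate as
missing and are excluded pairwise, never zero-filled.

The tissue specificity score of a gene with linear-scale expression
x_1..x_n over n tissues is the relative entropy against uniform:

    TSPS = sum_i f_i * log2(f_i / (1/n)),   f_i = x_i / sum_j x_j

with 0·log 0 := 0. TSPS is 0 for uniform expression and log2(n) for
single-tissue expression; it is invariant to rescaling, computed on
linear tissue means (the f_i are expression ratios, not log ratios).
Log base 2 makes the single-tissue maximum log2(n). The HCP/LCP
contrast reports class means, the fractions below 0.25
(housekeeping-like) and above 2 (tissue-specific), and a two-sided
Wilcoxon rank-sum p-value.

## Cross-species analyses

All correlations are Spearman (average ranks on ties), over
pairwise-complete ortholog pairs. Significance uses the Fisher
z-transformation, z = arctanh(r)·sqrt(N−3), referred to the standard
normal (two-sided); |r| = 1 is reported at the smallest positive double
and flagged. The Fisher p agrees with a permutation p within a factor
of two at n = 50 for moderate r (tested).

Category conservation cross-tabulates HCP/LCP labels of ortholog pairs
(conventionally restricted to genes with a single TSS in both
organisms) into HH/HL/LH/LL, reports the conserved fraction
(HH+LL)/total, and tests independence with a 1-df chi-square without
continuity correction (Yates available via a flag); expected cells
below 1 flag the p-value unreliable.

The divergence trend sorts ortholog pairs by dCpG (nCpG_A − nCpG_B),
slides a 400-pair window (step 1; both configurable) and reports
per-window means of dCpG and of the per-tissue log2 expression ratio.
An OLS slope over the window means summarizes the trend. The
differential-expression contrast splits pairs at a two-fold change
(|log2 ratio| ≥ 1) into up/down groups and compares their dCpG
distributions by rank-sum test.

## The synthetic-data generator

The generator emulates the marginal statistics the analyses consume, so
the full pipeline is testable without genome or RNA-seq downloads.

**Sequences.** Each 3 kb window is emitted by a first-order Markov
chain over {A,C,G,T} whose stationary composition is exactly the GC
target (0.5 by default, split evenly between C and G) and whose C→G
transition is tuned so the expected CpG rate equals
`target_nCpG · (gc/2)²`. The non-C rows draw iid from the composition;
the G row absorbs the column-balance terms, which keeps the stationary
composition exact and makes realized nCpG unbiased for the target
(verified over targets 0.12–1.6). Feasibility caps targets at
min(2, 2/gc). A single window still fluctuates with binomial sampling
noise (SD ≈ 0.04–0.1 depending on the target), so the *realized* nCpG
of every emitted window is measured immediately and recorded as truth;
downstream couplings use realized values. A fast values-only mode skips
sequence emission and adds Gaussian noise (SD 0.04, the window-sampling
scale) to the targets instead.

**Gene latents.** TSS targets are drawn from a two-component truncated
normal mixture; defaults are the human promoter components — LCP
N(0.120, 0.083²) with weight 0.557, HCP N(0.631, 0.242²) with weight
0.443. TTS targets come from a single unimodal component, N(0.30,
0.10²) (high-CpG terminators are not protected from methylation, so no
second mode; mean/SD chosen to sit in the low-mode range). Genes get
random strands; each transcript occupies its own spaced block on a
chromosome so windows never overlap, and minus-strand transcripts have
TSS > TTS as annotation requires.

**Expression.** log2 total expression = 3.0 + a·nCpG_TSS + N(0, 2.0²)
with coupling a = 4.0 by default, which yields a Spearman correlation
between promoter nCpG and expression of ≈0.5 — the scale seen in
RNA-seq data. Tissue profiles are Dirichlet draws (concentration 0.3
for LCP — sparse, tissue-specific; 5.0 for HCP — near-uniform), mixed
with a basal floor of 0.1 of the gene's level so no tissue falls below
detection; without the floor, sparse profiles sink below the log2
pseudocount and compress cross-species log-ratios, breaking the
generator's own divergence coupling. Two replicates per tissue with
log2 noise SD 0.25; 8% of LCP and 2% of HCP genes are non-expressed
(all-zero rows).

**Divergence.** Organism B's targets are A's plus Gaussian drift — SD
0.15 at TSS, 0.25 at TTS by default, the distant-species regime in
which the expression-divergence trend is detectable (TSS more conserved
than TTS). B's log2 expression totals equal A's − β·dCpG + N(0, 1.0),
with β = 1 by default, so up-regulation in A tracks CpG gain in A
relative to B. Tissue profiles and the non-expressed mask are shared
across the pair.

All randomness flows from one seed through `numpy` spawned substreams;
the same seed reproduces every file byte-identically.

**What the generator does not emulate:** mutational mechanism
(deamination kinetics, biased gene conversion), CpG islands as spatial
features, isoform structure, GC heterogeneity along chromosomes,
cross-species RPKM normalization artifacts, or phylogenetic structure
beyond a single organism pair. Passing tests therefore demonstrate that
the pipeline recovers the statistical structure it assumes — not that
real genomes satisfy those assumptions.

## Problem sizes and determinism

Simulated studies use 300–5,000 genes (sequence-realized and
values-only respectively) and 50,000 draws for density-threshold
recovery — large enough that recovery tolerances (threshold ±0.05,
trend slope within 30%, qualitative orderings across 10–20 seeds) are
comfortably resolvable. Every stochastic test is seeded; KDE grids,
tie rules and aggregation orders are deterministic.

## Known limitations

- Silverman bandwidth under-resolves the bimodal structure below a few
  thousand promoters (see above).
- The valley threshold is a density feature, not a component boundary:
  the mass above the valley is not the high-component weight when the
  components overlap asymmetrically.
- Chromosome-edge windows keep their (shorter) actual length, which
  raises their nCpG variance slightly.
- The trend slope from overlapping sliding windows has strongly
  autocorrelated residuals; it is a point summary, and no standard
  error is reported for it.
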