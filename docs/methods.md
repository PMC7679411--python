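# Methods

This note documents the models, rules and numerical choices behind `crest`,
and what the synthetic benchmarks do and do not demonstrate.

## Coordinate model and interval algebra

All coordinates are 0-based, half-open (`[start, end)`), the native
convention of the BED/bedGraph files the pipeline consumes; `[a,b)` and
`[b,c)` never intersect. Interval sets are sorted per chromosome and merged
(overlapping or abutting runs collapsed) before any base counting, so
`intersect_bases`, `union_bases` and the Jaccard index are invariant to how
either input is fragmented. `overlapping_subset` keeps whole intervals
rather than clipped fragments because the downstream unit of classification
is the whole H3K27ac peak. The bedGraph reader rejects overlapping steps
instead of summing them: merged tracks are step functions, and silent
summation would hide malformed upstream output. An optional exclusion
("blacklist") set can be subtracted from any peak set before analysis; the
subtraction clips around excluded bases.

The whole algebra is verified, exactly, against a naive per-base membership
oracle on random small genomes in the test suite.

## Gene-set classification

Responsiveness is `p_adj < α` (strict; default α = 0.05, BH-adjusted
p-values taken as given) **and** a strict fold-change direction: knockdown
contrasts require log2FC < 0, induction contrasts log2FC > 0. Significance
alone is deliberately insufficient — the classes are defined by
*down*-regulation on knockdown and *up*-regulation on induction. The common
downstream set is the intersection over all knockdown contrasts (a gene
missing from a table counts as non-responsive there); the inducible set is
the union over induction contrasts; canonical/specific is the
intersection/difference partition. Differential expression estimation
itself is out of scope: the pipeline consumes one contrast table per
context.

The correlation filter over a cohort is parameterized rather than fixed
(the upstream procedure it mirrors is not fully specified): Spearman
correlation with threshold 0.3 by default, both exposed in configuration.
Rank correlation is the default because cohort expression scales are
arbitrary. Genes absent from the cohort or with zero variance are reported
as skipped, not errors.

## Dependent-enhancer calling

Coverage tracks are scaled to a common total (depth normalization) before
comparison; `call_enhancers` refuses tracks whose totals differ by more
than 1e-6 relative. Signal is quantified over the whole H3K27ac peak
interval (not summits or fixed windows) — the peak is the unit being
classified. The dependency rule is
`log2((S_kd + c)/(S_ctrl + c)) < t` with pseudocount c = 1.0 normalized
signal unit (the ratio must be defined at zero coverage) and threshold
t = −0.5, strict, both configurable. Replicate tracks can be averaged with
`merge_tracks_mean` (piecewise mean over the union of step boundaries).

Peak→gene assignment: each called peak is assigned to the gene with the
nearest TSS within a window (default 100 kb; distance 0 if the TSS lies in
the peak, otherwise bases from the nearest covered base; ties break by
lexicographic gene id for determinism). A classified gene is a direct
target iff at least one assigned peak is dependent and a TF peak lies
within the window of its TSS. The window default is a conventional generous
bound — the exemplar enhancer sits ~10 kb from its TSS — and is
configuration-exposed, not a scientific claim. The reported dependent
fraction is over peak calls, not base pairs.

## Colocalization

The reference set is TF peaks overlapping the enhancer mark. Jaccard is
computed on base pairs of the merged sets (the convention of
genome-arithmetic tools). The permutation null repositions every query
interval uniformly at random within its own chromosome, preserving interval
lengths and chromosome assignment (starts drawn so intervals fit), and uses
the add-one estimator p = (k+1)/(n_perm+1), which never returns zero and
makes p uniform on a lattice under a true null. Per-factor permutation
seeds derive from the master seed and the factor's sorted position, so the
ranking is independent of catalog insertion order; ties in Jaccard break by
factor name. The null is a documented Monte-Carlo choice, not a claim of
identity with any external tool's analytic null.

## Activity scoring and statistics

Z-scoring is per gene across all samples with the n−1 denominator
(cohort-sample semantics); zero-variance genes become NaN and only raise
when actually requested downstream. The activity score is the arithmetic
mean of the signature genes' z-scores — invariant to per-gene affine
rescaling of the raw matrix. Stratification is quantile-based with stable
(score, sample-id) ordering; group sizes differ by at most one; the number
of strata defaults to 3 and is configurable. The stratified comparison is
classical one-way ANOVA (error on zero within-group variance) with
Bonferroni-adjusted pairwise t-tests. The Mann–Whitney test uses mid-ranks
for ties and an exact two-sided p (full null enumeration) when the pooled
sample size is ≤ 16 with no ties, otherwise the normal approximation with
tie and continuity corrections. The 2×2 chi-square uses the closed form
with optional Yates correction (off by default). Scientific-computing
primitives (BH step-up, rank tests, F/χ²/t distributions) are delegated to
scipy/statsmodels; the test suite checks every statistic against
independent textbook-formula or enumeration oracles.

## Synthetic data: what it emulates

The generators plant, at desk scale, the structures the pipeline infers;
defaults follow the emulated study design.

* **Contrasts** (3 knockdown + 2 induction tables, 10,000 genes): 87
  canonical + 36 specific + 9,877 null genes. Responsive p-values are drawn
  from Beta(0.1, 20) truncated below α; non-responsive from
  α + (1−α)·U(0,1); responsive |log2FC| ~ |N(2, 0.4)| with the required
  sign. Canonical genes respond in both induction contexts with probability
  0.5, otherwise in exactly one. The corruption model (`flip_fraction`)
  picks that fraction of genes and toggles each one's call in a single
  uniformly chosen table — so at corruption rate f, at most a fraction f of
  planted genes can be lost from the common set, the bound the robustness
  benchmark checks (precision and recall ≥ 0.95 at f = 0.05).
* **Epigenome**: a slot layout (one feature per 10 kb slot) keeps
  nearest-TSS assignment unambiguous by construction. In benchmark mode,
  200 TF-bound H3K27ac peaks (500–2000 bp) on 2×1 Mb gene-free
  chromosomes, 50% dependent with true knockdown/control signal ratio 0.4
  (true log2 ratio ≈ −1.32). In linked mode, classified genes get TSS
  slots on chromosome 1; 77 canonical and 21 specific genes get dependent
  TF-bound enhancers a few hundred bases to a few kb upstream, 10 canonical
  genes get TF-bound but independent enhancers, and the exemplar
  (NOTCH3-like) gene gets its dependent enhancer ~9.5 kb upstream of the
  TSS in an enlarged slot; remaining enhancers and mark-only/TF-only peaks
  live on a gene-free chromosome 2, and the overall dependent fraction
  defaults to 2/3. Coverage is Poisson per 10-bp bin around per-base rates
  (0.1 in peaks — mean per-peak control signal ≥ 50 — and 0.02 background);
  noise can be disabled for exact tests. Depth normalization slightly
  rescales the knockdown track upward (its total is lower by
  construction), which the ±0.82-log2 margins absorb.
* **Cofactors**: for target Jaccard j against a reference of B bases, a
  factor copies c = 2Bj/(1+j) reference bases and adds B − c contiguous
  filler bases from the reference's complement, so its footprint equals the
  reference's and the realized Jaccard is j up to integer rounding
  (recorded in ground truth; always within 0.02). Default catalog: GATA3
  0.6, MAFK 0.4, PBX3 0.2, CEBPB 0.05.
* **Cohort**: 503 samples with latent activity ~ N(0,1); signature genes =
  a·activity + N(0, σ²), the query gene and 12 further planted candidates =
  b·activity + noise (defaults a = b = σ = 1, 13 correlated candidates
  including the query), other candidates and null genes pure noise.

Identical configuration and seed give byte-identical output files; every
generator writes its ground truth, and recovery tests read truth only from
those files.

What passing these benchmarks does **not** show: the generators have no
fragment-length, GC or mappability structure, no correlated replicate
noise, no peak-calling uncertainty, and independent Gaussian/Poisson noise
throughout — real ChIP-seq and cohort data are harder. The benchmarks
validate the *rules* (set algebra, thresholding, ranking, scoring) and
their noise margins, not performance on real libraries.

## Pipeline

Stages run in order classify → call-enhancers → direct-targets → coloc →
score-activity from a single YAML configuration (paths relative to the
file; CLI flags override). Every intermediate is a headered TSV; the
report's counts equal the emitted tables' row counts; reruns are
byte-identical because timestamps appear only in `run.log`. A stage failure
writes a `FAILED` marker naming the stage and aborts. Supplying no
induction contrasts is a supported degenerate design: all common genes
become specific and the report flags it. The group comparison of
dependent-enhancer signal at specific vs canonical loci (two-tailed
Mann–Whitney) is computed and reported; the default generator plants no
difference between the groups, so no benchmark asserts its outcome.

## Problem sizes

Default benchmark sizes (10,000 genes; 2–4 Mb genomes with 200 enhancers;
999 permutations for rankings and 99 for the calibration replicates; a
503-sample cohort; 100 replicates for null calibrations) were chosen so the
complete suite runs in well under a minute on one CPU while keeping the
planted effects at the scale the rules are meant to resolve.

## Known limitations

* Interval structures are flat sorted arrays; fine at desk scale
  (≤ 10⁵ intervals), not engineered for whole-genome catalogs.
* The permutation null ignores chromatin accessibility and peak clustering;
  real colocalization nulls are more conservative.
* BED round-trips preserve name/score only with the column layout the set
  itself uses (a `.` placeholder reads back as absent).
* The correlation filter's statistic and cutoff are defaults, not derived
  quantities; sensitivity to them is the user's to explore.
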