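# Methods

`xhyb` re-implements, as a tested pipeline, the analysis used when a species
without its own microarray is assayed on a relative's chip (cross-species
hybridisation, CSH).  This note records the models, the parameters that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the procedure was genuinely underdetermined.

## The analysis chain

1. **gDNA probe masking.** Genomic DNA of each genotype is hybridised to the
   heterologous array.  A perfect-match probe pair is trusted for that
   genotype iff its gDNA intensity exceeds a threshold τ (strict `>`; ties at
   τ are excluded — the convention is arbitrary but fixed and documented).
   A probe set survives when at least `min_pairs_per_set` of its pairs
   survive.  The default minimum is 1: a gene should only disappear from the
   analysis when *every* probe interrogating it has failed, which is also the
   only setting consistent with the empirically slow decline of probe-set
   counts relative to probe-pair counts as τ rises.  The retained pairs/sets
   form a genotype-specific custom chip definition; each genotype is
   summarized under its own mask, and cross-genotype comparisons are made on
   probe-set ids, never through a joint mask.

2. **Masked RMA summarization.** Retained probes are log2-transformed,
   quantile-normalized across hybridisations, and each probe set is collapsed
   to one value per sample by Tukey median polish of its probe × sample
   submatrix (summary = overall + column effect).  Probe affinities are
   multiplicative in intensity, hence additive row effects after log2, and
   are absorbed exactly by the polish.  Two deliberate choices:
   * The classical convolution (normal + exponential) background-correction
     step is a no-op hook.  Masking itself removes the background-dominated
     (non-binding) probes, which in CSH data are the dominant background
     mechanism; an optical-background model would be unidentifiable here.
   * Normalization is computed over the masked probes only (the matrix that
     is actually summarized).  `normalize_before_mask=True` gives the other
     order for comparison.
   * Note that quantile normalization forces all columns onto one value
     multiset; when condition distributions genuinely differ (planted DE),
     it perturbs individual values at the ~1e-2 level.  Exact noise-free
     identity checks therefore use `normalize=False`, which the config
     exposes.

3. **Expressed-gene calling.** Expression is rescaled so 1.0 is the array
   average; the descending ranked curve of per-set relative values is
   smoothed by a centred moving average (default window 51) and the cutoff
   is placed at the interior rank (default band 10–90%) where the absolute
   gradient is smallest — the end of the high-expression plateau.  The
   common description of this point as the sigmoid's "inflection" is
   internally inconsistent (a sigmoid's inflection is its *steepest* point);
   the shallowest-gradient reading is taken as authoritative.  Exact
   gradient ties resolve to the smallest rank, i.e. the most stringent
   cutoff.  A fixed cutoff (e.g. 0.97 of the array average) can be supplied
   instead; such cutoffs are data-derived, not universal.  The ranked curve
   is computed from water-sufficient samples per genotype by default — the
   question being asked is what the transcriptome looks like *before*
   stress.

4. **Differential expression.** Per genotype and treatment pair: Welch
   (unequal-variance) t-test per probe set, Benjamini–Hochberg adjustment
   over all sets tested in that contrast, and two gates: q ≤ 0.05
   (inclusive) and linear fold change > 2 (strict).  A pooled-variance
   variant is available by flag; Welch is the default because replicate
   variances under stress need not match controls.  Degenerate zero-variance
   cases are defined, not errors: equal means give (t=0, p=1), unequal means
   give p=0 with a flag.

5. **Responsive vs perturbed.** A stress DEG is *responsive* when the
   recovery-vs-water-sufficient contrast is non-significant for it (it
   returned to the pre-treatment level), else *perturbed* (a
   dehydration-induced state change, possibly epigenetic).  Non-significance
   is absence of evidence, so this rule is biased toward "responsive" for
   genes with weak perturbed effects — visibly so in the synthetic runs,
   where perturbed genes whose retained effect sits near the fold-change
   gate are over-called responsive (recovered responsive fractions run a
   few points above the planted 0.75).  The alternative reading — a DEG is
   responsive when water-limited-vs-recovery *is* significant — is exposed
   as `classify_rule="sig_stress_vs_recovery"`.

6. **Co-expression networks.** Spearman rank correlation (average ranks)
   between DEG probe sets across all of a genotype's samples; an edge
   requires |ρ| ≥ 0.9.  The absolute value is deliberate: stress-induced and
   stress-repressed members of one regulon are anti-correlated and should be
   connected; `mode="positive"` restricts to positive correlation.  The
   "whole" network spans the union of DEGs from all three pairwise
   treatment contrasts of a genotype; the "dehydration-specific" subnetwork
   is the induced subgraph on the water-limited-vs-water-sufficient DEGs.
   Merged networks keep provenance: shared nodes get origin `both`,
   direction conflicts are recorded (never dropped), and edges remember
   which genotype(s) contributed them.  Transcription factors are ranked by
   vertex degree in the whole network and in the drought subnetwork; role
   and TF annotations come from a user-supplied TSV, never inference.

7. **2^-ΔΔCt.** Included because qPCR is the standard bench validation of
   array fold changes: ΔCt normalizes a target gene's Ct to a reference
   (housekeeping) gene within each sample, ΔΔCt to a calibrator condition,
   and 2^-ΔΔCt is the fold change.

## The synthetic generator

The generator emulates the study design the pipeline targets: two genotypes
with near-identical genomes assayed on a relative's array, a
water-sufficient / water-limited / recovery design with 3 / 4 / 3 replicates
per genotype, planted DE with mostly <4-fold changes, a small cross-genotype
DEG overlap, a 75/25 responsive/perturbed split, and co-fluctuating modules.

Model, per probe pair j of set g in sample s:

    intensity = affinity_j · 2^(baseline_g + effect + latent) · exp(ε),
    ε ~ Normal(0, noise_sd·ln 2)          if the probe binds,
    intensity = 2^Normal(bg_mean, bg_sd)  otherwise.

* **Divergence** is Bernoulli probe dropout (`bind_prob`, default 0.9), not
  a sequence model: one uniform draw per probe pair is shared across
  genotypes, so equal binding probabilities give identical binding sets —
  the near-identical-genome regime in which the two masks overlap almost
  completely.  Dropout per *pair* with survival per *set* reproduces the
  slow probe-set decline that makes CSH viable.
* **Affinities** are lognormal (log2 SD 0.5), shared between genotypes, and
  identical between the gDNA and RNA channels of a probe.
* **Effects**: the planted log2 fold change applies under water-limited
  treatment; responsive sets have zero effect at recovery; perturbed sets
  retain the full stress effect at recovery (no published effect size exists
  for the perturbed state, so the simplest persistent model is used).
  Planted |log2FC| is uniform on (1.1, 2.0) by default — folds of 2.1–4,
  i.e. everything passes the >2 gate while staying "mostly below 4-fold".
  Common DE genes share sign and magnitude across genotypes;
  genotype-specific DE sets are disjoint between genotypes, so the planted
  overlap is exact.
* **Modules** are blocks of non-DE sets sharing one Normal(0, 1.0) draw per
  (module, sample) — coordinated ~2-fold co-fluctuations.  The amplitude is
  a design choice: with ten samples per genotype, a Spearman threshold of
  0.9 can only resolve co-regulation when the shared swing dominates
  summarized noise by roughly an order of magnitude, so this is the regime
  the network stage's own threshold presupposes.  Modules are planted
  outside the DE sets so DE statistics and correlation structure can be
  recovered independently.
* **Scale**: signal log2 mean 10, background log2 mean 6, SDs 1 — fixture
  choices on an arbitrary but internally consistent scale.  Absolute τ
  values from scanner-scale studies do not transfer; masks here use τ=256,
  the geometric midpoint of background and signal.

What the generator does **not** emulate: spatial array artefacts, optical
background on binding probes, batch/scanner effects, MM probes,
heavy-tailed noise, correlated probe failures along a transcript, and any
genuine sequence model of divergence.  Passing recovery tests therefore
demonstrates correctness of the *analysis machinery* under the stated
statistical structure, not robustness to every pathology of real CSH data.

## Numerical choices

* Median polish: alternating row/column median sweeps; stop when the total
  absolute residual changes by less than `polish_tolerance` (default 0.01)
  or after `max_polish_iterations` (default 10).  Exact on additive
  matrices after one sweep.
* Quantile normalization: reference is the per-rank cross-column mean; ties
  within a column receive the mean of the reference values at their tied
  ranks; stable (mergesort) ordering throughout, making runs bit-for-bit
  reproducible.
* Spearman: average ranks; constant rows give undefined correlations that
  are recorded as missing and never become edges.
* PCA: probe sets are row-centred, sample structure comes from the SVD;
  variance fractions are squared singular values over their total.
* One top-level seed streams to all stochastic stages in a fixed order
  (layout, truth, gDNA, RNA), so a run is replayable byte-for-byte; report
  tables carry no timestamps.

## Problem sizes

Default synthetic runs use 2,000 probe sets × 11 pairs with 100 planted
DEGs per genotype (9 common); the mask-sweep checks use 10,000 sets.  These
sizes give stable recovery statistics (binomial error on a sensitivity of
0.95 at n=100 is ~2%) while keeping a full two-genotype run in seconds.
The null-calibration check aggregates 20 independent 400-set runs.

## Known limitations

* The responsive/perturbed rule's absence-of-evidence bias (above).
* The fold-change gate interacts with quantile normalization: planted
  effects near the gate are shrunk slightly, costing sensitivity for genes
  with folds just above 2.
* With ten samples per genotype, sample Spearman is coarse (steps of
  6/990); thresholding it at 0.9 is unstable for true correlations below
  ~0.99, which is why weakly co-fluctuating modules fragment.
* GraphML export drops attributes whose value is None (the format cannot
  represent them); SIF carries topology only.
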