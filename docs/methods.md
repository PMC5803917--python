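# Methods

## The analysis model

`skinora` implements knowledge-base-driven over-representation analysis
(ORA) for paired before/after treatment transcriptomics, in the style used
for skin-centric microarray studies of topical drug action. The pipeline
is deliberately simple and fully deterministic:

1. **Normalization.** Each sample's intensities are divided by that
   sample's median (50th percentile) on the linear scale, so every sample
   has median 1 afterwards. This is the MAS5-style per-chip scaling;
   nothing else (no background correction, no quantile normalization) is
   done, because the pipeline starts from already-summarized probe values.
2. **Detection filtering.** A probe is kept only if it has
   Present-or-Marginal calls in at least 70% of the samples of *every*
   analysis group — (arm, condition) pair — of the arm under analysis.
   The boundary is inclusive: 7 of 10 passes, 6 of 10 does not. Marginal
   counts exactly like Present. The alternative "at least one group"
   reading is available (`require="any"`) because the phrase "per analysis
   group" is genuinely ambiguous; the every-group default is the
   conservative choice.
3. **Probe collapse.** Each gene receives the median of its surviving
   probes, per sample. Even-count medians are the mean of the two central
   values (this convention is applied consistently in normalization,
   collapse and fold-change aggregation).
4. **Fold change.** log2(treated + ε) − log2(baseline + ε) with ε = 1e-6
   on the linear scale. Per-sample mode pairs each treated sample with its
   own patient's baseline — the design is a paired before/after cohort, so
   pairing is the natural reading; comparison against the pooled baseline
   median is available (`baseline="pooled"`). Aggregate mode compares the
   median over treated samples with the median over baseline samples
   (single fold-change column), matching what single-list enrichment tools
   consume. Genes that are zero in every sample of the arm are excluded
   and counted in the log; a sporadic 0/0 pair yields log2FC = 0 via ε.
5. **DEG calling.** Pure thresholding, boundary inclusive: up means
   log2FC ≥ +c, down means log2FC ≤ −c, default c = 1 (two-fold). There is
   deliberately no gene-level statistical test; significance enters only
   at the pathway level.
6. **Enrichment.** Per pathway and per column, genes of the knowledge-base
   universe are cross-classified into the 2×2 table (DEG vs not) × (in
   pathway vs not) and the one-sided upper-tail Fisher exact p-value is
   computed. A pathway is enriched when p < α (default 0.05, strict).
   Across samples, results are summarized as the number of samples in
   which each pathway is enriched.

## The Fisher tail

The hypergeometric point probability is evaluated through log-gamma
binomial coefficients and the upper tail P(X ≥ a) through a log-sum-exp
over the attainable table range; this is numerically exact to ≈1e-13
relative (verified against integer-arithmetic enumeration over every
contingency table with n ≤ 60 — 635,375 tables — in the test suite and the
acceptance script). Tables where a is at its margin-enforced minimum
return exactly 1.0.

Choices where the method description leaves room:

- **Sidedness.** The one-sided upper tail is the default: "enrichment"
  asks about over-representation, and smaller p ⇔ more DEGs in the
  pathway than chance only makes sense one-sidedly. The two-sided test
  (summing all tables with point probability ≤ the observed one, with a
  1e-7 relative tolerance for ties, the same convention SciPy uses) is
  available via `tail="two-sided"`.
- **Direction pooling.** Up- and down-regulated genes form one DEG pool;
  the contingency counts are direction-blind.
- **Universe.** The universe is the knowledge base's gene population (the
  union of its pathway gene sets), not the measured platform: d and n
  count KB genes. DEGs outside the KB are discarded before counting.
  `universe="kb-intersect-measured"` restricts to KB ∩ measured genes for
  users who prefer a platform-aware null.
- **Multiplicity.** No correction by default (the conventional p < 0.05
  per pathway per sample); optional Benjamini–Hochberg within each column
  (`bh=True`, via statsmodels).
- **Ordering.** Results sort by (p ascending, pathway name ascending) so
  output is deterministic under ties.

## Sensitivity analysis

DEG calling and enrichment are re-run at several cutoffs (default 0.5,
1.0, 1.5 log2). Because DEG sets nest as the cutoff grows, a pathway
driven by strong coherent signal tends to be enriched at every cutoff; the
report's `core_pathways` (enriched at all cutoffs in ≥1 sample) makes that
robustness explicit.

## Expression overlay

Pathway genes are discretized per column into four states at the DEG
cutoff — up / down / unchanged / not_measured — rather than a continuous
colormap, because downstream interpretation is phrased in up/down terms;
the continuous log2FC is retained as a node attribute. Exports are node
and edge TSVs plus GraphML (states and fold changes as per-column node
attributes, edge `sign` attribute), consumable by standard graph viewers;
rendering is out of scope.

## Synthetic cohorts

The generator emulates the *shape* of a paired topical-treatment
microarray study: `n_patients` (default 10) per arm (default BM and PC),
one baseline and one treated sample each, 1–3 probes per gene, and
detection calls drawn independently of intensity.

Model: gene g has latent log2 expression μ_g ~ Normal(6, 1); each probe
adds a fixed offset ~ Normal(0, 0.2); every observation adds measurement
noise ~ Normal(0, noise_sd), default 0.3 log2 units. A planted effect adds
a fixed shift Δ to `affected_gene_fraction` of a pathway's genes in the
treated sample of `responder_fraction` of patients. Intensities are
2^(log2 value), so a null gene's paired log2 fold change is
Normal(0, √2·noise_sd) — the probe offset cancels — which gives the
closed-form null DEG rate the tests check. Calls are Absent with rate
0.05 and Marginal with rate 0.05 by default, independent of intensity, so
the detection filter can be tested orthogonally to the signal.

Every pathway-assignment, ground-truth and data draw comes from one
`numpy` Generator seeded by `seed`; identical configs produce
byte-identical cohorts. Pathway assignment tiles a permutation of all
genes, so the KB universe equals the full simulated gene population;
overlap can be added explicitly (`overlap_fraction`) and arises anyway
when requested pathway slots exceed the gene count.

What the generator does *not* emulate: probe-level chemistry and
saturation, intensity-dependent detection calls, batch/array spatial
effects, correlated gene-gene noise, or patient-level baseline severity
differences. Passing calibration and power checks on these cohorts
demonstrates the statistical machinery is correct and well calibrated
under the stated model; it does not certify behavior under real-array
artifacts.

## Calibration and power studies

- **Type-I error**: 200 replicate null cohorts (400 genes, 13 pathways of
  ~30 genes, 10 patients, one arm, noise_sd 0.3); the statistic is the
  fraction of (pathway, sample, replicate) tests with p < 0.05, expected
  at or below 0.05 because the exact test is conservative under
  discreteness. Measured ≈ 0.014.
- **Power**: 100 replicates of a 2000-gene universe tiled by 67 pathways
  of 30 genes, one pathway planted with Δ = 2 log2 in 80% of its genes for
  all 10 patients. Recovery means enriched in ≥ responder_fraction ·
  n_patients − 1 samples; top-rank means smallest median p across samples.
  Both measured at 100%.

Problem sizes were fixed once to keep the studies cheap while leaving the
conclusions unambiguous (the type-I estimate has Monte-Carlo SE ≈ 0.001 at
26,000 calls; the power setting is far from the decision boundary).

## Degenerate inputs and numerical conventions

- Empty GMT → empty KB; enrichment refuses an empty universe.
- A sample whose median intensity is not strictly positive aborts
  normalization with the sample named.
- An unpaired treated sample aborts at design construction.
- p-values are clamped to ≤ 1.0 after summation; contingency counts must
  be non-negative integers.
- All file outputs (TSV/GMT/GraphML/manifest) are deterministically
  ordered; the run manifest stores a SHA-256 per file so reruns are
  verifiably identical.

## Known limitations

- ORA ignores pathway topology; edges are used only for overlay, and
  rank-based (GSEA-style) or permutation statistics are out of scope.
- The bundled demo knowledge base is a small synthetic stand-in for a
  curated skin pathway resource, adequate for demonstrations and tests,
  not for biological inference.
- GEO reproduction (`reproduce-geo`) needs network access and a
  platform-specific probe→gene mapping; sample-title design inference is
  heuristic and fails loudly (listing unresolved samples) rather than
  guessing.
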