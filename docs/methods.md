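# Methods

This note documents the models and procedures implemented in glorimap,
the assumptions behind them, the defaults and why, and what the
synthetic-data experiments do and do not demonstrate.

## Coordinate conventions

All coordinates are 0-based, half-open, in transcript space. Genome-space
mapping, strand bookkeeping and alignment are upstream concerns: the
pipeline starts from transcript-space reads or pileups. SAM input is
supported, with minus-strand alignments reverse-complemented into
transcript sense before pileup. Sequences are RNA-alphabet (A/C/G/U) in
memory; FASTA on disk uses T, converted on read/write. Inosine — the
product of the conversion chemistry — is written and read as G, which is
what a sequencer reports.

## The generative model

`simulate.py` emulates a GLORI experiment on a planarian-like
transcriptome:

- **Transcripts.** Sequences are i.i.d. draws with P(G) = P(C) =
  gc_content/2, default GC 0.32 (low-GC genomes are where the simple
  +1-rule sequence context matters most). Lengths are uniform on
  `length_range`; exon counts uniform on `exon_count_range` with
  junction positions uniform distinct interior points; expression
  weights are log-normal (σ = 0.8), giving the order-of-magnitude
  depth spread that creates the detectability confound downstream.
- **Sites.** An adenosine is rule-eligible if followed by C (+1 C class)
  or by U with another U at +4. Eligible positions within
  `eij_exclusion_nt` (default 100 nt) of a junction are suppressed
  entirely; the remainder is selected with probability proportional to
  exp(three_prime_bias · p/L), normalised so the mean equals
  `site_rate` (default 0.04). Stoichiometries are Beta draws:
  Beta(20, 2) (mean 0.91) for +1 C sites, Beta(6, 6) (mean 0.5) for the
  +1 U/+4 U class — high versus moderate methylation potential.
  No quantitative form for the 3′ bias is asserted; it is exposed as a
  tunable exponential weight.
- **Reads.** One read = one molecule. Each covered site is methylated
  with probability equal to its stoichiometry, independently across
  sites; a `coupling` flag replaces the independent draws with a single
  shared latent uniform per molecule (comonotone coupling) purely as a
  positive control for the linkage test. In treated reads every
  unmethylated A converts to G with probability
  `conversion_efficiency` (default 0.99); methylated As are protected;
  untreated reads are verbatim reference. Read counts per transcript
  are Poisson with mean ∝ expression weight.
- **Homologs** substitute each position independently, C/G positions at
  one rate and A/U at another (indel-free, so windows remain
  Hamming-comparable), with optional per-offset overrides relative to
  planted sites to create localised signals.
- **DE tables** draw baseMean log-normally; P(m⁶A) rises with expression
  rank (the coverage-detectability confound), and P(DE) depends on
  expression plus exactly `effect` for m⁶A genes after conditioning —
  so the expression-matched bootstrap has a known target.
- **Gene sets** share exactly the requested overlap.

Not modelled: sequencing errors, indels, splice isoforms, PCR
duplicates, quality scores, incomplete protection of methylated sites.
Passing tests therefore demonstrate correctness of the statistics under
the stated generative assumptions, not robustness to alignment artifacts
or error-prone base calls in real libraries.

## Scoring and site calling

The GLORI score at a reference-A position is A/(A+G); with conversion
efficiency *e* and stoichiometry *s*, E[score] = s + (1−s)(1−e).
Positions with A+G < 10 are discarded, transcripts with < 10 reads and
reads spanning > 700 nt are dropped at pileup. The per-sample background
is the pooled ΣA/(ΣA+ΣG) over all reference-A positions — pooled counts,
not a mean of per-position ratios, so low-coverage positions do not
dominate. The per-position test is a one-sided Fisher's exact test
(A-enrichment over background; only protection from conversion is
biologically meaningful), applied to positions with score > 0.1 and
A+G ≥ 10, significant at raw P < 0.05 — no multiple-testing correction,
mirroring the co-filtered raw-p convention for this assay (a BH switch
is available but off by default). The background enters the 2×2 table as
integer pseudo-counts at a fixed 10⁶ total; at the count scales involved
this is indistinguishable from carrying the raw pooled totals. A site is
emitted when it passes in ≥ `replicate_support` samples (default 1, the
"any sample" rule; figure-style stricter support is a parameter, not a
hard-coded choice). Replicate aggregation is the median.

At one-sample support and raw P < 0.05, positions with coverage near the
10× floor can pass on two or three unconverted reads; such borderline
calls have low median scores and are expected noise of the mirrored
filter chain, quantified in the null-calibration experiment below.

## Topology

Metagene bin: position p on a length-L transcript maps to bin
⌊10·p/L⌋+1, clamped to 10 — exhaustive and exclusive. EIJ distance is
the minimum |p − j| over junctions (undefined for single-exon
transcripts). Spacing: per gene with ≥ 2 sites, the distance from the
highest-median-score site (ties break 5′-most) to its nearest other
site. Adjacent-score correlation: Pearson r over all same-gene pairs
within 40 nt — the window matches the linkage analysis and is a flag,
since nothing pins it intrinsically. The 3′-bin score contrast uses a
two-tailed Student t test of the 3′-most bin against all others pooled.

## Linkage

Pair selection: gap ≤ 40 nt, both condition-median scores in
[0.4, 0.7] (outside this band one joint outcome is too rare to test),
and one member the gene's *dominant* site — read here as the gene's
highest-median-score site; this reading is an interpretation, flagged as
such. Reads spanning both positions are cross-tabulated on
{A, G} × {A, G}; reads with any other base at either site are tallied
separately (`n_other`) and excluded — under the conversion chemistry a
C/U at a reference-A site is uninterpretable. The test is Pearson's
chi-square without continuity correction on the 2×2 table, guarded by a
minimum of 10 informative spanning reads; a zero margin returns NaN.
Control replicates are pooled before testing. The survey reports the
p-value histogram, the fraction below 0.05 and a Kolmogorov–Smirnov
statistic against uniformity as a diagnostic.

## Sequence-context model

Contexts are 13 nt (±6), N-padded at transcript ends; one-hot encoding
gives 52 features (N → all-zero block). Sites with median condition
coverage < 40 are excluded — score estimates below that depth are too
noisy to regress on. The model is scikit-learn's
GradientBoostingRegressor with 300 estimators, depth 3, learning rate
0.1 (unremarkable defaults for a 52-feature tabular problem, recorded in
the report for reproducibility), an 80/20 train/test split and a fixed
seed; MSE and R² are reported on the held-out split and, separately, on
the full filtered set (both, since either convention is defensible).
Percentile ranks of predictions are computed on the full filtered
dataset. The predicted-vs-observed contrast takes the top 1% of
predictions and splits them into "coherent" (observed median > 0.8) and
"low score" (< 0.1) groups, comparing their EIJ-distance medians.

The logo matrix reports information content
IC(pos) = 2 + Σ_b f_b log₂ f_b bits under a uniform background, with
letter heights f_b·IC; no small-sample correction by default. Rendering
is left to the caller — the matrix is the deliverable.

## Conservation

The 13-nt context is scanned against the full homolog sequence at every
offset; the best window maximises matches. Matches are discarded when
the best score is attained by ≥ 2 windows (ambiguous) or the Hamming
distance exceeds 3. Matching is indel-free by construction; a homolog
with an indel near the site fails retention rather than being
realigned — documented behaviour, not a limitation to be fixed. With
several homolog transcripts per species, the best retained match per
species is used. Positional conservation compares each position's match
proportion against the pooled proportion of the other 12 positions with
a two-sample proportion test (chi-square with continuity correction,
matching R's `prop.test` defaults; a degenerate margin with equal
proportions returns p = 1), Bonferroni-adjusted ×13 exactly
(min(1, 13p)). The class-wise analysis contrasts substitution fractions
at each position between reference-C/G and reference-A/U sites the same
way.

## Enrichment statistics

**Expression-matched bootstrap.** Genes with baseMean < 200 are dropped;
missing adjusted p-values are set to 1; DE means padj < 0.05.
log₁₀(baseMean) is cut into 10 quantile bins. Each of 1000 iterations
draws, per bin, equal numbers of genes with replacement from the m⁶A and
non-m⁶A groups, with per-group totals of 0.8 × min(group sizes). Bin
quotas are proportional to pooled bin occupancy (an even 1/10 split is
available behind `flat_quotas`; the wording "equal numbers per bin" is
ambiguous between the two, and occupancy-proportional avoids
oversampling sparse tails). A bin empty in either group is skipped with
its quota redistributed. The reported difference is the plain DE-rate
difference between the filtered groups; p doubles the smaller tail of
the bootstrap distribution around zero (clipped to [0, 1]), the CI is
the 2.5th–97.5th percentile, and matching quality is the mean absolute
difference in mean log₁₀ baseMean between sampled groups. Because each
iteration resamples only 0.8× the smaller group, the procedure is
mildly conservative: measured type-I error at α = 0.05 is ~1–2%.

**Jaccard permutation.** Each iteration draws |A| and |B| genes without
replacement from the universe; p = (1 + #{overlap ≥ observed})/(n+1),
so p is never zero. The default 10⁶ iterations are configurable
downward; draws are vectorised in chunks via random-key argpartition.

**Hypergeometric lineage test.** P(X ≥ k) for population N, K lineage
genes, sample n — `scipy.stats.hypergeom.sf(k−1, N, K, n)`, validated
against exhaustive enumeration for small N.

**DE classifier.** Up: padj < 10⁻⁵ and log₂FC > 0.5 (strict); down
symmetric; missing padj counts as 1.

## Self-validation experiments and problem sizes

`calibration.py` packages the experiments that `tests/` and
`scripts/acceptance.py` run; sizes were chosen once, for statistical
power at desk scale:

- Score recovery: 540 sites (60 per stoichiometry in 0.1..0.9) at 300×,
  efficiency 1.0 — median |error| ≈ 0.017, comfortably under the 3·SE
  binomial envelope.
- Null calling: 200 transcripts × 150 nt at a flat 100× (whole-transcript
  reads, weights pinned to 1 — the condition is uniform depth; with
  realistic weight spread, low-coverage transcripts reintroduce the
  borderline calls discussed above), ≥ 10⁴ adenosines: 0 full-chain
  calls, Fisher-stage rejections ~2.5% (discreteness makes the exact
  test conservative).
- Linkage: 500 independent pairs at 200× (type-I ≈ 0.05), 150 coupled
  pairs (power 1.0).
- Hamming: 1000 random instances, exact agreement with enumeration.
- Motif model: planted-rule arm at n = 1500 (R² ≈ 1, importance at +1);
  noise arm at n = 5000, where the fixed-capacity model's overfitting
  bias (which scales as 1/n, roughly −0.19 at n = 1500, −0.05 at
  n = 5000) sits well inside the ±0.1 null band.
- EIJ contrast: 1500 sites, half EIJ-proximal and suppressed; the
  contrast uses the top 10% of predictions so both groups are populated
  at this n (the 1% default applies at real-data scale).
- Bootstrap: 200 null repeats and 100 effect-0.2 repeats at n_iter = 500,
  1500 genes each.
- Permutation agreement: |U| = 50, 10-gene sets, 2×10⁴ draws, compared
  to the exact tail in Monte-Carlo SEs.
- Conservation: 250 genes (~470 retained matches) — at ~180 matches the
  realised rate of a 3× elevation fluctuates enough (binomial noise plus
  the retention filter's selection against substituted sites) to
  underpower the Yates+Bonferroni test on unlucky draws.

The end-to-end pipeline default (60–100 genes, 300×) runs in well under
a minute on one CPU.

## Known limitations

- The caller's raw-p, any-sample rule admits borderline low-score calls
  near the coverage floor; users wanting a stringent list should raise
  `replicate_support` or filter on the median score.
- The linkage "dominant site" criterion is one reading of an
  underspecified rule; results are reported per pair so alternative
  selections can be applied downstream.
- Conservation treats each species independently and does not infer
  orthology; it assumes the provided homolog mapping.
- The synthetic generator's independence of methylation across sites is
  an assumption the linkage test then verifies — circularity is avoided
  only in the sense that the test is calibrated against the generator's
  known truth, not against real molecules.
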