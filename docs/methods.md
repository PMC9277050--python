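# Methods

`fragmeth` implements a fragment-unit differential-methylation analysis for
reduced-representation bisulfite sequencing (RRBS), followed by a clinical
biomarker stage. This note describes the models, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical conventions.

## Analysis units

RRBS libraries are built from MspI digests. MspI recognises CCGG and cuts
C^CGG, so every cut coordinate is `site + 1`; candidate fragments are the
intervals between consecutive cuts on a contig (terminal segments are not
flanked by two cuts and are excluded by default, with a flag to keep them),
and size selection retains fragments of 40–220 bp inclusive. CCGG is its own
reverse complement, so a single forward-strand scan finds all sites; `N`
never matches. These size-selected fragments are the primary analysis units.

Three further unit types are supported: promoters (a symmetric ±2,000 bp
window around the TSS; strand enters only through which coordinate is the
TSS), gene bodies (TSS to TES), and CpG islands. CpG islands are taken from
an external BED track when one is supplied — the safer choice, since no two
annotations agree — with a Gardiner–Garden-style sliding-window detector
(windows of 200 bp, GC ≥ 0.50, observed/expected CpG ≥ 0.60, merged runs
≥ 200 bp) as the fallback. All coordinates are 0-based half-open internally;
1-based formats (Bismark coverage) are converted at the parser boundary. A
CpG may belong to several overlapping units (a fragment inside a promoter);
overlapping promoters are kept as separate units so gene attribution stays
exact.

## Unit-level methylation and DMF calling

Per unit and sample, methylated and total read counts are summed over the
unit's CpGs with coverage ≥ `min_cov` (default 5 reads); a unit enters the
matrix only if every sample has ≥ `min_sites` (default 1) covered CpGs, so
each cell is observed rather than imputed. Global methylation per sample is
the read-weighted fraction Σmeth/Σtotal, and the two-sample comparison of
per-sample global levels uses a pooled-variance Student t-test (the variant
that reproduces the published group comparison on the nine printed values,
p = 0.106).

A unit is a differentially methylated fragment (DMF) when all three gates
pass: P < 0.05, Benjamini–Hochberg Q < 0.05 over all tested units, and an
absolute difference of group means above 25 percentage points. Group means
are unweighted means of per-sample fractions — a mean over patients, not a
read-pooled ratio — and the sign of the difference assigns hyper/hypo.

The default per-unit test is the pooled-variance t-test on per-sample unit
fractions. The alternative, a two-sided Fisher exact test on read counts
pooled within groups, is retained behind `test="fisher"` because it is the
only option without replicates, but it treats every read as an independent
Bernoulli draw. Bisulfite counts are overdispersed across samples — the
generator's beta-binomial with φ = 0.1 at 30× depth has a variance-inflation
factor near 4 — and on this package's own null simulations pooled Fisher
flags ~20% of units at Q < 0.05 versus ~0–1% for the t-test. A test that
respects the sample as the unit of replication is the defensible default for
a replicated design. Degenerate zero-variance cells are handled explicitly
(p = 1 for equal means, p = 0 otherwise, logged).

BH adjustment is the standard step-up rule q(i) = min over j ≥ i of
p(j)·m/j, capped at 1 (cross-checked against statsmodels in the tests).

## Candidate genes

Significant DMFs are annotated to every gene whose promoter or gene body
they overlap by ≥ 1 bp (CGI overlap is recorded as a flag). Genes with at
least one promoter-associated DMF become candidates; a candidate's direction
is the unanimous sign of its promoter-overlapping DMFs, with mixed-sign
genes labelled `ambiguous` rather than silently dropped, so the hyper/hypo
partition always audits back to the DMF table. Output is ranked by largest
absolute methylation difference.

## Clinical stage

A continuous methylation marker is dichotomized at the control "mean + 2 SD"
cutoff, with sample SD (n − 1) by default and population SD behind a flag
(published values of this kind of cutoff do not disclose the convention).
Values strictly above the cutoff are hypermethylated — the cutoff is the
upper edge of the control envelope, so a value exactly on it is not called.
Under normal controls ~2.3% of control-like values exceed the cutoff, which
the tests verify by simulation.

Group comparisons follow clinical-table convention: continuous variables via
Mann–Whitney U (exact permutation null when n₁+n₂ ≤ 12 without ties,
tie-corrected normal approximation otherwise; Student t available),
categorical variables via Pearson chi-square without continuity correction,
switching to the Fisher exact test for 2×2 tables with any expected cell
below 5. Two-sided Fisher p-values use the minimum-likelihood convention
(sum of all tables with the observed margins whose probability does not
exceed the observed one); this is the convention that reproduces the
published mutation-table p-values (0.266/1.000/0.016/0.406/0.340), whereas
doubling the one tail does not. Missing values are dropped pairwise, so
denominators vary by variable as they do in published tables.

## Survival stage

Kaplan–Meier curves use the product-limit estimator; subjects censored at an
event time remain at risk for that event. The log-rank statistic is
(Σ(O₁−E₁))²/ΣV with hypergeometric expectation and variance at each event
time, referred to χ²₁.

The Cox model maximises the Efron tie-corrected partial likelihood (Breslow
by flag) with Newton–Raphson, step-halving whenever a step would lower the
likelihood, converging when max|score| < 1e-7 or when the Newton step is
below 1e-10 (near the optimum the score itself is limited by floating-point
accumulation; risk-set sums are kept in extended precision, which in
practice leaves the score at ~1e-14). Standard errors come from the inverse
observed information; inference is Wald with fixed 1.96 for the 95% CI.
Fits whose score vanishes only at runaway coefficients (|β| > 15) are
flagged unconverged — the monotone-likelihood signature of perfect
separation. Multivariate model building enters every covariate with
univariate Wald p strictly below 0.200 into one joint fit; when nothing
qualifies only the univariate results are reported. For published-table
reproductions, age is dichotomized (≤60 vs >60) and IPSS risk is treated as
a single ordinal covariate.

## Synthetic data

The generators make the whole chain testable offline; they define the study
conditions rather than approximating any particular dataset.

**Genome.** Contigs are random A/T background into which CG dinucleotides,
CCGG motifs and CpG islands are planted explicitly (motifs are thinned to a
small exclusion zone so they never collide). Because the background contains
no C–G adjacency, every motif is a planted one: `ccgg_rate=0` provably
yields an undigestible genome and motif counts follow their binomial
expectation. Genes are evenly spaced so promoters stay disjoint, and each
TSS carries a planted 504 bp CpG island whose 42 bp repeat embeds one CCGG,
so island-internal fragments survive size selection and every promoter has
analysable units. The default planted CpG rate is 0.04/bp — above the
genome-wide ~0.01/bp deliberately, because the toy genome stands in for the
RRBS-captured fraction of a genome, which is CpG-enriched by construction;
at 0.04/bp a fragment carries ~5 CpGs, as real RRBS analysis units do.
The base composition is otherwise unrealistic (no isochores, no repeats),
which is irrelevant to the statistics downstream of site discovery.

**Methylome.** The design mirrors the RRBS cohort the pipeline was built
around: 5 cases vs 4 controls. Per CpG and sample, a methylation probability
is drawn from a beta distribution with mean μ (baseline 0.5) and dispersion
φ (default 0.1; Var = μ(1−μ)φ), depth is Poisson (mean 30; depth and
dispersion are conventional values, as RRBS library statistics are rarely
published), and methylated counts are binomial. Planted effects shift μ by a
signed delta for all CpGs of the chosen units in case samples only,
clamped to [0,1] with a warning. Effects are applied at the unit level —
matching the granularity at which the analysis tests — and a promoter-wide
effect is planted by naming the promoter unit itself.

**Clinical cohort.** Event times are exponential with hazard
h₀·exp(β·hyper), censoring is an independent exponential, and mutation flags
are independent Bernoulli columns; the continuous marker is consistent with
the binary status. Prevalence of hypermethylation defaults to 0.35 (the
ballpark of a 37/105 split). Exponential truth gives closed-form recovery
targets for the Cox tests.

What passing tests therefore show: correctness of the coordinate logic, the
tests and the thresholds, FDR calibration under realistic overdispersion,
and power at a 40-point planted effect. What they do not show: behaviour
under real-data features the generators omit — read-level artifacts,
incomplete bisulfite conversion, SNPs under CpGs, batch effects,
non-exponential hazards, informative censoring.

## Operating characteristics (recomputed, not asserted)

`fragmeth.calibration` re-runs the studies behind the headline numbers at
every invocation: DMF calling on a ~1,650-unit null flags 0–1% of units at
Q < 0.05 (bound: 5% + 2 binomial SE); sensitivity on 220 planted ±0.4
effects is ≈ 0.92–0.96 with 100% direction agreement; promoter-effect genes
are recovered with recall 1.0 and correct labels; the Cox coefficient
(β = 0.7, n = 1000, 200 replicates) shows |bias| < 0.01 and ~95% CI
coverage. Problem sizes (two 120 kb contigs, 200 Cox replicates) keep a full
run under a minute while leaving every rate estimable.

## Known limitations

- The per-unit t-test assumes approximate normality of per-sample fractions;
  with very few CpGs per unit and extreme μ it is conservative rather than
  exact. No beta-binomial regression or smoothing is provided.
- The CGI detector is a single-scale sliding window, not the multi-criteria
  hidden-Markov annotations modern genome browsers ship.
- The Cox implementation covers fixed covariates only: no stratification,
  time-varying effects, or robust variance.
- Genome-scale published counts (numbers of DMFs per unit type, candidate
  totals) depend on the original raw reads and unreported test settings and
  are therefore out of reach of any reimplementation; the pipeline instead
  demonstrates calibration and power on data with known truth.
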