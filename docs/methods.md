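# Methods

This note documents the models and procedures implemented in
`poolscape`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Pool-seq sites and per-SNP FST

A sync record carries raw per-pool read counts in the fixed base order
A:T:C:G:N:del. Sites are reduced to biallelic form for one pool pair:
an allele is *real* when its combined read count across the two pools
reaches `min_count` (default 6); sites with fewer than two real alleles
are non-informative, sites with more are multiallelic, and both are
rejected with a structured reason. Coverage and frequencies are
computed over the two real alleles only, so sub-threshold error reads
never perturb frequency estimates. Default filters (per-pool coverage
in [80, 500], combined minor allele frequency ≥ 0.05) reflect a
high-coverage pooled exome design with pools of 20 diploids (40 haploid
genomes). The MAF filter belongs to the outlier-scan branch only; the
demographic branch keeps low-MAF sites.

Per-SNP FST uses the heterozygosity form: with per-pool minor-allele
frequencies f₁, f₂,

    π_p = 2 f_p (1 − f_p),  π_S = (π₁ + π₂)/2,
    f̄ = (f₁ + f₂)/2,        π_T = 2 f̄ (1 − f̄),
    F_ST = (π_T − π_S) / π_T   (0 when π_T = 0).

The unweighted mean f̄ keeps unequal coverages from biasing π_T toward
the deeper pool. The uncorrected form is the default because the
downstream scan is rank-based (top percentile), which is insensitive to
monotone finite-sample corrections at comparable coverage; an optional
`corrected` flag applies the n/(n−1) factor with n = min(pool haploid
size, coverage) per pool, and corrected values are not clamped at zero
since outlier calling is quantile-based.

## Island scan

The scan slides a window of 10 adjacent SNPs in steps of 2 along each
chromosome. The outlier threshold is the genome-wide 0.99 sample
quantile of per-SNP FST under the linear-interpolation convention
h = (n−1)q + 1 (stated explicitly because quantile definitions differ
across ecosystems); the outlier predicate is *strictly greater than*
the threshold, so ties at the threshold are non-outliers. Significance
comes from an empirical null: 100,000 resamples of 10 SNPs drawn with
replacement from the genome-wide FST vector, tallied by outlier count.
The null does not depend on the window, so it is built once per species
pair and reused. A window's p-value is the upper-tail proportion of
resamples with at least the observed outlier count; windows with
p < 0.001 are significant by default (the alpha is exposed because the
analysis can also be run at stricter levels). With an exact outlier
fraction of 0.01 the null converges to Binomial(10, 0.01), which makes
3 of 10 outlier SNPs the significance boundary at alpha 0.001
(P(X ≥ 3) ≈ 1.14 × 10⁻⁴, P(X ≥ 2) ≈ 4.3 × 10⁻³).

Significant windows sharing at least one member SNP merge into maximal
non-overlapping islands (step-2 windows overlap by 8 SNPs, so a
significant run collapses into one island). Island-vs-island sharing
and gene membership both use the ≥ 1 bp overlap rule on 1-based
inclusive coordinates; BED output converts to 0-based half-open on
write. Gene-set enrichment is an exact hypergeometric upper tail per
term (population = background genes, successes = term genes present in
the background, draws = candidates), Bonferroni-corrected by the number
of terms with at least one background gene.

## Two-deme structured coalescent

Genealogies are simulated backward in time with exponential competing
risks. Within deme d with k_d active lineages, coalescence occurs at
rate k_d(k_d−1)/2 · 1/ν_d; each lineage in deme 1 migrates to deme 2 at
rate m₁₂ (and symmetrically). Time is measured in units of 2·N_ref
generations, sizes ν are relative to N_ref, and migration rates are
per-lineage backward rates on the same scale; the factor-of-two
migration convention is fixed by the analytic checks in the test suite
(E[T₂] = ν in a single deme; a clean split at T with one lineage per
deme gives mean pairwise coalescence time T + ν_anc) and by a
cross-validation against msprime on a matched two-deme scenario.
Waiting times that cross an epoch boundary are clipped to the boundary
and redrawn under the new rates, which is exact for piecewise-constant
rates — there is no time discretization. The ancestral phase is a
single population of size ν_anc = 1.

The expected joint SFS uses the branch-length estimator: cell (i, j)
accumulates the total branch length subtending exactly i deme-1 and j
deme-2 samples, which is proportional to the expected SNP density at
those counts under infinite sites. This has lower variance per
genealogy than dropping mutations, with the same expectation. Branch
lengths are accrued per lineage between coalescence events, so
migration events cost O(1) and high-migration models stay tractable.
Synthetic SNP frequency pairs place exactly one mutation per
independent genealogy, uniformly by branch length, so every emitted SNP
segregates in the combined sample (unlinked SNPs; linkage inside
islands is emulated downstream by the data generator, not here).

Folding maps cell (i, j) onto its conjugate (n₁−i, n₂−j) when the total
count i + j exceeds half the total sample size; cells exactly at half
split the pair's mass evenly, and self-conjugate cells keep their mass
once, so total mass is conserved.

The seven model families follow the standard two-population divergence
taxonomy, with free-parameter counts used for AIC: no_mig (3), sym_mig
(4), asym_mig (5), anc_sym_mig (5), anc_asym_mig (6),
sec_contact_sym_mig (5), sec_contact_asym_mig (6). Secondary-contact
models place the isolation interval (T1) before the migration interval
(T2, most recent); ancient-migration models mirror that orientation.

## Demographic inference

The observed spectrum comes from per-pool minor-allele frequencies:
one SNP is kept per megabase bin (bins anchored at position 1, one
uniform draw per non-empty bin) to approximate linkage equilibrium,
each frequency is converted to a count out of the pool haploid size by
half-up rounding (a deterministic, testable rule; binomial draws are a
flag away for users who prefer stochastic rounding), SNPs invariant
after rounding are dropped, and the tallies are folded. No projection
to smaller sample sizes is applied.

The fit maximizes a multinomial composite log-likelihood
LL = Σ obs·log q over unmasked cells, with q the model spectrum
normalized over unmasked cells and floored at 10⁻¹² of its total so an
empty Monte-Carlo cell cannot produce −∞. θ̂ is the ratio of observed
mass to raw (branch-length) model mass — a derived scale factor, not a
fitted parameter, which is consistent with treating only the
demographic parameters as free in AIC.

Optimization is a multi-round search in log-parameter space: round 1
draws log-uniform starts (augmented by nested warm starts, below),
later rounds perturb the incumbent with shrinking spread, and the best
`polish_top` points per round are polished with adaptive Nelder-Mead
started from a deliberately wide initial simplex (0.7 log units per
coordinate) so the polish can traverse orders of magnitude; richer
families receive proportionally more simplex iterations. All
evaluations within one fit share a single random seed (common random
numbers), making the search surface deterministic, the best
log-likelihood monotone across rounds, and the whole fit reproducible.
When ranking families, every family's best fit is re-evaluated at
higher genealogy count with one seed shared across families, so
Monte-Carlo noise largely cancels from the AIC comparison.

Nested warm starts: each family's start list includes the embedded
optima of its nested submodels (for example, asym_mig starts from the
sym_mig optimum with m₁₂ = m₂₁ = m; secondary-contact families start
from the constant-migration optimum with T split into isolation and
contact intervals at several fractions). Every family receives its own
embeddings, so the chain does not bias the comparison toward any one
family; it addresses the practical failure mode where a 6-parameter
family cannot locate its optimum from random starts alone.

Search bounds are ν ∈ [10⁻³, 50], m ∈ [10⁻⁵, 15], T ∈ [10⁻³, 30]; the
migration cap comfortably contains fitted values reported for
comparable analyses (≤ ~9) and keeps the simulator away from
pathologically migration-dominated regions during the search.

Desk-scale defaults (2 rounds × 5 replicates, 2 × 10⁴ genealogies per
evaluation) are deliberately small; the model-selection experiments in
the test suite use one 40-start round triaged at 10³ genealogies,
polished at 2.5 × 10³, with a 1.2 × 10⁵-genealogy shared final
evaluation, and the four-round 10/20/30/40 schedule used for full-scale
analyses is available through configuration. A nested-consistency sweep
runs after the per-family fits: a family can never genuinely fit worse
than a submodel nested inside it, so any such inversion left by the
search triggers one warm-started refit of the richer family from the
submodel's embedded optimum. Parameters are reported in coalescent
units; no conversion to years or individuals is attempted.

## Synthetic data generator

The generator emulates a two-pool exome design: two pools of 20
diploids, 5,000 biallelic SNPs over two 10-Mbp chromosomes (uniform
positions), per-pool coverage Poisson(150) truncated to [80, 500] so
defaults survive the coverage filters, and binomial read sampling at
the true pool frequency (the haplotype-sampling stage is already
captured by the coalescent sample frequencies; sequencing error is
optional and off by default). Reads map to bases A (major) and T
(minor) by convention.

Background frequency pairs come from the structured coalescent under a
configurable demography; the default, sym_mig(ν₁ = ν₂ = 1, m = 5,
T = 0.1), was chosen so the mean per-SNP pooled FST lands at the few
percent observed for a recently diverged species pair. Because real
pool-seq callsets are reported after MAF filtering, background pairs
are drawn conditional on combined sample MAF ≥ 0.05 (rejection
sampling); setting `background_maf_min = 0` recovers the raw
segregating-site law.

Divergence islands are imposed at the frequency level: disjoint blocks
of 20 consecutive SNPs (with a guard gap so called islands stay
distinct) whose frequency pairs are redrawn from Beta(8, 2) ×
Beta(2, 8) — strong but noisy differentiation. This deliberately skips
any model of linked selection: the scan needs controllable truth, and a
selection model would add parameters the analysis never estimates.
Consequences for interpretation: passing recovery tests shows the scan
detects localized frequency divergence of this magnitude against a
weak background at this SNP density; it says nothing about linked
selection footprints, recombination-rate variation, or reference bias
in real data.

A power note on the island criterion: the outlier budget is capped at
1% of the scan set (~50 SNPs) while islands contribute 160 SNPs, so
roughly a third of island SNPs can be outliers and per-island detection
power is about 0.8-0.9 under the default conditions. Recovery of at
least 80% of the 8 injected islands is therefore expected but not
guaranteed for every seed; the fixed-seed recovery test and the
false-call bound (≤ 1) are the stable checks.

## Numerical and degenerate-input choices

- Quantile thresholds require ≥ 100 values; the outlier predicate is
  strict, so an all-equal FST vector yields zero outliers.
- Windows never cross chromosomes; trailing runs shorter than 10 SNPs
  yield no window; unsorted input is an error, never silently sorted.
- p-values are empirical tail proportions; observed count 0 gives
  exactly p = 1.
- A pool with zero coverage over the two real alleles gets frequency 0
  and is removed by the coverage filter.
- Tie between the two real alleles' combined counts: the
  alphabetically first base is major.
- `resample_null` draws in chunks of 200,000 resamples to bound memory.
- Model spectra with empty cells are floored (10⁻¹² of total mass)
  rather than masked, so likelihoods stay finite and comparable.

## Known limitations

- Per-SNP FST is the uncorrected heterozygosity estimator; absolute
  values are not comparable to estimators with explicit finite-pool
  corrections, though ranks (and hence the scan) are robust.
- The composite likelihood treats SNPs as independent; megabase
  thinning reduces but does not remove linkage, and no effective-size
  correction is applied to the likelihood.
- Monte-Carlo expected spectra make log-likelihoods noisy at small
  genealogy counts; rankings should use the shared-seed final
  re-evaluation, and parameter uncertainty is out of scope.
- The coalescent supports exactly two demes plus a single ancestral
  population, without recombination or selection.
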