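# Methods

`conetdiff` implements a two-condition gene co-expression workflow for
normalized log2 expression matrices: per-gene differential expression (DE)
with false-discovery control, per-condition all-pairs correlation networks
filtered by the PCIT trio test, phenotypic and regulatory impact factors
(PIF, RIF1, RIF2) scored over *all* genes as candidate regulators,
differential hubbing of strong retained edges, and gene-set
over-representation.  The canonical application is a wild-type vs knockout
contrast (e.g. myostatin-null muscle) with few replicates per genotype, but
nothing is specific to that system.

Throughout, one condition is designated the reference **A** (wild-type-like)
and the other **B**; every signed quantity — fold change, PIF, RIF, dh — is
A-minus-B or A/B.  Swapping the labels inverts fold changes and negates PIF,
RIF1, RIF2 and dh exactly; the test suite asserts these identities.

## Differential expression

Each gene is tested under a completely randomized two-group design,
y_ij = mu + G_i + eps_ij, with a pooled-variance two-sample t on the log2
values.  By default the gene-wise variances s_g^2 (d residual df each) are
shrunk toward an empirical-Bayes prior: the prior (d0, s0^2) is fitted by
the method of moments on log s_g^2 (Smyth-style, with a Newton inversion of
the trigamma function), the posterior variance is
s~_g^2 = (d0 s0^2 + d s_g^2)/(d0 + d), and the moderated t is referred to a
t distribution with d + d0 df (normal when d0 is infinite).  One unit test
verifies agreement with R/limma's `eBayes` on a random fixture to ~1e-8
relative; the plain t (available by flag) is cross-checked against
`scipy.stats.ttest_ind`.  Genes with zero pooled variance are reported with
t = 0, p = 1 and a warning rather than an error, so degenerate synthetic
limits pass through the pipeline.

Fold change is reported as A/B = 2^(mean_A − mean_B) on the linear scale;
"Up" means fold change > 1.  When a probe-level annotation maps several
probes to one gene symbol, the result table can be collapsed to the probe
with the smallest q-value per symbol (ties keep the first probe in input
order — the tie-break is a convention, chosen for determinism).

FDR control offers Benjamini–Hochberg (step-up) and Storey q-values.  The
Storey null proportion pi0 is estimated on the lambda grid 0.05, 0.10, …,
0.95 as pi0(lambda) = #{p > lambda}/(m(1 − lambda)), extrapolated to
lambda = 1 with a cubic polynomial least-squares fit.  A cubic polynomial
replaces the smoothing spline some implementations use because it is
deterministic with no smoothing-parameter choice; whenever the extrapolated
pi0 leaves (0, 1] the estimator falls back to pi0 = 1, i.e. plain BH, so
q-values are never anti-conservative relative to BH.  DE calls use q < 0.05
by default.

## PCIT edge filtering

For each condition with at least three samples, the network is the full
Pearson correlation matrix (zero-variance genes are flagged and set to
r = 0).  PCIT then asks, for every gene pair (x, y) and every third gene z,
whether the direct correlation is explainable through z.  The three
first-order partial correlations of the trio are computed as
r_xy·z = (r_xy − r_xz r_yz)/sqrt((1 − r_xz²)(1 − r_yz²)) with the
denominator clamped below at 1e-12; the trio tolerance eps is the mean of
the ratios partial/direct over the trio's pairs whose direct |r| exceeds
1e-8 (a trio with no qualifying pair imposes no constraint).  The edge
(x, y) is locally dominated in the trio iff |r_xy| < |eps·r_xz| **and**
|r_xy| < |eps·r_yz| — strictly, so ties retain the edge — and an edge is
significant iff no z dominates it.  With fewer than three genes all
off-diagonal edges are significant.  The conditioning gene z ranges over
every gene in the analysis set (post probe-exclusion).

The production implementation vectorizes the trio scan per conditioning
gene z (G slices of G×G work, preallocated buffers); a scalar triple-loop
reference implementation evaluates the identical arithmetic in the
identical order.  Equality of the two edge sets — exact boolean equality,
seed by seed, on random matrices — is the core correctness surface and is
asserted over 130 random instances in the suite.  G = 500 completes in
about 3 s on one CPU; the scalar reference is O(G³) in Python and intended
for G ≤ ~25.

## PIF and RIF

With e_jA, e_jB the mean log2 expression of gene j per condition,

    PIF_j  = ((e_jA + e_jB)/2) · (e_jA − e_jB)

couples abundance and differential expression.  For a candidate regulator i
and target set T (the DE genes at q < alpha; self-pairs excluded), with
differential wiring DW_ij = r_ijA − r_ijB on the *raw* correlations,

    RIF1_i = (1/|T_i|) Σ_j PIF_j · DW_ij²
    RIF2_i = (1/|T_i|) Σ_j (e_jA r_ijA)² − (e_jB r_ijB)²

Raw correlations rather than PCIT-filtered ones enter RIF because
differential wiring is defined on all pairs; the PCIT + |r| ≥ 0.90 capture
applies only to the hubbing step below.  Candidate regulators default to
every gene, which is the point of the method: regulators need not be
annotated transcription factors, and need not be DE themselves.  A
regulator that is itself a target sums over the remaining |T| − 1 targets
(its self-terms would contribute r = 1 in both conditions).  Raw columns
are Z-standardized (sample sd) over the regulator universe, and reports
list the top-k positive and top-k negative Z separately, ties broken by
input order.  A scalar per-pair oracle in the tests pins the vectorized
sums to 1e-10 relative.

An empty target set raises a design error rather than returning zeros: RIF
contrasts wiring *to DE targets*, and a dataset with no DE genes has no
defined RIF (the pipeline stage is skipped with a logged reason in that
case, and downstream stages still run).

## Differential hubbing

Per condition, k_g counts partners h ≠ g whose edge is PCIT-significant
**and** has |r| ≥ 0.90 (both clauses; a flag gives the |r|-only variant for
sensitivity analysis).  The strict threshold compensates for the small
replicate numbers typical of these designs.  The contrast dh = k_A − k_B is
reported with both counts, ranked by |dh|.

## Gene-set over-representation

Lists are tested against user-supplied GMT collections on the 2×2
membership table with the hypergeometric upper tail; `ease` mode (default)
decrements the overlap count by one before testing, reproducing the
conservative DAVID-style variant, and `fisher` is the exact one-tailed
test.  Totals follow the annotated-universe convention (List Total and Pop
Total count only genes covered by at least one set); the background
defaults to all genes on the analyzed matrix and is user-overridable, since
the annotated universe of any external service is not recoverable.  Fold
enrichment is (count/list_total)/(pop_hits/pop_total), and Benjamini is BH
over all tested sets.  The suite recomputes five published KEGG rows from
their printed count columns and matches the printed fold enrichments at two
decimals; the hypergeometric tail is pinned to a brute-force `math.comb`
summation.

## Synthetic data

The generator emulates a two-genotype microarray experiment after upstream
normalization.  Defaults mirror the emulated design: 5 replicates per
genotype (pooled-sample style), baseline means ~ Normal(8, 1.5²) log2
units, homoscedastic replicate noise sd 0.25 (post-normalization microarray
residuals are approximately Gaussian on the log2 scale), and a planted DE
shift of 1.5 log2 units in condition A.

Planted wiring uses one latent factor per structure, with the driver gene's
expression *as* the factor: x_driver = mu + f, f ~ N(0,1) per sample, and
each target x_target = mu (+ delta if DE) + b_c f + eps, where
b_c = sigma·lambda_c/sqrt(1 − lambda_c²) makes the target's population
correlation with the factor equal the requested loading lambda_c in
condition c.  Consequently corr(driver, target) = lambda and
corr(target, target′) = lambda² within the active condition.  This
asymmetry is deliberate: it is what makes "the regulator/hub" a recoverable,
identifiable object.  Targets of a common driver are necessarily
inter-correlated (no joint distribution can make one gene correlate at 0.9
with thirty mutually independent genes), but at lambda² their edges sit
below both the driver–target edges and the 0.90 hubbing threshold, so the
driver — and only the driver — surfaces in RIF and dh rankings.  The driver
carries no extra replicate noise (its replicate variation *is* the factor).

What the generator does not emulate: probe-level effects, array spatial
artifacts, heteroscedastic or heavy-tailed noise, correlated background
structure, or pooling-variance effects beyond the replicate count.  Passing
recovery benchmarks therefore demonstrates correctness of the estimators
under the stated model, not performance on real arrays.

## Validation benchmarks and their power

`conetdiff.benchmarks` re-runs the full chain on simulated data with known
truth; `scripts/acceptance.py` executes them all.  Problem sizes were
chosen to exercise the network stages at realistic signal strength while
keeping a full run in minutes on one CPU: regulator recovery uses 500
genes, 30 DE targets (delta 1.5), loading 0.85 in A only, n = 20 per
condition, 50 replicates; hub recovery uses 500 genes, 50 targets at
loading 0.9, 50 replicates; null calibration uses 200 structure-free genes,
20 replicates.  All replicate seeds derive from one base seed via
`numpy.random.SeedSequence`.

A power note on RIF1: with loading lambda = 0.85 the regulator/target raw
separation is DW² ≈ lambda² vs lambda⁴ (0.72 vs 0.52), and the per-replicate
probability that the regulator lands in the top 1% of |RIF1 Z| is about
0.95 at these settings — the benchmark sits near its threshold, and single
replicates can place a strongly wired *target* above the regulator.  RIF2
separates more cleanly (the regulator's expression predicts targets
directly) and recovers essentially always, as does the hub benchmark, where
target–target edges fall below the 0.90 filter.  Hub recovery counts a
replicate as successful when the hub *attains* the maximum |dh|: in the
occasional replicate whose factor realization has low sample variance, all
hub–target correlations drop below the 0.90 cut together and several genes
tie at a small |dh|, the hub among them.

## Numerical conventions

* Text round-trips write 10 significant digits.
* Z-standardization uses the sample sd (ddof = 1); a zero-sd column maps to
  Z = 0.
* All argsorts are stable; every tie-break is "first in input order".
* Partial-correlation denominators clamp at 1e-12; tolerance ratios skip
  direct correlations with |r| ≤ 1e-8.
* Pipeline outputs carry no timestamps, so identical config + seed gives
  byte-identical files (asserted via sha256 in the tests).

## Known limitations

* The PCIT scalar reference is quadratic-memory-free but cubic-time; use it
  only for validation at small G.
* Storey's pi0 with very few p-values is unstable; the BH fallback bounds
  the damage but small-m q-values are effectively BH.
* PIF magnitudes depend on the (arbitrary) log2 offset of the platform;
  comparisons are meaningful within one dataset, not across platforms.
* The enrichment module supplies no gene-set database; collections are user
  inputs in GMT form.
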