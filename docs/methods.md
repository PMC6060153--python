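# Methods

This note documents the statistical models, the defaults and why they
were chosen, the numerical choices, and what the synthetic-data tests do
and do not establish.

## Coordinates and data model

All intervals are 0-based half-open internally; VCF positions are shifted
on ingest/egress, BED/BEDPE are native. Genotypes are stored as phased
haplotype pairs; dosage is the alternate-allele count (0/1/2). Missing
genotypes are excluded pairwise per test rather than imputed: the
package's intended inputs are fully imputed panels, so a missing value in
synthetic or user data indicates a deliberate hole and silently imputing
it would hide that. LD (D, D′, r²) is always computed from phased
haplotype tallies; unphased genotypes are rejected rather than resolved by
EM, which keeps the LD surface small and exactly testable against
hand-counted 2×2 tables.

## Consensus peaks

A genomic base belongs to a candidate region when peaks from at least
`min_support` individuals (default 13, a majority of 25) cover it; this
per-base reading is the standard multi-sample consensus rule.
Support-passing regions separated by *fewer than* `merge_gap` bp (default
147, one nucleosome footprint) are merged — the inequality is strict, so
a 146 bp gap merges and a 147 bp gap does not. Merging is applied after
support thresholding; the per-interval support recorded is the maximum
coverage across the merged span. Candidate hQTL variants are autosomal
variants inside any consensus interval that are heterozygous in at least
one sample.

## Combined haplotype test

Per SNP region the joint log-likelihood is

```
L(α, β, m) = Σ_hets log BetaBin(ref_as | n_as, π = α/(α+β), ρ)
           + Σ_all  log NB(total | μ_j, φ),   μ_j = s_j · m · (g_ref,j·α + g_alt,j·β)/2
```

with `α + β = 2` so that the allelic ratio `t = log2(α/β)` is the single
effect parameter; `g_ref + g_alt = 2` encodes genotype (homozygous
reference contributes `α`, heterozygous 1, homozygous alternate `β`), and
`s_j` is a per-sample size factor. The null fixes `α = β = 1`. The
likelihood-ratio statistic is referred to χ²(1); the permutation
calibration (`calibrate`) provides a global check of that reference
distribution. A negative binomial was chosen for the depth component —
the natural overdispersed count law when no replicate structure motivates
a beta layer on the depth side.

Numerics: the depth mean `m` is profiled out by bounded scalar
minimisation (tolerance 1e-8 on log m) and the effect `t` is then
optimised on the profile likelihood (Brent, tolerance 1e-6), box-bounded
to `|t| ≤ 6` (allelic ratios within [1/64, 64]); an estimate pinned at the
box is flagged `at_bound`. An earlier two-dimensional quasi-Newton
implementation left enough optimisation error to visibly distort the null
p-value distribution at 2,000 regions; the profile approach removes that.
The χ²(1) approximation itself is good but not perfect at 25 samples and
allele-specific depth 30 — empirical deviations of up to ~0.03 in the
p-value CDF can appear for unlucky genotype ensembles, which is the
expected small-sample/discreteness error of a likelihood-ratio test on
counts.

**Testability.** A region is testable with ≥ 15 allele-specific reads
summed over samples and at least one heterozygote (10 reads in
replication mode, for thinner data).

**Dispersions.** ρ (beta-binomial) and φ (negative-binomial) are learned
once across all testable regions and held fixed per-SNP. For ρ the
per-region allele fraction π is *integrated out* over a uniform prior
(40-node Gauss–Legendre quadrature) rather than profiled: with ~10
heterozygotes per region, profiling the incidental means biases ρ̂
downward by ~15% (0.043 for a true 0.05 in simulation), which makes the
per-SNP test anticonservative; the marginal estimator is unbiased in the
same simulation (0.050). For φ the per-region mean is profiled (one
nuisance parameter per ~25 observations, where profile bias is
negligible). Poisson-like data drive φ̂ to its upper bound (1e6), the
Poisson limit.

**GC-content adjustment** is a no-op hook: a user-supplied per-sample
multiplicative offset is accepted (`gc_offset`), but no GC curve is
estimated — synthetic data carry no GC structure, and the functional form
of such corrections is data-dependent. Genotypes are treated as known;
no haplotype-probability calibration layer is implemented.

**Tiers.** Holm step-down FWER across all tested SNPs; `significant` at
FWER ≤ 0.1, `suggestive` at ≤ 0.2. Holm and Benjamini–Hochberg are
delegated to `statsmodels.stats.multitest` behind the package's own
interface and are cross-checked against explicit step-down/step-up
oracles in the tests.

## Risk-haplotype enrichment

The matchable pool is the set of variants in consensus peaks. Decile
edges are computed on the pool's empirical MAF and |TSS-distance|
distributions (10 × 10 = at most 100 categories); edges are right-closed
and duplicate edge values collapse bins. Query variants (hQTLs) are
excluded from the matchable pool, so null sets never contain the query.
Each permutation draws, per category and without replacement, exactly as
many pool variants as the query holds there — null sets therefore
reproduce the query's category histogram exactly (asserted as an exact
test). Risk-haplotype membership is by variant-id set: the union of
haplotype blocks containing a catalog index SNP (an index SNP in no block
contributes itself). The permutation p uses the add-one estimator
`(1 + #{null ≥ obs})/(1 + n_perm)` (never 0) and the expected count is
the null mean. An optional exclusion interval drops variants (query and
pool) before binning, e.g. to remove an HLA-like region. Fisher's exact
test (one-sided, greater) on the 2×2 set × catalog table accompanies the
permutation p.

Validity caveat built into the test design: the null count distribution
shrinks relative to the query count's sampling law when the pool is not
much larger than the query (without-replacement draws from a finite
pool), and ties in the integer overlap counts make the add-one estimator
conservative. The enrichment checks therefore use a pool 20× the query
(10,000 pool variants, 500 queries), mirroring the regime such analyses
are run in (pools of hundreds of thousands vs thousands of queries).

## Cis-eQTL mapping

Genes with positive expression in > 50% of samples and coefficient of
variation ≥ 0.15 (computed on raw CPM — the inverse-normal transform
destroys CV) are transformed per gene to normal quantiles at
`(rank − 3/8)/(n + 1/4)` with average ranks for ties. Pairs are tested
when the SNP lies strictly within 1 Mb of the nearest transcript edge
(TSS/TES interval, not TSS alone) and SNP MAF ≥ 0.05. Ordinary least
squares of transformed expression on dosage, t-test p, BH FDR over all
tested pairs at q ≤ 0.05, then per-gene greedy pruning in ascending p
retaining SNPs with r² < 0.8 against everything already retained; the
smallest-p retained SNP per gene is its lead. No latent-factor
normalisation is implemented; the synthetic generator can add a shared
log-normal sample factor, which the rank transform partially absorbs —
a documented limitation, not an emulation of factor-correction methods.

## Joint-effect models

`fit_nb_glm` fits a log-link negative-binomial GLM by IRLS
(statsmodels `GLM` with the NB family) alternating with profile-ML
updates of the dispersion α (variance `μ + αμ²`; θ = 1/α), the behaviour
of `glm.nb`. Null (intercept-only) and residual deviances are evaluated
at the final α, so `D² = (null − residual)/null deviance` lies in [0, 1];
D² is monotone under nested designs only at fixed α, and the test asserts
it in that regime. The implementation is verified against an
independently hand-coded IRLS to 1e-6 on a 12-observation fixture.

**Local (block) analysis.** Eligible blocks have ≥ 6 variants and an
eQTL–hQTL pair in strong LD (D′ ≥ 0.8) but not highly correlated
(r² < 0.6). With several candidates, the lead eQTL is the variant whose
dosage alone explains the most deviance of its target gene and the lead
hQTL is the most significant allelic-imbalance hit ("lead" is read as
most significant, i.e. minimum nominal p). The observed statistic is the
D² of the full interaction model `counts ~ 1 + d_e + d_h + d_e·d_h` (the
same model serves the local and distal analyses); the null substitutes
each non-QTL block variant for the hQTL. If fewer distinct substitutions
than `n_perm` (default 10,000) exist, they are exhausted and resampled
with replacement; the add-one permutation p is reported with a
Clopper–Pearson 95% interval on the exceedance proportion. A substitution
collinear with the eQTL falls back to the main-effect-only design — it
carries no information beyond the eQTL. Note the resampling makes the
permutation p's support finer than the number of distinct substitutions;
uniformity of the null p is only approximate when a block has very few
non-QTL variants (the calibration checks use ~30).

**Distal interaction scan.** Pairs must be LD-independent (r² < 0.6 *and*
D′ < 0.6), on different haplotype blocks, with the hQTL inside an
H3K27ac loop anchor whose loop component connects to the target gene, and
with all nine dosage combinations observed (guarding the interaction term
against empty cells). Loops are pre-filtered to ≥ 4 paired-end tags and
anchor-midpoint span within [5 kb, 2 Mb]. The interaction coefficient is
tested by a two-tailed Wald z (dispersion fixed at its profile-ML value,
as in `glm.nb` output), with BH FDR across fitted pairs. CPM expression
is de-normalised to expected counts via stored library sizes and rounded
to the nearest integer before fitting — the NB response must be counts,
and rounding expected counts is the least-assumption discretisation.

**Chromatin networks and topology.** Overlapping loop anchors are merged
into nodes; loops are edges; connected components of this graph are the
chromatin networks, and a gene's network is any component overlapping its
target range (10 kb upstream of the TSS, strand-aware, through the TES).
Topology labels are evaluated in fixed precedence, first match wins:

1. *Anchored* — some anchor contains both SNPs;
2. *Unanchored* — the hQTL is in no anchor;
3. *Looped* — a loop joins an anchor holding the hQTL to an anchor
   holding the eQTL;
4. *Off-target* — no loop containing the hQTL reaches the target range;
5. *Joint* — some loop connects an anchor overlapping the hQTL's
   haplotype block to one overlapping the eQTL's block;
6. *Disjoint* — otherwise.

The precedence order resolves the inherent overlap of these definitions
(a literal reading makes several labels swallow the rest); this ordering
makes all six reachable and is asserted against a brute-force truth-table
oracle on 1,000 random configurations. The scan's eligibility filter
already requires an anchored hQTL, so *Unanchored* can only arise when
the classifier is applied to broader candidate sets — the classifier is
deliberately total over the six labels. Quadrants classify converged fits
by `sign(eQTL main effect) × sign(interaction)`: (+,−)
enhancing-opposed, (−,+) repressive-opposed, (+,+) enhancing-concordant,
(−,−) repressive-concordant; an exactly zero coefficient yields the tie
label `boundary`, excluded from quadrant counts.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure each stage consumes,
at the scale of the motivating study design (25 samples for the
histone-mark arm, 358 for the expression arm):

* **LD** by finite haplotype pools per block — each sample draws two
  haplotypes independently from the block pool, so within-block D′/r² are
  set exactly by pool composition and blocks are independent. There is no
  recombination or coalescent model; "LD decay" within a block does not
  exist unless encoded in the pool.
* **Allele-specific counts** from the CHT generative model itself:
  zero-truncated Poisson allele-specific depth (depth is a nuisance; the
  test conditions on it), beta-binomial allele split, NB region totals
  whose mean scales with genotype. Defaults: ρ = 0.05, φ = 20, AS depth
  30, region depth 200 — moderate overdispersion and the read depths the
  calibration checks are run at. Totals are floored at `ref + alt`
  (allele-specific reads are a subset of the region), a truncation the
  model ignores; it is negligible at the default depth ratio.
* **Expression** as NB counts with log-linear dosage effects
  `μ0 + β_e d_e + β_h d_h + γ d_e d_h`, library sizes log-normal around
  30 million reads (CPM and counts inter-convert exactly via the stored
  library sizes), and optional sample-level log-normal confounding.
* **Loops** placed exactly as laid out (e.g. hQTL anchors connected to
  promoters); **catalogs** built by selecting blocks at a background rate
  inflated by a requested fold for hQTL-bearing blocks, so enrichment is
  controlled in expectation; **peak sets** as jittered, dropout-thinned
  copies of true peaks.

Because the generator implements the same parametric families the tests
assume, passing calibration and recovery checks demonstrates correctness
of the inference machinery, not robustness to real-data violations
(unmodelled GC structure, mapping bias, PEER-type latent factors,
read-level correlations, population structure). The no-op GC hook and
the absence of haplotype-probability calibration are the two places a
real-data analysis would need additional input.

## Problem sizes in the checks

The statistical acceptance checks run at: 2,000 independent null regions
(calibration), 200 replicates per effect-size grid point, 200 fold-1 and
100 fold-2 enrichment runs at 200 permutations over a 10,000-variant
pool, 200 null and 100 powered D² scans at n = 358, and 1,000 + 200
interaction fits. `scripts/acceptance.py` uses the same generators at
1,000 regions / 100 replicates per quantity. These sizes put Monte-Carlo
error comfortably inside each check's tolerance band.
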