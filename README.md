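# hqtlnet

Histone-QTL mapping and joint expression modelling in chromatin-loop
networks.

Genetic variants can leave allele-specific "footprints" on the epigenome:
at a heterozygous site inside an enhancer, ChIP-seq reads for a histone
mark such as H3K27ac or H3K4me1 may systematically favour one parental
allele. Variants inducing such imbalance are **histone QTLs (hQTLs)**.
`hqtlnet` implements a complete, tested analysis chain for mapping hQTLs
in a population of lymphoblastoid cell lines and relating them to disease
risk haplotypes and gene expression:

1. **Consensus enhancer peaks** — per-base majority vote over
   per-individual reproducible peak calls (support ≥ 13 of 25 by default),
   with candidate regions closer than 147 bp merged.
2. **Combined haplotype test (CHT)** — a joint likelihood-ratio test per
   SNP region combining a beta-binomial model of reference-allele read
   counts in heterozygotes, `ref_as ~ BetaBin(n_as, π, ρ)` with
   `π = α/(α+β)`, and a negative-binomial model of genotype-dependent
   total read depth, `total ~ NB(s·m·(g_ref·α + g_alt·β)/2, φ)`. With the
   normalisation `α + β = 2`, the allelic ratio `α/β` is the single
   effect parameter (effect size `ES = α/β`, reported as `log2(ES)`);
   `α = β = 1` is the null. Dispersions (ρ, φ) are learned once across
   testable regions (≥ 15 allele-specific reads) and held fixed.
   Significance is Holm-adjusted with tiers at FWER ≤ 0.1 (significant)
   and ≤ 0.2 (suggestive).
3. **Risk-haplotype enrichment** — hQTLs are binned into 10 × 10
   MAF-decile × TSS-distance-decile categories; null variant sets matched
   on those categories are resampled from the consensus-peak pool
   (1000 permutations by default), and enrichment of hQTLs on
   catalog risk haplotypes (PLINK LD blocks around index SNPs) is scored
   by a one-sided Fisher test and a permutation p-value.
4. **Cis-eQTL mapping** — rank-based inverse-normal expression regressed
   on dosage within 1 Mb, with MAF ≥ 0.05 and CV ≥ 0.15 filters, BH FDR,
   and greedy LD proxy pruning at r² < 0.8.
5. **Joint-effect models** — negative-binomial GLMs (log link, profile-ML
   dispersion, as in `glm.nb`) quantifying deviance explained,
   `D² = (null deviance − residual deviance)/null deviance`:
   a *local* analysis asking whether the hQTL on an eQTL's haplotype
   block explains expression variance beyond any other block variant
   (null: substitute the hQTL with each non-QTL variant; up to 10,000
   permutations), and a *distal* eQTL × hQTL interaction scan
   (`counts ~ 1 + d_e + d_h + d_e·d_h`, two-tailed z-test of the
   interaction, BH FDR) restricted to LD-independent pairs
   (r² < 0.6, D′ < 0.6) whose hQTL sits in an H3K27ac loop anchor inside
   the target gene's chromatin network. Significant interactions are
   classified by loop topology (Anchored / Unanchored / Looped /
   Off-target / Joint / Disjoint) and by coefficient-sign quadrant.
6. **Synthetic data** — every input the chain consumes (phased VCF,
   per-individual peak BEDs, allele-specific count tables, CPM expression,
   HiChIP BEDPE loops, risk catalogs, haplotype blocks) can be generated
   with controlled LD, effect sizes, overdispersion and enrichment, so the
   whole pipeline is testable without any download.

The package is aimed at statistical geneticists and epigenomics analysts
who want a transparent, seedable re-implementation of this analysis chain
for methods work, power studies, and validation on their own data.

## Worked example

Plant one strong hQTL (log2 effect size 1.5) among 59 null enhancer
regions for 25 individuals and scan:

```python
import numpy as np
from hqtlnet import simulate as sim
from hqtlnet.cht import scan

rng = np.random.default_rng(0)
blocks = sim.default_blocks(60, 1, rng, block_gap=500)
gt, _ = sim.simulate_genotypes(sim.SimSpec(n_samples=25, blocks=blocks, seed=1))
snps = list(gt.variants.index)

specs = [sim.HqtlSpec(s, 1.5 if s == "b0v0" else 0.0,
                      as_overdispersion=0.05, depth_dispersion=20.0,
                      mean_as_depth=50.0) for s in snps]
rc = sim.simulate_as_counts(gt, specs, seed=2)

results = scan(gt, rc)
top = results.sort_values("p_nominal").head(3)
print(top[["snp_id", "effect_size", "log2_es", "p_nominal",
           "fwer_adjusted", "tier"]].to_string(index=False))
```

prints

```
snp_id  effect_size   log2_es    p_nominal  fwer_adjusted        tier
  b0v0     3.292544  1.719203 8.964983e-31   5.378990e-29 significant
 b53v0     1.357464  0.440914 2.143242e-03   1.264513e-01  suggestive
 b26v0     0.805707 -0.311672 2.003713e-02   1.000000e+00          ns
```

The planted variant is recovered as the only FWER-significant hit with an
estimated `log2(ES)` of 1.72 (true value 1.5; at 12 heterozygotes the
estimate is noisy but unbiased), meaning roughly 3.3× more
reference-allele than alternate-allele histone reads. The next-best
region is a null that reaches only the suggestive tier, and everything
else is flat.

A command-line interface mirrors the library, one subcommand per stage
(`simulate`, `peaks`, `cht`, `enrich`, `eqtl`, `d2`, `interact`), each
reading a YAML config and writing TSV outputs plus a JSON run manifest:

```
hqtlnet simulate --out fixture/ --n-samples 25 --seed 3
hqtlnet cht --vcf fixture/genotypes.vcf --counts fixture/counts.tsv --out cht.tsv
```

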