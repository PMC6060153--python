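"""Combined haplotype test: testability, dispersion learning, fit, scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hqtlnet import simulate as sim
from hqtlnet.cht import (
    ChtResult,
    DispersionParams,
    bb_loglik,
    calibrate,
    estimate_dispersions,
    fit_cht,
    regions_from_counts,
    scan,
)
from hqtlnet.cht import testable as region_testable
from hqtlnet.types import RunConfig, ValidationError


class TestTestable:
    @pytest.mark.parametrize("total_as,n_het,expected", [
        (14, 1, False),   # one read short of the threshold
        (15, 1, True),
        (100, 0, False),  # AS reads without hets flags inconsistent input
    ])
    def test_threshold_and_het_requirement(self, total_as, n_het, expected):
        n = 10
        ref = np.zeros(n, dtype=int)
        ref[:max(n_het, 1)] = total_as
        dosage = np.zeros(n, dtype=int)
        dosage[:n_het] = 1
        assert region_testable(ref, np.zeros(n, dtype=int), dosage, 15) is expected

    def test_replication_threshold(self):
        ref = np.array([10]); alt = np.array([0]); dosage = np.array([1])
        assert region_testable(ref, alt, dosage, min_as_reads=10)
        assert not region_testable(ref, alt, dosage, min_as_reads=15)


def _simulate_regions(n_regions, rho, phi, depth, seed, n=25, log2_es=0.0):
    rng = np.random.default_rng(seed)
    blocks = sim.default_blocks(max(n_regions // 4, 1), 4, rng)
    gt, _ = sim.simulate_genotypes(sim.SimSpec(n_samples=n, blocks=blocks,
                                               seed=seed + 1))
    snps = list(gt.variants.index[:n_regions])
    specs = [sim.HqtlSpec(s, log2_es, rho, phi, depth) for s in snps]
    rc = sim.simulate_as_counts(gt, specs, seed=seed + 2)
    return gt, rc, snps


class TestDispersions:
    def test_binomial_limit(self):
        gt, rc, snps = _simulate_regions(100, rho=0.0, phi=1e5, depth=30, seed=41)
        disp = estimate_dispersions(regions_from_counts(rc, gt, snps))
        assert disp.rho < 0.02
        assert disp.phi > 1e3  # Poisson-simulated totals push phi to the boundary

    def test_recovers_moderate_overdispersion(self):
        gt, rc, snps = _simulate_regions(500, rho=0.10, phi=20.0, depth=30, seed=43)
        disp = estimate_dispersions(regions_from_counts(rc, gt, snps))
        assert 0.07 <= disp.rho <= 0.13
        assert 10 <= disp.phi <= 40

    def test_degenerate_data_rejected(self):
        regions = [{"k": [1], "n": [1], "y": [5, 5], "s": [1.0, 1.0]}]
        with pytest.raises(ValidationError, match="degenerate"):
            estimate_dispersions(regions)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            DispersionParams(rho=1.2, phi=1.0)
        with pytest.raises(ValidationError):
            DispersionParams(rho=0.1, phi=0.0)


class TestFitCht:
    def test_null_data_give_null_mle(self):
        # balanced AS reads and genotype-independent totals: ES = 1, LRT ~ 0
        ref = np.array([20, 20, 0, 0])
        alt = np.array([20, 20, 0, 0])
        total = np.array([100, 100, 100, 100])
        dosage = np.array([1, 1, 0, 2])
        r = fit_cht("s", ref, alt, total, dosage, np.ones(4),
                    DispersionParams(0.0, 1e4))
        assert r.effect_size == pytest.approx(1.0, abs=1e-3)
        assert r.lrt_stat == pytest.approx(0.0, abs=1e-6)

    def test_single_het_binomial_mle(self):
        # one het, ref 30 / alt 10, no depth information: pi = 0.75, ES = 3
        r = fit_cht("s", np.array([30]), np.array([10]), np.array([40]),
                    np.array([1]), np.ones(1), DispersionParams(0.0, 1e4))
        assert r.alpha_hat / (r.alpha_hat + r.beta_hat) == pytest.approx(0.75, abs=1e-3)
        assert r.effect_size == pytest.approx(3.0, rel=1e-2)
        # grid-search verification of the binomial MLE
        grid = np.linspace(0.01, 0.99, 981)
        ll = [bb_loglik(np.array([30.0]), np.array([40.0]), p, 0.0)[0] for p in grid]
        assert grid[int(np.argmax(ll))] == pytest.approx(0.75, abs=0.005)

    def test_all_ref_reads_hit_box_bound(self):
        r = fit_cht("s", np.array([40]), np.array([0]), np.array([40]),
                    np.array([1]), np.ones(1), DispersionParams(0.0, 1e4))
        assert r.at_bound
        assert r.effect_size == pytest.approx(64.0, rel=1e-3)

    def test_lrt_invariant_to_sample_relabeling(self):
        gt, rc, snps = _simulate_regions(4, 0.05, 20.0, 30, seed=47)
        disp = DispersionParams(0.05, 20.0)
        snp = snps[0]
        sub = rc.for_snp(snp, gt.samples)
        args = (sub["ref_as"].to_numpy(), sub["alt_as"].to_numpy(),
                sub["total_region"].to_numpy(), gt.dosage(snp),
                sub["size_factor"].to_numpy())
        r1 = fit_cht(snp, *args, disp)
        perm = np.random.default_rng(0).permutation(len(gt.samples))
        r2 = fit_cht(snp, *[a[perm] for a in args], disp)
        assert r1.lrt_stat == pytest.approx(r2.lrt_stat, abs=1e-5)

    def test_size_factor_scaling_leaves_p_unchanged(self):
        gt, rc, snps = _simulate_regions(4, 0.05, 20.0, 30, seed=53)
        disp = DispersionParams(0.05, 20.0)
        snp = snps[1]
        sub = rc.for_snp(snp, gt.samples)
        base = fit_cht(snp, sub["ref_as"], sub["alt_as"], sub["total_region"],
                       gt.dosage(snp), np.ones(25), disp)
        scaled = fit_cht(snp, sub["ref_as"], sub["alt_as"], sub["total_region"],
                         gt.dosage(snp), np.full(25, 3.7), disp)
        assert base.p_nominal == pytest.approx(scaled.p_nominal, abs=1e-6)

    def test_median_recovery_at_simulated_effect(self):
        # log2 ES = 1 at AS depth 50: median estimate within +-0.2
        estimates = []
        for rep in range(60):
            gt, rc, snps = _simulate_regions(1, 0.05, 20.0, 50,
                                             seed=1000 + rep, log2_es=1.0)
            sub = rc.for_snp(snps[0], gt.samples)
            r = fit_cht(snps[0], sub["ref_as"], sub["alt_as"],
                        sub["total_region"], gt.dosage(snps[0]),
                        sub["size_factor"], DispersionParams(0.05, 20.0))
            estimates.append(r.log2_es)
        assert abs(np.median(estimates) - 1.0) <= 0.2


class TestScan:
    def test_strong_signal_ranks_first_and_tiers_partition(self):
        rng = np.random.default_rng(61)
        blocks = sim.default_blocks(25, 4, rng)
        gt, _ = sim.simulate_genotypes(sim.SimSpec(n_samples=25, blocks=blocks,
                                                   seed=62))
        snps = list(gt.variants.index)
        specs = [sim.HqtlSpec(s, 0.0, 0.05, 20.0, 30.0) for s in snps[1:]]
        specs.append(sim.HqtlSpec(snps[0], 3.0, 0.05, 20.0, 60.0))
        rc = sim.simulate_as_counts(gt, specs, seed=63)
        res = scan(gt, rc, DispersionParams(0.05, 20.0))
        assert res.sort_values("p_nominal").iloc[0]["snp_id"] == snps[0]
        assert set(res["tier"]) <= {"significant", "suggestive", "ns"}
        top = res.loc[res["snp_id"] == snps[0]].iloc[0]
        assert top["tier"] == "significant"

    def test_calibrate_permutation_is_seeded_and_null_uniform(self):
        gt, rc, snps = _simulate_regions(40, 0.05, 20.0, 30, seed=71)
        disp = DispersionParams(0.05, 20.0)
        qq1 = calibrate(gt, rc, disp, n_perm=1, seed=5)
        qq2 = calibrate(gt, rc, disp, n_perm=1, seed=5)
        pd.testing.assert_frame_equal(qq1, qq2)
        ks = stats.kstest(qq1["permuted_p"].dropna(), "uniform")
        assert ks.pvalue > 0.01
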