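"""NB GLM core, D^2 permutation scan, loop filters, topology and quadrants."""

import numpy as np
import pandas as pd
import pytest

from hqtlnet import simulate as sim
from hqtlnet.chromatin import (
    LoopGraph,
    all_nine_combinations,
    classify_quadrant,
    classify_topology,
    d2_scan,
    dosage_d2,
    eligible_blocks,
    eligible_pairs,
    filter_loops,
    fit_nb_glm,
    interaction_scan,
    target_range,
    _interaction_design,
)
from hqtlnet.types import GenomicInterval, GenotypeTable, Loop, RunConfig, ValidationError

from .oracles import nb_irls, topology_truth


@pytest.fixture
def toy_counts():
    # 12-observation fixture with a 3-level covariate
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2], dtype=float)
    y = np.array([12, 9, 15, 11, 21, 25, 18, 30, 45, 38, 52, 41], dtype=float)
    return y, np.column_stack([np.ones(12), x])


class TestNbGlm:
    def test_deviances_match_hand_irls_oracle(self, toy_counts):
        y, X = toy_counts
        fit = fit_nb_glm(y, X)
        coef, resid_dev, null_dev = nb_irls(y, X, fit.alpha)
        np.testing.assert_allclose(fit.params, coef, atol=1e-6)
        assert fit.residual_deviance == pytest.approx(resid_dev, abs=1e-6)
        assert fit.null_deviance == pytest.approx(null_dev, abs=1e-6)

    def test_intercept_only_design_gives_zero_d2(self, toy_counts):
        y, _ = toy_counts
        fit = fit_nb_glm(y, np.ones((12, 1)))
        assert fit.d2 == pytest.approx(0.0, abs=1e-10)

    def test_saturated_design_gives_d2_one(self):
        y = np.array([5.0, 11.0, 23.0, 47.0])
        X = np.eye(4)
        fit = fit_nb_glm(y, X, alpha=0.05)
        assert fit.residual_deviance == pytest.approx(0.0, abs=1e-6)
        assert fit.d2 == pytest.approx(1.0, abs=1e-6)

    def test_rank_deficient_design_rejected(self, toy_counts):
        y, X = toy_counts
        bad = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValidationError, match="rank"):
            fit_nb_glm(y, bad)

    def test_d2_in_unit_interval_and_monotone_in_nested_designs(self):
        rng = np.random.default_rng(1)
        x1 = rng.integers(0, 3, size=80).astype(float)
        x2 = rng.integers(0, 3, size=80).astype(float)
        y = rng.poisson(np.exp(2.0 + 0.3 * x1))
        alpha = 0.1  # fixed dispersion for the nesting property
        d2s = [
            fit_nb_glm(y, np.ones((80, 1)), alpha=alpha).d2,
            fit_nb_glm(y, np.column_stack([np.ones(80), x1]), alpha=alpha).d2,
            fit_nb_glm(y, _interaction_design(x1, x2), alpha=alpha).d2,
        ]
        assert all(0.0 <= d <= 1.0 for d in d2s)
        assert d2s[0] <= d2s[1] + 1e-10
        assert d2s[1] <= d2s[2] + 1e-10


class TestLoopFilters:
    def _loop(self, pets=4, span=100_000):
        a = GenomicInterval("chr1", 10_000, 12_000)
        b = GenomicInterval("chr1", 10_000 + span, 12_000 + span)
        return Loop(a, b, pets)

    @pytest.mark.parametrize("pets,span,kept", [
        (3, 100_000, False),   # one PET short
        (4, 100_000, True),
        (4, 4_000, False),     # below 5 kb minimum span
        (4, 5_000, True),
        (4, 2_000_000, True),
        (4, 2_500_000, False),  # above 2 Mb maximum span
    ])
    def test_pet_and_span_boundaries(self, pets, span, kept):
        kept_loops = filter_loops([self._loop(pets, span)])
        assert (len(kept_loops) == 1) is kept


class TestEligibility:
    def _pair_table(self, de, dh):
        n = len(de)
        variants = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [100, 100_000],
            "ref": ["A", "A"], "alt": ["G", "G"],
        }, index=pd.Index(["e", "h"], name="id"))
        h1 = np.array([[min(d, 1) for d in de], [min(d, 1) for d in dh]], np.int8)
        h2 = np.array([[max(d - 1, 0) for d in de], [max(d - 1, 0) for d in dh]], np.int8)
        return GenotypeTable(variants, [f"s{i}" for i in range(n)], h1, h2)

    def test_nine_genotype_combination_completeness(self):
        full = [(a, b) for a in (0, 1, 2) for b in (0, 1, 2)]
        de = np.array([a for a, _ in full])
        dh = np.array([b for _, b in full])
        assert all_nine_combinations(de, dh)
        assert not all_nine_combinations(de[:-1], dh[:-1])  # (2,2) cell empty

    def test_block_size_and_ld_filters(self):
        rng = np.random.default_rng(2)
        # two haplotypes -> D' = 1 between all block variants
        haps = [tuple([1] * 6), tuple([0] * 6)]
        blocks_spec = [sim.BlockSpec("chr1", 1000, haps, [0.5, 0.5])]
        gt, blocks = sim.simulate_genotypes(
            sim.SimSpec(n_samples=200, blocks=blocks_spec, seed=3))
        expr = sim.simulate_expression(
            gt, [sim.GeneModel("g", eqtl_snp="b0v0", beta_e=0.3)], seed=4)
        counts = expr.counts()
        eqtls = pd.DataFrame({"snp_id": ["b0v0"], "gene_id": ["g"]})
        hqtls = pd.DataFrame({"snp_id": ["b0v3"], "p_nominal": [1e-9]})
        # r^2 = 1 >= 0.6: pair is not eligible
        assert len(eligible_blocks(blocks, eqtls, hqtls, gt, counts)) == 0
        # block below six variants is excluded regardless of LD
        small = blocks.copy()
        small.at["block0", "snps"] = ["b0v0", "b0v1", "b0v2", "b0v3", "b0v4"]
        small.at["block0", "nsnps"] = 5
        assert len(eligible_blocks(small, eqtls, hqtls, gt, counts)) == 0

    def test_eligible_block_selects_leads(self):
        # pool where eqtl and hqtl are in strong D' but low r^2
        haps = [(1, 1, 0, 1, 0, 0), (0, 0, 1, 0, 1, 1),
                (1, 0, 0, 0, 0, 1), (0, 1, 1, 1, 1, 0)]
        blocks_spec = [sim.BlockSpec("chr1", 1000, haps, [0.4, 0.3, 0.2, 0.1])]
        gt, blocks = sim.simulate_genotypes(
            sim.SimSpec(n_samples=358, blocks=blocks_spec, seed=5))
        from hqtlnet.ld import ld_stats
        ld = ld_stats("b0v0", "b0v1", gt)
        expr = sim.simulate_expression(
            gt, [sim.GeneModel("g", eqtl_snp="b0v0", beta_e=0.4)], seed=6)
        eqtls = pd.DataFrame({"snp_id": ["b0v0"], "gene_id": ["g"]})
        hqtls = pd.DataFrame({"snp_id": ["b0v1"], "p_nominal": [1e-8]})
        res = eligible_blocks(blocks, eqtls, hqtls, gt, expr.counts())
        if ld.d_prime >= 0.8 and ld.r2 < 0.6:
            assert len(res) == 1
            assert res.iloc[0]["lead_eqtl"] == "b0v0"
            assert res.iloc[0]["lead_hqtl"] == "b0v1"
        else:
            assert len(res) == 0


@pytest.fixture(scope="module")
def block_world():
    rng = np.random.default_rng(7)
    blocks_spec = sim.default_blocks(1, 8, rng, n_haplotypes=8)
    gt, blocks = sim.simulate_genotypes(
        sim.SimSpec(n_samples=358, blocks=blocks_spec, seed=8))
    return gt, list(blocks.iloc[0]["snps"])


class TestD2Scan:

    def test_duplicate_dosage_column_ties_perm_p(self, block_world):
        gt, snps = block_world
        expr = sim.simulate_expression(
            gt, [sim.GeneModel("g", eqtl_snp=snps[0], beta_e=0.3)], seed=9)
        y = expr.counts().loc["g"].to_numpy(float)
        # make one null variant carry exactly the hQTL's dosages
        gt2 = GenotypeTable(gt.variants.drop(columns="maf"), gt.samples,
                            gt.hap1.copy(), gt.hap2.copy())
        ih = gt2.variants.index.get_loc(snps[3])
        iv = gt2.variants.index.get_loc(snps[5])
        gt2.hap1[iv] = gt2.hap1[ih]
        gt2.hap2[iv] = gt2.hap2[ih]
        res = d2_scan(snps, snps[0], snps[3], y, gt2, n_perm=200, seed=10)
        assert res.perm_p >= 2 / 201

    def test_hqtl_with_real_effect_detected(self, block_world):
        gt, snps = block_world
        expr = sim.simulate_expression(
            gt, [sim.GeneModel("g", eqtl_snp=snps[0], beta_e=0.3,
                               hqtl_snp=snps[3], beta_h=0.5)], seed=11)
        y = expr.counts().loc["g"].to_numpy(float)
        res = d2_scan(snps, snps[0], snps[3], y, gt, n_perm=200, seed=12)
        assert res.perm_p < 0.05
        assert res.ci_low <= res.perm_p <= res.ci_high

    def test_single_snp_block_rejected(self, block_world):
        gt, snps = block_world
        with pytest.raises(ValidationError, match="non-QTL"):
            d2_scan([snps[0], snps[1]], snps[0], snps[1],
                    np.ones(358), gt, n_perm=10, seed=0)


class TestInteractionScan:
    def test_gamma_recovered_and_shuffling_kills_it(self):
        rng = np.random.default_rng(13)
        blocks_spec = sim.default_blocks(2, 2, rng, block_gap=200_000)
        gt, _ = sim.simulate_genotypes(
            sim.SimSpec(n_samples=358, blocks=blocks_spec, seed=14))
        expr = sim.simulate_expression(
            gt, [sim.GeneModel("g", eqtl_snp="b0v0", beta_e=0.4,
                               hqtl_snp="b1v0", beta_h=0.1, gamma=0.5)], seed=15)
        counts = expr.counts()
        pairs = pd.DataFrame({"eqtl_id": ["b0v0"], "hqtl_id": ["b1v0"],
                              "gene_id": ["g"], "eligible": [True],
                              "reason": [""]})
        res = interaction_scan(pairs, counts, gt)
        assert res.iloc[0]["gamma"] == pytest.approx(0.5, abs=0.15)
        assert res.iloc[0]["p_interaction"] < 1e-6
        # permuting expression sample labels destroys the interaction signal
        # (individual permuted p-values can stay modest because the marginal
        # mixture is not a single NB, so compare the median over shuffles)
        perm_ps = []
        for s in range(7):
            perm = np.random.default_rng(16 + s).permutation(gt.n_samples)
            shuffled = counts.copy()
            shuffled.loc["g"] = counts.loc["g"].to_numpy()[perm]
            perm_ps.append(interaction_scan(pairs, shuffled, gt)
                           .iloc[0]["p_interaction"])
        assert np.median(perm_ps) > 1e-3
        assert np.median(perm_ps) > res.iloc[0]["p_interaction"] * 1e3


class TestTopology:
    def _world(self):
        variants = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [1_050, 9_050],
            "ref": ["A", "A"], "alt": ["G", "G"],
        }, index=pd.Index(["h", "e"], name="id"))
        hap = np.array([[0, 1], [0, 1]], np.int8)
        gt = GenotypeTable(variants, ["s0", "s1"], hap, hap.copy())
        genes = pd.DataFrame({"chrom": ["chr1"], "tss": [20_000],
                              "tes": [25_000], "strand": ["+"]},
                             index=pd.Index(["g"], name="gene_id"))
        blocks = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [1_000, 9_000],
            "end": [1_100, 9_100], "nsnps": [1, 1],
            "snps": [["h"], ["e"]],
        }, index=pd.Index(["hb", "eb"], name="block_id"))
        return gt, genes, blocks

    def test_same_anchor_is_anchored(self):
        gt, genes, blocks = self._world()
        loops = [Loop(GenomicInterval("chr1", 1_000, 10_000),
                      GenomicInterval("chr1", 19_000, 21_000), 5)]
        assert classify_topology("h", "e", "g", gt, loops, genes, blocks) == "Anchored"

    def test_no_anchor_is_unanchored(self):
        gt, genes, blocks = self._world()
        loops = [Loop(GenomicInterval("chr1", 5_000, 6_000),
                      GenomicInterval("chr1", 19_000, 21_000), 5)]
        assert classify_topology("h", "e", "g", gt, loops, genes, blocks) == "Unanchored"

    def test_partner_anchor_is_looped(self):
        gt, genes, blocks = self._world()
        loops = [Loop(GenomicInterval("chr1", 1_000, 1_100),
                      GenomicInterval("chr1", 9_000, 9_100), 5)]
        assert classify_topology("h", "e", "g", gt, loops, genes, blocks) == "Looped"

    def test_loop_missing_target_is_off_target(self):
        gt, genes, blocks = self._world()
        loops = [Loop(GenomicInterval("chr1", 1_000, 1_100),
                      GenomicInterval("chr1", 40_000, 41_000), 5)]
        assert classify_topology("h", "e", "g", gt, loops, genes, blocks) == "Off-target"

    def test_block_bridge_is_joint(self):
        gt, genes, blocks = self._world()
        loops = [
            # hQTL's loop reaches the target range
            Loop(GenomicInterval("chr1", 1_000, 1_100),
                 GenomicInterval("chr1", 19_000, 21_000), 5),
            # a second loop bridges the two haplotype blocks
            Loop(GenomicInterval("chr1", 1_000, 1_100),
                 GenomicInterval("chr1", 9_000, 9_100), 5),
        ]
        # the bridge loop makes this Looped first; remove eQTL from anchor
        loops[1] = Loop(GenomicInterval("chr1", 950, 1_020),
                        GenomicInterval("chr1", 9_060, 9_070), 5)
        label = classify_topology("h", "e", "g", gt, loops, genes, blocks)
        assert label == "Joint"

    def test_strand_aware_target_range(self):
        plus = pd.Series({"chrom": "chr1", "tss": 50_000, "tes": 60_000,
                          "strand": "+"})
        minus = pd.Series({"chrom": "chr1", "tss": 60_000, "tes": 50_000,
                           "strand": "-"})
        assert target_range(plus).start == 40_000
        assert target_range(plus).end == 60_000
        assert target_range(minus).start == 50_000
        assert target_range(minus).end == 70_000

    def test_matches_truth_table_on_random_configurations(self):
        gt, genes, blocks = self._world()
        rng = np.random.default_rng(17)
        labels = set()
        for _ in range(1000):
            loops, tuples = [], []
            for _k in range(int(rng.integers(1, 5))):
                s1 = int(rng.integers(0, 40_000))
                w1 = int(rng.integers(100, 3_000))
                s2 = int(rng.integers(0, 40_000))
                w2 = int(rng.integers(100, 3_000))
                a, b = sorted([(s1, s1 + w1), (s2, s2 + w2)])
                if a[1] > b[0]:  # keep anchors disjoint within a loop
                    continue
                loops.append(Loop(GenomicInterval("chr1", *a),
                                  GenomicInterval("chr1", *b), 5))
                tuples.append((a, b))
            if not loops:
                continue
            h_pos = int(rng.integers(0, 42_000))
            e_pos = int(rng.integers(0, 42_000))
            gt.variants.loc["h", "pos"] = h_pos
            gt.variants.loc["e", "pos"] = e_pos
            blocks.loc["hb", ["start", "end"]] = [h_pos - 50, h_pos + 50]
            blocks.loc["eb", ["start", "end"]] = [e_pos - 50, e_pos + 50]
            got = classify_topology("h", "e", "g", gt, loops, genes, blocks)
            want = topology_truth(
                h_pos, e_pos, tuples, (10_000, 25_000),
                (h_pos - 50, h_pos + 50), (e_pos - 50, e_pos + 50))
            assert got == want
            labels.add(got)
        # the random ensemble should exercise most labels
        assert {"Anchored", "Unanchored", "Looped", "Off-target"} <= labels

    def test_missing_gene_annotation_rejected(self):
        gt, genes, blocks = self._world()
        with pytest.raises(ValidationError, match="annotation"):
            classify_topology("h", "e", "nope", gt, [], genes, blocks)


class TestQuadrants:
    @pytest.mark.parametrize("be,ga,label", [
        (0.4, -0.2, "enhancing-opposed"),
        (0.4, 0.2, "enhancing-concordant"),
        (-0.4, 0.2, "repressive-opposed"),
        (-0.4, -0.2, "repressive-concordant"),
        (0.0, 0.2, "boundary"),
    ])
    def test_sign_rule(self, be, ga, label):
        from hqtlnet.chromatin import JointModelFit
        fit = JointModelFit(np.array([1.0, be, 0.1, ga]), np.ones(4),
                            0.1, 1.0, 0.5, 0.5, True)
        assert classify_quadrant(fit) == label

    def test_quadrants_partition_converged_records(self):
        rng = np.random.default_rng(18)
        blocks_spec = sim.default_blocks(2, 2, rng, block_gap=300_000)
        gt, _ = sim.simulate_genotypes(
            sim.SimSpec(n_samples=200, blocks=blocks_spec, seed=19))
        models = [sim.GeneModel(f"g{k}", eqtl_snp="b0v0", beta_e=0.3,
                                hqtl_snp="b1v0", gamma=0.0) for k in range(6)]
        expr = sim.simulate_expression(gt, models, seed=20)
        pairs = pd.DataFrame({
            "eqtl_id": ["b0v0"] * 6, "hqtl_id": ["b1v0"] * 6,
            "gene_id": [f"g{k}" for k in range(6)],
            "eligible": [True] * 6, "reason": [""] * 6,
        })
        res = interaction_scan(pairs, expr.counts(), gt)
        conv = res[res["converged"]]
        assert set(conv["quadrant"]) <= set(
            ["enhancing-opposed", "repressive-opposed",
             "enhancing-concordant", "repressive-concordant", "boundary"])
        assert len(conv) == conv["quadrant"].notna().sum()
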