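"""Synthetic-population generator: structure, determinism, calibration."""
import numpy as np
import pytest

import bayesqtl as bq
from bayesqtl.synth import SimConfig


def _r2(x, y):
    c = np.corrcoef(x, y)[0, 1]
    return c * c


class TestSimulateGenotypes:
    def test_coding_and_no_missing_by_default(self, small_genotypes):
        Z = small_genotypes.genotypes
        assert not np.isnan(Z).any()
        assert set(np.unique(Z)) <= {-1.0, 0.0, 1.0}

    def test_deterministic_under_fixed_seed(self, small_cfg):
        G1 = bq.simulate_genotypes(small_cfg)
        G2 = bq.simulate_genotypes(small_cfg)
        assert np.array_equal(G1.genotypes, G2.genotypes)
        assert G1.marker_map.equals(G2.marker_map)

    def test_map_monotone_within_chromosome(self, small_genotypes):
        for _, sub in small_genotypes.marker_map.groupby("chrom"):
            assert np.all(np.diff(sub["pos_bp"].to_numpy()) > 0)

    def test_missing_rate_matches_request(self):
        cfg = SimConfig(n_animals=200, n_snps=1000, n_chromosomes=2,
                        missing_rate=0.07, seed=3)
        G = bq.simulate_genotypes(cfg)
        assert np.isnan(G.genotypes).mean() == pytest.approx(0.07, abs=0.01)

    def test_block_ld_exceeds_background(self):
        """Adjacent markers inside an LD block are correlated; with block
        length 1 adjacency carries no extra correlation."""
        rng = np.random.default_rng(0)

        def mean_adjacent_r2(cfg):
            Z = bq.simulate_genotypes(cfg).genotypes
            vals = []
            for _ in range(1000):
                j = rng.integers(0, Z.shape[1] - 1)
                if Z[:, j].std() == 0 or Z[:, j + 1].std() == 0:
                    continue
                vals.append(_r2(Z[:, j], Z[:, j + 1]))
            return np.mean(vals)

        def mean_distant_r2(cfg):
            Z = bq.simulate_genotypes(cfg).genotypes
            vals = []
            for _ in range(1000):
                j, k = rng.integers(0, Z.shape[1], size=2)
                if abs(j - k) < 50 or Z[:, j].std() == 0 or Z[:, k].std() == 0:
                    continue
                vals.append(_r2(Z[:, j], Z[:, k]))
            return np.mean(vals)

        blocky = SimConfig(n_animals=500, n_snps=2000, n_chromosomes=2,
                           ld_block_len=20, seed=5)
        nold = SimConfig(n_animals=500, n_snps=2000, n_chromosomes=2,
                         ld_block_len=1, seed=5)
        assert mean_adjacent_r2(blocky) > mean_distant_r2(blocky) + 0.1
        assert abs(mean_adjacent_r2(nold) - mean_distant_r2(nold)) < 0.05

    def test_half_sib_structure_raises_paternal_relatedness(self):
        """Sibs sharing a sire are more genotype-correlated than non-sibs."""
        cfg = SimConfig(n_animals=400, n_snps=1000, n_chromosomes=2,
                        n_sires=10, seed=8)
        Z = bq.simulate_genotypes(cfg).genotypes
        Zc = Z - Z.mean(axis=0)
        sib = np.mean([np.corrcoef(Zc[i], Zc[i + 10])[0, 1] for i in range(100)])
        nonsib = np.mean([np.corrcoef(Zc[i], Zc[i + 11])[0, 1] for i in range(100)])
        assert sib > nonsib

    @pytest.mark.parametrize("bad", [
        dict(n_animals=0), dict(maf_min=0.0), dict(maf_min=0.4, maf_max=0.3),
        dict(maf_max=0.6), dict(missing_rate=1.0), dict(h2=1.5),
        dict(n_qtl=10_001), dict(reliability_min=0.0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(n_snps=10_000, **bad)


class TestSimulateTraits:
    def test_zero_heritability_has_no_genetic_signal(self, small_genotypes, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "h2": 0.0})
        phen, truth = bq.simulate_traits(small_genotypes, cfg)
        assert np.allclose(truth.true_breeding_values, 0.0)
        assert truth.sigma2_u_true == 0.0

    def test_high_heritability_regression_slope_near_one(self):
        cfg = SimConfig(n_animals=2000, n_snps=2000, n_chromosomes=2,
                        h2=0.99, seed=13)
        G = bq.simulate_genotypes(cfg)
        phen, truth = bq.simulate_traits(G, cfg)
        slope = np.polyfit(truth.true_breeding_values, phen.value, 1)[0]
        assert abs(slope - 1.0) < 0.1

    def test_single_qtl_carries_requested_variance(self):
        cfg = SimConfig(n_animals=2000, n_snps=1000, n_chromosomes=1,
                        n_qtl=1, qtl_var_fraction=1.0, h2=0.3, seed=17)
        G = bq.simulate_genotypes(cfg)
        phen, truth = bq.simulate_traits(G, cfg)
        j = truth.qtl_indices[0]
        g = G.genotypes[:, j] * truth.qtl_effects[0]
        assert g.var() / phen.value.var() == pytest.approx(0.3, abs=0.05)

    def test_realized_heritability_tracks_config(self):
        cfg = SimConfig(n_animals=2000, n_snps=2000, n_chromosomes=2,
                        h2=0.35, seed=19)
        G = bq.simulate_genotypes(cfg)
        phen, truth = bq.simulate_traits(G, cfg)
        realized = truth.true_breeding_values.var() / phen.value.var()
        assert realized == pytest.approx(0.35, abs=0.05)

    def test_h2_of_one_rejected(self, small_genotypes, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "h2": 1.0})
        with pytest.raises(ValueError):
            bq.simulate_traits(small_genotypes, cfg)

    def test_station_weights_are_unit(self, small_genotypes, small_cfg):
        phen, _ = bq.simulate_traits(small_genotypes, small_cfg)
        assert np.all(phen.weight == 1.0)


class TestSimulateDebv:
    def test_weight_formula(self):
        assert bq.reliability_weight(np.array([0.5]))[0] == pytest.approx(1.0)
        r = np.linspace(0.05, 0.95, 19)
        w = bq.reliability_weight(r)
        assert np.all(np.diff(w) > 0)  # strictly increasing in reliability

    def test_reliability_bounds_enforced(self):
        with pytest.raises(ValueError):
            bq.reliability_weight(np.array([0.0]))
        with pytest.raises(ValueError):
            bq.reliability_weight(np.array([1.0]))

    def test_near_perfect_reliability_recovers_breeding_values(self, small_cfg,
                                                               small_genotypes):
        _, truth = bq.simulate_traits(small_genotypes, small_cfg)
        r = np.full(small_genotypes.n_animals, 0.9999)
        phen = bq.simulate_debv(truth, small_cfg, reliabilities=r)
        assert np.allclose(phen.value, truth.true_breeding_values, atol=0.2)

    def test_higher_reliability_stratum_correlates_better(self):
        cfg = SimConfig(n_animals=2000, n_snps=500, n_chromosomes=1,
                        h2=0.4, seed=23)
        G = bq.simulate_genotypes(cfg)
        _, truth = bq.simulate_traits(G, cfg)
        r = np.where(np.arange(2000) < 1000, 0.1, 0.9)
        phen = bq.simulate_debv(truth, cfg, reliabilities=r)
        lo = np.corrcoef(phen.value[:1000], truth.true_breeding_values[:1000])[0, 1]
        hi = np.corrcoef(phen.value[1000:], truth.true_breeding_values[1000:])[0, 1]
        assert hi > lo


class TestMilkYieldCombination:
    @pytest.mark.parametrize("m60,m120,expected", [
        (3.0, 6.0, 5.0),
        (4.2, 4.2, 4.2),
        (0.0, 0.0, 0.0),
    ])
    def test_weighted_average(self, m60, m120, expected):
        assert bq.my_combine(m60, m120) == pytest.approx(expected)

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValueError):
            bq.my_combine(-1.0, 5.0)
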