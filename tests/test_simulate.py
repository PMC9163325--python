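import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rhizoqtl as rq
from rhizoqtl.simulate import DEFAULT_RESIDUAL_SD


class TestSimulateF2:
    def test_zero_map_length_gives_no_recombinants(self):
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(1e6,),
                           map_lengths_morgans=(0.0,), n_markers_per_chrom=10,
                           n_f2=50, seed=3)
        with pytest.warns(UserWarning, match="fully linked"):
            geno = rq.simulate_f2(cfg)
        # every individual carries a single genotype across all 10 markers
        assert (geno.genotypes == geno.genotypes[:, [0]]).all()

    def test_single_marker_segregates_1_2_1(self):
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(1e6,),
                           map_lengths_morgans=(1.0,), n_markers_per_chrom=1,
                           n_f2=10_000, seed=5)
        g = rq.simulate_f2(cfg).genotypes[:, 0]
        n = len(g)
        for code, p in zip((0, 1, 2), (0.25, 0.5, 0.25)):
            obs = (g == code).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 3 * se

    def test_chi_square_1_2_1_across_seeds(self):
        """Mendelian goodness of fit: >=99/100 seeds pass at alpha=0.001."""
        passes = 0
        for seed in range(100):
            cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(1e6,),
                               map_lengths_morgans=(1.0,), n_markers_per_chrom=1,
                               n_f2=10_000, seed=seed)
            g = rq.simulate_f2(cfg).genotypes[:, 0]
            obs = np.bincount(g, minlength=3)
            _, p = stats.chisquare(obs, f_exp=np.array([0.25, 0.5, 0.25]) * len(g))
            passes += p > 0.001
        assert passes >= 99

    def test_recombination_follows_haldane(self, flat_marker_map):
        """Two markers 0.1 M apart recombine at c = (1 - e^-0.2)/2 ~ 0.0906."""
        mm = flat_marker_map([1, 10_000_000], [0.0, 0.1])
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(10e6,),
                           map_lengths_morgans=(0.1,), n_markers_per_chrom=2,
                           n_f2=10, seed=9)
        gametes, _ = rq.simulate_gametes(cfg, 20_000, marker_map=mm)
        c = (1 - np.exp(-0.2)) / 2
        obs = (gametes[:, 0] != gametes[:, 1]).mean()
        assert abs(obs - c) < 3 * np.sqrt(c * (1 - c) / 20_000)

    def test_bit_reproducible(self, small_config):
        a = rq.simulate_f2(small_config)
        b = rq.simulate_f2(small_config)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.marker_map, b.marker_map)

    def test_marker_map_sorted_strictly_increasing(self, small_config):
        mm = rq.simulate_f2(small_config).marker_map
        for _, sub in mm.groupby("chrom"):
            assert (np.diff(sub["pos_bp"]) > 0).all()


class TestSimulatePhenotypes:
    def test_pure_noise_variance_matches_residual(self):
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(1e6,),
                           map_lengths_morgans=(0.5,), n_markers_per_chrom=5,
                           n_f2=20_000, heritability_target=0.0,
                           residual_sd=0.5, block_effect_sd=0.0, seed=2)
        ph = rq.simulate_phenotypes(rq.simulate_f2(cfg), cfg)
        log_ratio = np.log(ph["ras_g"] / ph["rt_g"])
        assert np.var(log_ratio) == pytest.approx(0.25, rel=0.05)

    def test_default_residual_when_unconfigured(self):
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(1e6,),
                           map_lengths_morgans=(0.5,), n_markers_per_chrom=5,
                           n_f2=20_000, block_effect_sd=0.0, seed=2)
        ph = rq.simulate_phenotypes(rq.simulate_f2(cfg), cfg)
        log_ratio = np.log(ph["ras_g"] / ph["rt_g"])
        assert np.std(log_ratio) == pytest.approx(DEFAULT_RESIDUAL_SD, rel=0.05)

    def test_ols_recovers_additive_effect(self):
        a = 0.4
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(10e6,),
                           map_lengths_morgans=(0.5,), n_markers_per_chrom=50,
                           n_f2=4000, qtls=[(1, 5_000_000, a, 0.0)],
                           heritability_target=0.5, block_effect_sd=0.0, seed=4)
        geno = rq.simulate_f2(cfg)
        ph = rq.simulate_phenotypes(geno, cfg)
        y = np.log(ph["ras_g"] / ph["rt_g"]).to_numpy()
        pos = geno.marker_map["pos_bp"].to_numpy()
        g = geno.genotypes[:, np.argmin(np.abs(pos - 5_000_000))].astype(float)
        slope, _, _, _, se = stats.linregress(g, y)[:5]
        assert abs(slope - a) < 3 * se

    def test_heritability_one_with_residual_rejected(self):
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(1e6,),
                           map_lengths_morgans=(0.5,), n_markers_per_chrom=5,
                           n_f2=50, qtls=[(1, 5e5, 1.0, 0.0)],
                           heritability_target=1.0, residual_sd=0.2, seed=1)
        with pytest.raises(rq.ConfigError, match="contradicts"):
            rq.simulate_phenotypes(rq.simulate_f2(cfg), cfg)

    def test_heritability_target_without_qtls_rejected(self):
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(1e6,),
                           map_lengths_morgans=(0.5,), n_markers_per_chrom=5,
                           n_f2=50, heritability_target=0.5, seed=1)
        with pytest.raises(rq.ConfigError, match="QTL"):
            rq.simulate_phenotypes(rq.simulate_f2(cfg), cfg)


class TestSimulateBulkReads:
    def _het_genotypes(self, n_ind=50, n_markers=2000):
        mm = pd.DataFrame({"chrom": "chr1",
                           "pos_bp": np.arange(1, n_markers + 1) * 1000,
                           "pos_morgans": np.arange(n_markers) * 1e-4})
        return rq.F2Genotypes(genotypes=np.ones((n_ind, n_markers), dtype=np.int8),
                              marker_map=mm)

    def test_fixed_bulk_yields_fixed_frequency(self):
        mm = pd.DataFrame({"chrom": ["chr1"], "pos_bp": [100], "pos_morgans": [0.0]})
        geno = rq.F2Genotypes(genotypes=np.full((10, 1), 2, dtype=np.int8),
                              marker_map=mm)
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(1e3,),
                           map_lengths_morgans=(0.1,), n_markers_per_chrom=1,
                           n_f2=10, mean_depth=100, depth_dispersion=0.0,
                           missing_rate=0.0, multiallelic_rate=0.0, seed=8)
        vt = rq.simulate_bulk_reads(geno, geno.ids[:5], geno.ids[5:], cfg)
        assert vt.loc[0, "ref_depth_low"] == 0
        assert vt.loc[0, "alt_depth_low"] > 0  # all reads carry the alt allele

    def test_binomial_frequency_noise(self):
        """True frequency 0.5 at depth ~887: sd of f ~ sqrt(0.25/887)."""
        geno = self._het_genotypes()
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(10e6,),
                           map_lengths_morgans=(0.1,), n_markers_per_chrom=2000,
                           n_f2=50, mean_depth=887, depth_dispersion=0.0,
                           missing_rate=0.0, multiallelic_rate=0.0, seed=12)
        vt = rq.simulate_bulk_reads(geno, geno.ids[:25], geno.ids[25:], cfg)
        f = vt["alt_depth_low"] / (vt["alt_depth_low"] + vt["ref_depth_low"])
        assert np.std(f) == pytest.approx(np.sqrt(0.25 / 887), rel=0.15)

    def test_missingness_rate(self):
        geno = self._het_genotypes(n_markers=1000)
        cfg = rq.SimConfig(n_chromosomes=1, chrom_lengths_bp=(10e6,),
                           map_lengths_morgans=(0.1,), n_markers_per_chrom=1000,
                           n_f2=50, mean_depth=100, missing_rate=0.5,
                           multiallelic_rate=0.0, seed=13)
        vt = rq.simulate_bulk_reads(geno, geno.ids[:25], geno.ids[25:], cfg)
        n_miss = int(vt["missing_low"].sum())
        assert abs(n_miss - 500) < 3 * np.sqrt(1000 * 0.25)
        assert (vt.loc[vt["missing_low"], ["ref_depth_low", "alt_depth_low"]] == 0).all().all()

    def test_empty_or_overlapping_bulks_rejected(self, small_config):
        geno = rq.simulate_f2(small_config)
        with pytest.raises(rq.ConfigError):
            rq.simulate_bulk_reads(geno, [], geno.ids[:5], small_config)
        with pytest.raises(rq.ConfigError, match="disjoint"):
            rq.simulate_bulk_reads(geno, geno.ids[:5], geno.ids[4:9], small_config)

    def test_qtl_pushes_bulk_frequencies_apart(self, small_config):
        """High bulk enriched for the high-parent (alternate) allele at the QTL."""
        hits = 0
        for seed in range(10):
            cfg = rq.SimConfig(**{**small_config.__dict__, "seed": seed})
            geno = rq.simulate_f2(cfg)
            ph = rq.simulate_phenotypes(geno, cfg)
            model = rq.fit_block_model(ph)
            low, high = rq.select_bulks(model.table)
            vt = rq.simulate_bulk_reads(geno, low, high, cfg)
            near = (vt["chrom"] == "chr1") & (abs(vt["pos"] - 20e6) < 1e6)
            f_low = (vt.loc[near, "alt_depth_low"]
                     / (vt.loc[near, "alt_depth_low"] + vt.loc[near, "ref_depth_low"])).mean()
            f_high = (vt.loc[near, "alt_depth_high"]
                      / (vt.loc[near, "alt_depth_high"] + vt.loc[near, "ref_depth_high"])).mean()
            hits += (f_high > 0.5) and (f_low < 0.5)
        assert hits >= 9

    def test_reads_bit_reproducible(self, small_config):
        geno = rq.simulate_f2(small_config)
        low, high = geno.ids[:20], geno.ids[20:40]
        a = rq.simulate_bulk_reads(geno, low, high, small_config)
        b = rq.simulate_bulk_reads(geno, low, high, small_config)
        pd.testing.assert_frame_equal(a, b)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_f2": 0},
        {"missing_rate": 1.5},
        {"heritability_target": -0.1},
        {"chrom_lengths_bp": (0.0,), "n_chromosomes": 1, "map_lengths_morgans": (1.0,)},
        {"qtls": [(1, 999e6, 1.0, 0.0)]},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(rq.ConfigError):
            rq.SimConfig(**kwargs)
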