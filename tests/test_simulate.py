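"""Generator contracts: HWE, determinism, ascertainment, partition shares."""

import numpy as np
import pytest

from greml import (
    Architecture,
    ConfigurationError,
    ResourceBudgetError,
    SimConfig,
    compute_grm,
    inject_platform_artifact,
    reml_fit,
    simulate_bivariate,
    simulate_genotypes,
    simulate_liability_phenotype,
    simulate_quantitative,
)
from greml.presets import PRESETS, config_for_preset


class TestSimulateGenotypes:
    def test_hwe_frequencies_at_half(self):
        cfg = SimConfig(n_snps=200, n_cases=2000, n_controls=2000,
                        maf_spectrum=("fixed", 0.5), seed=1)
        G = simulate_genotypes(cfg)
        counts = np.array([(G.calls == k).mean() for k in (0, 1, 2)])
        np.testing.assert_allclose(counts, [0.25, 0.5, 0.25], atol=0.01)

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_snps=300, n_cases=50, n_controls=50, seed=9)
        G1, G2 = simulate_genotypes(cfg), simulate_genotypes(cfg)
        np.testing.assert_array_equal(G1.calls, G2.calls)
        assert G1.snps.equals(G2.snps)

    def test_sample_mafs_within_support(self):
        cfg = SimConfig(n_snps=5000, n_cases=250, n_controls=250,
                        maf_spectrum=("uniform", 0.01, 0.5), seed=2)
        G = simulate_genotypes(cfg)
        maf = G.maf
        assert (maf[np.isfinite(maf)] <= 0.5).all()
        assert (maf[np.isfinite(maf)] >= 0).all()

    def test_chromosome_weights_respected(self):
        w = np.zeros(22)
        w[[0, 9]] = [0.7, 0.3]
        cfg = SimConfig(n_snps=4000, n_cases=10, n_controls=10,
                        chromosome_weights=w, seed=3)
        G = simulate_genotypes(cfg)
        frac_chr1 = (G.snps["chrom"] == 1).mean()
        assert frac_chr1 == pytest.approx(0.7, abs=0.03)
        assert set(G.snps["chrom"]) == {1, 10}

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ConfigurationError, match="support"):
            SimConfig(n_snps=10, n_cases=1, n_controls=1,
                      maf_spectrum=("uniform", 0.0005, 0.5))


class TestLiabilityPhenotype:
    def test_null_architecture_gives_null_heritability(self):
        cfg = SimConfig(n_snps=800, n_cases=100, n_controls=300, seed=4)
        G = simulate_genotypes(cfg)
        arch = Architecture(name="null", h2_liability=0.0, prevalence_K=0.05,
                            partition_shares={"all": 0.0},
                            n_causal_per_partition={"all": 0})
        Gs, ph = simulate_liability_phenotype(G, arch, seed=5)
        assert (ph.genetic_values == 0).all()
        fit = reml_fit([compute_grm(Gs)], ph.status.astype(float))
        assert fit.h2_total < 0.25

    def test_realized_prevalence_matches_threshold(self):
        cfg = SimConfig(n_snps=500, n_cases=40, n_controls=160, seed=6)
        G = simulate_genotypes(cfg)
        Gs, ph = simulate_liability_phenotype(G, PRESETS["TS_GLOBAL"], seed=7,
                                              n_cases=40, n_controls=160)
        assert ph.realized_prevalence == pytest.approx(0.008, abs=0.0025)
        assert ph.case_fraction == 40 / 200  # exact by construction

    def test_liability_variance_near_one(self):
        cfg = SimConfig(n_snps=600, n_cases=5000, n_controls=5000, seed=8)
        G = simulate_genotypes(cfg)
        arch = Architecture(name="h5", h2_liability=0.5, prevalence_K=0.1,
                            n_causal_per_partition={"all": 300})
        y, _ = simulate_quantitative(G, arch, seed=9)
        assert np.var(y) == pytest.approx(1.0, abs=0.02)

    def test_rare_partition_share_self_check(self):
        # TS MAF preset: rare tranche should carry ~21% of genetic variance
        cfg = config_for_preset("TS_MAF", n_total=4000, n_snps=4000, seed=10)
        G = simulate_genotypes(cfg)
        y, parts = simulate_quantitative(G, PRESETS["TS_MAF"], seed=11)
        var_parts = {k: np.var(v) for k, v in parts.items()}
        total = sum(var_parts.values())
        rare_share = var_parts["maf_0.001_0.05"] / total
        assert rare_share == pytest.approx(0.21, abs=0.03)

    def test_reproducible_and_budget_error(self):
        cfg = SimConfig(n_snps=200, n_cases=30, n_controls=70, seed=12)
        G = simulate_genotypes(cfg)
        a = simulate_liability_phenotype(G, PRESETS["OCD_GLOBAL"], seed=13)
        b = simulate_liability_phenotype(G, PRESETS["OCD_GLOBAL"], seed=13)
        np.testing.assert_array_equal(a[0].calls, b[0].calls)
        np.testing.assert_array_equal(a[1].status, b[1].status)
        with pytest.raises(ResourceBudgetError, match="population"):
            simulate_liability_phenotype(G, PRESETS["TS_GLOBAL"], seed=14,
                                         n_cases=500, n_controls=100,
                                         chunk_size=100, max_chunks=2)


class TestBivariateGenerator:
    def _panels(self, seed, n=150, m=600):
        c1 = SimConfig(n_snps=m, n_cases=30, n_controls=n - 30, seed=seed)
        c2 = SimConfig(n_snps=m, n_cases=30, n_controls=n - 30, seed=seed)
        G1 = simulate_genotypes(c1)
        G2 = simulate_genotypes(c2)
        G2.samples["fid"] = "B" + G2.samples["fid"]
        G2.samples["iid"] = "B" + G2.samples["iid"]
        return G1, G2

    def test_perfect_correlation_degenerate(self):
        G1, G2 = self._panels(20)
        arch = Architecture(name="rg1", h2_liability=0.5, prevalence_K=0.05,
                            rg=1.0, n_causal_per_partition={"all": 200})
        (Ga, pa), (Gb, pb) = simulate_bivariate(G1, G2, arch, seed=21)
        b1 = pa.truth["beta"].to_numpy()
        b2 = pb.truth["beta"].to_numpy()
        assert np.corrcoef(b1, b2)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_preset_effect_correlation(self):
        G1, G2 = self._panels(22)
        (Ga, pa), (Gb, pb) = simulate_bivariate(G1, G2, PRESETS["TSOCD_BIVAR"], seed=23)
        r = np.corrcoef(pa.truth["beta"], pb.truth["beta"])[0, 1]
        # 500 causal pairs: se ~ (1 - r^2)/sqrt(n) ~ 0.037
        assert r == pytest.approx(0.41, abs=0.12)
        assert pa.case_fraction == pytest.approx(30 / 150)
        assert not (set(Ga.sample_ids) & set(Gb.sample_ids))

    def test_overlapping_samples_rejected(self):
        G1, _ = self._panels(24)
        with pytest.raises(ConfigurationError, match="overlap"):
            simulate_bivariate(G1, G1, PRESETS["TSOCD_BIVAR"], seed=25)


def test_architecture_yaml_round_trip(tmp_path):
    arch = PRESETS["TS_MAF"]
    arch.to_yaml(tmp_path / "a.yaml")
    back = Architecture.from_yaml(tmp_path / "a.yaml")
    assert back.partition_shares == arch.partition_shares
    assert back.h2_liability == arch.h2_liability
    assert back.prevalence_K == arch.prevalence_K


class TestPlatformArtifact:
    def test_zero_fraction_is_identity(self, small_panel):
        labels = np.repeat(["a", "b"], small_panel.n_samples // 2)
        out = inject_platform_artifact(small_panel, labels, 0.0, 0.2, seed=30)
        np.testing.assert_array_equal(out.calls, small_panel.calls)

    def test_shifted_group_frequencies_move(self, small_panel):
        labels = np.repeat(["a", "b"], small_panel.n_samples // 2)
        out = inject_platform_artifact(small_panel, labels, 0.3, 0.25, seed=31)
        aff = out.annotations["platform_affected"]
        assert aff.sum() == round(0.3 * small_panel.n_snps)
        grp2 = labels == "b"
        d_aff = (out.calls[grp2][:, aff].mean() - small_panel.calls[grp2][:, aff].mean()) / 2
        assert d_aff == pytest.approx(0.25, abs=0.04)
        # unaffected SNPs and the other platform group untouched
        np.testing.assert_array_equal(out.calls[~grp2], small_panel.calls[~grp2])
        np.testing.assert_array_equal(out.calls[:, ~aff], small_panel.calls[:, ~aff])

    def test_clamping_warns(self, small_panel):
        labels = np.repeat(["a", "b"], small_panel.n_samples // 2)
        with pytest.warns(UserWarning, match="clamped"):
            inject_platform_artifact(small_panel, labels, 0.5, 0.95, seed=32)
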