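"""Partitioned heritability: bin construction, joint fits, chromosome tables."""

import numpy as np
import pytest

from greml import (
    Architecture,
    SimConfig,
    chromosome_length_correlation,
    compute_grm,
    expected_chromosome_h2,
    make_annotation_spec,
    make_maf_bins,
    partitioned_reml,
    per_chromosome_analysis,
    reml_fit,
    simulate_genotypes,
    simulate_quantitative,
)
from greml.simulate import MAF_BIN_EDGES

from conftest import make_genotype_matrix


def _calls_with_maf(mafs, n=200, seed=0):
    rng = np.random.default_rng(seed)
    cols = []
    for p in mafs:
        k = int(round(p * 2 * n))
        col = np.zeros(2 * n, dtype=np.int8)
        col[:k] = 1
        rng.shuffle(col)
        cols.append(col[:n] + col[n:])
    return np.column_stack(cols)


class TestMakeMafBins:
    def test_interval_lookup_with_standard_edges(self):
        G = make_genotype_matrix(_calls_with_maf([0.01, 0.07, 0.45]))
        spec = make_maf_bins(G)
        assert spec.labels[0] == "maf_0.001_0.05"
        occupancy = [int(np.flatnonzero(m)[0]) if m.any() else None for m in spec.masks]
        assert occupancy == [0, 1, None, None, None, 2]

    def test_exact_edge_goes_to_lower_bin(self):
        G = make_genotype_matrix(_calls_with_maf([0.05]))
        spec = make_maf_bins(G)
        assert spec.masks[0][0] and not spec.masks[1][0]

    def test_below_first_edge_excluded(self):
        G = make_genotype_matrix(np.zeros((50, 2), dtype=np.int8))
        with pytest.warns(UserWarning):
            spec = make_maf_bins(G)
        assert spec.excluded.all()

    def test_occupancy_tracks_edge_widths(self):
        cfg = SimConfig(n_snps=6000, n_cases=400, n_controls=400,
                        maf_spectrum=("uniform", 0.05, 0.5), seed=50)
        G = simulate_genotypes(cfg)
        spec = make_maf_bins(G)
        occ = spec.snp_counts / G.n_snps
        widths = np.diff(MAF_BIN_EDGES)
        exp = np.array([0] + list(widths[1:] / widths[1:].sum()))
        np.testing.assert_allclose(occ, exp, atol=0.05)

    def test_bad_edges_rejected(self, small_panel):
        with pytest.raises(ValueError, match="increasing"):
            make_maf_bins(small_panel, edges=(0.1, 0.05))


@pytest.fixture(scope="module")
def genic_sim():
    cfg = SimConfig(n_snps=1800, n_cases=300, n_controls=300,
                    annotation_probs={"genic": 0.5}, seed=51)
    G = simulate_genotypes(cfg)
    arch = Architecture(
        name="genic1", h2_liability=0.5, prevalence_K=0.1,
        partition_shares={"genic": 1.0, "intergenic": 0.0},
        n_causal_per_partition={"genic": 200, "intergenic": 0},
    )
    y, _ = simulate_quantitative(G, arch, seed=52)
    return G, y


class TestPartitionedReml:
    def test_all_variance_in_one_partition(self, genic_sim):
        G, y = genic_sim
        spec = make_annotation_spec(G, "genic", complement_label="intergenic")
        res = partitioned_reml(G, spec, y)
        assert res.share("genic") > 0.8
        assert res.share("intergenic") < 0.2
        assert res.table["share_of_total"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_partition_equals_univariate(self, genic_sim):
        G, y = genic_sim
        from greml.partition import PartitionSpec

        spec = PartitionSpec(kind="annotation", labels=["all"],
                             masks=[np.ones(G.n_snps, bool)])
        res = partitioned_reml(G, spec, y)
        fit = reml_fit([compute_grm(G)], y)
        assert res.fit.loglik == pytest.approx(fit.loglik, abs=1e-6)
        assert res.fit.h2_total == pytest.approx(fit.h2_total, abs=1e-6)

    def test_share_invariant_to_phenotype_rescaling(self, genic_sim):
        G, y = genic_sim
        spec = make_annotation_spec(G, "genic")
        a = partitioned_reml(G, spec, y)
        b = partitioned_reml(G, spec, 2.5 * y)
        assert a.share("genic") == pytest.approx(b.share("genic"), abs=1e-4)


@pytest.fixture(scope="module")
def chrom_sim():
    w = np.zeros(22)
    w[:4] = 0.25
    cfg = SimConfig(n_snps=1600, n_cases=250, n_controls=250,
                    chromosome_weights=w, seed=53)
    G = simulate_genotypes(cfg)
    return G


class TestPerChromosome:
    def test_causal_confined_to_one_chromosome(self, chrom_sim):
        G = chrom_sim
        rng = np.random.default_rng(54)
        mask = (G.snps["chrom"] == 2).to_numpy()
        p = G.meta["true_maf"]
        Z = (G.calls - 2 * p) / np.sqrt(2 * p * (1 - p))
        idx = np.flatnonzero(mask)[:150]
        b = rng.standard_normal(150)
        b *= np.sqrt(0.5) / np.linalg.norm(b)
        y = Z[:, idx] @ b + rng.normal(0, np.sqrt(0.5), G.n_samples)
        with pytest.warns(UserWarning, match="absent"):
            tab = per_chromosome_analysis(G, y, mode="separate")
        est = tab.set_index("chrom")["h2_obs"]
        assert est[2] > 0.25
        assert est[2] > 2.5 * max(est[c] for c in (1, 3, 4))

    def test_sum_matches_univariate_consistency(self, chrom_sim):
        G = chrom_sim
        arch = Architecture(name="u", h2_liability=0.5, prevalence_K=0.1,
                            n_causal_per_partition={"all": 300})
        y, _ = simulate_quantitative(G, arch, seed=55)
        with pytest.warns(UserWarning, match="absent"):
            tab = per_chromosome_analysis(G, y, mode="separate")
        total = tab.loc[tab["chrom"] == 0, "h2_obs"].iloc[0]
        uni = reml_fit([compute_grm(G)], y).h2_total
        assert total == pytest.approx(uni, abs=0.18)  # within MC error at this size

    def test_single_chromosome_panel_equals_univariate(self):
        w = np.zeros(22)
        w[0] = 1.0
        cfg = SimConfig(n_snps=500, n_cases=100, n_controls=100,
                        chromosome_weights=w, seed=56)
        G = simulate_genotypes(cfg)
        rng = np.random.default_rng(57)
        y = rng.standard_normal(G.n_samples)
        with pytest.warns(UserWarning, match="absent"):
            tab = per_chromosome_analysis(G, y, mode="separate")
        assert len(tab) == 2  # chr1 + total row
        uni = reml_fit([compute_grm(G)], y)
        assert tab.loc[0, "h2_obs"] == pytest.approx(uni.h2_total, abs=1e-6)


class TestExpectedH2:
    def test_proportionality(self):
        df = expected_chromosome_h2(0.58, [100, 900])
        assert df["expected_h2"].iloc[0] == pytest.approx(0.058)

    def test_equal_weights_uniform(self):
        df = expected_chromosome_h2(0.44, np.ones(22))
        np.testing.assert_allclose(df["expected_h2"], 0.02)

    def test_flagging_uses_observed_se(self):
        df = expected_chromosome_h2(
            0.5, [1, 1], observed=np.array([0.25, 0.6]),
            se_observed=np.array([0.05, 0.05]),
        )
        assert not df["flagged"].iloc[0] and df["flagged"].iloc[1]

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            expected_chromosome_h2(0.5, [0, 0])


class TestLengthCorrelation:
    def test_proportional_gives_r_one(self):
        lens = np.arange(1, 23, dtype=float)
        r, _ = chromosome_length_correlation(0.01 * lens, lens)
        assert r == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        r, p = chromosome_length_correlation([1, 3, 2, 4], [1, 2, 3, 4])
        assert r == pytest.approx(0.8)

    def test_leave_one_out(self):
        obs = [1.0, 3.0, 2.0, 4.0, 50.0]
        lens = [1.0, 2.0, 3.0, 4.0, 5.0]
        r_full, _ = chromosome_length_correlation(obs, lens)
        r_loo, _ = chromosome_length_correlation(obs, lens, leave_out=5)
        assert r_loo == pytest.approx(0.8)
        assert r_full != pytest.approx(0.8)

    def test_null_centered_on_zero(self, rng):
        rs = []
        lens = np.arange(1, 23, dtype=float)
        for _ in range(200):
            r, _ = chromosome_length_correlation(rng.standard_normal(22), lens)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05
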