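"""QC filter battery: exact tests against enumeration oracles, pruning, scans."""

import numpy as np
import pytest
from scipy.special import comb

from greml import (
    QCThresholds,
    differential_missingness_test,
    hwe_exact_test,
    inject_platform_artifact,
    platform_association_scan,
    prune_related,
    run_qc,
    sample_call_rate_filter,
)
from greml.grm import GRM

from conftest import make_genotype_matrix


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact HWE p: enumerate heterozygote counts at fixed allele counts."""
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    n_common = 2 * n - n_rare
    probs = {}
    for het in range(n_rare % 2, min(n_rare, n_common) + 1, 2):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        # multinomial count of genotype configurations / ways to pair alleles
        probs[het] = (
            comb(n, hom_r, exact=True)
            * comb(n - hom_r, het, exact=True)
            * 2**het
            / comb(2 * n, n_rare, exact=True)
        )
    tot = sum(probs.values())
    p_obs = probs[n_Aa] / tot
    return sum(v / tot for v in probs.values() if v / tot <= p_obs * (1 + 1e-12))


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    from scipy.stats import hypergeom

    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestHWE:
    @pytest.mark.parametrize(
        "counts,expected",
        [((50, 0, 0), 1.0), ((25, 50, 25), 1.0)],
    )
    def test_degenerate_and_modal_tables(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts",
        [(0, 100, 0), (10, 20, 5), (3, 1, 3), (0, 5, 45), (12, 0, 12), (1, 2, 1)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 1)


class TestDifferentialMissingness:
    @pytest.mark.parametrize("args", [(5, 100, 5, 100), (0, 100, 0, 100)])
    def test_identical_rows_give_p_one(self, args):
        assert differential_missingness_test(*args) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "mc,tc,mk,tk", [(20, 100, 2, 100), (7, 30, 1, 50), (0, 10, 5, 10)]
    )
    def test_matches_hypergeometric_enumeration(self, mc, tc, mk, tk):
        oracle = fisher_enumeration_oracle(mc, tc - mc, mk, tk - mk)
        assert differential_missingness_test(mc, tc, mk, tk) == pytest.approx(
            oracle, rel=1e-6
        )

    def test_empty_margin_flagged(self):
        with pytest.warns(UserWarning, match="empty margin"):
            assert differential_missingness_test(0, 0, 1, 10) == 1.0


class TestSampleCallRate:
    def test_no_missingness_keeps_all(self, rng):
        G = make_genotype_matrix(rng.integers(0, 3, size=(20, 50)))
        assert sample_call_rate_filter(G, 0.999).all()

    def test_mixed_fixture_matches_counting(self, rng):
        calls = rng.integers(0, 3, size=(30, 1000)).astype(np.int8)
        n_miss = rng.integers(0, 40, size=30)
        for i, k in enumerate(n_miss):
            calls[i, rng.choice(1000, k, replace=False)] = -1
        G = make_genotype_matrix(calls)
        kept = sample_call_rate_filter(G, 0.999)
        np.testing.assert_array_equal(kept, (1000 - n_miss) / 1000 >= 0.999)


def _grm_from(A, prio_n=None):
    n = A.shape[0]
    ids = [(f"F{i}", f"I{i}") for i in range(n)]
    return GRM(ids=ids, A=np.asarray(A, float), pair_counts=np.full((n, n), 100.0))


class TestPruneRelated:
    def test_duplicate_pair_loses_one(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.98
        kept = prune_related(_grm_from(A), 0.05)
        assert len(kept) == 2 and (("F2", "I2") in kept)
        assert (("F0", "I0") in kept) != (("F1", "I1") in kept)

    def test_unrelated_sample_untouched(self):
        A = np.eye(4) + 0.01
        assert len(prune_related(_grm_from(A), 0.05)) == 4

    def test_chain_removes_middle_only(self):
        # A-B and B-C related: greedy degree rule removes B (the brute-force minimum)
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.3
        A[1, 2] = A[2, 1] = 0.3
        kept = prune_related(_grm_from(A), 0.05)
        assert kept == [("F0", "I0"), ("F2", "I2")]

    def test_priority_keeps_cases(self):
        A = np.eye(2)
        A[0, 1] = A[1, 0] = 0.5
        kept = prune_related(_grm_from(A), 0.05, priority=[0, 1])  # sample 1 is a case
        assert kept == [("F1", "I1")]

    def test_kept_set_below_threshold(self, rng):
        A = np.eye(12)
        for _ in range(8):
            i, j = rng.choice(12, 2, replace=False)
            A[i, j] = A[j, i] = rng.uniform(0.06, 0.9)
        kept = prune_related(_grm_from(A), 0.05)
        idx = [int(f[1:]) for f, _ in kept]
        off = A[np.ix_(idx, idx)].copy()
        np.fill_diagonal(off, 0)
        assert off.max() <= 0.05


class TestPlatformScan:
    def test_null_calibration_and_degenerate(self, rng):
        n, m = 260, 900
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, size=m), size=(n, m)).astype(np.int8)
        calls[:, 0] = 1  # constant SNP -> degenerate, p = 1
        G = make_genotype_matrix(calls)
        labels = np.repeat(["chipA", "chipB"], n // 2)
        scan = platform_association_scan(G, labels)
        assert scan.loc[0, "degenerate"] and scan.loc[0, "p"] == 1.0
        p = scan["p"].to_numpy()[1:]
        frac_05 = np.mean(p < 0.05)
        assert 0.02 <= frac_05 <= 0.09  # ~binomial CI around nominal 5%
        assert np.mean(p < 0.001) <= 0.01

    def test_power_on_injected_artifact(self, rng):
        n, m = 600, 120
        maf = rng.uniform(0.2, 0.4, size=m)
        calls = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
        G = make_genotype_matrix(calls, maf_meta=maf)
        labels = np.repeat(["chipA", "chipB"], n // 2)
        Gart = inject_platform_artifact(G, labels, affected_fraction=0.5,
                                        shift=0.2, seed=5)
        scan = platform_association_scan(Gart, labels)
        affected = Gart.annotations["platform_affected"]
        hit = (scan["p"].to_numpy() < 0.001) & affected
        assert hit.sum() / affected.sum() > 0.5  # far above the 0.1% null rate


class TestRunQC:
    def test_idempotent_and_single_reason(self, rng):
        n, m = 160, 300
        maf = rng.uniform(0.05, 0.5, size=m)
        calls = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
        status = (np.arange(n) < 40).astype(int)
        # force differential missingness on SNP 0 and HWE failure on SNP 1
        calls[:30, 0] = -1
        calls[:, 1] = 1
        G = make_genotype_matrix(calls, maf_meta=maf)
        th = QCThresholds(snp_call_rate=0.5)  # let differential missingness fire first
        G1, s1, rep1 = run_qc(G, status, th)
        reasons = rep1.snp_table["dropped_reason"]
        assert reasons.iloc[0] == "diff_missingness"
        assert reasons.iloc[1] == "hwe"
        assert (reasons != "").sum() == rep1.n_snps_in - rep1.n_snps_kept
        G2, s2, rep2 = run_qc(G1, s1, th)
        assert rep2.n_snps_kept == G1.n_snps
        assert rep2.n_samples_kept == G1.n_samples

    def test_thresholds_validate(self):
        with pytest.raises(ValueError):
            QCThresholds(hwe_p=1.5)
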