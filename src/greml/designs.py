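"""Replicate study designs: simulate under a preset, analyse, collect estimates.

Each function runs one of the validation designs end to end — generate an
ascertained case-control dataset under a shipped architecture preset, push
it through the estimation pipeline, and return the per-replicate estimates.
They exist so that the same design is exercised identically by the test
suite, the acceptance script and the examples.

Replicate seeds are spawned from a single base seed, so a design is fully
reproducible and replicates are independent.
"""

from __future__ import annotations

import numpy as np

from .bivariate import bivar_reml_fit
from .genotype_io import GenotypeMatrix
from .partition import make_annotation_spec, make_maf_bins, partitioned_reml
from .pipeline import age_of_onset_split, permutation_null, run_univariate
from .presets import CASE_FRACTIONS, PRESETS, config_for_preset
from .simulate import simulate_bivariate, simulate_genotypes, simulate_liability_phenotype

__all__ = [
    "global_heritability_replicates",
    "bivariate_rg_replicates",
    "maf_rare_share_replicates",
    "genic_share_replicates",
    "permutation_null_mean",
    "early_onset_replicates",
]


def _rep_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def global_heritability_replicates(
    preset: str,
    n_reps: int = 10,
    seed: int = 0,
    n_total: int = 2000,
    n_snps: int = 5000,
    n_pcs: int = 0,
) -> np.ndarray:
    """Liability-scale h2 estimates from replicate univariate case-control studies.

    Each replicate: simulate an ascertained sample under the preset at its
    source cohort's case fraction, fit single-GRM AI-REML (intercept + n_pcs
    PCs), convert to the liability scale at the preset's K and the realized
    sample case fraction.
    """
    arch = PRESETS[preset]
    out = []
    for s in _rep_seeds(seed, n_reps):
        cfg = config_for_preset(preset, n_total=n_total, n_snps=n_snps, seed=s)
        panel = simulate_genotypes(cfg)
        G, ph = simulate_liability_phenotype(panel, arch, seed=s + 1)
        rep = run_univariate(G, ph.status, K=arch.prevalence_K, n_pcs=n_pcs)
        out.append(rep.h2_liab)
    return np.asarray(out)


def bivariate_rg_replicates(
    n_reps: int = 10,
    seed: int = 0,
    n_each: int = 1000,
    n_snps: int = 5000,
    preset: str = "TSOCD_BIVAR",
) -> np.ndarray:
    """Genetic-correlation estimates from replicate disjoint-sample bivariate fits."""
    arch = PRESETS[preset]
    f1 = CASE_FRACTIONS["TS_GLOBAL"]
    f2 = CASE_FRACTIONS["OCD_GLOBAL"]
    out = []
    for s in _rep_seeds(seed, n_reps):
        c1 = config_for_preset(preset, n_total=n_each, n_snps=n_snps,
                               seed=s, case_fraction=f1)
        c2 = config_for_preset(preset, n_total=n_each, n_snps=n_snps,
                               seed=s + 1, case_fraction=f2)
        G1 = simulate_genotypes(c1)
        G2 = simulate_genotypes(c2)
        G2.samples = G2.samples.assign(fid="B" + G2.samples["fid"],
                                       iid="B" + G2.samples["iid"])
        (Ga, pa), (Gb, pb) = simulate_bivariate(G1, G2, arch, seed=s + 2)
        fit = bivar_reml_fit((Ga, Gb), pa.status.astype(float),
                             pb.status.astype(float))
        out.append(fit.rg)
    return np.asarray(out)


def maf_rare_share_replicates(
    preset: str,
    n_reps: int = 10,
    seed: int = 0,
    n_total: int = 1500,
    n_snps: int = 4000,
) -> np.ndarray:
    """Rare-bin (MAF 0.001-0.05) share of genetic variance from six-bin joint REML."""
    arch = PRESETS[preset]
    out = []
    for s in _rep_seeds(seed, n_reps):
        cfg = config_for_preset(preset, n_total=n_total, n_snps=n_snps, seed=s)
        panel = simulate_genotypes(cfg)
        G, ph = simulate_liability_phenotype(panel, arch, seed=s + 1)
        spec = make_maf_bins(G)
        res = partitioned_reml(G, spec, ph.status.astype(float),
                               K=arch.prevalence_K, P=float(ph.status.mean()))
        out.append(res.share("maf_0.001_0.05"))
    return np.asarray(out)


def genic_share_replicates(
    preset: str = "TS_GENIC",
    n_reps: int = 10,
    seed: int = 0,
    n_total: int = 1500,
    n_snps: int = 4000,
) -> np.ndarray:
    """Genic share of genetic variance from a genic/intergenic joint REML."""
    arch = PRESETS[preset]
    out = []
    for s in _rep_seeds(seed, n_reps):
        cfg = config_for_preset(preset, n_total=n_total, n_snps=n_snps, seed=s)
        panel = simulate_genotypes(cfg)
        G, ph = simulate_liability_phenotype(panel, arch, seed=s + 1)
        spec = make_annotation_spec(G, "genic", complement_label="intergenic")
        res = partitioned_reml(G, spec, ph.status.astype(float),
                               K=arch.prevalence_K, P=float(ph.status.mean()))
        out.append(res.share("genic"))
    return np.asarray(out)


def permutation_null_mean(
    preset: str = "TS_GLOBAL",
    n_perm: int = 10,
    seed: int = 0,
    n_total: int = 2000,
    n_snps: int = 5000,
) -> float:
    """Mean liability-scale estimate over phenotype permutations of one dataset."""
    arch = PRESETS[preset]
    s = _rep_seeds(seed, 1)[0]
    cfg = config_for_preset(preset, n_total=n_total, n_snps=n_snps, seed=s)
    panel = simulate_genotypes(cfg)
    G, ph = simulate_liability_phenotype(panel, arch, seed=s + 1)
    df = permutation_null(G, ph.status, K=arch.prevalence_K, n_perm=n_perm,
                          seed=s + 2, n_pcs=0)
    return float(df.loc[df["perm"] == 0, "h2_liab"].iloc[0])


def early_onset_replicates(
    n_reps: int = 10,
    seed: int = 0,
    n_total: int = 2000,
    n_snps: int = 5000,
) -> np.ndarray:
    """Early-onset stratum estimates via the age-of-onset split pipeline.

    All simulated cases carry an early onset age, so the early stratum is the
    full case set analysed through the split machinery.
    """
    arch = PRESETS["OCD_EARLY"]
    out = []
    for s in _rep_seeds(seed, n_reps):
        cfg = config_for_preset("OCD_EARLY", n_total=n_total, n_snps=n_snps, seed=s)
        panel = simulate_genotypes(cfg)
        G, ph = simulate_liability_phenotype(panel, arch, seed=s + 1)
        onset = np.where(ph.status == 1, 10.0, np.nan)
        split = age_of_onset_split(G, ph.status, onset, K=arch.prevalence_K,
                                   cutoff=16, n_pcs=0)
        out.append(split["early"].h2_liab)
    return np.asarray(out)
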