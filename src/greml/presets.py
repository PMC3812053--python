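"""Shipped architecture presets.

Each preset encodes the liability-scale heritability, population prevalence
and variance-partition structure of one analysis arm: Tourette Syndrome (TS)
and obsessive-compulsive disorder (OCD) global heritability, their MAF and
genic partitions, the TS/OCD bivariate design, and the early-onset OCD
stratum.  The MAF tranche labels follow the six standard bin edges
(0.001-0.05, 0.05-0.1, 0.1-0.2, 0.2-0.3, 0.3-0.4, 0.4-0.5].

Sample-size presets mirror the cohorts the architectures were estimated in:
TS 617 cases / 4,116 controls, OCD 1,061 / 4,236, early-onset OCD 732 /
3,985 — exposed as case fractions so a simulation of any total size keeps
the same ascertainment ratio.
"""

from __future__ import annotations

from .simulate import MAF_BIN_EDGES, Architecture, SimConfig

__all__ = ["PRESETS", "CASE_FRACTIONS", "get_preset", "config_for_preset", "maf_bin_label"]


def maf_bin_label(lo: float, hi: float) -> str:
    return f"maf_{lo:g}_{hi:g}"


_MAF_LABELS = [
    maf_bin_label(lo, hi) for lo, hi in zip(MAF_BIN_EDGES[:-1], MAF_BIN_EDGES[1:])
]

# common-bin remainder split equally across the five MAF bins above 0.05
_TS_RARE = 0.21
_OCD_RARE = 0.0


def _maf_shares(rare_share: float) -> dict:
    shares = {_MAF_LABELS[0]: rare_share}
    rest = (1.0 - rare_share) / (len(_MAF_LABELS) - 1)
    shares.update({lab: rest for lab in _MAF_LABELS[1:]})
    return shares


def _maf_causals(rare_n: int, common_n: int) -> dict:
    out = {_MAF_LABELS[0]: rare_n}
    out.update({lab: common_n for lab in _MAF_LABELS[1:]})
    return out


PRESETS: dict[str, Architecture] = {
    "TS_GLOBAL": Architecture(
        name="TS_GLOBAL", h2_liability=0.58, prevalence_K=0.008,
        partition_shares={"all": 1.0}, n_causal_per_partition={"all": 500},
    ),
    "OCD_GLOBAL": Architecture(
        name="OCD_GLOBAL", h2_liability=0.37, prevalence_K=0.025,
        partition_shares={"all": 1.0}, n_causal_per_partition={"all": 500},
    ),
    "TS_MAF": Architecture(
        name="TS_MAF", h2_liability=0.58, prevalence_K=0.008,
        partition_shares=_maf_shares(_TS_RARE),
        n_causal_per_partition=_maf_causals(80, 84),
    ),
    "OCD_MAF": Architecture(
        name="OCD_MAF", h2_liability=0.37, prevalence_K=0.025,
        partition_shares=_maf_shares(_OCD_RARE),
        n_causal_per_partition=_maf_causals(0, 100),
    ),
    "TS_GENIC": Architecture(
        name="TS_GENIC", h2_liability=0.58, prevalence_K=0.008,
        partition_shares={"genic": 0.53, "intergenic": 0.47},
        n_causal_per_partition={"genic": 250, "intergenic": 250},
    ),
    "OCD_GENIC": Architecture(
        name="OCD_GENIC", h2_liability=0.37, prevalence_K=0.025,
        partition_shares={"genic": 0.40, "intergenic": 0.60},
        n_causal_per_partition={"genic": 250, "intergenic": 250},
    ),
    "TSOCD_BIVAR": Architecture(
        name="TSOCD_BIVAR", h2_liability=0.58, prevalence_K=0.008,
        h2_liability_2=0.37, prevalence_K_2=0.025, rg=0.41,
        partition_shares={"all": 1.0}, n_causal_per_partition={"all": 500},
    ),
    "OCD_EARLY": Architecture(
        name="OCD_EARLY", h2_liability=0.43, prevalence_K=0.025,
        partition_shares={"all": 1.0}, n_causal_per_partition={"all": 500},
    ),
}

# case fraction of the cohort each architecture was estimated in
CASE_FRACTIONS: dict[str, float] = {
    "TS_GLOBAL": 617 / 4733,
    "OCD_GLOBAL": 1061 / 5297,
    "TS_MAF": 617 / 4733,
    "OCD_MAF": 1061 / 5297,
    "TS_GENIC": 617 / 4733,
    "OCD_GENIC": 1061 / 5297,
    "TSOCD_BIVAR": 617 / 4733,   # trait 1; trait 2 uses the OCD fraction
    "OCD_EARLY": 732 / 4717,
}


def get_preset(name: str) -> Architecture:
    return PRESETS[name]


def config_for_preset(
    name: str,
    n_total: int = 2000,
    n_snps: int = 5000,
    seed: int = 0,
    case_fraction: float | None = None,
) -> SimConfig:
    """A SimConfig whose case fraction matches the preset's source cohort.

    Genic presets get a 50% genic annotation; the default MAF spectrum
    (5% of SNPs in a 0.005-0.05 rare tranche) already feeds the MAF bins.
    """
    frac = CASE_FRACTIONS[name] if case_fraction is None else case_fraction
    n_cases = int(round(frac * n_total))
    annot = {"genic": 0.5} if "GENIC" in name else {}
    return SimConfig(
        n_snps=n_snps,
        n_cases=n_cases,
        n_controls=n_total - n_cases,
        annotation_probs=annot,
        seed=seed,
    )
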