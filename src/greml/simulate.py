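"""Liability-threshold case-control simulator.

Generates biallelic genotypes in HWE with a configurable MAF spectrum,
polygenic liabilities with partition-specific variance shares, threshold
ascertainment at population prevalence K, bivariate traits on disjoint
samples with a chosen genetic correlation, and injectable platform/batch
genotype artifacts.  All randomness flows through named substreams spawned
from a single seed, so every output is bit-reproducible and phenotypes can
be re-drawn on fixed genotypes.

Causal effects are drawn on the standardised-genotype scale (equal expected
variance per causal SNP within a partition, i.e. the MAF-coupling the GRM
estimator itself assumes) and the per-partition effect vectors are scaled so
each partition contributes exactly ``share_j * h2`` of liability variance;
the residual is N(0, 1 - h2), making the liability variance 1.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotype_io import GenotypeMatrix

__all__ = [
    "Architecture",
    "SimConfig",
    "PhenotypeSet",
    "ConfigurationError",
    "ResourceBudgetError",
    "simulate_genotypes",
    "simulate_liability_phenotype",
    "simulate_quantitative",
    "simulate_bivariate",
    "inject_platform_artifact",
    "partition_masks",
    "draw_effects",
    "MAF_BIN_EDGES",
]

MAF_BIN_EDGES = (0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

# approximate autosome physical lengths (Mb), used as default SNP weights
CHROM_LENGTHS_MB = np.array(
    [247, 243, 199, 191, 181, 171, 159, 146, 140, 135,
     134, 132, 114, 106, 100, 89, 79, 76, 63, 62, 47, 50],
    dtype=float,
)

DEFAULT_MAF_SPECTRUM = ("mixture", [(0.05, 0.005, 0.05), (0.95, 0.05, 0.5)])


class ConfigurationError(ValueError):
    pass


class ResourceBudgetError(RuntimeError):
    pass


@dataclass
class Architecture:
    """Simulation preset: what the genetic architecture of the trait looks like.

    ``partition_shares`` maps partition labels (annotation names, ``maf_LO_HI``
    MAF tranches, ``intergenic``/``not_X`` complements, or ``all``) to their
    share of the total genetic variance.  For bivariate presets ``rg`` and the
    second trait's ``h2_liability_2`` / ``prevalence_K_2`` are set.
    """

    name: str
    h2_liability: float
    prevalence_K: float
    partition_shares: dict = field(default_factory=lambda: {"all": 1.0})
    n_causal_per_partition: dict = field(default_factory=lambda: {"all": 500})
    rg: float | None = None
    h2_liability_2: float | None = None
    prevalence_K_2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_liability <= 1.0:
            raise ConfigurationError("h2_liability must be in [0, 1]")
        if not 0.0 < self.prevalence_K < 1.0:
            raise ConfigurationError("prevalence_K must be in (0, 1)")
        tot = sum(self.partition_shares.values())
        if self.h2_liability > 0 and abs(tot - 1.0) > 1e-12:
            raise ConfigurationError(f"partition shares sum to {tot}, not 1")
        for label, share in self.partition_shares.items():
            if share > 0 and self.n_causal_per_partition.get(label, 0) < 1:
                raise ConfigurationError(
                    f"partition {label!r} has share {share} but no causal SNPs"
                )
        if self.rg is not None and not -1.0 <= self.rg <= 1.0:
            raise ConfigurationError("rg must be in [-1, 1]")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: v for k, v in self.__dict__.items() if v is not None}, fh
            )

    @classmethod
    def from_yaml(cls, path) -> "Architecture":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimConfig:
    """Shape of the simulated genotype panel and the analysed sample."""

    n_snps: int
    n_cases: int
    n_controls: int
    maf_spectrum: tuple = DEFAULT_MAF_SPECTRUM
    chromosome_weights: np.ndarray | None = None
    annotation_probs: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.chromosome_weights is None:
            self.chromosome_weights = CHROM_LENGTHS_MB / CHROM_LENGTHS_MB.sum()
        w = np.asarray(self.chromosome_weights, dtype=float)
        if w.size != 22 or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ConfigurationError("chromosome_weights must be 22 fractions summing to 1")
        self.chromosome_weights = w
        for name, pr in self.annotation_probs.items():
            if not 0.0 <= pr <= 1.0:
                raise ConfigurationError(f"annotation prob {name!r} outside [0, 1]")
        _validate_spectrum(self.maf_spectrum)


def _validate_spectrum(spec) -> None:
    kind = spec[0]
    if kind == "fixed":
        lo = hi = spec[1]
    elif kind == "uniform":
        lo, hi = spec[1], spec[2]
    elif kind == "mixture":
        los, his = zip(*[(c[1], c[2]) for c in spec[1]])
        lo, hi = min(los), max(his)
        if abs(sum(c[0] for c in spec[1]) - 1.0) > 1e-9:
            raise ConfigurationError("mixture weights must sum to 1")
    else:
        raise ConfigurationError(f"unknown MAF spectrum kind {kind!r}")
    if lo < 0.001 or hi > 0.5 or lo > hi:
        raise ConfigurationError("MAF spectrum support must lie within (0.001, 0.5]")


def _draw_maf(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "fixed":
        return np.full(n, float(spec[1]))
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=n)
    weights = np.array([c[0] for c in spec[1]])
    comp = rng.choice(len(weights), size=n, p=weights)
    out = np.empty(n)
    for j, (_, lo, hi) in enumerate(spec[1]):
        sel = comp == j
        out[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
    return out


def _streams(seed: int, *names: str) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw an (n_cases + n_controls) x n_snps HWE genotype panel.

    Each SNP's counted allele is its minor allele with frequency drawn from
    ``config.maf_spectrum``; chromosomes follow ``chromosome_weights`` and
    annotation flags are independent Bernoulli draws.  Deterministic per seed.
    """
    rngs = _streams(config.seed, "panel", "genotypes")
    m = config.n_snps
    n = config.n_cases + config.n_controls
    maf = _draw_maf(config.maf_spectrum, m, rngs["panel"])
    chrom = np.sort(rngs["panel"].choice(np.arange(1, 23), size=m,
                                         p=config.chromosome_weights))
    pos = np.zeros(m, dtype=int)
    for c in range(1, 23):
        k = int((chrom == c).sum())
        pos[chrom == c] = np.arange(1, k + 1) * 5000
    snps = pd.DataFrame(
        {
            "snp": [f"rs{j + 1:06d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "C",
            "cm": 0.0,
        }
    )
    annotations = {
        name: rngs["panel"].random(m) < pr
        for name, pr in config.annotation_probs.items()
    }
    calls = rngs["genotypes"].binomial(2, maf, size=(n, m)).astype(np.int8)
    samples = pd.DataFrame(
        {
            "fid": [f"F{i + 1:05d}" for i in range(n)],
            "iid": [f"I{i + 1:05d}" for i in range(n)],
        }
    )
    return GenotypeMatrix(
        samples=samples,
        snps=snps,
        calls=calls,
        annotations=annotations,
        meta={
            "true_maf": maf,
            "n_cases": config.n_cases,
            "n_controls": config.n_controls,
            "seed": config.seed,
        },
    )


_MAF_LABEL = re.compile(r"^maf_([0-9.]+)_([0-9.]+)$")


def partition_masks(G: GenotypeMatrix, labels) -> dict:
    """Resolve partition labels to boolean SNP masks on the panel.

    Labels may be ``all``, an annotation name, ``not_<annotation>`` (alias
    ``intergenic`` for the genic complement), or ``maf_LO_HI`` for the MAF
    tranche (LO, HI] evaluated on the panel's generating MAF.
    """
    maf = np.asarray(G.meta.get("true_maf", G.maf), dtype=float)
    masks = {}
    for label in labels:
        if label == "all":
            masks[label] = np.ones(G.n_snps, dtype=bool)
        elif label in G.annotations:
            masks[label] = np.asarray(G.annotations[label], dtype=bool)
        elif label == "intergenic" and "genic" in G.annotations:
            masks[label] = ~np.asarray(G.annotations["genic"], dtype=bool)
        elif label.startswith("not_") and label[4:] in G.annotations:
            masks[label] = ~np.asarray(G.annotations[label[4:]], dtype=bool)
        else:
            match = _MAF_LABEL.match(label)
            if match is None:
                raise ConfigurationError(f"partition label {label!r} not found in panel")
            lo, hi = float(match.group(1)), float(match.group(2))
            masks[label] = (maf > lo) & (maf <= hi)
    return masks


def draw_effects(G: GenotypeMatrix, arch: Architecture, rng: np.random.Generator):
    """Pick causal SNPs and standardised-scale effects per partition.

    Returns ``(causal_idx, beta, truth)`` where ``truth`` is a table with one
    row per causal SNP (snp id, partition, effect).  Within each partition the
    effect vector is rescaled so its squared norm equals ``share * h2``.
    """
    masks = partition_masks(G, arch.partition_shares.keys())
    idx_all, beta_all, rows = [], [], []
    for label, share in arch.partition_shares.items():
        var_j = share * arch.h2_liability
        if var_j <= 0:
            continue
        pool = np.flatnonzero(masks[label])
        want = int(arch.n_causal_per_partition[label])
        if pool.size == 0:
            raise ConfigurationError(f"partition {label!r} holds no SNPs in this panel")
        if want > pool.size:
            warnings.warn(
                f"partition {label!r}: only {pool.size} SNPs available, "
                f"capping n_causal at that"
            )
            want = pool.size
        chosen = rng.choice(pool, size=want, replace=False)
        b = rng.standard_normal(want)
        b *= np.sqrt(var_j) / np.linalg.norm(b)
        idx_all.append(chosen)
        beta_all.append(b)
        rows.extend(
            (G.snps["snp"].iloc[j], label, bj) for j, bj in zip(chosen, b)
        )
    if idx_all:
        causal_idx = np.concatenate(idx_all)
        beta = np.concatenate(beta_all)
    else:
        causal_idx = np.empty(0, dtype=int)
        beta = np.empty(0)
    truth = pd.DataFrame(rows, columns=["snp", "partition", "beta"])
    return causal_idx, beta, truth


@dataclass
class PhenotypeSet:
    """Binary phenotype with its generating truth."""

    status: np.ndarray                 # 1 = case, 0 = control
    genetic_values: np.ndarray         # true liability-scale genetic value
    liability: np.ndarray
    realized_prevalence: float
    truth: pd.DataFrame                # causal SNP ids, partitions, effects
    prevalence_K: float
    h2_liability: float

    @property
    def case_fraction(self) -> float:
        return float(self.status.mean())


def _standardizer(G: GenotypeMatrix, causal_idx):
    p = np.asarray(G.meta.get("true_maf", G.freq), dtype=float)[causal_idx]
    return p, np.sqrt(2.0 * p * (1.0 - p))


def _ascertain(
    G, causal_idx, beta, h2, K, n_cases, n_controls,
    rng_pop, rng_resid, rng_sample, chunk_size, max_chunks, id_prefix,
):
    """Chunked population generation with threshold ascertainment.

    Only causal-SNP genotypes are materialised while screening the population;
    the non-causal genotypes of the retained individuals are drawn afterwards
    (they are independent of liability, so this is distributionally exact).
    """
    p_causal, sd_causal = _standardizer(G, causal_idx)
    thresh = norm.isf(K)
    sd_e = np.sqrt(max(0.0, 1.0 - h2))

    case_rows, case_g, case_liab = [], [], []
    # uniform reservoir over all unaffected individuals seen so far
    res_rows = np.zeros((n_controls, causal_idx.size), dtype=np.int8)
    res_g = np.zeros(n_controls)
    res_liab = np.zeros(n_controls)
    n_unaff_seen = 0
    n_total = 0
    n_affected = 0

    for _ in range(max_chunks):
        Xc = rng_pop.binomial(2, p_causal, size=(chunk_size, causal_idx.size)).astype(np.int8)
        if causal_idx.size:
            g = ((Xc - 2.0 * p_causal) / sd_causal) @ beta
        else:
            g = np.zeros(chunk_size)
        liab = g + rng_resid.normal(0.0, sd_e, size=chunk_size) if sd_e > 0 else g.copy()
        aff = liab > thresh
        n_total += chunk_size
        n_affected += int(aff.sum())

        need = n_cases - len(case_rows)
        take = np.flatnonzero(aff)[:need]
        for i in take:
            case_rows.append(Xc[i])
            case_g.append(g[i])
            case_liab.append(liab[i])

        for i in np.flatnonzero(~aff):
            if n_unaff_seen < n_controls:
                res_rows[n_unaff_seen] = Xc[i]
                res_g[n_unaff_seen] = g[i]
                res_liab[n_unaff_seen] = liab[i]
            else:
                j = rng_sample.integers(0, n_unaff_seen + 1)
                if j < n_controls:
                    res_rows[j] = Xc[i]
                    res_g[j] = g[i]
                    res_liab[j] = liab[i]
            n_unaff_seen += 1

        if len(case_rows) >= n_cases and n_unaff_seen >= n_controls:
            break
    else:
        need_pop = int(np.ceil(n_cases / K))
        raise ResourceBudgetError(
            f"could not ascertain {n_cases} cases at K={K} within "
            f"{max_chunks} chunks of {chunk_size}; needs a population of "
            f"roughly {need_pop} individuals — raise chunk_size or max_chunks"
        )

    n = n_cases + n_controls
    maf = np.asarray(G.meta.get("true_maf", G.freq), dtype=float)
    calls = rng_pop.binomial(2, maf, size=(n, G.n_snps)).astype(np.int8)
    if causal_idx.size:
        calls[:n_cases, causal_idx] = np.asarray(case_rows, dtype=np.int8)
        calls[n_cases:, causal_idx] = res_rows
    g_all = np.concatenate([np.asarray(case_g), res_g])
    liab_all = np.concatenate([np.asarray(case_liab), res_liab])
    status = np.zeros(n, dtype=np.int8)
    status[:n_cases] = 1

    samples = pd.DataFrame(
        {
            "fid": [f"{id_prefix}F{i + 1:05d}" for i in range(n)],
            "iid": [f"{id_prefix}I{i + 1:05d}" for i in range(n)],
        }
    )
    G_sample = GenotypeMatrix(
        samples=samples,
        snps=G.snps.copy(),
        calls=calls,
        annotations={k: np.asarray(v).copy() for k, v in G.annotations.items()},
        meta=dict(G.meta, n_cases=n_cases, n_controls=n_controls),
    )
    return G_sample, status, g_all, liab_all, n_affected / n_total


def simulate_liability_phenotype(
    G: GenotypeMatrix,
    arch: Architecture,
    seed: int,
    n_cases: int | None = None,
    n_controls: int | None = None,
    chunk_size: int = 10_000,
    max_chunks: int = 100,
):
    """Ascertained case-control sample under the liability-threshold model.

    Returns ``(G_sample, PhenotypeSet)``: a fresh genotype matrix for the
    ascertained individuals (same SNP panel as ``G``) and the phenotype with
    its generating truth.  Cases are individuals whose liability exceeds
    ``Phi^-1(1 - K)``; controls are a uniform draw from the unaffected.
    """
    n_cases = G.meta.get("n_cases") if n_cases is None else n_cases
    n_controls = G.meta.get("n_controls") if n_controls is None else n_controls
    if n_cases is None or n_controls is None:
        raise ConfigurationError("n_cases/n_controls not given and absent from panel meta")
    rngs = _streams(seed, "effects", "population", "residuals", "sampling")
    causal_idx, beta, truth = draw_effects(G, arch, rngs["effects"])
    G_s, status, g, liab, prev = _ascertain(
        G, causal_idx, beta, arch.h2_liability, arch.prevalence_K,
        n_cases, n_controls, rngs["population"], rngs["residuals"],
        rngs["sampling"], chunk_size, max_chunks, id_prefix="",
    )
    pheno = PhenotypeSet(
        status=status,
        genetic_values=g,
        liability=liab,
        realized_prevalence=prev,
        truth=truth,
        prevalence_K=arch.prevalence_K,
        h2_liability=arch.h2_liability,
    )
    return G_s, pheno


def simulate_quantitative(G: GenotypeMatrix, arch: Architecture, seed: int):
    """Unascertained liability as a quantitative trait on the panel's own sample.

    Returns ``(y, g_parts)`` where ``y`` has unit variance in expectation and
    ``g_parts`` maps each partition label to its genetic-value vector — handy
    for checking realized variance shares against the preset.
    """
    rngs = _streams(seed, "effects", "population", "residuals", "sampling")
    causal_idx, beta, truth = draw_effects(G, arch, rngs["effects"])
    p, sd = _standardizer(G, causal_idx)
    Z = (G.calls[:, causal_idx] - 2.0 * p) / sd
    g_parts = {}
    # map causal columns back to partitions via the truth table
    snp_to_col = {s: j for j, s in enumerate(truth["snp"])}
    for label in arch.partition_shares:
        cols = [snp_to_col[s] for s, lab in zip(truth["snp"], truth["partition"]) if lab == label]
        g_parts[label] = Z[:, cols] @ beta[cols] if cols else np.zeros(G.n_samples)
    g = Z @ beta if causal_idx.size else np.zeros(G.n_samples)
    y = g + rngs["residuals"].normal(0.0, np.sqrt(max(0.0, 1.0 - arch.h2_liability)),
                                     size=G.n_samples)
    return y, g_parts


def simulate_bivariate(
    G1: GenotypeMatrix,
    G2: GenotypeMatrix,
    arch: Architecture,
    seed: int,
    chunk_size: int = 10_000,
    max_chunks: int = 100,
):
    """Two ascertained case-control traits with correlated per-SNP effects.

    ``G1`` and ``G2`` must share the SNP panel and have disjoint sample ids.
    Per-SNP effect pairs are bivariate normal with correlation ``arch.rg``;
    each trait then follows the liability-threshold machinery on its own
    sample at its own prevalence and heritability.
    """
    if arch.rg is None:
        raise ConfigurationError("architecture has no rg; not a bivariate preset")
    if not G1.snps["snp"].equals(G2.snps["snp"]):
        raise ConfigurationError("panels do not share the same SNP set")
    overlap = set(G1.sample_ids) & set(G2.sample_ids)
    if overlap:
        raise ConfigurationError(
            f"sample sets overlap ({len(overlap)} ids, e.g. {sorted(overlap)[:3]})"
        )
    h2_1 = arch.h2_liability
    h2_2 = arch.h2_liability_2 if arch.h2_liability_2 is not None else h2_1
    K2 = arch.prevalence_K_2 if arch.prevalence_K_2 is not None else arch.prevalence_K

    rngs = _streams(seed, "effects", "pop1", "resid1", "samp1", "pop2", "resid2", "samp2")
    causal_idx, b_raw, truth = draw_effects(G1, arch, rngs["effects"])
    ncau = causal_idx.size
    rg = float(arch.rg)
    pair = rngs["effects"].standard_normal((ncau, 2))
    b1 = pair[:, 0]
    b2 = rg * pair[:, 0] + np.sqrt(max(0.0, 1.0 - rg**2)) * pair[:, 1]
    b1 *= np.sqrt(h2_1) / np.linalg.norm(b1)
    b2 *= np.sqrt(h2_2) / np.linalg.norm(b2)

    out = []
    for G, beta, h2, K, tag, pop, res, samp in (
        (G1, b1, h2_1, arch.prevalence_K, "T1", "pop1", "resid1", "samp1"),
        (G2, b2, h2_2, K2, "T2", "pop2", "resid2", "samp2"),
    ):
        n_cases = G.meta.get("n_cases")
        n_controls = G.meta.get("n_controls")
        G_s, status, g, liab, prev = _ascertain(
            G, causal_idx, beta, h2, K, n_cases, n_controls,
            rngs[pop], rngs[res], rngs[samp], chunk_size, max_chunks,
            id_prefix=f"{tag}_",
        )
        tr = truth.copy()
        tr["beta"] = beta
        out.append(
            (
                G_s,
                PhenotypeSet(
                    status=status, genetic_values=g, liability=liab,
                    realized_prevalence=prev, truth=tr,
                    prevalence_K=K, h2_liability=h2,
                ),
            )
        )
    return out[0], out[1]


def inject_platform_artifact(
    G: GenotypeMatrix,
    platform_labels,
    affected_fraction: float,
    shift: float,
    seed: int,
) -> GenotypeMatrix:
    """Perturb allele frequencies in one platform group for a random SNP subset.

    For ``affected_fraction`` of SNPs the second platform group's genotypes
    are resampled at frequency ``p + shift`` (clamped into (0, 1) with a
    warning).  Affected SNP ids are recorded in ``meta['platform_affected']``
    and as an annotation mask.
    """
    labels = np.asarray(platform_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ConfigurationError(f"need exactly two platform labels, got {uniq.size}")
    if not 0.0 <= affected_fraction <= 1.0:
        raise ConfigurationError("affected_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = G.subset()
    if affected_fraction == 0.0:
        out.meta["platform_affected"] = []
        out.annotations["platform_affected"] = np.zeros(G.n_snps, dtype=bool)
        return out
    m_aff = int(round(affected_fraction * G.n_snps))
    snp_sel = rng.choice(G.n_snps, size=m_aff, replace=False)
    grp2 = labels == uniq[1]
    p = np.asarray(G.meta.get("true_maf", G.freq), dtype=float)[snp_sel]
    p_new = p + shift
    clamped = (p_new <= 0.0) | (p_new >= 1.0)
    if clamped.any():
        warnings.warn(
            f"{int(clamped.sum())} shifted frequencies clamped into (0, 1)"
        )
        p_new = np.clip(p_new, 1e-4, 1.0 - 1e-4)
    out.calls[np.ix_(grp2, snp_sel)] = rng.binomial(
        2, p_new, size=(int(grp2.sum()), m_aff)
    ).astype(np.int8)
    affected_ids = G.snps["snp"].iloc[snp_sel].tolist()
    out.meta["platform_affected"] = affected_ids
    mask = np.zeros(G.n_snps, dtype=bool)
    mask[snp_sel] = True
    out.annotations["platform_affected"] = mask
    return out


def write_dataset(G: GenotypeMatrix, pheno: PhenotypeSet, prefix) -> None:
    """Write PLINK files, a 1=control/2=case phenotype file and a truth sidecar."""
    from pathlib import Path

    from .genotype_io import write_phenotype, write_plink

    prefix = Path(prefix)
    write_plink(G, prefix)
    write_phenotype(str(prefix) + ".phen", G.samples, pheno.status + 1)
    pheno.truth.to_csv(str(prefix) + ".truth.tsv", sep="\t", index=False)
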