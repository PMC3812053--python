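"""Genomic partitioning of heritability: MAF bins, annotations, chromosomes.

Each partition contributes its own GRM; a joint multi-GRM REML fit then
splits the genetic variance, restricting leakage between partitions.  Per-
partition heritabilities are converted to the liability scale with the
shared transform factor, and "% of total" shares are computed against the
sum of the genetic components of the same joint model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .genotype_io import GenotypeMatrix
from .grm import compute_grm
from .liability import LiabilityParams, observed_to_liability
from .reml import VarianceComponentFit, null_reml_loglik, reml_fit, reml_lrt
from .simulate import CHROM_LENGTHS_MB, MAF_BIN_EDGES

__all__ = [
    "PartitionSpec",
    "PartitionResult",
    "make_maf_bins",
    "make_annotation_spec",
    "partitioned_reml",
    "per_chromosome_analysis",
    "expected_chromosome_h2",
    "chromosome_length_correlation",
]

_MIN_PARTITION_SNPS = 50


@dataclass
class PartitionSpec:
    """Ordered, disjoint SNP partition covering the analysis panel."""

    kind: str  # chromosome | maf_bins | annotation
    labels: list
    masks: list  # boolean arrays over SNPs
    maf_edges: tuple | None = None
    excluded: np.ndarray | None = None  # SNPs in no partition (e.g. below lowest edge)

    def __post_init__(self) -> None:
        stack = np.array([np.asarray(m, bool) for m in self.masks])
        if (stack.sum(axis=0) > 1).any():
            raise ValueError("partition masks must be disjoint")

    @property
    def snp_counts(self) -> np.ndarray:
        return np.array([int(np.sum(m)) for m in self.masks])


def make_maf_bins(G: GenotypeMatrix, edges=MAF_BIN_EDGES) -> PartitionSpec:
    """Half-open MAF bins (lo, hi] on the analysis-sample MAF.

    SNPs at or below the first edge are excluded (reported in ``excluded``);
    empty bins are retained with a warning so the joint fit can drop them
    with notice.
    """
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    if edges[0] < 0 or edges[-1] > 0.5:
        raise ValueError("edges must lie within (0, 0.5]")
    maf = G.maf
    labels, masks = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (maf > lo) & (maf <= hi)
        labels.append(f"maf_{lo:g}_{hi:g}")
        masks.append(mask)
        if mask.sum() == 0:
            warnings.warn(f"MAF bin ({lo:g}, {hi:g}] holds no SNPs")
    excluded = maf <= edges[0]
    return PartitionSpec(kind="maf_bins", labels=labels, masks=masks,
                         maf_edges=edges, excluded=excluded)


def make_annotation_spec(G: GenotypeMatrix, annotation: str,
                         complement_label: str | None = None) -> PartitionSpec:
    """Annotation vs complement two-partition spec (genic/intergenic etc.)."""
    if annotation not in G.annotations:
        raise KeyError(f"annotation {annotation!r} not present on panel")
    mask = np.asarray(G.annotations[annotation], bool)
    comp = complement_label or f"not_{annotation}"
    return PartitionSpec(kind="annotation", labels=[annotation, comp],
                         masks=[mask, ~mask])


@dataclass
class PartitionResult:
    """Joint multi-GRM fit with per-partition liability h2 and shares."""

    table: pd.DataFrame
    fit: VarianceComponentFit
    total_h2_liab: float
    se_total_h2_liab: float
    factor: float
    labels: list = field(default_factory=list)

    def share(self, label: str) -> float:
        return float(self.table.set_index("partition").loc[label, "share_of_total"])


def partitioned_reml(
    G: GenotypeMatrix,
    spec: PartitionSpec,
    y: np.ndarray,
    X: np.ndarray | None = None,
    K: float | None = None,
    P: float | None = None,
) -> PartitionResult:
    """Joint REML over one GRM per partition, with liability-scale shares."""
    labels, grms, counts = [], [], []
    for label, mask in zip(spec.labels, spec.masks):
        nsnp = int(np.sum(mask))
        if nsnp == 0:
            warnings.warn(f"partition {label!r} empty; dropped from the joint fit")
            continue
        if nsnp < _MIN_PARTITION_SNPS:
            warnings.warn(f"partition {label!r} holds only {nsnp} SNPs")
        labels.append(label)
        counts.append(nsnp)
        grms.append(compute_grm(G, mask, snp_set=label))
    if len(labels) < 1:
        raise ValueError("no non-empty partitions")

    fit = reml_fit(grms, y, X)
    if K is not None:
        P = float(np.mean(y > np.median(y))) if P is None else P
        params = LiabilityParams(K=K, P=P)
        factor = params.factor
    else:
        factor = 1.0

    genetic = fit.sigma2[:-1]
    total_g = genetic.sum()
    shares = genetic / total_g
    h2_liab = fit.h2_observed * factor
    se_liab = fit.se_h2_observed * factor
    table = pd.DataFrame(
        {
            "partition": labels,
            "n_snps": counts,
            "frac_snps": np.asarray(counts) / G.n_snps,
            "sigma2": genetic,
            "se_sigma2": fit.se_sigma2[:-1],
            "h2_liab": h2_liab,
            "se_h2_liab": se_liab,
            "share_of_total": shares,
        }
    )
    return PartitionResult(
        table=table,
        fit=fit,
        total_h2_liab=float(fit.h2_total * factor),
        se_total_h2_liab=float(fit.se_h2_total * factor),
        factor=factor,
        labels=labels,
    )


def per_chromosome_analysis(
    G: GenotypeMatrix,
    y: np.ndarray,
    X: np.ndarray | None = None,
    mode: str = "separate",
    K: float | None = None,
    P: float | None = None,
) -> pd.DataFrame:
    """Per-chromosome heritability, fitted separately or jointly.

    ``separate`` runs one single-GRM REML per chromosome (each with an LRT
    against the no-genetic-variance model); ``joint`` fits all chromosome
    GRMs in one model.  A ``total`` row sums the per-chromosome estimates.
    """
    if mode not in ("separate", "joint"):
        raise ValueError("mode must be 'separate' or 'joint'")
    chroms = [c for c in range(1, 23) if (G.snps["chrom"] == c).any()]
    if len(chroms) < 22:
        missing = sorted(set(range(1, 23)) - set(chroms))
        warnings.warn(f"chromosomes absent from panel, skipped: {missing}")
    factor = LiabilityParams(K=K, P=P).factor if K is not None else 1.0
    n = G.n_samples
    Xd = np.ones((n, 1)) if X is None else X

    rows = []
    if mode == "separate":
        ll0, _ = null_reml_loglik(y, Xd)
        for c in chroms:
            mask = (G.snps["chrom"] == c).to_numpy()
            fit = reml_fit([compute_grm(G, mask, snp_set=f"chr{c}")], y, Xd)
            stat, pv = reml_lrt(fit.loglik, ll0, df=1, boundary=True)
            rows.append(
                {
                    "chrom": c,
                    "n_snps": int(mask.sum()),
                    "h2_obs": fit.h2_observed[0],
                    "se_obs": fit.se_h2_observed[0],
                    "h2_liab": fit.h2_observed[0] * factor,
                    "se_liab": fit.se_h2_observed[0] * factor,
                    "lrt": stat,
                    "p": pv,
                }
            )
    else:
        grms = [compute_grm(G, (G.snps["chrom"] == c).to_numpy(), snp_set=f"chr{c}")
                for c in chroms]
        fit = reml_fit(grms, y, Xd)
        for j, c in enumerate(chroms):
            rows.append(
                {
                    "chrom": c,
                    "n_snps": int((G.snps["chrom"] == c).sum()),
                    "h2_obs": fit.h2_observed[j],
                    "se_obs": fit.se_h2_observed[j],
                    "h2_liab": fit.h2_observed[j] * factor,
                    "se_liab": fit.se_h2_observed[j] * factor,
                    "lrt": np.nan,
                    "p": np.nan,
                }
            )
    df = pd.DataFrame(rows)
    total = {
        "chrom": 0,
        "n_snps": int(df["n_snps"].sum()),
        "h2_obs": float(df["h2_obs"].sum()),
        "se_obs": float(np.sqrt((df["se_obs"] ** 2).sum())),
        "h2_liab": float(df["h2_liab"].sum()),
        "se_liab": float(np.sqrt((df["se_liab"] ** 2).sum())),
        "lrt": np.nan,
        "p": np.nan,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def expected_chromosome_h2(total_h2: float, weights,
                           observed: np.ndarray | None = None,
                           se_observed: np.ndarray | None = None) -> pd.DataFrame:
    """Expected per-chromosome h2 under a uniform polygenic model.

    ``weights`` are SNP or gene counts per chromosome; expected_c =
    total_h2 * w_c / sum(w).  If observed estimates and SEs are given, flags
    chromosomes deviating by more than 1.96 observed SEs.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    expected = total_h2 * w / w.sum()
    df = pd.DataFrame({"weight": w, "expected_h2": expected})
    if observed is not None:
        obs = np.asarray(observed, dtype=float)
        se = np.asarray(se_observed, dtype=float)
        df["observed_h2"] = obs
        df["flagged"] = np.abs(obs - expected) > 1.96 * se
    return df


def chromosome_length_correlation(observed_h2, lengths=None,
                                  leave_out: int | None = None):
    """Pearson correlation of per-chromosome h2 with chromosome length.

    ``lengths`` defaults to approximate autosome lengths; ``leave_out`` drops
    one chromosome (1-based index into the provided vectors' order) before
    correlating, for influence checks.
    """
    obs = np.asarray(observed_h2, dtype=float)
    lens = CHROM_LENGTHS_MB[: obs.size] if lengths is None else np.asarray(lengths, float)
    if obs.size != lens.size:
        raise ValueError("observed and length vectors differ in size")
    if leave_out is not None:
        keep = np.arange(obs.size) != (leave_out - 1)
        obs, lens = obs[keep], lens[keep]
    if obs.size < 3:
        raise ValueError("need at least 3 chromosomes")
    if np.ptp(obs) == 0 or np.ptp(lens) == 0:
        warnings.warn("zero variance; correlation undefined")
        return np.nan, np.nan
    r, p = pearsonr(obs, lens)
    return float(r), float(p)
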