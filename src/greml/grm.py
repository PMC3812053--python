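"""Genetic relationship matrices (GRMs) and their principal components.

The GRM entry for individuals j, k over a SNP set S is the allele-frequency
standardised cross-product

    A_jk = (1/N_jk) * sum_{i in S} (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with ``N_jk`` the number of SNPs non-missing in both individuals.  The
diagonal defaults to the inbreeding-adjusted form used by GCTA,

    A_jj = 1 + (1/N_j) * sum_i [x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2] / (2 p_i (1 - p_i)),

which agrees in expectation with the plain cross-product under HWE.  Allele
frequencies ``p_i`` are computed on the analysis sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, read_grm_bin, write_grm_bin

__all__ = ["GRM", "compute_grm", "compute_cross_standardized", "grm_pca",
           "write_eigenvec"]


@dataclass
class GRM:
    """Symmetric relatedness matrix with per-pair non-missing SNP counts."""

    ids: list
    A: np.ndarray
    pair_counts: np.ndarray
    snp_set: str = "all"
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def eigh(self):
        """Cached eigendecomposition (ascending eigenvalues), reused by REML."""
        if self._eig is None:
            w, Q = np.linalg.eigh(self.A)
            self._eig = (w, Q)
        return self._eig

    def to_file(self, prefix) -> None:
        write_grm_bin(self.ids, self.A, self.pair_counts, prefix)

    @classmethod
    def from_file(cls, prefix, snp_set: str = "all") -> "GRM":
        ids, A, N = read_grm_bin(prefix)
        return cls(ids=ids, A=A, pair_counts=N, snp_set=snp_set)


def _standardize(G: GenotypeMatrix, snp_idx: np.ndarray):
    """Standardised genotypes Z (missing -> 0), missingness indicator W, kept idx."""
    X = G.calls[:, snp_idx].astype(float)
    miss = X < 0
    X[miss] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(X, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"skipping {int((~poly).sum())} monomorphic/all-missing SNPs in GRM",
            stacklevel=3,
        )
    X = X[:, poly]
    p = p[poly]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    Z = (X - 2.0 * p) / denom
    Z[np.isnan(Z)] = 0.0
    W = (~np.isnan(X)).astype(float)
    return Z, W, p, snp_idx[poly]


def compute_grm(
    G: GenotypeMatrix,
    snp_mask: np.ndarray | None = None,
    diagonal: str = "gcta",
    snp_set: str = "all",
) -> GRM:
    """Estimate the GRM from the SNPs selected by ``snp_mask``.

    Parameters
    ----------
    snp_mask : boolean array over SNPs, or None for all SNPs.
    diagonal : ``"gcta"`` (inbreeding-adjusted, default) or ``"crossproduct"``.
    """
    if snp_mask is None:
        snp_idx = np.arange(G.n_snps)
    else:
        snp_idx = np.flatnonzero(np.asarray(snp_mask))
    if snp_idx.size == 0:
        raise ValueError("empty SNP mask: a GRM needs at least one SNP")

    Z, W, p, kept = _standardize(G, snp_idx)
    if Z.shape[1] == 0:
        raise ValueError("no polymorphic SNPs left in the mask")

    counts = W @ W.T
    with np.errstate(invalid="ignore", divide="ignore"):
        A = (Z @ Z.T) / counts
    A[counts == 0] = 0.0

    if diagonal == "gcta":
        X = G.calls[:, kept].astype(float)
        obs = X >= 0
        X[~obs] = 0.0
        num = (X * X - (1.0 + 2.0 * p) * X + 2.0 * p * p) / (2.0 * p * (1.0 - p))
        num[~obs] = 0.0
        nj = obs.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            diag = 1.0 + num.sum(axis=1) / nj
        diag[nj == 0] = 0.0
        np.fill_diagonal(A, diag)
    elif diagonal != "crossproduct":
        raise ValueError(f"unknown diagonal mode {diagonal!r}")

    return GRM(ids=G.sample_ids, A=A, pair_counts=counts, snp_set=snp_set)


def compute_cross_standardized(G: GenotypeMatrix, snp_mask=None):
    """Return (Z, kept_idx): standardised genotype matrix for cross-sample blocks."""
    if snp_mask is None:
        snp_idx = np.arange(G.n_snps)
    else:
        snp_idx = np.flatnonzero(np.asarray(snp_mask))
    Z, _, _, kept = _standardize(G, snp_idx)
    return Z, kept


def grm_pca(grm: GRM, k: int) -> np.ndarray:
    """Top-k principal components (unit eigenvectors) of the GRM.

    Components are ordered by decreasing eigenvalue; each column's sign is fixed
    so its largest-magnitude loading is positive.
    """
    if not np.isfinite(grm.A).all():
        raise ValueError("GRM contains non-finite entries")
    if k >= grm.n:
        raise ValueError("k must be < number of samples")
    w, Q = grm.eigh()
    order = np.argsort(w)[::-1][:k]
    pcs = Q[:, order]
    flip = np.sign(pcs[np.abs(pcs).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    return pcs * flip


def write_eigenvec(path, ids, pcs) -> None:
    """Write principal components as whitespace FID IID pc1..pck (.eigenvec dialect)."""
    pcs = np.asarray(pcs)
    with open(path, "w") as fh:
        for (fid, iid), row in zip(ids, pcs):
            fh.write(f"{fid} {iid} " + " ".join(f"{v:.6g}" for v in row) + "\n")
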