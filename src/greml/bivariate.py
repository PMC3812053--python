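"""Bivariate REML: genetic correlation between two traits on disjoint samples.

The two samples share a SNP panel, so the stacked phenotype vector
``y = (y1, y2)`` has covariance built from within- and cross-sample GRM
blocks:

    V = | vg1*A11 + ve1*I     cg12*A12         |
        | cg12*A21            vg2*A22 + ve2*I  |

with A computed on the combined sample.  Because the samples are disjoint
the residual covariance is structurally zero (it would be unidentifiable).
The genetic correlation is rg = cg12 / sqrt(vg1 * vg2) with a delta-method
SE from the inverse average-information matrix; values straying outside
[-1, 1] are clamped and flagged, never silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genotype_io import GenotypeMatrix
from .grm import compute_cross_standardized
from .reml import _DenseBackend, _FLOOR_FRAC, optimize_ai_reml

__all__ = ["BivariateFit", "bivar_reml_fit", "rg_lrt", "cross_grm_blocks"]


@dataclass
class BivariateFit:
    sigma2_g1: float
    sigma2_g2: float
    cov_g12: float
    sigma2_e1: float
    sigma2_e2: float
    rg: float
    se_rg: float
    rg_clamped: bool
    loglik: float
    n_iter: int
    converged: bool
    n1: int
    n2: int
    ai_inv: np.ndarray | None = None


def cross_grm_blocks(G1: GenotypeMatrix, G2: GenotypeMatrix):
    """GRM blocks (A11, A22, A12) from the pooled standardisation of a shared panel."""
    if not G1.snps["snp"].equals(G2.snps["snp"]):
        raise ValueError("the two samples must share the same SNP panel")
    stacked = GenotypeMatrix(
        samples=pd.concat([G1.samples, G2.samples], ignore_index=True),
        snps=G1.snps,
        calls=np.vstack([G1.calls, G2.calls]),
    )
    Z, kept = compute_cross_standardized(stacked)
    M = Z.shape[1]
    A = (Z @ Z.T) / M
    n1 = G1.n_samples
    return A[:n1, :n1], A[n1:, n1:], A[:n1, n1:]


def bivar_reml_fit(
    G: tuple[GenotypeMatrix, GenotypeMatrix] | None = None,
    pheno1: np.ndarray | None = None,
    pheno2: np.ndarray | None = None,
    X1: np.ndarray | None = None,
    X2: np.ndarray | None = None,
    blocks: tuple | None = None,
    constrain_rg0: bool = False,
    max_iter: int = 100,
) -> BivariateFit:
    """AI-REML fit of the five-parameter bivariate model.

    Either pass ``G = (G1, G2)`` (genotype matrices on disjoint samples) or
    precomputed ``blocks = (A11, A22, A12)``.  ``constrain_rg0`` drops the
    genetic covariance from the model (the reduced fit for the LRT).
    """
    if blocks is None:
        G1, G2 = G
        overlap = set(G1.sample_ids) & set(G2.sample_ids)
        if overlap:
            raise ValueError(
                f"samples overlap between traits: {sorted(overlap)[:5]}"
            )
        A11, A22, A12 = cross_grm_blocks(G1, G2)
    else:
        A11, A22, A12 = blocks
    y1 = np.asarray(pheno1, dtype=float)
    y2 = np.asarray(pheno2, dtype=float)
    n1, n2 = y1.size, y2.size
    n = n1 + n2
    if A11.shape != (n1, n1) or A22.shape != (n2, n2) or A12.shape != (n1, n2):
        raise ValueError("GRM block shapes do not match phenotype lengths")

    X1 = np.ones((n1, 1)) if X1 is None else np.atleast_2d(np.asarray(X1, float))
    X2 = np.ones((n2, 1)) if X2 is None else np.atleast_2d(np.asarray(X2, float))
    if X1.shape[0] != n1:
        X1 = X1.T
    if X2.shape[0] != n2:
        X2 = X2.T
    X = np.zeros((n, X1.shape[1] + X2.shape[1]))
    X[:n1, : X1.shape[1]] = X1
    X[n1:, X1.shape[1]:] = X2
    y = np.concatenate([y1, y2])

    def pad(block, r0, c0):
        B = np.zeros((n, n))
        B[r0 : r0 + block.shape[0], c0 : c0 + block.shape[1]] = block
        return B

    Bg1 = pad(A11, 0, 0)
    Bg2 = pad(A22, n1, n1)
    Bc = pad(A12, 0, n1)
    Bc = Bc + Bc.T
    Be1 = pad(np.eye(n1), 0, 0)
    Be2 = pad(np.eye(n2), n1, n1)

    v1 = float(np.var(y1 - X1 @ np.linalg.lstsq(X1, y1, rcond=None)[0], ddof=X1.shape[1]))
    v2 = float(np.var(y2 - X2 @ np.linalg.lstsq(X2, y2, rcond=None)[0], ddof=X2.shape[1]))

    if constrain_rg0:
        Bs = [Bg1, Bg2, Be1, Be2]
        theta0 = np.array([v1 / 2, v2 / 2, v1 / 2, v2 / 2])
        floors = np.array([_FLOOR_FRAC * v1, _FLOOR_FRAC * v2,
                           _FLOOR_FRAC * v1, _FLOOR_FRAC * v2])
    else:
        Bs = [Bg1, Bg2, Bc, Be1, Be2]
        theta0 = np.array([v1 / 2, v2 / 2, 0.0, v1 / 2, v2 / 2])
        floors = np.array([_FLOOR_FRAC * v1, _FLOOR_FRAC * v2, np.nan,
                           _FLOOR_FRAC * v1, _FLOOR_FRAC * v2])

    backend = _DenseBackend(Bs, y, X)
    theta, ll, AI, n_iter, converged = optimize_ai_reml(
        backend, theta0, floors, max_iter=max_iter
    )
    cov = np.linalg.pinv(AI)

    if constrain_rg0:
        vg1, vg2, ve1, ve2 = theta
        c = 0.0
        rg, se_rg, clamped = 0.0, 0.0, False
    else:
        vg1, vg2, c, ve1, ve2 = theta
        denom = np.sqrt(vg1 * vg2)
        rg_raw = c / denom if denom > 0 else np.nan
        clamped = bool(abs(rg_raw) > 1.0)
        rg = float(np.clip(rg_raw, -1.0, 1.0))
        # delta method on (vg1, vg2, c)
        grad = np.zeros(5)
        grad[0] = -0.5 * c / (vg1 * denom)
        grad[1] = -0.5 * c / (vg2 * denom)
        grad[2] = 1.0 / denom
        se_rg = float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    return BivariateFit(
        sigma2_g1=float(vg1), sigma2_g2=float(vg2), cov_g12=float(c),
        sigma2_e1=float(ve1), sigma2_e2=float(ve2),
        rg=rg, se_rg=se_rg, rg_clamped=clamped,
        loglik=ll, n_iter=n_iter, converged=converged,
        n1=n1, n2=n2, ai_inv=cov,
    )


def rg_lrt(fit_free: BivariateFit, fit_rg0: BivariateFit) -> dict:
    """LRT of rg = 0; reports both the two-sided chi2(1) and one-sided halved p."""
    if fit_free.n1 != fit_rg0.n1 or fit_free.n2 != fit_rg0.n2:
        raise ValueError("fits are not on the same data; LRT is not nested")
    stat = max(0.0, 2.0 * (fit_free.loglik - fit_rg0.loglik))
    p_two = float(chi2.sf(stat, 1))
    return {"lrt": stat, "p": p_two, "p_one_sided": 0.5 * p_two}
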