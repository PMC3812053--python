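"""End-to-end study flows: univariate heritability, null controls, subgroup splits.

`run_univariate` chains the stages a single-trait analysis needs —
optional QC, GRM, principal components, AI-REML with intercept + PCs, and
the liability-scale conversion at the chosen prevalence — and returns one
report object.  Around it sit the study's control procedures: phenotype
permutations (estimate stability under the null), the platform dummy
analysis (platform label treated as a phenotype, expecting no heritability
on clean data), and the age-of-onset case split.  Every flow is a pure
function of its inputs and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, read_phenotype, read_plink
from .grm import GRM, compute_grm, grm_pca
from .liability import LiabilityParams, observed_to_liability
from .qc import QCReport, QCThresholds, run_qc
from .reml import VarianceComponentFit, fit_to_hsq, null_reml_loglik, reml_fit, reml_lrt

__all__ = [
    "StudyConfig",
    "UnivariateReport",
    "StageError",
    "run_univariate",
    "run_univariate_study",
    "permutation_null",
    "platform_dummy_analysis",
    "age_of_onset_split",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class StudyConfig:
    """File-driven configuration for one univariate study run."""

    bed_prefix: str
    phenotype_path: str
    prevalence_K: float
    covariate_path: str | None = None
    n_pcs: int = 20
    qc: bool = True
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    n_permutations: int = 10
    seed: int = 0
    out_prefix: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_K < 1.0:
            raise ValueError("prevalence K must be in (0, 1)")


@dataclass
class UnivariateReport:
    fit: VarianceComponentFit
    h2_observed: float
    se_observed: float
    h2_liab: float
    se_liab: float
    factor: float
    K: float
    P: float
    lrt: float
    p_mixture: float
    p_chi2: float
    n_cases: int
    n_controls: int
    qc_report: QCReport | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("h2_observed", self.h2_observed, self.se_observed),
                ("h2_liability", self.h2_liab, self.se_liab),
                ("factor", self.factor, np.nan),
                ("K", self.K, np.nan),
                ("P", self.P, np.nan),
                ("LRT", self.lrt, np.nan),
                ("p_mixture", self.p_mixture, np.nan),
                ("p_chi2", self.p_chi2, np.nan),
                ("n_cases", self.n_cases, np.nan),
                ("n_controls", self.n_controls, np.nan),
            ],
            columns=["quantity", "value", "se"],
        )


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_univariate(
    G: GenotypeMatrix,
    status: np.ndarray,
    K: float,
    n_pcs: int = 20,
    covariates: np.ndarray | None = None,
    do_qc: bool = False,
    qc_thresholds: QCThresholds | None = None,
    platform_labels=None,
    grm: GRM | None = None,
) -> UnivariateReport:
    """QC -> GRM -> PCA -> REML -> liability conversion for one binary trait.

    ``status`` is 0/1; the sample case fraction P is taken from it.  Passing
    a precomputed ``grm`` (with its cached eigendecomposition) skips the GRM
    stage — used by the permutation null to re-fit cheaply.
    """
    status = np.asarray(status).astype(int)
    if np.ptp(status) == 0:
        raise StageError("stage 'phenotype' failed: phenotype has zero variance")
    qc_report = None
    if do_qc:
        with _stage("qc"):
            G, status, qc_report = run_qc(
                G, status, qc_thresholds, platform_labels=platform_labels
            )
    if grm is None:
        with _stage("grm"):
            grm = compute_grm(G)
    with _stage("pca"):
        pcs = grm_pca(grm, n_pcs) if n_pcs > 0 else None
    with _stage("reml"):
        n = status.size
        X = np.ones((n, 1))
        if pcs is not None:
            X = np.column_stack([X, pcs])
        if covariates is not None:
            X = np.column_stack([X, covariates])
        y = status.astype(float)
        fit = reml_fit([grm], y, X)
        ll0, _ = null_reml_loglik(y, X)
        stat, p_mix = reml_lrt(fit.loglik, ll0, df=1, boundary=True)
        _, p_chi2 = reml_lrt(fit.loglik, ll0, df=1, boundary=False)
    with _stage("liability"):
        P = float(status.mean())
        est = observed_to_liability(
            float(fit.h2_observed[0]), float(fit.se_h2_observed[0]),
            LiabilityParams(K=K, P=P),
        )
    return UnivariateReport(
        fit=fit,
        h2_observed=float(fit.h2_observed[0]),
        se_observed=float(fit.se_h2_observed[0]),
        h2_liab=est.h2_liab,
        se_liab=est.se_liab,
        factor=est.factor,
        K=K,
        P=P,
        lrt=stat,
        p_mixture=p_mix,
        p_chi2=p_chi2,
        n_cases=int(status.sum()),
        n_controls=int((status == 0).sum()),
        qc_report=qc_report,
    )


def run_univariate_study(config: StudyConfig) -> UnivariateReport:
    """File-driven variant of :func:`run_univariate`; writes TSVs + a manifest."""
    with _stage("input"):
        G = read_plink(config.bed_prefix)
        phen = read_phenotype(config.phenotype_path)
        status_map = {(f, i): v for f, i, v in
                      zip(phen["fid"], phen["iid"], phen["v0"])}
        status = np.array([status_map[t] for t in G.sample_ids], dtype=float)
        # accept the 1=control/2=case dialect as well as 0/1
        if set(np.unique(status[np.isfinite(status)])) <= {1.0, 2.0}:
            status = status - 1
        keep = np.isfinite(status)
        G = G.subset(sample_idx=np.flatnonzero(keep))
        status = status[keep].astype(int)
        covar = None
        if config.covariate_path:
            cv = read_phenotype(config.covariate_path)
            cmap = {(f, i): r for f, i, r in
                    zip(cv["fid"], cv["iid"],
                        cv.drop(columns=["fid", "iid"]).to_numpy())}
            covar = np.array([cmap[t] for t in G.sample_ids], dtype=float)

    report = run_univariate(
        G, status, config.prevalence_K, n_pcs=config.n_pcs,
        covariates=covar, do_qc=config.qc, qc_thresholds=config.qc_thresholds,
    )
    if config.out_prefix:
        out = Path(config.out_prefix)
        out.parent.mkdir(parents=True, exist_ok=True)
        fit_to_hsq(report.fit, (report.lrt, report.p_mixture)).to_csv(
            str(out) + ".hsq", sep="\t", index=False
        )
        report.summary().to_csv(str(out) + ".liability.tsv", sep="\t", index=False)
        manifest = {
            "seed": config.seed,
            "prevalence_K": config.prevalence_K,
            "n_pcs": config.n_pcs,
            "qc": config.qc,
            "n_samples": report.n_cases + report.n_controls,
            "converged": bool(report.fit.converged),
        }
        with open(str(out) + ".manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return report


def permutation_null(
    G: GenotypeMatrix,
    status: np.ndarray,
    K: float,
    n_perm: int = 10,
    seed: int = 0,
    n_pcs: int = 20,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Stability check: refit after permuting case/control labels.

    Case/control counts are preserved; covariates (and PCs) stay attached to
    individuals.  The GRM and its eigendecomposition are computed once and
    reused.  Returns per-permutation estimates with a mean/SD summary row.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    status = np.asarray(status).astype(int)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    grm = compute_grm(G)
    rows = []
    for b in range(n_perm):
        perm = rng.permutation(status.size)
        rep = run_univariate(
            G, status[perm], K, n_pcs=n_pcs, covariates=covariates,
            do_qc=False, grm=grm,
        )
        rows.append(
            {"perm": b + 1, "h2_obs": rep.h2_observed, "h2_liab": rep.h2_liab,
             "se_liab": rep.se_liab, "p_mixture": rep.p_mixture}
        )
    df = pd.DataFrame(rows)
    summary = {
        "perm": 0, "h2_obs": df["h2_obs"].mean(), "h2_liab": df["h2_liab"].mean(),
        "se_liab": df["h2_liab"].std(ddof=1) if n_perm > 1 else np.nan,
        "p_mixture": np.nan,
    }
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


def platform_dummy_analysis(
    G: GenotypeMatrix,
    platform_labels,
    n_pcs: int = 20,
    do_qc: bool = False,
    qc_thresholds: QCThresholds | None = None,
) -> UnivariateReport:
    """Treat platform membership as a phenotype; clean data should show h2 ~ 0.

    The liability conversion is run at K = P (the label is not ascertained),
    so the report's observed-scale estimate is the quantity of interest.
    """
    labels = np.asarray(platform_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("need exactly two platform groups")
    status = (labels == uniq[1]).astype(int)
    return run_univariate(
        G, status, K=float(status.mean()), n_pcs=n_pcs,
        do_qc=do_qc, qc_thresholds=qc_thresholds, platform_labels=labels,
    )


def age_of_onset_split(
    G: GenotypeMatrix,
    status: np.ndarray,
    onset: np.ndarray,
    K: float,
    cutoff: float = 16,
    n_pcs: int = 20,
) -> dict:
    """Early-onset (onset <= cutoff) vs adult-onset case strata.

    Each stratum is analysed against the full control set.  Cases with
    missing onset are excluded and counted.  Returns a dict with the two
    reports (None for an empty stratum, with a notice) and bookkeeping.
    """
    status = np.asarray(status).astype(int)
    onset = np.asarray(onset, dtype=float)
    cases = status == 1
    if cases.any() and not np.isfinite(onset[cases]).any():
        raise ValueError("all cases are missing an age of onset")
    missing = cases & ~np.isfinite(onset)
    early = cases & (onset <= cutoff)
    adult = cases & (onset > cutoff)
    controls = status == 0

    out = {"n_missing_onset": int(missing.sum()),
           "n_early": int(early.sum()), "n_adult": int(adult.sum()),
           "early": None, "adult": None, "notices": []}
    for name, mask in (("early", early), ("adult", adult)):
        if mask.sum() == 0:
            out["notices"].append(f"{name}-onset stratum is empty; skipped")
            continue
        idx = np.flatnonzero(mask | controls)
        rep = run_univariate(
            G.subset(sample_idx=idx), status[idx], K, n_pcs=n_pcs, do_qc=False
        )
        out[name] = rep
    return out
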