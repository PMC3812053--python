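"""SNP- and sample-level quality control for case-control GWAS panels.

Implements the stringent filter battery used before GREML analysis:
differential case/control missingness (Fisher exact, p < 0.05), deviation
from Hardy-Weinberg equilibrium (exact conditional test, p < 0.05), a
platform-association screen (per-SNP logistic regression of platform label
on dosage adjusting for ten principal components, p < 0.001), sample call
rate (>= 99.9%) and relatedness pruning (pi-hat > 0.05, operationalised as
the GRM off-diagonal).  Filters run in a fixed order and each dropped item
records exactly one primary reason, so a second pass is a no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .genotype_io import GenotypeMatrix
from .grm import GRM, compute_grm

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "differential_missingness_test",
    "platform_association_scan",
    "sample_call_rate_filter",
    "prune_related",
    "run_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    diff_missingness_p: float = 0.05
    hwe_p: float = 0.05
    platform_p: float = 0.001
    sample_call_rate: float = 0.999
    pihat_max: float = 0.05
    n_platform_pcs: int = 10
    snp_call_rate: float = 0.98
    hwe_mode: str = "pooled"  # or "controls"

    def __post_init__(self) -> None:
        for name in ("diff_missingness_p", "hwe_p", "platform_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 < self.sample_call_rate <= 1.0:
            raise ValueError("sample_call_rate must be in (0, 1]")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of tables no more probable than the
    observed one.  Monomorphic sites return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # minor allele count
    if n_rare == 0:
        return 1.0

    # log-probability of each attainable het count (same parity as n_rare)
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    logp = (
        gammaln(n + 1)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_common - hets) / 2 + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(2 * n + 1)
    )
    p_all = np.exp(logp - logp.max())
    p_all /= p_all.sum()
    p_obs = p_all[hets == n_Aa][0]
    return float(min(1.0, p_all[p_all <= p_obs * (1 + 1e-12)].sum()))


def differential_missingness_test(miss_cases: int, tot_cases: int,
                                  miss_controls: int, tot_controls: int) -> float:
    """Two-sided Fisher exact test on the missing x case/control 2x2 table."""
    if miss_cases > tot_cases or miss_controls > tot_controls:
        raise ValueError("missing counts exceed totals")
    if tot_cases == 0 or tot_controls == 0:
        warnings.warn("empty margin in differential-missingness table; p = 1")
        return 1.0
    table = [
        [miss_cases, tot_cases - miss_cases],
        [miss_controls, tot_controls - miss_controls],
    ]
    return float(fisher_exact(table, alternative="two-sided")[1])


def platform_association_scan(G: GenotypeMatrix, platform_labels,
                              pcs: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP logistic regression of platform membership on genotype dosage.

    Returns a frame with Wald p-values for the genotype term; fits that fail
    (separation, non-convergence, monomorphic SNPs) are flagged and treated
    as failing QC downstream (p = NaN, converged = False) except monomorphic
    SNPs which are degenerate (term dropped, p = 1).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    labels = np.asarray(platform_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("platform scan needs exactly two platform groups")
    yb = (labels == uniq[1]).astype(float)
    n = G.n_samples
    base = [np.ones(n)]
    if pcs is not None:
        base.append(np.asarray(pcs, dtype=float))
    out = []
    for j in range(G.n_snps):
        x = G.calls[:, j].astype(float)
        obs = x >= 0
        if np.ptp(x[obs]) == 0:
            out.append((G.snps["snp"].iloc[j], 1.0, False, True))
            continue
        Xd = np.column_stack([b[obs] if b.ndim == 1 else b[obs] for b in base] + [x[obs]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yb[obs], Xd).fit(disp=0, maxiter=50)
            if not res.mle_retvals.get("converged", False):
                out.append((G.snps["snp"].iloc[j], np.nan, False, False))
            else:
                out.append((G.snps["snp"].iloc[j], float(res.pvalues[-1]), True, False))
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            out.append((G.snps["snp"].iloc[j], np.nan, False, False))
    return pd.DataFrame(out, columns=["snp", "p", "converged", "degenerate"])


def sample_call_rate_filter(G: GenotypeMatrix, threshold: float) -> np.ndarray:
    """Boolean mask of samples whose non-missing genotype fraction >= threshold."""
    rate = (G.calls >= 0).mean(axis=1)
    return rate >= threshold


def prune_related(grm: GRM, pihat_max: float, priority=None) -> list:
    """Greedy relatedness pruning on the GRM off-diagonal (pi-hat proxy).

    Repeatedly removes the individual involved in the most pairs above
    ``pihat_max``; ties prefer dropping lower-priority individuals (e.g.
    controls before cases), then the lexicographically larger id.  The
    returned kept ids have all pairwise values <= pihat_max.
    """
    n = grm.n
    A = grm.A.copy()
    np.fill_diagonal(A, 0.0)
    prio = np.zeros(n) if priority is None else np.asarray(priority, dtype=float)
    alive = np.ones(n, dtype=bool)
    over = A > pihat_max
    while True:
        deg = (over & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        cand = np.flatnonzero(deg == deg.max())
        # drop lowest-priority first; among those, the lexicographically larger id
        low = min(prio[i] for i in cand)
        pool = [i for i in cand if prio[i] == low]
        drop = max(pool, key=lambda i: tuple(str(x) for x in grm.ids[i]))
        alive[drop] = False
    return [grm.ids[i] for i in np.flatnonzero(alive)]


@dataclass
class QCReport:
    """Per-SNP and per-sample outcomes of one QC pass."""

    snp_table: pd.DataFrame
    sample_table: pd.DataFrame
    n_snps_in: int = 0
    n_snps_kept: int = 0
    n_samples_in: int = 0
    n_samples_kept: int = 0
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def to_tsv(self, snp_path, sample_path) -> None:
        self.snp_table.to_csv(snp_path, sep="\t", index=False)
        self.sample_table.to_csv(sample_path, sep="\t", index=False)


def run_qc(
    G: GenotypeMatrix,
    status: np.ndarray,
    thresholds: QCThresholds | None = None,
    platform_labels=None,
    platform_pcs: np.ndarray | None = None,
    max_passes: int = 5,
) -> tuple[GenotypeMatrix, np.ndarray, QCReport]:
    """Full QC battery in fixed order; returns (filtered G, kept status, report).

    Order: SNP call rate / monomorphic -> differential missingness -> HWE
    (cases+controls pooled by default) -> platform scan (if labels given) ->
    sample call rate -> relatedness pruning.  Because sample removal can shift
    the SNP-level statistics, the battery is iterated (up to ``max_passes``)
    until nothing more is dropped, so the output is a fixed point: running QC
    on it again changes nothing.  Each dropped SNP/sample records its first
    failing test as the primary reason, from the pass in which it fell.
    """
    th = thresholds or QCThresholds()
    status_in = np.asarray(status).astype(int)
    m0, n0 = G.n_snps, G.n_samples
    snp_reason = np.array([""] * m0, dtype=object)
    sample_reason = np.array([""] * n0, dtype=object)
    snp_pvals = {k: np.full(m0, np.nan) for k in ("diff_miss", "hwe", "platform")}
    snp_alive = np.arange(m0)
    sample_alive = np.arange(n0)
    Gcur, scur = G, status_in
    labels_cur = None if platform_labels is None else np.asarray(platform_labels)
    pcs_cur = platform_pcs

    for _ in range(max_passes):
        Gnext, snext, keep_snp, keep_sample, reasons_s, reasons_i, pv = _qc_pass(
            Gcur, scur, th, labels_cur, pcs_cur
        )
        for key in snp_pvals:
            snp_pvals[key][snp_alive] = pv[key]
        snp_reason[snp_alive[~keep_snp]] = reasons_s[~keep_snp]
        sample_reason[sample_alive[~keep_sample]] = reasons_i[~keep_sample]
        changed = (~keep_snp).any() or (~keep_sample).any()
        snp_alive = snp_alive[keep_snp]
        sample_alive = sample_alive[keep_sample]
        if labels_cur is not None:
            labels_cur = labels_cur[keep_sample]
        if pcs_cur is not None:
            pcs_cur = pcs_cur[keep_sample]
        Gcur, scur = Gnext, snext
        if not changed:
            break

    snp_table = pd.DataFrame(
        {
            "snp": G.snps["snp"],
            "p_diff_missingness": snp_pvals["diff_miss"],
            "p_hwe": snp_pvals["hwe"],
            "p_platform": snp_pvals["platform"],
            "dropped_reason": snp_reason,
        }
    )
    sample_table = pd.DataFrame(
        {"fid": G.samples["fid"], "iid": G.samples["iid"],
         "dropped_reason": sample_reason}
    )
    report = QCReport(
        snp_table=snp_table,
        sample_table=sample_table,
        n_snps_in=m0,
        n_snps_kept=snp_alive.size,
        n_samples_in=n0,
        n_samples_kept=sample_alive.size,
        thresholds=th,
    )
    return Gcur, scur, report


def _qc_pass(
    G: GenotypeMatrix,
    status: np.ndarray,
    th: QCThresholds,
    platform_labels,
    platform_pcs,
):
    """One pass of the ordered battery on the current panel."""
    status = np.asarray(status).astype(int)
    m = G.n_snps
    reason = np.array([""] * m, dtype=object)
    pvals = {"diff_miss": np.full(m, np.nan), "hwe": np.full(m, np.nan),
             "platform": np.full(m, np.nan)}

    obs = G.calls >= 0
    call_rate = obs.mean(axis=0)
    p = G.freq
    mono = ~np.isfinite(p) | (p <= 0) | (p >= 1)
    reason[(call_rate < th.snp_call_rate) & (reason == "")] = "snp_call_rate"
    reason[mono & (reason == "")] = "monomorphic"

    cases = status == 1
    controls = ~cases
    for j in np.flatnonzero(reason == ""):
        mc = int((~obs[cases, j]).sum())
        mk = int((~obs[controls, j]).sum())
        pv = differential_missingness_test(mc, int(cases.sum()), mk, int(controls.sum()))
        pvals["diff_miss"][j] = pv
        if pv < th.diff_missingness_p:
            reason[j] = "diff_missingness"

    hwe_rows = controls if th.hwe_mode == "controls" else np.ones(G.n_samples, bool)
    for j in np.flatnonzero(reason == ""):
        x = G.calls[hwe_rows, j]
        x = x[x >= 0]
        pv = hwe_exact_test(int((x == 2).sum()), int((x == 1).sum()), int((x == 0).sum()))
        pvals["hwe"][j] = pv
        if pv < th.hwe_p:
            reason[j] = "hwe"

    if platform_labels is not None:
        keep_so_far = reason == ""
        sub = G.subset(snp_idx=np.flatnonzero(keep_so_far))
        pcs = platform_pcs[:, : th.n_platform_pcs] if platform_pcs is not None else None
        scan = platform_association_scan(sub, platform_labels, pcs)
        sub_idx = np.flatnonzero(keep_so_far)
        pvals["platform"][sub_idx] = scan["p"].to_numpy()
        bad = (scan["p"].to_numpy() < th.platform_p) | (~scan["converged"].to_numpy()
                                                        & ~scan["degenerate"].to_numpy())
        reason[sub_idx[bad]] = "platform"

    snp_keep = reason == ""
    G1 = G.subset(snp_idx=np.flatnonzero(snp_keep))
    s_reason = np.array([""] * G.n_samples, dtype=object)
    cr_ok = sample_call_rate_filter(G1, th.sample_call_rate)
    s_reason[~cr_ok] = "sample_call_rate"

    keep_idx = np.flatnonzero(s_reason == "")
    G2 = G1.subset(sample_idx=keep_idx)
    grm = compute_grm(G2)
    prio = status[keep_idx].astype(float)  # keep cases over controls
    kept_ids = set(map(tuple, prune_related(grm, th.pihat_max, priority=prio)))
    for local, gi in enumerate(keep_idx):
        if tuple(G2.sample_ids[local]) not in kept_ids:
            s_reason[gi] = "relatedness"

    final_idx = np.flatnonzero(s_reason == "")
    G_out = G1.subset(sample_idx=final_idx)
    return (
        G_out,
        status[final_idx],
        snp_keep,
        s_reason == "",
        reason,
        s_reason,
        pvals,
    )
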