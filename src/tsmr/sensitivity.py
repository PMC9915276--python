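"""Sensitivity battery: heterogeneity, pleiotropy, outliers, leave-one-out.

Cochran's Q quantifies heterogeneity of the per-SNP causal estimates about
the IVW (or Egger) fit; the Egger intercept tests for directional horizontal
pleiotropy; MR-PRESSO detects pleiotropic outlier SNPs by comparing the
observed leave-one-out residual sum of squares to a parametric null; the
leave-one-out table and the forest/scatter/funnel plot data underpin the
usual robustness graphics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw, mr_egger, to_odds_ratio, wald_ratio
from .summary_data import HarmonizedSet


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity statistic about one fit."""

    method: str  # "ivw" or "egger"
    q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_obs: float
    global_pval: float
    outlier_snp_ids: list[str]
    outlier_pvals: dict[str, float]
    raw_estimate: MREstimate
    corrected_estimate: MREstimate | None
    distortion_pval: float | None
    n_sim: int
    seed: int


@dataclass
class LeaveOneOutTable:
    """Per-SNP omission estimates plus the all-SNP row."""

    rows: pd.DataFrame  # columns: snp, beta, se, pval (last row snp == "All")
    full: MREstimate

    @property
    def n_snp(self) -> int:
        return len(self.rows) - 1


# ---------------------------------------------------------------------------
# Heterogeneity


def cochran_q(set_: HarmonizedSet, method: str = "ivw") -> QResult:
    """Cochran's Q about the IVW fixed-effect fit or the Egger fit.

    IVW: ``Q = Σ wj (ratio_j − β̂)²`` with ``wj = (bx_j/sy_j)²`` and β̂ the
    fixed-effect IVW estimate; df = n−1. Egger: weighted squared residuals of
    the intercept model; df = n−2. p is the upper tail of the chi-square.
    """
    n = set_.n_snp
    if method == "ivw":
        if n < 2:
            raise ValueError("Q about IVW needs at least 2 instruments")
        beta = ivw(set_, effects="fixed").beta
        w = (set_.bx / set_.sy) ** 2
        q = float(np.sum(w * (set_.wald_ratios() - beta) ** 2))
        df = n - 1
    elif method == "egger":
        if n < 3:
            raise ValueError("Q about Egger needs at least 3 instruments")
        q = mr_egger(set_).slope.meta["Q"]
        df = n - 2
    else:
        raise ValueError(f"unknown method {method!r}")
    return QResult(method, q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(set_: HarmonizedSet) -> tuple[float, float, float]:
    """Egger intercept, its SE, and the t-test p-value (n−2 df).

    An intercept far from zero indicates directional horizontal pleiotropy.
    """
    res = mr_egger(set_)
    return res.intercept, res.intercept_se, res.intercept_pval


# ---------------------------------------------------------------------------
# MR-PRESSO


def _loo_slopes(bx, by, w):
    """Leave-one-out zero-intercept WLS slopes, vectorized over the left-out SNP."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    set_: HarmonizedSet,
    n_sim: int = 1000,
    outlier_threshold: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier detection, corrected fit.

    The observed statistic is the weighted residual sum of squares of each
    SNP about the IVW fit that excludes it. The null distribution comes from
    ``n_sim`` parametric datasets drawn under those leave-one-out fits
    (bx* ~ N(bx, sx), by* ~ N(β̂₋ⱼ·bx_j, sy)); the global p-value is the
    +1-continuity empirical exceedance. Per-SNP outlier p-values compare each
    observed residual to its simulated distribution and are Bonferroni-scaled
    by n before comparison with ``outlier_threshold``. When outliers are
    found, the corrected estimate is the IVW fit on the remainder and the
    distortion test compares the observed raw-vs-corrected shift to the shift
    from removing equally many random SNPs.
    """
    n = set_.n_snp
    if n < 4:
        raise ValueError("PRESSO underdetermined: need at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim too small for a meaningful empirical p-value")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = set_.bx, set_.sx, set_.by, set_.sy
    w = 1.0 / sy**2

    loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    expected = loo * bx
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    by_sim = rng.normal(expected, sy, size=(n_sim, n))
    sxy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    loo_sim = (sxy - w * bx_sim * by_sim) / (sxx - w * bx_sim**2)
    resid_sim = w * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)

    raw = to_odds_ratio(ivw(set_))
    outliers: list[str] = []
    outlier_pvals: dict[str, float] = {}
    if global_pval < outlier_threshold:
        per_snp_p = (1.0 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (n_sim + 1.0)
        for snp, p in zip(set_.snp_ids, per_snp_p):
            outlier_pvals[snp] = float(min(1.0, p * n))  # Bonferroni
            if outlier_pvals[snp] < outlier_threshold:
                outliers.append(snp)

    corrected = None
    distortion_pval = None
    if outliers:
        keep = [i for i, s in enumerate(set_.snp_ids) if s not in outliers]
        corrected = to_odds_ratio(replace(ivw(set_.subset(keep)), method="mr_presso_corrected"))
        distortion_pval = _distortion_test(set_, len(outliers), raw.beta,
                                           corrected.beta, rng)
    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_snp_ids=outliers,
        outlier_pvals=outlier_pvals,
        raw_estimate=replace(raw, method="mr_presso_raw"),
        corrected_estimate=corrected,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


def _distortion_test(set_, n_out, beta_raw, beta_corrected, rng, n_boot=1000):
    """Is the raw-vs-corrected shift larger than removing random SNPs would give?"""
    if beta_corrected == 0:
        return 1.0
    obs = abs((beta_raw - beta_corrected) / beta_corrected)
    n = set_.n_snp
    shifts = np.empty(n_boot)
    for b in range(n_boot):
        drop = rng.choice(n, size=n_out, replace=False)
        keep = np.setdiff1d(np.arange(n), drop)
        est = ivw(set_.subset(keep))
        shifts[b] = abs((est.beta - beta_corrected) / beta_corrected)
    return (1.0 + float(np.sum(shifts >= obs))) / (n_boot + 1.0)


# ---------------------------------------------------------------------------
# Leave-one-out


def leave_one_out(set_: HarmonizedSet, method: str = "ivw") -> LeaveOneOutTable:
    """Re-estimate after omitting each SNP in turn, plus the all-SNP row.

    A stable analysis shows every omission row close to the full estimate;
    a single influential or pleiotropic SNP shows up as the row that moves.
    """
    if set_.n_snp < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    if method != "ivw":
        raise ValueError("only the IVW leave-one-out is implemented")
    rows = []
    for snp in set_.snp_ids:
        est = ivw(set_.drop_snp(snp))
        rows.append({"snp": snp, "beta": est.beta, "se": est.se, "pval": est.pval})
    full = ivw(set_)
    rows.append({"snp": "All", "beta": full.beta, "se": full.se, "pval": full.pval})
    return LeaveOneOutTable(pd.DataFrame(rows), full)


# ---------------------------------------------------------------------------
# Plot data


def plot_data(set_: HarmonizedSet, results: list[MREstimate]) -> dict[str, pd.DataFrame]:
    """Structured tables behind the forest, scatter and funnel plots.

    * ``forest``: one row per method with beta and 95% CI;
    * ``scatter``: per-SNP (bx, by, sx, sy) plus per-method fit lines
      (slope = the method's beta; intercept = the Egger intercept for
      mr_egger, else 0);
    * ``funnel``: per-SNP Wald ratio against its precision 1/se(ratio), with
      the IVW estimate as the reference line.
    """
    forest = pd.DataFrame(
        [
            {
                "method": r.method, "n_snp": r.n_snp, "beta": r.beta, "se": r.se,
                "lo95": r.beta - 1.959963984540054 * r.se,
                "hi95": r.beta + 1.959963984540054 * r.se,
            }
            for r in results
        ]
    )
    lines = []
    egger_int = None
    if any(r.method == "mr_egger" for r in results) and set_.n_snp >= 3:
        egger_int = mr_egger(set_).intercept
    for r in results:
        lines.append(
            {
                "method": r.method,
                "slope": r.beta,
                "intercept": egger_int if r.method == "mr_egger" else 0.0,
            }
        )
    scatter = pd.DataFrame(
        {
            "snp": set_.snp_ids, "beta_exposure": set_.bx, "se_exposure": set_.sx,
            "beta_outcome": set_.by, "se_outcome": set_.sy,
        }
    )
    ratios = set_.wald_ratios()
    se_ratio = set_.sy / np.abs(set_.bx)
    funnel = pd.DataFrame(
        {"snp": set_.snp_ids, "ratio": ratios, "precision": 1.0 / se_ratio}
    )
    funnel.attrs["ivw_beta"] = ivw(set_).beta
    return {"forest": forest, "scatter": scatter, "scatter_lines": pd.DataFrame(lines),
            "funnel": funnel}


def sensitivity_report(
    set_: HarmonizedSet, n_sim: int = 1000, seed: int = 0, include_presso: bool = True
) -> dict:
    """Q tests, Egger intercept test and (optionally) PRESSO for one set."""
    intercept, int_se, int_p = egger_intercept_test(set_)
    q_ivw = cochran_q(set_, "ivw")
    q_egger = cochran_q(set_, "egger")
    presso = mr_presso(set_, n_sim=n_sim, seed=seed) if include_presso else None
    return {
        "egger_intercept": intercept,
        "egger_intercept_se": int_se,
        "egger_intercept_pval": int_p,
        "q_ivw": q_ivw,
        "q_egger": q_egger,
        "presso": presso,
    }
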