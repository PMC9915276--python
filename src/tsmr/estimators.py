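"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~tsmr.summary_data.HarmonizedSet` and return
an :class:`MREstimate` on the log-odds (beta) scale; :func:`to_odds_ratio`
maps an estimate to the OR scale with a Wald confidence interval.

Conventions follow the de-facto reference implementations in the MR
literature: the inverse-variance-weighted (IVW) estimator is the weighted
zero-intercept regression of outcome on exposure effects with multiplicative
random effects (residual dispersion floored at 1) and a normal p-value;
MR-Egger is the weighted regression with a free intercept and t-distributed
tests on n−2 degrees of freedom; the weighted median interpolates the
weighted empirical CDF of Wald ratios at 0.5; the mode-based estimators take
the argmax of a kernel-smoothed density of the ratios on the exact evaluation
grid used by R's ``density()`` (so published mode estimates, which inherit
that grid's discretization, are reproduced).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_data import HarmonizedSet

#: Table-shaped method order used by :func:`estimate_all`.
METHOD_ORDER = (
    "mr_egger",
    "weighted_median",
    "ivw",
    "simple_mode",
    "weighted_mode",
    "mr_presso",
)


@dataclass
class MREstimate:
    """One method's causal-effect estimate.

    ``beta``/``se``/``pval`` live on the exposure-unit log-odds scale;
    ``or_point`` and the CI bounds are populated by :func:`to_odds_ratio`.
    ``meta`` records reproducibility details (bootstrap reps, seed, ...).
    """

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_point: float | None = None
    or_lower: float | None = None
    or_upper: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("se must be > 0")
        if not (0 < self.pval <= 1):
            # guard against exact-zero underflow from sf()
            self.pval = max(self.pval, 5e-324)


@dataclass
class EggerResult:
    """MR-Egger fit: causal slope plus the intercept pleiotropy test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Wald ratio and IVW


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-SNP causal estimate ``by/bx`` with first-order SE ``sy/|bx|``."""
    if bx == 0:
        raise ValueError("null instrument: exposure effect is zero")
    if sx <= 0 or sy <= 0:
        raise ValueError("standard errors must be > 0")
    beta = by / bx
    se = sy / abs(bx)
    return MREstimate("wald_ratio", 1, beta, se, _norm_p(beta / se))


def ivw(set_: HarmonizedSet, effects: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate across all instruments.

    Equivalent to the weighted mean of Wald ratios with weights
    ``(bx/sy)²``, or to a zero-intercept weighted regression of ``by`` on
    ``bx`` with weights ``1/sy²``. With ``effects="multiplicative_random"``
    (the default, and the convention behind published IVW tables) the fixed-
    effect SE is scaled by the residual dispersion ``√(Q/(n−1))`` floored at
    1; ``effects="fixed"`` uses the unscaled SE. A single-SNP set delegates
    to :func:`wald_ratio`.
    """
    if effects not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects mode {effects!r}")
    n = set_.n_snp
    if n == 0:
        raise ValueError("empty instrument set")
    if n == 1:
        est = wald_ratio(set_.bx[0], set_.sx[0], set_.by[0], set_.sy[0])
        return replace(est, method=f"ivw_{'fe' if effects == 'fixed' else 're'}")
    bx, by, sy = set_.bx, set_.by, set_.sy
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = 1.0 / math.sqrt(sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    if effects == "fixed":
        se = se_fixed
        method = "ivw_fe"
    else:
        dispersion = math.sqrt(q / (n - 1))
        se = se_fixed * max(1.0, dispersion)
        method = "ivw_re"
    return MREstimate(method, n, beta, se, _norm_p(beta / se), meta={"Q": q})


# ---------------------------------------------------------------------------
# MR-Egger


def _oriented(set_: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip (bx, by) pairs so all exposure effects are non-negative."""
    sign = np.where(set_.bx < 0, -1.0, 1.0)
    return set_.bx * sign, set_.by * sign, set_.sy


def mr_egger(set_: HarmonizedSet, floor_dispersion: bool = True) -> EggerResult:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Instruments are first oriented so every exposure effect is non-negative
    (the fit is otherwise not identified under allele-coding flips). Weights
    are ``1/sy²``; both coefficient SEs are scaled by the residual dispersion,
    floored at 1 when ``floor_dispersion`` (the reporting convention). With
    ``floor_dispersion=False`` the plain WLS t-test is returned, which is
    exactly calibrated under a homogeneous null. p-values use the t
    distribution with n−2 df. The intercept estimates the average directional
    pleiotropy; the slope is the causal effect.
    """
    n = set_.n_snp
    if n < 3:
        raise ValueError("Egger underdetermined: need at least 3 instruments")
    bx, by, sy = _oriented(set_)
    w = 1.0 / sy**2
    sw = np.sum(w)
    swx = np.sum(w * bx)
    swxx = np.sum(w * bx**2)
    swy = np.sum(w * by)
    swxy = np.sum(w * bx * by)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy * swxx - swx * swxy) / det
    resid = by - intercept - slope * bx
    sigma2 = float(np.sum(w * resid**2)) / (n - 2)
    var_slope = sw / det * sigma2
    var_int = swxx / det * sigma2
    if floor_dispersion:
        scale = 1.0 / min(1.0, math.sqrt(sigma2))  # inflate when underdispersed
        se_slope = math.sqrt(var_slope) * scale
        se_int = math.sqrt(var_int) * scale
    else:
        se_slope = math.sqrt(var_slope)
        se_int = math.sqrt(var_int)
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), n - 2))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), n - 2))
    est = MREstimate("mr_egger", n, float(slope), se_slope, p_slope,
                     meta={"Q": float(np.sum(w * resid**2))})
    return EggerResult(est, float(intercept), se_int, p_int)


# ---------------------------------------------------------------------------
# Weighted median


def _ratio_variance(set_: HarmonizedSet) -> np.ndarray:
    """Delta-method variance of each Wald ratio (second-order)."""
    bx, sx, by, sy = set_.bx, set_.sx, set_.by, set_.sy
    return sy**2 / bx**2 + by**2 * sx**2 / bx**4


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated 50th percentile of the sorted ratios.

    Cumulative weights are taken at the midpoint of each observation's mass
    (``cumsum(w) − w/2``, normalized) and the estimate interpolates linearly
    between the two observations bracketing 0.5.
    """
    order = np.argsort(ratios)
    b, w = np.asarray(ratios, float)[order], np.asarray(weights, float)[order]
    cw = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cw[0] >= 0.5:  # more than half the mass on the smallest ratio
        return float(b[0])
    if cw[-1] < 0.5:
        return float(b[-1])
    below = int(np.max(np.nonzero(cw < 0.5)[0]))
    return float(
        b[below]
        + (b[below + 1] - b[below]) * (0.5 - cw[below]) / (cw[below + 1] - cw[below])
    )


def median_estimator(
    set_: HarmonizedSet,
    weighted: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Simple or weighted median of the per-SNP Wald ratios.

    Weighted uses the inverse delta-method ratio variance as weights (the
    convention behind published weighted-median estimates); simple uses equal
    weights. The SE comes from a parametric bootstrap: ``n_boot`` resamples of
    (bx, by) from N(bx, sx) and N(by, sy), recomputing the median with the
    original weights, SE = sd of the resampled estimates. The p-value is a
    two-sided normal test. Consistent when at least half the weight lies on
    valid instruments.
    """
    n = set_.n_snp
    if n == 1:
        est = wald_ratio(set_.bx[0], set_.sx[0], set_.by[0], set_.sy[0])
        return replace(est, method="weighted_median" if weighted else "simple_median")
    if n < 3:
        raise ValueError("median estimator needs at least 3 instruments")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} is small; bootstrap SE will be noisy")
    ratios = set_.wald_ratios()
    weights = 1.0 / _ratio_variance(set_) if weighted else np.ones(n)
    point = weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(set_.bx, set_.sx, size=(n_boot, n))
    by_b = rng.normal(set_.by, set_.sy, size=(n_boot, n))
    boots = np.array(
        [weighted_median_point(by_b[i] / bx_b[i], weights) for i in range(n_boot)]
    )
    se = float(np.std(boots, ddof=1))
    method = "weighted_median" if weighted else "simple_median"
    return MREstimate(method, n, point, se, _norm_p(point / se),
                      meta={"n_boot": n_boot, "seed": seed})


# ---------------------------------------------------------------------------
# Mode-based estimators


def r_density_grid(
    x: np.ndarray, weights: np.ndarray, bw: float, n: int = 512, cut: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE evaluated exactly as R's ``density.default``.

    Linear binning of the (normalized) weights onto ``n`` points spanning
    ``[min(x) − (cut+4)·bw, max(x) + (cut+4)·bw]``, FFT convolution with the
    kernel sampled on R's grid (including its off-by-one spacing quirk), then
    linear interpolation onto ``n`` output points over
    ``[min(x) − cut·bw, max(x) + cut·bw]``. Reproducing this grid matters:
    mode estimates published via the R toolchain sit on it.
    """
    x = np.asarray(x, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    from_, to = x.min() - cut * bw, x.max() + cut * bw
    lo, up = from_ - 4.0 * bw, to + 4.0 * bw
    y = np.zeros(2 * n)
    step = (up - lo) / (n - 1)
    pos = (x - lo) / step
    ix = np.floor(pos).astype(int)
    frac = pos - ix
    np.add.at(y, ix, w * (1.0 - frac))
    np.add.at(y, np.minimum(ix + 1, n - 1), w * frac)
    kords = np.linspace(0.0, 2.0 * (up - lo), 2 * n)
    kords[n + 1 :] = -kords[n - 1 : 0 : -1]
    kern = stats.norm.pdf(kords, scale=bw)
    conv = np.fft.ifft(np.fft.fft(y) * np.conj(np.fft.fft(kern)))
    dens = np.maximum(conv.real[:n], 0.0)  # ifft already carries the 1/len(y)
    xords = np.linspace(lo, up, n)
    xout = np.linspace(from_, to, n)
    return xout, np.interp(xout, xords, dens)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: 0.9·min(sd, MAD)/n^{1/5}, scaled by phi."""
    s = (
        0.9
        * min(np.std(ratios, ddof=1), stats.median_abs_deviation(ratios, scale="normal"))
        / len(ratios) ** 0.2
    )
    return max(1e-8, s * phi)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    if np.ptp(ratios) == 0.0:
        return float(ratios[0])
    bw = _mode_bandwidth(ratios, phi)
    grid, dens = r_density_grid(ratios, weights, bw)
    return float(grid[np.argmax(dens)])


def mode_estimator(
    set_: HarmonizedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimate: argmax of a smoothed density of Wald ratios.

    Normal kernel with the modified-Silverman bandwidth (on the unweighted
    spread of the ratios) times ``phi``; weights are the inverse delta-method
    ratio variances when ``weighted``, equal otherwise. The SE is the
    normal-scaled MAD of a seeded parametric bootstrap (robust to the
    occasional mode jump between clusters); p is a two-sided normal test.
    Consistent when the largest homogeneous cluster of instruments is valid.
    """
    n = set_.n_snp
    if n == 1:
        est = wald_ratio(set_.bx[0], set_.sx[0], set_.by[0], set_.sy[0])
        return replace(est, method="weighted_mode" if weighted else "simple_mode")
    if n < 3:
        raise ValueError("mode estimator needs at least 3 instruments")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    ratios = set_.wald_ratios()
    weights = 1.0 / _ratio_variance(set_) if weighted else np.ones(n)
    point = _mode_point(ratios, weights, phi)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(set_.bx, set_.sx, size=(n_boot, n))
    by_b = rng.normal(set_.by, set_.sy, size=(n_boot, n))
    boots = np.array(
        [_mode_point(by_b[i] / bx_b[i], weights, phi) for i in range(n_boot)]
    )
    se = float(stats.median_abs_deviation(boots, scale="normal"))
    if se == 0.0:
        se = max(float(np.std(boots, ddof=1)), 5e-324)
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, n, point, se, _norm_p(point / se),
                      meta={"n_boot": n_boot, "seed": seed, "phi": phi})


# ---------------------------------------------------------------------------
# Odds-ratio conversion and the combined table


def to_odds_ratio(est: MREstimate, alpha: float = 0.05) -> MREstimate:
    """Populate OR fields: ``exp(beta)`` with Wald ``1−alpha`` CI."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    return replace(
        est,
        or_point=math.exp(est.beta),
        or_lower=math.exp(est.beta - z * est.se),
        or_upper=math.exp(est.beta + z * est.se),
    )


def estimate_all(
    set_: HarmonizedSet,
    methods: Sequence[str] = METHOD_ORDER,
    *,
    ivw_effects: str = "multiplicative_random",
    n_boot: int = 1000,
    phi: float = 1.0,
    presso_n_sim: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[MREstimate]:
    """Run the configured estimators and return Table-shaped results.

    Methods whose preconditions fail on the given set (e.g. Egger on two
    SNPs) are skipped, not fatal; each returned estimate has its OR fields
    populated. Ordering follows ``methods``.
    """
    results: list[MREstimate] = []
    for i, method in enumerate(methods):
        sub_seed = None if seed is None else seed + 1000 * i
        try:
            if method == "ivw":
                est = ivw(set_, effects=ivw_effects)
            elif method == "mr_egger":
                est = mr_egger(set_).slope
            elif method == "weighted_median":
                est = median_estimator(set_, True, n_boot, sub_seed)
            elif method == "simple_median":
                est = median_estimator(set_, False, n_boot, sub_seed)
            elif method == "simple_mode":
                est = mode_estimator(set_, False, phi, n_boot, sub_seed)
            elif method == "weighted_mode":
                est = mode_estimator(set_, True, phi, n_boot, sub_seed)
            elif method == "wald_ratio":
                est = wald_ratio(set_.bx[0], set_.sx[0], set_.by[0], set_.sy[0])
            elif method == "mr_presso":
                from .sensitivity import mr_presso  # avoid a module cycle

                pres = mr_presso(set_, n_sim=presso_n_sim,
                                 seed=0 if sub_seed is None else sub_seed)
                est = pres.corrected_estimate or pres.raw_estimate
                est = replace(est, method="mr_presso",
                              meta={**est.meta, "global_pval": pres.global_pval})
            else:
                raise ValueError(f"unknown method {method!r}")
        except ValueError as exc:
            if "unknown method" in str(exc):
                raise
            continue  # precondition failure: skip, not fatal
        results.append(to_odds_ratio(est, alpha))
    return results
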