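"""Seeded generator of paired exposure/outcome GWAS summary statistics.

Emulates the data-generating process two-sample MR assumes: independent
(post-clumping) instruments with true effects γⱼ on the exposure, outcome
effects Γⱼ = θ·γⱼ + αⱼ, and summary statistics observed with sampling noise
on the scale set by each study's sample size. The pleiotropy term αⱼ can be
absent, balanced (zero-mean) or directional, optionally correlated with γⱼ
(an InSiDE violation), and a stated fraction of SNPs can be displaced into
outliers. Ground truth travels with the data so recovery is checkable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import HarmonizedSet, SummaryStatRecord

_INT32_MAX = 2**31 - 1


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one simulated two-sample MR dataset.

    Defaults mirror the scale of the packaged COVID-19/ME-CFS analysis:
    20 instruments, an exposure GWAS of ~750k and an outcome GWAS of ~460k
    samples, instrument effect magnitudes 0.05–0.25 — large enough that
    every simulated instrument clears genome-wide significance.
    """

    n_snp: int = 20
    theta: float = 0.0  # true causal effect
    gamma_range: tuple[float, float] = (0.05, 0.25)  # |instrument effect| bounds
    gamma_sign: str = "random"  # random | positive (pre-oriented instruments)
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False
    n_exposure: int = 750_000
    n_outcome: int = 460_000
    outlier_frac: float = 0.0
    outlier_shift: float = 10.0  # displacement in units of the outcome SE
    noiseless: bool = False  # observed betas equal their expectations (limit check)
    seed: int = 0

    def __post_init__(self):
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("sample sizes must be >= 2")
        if not (0 <= self.outlier_frac < 1):
            raise ValueError("outlier_frac must be in [0, 1)")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy model {self.pleiotropy!r}")
        if self.gamma_sign not in ("random", "positive"):
            raise ValueError(f"gamma_sign must be 'random' or 'positive', got {self.gamma_sign!r}")


def generate(scenario: SyntheticScenario):
    """Draw one dataset: (exposure records, outcome records, truth dict).

    Per SNP j: γⱼ = ±U(gamma_range) is the true exposure effect and
    sx_j = 1/√(2·eaf(1−eaf)·n_exposure) its standard error (the usual
    per-allele SE scale for a standardized trait); the observed exposure beta
    is N(γⱼ, sx_j). The outcome effect is θ·γⱼ + αⱼ observed as
    N(·, sy_j) with sy_j on the outcome-study scale. αⱼ follows the
    pleiotropy model; under an InSiDE violation it gains a +0.5·sd·(γⱼ/γ̄)
    loading on the instrument effect. ``round(outlier_frac·n)`` SNPs are then
    displaced by ``outlier_shift·sy``. Everything is reproducible from
    ``scenario.seed``; the truth dict carries θ, the per-SNP γ and α, and
    the outlier SNP ids.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    n = s.n_snp
    eaf = rng.uniform(0.1, 0.9, n)
    gamma = rng.uniform(*s.gamma_range, n)
    if s.gamma_sign == "random":
        gamma = gamma * rng.choice([-1.0, 1.0], n)
    het = 2.0 * eaf * (1.0 - eaf)
    sx = 1.0 / np.sqrt(het * s.n_exposure)
    sy = 1.0 / np.sqrt(het * s.n_outcome)

    if s.pleiotropy == "none":
        alpha = np.zeros(n)
    elif s.pleiotropy == "balanced":
        alpha = rng.normal(0.0, s.pleiotropy_sd, n)
    else:  # directional
        alpha = rng.normal(s.pleiotropy_mean, s.pleiotropy_sd, n)
    if s.inside_violation:
        alpha = alpha + 0.5 * max(s.pleiotropy_sd, abs(s.pleiotropy_mean)) * (
            gamma / np.mean(np.abs(gamma))
        )

    if s.noiseless:
        bx_hat = gamma.copy()
        by_hat = s.theta * gamma + alpha
    else:
        bx_hat = rng.normal(gamma, sx)
        by_hat = rng.normal(s.theta * gamma + alpha, sy)

    n_out = int(round(s.outlier_frac * n))
    outlier_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    by_hat = by_hat.copy()
    by_hat[outlier_idx] += s.outlier_shift * sy[outlier_idx]

    snp_ids = [f"rs{900000 + j}" for j in range(n)]
    chroms = [str(1 + j % 22) for j in range(n)]
    pos = [1_000_000 + 20_000_000 * (j // 22) for j in range(n)]  # >10 Mb apart per chrom
    p_exp_all = np.maximum(2.0 * stats.norm.sf(np.abs(bx_hat / sx)), 5e-324)
    p_out_all = np.maximum(2.0 * stats.norm.sf(np.abs(by_hat / sy)), 5e-324)
    exposure, outcome = [], []
    for j in range(n):
        p_exp = float(p_exp_all[j])
        p_out = float(p_out_all[j])
        exposure.append(
            SummaryStatRecord(snp_ids[j], chroms[j], pos[j], "A", "G",
                              float(bx_hat[j]), float(sx[j]), p_exp,
                              eaf=float(eaf[j]), n=s.n_exposure)
        )
        outcome.append(
            SummaryStatRecord(snp_ids[j], chroms[j], pos[j], "A", "G",
                              float(by_hat[j]), float(sy[j]), p_out,
                              eaf=float(eaf[j]), n=s.n_outcome)
        )
    truth = {
        "theta": s.theta,
        "gamma": gamma,
        "alpha": alpha,
        "outlier_snp_ids": [snp_ids[i] for i in outlier_idx],
        "scenario": s,
    }
    return exposure, outcome, truth


def generate_harmonized(scenario: SyntheticScenario) -> tuple[HarmonizedSet, dict]:
    """Convenience: generate and assemble directly into a HarmonizedSet."""
    exposure, outcome, truth = generate(scenario)
    rows = pd.DataFrame(
        {
            "snp": [r.snp_id for r in exposure],
            "beta_exposure": [r.beta for r in exposure],
            "se_exposure": [r.se for r in exposure],
            "beta_outcome": [r.beta for r in outcome],
            "se_outcome": [r.se for r in outcome],
            "eaf": [r.eaf for r in exposure],
        }
    )
    set_ = HarmonizedSet(
        "synthetic exposure", "synthetic outcome", rows,
        provenance=f"synthetic scenario seed={scenario.seed}",
    )
    return set_, truth


def scenario_grid(base: SyntheticScenario, axes: dict[str, list]) -> list[SyntheticScenario]:
    """Cartesian sweep over scenario fields with derived seeds.

    Scenario i in the deterministic enumeration order gets seed
    ``(base.seed + i) mod 2³¹``. Unknown field names raise.
    """
    valid = set(SyntheticScenario.__dataclass_fields__)
    for name in axes:
        if name not in valid:
            raise ValueError(f"unknown scenario field {name!r}")
    if not axes:
        return [base]
    names = list(axes)
    out = []
    for i, combo in enumerate(itertools.product(*(axes[k] for k in names))):
        kwargs = dict(zip(names, combo))
        kwargs["seed"] = (base.seed + i) % _INT32_MAX
        out.append(replace(base, **kwargs))
    return out

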