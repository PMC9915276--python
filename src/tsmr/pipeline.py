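"""End-to-end analysis: select → harmonize → estimate → sensitivity → report.

:func:`run_analysis` drives the whole pipeline from an
:class:`AnalysisConfig` and returns a :class:`ResultBundle` whose tables
mirror the standard report shapes: a per-method estimates table
(method, nsnp, beta, se, pval, OR with 95% CI) and a sensitivity table
(Egger intercept p, Egger Q p, IVW Q p, PRESSO global p). Everything is
deterministic given the config and its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import FIXTURE_NAMES, load_instruments
from .estimators import METHOD_ORDER, estimate_all
from .sensitivity import leave_one_out, plot_data, sensitivity_report
from .summary_data import HarmonizedSet, harmonize, read_summary_stats, select_instruments

logger = logging.getLogger(__name__)

_STOCHASTIC = {"weighted_median", "simple_median", "simple_mode", "weighted_mode", "mr_presso"}


@dataclass
class AnalysisConfig:
    """Settings for one exposure/outcome analysis.

    Either ``fixture`` names a packaged instrument set, or ``exposure_path``
    and ``outcome_path`` point at summary-stat tables to be filtered
    (``p_threshold``), harmonized and analysed. Defaults follow standard MR
    practice: genome-wide p < 5e-8, clumping r² 0.001 within 10,000 kb,
    alpha 0.05.
    """

    fixture: str | None = None
    exposure_path: str | None = None
    outcome_path: str | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    methods: tuple[str, ...] = METHOD_ORDER
    ivw_effects: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int | None = None
    alpha: float = 0.05
    palindromic_policy: str = "drop"
    output_dir: str | None = None


@dataclass
class ResultBundle:
    estimates: pd.DataFrame
    sensitivity: dict
    loo: pd.DataFrame
    plots: dict[str, pd.DataFrame]
    config: AnalysisConfig
    log: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        sens = self.sensitivity
        sens_json = {
            "egger_intercept": sens["egger_intercept"],
            "egger_intercept_pval": sens["egger_intercept_pval"],
            "q_ivw": {"q": sens["q_ivw"].q, "df": sens["q_ivw"].df, "pval": sens["q_ivw"].pval},
            "q_egger": {"q": sens["q_egger"].q, "df": sens["q_egger"].df,
                        "pval": sens["q_egger"].pval},
        }
        if sens["presso"] is not None:
            sens_json.update(
                presso_global_pval=sens["presso"].global_pval,
                presso_outliers=sens["presso"].outlier_snp_ids,
                presso_n_sim=sens["presso"].n_sim,
                presso_seed=sens["presso"].seed,
            )
        return {
            "version": __version__,
            "config": _config_dict(self.config),
            "estimates": _round_df(self.estimates).to_dict(orient="records"),
            "sensitivity": sens_json,
            "leave_one_out": _round_df(self.loo).to_dict(orient="records"),
            "log": self.log,
        }


def _config_dict(cfg: AnalysisConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["methods"] = list(d["methods"])
    return d


def _round_df(df: pd.DataFrame, ndigits: int = 9) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].round(ndigits)
    return out


def validate_config(raw: dict | AnalysisConfig) -> AnalysisConfig:
    """Inject defaults and reject invalid combinations with named messages."""
    cfg = raw if isinstance(raw, AnalysisConfig) else AnalysisConfig(**raw)
    if cfg.fixture is None and (cfg.exposure_path is None or cfg.outcome_path is None):
        raise ValueError("config: provide either 'fixture' or both exposure/outcome paths")
    if cfg.fixture is not None and cfg.fixture not in FIXTURE_NAMES:
        raise ValueError(f"config: unknown fixture {cfg.fixture!r}; choose from {FIXTURE_NAMES}")
    if not (0 < cfg.alpha < 1):
        raise ValueError(f"config: alpha must be in (0, 1), got {cfg.alpha}")
    if not (0 < cfg.p_threshold < 1):
        raise ValueError(f"config: p_threshold must be in (0, 1), got {cfg.p_threshold}")
    unknown = [m for m in cfg.methods if m not in METHOD_ORDER + ("simple_median", "wald_ratio")]
    if unknown:
        raise ValueError(f"config: unknown method name(s) {unknown}")
    if cfg.seed is None and (_STOCHASTIC & set(cfg.methods)):
        raise ValueError(
            "config: a seed is required when stochastic methods "
            f"({sorted(_STOCHASTIC & set(cfg.methods))}) are enabled"
        )
    return cfg


def _resolve_input(cfg: AnalysisConfig, log: list[str]) -> HarmonizedSet:
    if cfg.fixture is not None:
        log.append(f"loaded packaged instrument set '{cfg.fixture}'")
        return load_instruments(cfg.fixture)
    exposure = read_summary_stats(cfg.exposure_path)
    outcome = read_summary_stats(cfg.outcome_path)
    selected = select_instruments(exposure, cfg.p_threshold)
    log.append(f"selected {len(selected)}/{len(exposure)} instruments at p < {cfg.p_threshold}")
    set_ = harmonize(selected, outcome, palindromic_policy=cfg.palindromic_policy)
    log.append(set_.provenance)
    return set_


def run_analysis(config: AnalysisConfig | dict) -> ResultBundle:
    """Run the full pipeline; deterministic given config and seed."""
    cfg = validate_config(config)
    log: list[str] = []
    set_ = _resolve_input(cfg, log)
    results = estimate_all(
        set_,
        methods=cfg.methods,
        ivw_effects=cfg.ivw_effects,
        n_boot=cfg.n_boot,
        presso_n_sim=cfg.presso_n_sim,
        seed=cfg.seed,
        alpha=cfg.alpha,
    )
    estimates = pd.DataFrame(
        [
            {
                "exposure": set_.exposure_name, "method": r.method, "nsnp": r.n_snp,
                "beta": r.beta, "se": r.se, "pval": r.pval,
                "or": r.or_point, "or_lo95": r.or_lower, "or_hi95": r.or_upper,
            }
            for r in results
        ]
    )
    include_presso = "mr_presso" in cfg.methods
    if not include_presso:
        log.append("MR-PRESSO not in configured methods; global test disabled")
        logger.info("MR-PRESSO disabled: not among configured methods")
    sens = sensitivity_report(set_, n_sim=cfg.presso_n_sim,
                              seed=0 if cfg.seed is None else cfg.seed,
                              include_presso=include_presso)
    loo = leave_one_out(set_).rows
    plots = plot_data(set_, results)
    log.append(f"estimated {len(results)} methods on {set_.n_snp} instruments")
    return ResultBundle(estimates, sens, loo, plots, cfg, log)


def render_report(bundle: ResultBundle, fmt: str = "tsv", output_dir=None) -> list[Path]:
    """Write the bundle as TSV tables, a JSON document, or a markdown report.

    Numeric columns are rounded to 5 decimals in TSV/markdown so the files
    are byte-stable across runs with the same config and seed.
    """
    outdir = Path(output_dir or bundle.config.output_dir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sens_rows = _sensitivity_table(bundle)
    if fmt == "tsv":
        est = bundle.estimates.copy()
        for c in ("beta", "se", "pval", "or", "or_lo95", "or_hi95"):
            est[c] = est[c].map(lambda v: f"{v:.5f}")
        p = outdir / "estimates.tsv"
        est.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / "sensitivity.tsv"
        sens_rows.to_csv(p, sep="\t", index=False, float_format="%.5f")
        written.append(p)
        p = outdir / "leave_one_out.tsv"
        bundle.loo.to_csv(p, sep="\t", index=False, float_format="%.5g")
        written.append(p)
    elif fmt == "json":
        p = outdir / "results.json"
        p.write_text(json.dumps(bundle.to_json_dict(), indent=2, sort_keys=True) + "\n")
        written.append(p)
    elif fmt == "markdown":
        p = outdir / "report.md"
        p.write_text(_markdown_report(bundle, sens_rows))
        written.append(p)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return written


def _sensitivity_table(bundle: ResultBundle) -> pd.DataFrame:
    sens = bundle.sensitivity
    name = bundle.estimates["exposure"].iloc[0] if len(bundle.estimates) else "exposure"
    tests = ["egger_intercept_pval", "q_egger_pval", "q_ivw_pval"]
    values = [sens["egger_intercept_pval"], sens["q_egger"].pval, sens["q_ivw"].pval]
    if sens["presso"] is not None:
        tests.append("presso_global_pval")
        values.append(sens["presso"].global_pval)
    return pd.DataFrame({"test": tests, name: values})


def combined_sensitivity_table(bundles: list[ResultBundle]) -> pd.DataFrame:
    """One sensitivity table with a column per exposure (report shape)."""
    tables = [_sensitivity_table(b).set_index("test") for b in bundles]
    return pd.concat(tables, axis=1).reset_index()


def _markdown_report(bundle: ResultBundle, sens_rows: pd.DataFrame) -> str:
    ivw_row = bundle.estimates[bundle.estimates["method"].str.startswith("ivw")]
    lines = [f"# MR report: {bundle.estimates['exposure'].iloc[0]}", ""]
    if len(ivw_row):
        r = ivw_row.iloc[0]
        lines.append(
            f"Primary (IVW) estimate: OR {r['or']:.3f} "
            f"(95% CI {r['or_lo95']:.3f}-{r['or_hi95']:.3f}), p = {r['pval']:.3f}."
        )
        lines.append("")
    lines.append("## Estimates")
    lines.append("")
    lines.append(_round_df(bundle.estimates, 5).to_markdown(index=False))
    lines.append("")
    lines.append("## Sensitivity")
    lines.append("")
    lines.append(_round_df(sens_rows, 5).to_markdown(index=False))
    lines.append("")
    return "\n".join(lines)
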