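"""End-to-end pipelines comparing three estimation methods.

Method A — design-based direct estimation on geocoded respondents only.
Method B — spatial smoothing of the method-A inputs (still geocode-complete
           cases only, so subject to missing-data bias).
Method C — spatial smoothing with multiple imputation of missing tracts, so
           every respondent with a zip contributes.

The tract pipeline emits per-area tables for all three methods, summary
statistics (min/max/median of prevalence and of credible/confidence
interval half-widths) and pairwise cross-method correlations.  The HRA
pipeline assigns every respondent a health reporting area first, then
reports direct and smoothed estimates side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit
from scipy.stats import pearsonr, spearmanr

from ._rng import spawn_seed
from .direct import direct_estimate, direct_interval, empirical_logit
from .geography import GeographyModel, generate_geography
from .mi import ImputationRun, assign_hra, pool_estimates, run_mi_smoothing
from .raking import rake_weights
from .smoothing import SmoothingResults, SmoothingSpec, fit_smoothing_model
from .survey import (
    SurveyConfig,
    apply_missingness,
    calibrate_missingness,
    population_margins,
    simulate_survey,
)
from .truth import TruthSurface, simulate_truth

__all__ = [
    "PipelineConfig",
    "MethodSummary",
    "ComparisonReport",
    "TractPipelineResults",
    "HraPipelineResults",
    "run_tract_pipeline",
    "run_hra_pipeline",
    "write_report",
]


@dataclass
class PipelineConfig:
    """Synthetic-run configuration; defaults mirror the motivating study's
    scale (396 tracts, 48 HRAs, ~16,000 respondents, 26% missing geocodes,
    90% intervals, 100 imputations)."""

    n_tracts: int = 396
    n_zips: int = 57
    n_hras: int = 48
    mu: float = float(logit(0.12))
    sigma_u: float = 0.35
    sigma_v: float = 0.15
    n_respondents: int = 16_000
    missing_target: float = 0.26
    total_population: float = 1_500_000.0
    smoothing: SmoothingSpec = dc_field(default_factory=SmoothingSpec)
    M: int = 100
    level: float = 0.90
    hra_threshold: float = 0.95
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        smooth = SmoothingSpec(**raw.pop("smoothing", {}))
        known = {f for f in cls.__dataclass_fields__ if f != "smoothing"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(smoothing=smooth, **raw)

    def echo(self) -> list[str]:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "smoothing"}
        lines = [f"config.{k} = {v}" for k, v in d.items()]
        lines += [f"config.smoothing.{k} = {getattr(self.smoothing, k)}"
                  for k in self.smoothing.__dataclass_fields__]
        return lines


@dataclass
class MethodSummary:
    method: str
    prev_min: float
    prev_max: float
    prev_median: float
    hw_min: float
    hw_max: float
    hw_median: float
    areas_reported: int
    areas_excluded: int

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "prev_min": self.prev_min,
            "prev_max": self.prev_max,
            "prev_median": self.prev_median,
            "hw_min": self.hw_min,
            "hw_max": self.hw_max,
            "hw_median": self.hw_median,
            "areas_reported": self.areas_reported,
            "areas_excluded": self.areas_excluded,
        }


def _summarize_method(method: str, table: pd.DataFrame, point: str,
                      hw_mask: np.ndarray | None = None) -> MethodSummary:
    p = table[point].to_numpy(float)
    reported = np.isfinite(p)
    hw = table["ci_half_width"].to_numpy(float)
    keep_hw = np.isfinite(hw) if hw_mask is None else (np.isfinite(hw) & hw_mask)
    return MethodSummary(
        method=method,
        prev_min=float(np.min(p[reported])),
        prev_max=float(np.max(p[reported])),
        prev_median=float(np.median(p[reported])),
        hw_min=float(np.min(hw[keep_hw])),
        hw_max=float(np.max(hw[keep_hw])),
        hw_median=float(np.median(hw[keep_hw])),
        areas_reported=int(reported.sum()),
        areas_excluded=int(reported.sum() - keep_hw.sum()),
    )


@dataclass
class ComparisonReport:
    """Pairwise correlations of per-area point estimates, plus the
    side-by-side table they were computed on."""

    correlations: pd.DataFrame  # columns: pair, pearson, spearman, n_areas
    table: pd.DataFrame


def _compare(columns: dict[str, pd.Series]) -> ComparisonReport:
    tab = pd.DataFrame(columns)
    names = list(columns)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sub = tab[[a, b]].dropna()
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "pearson": float(pearsonr(sub[a], sub[b])[0]),
                    "spearman": float(spearmanr(sub[a], sub[b])[0]),
                    "n_areas": len(sub),
                }
            )
    return ComparisonReport(correlations=pd.DataFrame(rows), table=tab.reset_index())


# ---------------------------------------------------------------------------
# Tract-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class TractPipelineResults:
    config: PipelineConfig
    geo: GeographyModel
    truth: TruthSurface
    respondents: pd.DataFrame
    weights: np.ndarray
    table_a: pd.DataFrame
    table_b: pd.DataFrame
    table_c: pd.DataFrame
    summaries: dict[str, MethodSummary]
    comparison: ComparisonReport
    fit_b: SmoothingResults
    mi_run: ImputationRun
    log: list[str]

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "method_a": self.table_a,
            "method_b": self.table_b,
            "method_c": self.table_c,
            "summaries": pd.DataFrame([s.as_row() for s in self.summaries.values()]),
            "correlations": self.comparison.correlations,
            "comparison": self.comparison.table,
        }
        out["truth"] = pd.DataFrame(
            {"area_id": self.truth.tract_ids, "p_true": self.truth.p_true}
        )
        return out


def _simulate_inputs(config: PipelineConfig):
    """Shared synthetic-data stage: geography, truth, survey, missingness,
    raking.  Sub-seeds 0-3 fix each stochastic stage separately."""
    log: list[str] = list(config.echo())
    geo = generate_geography(config.n_tracts, config.n_zips, config.n_hras,
                             seed=spawn_seed(config.seed, 0))
    truth = simulate_truth(geo, mu=config.mu, sigma_u=config.sigma_u,
                           sigma_v=config.sigma_v, seed=spawn_seed(config.seed, 1))
    survey_cfg = SurveyConfig()
    full = simulate_survey(truth, geo, config.n_respondents, survey_cfg,
                           seed=spawn_seed(config.seed, 2))
    if config.missing_target > 0:
        miss = calibrate_missingness(geo, survey_cfg, target_rate=config.missing_target)
        resp = apply_missingness(full, miss, seed=spawn_seed(config.seed, 3))
    else:
        resp = full
    margins = population_margins(geo, survey_cfg, total_population=config.total_population)
    raked = rake_weights(resp, margins)
    n_geo = int(resp["tract"].notna().sum())
    n_miss = int(resp["tract"].isna().sum())
    log += [
        f"seed.master = {config.seed}",
        *(f"seed.stage[{i}] = {spawn_seed(config.seed, i)}" for i in range(4)),
        f"respondents.total = {len(resp)}",
        f"respondents.geocoded = {n_geo}",
        f"respondents.missing_tract = {n_miss}",
        f"accounting.check = {n_geo} + {n_miss} = {n_geo + n_miss}",
        f"raking.iterations = {raked.iterations}",
        f"raking.max_deviation = {raked.max_deviation:.3e}",
    ]
    return geo, truth, resp, raked.weights, log


def run_tract_pipeline(config: PipelineConfig) -> TractPipelineResults:
    geo, truth, resp, weights, log = _simulate_inputs(config)
    level = config.level

    geocoded = resp["tract"].notna().to_numpy()
    directs = empirical_logit(
        direct_estimate(resp[geocoded], weights[geocoded], "tract", areas=geo.tract_ids)
    )
    table_a = direct_interval(directs, level=level)
    n_degen = int(directs["degenerate"].sum())
    log.append(f"method_a.degenerate_areas = {n_degen}")

    fit_b = fit_smoothing_model(directs, geo.tract_graph(), config.smoothing,
                                seed=spawn_seed(config.seed, 4))
    table_b = fit_b.estimates(level=level)
    log.append("method_b.ess = " + ", ".join(
        f"{k}={v:.0f}" for k, v in fit_b.effective_sample_sizes().items()))

    mi_run = run_mi_smoothing(resp, weights, geo, spec=config.smoothing, M=config.M,
                              seed=spawn_seed(config.seed, 5))
    table_c = pool_estimates(mi_run, level=level)
    log.append(f"method_c.M = {mi_run.M}")
    log += [f"method_c.sub_seed[{m}] = {s}" for m, s in enumerate(mi_run.sub_seeds)]

    summaries = {
        "A": _summarize_method("A", table_a, "p_hat",
                               hw_mask=~table_a["degenerate"].to_numpy(bool)),
        "B": _summarize_method("B", table_b, "median"),
        "C": _summarize_method("C", table_c, "median"),
    }
    comparison = _compare(
        {
            "A": table_a.set_index("area_id")["p_hat"],
            "B": table_b.set_index("area_id")["median"],
            "C": table_c.set_index("area_id")["median"],
        }
    )
    return TractPipelineResults(
        config=config, geo=geo, truth=truth, respondents=resp, weights=weights,
        table_a=table_a, table_b=table_b, table_c=table_c, summaries=summaries,
        comparison=comparison, fit_b=fit_b, mi_run=mi_run, log=log,
    )


# ---------------------------------------------------------------------------
# HRA-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class HraPipelineResults:
    config: PipelineConfig
    geo: GeographyModel
    truth: TruthSurface
    respondents: pd.DataFrame
    table: pd.DataFrame
    comparison: ComparisonReport
    fit: SmoothingResults
    log: list[str]

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"hra": self.table, "correlations": self.comparison.correlations}


def run_hra_pipeline(config: PipelineConfig) -> HraPipelineResults:
    geo, truth, resp, weights, log = _simulate_inputs(config)
    level = config.level

    resp_h = assign_hra(resp, geo, threshold=config.hra_threshold,
                        seed=spawn_seed(config.seed, 6))
    directs = empirical_logit(
        direct_estimate(resp_h, weights, "hra", areas=geo.hra_ids)
    )
    direct_tab = direct_interval(directs, level=level)
    fit = fit_smoothing_model(directs, geo.hra_graph(), config.smoothing,
                              seed=spawn_seed(config.seed, 7))
    smooth_tab = fit.estimates(level=level)

    table = pd.DataFrame(
        {
            "area_id": direct_tab["area_id"],
            "n": direct_tab["n"],
            "direct": direct_tab["p_hat"],
            "direct_lower": direct_tab["lower"],
            "direct_upper": direct_tab["upper"],
            "direct_hw": direct_tab["ci_half_width"],
            "smoothed": smooth_tab["median"].to_numpy(),
            "smoothed_lower": smooth_tab["lower"].to_numpy(),
            "smoothed_upper": smooth_tab["upper"].to_numpy(),
            "smoothed_hw": smooth_tab["ci_half_width"].to_numpy(),
            "level": level,
        }
    )
    comparison = _compare(
        {
            "direct": direct_tab.set_index("area_id")["p_hat"],
            "smoothed": smooth_tab.set_index("area_id")["median"],
        }
    )
    log.append(f"hra.seed = {spawn_seed(config.seed, 6)}")
    log.append("hra.ess = " + ", ".join(
        f"{k}={v:.0f}" for k, v in fit.effective_sample_sizes().items()))
    return HraPipelineResults(
        config=config, geo=geo, truth=truth, respondents=resp_h, table=table,
        comparison=comparison, fit=fit, log=log,
    )


def write_report(results, out_dir) -> list[Path]:
    """Write every results table as a delimited file plus a run log."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, tab in results.tables().items():
            p = out / f"{name}.csv"
            tab.to_csv(p, index=False)
            paths.append(p)
        logp = out / "run_log.txt"
        logp.write_text("\n".join(results.log) + "\n")
        paths.append(logp)
    except OSError as exc:
        raise RuntimeError(f"cannot write report to {out}: {exc}") from exc
    return paths
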