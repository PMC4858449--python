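"""Missing-geography handling: crosswalk imputation, pooling, HRA assignment.

Respondents with a known zip but no geocoded census tract are completed by
drawing a tract within the zip with probabilities equal to the crosswalk's
residential-address ratios.  Repeating the draw M times and re-running the
whole estimation chain on each completed data set (multiple imputation)
propagates the allocation uncertainty; the M posteriors are pooled as an
equally-weighted mixture of their prevalence-scale draws, so pooled
intervals widen exactly as the between-imputation spread dictates and the
M=1 case reduces to the single fit.

HRA (health reporting area) assignment is separate and single-shot: a
geocoded respondent takes their tract's HRA; others go deterministically to
the dominant HRA when one holds >= 95% of the zip's population, else by a
categorical draw over the zip's population shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import rng_from_seed, spawn_seed
from .direct import direct_estimate, empirical_logit
from .geography import GeographyModel
from .smoothing import SmoothingResults, SmoothingSpec, fit_smoothing_model

__all__ = [
    "allocate_missing",
    "ImputationRun",
    "run_mi_smoothing",
    "pool_estimates",
    "assign_hra",
]


def allocate_missing(
    respondents: pd.DataFrame,
    crosswalk: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Complete missing tracts by categorical draws from crosswalk ratios.

    Observed tracts are never altered.  Fails listing any zip of a
    missing-tract respondent that the crosswalk does not cover.
    """
    rng = rng_from_seed(seed)
    out = respondents.copy()
    out["tract"] = out["tract"].astype(object)  # may be all-NaN float on input
    missing = out["tract"].isna()
    if not missing.any():
        return out

    known_zips = set(crosswalk["zip"])
    offending = sorted(set(out.loc[missing, "zip"]) - known_zips)
    if offending:
        raise ValueError(f"zips absent from crosswalk: {offending}")

    by_zip = {
        z: (grp["tract"].to_numpy(object), grp["res_ratio"].to_numpy(float))
        for z, grp in crosswalk.groupby("zip", sort=False)
    }
    # draw zip by zip in sorted order for reproducibility independent of row order
    for z in sorted(set(out.loc[missing, "zip"])):
        rows = missing & (out["zip"] == z)
        tracts, ratios = by_zip[z]
        draws = rng.choice(len(tracts), size=int(rows.sum()), p=ratios / ratios.sum())
        out.loc[rows, "tract"] = tracts[draws]
    return out


@dataclass
class ImputationRun:
    """M completed data sets and their fitted smoothing models."""

    M: int
    completed: list[pd.DataFrame]
    fits: list[SmoothingResults]
    sub_seeds: list[int]

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if len(set(self.sub_seeds)) != len(self.sub_seeds):
            raise ValueError("sub-seeds must be distinct")
        for m, tab in enumerate(self.completed):
            if tab["tract"].isna().any():
                raise ValueError(f"imputation {m}: completed table still has missing tracts")


def run_mi_smoothing(
    respondents: pd.DataFrame,
    weights: np.ndarray,
    geo: GeographyModel,
    spec: SmoothingSpec | None = None,
    M: int = 100,
    seed: int = 0,
    adjacency: nx.Graph | None = None,
    areas: list[str] | None = None,
) -> ImputationRun:
    """Impute M times and re-fit the full chain on each completed data set.

    Raking weights are held fixed across imputations (only geography is
    re-drawn).  Sub-seed m drives both the m-th allocation and the m-th
    sampler, so any single imputation can be reproduced in isolation.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    spec = spec or SmoothingSpec()
    adjacency = adjacency if adjacency is not None else geo.tract_graph()
    areas = areas if areas is not None else list(geo.tract_ids)

    completed, fits, seeds = [], [], []
    for m in range(M):
        sub = spawn_seed(seed, m)
        try:
            comp = allocate_missing(respondents, geo.crosswalk, seed=sub)
            directs = empirical_logit(
                direct_estimate(comp, weights, area_field="tract", areas=areas)
            )
            fit = fit_smoothing_model(directs, adjacency, spec, seed=sub)
        except Exception as exc:
            raise RuntimeError(f"imputation {m} (sub-seed {sub}) failed: {exc}") from exc
        completed.append(comp)
        fits.append(fit)
        seeds.append(sub)
    return ImputationRun(M=M, completed=completed, fits=fits, sub_seeds=seeds)


def pool_estimates(run: ImputationRun, level: float = 0.90) -> pd.DataFrame:
    """Pool the M posteriors as an equal-weight mixture of prevalence draws.

    Per area: concatenate the retained prevalence-scale draws of all M fits
    and report the mixture median and equal-tailed interval.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    ids = run.fits[0].area_ids
    for fit in run.fits[1:]:
        if fit.area_ids != ids:
            raise ValueError("imputation fits do not cover identical areas")
    draws = np.concatenate([fit.prevalence_draws for fit in run.fits], axis=0)
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(draws, [alpha, 0.5, 1.0 - alpha], axis=0)
    return pd.DataFrame(
        {
            "area_id": ids,
            "median": med,
            "lower": lo,
            "upper": hi,
            "ci_half_width": (hi - lo) / 2.0,
            "level": level,
            "M": run.M,
        }
    )


def assign_hra(
    respondents: pd.DataFrame,
    geo: GeographyModel,
    threshold: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Give every respondent exactly one HRA.

    Geocoded respondents take their tract's HRA.  For the rest, a zip whose
    largest HRA population share meets ``threshold`` is assigned
    deterministically to that HRA; otherwise the HRA is drawn categorically
    with the zip's population shares.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    rng = rng_from_seed(seed)
    out = respondents.copy()
    out["hra"] = out["tract"].map(geo.tract_to_hra).astype(object)

    unassigned = out["hra"].isna()
    if not unassigned.any():
        return out
    shares = {
        z: (grp["hra"].to_numpy(object), grp["pop_share"].to_numpy(float))
        for z, grp in geo.hra_share.groupby("zip", sort=False)
    }
    missing_zip = sorted(set(out.loc[unassigned, "zip"]) - set(shares))
    if missing_zip:
        raise ValueError(f"zips with no hra_share rows: {missing_zip}")
    for z in sorted(set(out.loc[unassigned, "zip"])):
        rows = unassigned & (out["zip"] == z)
        hras, ps = shares[z]
        if ps.max() >= threshold:
            out.loc[rows, "hra"] = hras[int(np.argmax(ps))]
        else:
            draws = rng.choice(len(hras), size=int(rows.sum()), p=ps / ps.sum())
            out.loc[rows, "hra"] = hras[draws]
    return out
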