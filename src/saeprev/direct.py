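"""Design-based direct estimation per area, and the empirical-logit transform.

The direct (Horvitz–Thompson ratio) estimator of an area proportion is
p_hat = sum(w_i y_i) / sum(w_i) with the single-stage with-replacement
design variance

    var_p = sum w_i^2 (y_i - p_hat)^2 / (sum w_i)^2 .

The empirical logit theta_hat = log(p_hat / (1 - p_hat)) with delta-method
variance var_theta = var_p / (p_hat (1 - p_hat))^2 turns each area's
summary into a Gaussian working observation for the spatial model.  Areas
with p_hat in {0, 1}, zero design variance, or no respondents are flagged
degenerate: they contribute no working likelihood and are later estimated
purely from the spatial prior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import norm

__all__ = ["direct_estimate", "empirical_logit", "direct_interval", "DIRECT_COLUMNS"]

DIRECT_COLUMNS = ["area_id", "n", "p_hat", "var_p", "theta_hat", "var_theta", "degenerate"]


def direct_estimate(
    respondents: pd.DataFrame,
    weights: np.ndarray,
    area_field: str = "tract",
    areas: list[str] | None = None,
) -> pd.DataFrame:
    """Weighted prevalence and design variance per area.

    ``areas`` lists the areas to report; areas without respondents are
    emitted with n=0 and degenerate=True so the smoothing stage can still
    predict them.  Respondents with a null ``area_field`` are ignored.
    """
    w = np.asarray(weights, float)
    if len(w) != len(respondents):
        raise ValueError("weights must align with respondents")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    df = respondents.assign(_w=w)
    df = df[df[area_field].notna()]
    y = df["y"].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome y must be binary")

    rows = []
    for area, grp in df.groupby(area_field, sort=True):
        wi = grp["_w"].to_numpy(float)
        yi = grp["y"].to_numpy(float)
        sw = wi.sum()
        p = float(wi @ yi / sw)
        var = float(np.sum(wi**2 * (yi - p) ** 2) / sw**2)
        rows.append((area, len(grp), p, var))
    out = pd.DataFrame(rows, columns=["area_id", "n", "p_hat", "var_p"])

    if areas is not None:
        missing = [a for a in areas if a not in set(out["area_id"])]
        empty = pd.DataFrame(
            {"area_id": missing, "n": 0, "p_hat": np.nan, "var_p": np.nan}
        )
        out = (
            pd.concat([out, empty], ignore_index=True)
            .set_index("area_id")
            .loc[list(areas)]
            .reset_index()
        )
    out["degenerate"] = (
        (out["n"] == 0) | out["p_hat"].isin([0.0, 1.0]) | (out["var_p"] == 0.0)
    )
    out["theta_hat"] = np.nan
    out["var_theta"] = np.nan
    return out[DIRECT_COLUMNS]


def empirical_logit(directs: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Fill theta_hat and var_theta for non-degenerate areas.

    With ``strict=True`` any degenerate row is refused; by default such
    rows pass through with theta/var left empty for prediction-only
    handling downstream.
    """
    out = directs.copy()
    deg = out["degenerate"].to_numpy(bool)
    if strict and deg.any():
        bad = out.loc[deg, "area_id"].tolist()
        raise ValueError(f"empirical logit undefined for degenerate areas: {bad}")
    ok = ~deg
    p = out.loc[ok, "p_hat"].to_numpy(float)
    v = out.loc[ok, "var_p"].to_numpy(float)
    out.loc[ok, "theta_hat"] = logit(p)
    out.loc[ok, "var_theta"] = v / (p * (1.0 - p)) ** 2
    return out


def direct_interval(directs: pd.DataFrame, level: float = 0.90) -> pd.DataFrame:
    """Normal interval on the logit scale, back-transformed to prevalence.

    Adds lower/upper/ci_half_width columns; degenerate areas get NaNs.
    Logit-scale construction keeps the bounds inside (0, 1).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    from scipy.special import expit

    out = empirical_logit(directs)
    z = norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(out["var_theta"].to_numpy(float))
    th = out["theta_hat"].to_numpy(float)
    out["lower"] = expit(th - z * se)
    out["upper"] = expit(th + z * se)
    out["ci_half_width"] = (out["upper"] - out["lower"]) / 2.0
    return out
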