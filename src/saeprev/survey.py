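"""Synthetic survey sampling with informative selection and geocode missingness.

Emulates the features of a random-digit-dial health survey that matter to
the downstream estimators:

* unequal selection — each demographic category carries a relative
  inclusion intensity (older respondents over-represented, etc.); the base
  design weight is the inverse of the respondent's product intensity;
* outcome heterogeneity — categories shift the outcome's log-odds, so the
  unweighted county mean is biased under informative selection and raking
  has something to correct;
* covariate-dependent missingness of the small-area geocode — a logistic
  model on age, race and region blanks the census tract while the zip code
  is always retained, mirroring the observed pattern that geocode
  missingness concentrates among younger, nonwhite and southern
  respondents.

Respondents are carried as a pandas DataFrame with columns
``id, zip, tract, age, sex, race, region, y, base_weight``; a missing tract
is NaN in memory and an empty field on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._rng import rng_from_seed
from .geography import GeographyModel
from .truth import TruthSurface

__all__ = [
    "DemographicMargin",
    "SurveyConfig",
    "MissingnessConfig",
    "simulate_survey",
    "apply_missingness",
    "county_prevalence",
    "population_margins",
]

RESPONDENT_COLUMNS = ["id", "zip", "tract", "age", "sex", "race", "region", "y", "base_weight"]


@dataclass
class DemographicMargin:
    """One demographic variable: categories with population shares,
    relative selection intensities, and additive log-odds effects on the
    outcome."""

    name: str
    categories: list[str]
    pop_shares: np.ndarray
    intensities: np.ndarray
    logit_effects: np.ndarray

    def __post_init__(self) -> None:
        self.pop_shares = np.asarray(self.pop_shares, float)
        self.intensities = np.asarray(self.intensities, float)
        self.logit_effects = np.asarray(self.logit_effects, float)
        k = len(self.categories)
        if not (len(self.pop_shares) == len(self.intensities) == len(self.logit_effects) == k):
            raise ValueError(f"margin {self.name}: category/array length mismatch")
        if not np.isclose(self.pop_shares.sum(), 1.0):
            raise ValueError(f"margin {self.name}: pop_shares must sum to 1")
        if np.any(self.intensities <= 0):
            raise ValueError(f"margin {self.name}: intensities must be positive")


def default_margins() -> list[DemographicMargin]:
    return [
        DemographicMargin(
            "age",
            ["18-34", "35-49", "50-64", "65+"],
            pop_shares=[0.32, 0.27, 0.24, 0.17],
            intensities=[0.55, 0.85, 1.30, 1.70],
            logit_effects=[0.35, 0.15, 0.00, -0.45],
        ),
        DemographicMargin(
            "sex",
            ["female", "male"],
            pop_shares=[0.51, 0.49],
            intensities=[1.15, 0.85],
            logit_effects=[-0.12, 0.12],
        ),
        DemographicMargin(
            "race",
            ["white", "nonwhite"],
            pop_shares=[0.65, 0.35],
            intensities=[1.15, 0.75],
            logit_effects=[-0.08, 0.15],
        ),
    ]


@dataclass
class SurveyConfig:
    """Selection and outcome configuration for the survey generator.

    ``margins`` are sampled independently of each other and of geography;
    ``region`` is derived from the zip (southern half of the zip range), so
    it is informative about place, enters the raking margins, and drives
    part of the missingness model.
    """

    margins: list[DemographicMargin] = field(default_factory=default_margins)
    south_fraction: float = 0.5  # zips with index >= (1-frac)*n_zips are 'south'

    def margin(self, name: str) -> DemographicMargin:
        for m in self.margins:
            if m.name == name:
                return m
        raise KeyError(name)


def _south_zips(geo: GeographyModel, config: SurveyConfig) -> set[str]:
    n = len(geo.zip_ids)
    cut = int(np.ceil((1.0 - config.south_fraction) * n))
    return set(geo.zip_ids[cut:])


def simulate_survey(
    truth: TruthSurface,
    geo: GeographyModel,
    n: int,
    config: SurveyConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw ``n`` respondents.

    Tracts are sampled proportional to residential population; demographic
    categories proportional to population share x selection intensity
    (selection is independent across margins and of geography, so the
    product form is exact); ``y`` is Bernoulli with log-odds equal to the
    tract's true log-odds plus the respondent's demographic effects;
    ``base_weight`` is the inverse product intensity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SurveyConfig()
    rng = rng_from_seed(seed)

    pop = geo.tract_population()
    tract_idx = rng.choice(len(geo.tract_ids), size=n, p=pop.to_numpy() / pop.sum())
    tract = np.asarray(geo.tract_ids, object)[tract_idx]
    t2z = geo.tract_to_zip()
    zips = np.array([t2z[t] for t in tract], object)

    eta = logit(truth.p_true)[tract_idx].astype(float)
    intensity = np.ones(n)
    cols: dict[str, np.ndarray] = {}
    for m in config.margins:
        probs = m.pop_shares * m.intensities
        probs = probs / probs.sum()
        ci = rng.choice(len(m.categories), size=n, p=probs)
        cols[m.name] = np.asarray(m.categories, object)[ci]
        intensity *= m.intensities[ci]
        eta += m.logit_effects[ci]

    south = _south_zips(geo, config)
    region = np.where([z in south for z in zips], "south", "north")
    y = (rng.random(n) < expit(eta)).astype(int)

    order = ["id", "zip", "tract", *cols, "region", "y", "base_weight"]
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "zip": zips,
            "tract": tract,
            **cols,
            "region": region,
            "y": y,
            "base_weight": 1.0 / intensity,
        }
    )[order]


def county_prevalence(truth: TruthSurface, geo: GeographyModel,
                      config: SurveyConfig | None = None) -> float:
    """Exact population prevalence implied by the generator.

    Average over tracts (population-weighted) and the full product of
    demographic cells of inverse-logit(tract log-odds + cell effects).
    """
    config = config or SurveyConfig()
    pop = geo.tract_population().to_numpy()
    pop = pop / pop.sum()
    eta0 = logit(truth.p_true)
    total = 0.0
    for cell in product(*(range(len(m.categories)) for m in config.margins)):
        w = 1.0
        shift = 0.0
        for m, ci in zip(config.margins, cell):
            w *= m.pop_shares[ci]
            shift += m.logit_effects[ci]
        total += w * float(pop @ expit(eta0 + shift))
    return total


def population_margins(geo: GeographyModel, config: SurveyConfig | None = None,
                       total_population: float = 1_500_000.0):
    """Raking margins implied by the generator: the demographic margins plus
    a region margin derived from zip populations.  Returns a RakingMargins."""
    from .raking import RakingMargins

    config = config or SurveyConfig()
    margins: dict[str, dict[str, float]] = {}
    for m in config.margins:
        margins[m.name] = {
            c: float(s * total_population) for c, s in zip(m.categories, m.pop_shares)
        }
    south = _south_zips(geo, config)
    south_pop = sum(1.0 / len(geo.zip_ids) for z in geo.zip_ids if z in south)
    margins["region"] = {
        "south": float(south_pop * total_population),
        "north": float((1.0 - south_pop) * total_population),
    }
    return RakingMargins(margins)


# ---------------------------------------------------------------------------
# Geocode missingness
# ---------------------------------------------------------------------------


@dataclass
class MissingnessConfig:
    """Logistic model for P(census tract missing | covariates).

    ``coefficients`` maps column name -> {category: log-odds shift}; the
    intercept sets the overall level.  The zip code is never blanked.
    """

    intercept: float
    coefficients: dict[str, dict[str, float]] = field(default_factory=dict)

    def probabilities(self, respondents: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(respondents), self.intercept)
        for col, shifts in self.coefficients.items():
            eta += respondents[col].map(shifts).fillna(0.0).to_numpy(float)
        p = expit(eta)
        if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
            raise ValueError("missingness probabilities outside [0, 1]")
        return p


DEFAULT_MISSINGNESS_COEFS = {
    "age": {"18-34": 0.55, "35-49": 0.25, "50-64": 0.0, "65+": -0.30},
    "race": {"white": 0.0, "nonwhite": 0.55},
    "region": {"north": 0.0, "south": 0.40},
}


def calibrate_missingness(
    geo: GeographyModel,
    config: SurveyConfig | None = None,
    target_rate: float = 0.26,
    coefficients: dict[str, dict[str, float]] | None = None,
) -> MissingnessConfig:
    """Choose the intercept so the marginal missing fraction under the
    survey's selection-weighted covariate mix equals ``target_rate``
    (26% by default — the rate observed in the motivating survey)."""
    config = config or SurveyConfig()
    coefs = coefficients if coefficients is not None else DEFAULT_MISSINGNESS_COEFS

    # joint cell distribution actually sampled (selection-weighted shares)
    cells: list[tuple[float, float]] = [(1.0, 0.0)]
    for m in config.margins:
        if m.name not in coefs:
            continue
        probs = m.pop_shares * m.intensities
        probs = probs / probs.sum()
        cells = [
            (w * probs[ci], s + coefs[m.name].get(m.categories[ci], 0.0))
            for (w, s) in cells
            for ci in range(len(m.categories))
        ]
    if "region" in coefs:
        south = _south_zips(geo, config)
        frac_south = len(south) / len(geo.zip_ids)  # equal-population zips
        cells = [
            (w * f, s + coefs["region"].get(reg, 0.0))
            for (w, s) in cells
            for f, reg in ((frac_south, "south"), (1.0 - frac_south, "north"))
        ]
    weights = np.array([w for w, _ in cells])
    shifts = np.array([s for _, s in cells])

    def marginal(b0: float) -> float:
        return float(weights @ expit(b0 + shifts)) - target_rate

    intercept = brentq(marginal, -20.0, 20.0)
    return MissingnessConfig(intercept=float(intercept), coefficients=coefs)


def apply_missingness(
    respondents: pd.DataFrame,
    miss_config: MissingnessConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Blank the tract field at covariate-dependent rates; zip stays."""
    rng = rng_from_seed(seed)
    p = miss_config.probabilities(respondents)
    out = respondents.copy()
    mask = rng.random(len(out)) < p
    out.loc[mask, "tract"] = np.nan
    return out


def write_respondents(respondents: pd.DataFrame, path) -> None:
    respondents.to_csv(path, index=False, na_rep="")


def read_respondents(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"zip": str, "tract": str})
    return df
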