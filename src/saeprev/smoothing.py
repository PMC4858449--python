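"""Hierarchical Bayesian spatial smoothing of area-level prevalence.

Three-stage model on the empirical logits of the direct estimates:

* stage 1 (working likelihood):  theta_hat_i ~ Normal(eta_i, V_i), with the
  delta-method variance V_i treated as fixed;
* stage 2:  eta_i = mu + u_i + v_i, where u is an intrinsic conditional
  autoregressive (ICAR) effect on the area adjacency graph with precision
  tau_u on the pairwise differences, and v_i ~iid Normal(0, 1/tau_v) — the
  Besag–York–Mollié (BYM) structure; reduced forms with only one of the
  two effects are available;
* stage 3:  Gamma(shape, rate) hyperpriors on the precisions and a flat
  prior on mu.

Because the stage-1 variances are fixed, every full conditional is Gaussian
or Gamma and the posterior is sampled by a Gibbs sampler.  The whole ICAR
field is drawn in one block from its Gaussian full conditional (a dense
Cholesky solve — cheap at the few-hundred-area scale this targets, and
essential for mixing: single-site updates crawl along the (u, tau_u)
ridge), then re-centred to sum to zero each sweep with the removed mean
absorbed into mu so the linear predictor is unchanged.

Areas flagged degenerate (no respondents, or p_hat in {0,1}) carry no
stage-1 term; their eta draws come from the spatial/unstructured prior
conditioned on the rest of the map, which is how the model produces strictly
positive prevalence estimates for areas whose direct estimate is 0%.

Usage follows the model/results pattern::

    model = PrevalenceSmoother(directs, adjacency, spec)
    fit = model.fit(seed=1)
    fit.estimates(level=0.90)   # per-area medians and credible intervals
    fit.cpo()                   # leave-one-out predictive diagnostics
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit, logsumexp

from ._rng import rng_from_seed

__all__ = [
    "SmoothingSpec",
    "PrevalenceSmoother",
    "SmoothingResults",
    "fit_smoothing_model",
    "compute_cpo",
    "select_model",
    "summarize",
]

logger = logging.getLogger(__name__)

STRUCTURES = ("iid_only", "icar_only", "icar_plus_iid")
_COMPLEXITY = {s: i for i, s in enumerate(STRUCTURES)}


@dataclass(frozen=True)
class SmoothingSpec:
    """Model structure, hyperpriors and sampler settings.

    Defaults: BYM structure, vague Gamma(0.5, 0.0005) priors on both
    precisions, 20,000 iterations with 5,000 burn-in thinned by 5, and 90%
    intervals.  ``fixed_tau_u`` / ``fixed_tau_v`` pin a precision instead of
    sampling it (useful for closed-form checks).
    """

    effect_structure: str = "icar_plus_iid"
    prior_shape: float = 0.5
    prior_rate: float = 0.0005
    iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 5
    level: float = 0.90
    fixed_tau_u: float | None = None
    fixed_tau_v: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.effect_structure not in STRUCTURES:
            raise ValueError(f"effect_structure must be one of {STRUCTURES}")
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be strictly inside (0, 1)")
        if self.prior_shape <= 0 or self.prior_rate <= 0:
            raise ValueError("Gamma hyperprior shape and rate must be positive")

    @property
    def has_icar(self) -> bool:
        return self.effect_structure in ("icar_only", "icar_plus_iid")

    @property
    def has_iid(self) -> bool:
        return self.effect_structure in ("iid_only", "icar_plus_iid")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


class PrevalenceSmoother:
    """Spatial smoothing model for area-level direct estimates.

    Parameters
    ----------
    directs : DataFrame
        Output of :func:`saeprev.direct.empirical_logit` — one row per area
        with theta_hat, var_theta and the degenerate flag.  Degenerate areas
        are retained for prediction.
    adjacency : networkx.Graph or None
        Area adjacency; node labels must cover every area_id.  May be None
        for the iid_only structure.
    spec : SmoothingSpec
    """

    def __init__(self, directs: pd.DataFrame, adjacency: nx.Graph | None,
                 spec: SmoothingSpec | None = None):
        self.spec = spec or SmoothingSpec()
        self.directs = directs.reset_index(drop=True)
        self.area_ids = list(self.directs["area_id"])
        n = len(self.area_ids)
        if len(set(self.area_ids)) != n:
            raise ValueError("duplicate area_id in direct estimates")

        deg = self.directs["degenerate"].to_numpy(bool)
        theta = self.directs["theta_hat"].to_numpy(float)
        V = self.directs["var_theta"].to_numpy(float)
        if np.any(~deg & ~(V > 0)):
            bad = [a for a, d, v in zip(self.area_ids, deg, V) if not d and not v > 0]
            raise ValueError(f"non-degenerate areas with non-positive var_theta: {bad}")
        if np.any(~deg & ~np.isfinite(theta)):
            raise ValueError("non-degenerate area with non-finite theta_hat")
        if (~deg).sum() < 1:
            raise ValueError("need at least one non-degenerate area")
        self.degenerate = deg
        self.theta = np.where(deg, 0.0, theta)
        self.V = np.where(deg, np.inf, V)
        self.prec_data = np.where(deg, 0.0, 1.0 / self.V)

        if self.spec.has_icar:
            if adjacency is None:
                raise ValueError("adjacency graph required for ICAR structures")
            missing = [a for a in self.area_ids if a not in adjacency]
            if missing:
                raise ValueError(f"areas absent from adjacency graph: {missing}")
            g = adjacency.subgraph(self.area_ids)
            if n > 1 and not nx.is_connected(g):
                raise ValueError("adjacency graph must be connected over the modelled areas")
            A = nx.to_scipy_sparse_array(g, nodelist=self.area_ids, format="csr", dtype=float)
            self._A = A
            self._degree = np.asarray(A.sum(axis=1)).ravel()
            coo = sparse.triu(A, k=1).tocoo()
            self._edge_i, self._edge_j = coo.row, coo.col
            # dense Laplacian for the blocked u-update; the target scale is
            # a few hundred areas, where an O(n^3) Cholesky per sweep is cheap
            self._laplacian = np.diag(self._degree) - A.toarray()
        else:
            self._A = None

    # -- sampling ----------------------------------------------------------

    def fit(self, seed: int | np.random.Generator | None = None) -> "SmoothingResults":
        """Run the Gibbs sampler and return retained draws."""
        spec = self.spec
        rng = rng_from_seed(spec.seed if seed is None else seed)
        n = len(self.area_ids)
        P = self.prec_data
        theta = self.theta
        a, b = spec.prior_shape, spec.prior_rate

        nondeg = ~self.degenerate
        mu = float(theta[nondeg].mean())
        resid_var = float(np.var(theta[nondeg])) if nondeg.sum() > 1 else 1.0
        tau0 = 1.0 / max(resid_var, 1e-3)
        u = np.zeros(n)
        v = np.zeros(n)
        tau_u = spec.fixed_tau_u if spec.fixed_tau_u is not None else tau0
        tau_v = spec.fixed_tau_v if spec.fixed_tau_v is not None else tau0

        T = spec.n_retained
        mu_d = np.empty(T)
        u_d = np.empty((T, n)) if spec.has_icar else None
        v_d = np.empty((T, n)) if spec.has_iid else None
        tau_u_d = np.empty(T) if spec.has_icar else None
        tau_v_d = np.empty(T) if spec.has_iid else None

        k = 0
        for it in range(1, spec.iterations + 1):
            if spec.has_iid:
                prec = P + tau_v
                mean = P * (theta - mu - u) / prec
                v = mean + rng.standard_normal(n) / np.sqrt(prec)

            if spec.has_icar:
                # blocked draw of the whole field: u | rest ~ N(Q^-1 b, Q^-1),
                # Q = tau_u L + diag(P).  Single-site sweeps mix far too
                # slowly along the (u, tau_u) ridge; the joint draw does not.
                Q = tau_u * self._laplacian + np.diag(P)
                b_vec = P * (theta - mu - v)
                c, low = cho_factor(Q, lower=True, check_finite=False)
                mean = cho_solve((c, low), b_vec, check_finite=False)
                noise = solve_triangular(
                    c, rng.standard_normal(n), lower=True, trans="T", check_finite=False
                )
                u = mean + noise
                shift = u.mean()
                u -= shift
                mu += shift

            prec_mu = P.sum()
            mean_mu = float(P @ (theta - u - v)) / prec_mu
            mu = mean_mu + rng.standard_normal() / np.sqrt(prec_mu)

            if spec.has_icar and spec.fixed_tau_u is None:
                ss_u = float(np.sum((u[self._edge_i] - u[self._edge_j]) ** 2))
                tau_u = rng.gamma(a + 0.5 * (n - 1), 1.0 / (b + 0.5 * ss_u))
            if spec.has_iid and spec.fixed_tau_v is None:
                tau_v = rng.gamma(a + 0.5 * n, 1.0 / (b + 0.5 * float(v @ v)))

            if it > spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
                if not (np.isfinite(mu) and np.isfinite(u).all() and np.isfinite(v).all()):
                    raise RuntimeError(
                        f"sampler diverged at iteration {it}: non-finite state "
                        f"(mu={mu!r}, tau_u={tau_u!r}, tau_v={tau_v!r})"
                    )
                mu_d[k] = mu
                if u_d is not None:
                    u_d[k] = u
                    tau_u_d[k] = tau_u
                if v_d is not None:
                    v_d[k] = v
                    tau_v_d[k] = tau_v
                k += 1

        return SmoothingResults(
            model=self,
            spec=spec,
            area_ids=self.area_ids,
            mu_draws=mu_d,
            u_draws=u_d,
            v_draws=v_d,
            tau_u_draws=tau_u_d,
            tau_v_draws=tau_v_d,
        )


@dataclass
class SmoothingResults:
    """Retained posterior draws plus derived summaries and diagnostics."""

    model: PrevalenceSmoother
    spec: SmoothingSpec
    area_ids: list[str]
    mu_draws: np.ndarray
    u_draws: np.ndarray | None
    v_draws: np.ndarray | None
    tau_u_draws: np.ndarray | None
    tau_v_draws: np.ndarray | None
    _cpo_cache: tuple | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return len(self.mu_draws)

    @property
    def eta_draws(self) -> np.ndarray:
        """(draws, areas) linear predictors."""
        eta = np.tile(self.mu_draws[:, None], (1, len(self.area_ids)))
        if self.u_draws is not None:
            eta = eta + self.u_draws
        if self.v_draws is not None:
            eta = eta + self.v_draws
        return eta

    @property
    def prevalence_draws(self) -> np.ndarray:
        return expit(self.eta_draws)

    # -- per-area summaries ------------------------------------------------

    def estimates(self, level: float | None = None) -> pd.DataFrame:
        """Posterior median and equal-tailed interval per area, on the
        prevalence scale."""
        level = self.spec.level if level is None else level
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.n_draws < 100:
            raise ValueError(
                f"only {self.n_draws} retained draws; need >= 100 for stable quantiles"
            )
        p = self.prevalence_draws
        alpha = (1.0 - level) / 2.0
        lo, med, hi = np.quantile(p, [alpha, 0.5, 1.0 - alpha], axis=0)
        return pd.DataFrame(
            {
                "area_id": self.area_ids,
                "median": med,
                "lower": lo,
                "upper": hi,
                "ci_half_width": (hi - lo) / 2.0,
                "level": level,
            }
        )

    # -- model comparison --------------------------------------------------

    def cpo(self) -> tuple[pd.DataFrame, float]:
        """Conditional predictive ordinates via the harmonic-mean identity.

        CPO_i = [ mean_t 1/N(theta_i | eta_i^(t), V_i) ]^-1 over retained
        draws, for non-degenerate areas only.  Draws where the density
        underflows to zero are excluded with a logged count.
        """
        if self._cpo_cache is not None:
            return self._cpo_cache
        m = self.model
        keep = ~m.degenerate
        eta = self.eta_draws[:, keep]
        theta, V = m.theta[keep], m.V[keep]
        logf = -0.5 * (np.log(2.0 * np.pi * V) + (theta - eta) ** 2 / V)
        finite = np.isfinite(logf)
        n_bad = int((~finite).sum())
        if n_bad:
            logger.warning("CPO: excluded %d non-finite density evaluations", n_bad)
        logf = np.where(finite, logf, np.inf)  # exp(-inf) = 0 drops the draw
        counts = finite.sum(axis=0)
        if np.any(counts == 0):
            raise RuntimeError("CPO undefined: all draws excluded for at least one area")
        log_cpo = np.log(counts) - logsumexp(-logf, axis=0)
        df = pd.DataFrame(
            {"area_id": np.asarray(self.area_ids, object)[keep], "cpo": np.exp(log_cpo)}
        )
        self._cpo_cache = (df, float(log_cpo.sum()))
        return self._cpo_cache

    @property
    def sum_log_cpo(self) -> float:
        return self.cpo()[1]

    # -- diagnostics -------------------------------------------------------

    def effective_sample_sizes(self) -> dict[str, float]:
        import arviz as az

        out = {"mu": float(az.ess(self.mu_draws[None, :]))}
        if self.tau_u_draws is not None:
            out["tau_u"] = float(az.ess(self.tau_u_draws[None, :]))
        if self.tau_v_draws is not None:
            out["tau_v"] = float(az.ess(self.tau_v_draws[None, :]))
        return out

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of a regression results table."""
        ess = self.effective_sample_sizes()
        lines = [
            "Spatial prevalence smoothing (Gibbs)",
            f"  structure      : {self.spec.effect_structure}",
            f"  areas          : {len(self.area_ids)} "
            f"({int(self.model.degenerate.sum())} prediction-only)",
            f"  retained draws : {self.n_draws} "
            f"(of {self.spec.iterations}, burn-in {self.spec.burn_in}, thin {self.spec.thinning})",
            f"  posterior mu   : {np.median(self.mu_draws):.4f} "
            f"[{np.quantile(self.mu_draws, 0.05):.4f}, {np.quantile(self.mu_draws, 0.95):.4f}]",
        ]
        if self.tau_u_draws is not None:
            lines.append(f"  median tau_u   : {np.median(self.tau_u_draws):.3f}")
        if self.tau_v_draws is not None:
            lines.append(f"  median tau_v   : {np.median(self.tau_v_draws):.3f}")
        lines.append(f"  sum log CPO    : {self.sum_log_cpo:.3f}")
        lines.append("  ESS            : " + ", ".join(f"{k}={v:.0f}" for k, v in ess.items()))
        return "\n".join(lines)

    def save_draws(self, path) -> None:
        """Persist prevalence-scale draws as a delimited table (areas as columns)."""
        pd.DataFrame(self.prevalence_draws, columns=self.area_ids).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_smoothing_model(
    directs: pd.DataFrame,
    adjacency: nx.Graph | None,
    spec: SmoothingSpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> SmoothingResults:
    return PrevalenceSmoother(directs, adjacency, spec).fit(seed=seed)


def compute_cpo(fit: SmoothingResults, directs: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """CPO per non-degenerate area and the summed log, after checking the
    fit was produced from these direct estimates."""
    if list(directs["area_id"]) != fit.area_ids:
        raise ValueError("direct estimates do not match the fitted areas")
    th = directs["theta_hat"].to_numpy(float)
    keep = ~directs["degenerate"].to_numpy(bool)
    if not np.allclose(th[keep], fit.model.theta[keep]):
        raise ValueError("direct estimates do not match the data the model was fitted to")
    return fit.cpo()


def select_model(fits: list[tuple[SmoothingSpec, SmoothingResults]]) -> SmoothingSpec:
    """Pick the spec with the highest sum of log CPOs; exact ties go to the
    simpler structure (iid_only < icar_only < icar_plus_iid)."""
    if len(fits) < 2:
        raise ValueError("need at least two candidate fits")
    ref = fits[0][1]
    for _, fit in fits[1:]:
        if fit.area_ids != ref.area_ids or not np.allclose(
            fit.model.theta, ref.model.theta
        ) or not (fit.model.degenerate == ref.model.degenerate).all():
            raise ValueError("candidate fits were not computed on identical data")
    scored = [(fit.sum_log_cpo, -_COMPLEXITY[spec.effect_structure], spec) for spec, fit in fits]
    scored.sort(key=lambda t: (t[0], t[1]), reverse=True)
    return scored[0][2]


def summarize(fit: SmoothingResults, level: float) -> pd.DataFrame:
    """Per-area posterior medians and equal-tailed credible intervals."""
    return fit.estimates(level=level)
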