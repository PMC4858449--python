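"""True prevalence surfaces on the tract graph.

The generating model matches the smoothing model's second stage: on the
logit scale each tract gets an intercept ``mu``, a spatially structured
effect ``u`` drawn from an intrinsic conditional autoregressive (ICAR) law
on the adjacency graph, and an unstructured effect ``v`` drawn i.i.d.
normal.  The ICAR draw is taken from the pseudo-inverse of the graph
Laplacian — eigendecompose L = D - A, drop the null space (the constant
vector), scale the remaining directions by 1/sqrt(eigenvalue), and
re-centre to sum zero.  ``sigma_u`` therefore scales the pairwise-difference
structure (Var = sigma_u^2 * L^+), the same convention the Gibbs sampler
uses for its precision tau_u = 1/sigma_u^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import expit, logit

from ._rng import rng_from_seed
from .geography import GeographyModel

__all__ = ["TruthSurface", "simulate_truth"]


@dataclass
class TruthSurface:
    """Per-tract true prevalence and its logit-scale components."""

    tract_ids: list[str]
    mu: float
    u: np.ndarray
    v: np.ndarray
    p_true: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.u.sum()) > 1e-9 * max(1.0, np.abs(self.u).max()):
            raise ValueError("spatial effect u must sum to zero")
        recon = expit(self.mu + self.u + self.v)
        if not np.allclose(recon, self.p_true, atol=1e-12):
            raise ValueError("p_true must equal inverse-logit(mu + u + v)")

    @property
    def eta(self) -> np.ndarray:
        return self.mu + self.u + self.v


def icar_draw(graph: nx.Graph, nodelist: list, sigma: float,
              rng: np.random.Generator) -> np.ndarray:
    """One zero-centred ICAR realisation with Var = sigma^2 L^+."""
    n = len(nodelist)
    if n == 1:
        return np.zeros(1)
    lap = nx.laplacian_matrix(graph, nodelist=nodelist).toarray().astype(float)
    evals, evecs = np.linalg.eigh(lap)
    pos = evals > 1e-10 * evals.max()
    if pos.sum() != n - 1:
        raise ValueError("ICAR draw undefined: adjacency graph is disconnected")
    z = rng.standard_normal(int(pos.sum()))
    u = sigma * (evecs[:, pos] / np.sqrt(evals[pos])) @ z
    return u - u.mean()


def simulate_truth(
    geo: GeographyModel,
    mu: float = float(logit(0.12)),
    sigma_u: float = 0.35,
    sigma_v: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> TruthSurface:
    """Draw a true prevalence surface over the geography's tracts.

    Defaults give a county-level prevalence near 12% — the order of adult
    smoking prevalence the model is meant for — with spatial structure
    strong enough that neighbouring tracts are informative about each other
    (sigma_u about twice sigma_v).
    """
    if sigma_u < 0 or sigma_v < 0:
        raise ValueError("sigma_u and sigma_v must be non-negative")
    rng = rng_from_seed(seed)
    n = len(geo.tract_ids)
    if sigma_u > 0:
        u = icar_draw(geo.tract_graph(), geo.tract_ids, sigma_u, rng)
    else:
        if n > 1 and not nx.is_connected(geo.tract_graph()):
            raise ValueError("ICAR draw undefined: adjacency graph is disconnected")
        u = np.zeros(n)
    v = sigma_v * rng.standard_normal(n)
    p = expit(mu + u + v)
    return TruthSurface(tract_ids=list(geo.tract_ids), mu=float(mu), u=u, v=v, p_true=p)
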