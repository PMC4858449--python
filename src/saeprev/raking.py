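"""Survey weight raking by iterative proportional fitting (IPF).

Starting from the base design weights, each margin's categories are scaled
in turn so the weighted sample totals match known population totals;
sweeps repeat until every margin is reproduced within tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RakingMargins", "RakingResult", "rake_weights"]


class RakingMargins:
    """Ordered raking margins: name -> {category: population total}.

    All margins must share the same grand total (each partitions the same
    population), checked to 1e-6 relative.
    """

    def __init__(self, margins: dict[str, dict[str, float]]):
        if not margins:
            raise ValueError("at least one margin required")
        self.margins = {
            name: {str(c): float(t) for c, t in cats.items()} for name, cats in margins.items()
        }
        totals = {name: sum(cats.values()) for name, cats in self.margins.items()}
        for name, cats in self.margins.items():
            if any(t <= 0 for t in cats.values()):
                raise ValueError(f"margin {name}: population totals must be positive")
        grand = next(iter(totals.values()))
        for name, t in totals.items():
            if abs(t - grand) > 1e-6 * grand:
                raise ValueError(
                    f"margin {name} grand total {t} differs from {grand} beyond 1e-6 relative"
                )
        self.grand_total = grand

    def __iter__(self):
        return iter(self.margins.items())

    def __len__(self) -> int:
        return len(self.margins)


@dataclass
class RakingResult:
    weights: np.ndarray
    iterations: int
    max_deviation: float  # worst relative margin error at exit
    converged: bool


def rake_weights(
    respondents: pd.DataFrame,
    margins: RakingMargins,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> RakingResult:
    """Iterative proportional fitting from ``base_weight``.

    Raises if a margin category with a positive population target has no
    respondents, or if the worst relative margin deviation still exceeds
    ``tol`` after ``max_iter`` sweeps.
    """
    w = respondents["base_weight"].to_numpy(float).copy()
    if np.any(w <= 0):
        raise ValueError("base weights must be positive")

    codes: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for name, cats in margins:
        if name not in respondents.columns:
            raise ValueError(f"margin {name}: column missing from respondents")
        cat_list = list(cats)
        targets = np.array([cats[c] for c in cat_list])
        code = pd.Categorical(
            respondents[name].astype(str), categories=cat_list
        ).codes.astype(np.intp)
        if np.any(code < 0):
            seen = set(respondents[name].astype(str)) - set(cat_list)
            raise ValueError(f"margin {name}: sample categories {sorted(seen)} not in margin")
        present = np.bincount(code, minlength=len(cat_list)) > 0
        empty = [c for c, ok in zip(cat_list, present) if not ok]
        if empty:
            raise ValueError(
                f"margin {name}: no respondents in categor{'y' if len(empty)==1 else 'ies'} "
                f"{empty} with nonzero population target"
            )
        codes[name] = (code, targets, len(cat_list))

    def worst_dev(wts: np.ndarray) -> float:
        dev = 0.0
        for code, targets, k in codes.values():
            cur = np.bincount(code, weights=wts, minlength=k)
            dev = max(dev, float(np.max(np.abs(cur - targets) / targets)))
        return dev

    it = 0
    for it in range(1, max_iter + 1):
        for code, targets, k in codes.values():
            cur = np.bincount(code, weights=w, minlength=k)
            w *= (targets / cur)[code]
        if worst_dev(w) < tol:
            return RakingResult(w, it, worst_dev(w), True)
    dev = worst_dev(w)
    raise RuntimeError(
        f"raking did not converge in {max_iter} sweeps; residual relative deviation {dev:.3e}"
    )
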