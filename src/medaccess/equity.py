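"""Lorenz curve and Gini coefficient of healthcare resources vs. population.

Spatial units (sub-districts) are ordered by per-capita resource (beds per
person) ascending; the Lorenz curve plots cumulative population share against
cumulative resource share, and the Gini coefficient is the trapezoidal
complement  G = 1 - sum_i (P_i - P_{i-1})(R_i + R_{i-1}).  A three-class
labeling flags districts as relatively reasonable (G < 0.40), relatively
large gap (0.40 <= G < 0.50) or highly unequal (G >= 0.50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABEL_REASONABLE = "Relatively Reasonable"
LABEL_LARGE_GAP = "Relatively Large Gap"
LABEL_HIGHLY_UNEQUAL = "Highly Unequal"


@dataclass
class LorenzCurve:
    """Cumulative (population, resource) shares, endpoints (0,0) and (1,1)."""

    p: np.ndarray  # cumulative population share, p[0] = 0, p[-1] = 1
    r: np.ndarray  # cumulative resource share
    order: np.ndarray  # unit indices in ascending per-capita order

    @property
    def n(self) -> int:
        return len(self.p) - 1


def lorenz(units: Sequence[tuple[float, float]]) -> LorenzCurve:
    """Lorenz curve of (population, resource) units.

    Units with zero population and zero resource are dropped (logged); a unit
    with resource but no population has undefined per-capita share and is
    rejected.
    """
    pop = np.asarray([u[0] for u in units], dtype=float)
    res = np.asarray([u[1] for u in units], dtype=float)
    if np.any(pop < 0) or np.any(res < 0):
        raise ValueError("populations and resources must be nonnegative")
    if np.any((pop == 0) & (res > 0)):
        raise ValueError("unit with zero population but positive resource: per-capita undefined")
    drop = (pop == 0) & (res == 0)
    if drop.any():
        logger.warning("dropping %d zero-population, zero-resource units", int(drop.sum()))
    keep = np.flatnonzero(~drop)
    pop, res = pop[keep], res[keep]
    if pop.sum() <= 0:
        raise ValueError("total population must be positive")
    if res.sum() <= 0:
        raise ValueError("all resources are zero")
    idx = np.argsort(res / pop, kind="stable")  # ascending per-capita resource
    order = keep[idx]
    pp, pc = pop[idx], res[idx]
    p = np.concatenate([[0.0], np.cumsum(pp) / pp.sum()])
    r = np.concatenate([[0.0], np.cumsum(pc) / pc.sum()])
    p[-1], r[-1] = 1.0, 1.0  # exact endpoints
    return LorenzCurve(p, r, order)


def gini(curve: LorenzCurve) -> float:
    """Trapezoidal Gini: G = 1 - sum (P_i - P_{i-1}) (R_i + R_{i-1})."""
    dp = np.diff(curve.p)
    return float(1.0 - np.sum(dp * (curve.r[1:] + curve.r[:-1])))


def classify_equity(g: float) -> str:
    """Three-class equity label from the Gini coefficient."""
    if not (0.0 <= g < 1.0):
        raise ValueError("Gini coefficient must lie in [0, 1)")
    if g < 0.40:
        return LABEL_REASONABLE
    if g < 0.50:
        return LABEL_LARGE_GAP
    return LABEL_HIGHLY_UNEQUAL


@dataclass
class GiniReport:
    G: float
    label: str
    table: pd.DataFrame  # per-unit population, resource, per-capita


def gini_report(
    units: Sequence[tuple[float, float]], ids: Sequence | None = None
) -> GiniReport:
    """Convenience wrapper: Lorenz -> Gini -> classification + per-unit table."""
    curve = lorenz(units)
    g = gini(curve)
    ids = list(range(len(units))) if ids is None else list(ids)
    pop = np.array([u[0] for u in units], dtype=float)
    res = np.array([u[1] for u in units], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = np.where(pop > 0, res / np.where(pop > 0, pop, 1.0), np.nan)
    table = pd.DataFrame(
        {"unit": ids, "population": pop, "resource": res, "per_capita": pc}
    )
    return GiniReport(g, classify_equity(g), table)
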