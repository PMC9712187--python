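"""Potential impact fraction (PIF) computation.

For an outcome with relative-risk curve RR(x) and a stratum whose UPF
energy share is distributed as P(x) at baseline and P'(x) under a
counterfactual scenario,

    PIF = [ int_0^m RR(x) P(x) dx  -  int_0^m RR(x) P'(x) dx ]
          / int_0^m RR(x) P(x) dx

i.e. the proportional reduction in expected relative risk when the
exposure distribution shifts.  The population attributable fraction (PAF)
is the special case where the counterfactual is a point mass at the TMREL.

Integrals are evaluated by composite trapezoid on a uniform grid.  Point
masses bypass quadrature (closed form).  Truncated densities (the
first-quintile counterfactual) are integrated on a 10x refined grid
aligned to their support, because the density's jump at the truncation
point otherwise breaks the error cancellation between numerator and
denominator that makes the default 0.1% grid accurate to ~1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import RRCurve
from .exposure_model import ExposureDistribution, Scenario, Stratum

__all__ = ["PIFResult", "compute_pif", "attributable_fraction", "mean_rr"]

DEFAULT_GRID_STEP = 0.1
DEFAULT_UPPER_LIMIT = 100.0
#: grid refinement applied over truncated supports
_TRUNC_REFINE = 10


def _support_grid(bound: float, step: float) -> np.ndarray:
    """Uniform grid [0, step, 2*step, ...] capped exactly at ``bound``."""
    n = int(np.floor(bound / step + 1e-12))
    grid = np.arange(n + 1) * step
    if grid[-1] < bound - 1e-12:
        grid = np.append(grid, bound)
    else:
        grid[-1] = bound
    return grid


def mean_rr(
    curve: RRCurve,
    dist: ExposureDistribution,
    grid_step: float = DEFAULT_GRID_STEP,
    m: float = DEFAULT_UPPER_LIMIT,
) -> float:
    """Population-average relative risk int_0^m RR(x) dP(x)."""
    if dist.family == "point_mass":
        return float(curve(min(dist.location, m)))
    bound = min(dist.upper, m)
    step = grid_step if dist.upper >= m else grid_step / _TRUNC_REFINE
    grid = _support_grid(bound, step)
    return float(np.trapezoid(curve(grid) * dist.pdf(grid), grid))


@dataclass(frozen=True)
class PIFResult:
    """PIF for one outcome x stratum x scenario cell."""

    outcome: str
    stratum: Stratum | None
    scenario: Scenario | None
    pif: float
    grid_step: float = DEFAULT_GRID_STEP
    upper_limit: float = DEFAULT_UPPER_LIMIT


def compute_pif(
    curve: RRCurve,
    baseline: ExposureDistribution,
    counterfactual: ExposureDistribution,
    grid_step: float = DEFAULT_GRID_STEP,
    m: float = DEFAULT_UPPER_LIMIT,
    stratum: Stratum | None = None,
    scenario: Scenario | None = None,
) -> PIFResult:
    """Potential impact fraction of moving ``baseline`` to ``counterfactual``.

    Both point masses: closed form 1 - RR(x') / RR(x).  Identical
    distributions give exactly 0.  PIF <= 1 always; PIF >= 0 whenever the
    counterfactual is stochastically below baseline.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if m <= 0:
        raise ValueError("upper integration limit must be positive")
    if baseline == counterfactual:
        pif = 0.0
    else:
        denom = mean_rr(curve, baseline, grid_step, m)
        if denom <= 0 or not np.isfinite(denom):
            raise ArithmeticError(
                f"non-positive baseline mean RR ({denom}); invalid inputs"
            )
        numer = mean_rr(curve, counterfactual, grid_step, m)
        pif = 1.0 - numer / denom
    return PIFResult(curve.spec.outcome, stratum, scenario, pif, grid_step, m)


def attributable_fraction(
    curve: RRCurve,
    baseline: ExposureDistribution,
    grid_step: float = DEFAULT_GRID_STEP,
    m: float = DEFAULT_UPPER_LIMIT,
    stratum: Stratum | None = None,
) -> PIFResult:
    """PAF: the PIF against a point-mass counterfactual at the TMREL."""
    tmrel = ExposureDistribution(
        curve.spec.x_tmrel, 0.0, "point_mass", location=curve.spec.x_tmrel
    )
    res = compute_pif(curve, baseline, tmrel, grid_step, m, stratum=stratum)
    return res
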