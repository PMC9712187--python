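"""Per-stratum UPF intake distributions and counterfactual scenarios.

Each age-sex stratum's UPF energy share is modelled as a log-normal
distribution moment-matched to the survey mean and standard deviation,
truncated to the feasible support (0, 100] % of total energy and
renormalised.  Counterfactual scenarios transform these distributions:

* ``proportional_reduction`` scales every individual's intake by (1 - r),
  which for a log-normal shifts the log-scale location by ln(1 - r);
* ``first_quintile`` truncates the baseline distribution at its own 20th
  percentile and renormalises, i.e. everyone adopts the intake pattern of
  the current bottom quintile (an alternative reading, a point mass at the
  bottom-quintile mean, is available via ``mode="point_mass_q1_mean"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "Stratum",
    "ExposureDistribution",
    "Scenario",
    "fit_exposure",
    "apply_scenario",
    "quintile_cutpoint",
]

#: Five-year age bands of the modelled (premature-CVD) population.
AGE_GROUPS = (
    "30-34", "35-39", "40-44", "45-49", "50-54", "55-59", "60-64", "65-69",
)
SEXES = ("male", "female")

_SQRT2PI = math.sqrt(2.0 * math.pi)
_SUPPORT_MAX = 100.0


@dataclass(frozen=True)
class Stratum:
    """One age-group x sex cell of the population."""

    sex: str
    age_group: str
    population: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(
                f"age group {self.age_group!r} outside the modelled 30-69 "
                f"range {AGE_GROUPS}"
            )
        if self.population < 0:
            raise ValueError("population must be non-negative")

    @property
    def label(self) -> str:
        return f"{self.sex} {self.age_group}"


@dataclass(frozen=True)
class ExposureDistribution:
    """UPF energy-share distribution on (0, upper] % of total energy.

    ``family`` is ``"lognormal"`` (with log-scale parameters ``mu_ln``,
    ``sigma_ln``, truncated at ``upper`` and renormalised) or
    ``"point_mass"`` (all mass at ``location``).  ``mean_pct`` / ``sd_pct``
    record the moment-matched inputs of the *untruncated* parent.
    """

    mean_pct: float
    sd_pct: float
    family: str = "lognormal"
    mu_ln: float = float("nan")
    sigma_ln: float = float("nan")
    upper: float = _SUPPORT_MAX
    location: float = float("nan")

    # -- normalisation ------------------------------------------------
    @property
    def _norm(self) -> float:
        """Mass of the untruncated parent below ``upper``."""
        if self.family == "point_mass":
            return 1.0
        return float(ndtr((math.log(self.upper) - self.mu_ln) / self.sigma_ln))

    def pdf(self, x):
        """Density of the truncated distribution (0 outside (0, upper])."""
        if self.family == "point_mass":
            raise ValueError("point-mass distribution has no density")
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        inside = (x > 0) & (x <= self.upper)
        xi = x[inside]
        z = (np.log(xi) - self.mu_ln) / self.sigma_ln
        out[inside] = np.exp(-0.5 * z * z) / (xi * self.sigma_ln * _SQRT2PI)
        out /= self._norm
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "point_mass":
            out = (x >= self.location).astype(float)
            return out if out.ndim else float(out)
        out = np.zeros_like(x)
        pos = x > 0
        z = (np.log(np.clip(x, 1e-300, None)) - self.mu_ln) / self.sigma_ln
        out[pos] = np.minimum(ndtr(z)[pos] / self._norm, 1.0)
        return out if out.ndim else float(out)

    def ppf(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError("quantile level must be in (0, 1)")
        if self.family == "point_mass":
            return self.location
        return float(math.exp(self.mu_ln + self.sigma_ln * ndtri(q * self._norm)))

    def numeric_moments(self, n: int = 200_001) -> tuple[float, float]:
        """Mean and SD of the truncated distribution by quadrature
        (validation aid)."""
        grid = np.linspace(0.0, self.upper, n)
        p = self.pdf(grid)
        m1 = np.trapezoid(grid * p, grid)
        m2 = np.trapezoid(grid**2 * p, grid)
        return float(m1), float(math.sqrt(max(m2 - m1**2, 0.0)))


@dataclass(frozen=True)
class Scenario:
    """A counterfactual transformation of exposure distributions."""

    kind: str  # baseline | proportional_reduction | first_quintile
    reduction_fraction: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("baseline", "proportional_reduction", "first_quintile"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "proportional_reduction":
            if self.reduction_fraction is None:
                raise ValueError("proportional_reduction needs a reduction_fraction")
            if not 0.0 <= self.reduction_fraction <= 1.0:
                raise ValueError("reduction_fraction must lie in [0, 1]")
        elif self.reduction_fraction is not None:
            raise ValueError(f"{self.kind} scenario takes no reduction_fraction")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.kind == "proportional_reduction":
            return f"reduce_{round(self.reduction_fraction * 100):g}pct"
        return self.kind

    @classmethod
    def baseline(cls) -> "Scenario":
        return cls("baseline")

    @classmethod
    def proportional(cls, r: float) -> "Scenario":
        return cls("proportional_reduction", reduction_fraction=r)

    @classmethod
    def first_quintile(cls) -> "Scenario":
        return cls("first_quintile")

    @classmethod
    def parse(cls, text: str) -> "Scenario":
        """Parse CLI syntax: ``baseline``, ``proportional:0.10``,
        ``quintile:1``."""
        head, _, arg = text.partition(":")
        head = head.strip().lower()
        if head == "baseline":
            return cls.baseline()
        if head == "proportional":
            return cls.proportional(float(arg))
        if head == "quintile":
            if arg and arg.strip() != "1":
                raise ValueError("only the first quintile is supported")
            return cls.first_quintile()
        raise ValueError(f"cannot parse scenario {text!r}")


def fit_exposure(mean_pct: float, sd_pct: float) -> ExposureDistribution:
    """Moment-match a log-normal to the stratum mean and SD (% energy).

    sigma_ln^2 = ln(1 + (sd/mean)^2), mu_ln = ln(mean) - sigma_ln^2 / 2,
    so the untruncated arithmetic mean and SD equal the inputs exactly.
    ``sd_pct = 0`` degenerates to a point mass.
    """
    if not 0.0 < mean_pct < 100.0:
        raise ValueError(f"mean_pct must lie in (0, 100), got {mean_pct}")
    if sd_pct < 0:
        raise ValueError("sd_pct must be non-negative")
    if sd_pct == 0:
        return ExposureDistribution(mean_pct, 0.0, family="point_mass", location=mean_pct)
    s2 = math.log(1.0 + (sd_pct / mean_pct) ** 2)
    mu = math.log(mean_pct) - s2 / 2.0
    return ExposureDistribution(mean_pct, sd_pct, "lognormal", mu, math.sqrt(s2))


def quintile_cutpoint(dist: ExposureDistribution, q: float = 0.2) -> float:
    """Exposure value below which a fraction ``q`` of the stratum lies."""
    return dist.ppf(q) if dist.family != "point_mass" else dist.location


def apply_scenario(
    dist: ExposureDistribution,
    scenario: Scenario,
    mode: str = "truncate",
) -> ExposureDistribution:
    """Transform a baseline distribution into its counterfactual.

    ``mode`` selects the first-quintile reading: ``"truncate"`` (default)
    truncates at the baseline 20th percentile and renormalises;
    ``"point_mass_q1_mean"`` collapses to a point mass at the mean intake
    of the bottom quintile.
    """
    if scenario.kind == "baseline":
        return dist

    if scenario.kind == "proportional_reduction":
        r = scenario.reduction_fraction
        if dist.family == "point_mass":
            return ExposureDistribution(
                dist.mean_pct * (1 - r), 0.0, "point_mass",
                location=dist.location * (1 - r),
            )
        if r == 1.0:  # full elimination: all mass at the zero-intake limit
            return ExposureDistribution(0.0, 0.0, "point_mass", location=0.0)
        return ExposureDistribution(
            dist.mean_pct * (1 - r),
            dist.sd_pct * (1 - r),
            "lognormal",
            dist.mu_ln + math.log(1 - r),
            dist.sigma_ln,
            upper=dist.upper,
        )

    # first quintile
    if dist.family == "point_mass":
        return dist
    cut = quintile_cutpoint(dist, 0.2)
    if mode == "truncate":
        return ExposureDistribution(
            dist.mean_pct, dist.sd_pct, "lognormal",
            dist.mu_ln, dist.sigma_ln, upper=min(cut, dist.upper),
        )
    if mode == "point_mass_q1_mean":
        trunc = ExposureDistribution(
            dist.mean_pct, dist.sd_pct, "lognormal",
            dist.mu_ln, dist.sigma_ln, upper=min(cut, dist.upper),
        )
        q1_mean, _ = trunc.numeric_moments()
        return ExposureDistribution(q1_mean, 0.0, "point_mass", location=q1_mean)
    raise ValueError(f"unknown first-quintile mode {mode!r}")
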