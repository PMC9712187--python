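"""Dose-response relative risk curves for ultra-processed food intake.

The relative risk of each cardiovascular outcome (ischaemic heart disease,
stroke) is modelled as a log-linear function of the share of total dietary
energy contributed by ultra-processed food (UPF).  The curve is anchored at
two points: the theoretical minimum risk exposure level (TMREL, where
RR = 1) and a reference intake at which a pooled meta-analytic RR applies.
Beyond the reference intake the same log-linear slope is extrapolated, so
risks compose multiplicatively: RR(a + b) = RR(a) * RR(b) when TMREL = 0.

Uncertainty in the pooled RR is propagated by sampling from a log-normal
distribution whose 95% interval matches the published confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Outcome",
    "RRSpec",
    "RRCurve",
    "build_rr_curve",
    "sample_rr",
    "DEFAULT_RR_SPECS",
]

#: 95% interval width in standard normal units (2 * 1.96).
_Z95_SPAN = 2.0 * 1.959963984540054


class Outcome:
    """Outcome labels used throughout the package."""

    CHD = "chd"
    STROKE = "stroke"
    ALL = (CHD, STROKE)


@dataclass(frozen=True)
class RRSpec:
    """Pooled relative risk for one outcome, anchored at a reference intake.

    Parameters
    ----------
    outcome
        ``"chd"`` or ``"stroke"``.
    rr_ref
        Pooled RR comparing intake at ``x_ref`` with intake at ``x_tmrel``.
    ci_low, ci_high
        95% confidence bounds of ``rr_ref``.
    x_ref
        Reference UPF energy share (% of total energy) at which
        ``rr_ref`` applies.
    x_tmrel
        Theoretical minimum risk exposure level (% energy); RR = 1 at and
        below this intake.
    """

    outcome: str
    rr_ref: float
    ci_low: float
    ci_high: float
    x_ref: float = 22.0
    x_tmrel: float = 0.0

    def __post_init__(self) -> None:
        if self.outcome not in Outcome.ALL:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.rr_ref <= 0 or self.ci_low <= 0 or self.ci_high <= 0:
            raise ValueError("relative risks must be positive")
        if not (self.ci_low <= self.rr_ref <= self.ci_high):
            raise ValueError(
                f"CI must bracket the point estimate: "
                f"{self.ci_low} <= {self.rr_ref} <= {self.ci_high} fails"
            )
        if not (0.0 <= self.x_tmrel < self.x_ref <= 100.0):
            raise ValueError(
                f"need 0 <= x_tmrel < x_ref <= 100, got "
                f"tmrel={self.x_tmrel}, ref={self.x_ref}"
            )

    def with_rr(self, rr_ref: float) -> "RRSpec":
        """Return a copy with the point estimate replaced (CI re-centred
        multiplicatively), used for Monte Carlo draws and RR multipliers."""
        f = rr_ref / self.rr_ref
        return replace(
            self, rr_ref=rr_ref, ci_low=self.ci_low * f, ci_high=self.ci_high * f
        )

    def with_anchors(self, x_tmrel: float | None = None, x_ref: float | None = None) -> "RRSpec":
        """Re-anchor the same pooled RR at alternative thresholds
        (deterministic sensitivity analyses)."""
        return replace(
            self,
            x_tmrel=self.x_tmrel if x_tmrel is None else x_tmrel,
            x_ref=self.x_ref if x_ref is None else x_ref,
        )


#: Pooled RRs from the meta-analytic evidence base, anchored at a 22.0%
#: energy share with TMREL at 0%.
DEFAULT_RR_SPECS: dict[str, RRSpec] = {
    Outcome.CHD: RRSpec(Outcome.CHD, 1.29, 1.12, 1.48),
    Outcome.STROKE: RRSpec(Outcome.STROKE, 1.34, 1.07, 1.68),
}


class RRCurve:
    """Continuous log-linear relative risk curve RR(x) on [0, 100].

    ``log RR(x)`` rises linearly from 0 at the TMREL to ``log rr_ref`` at
    the reference intake and continues with the same slope up to a 100%
    energy share; RR is clamped to 1 at and below the TMREL.
    """

    def __init__(self, spec: RRSpec):
        self.spec = spec
        self._slope = np.log(spec.rr_ref) / (spec.x_ref - spec.x_tmrel)

    @property
    def slope(self) -> float:
        """d log RR / dx above the TMREL (per % energy share)."""
        return self._slope

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.exp(self._slope * np.clip(x - self.spec.x_tmrel, 0.0, None))
        return out if out.ndim else float(out)

    def log_rr(self, x):
        x = np.asarray(x, dtype=float)
        out = self._slope * np.clip(x - self.spec.x_tmrel, 0.0, None)
        return out if out.ndim else float(out)

    def tabulate(self, step: float = 0.1, upper: float = 100.0):
        """Return ``(grid, RR values)`` on a uniform grid, mirroring the
        0.1%-interval tabulation the curve generalises."""
        if step <= 0:
            raise ValueError("step must be positive")
        n = int(round(upper / step))
        grid = np.arange(n + 1) * step
        return grid, self(grid)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        s = self.spec
        return (
            f"RRCurve({s.outcome}: RR({s.x_ref})={s.rr_ref}, "
            f"tmrel={s.x_tmrel})"
        )


def build_rr_curve(spec: RRSpec, rr_ref: float | None = None) -> RRCurve:
    """Build the log-linear RR curve for ``spec``.

    Parameters
    ----------
    spec
        Anchored pooled RR.
    rr_ref
        Optional override of the point estimate (e.g. a Monte Carlo draw
        or a sensitivity multiplier applied upstream).
    """
    if rr_ref is not None:
        if rr_ref <= 0:
            raise ValueError("rr_ref must be positive")
        spec = spec.with_rr(rr_ref)
    return RRCurve(spec)


def sample_rr(spec: RRSpec, rng: np.random.Generator, size=None):
    """Draw pooled-RR replicates from a log-normal uncertainty distribution.

    The log-scale mean is ``ln rr_ref`` and the log-scale SD is the width of
    the 95% CI on the log scale divided by 2*1.96, so the empirical 2.5th
    and 97.5th percentiles of the draws converge to the published CI.  A
    zero-width CI yields constant draws.
    """
    if spec.ci_low > spec.ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    sd_log = (np.log(spec.ci_high) - np.log(spec.ci_low)) / _Z95_SPAN
    draws = np.exp(rng.normal(np.log(spec.rr_ref), sd_log, size=size))
    return draws
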