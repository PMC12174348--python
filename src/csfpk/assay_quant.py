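"""Cell-based assay quantification for anti-NMDAR antibody work.

Covers the calibration computations around the flow-cytometry binding
and internalization assays:

* percent surface-receptor expression and percent inhibition, as linear
  normalizations between 100%/0% anchor controls;
* four-parameter logistic (4PL / sigmoid-Emax) fitting of standard
  curves and EC50 estimation;
* inverse calibration of sample responses to reference-antibody
  ("502-Ab equivalent") pseudo-concentrations, with censoring outside
  the quantifiable range instead of extrapolation;
* serum--CSF concordance statistics (OLS of CSF on serum pseudo-
  concentrations, Pearson R², slope t-test p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import CalibrationError, ValidationError

__all__ = [
    "FourPL",
    "StandardCurve",
    "ConcordancePair",
    "ConcordanceStats",
    "PercentResult",
    "PseudoConcentration",
    "percent_surface_expression",
    "percent_inhibition",
    "fit_4pl",
    "pseudo_concentration",
    "csf_serum_ratio",
    "concordance_stats",
    "round_half_up",
]


@dataclass(frozen=True)
class FourPL:
    """Four-parameter logistic curve.

    response(c) = bottom + (top - bottom) / (1 + (ec50/c)**hill)

    ``ec50`` is the concentration at the half-maximal response; ``hill``
    is the slope factor.  ``top`` may be below ``bottom`` for decreasing
    curves (e.g. surface expression vs pathogenic antibody).
    """

    bottom: float
    top: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValidationError("ec50 must be > 0")
        if self.top == self.bottom:
            raise ValidationError("top and bottom must differ")
        if self.hill <= 0:
            raise ValidationError("hill slope must be > 0")

    def response(self, concentration):
        c = np.asarray(concentration, dtype=float)
        with np.errstate(divide="ignore"):
            frac = np.where(c > 0, 1.0 / (1.0 + (self.ec50 / np.maximum(c, 1e-300)) ** self.hill), 0.0)
        out = self.bottom + (self.top - self.bottom) * frac
        return float(out) if np.isscalar(concentration) else out

    def inverse(self, response):
        """Concentration producing ``response``; NaN outside (bottom, top)."""
        y = np.asarray(response, dtype=float)
        lo, hi = sorted((self.bottom, self.top))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (self.top - y) / (y - self.bottom)
            c = np.where((y > lo) & (y < hi), self.ec50 * ratio ** (-1.0 / self.hill), np.nan)
        return float(c) if np.isscalar(response) else c


@dataclass(frozen=True)
class PercentResult:
    """A normalized percentage plus an out-of-[0,100] flag."""

    value: float
    out_of_range: bool

    def __float__(self) -> float:
        return self.value


def percent_surface_expression(mfi_sample: float, mfi_100: float, mfi_0: float) -> PercentResult:
    """Percent surface receptor expression between the 100% anchor
    (reference-antibody staining) and the 0% anchor.

    Values outside [0, 100] are returned as-is and flagged, never
    clipped.  Affine-invariant: a constant offset applied to all three
    MFIs (e.g. an unsubtracted background) cancels.
    """
    if mfi_100 == mfi_0:
        raise ValidationError("100% and 0% anchor MFIs must differ")
    value = 100.0 * (mfi_sample - mfi_0) / (mfi_100 - mfi_0)
    return PercentResult(value, not (0.0 <= value <= 100.0))


def percent_inhibition(
    signal: float, signal_no_competitor: float, signal_full_competition: float
) -> PercentResult:
    """Percent inhibition between the no-competitor (0%) and
    full-competition (100%) anchors of a competitive binding assay."""
    if signal_no_competitor == signal_full_competition:
        raise ValidationError("inhibition anchors must differ")
    value = (
        100.0
        * (signal - signal_no_competitor)
        / (signal_full_competition - signal_no_competitor)
    )
    return PercentResult(value, not (0.0 <= value <= 100.0))


@dataclass(frozen=True)
class FourPLFit:
    """Fitted curve plus diagnostics."""

    curve: FourPL
    ec50_ci: tuple[float, float]   # approximate 95% CI, concentration units
    rss: float
    n: int


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    seed: int | None = None,
    n_restarts: int = 8,
) -> FourPLFit:
    """Least-squares 4PL fit in log-concentration space with multi-start.

    Requires >= 5 points spanning the inflection: after sorting by
    concentration, the lowest- and highest-concentration responses must
    lie on opposite sides of the midrange response, otherwise the EC50
    is not bracketed by the data.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValidationError("concentrations and responses must be 1-D, equal length")
    if len(c) < 5:
        raise ValidationError("need >= 5 calibration points")
    if np.any(c <= 0):
        raise ValidationError("standard concentrations must be > 0")
    order = np.argsort(c)
    c, y = c[order], y[order]
    mid = 0.5 * (y.min() + y.max())
    if (y[0] - mid) * (y[-1] - mid) >= 0:
        raise CalibrationError("EC50 not bracketed: responses do not cross the midrange")

    increasing = y[-1] > y[0]
    logc = np.log(c)

    from scipy.special import expit

    def resid(x):
        b, t, log_ec50, log_hill = x
        frac = expit(np.exp(min(log_hill, 50.0)) * (logc - log_ec50))
        return b + (t - b) * frac - y

    rng = np.random.default_rng(seed)
    # anchor start: asymptotes at observed extremes, EC50 at the midrange crossing
    ec50_0 = float(np.exp(np.interp(mid, y if increasing else y[::-1], logc if increasing else logc[::-1])))
    starts = [(y[0], y[-1], math.log(ec50_0), 0.0)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            (
                y[0] + 0.1 * (y[-1] - y[0]) * rng.standard_normal(),
                y[-1] + 0.1 * (y[-1] - y[0]) * rng.standard_normal(),
                math.log(ec50_0) + rng.normal(scale=1.0),
                rng.normal(scale=0.7),
            )
        )
    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e12:
        raise CalibrationError("4PL fit failed to converge from any start")

    b, t, log_ec50, log_hill = best.x
    # present with a positive hill: an "increasing in log c" fit with
    # bottom/top swapped is the same curve
    curve = FourPL(bottom=b, top=t, ec50=math.exp(log_ec50), hill=math.exp(log_hill))
    if not (c[0] <= curve.ec50 <= c[-1]):
        raise CalibrationError(
            f"EC50 not bracketed: fitted EC50 {curve.ec50:.3g} lies outside the "
            f"standard range [{c[0]:.3g}, {c[-1]:.3g}]"
        )
    n, p = len(y), 4
    rss = float(2 * best.cost)
    ci = (curve.ec50, curve.ec50)
    if n > p:
        s2 = rss / (n - p)
        try:
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            sd_log = math.sqrt(max(cov[2, 2], 0.0))
            ci = (curve.ec50 * math.exp(-1.96 * sd_log), curve.ec50 * math.exp(1.96 * sd_log))
        except np.linalg.LinAlgError:
            pass
    return FourPLFit(curve=curve, ec50_ci=ci, rss=rss, n=n)


@dataclass(frozen=True)
class StandardCurve:
    """Reference-antibody dilution series with its fitted 4PL.

    The quantifiable range is bounded by the fitted responses at the
    lowest and highest standard concentrations; sample responses outside
    it are censored rather than extrapolated.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    fourpl: FourPL | None = None
    fit: FourPLFit | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.responses, dtype=float)
        if len(c) < 5:
            raise ValidationError("a standard curve needs >= 5 concentration levels")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValidationError("standard concentrations must be positive and sorted ascending")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", y)

    @classmethod
    def from_data(cls, concentrations, responses, seed: int | None = None) -> "StandardCurve":
        order = np.argsort(np.asarray(concentrations, dtype=float))
        c = np.asarray(concentrations, dtype=float)[order]
        y = np.asarray(responses, dtype=float)[order]
        fit = fit_4pl(c, y, seed=seed)
        return cls(concentrations=c, responses=y, fourpl=fit.curve, fit=fit)

    @property
    def quantifiable_response_range(self) -> tuple[float, float]:
        if self.fourpl is None:
            raise CalibrationError("standard curve has not been fitted")
        lo = self.fourpl.response(self.concentrations[0])
        hi = self.fourpl.response(self.concentrations[-1])
        return (min(lo, hi), max(lo, hi))

    @property
    def quantifiable_concentration_range(self) -> tuple[float, float]:
        return (float(self.concentrations[0]), float(self.concentrations[-1]))


@dataclass(frozen=True)
class PseudoConcentration:
    """Inverse-calibrated sample value, possibly censored."""

    value: float | None            # µg/mL reference-antibody equivalent
    censored: Literal["below", "above"] | None

    @property
    def determined(self) -> bool:
        return self.censored is None


def pseudo_concentration(response: float, curve: StandardCurve) -> PseudoConcentration:
    """Map a background-subtracted sample response through the inverse
    of the fitted standard curve.

    Responses outside the quantifiable range (beyond the fitted response
    at the lowest/highest standard) return a censored result.
    """
    if curve.fourpl is None:
        raise CalibrationError("standard curve has not been fitted")
    lo, hi = curve.quantifiable_response_range
    fp = curve.fourpl
    increasing = fp.response(curve.concentrations[-1]) > fp.response(curve.concentrations[0])
    if response < lo:
        return PseudoConcentration(None, "below" if increasing else "above")
    if response > hi:
        return PseudoConcentration(None, "above" if increasing else "below")
    value = fp.inverse(response)
    if not np.isfinite(value):
        # response exactly at an asymptote within float fuzz
        edge = "below" if (response <= lo) == increasing else "above"
        return PseudoConcentration(None, edge)
    return PseudoConcentration(float(value), None)


@dataclass(frozen=True)
class ConcordancePair:
    """Matched serum/CSF pseudo-concentrations for one patient.

    ``None`` marks a value that could not be determined.
    """

    patient_id: str
    serum_value: float | None
    csf_value: float | None

    def __post_init__(self) -> None:
        for v in (self.serum_value, self.csf_value):
            if v is not None and v < 0:
                raise ValidationError("pseudo-concentrations must be >= 0")

    @property
    def complete(self) -> bool:
        return self.serum_value is not None and self.csf_value is not None


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (0.25 -> 0.3 at one decimal), the
    convention behind reported ratio tables; banker's rounding would
    disagree on exact ties like 6.25 -> 6.2."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def csf_serum_ratio(pair: ConcordancePair) -> float | None:
    """CSF/serum pseudo-concentration ratio as a percentage, half-up
    rounded to one decimal; ``None`` when either value is undetermined."""
    if pair.serum_value is None or pair.csf_value is None:
        return None
    if pair.serum_value <= 0:
        raise ValidationError("serum value must be > 0 for a ratio")
    return round_half_up(100.0 * pair.csf_value / pair.serum_value, 1)


@dataclass(frozen=True)
class ConcordanceStats:
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int


def concordance_stats(pairs: Sequence[ConcordancePair]) -> ConcordanceStats:
    """OLS of CSF on serum pseudo-concentration (untransformed) over the
    complete pairs: Pearson R² and the two-sided slope t-test p-value."""
    complete = [p for p in pairs if p.complete]
    if len(complete) < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {len(complete)}")
    x = np.array([p.serum_value for p in complete])
    y = np.array([p.csf_value for p in complete])
    res = stats.linregress(x, y)
    return ConcordanceStats(
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(complete),
    )
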