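"""Non-compartmental analysis: Cmax, Tmax, AUC(0-t), terminal half-life.

AUC uses the linear trapezoid throughout.  The terminal phase is chosen
by log-linear regression over the last k = 3..8 positive points, keeping
the window with the best adjusted R² among those with negative slope —
a declared, reproducible rule since terminal-point selection conventions
vary between analysts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["NCAResult", "nca_summary", "exposure_ratio"]


@dataclass(frozen=True)
class NCAResult:
    """Summary PK metrics for one concentration-time series."""

    cmax: float                      # µg/mL
    tmax: float                      # h
    auc_0_t: float                   # µg·h/mL, linear trapezoid on [0, t_end]
    t_end: float                     # h
    t_half: float | None             # h; None when no valid terminal window
    lambda_z: float | None           # 1/h
    n_terminal_points: int
    terminal_fit_r2: float | None
    auc_inf: float | None = None     # extrapolated, only when requested


def nca_summary(
    times,
    concentrations,
    t_end: float | None = None,
    extrapolate: bool = False,
) -> NCAResult:
    """Non-compartmental summary of a single profile.

    Parameters
    ----------
    times, concentrations : array-like
        Sampling times (h, strictly increasing) and concentrations
        (µg/mL).  At least 3 positive concentrations are required.
    t_end : float, optional
        Upper AUC limit; defaults to the last sampling time.  If t_end
        falls between samples the profile is linearly interpolated.
    extrapolate : bool
        Also report AUC(0-inf) = AUC(0-t_end) + C(t_end)/lambda_z.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValidationError("times and concentrations must be 1-D and equal length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if len(c) < 3 or np.count_nonzero(c > 0) < 2:
        raise ValidationError("need at least 3 points with 2 positive concentrations")
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] or t_end <= t[0]:
        raise ValidationError(f"t_end {t_end} outside sampled range [{t[0]}, {t[-1]}]")

    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])

    mask = t <= t_end
    tt, cc = t[mask], c[mask]
    if tt[-1] < t_end:
        c_end = float(np.interp(t_end, t, c))
        tt = np.append(tt, t_end)
        cc = np.append(cc, c_end)
    auc = float(np.trapezoid(cc, tt))

    lam, r2, n_pts = _terminal_slope(tt, cc)
    t_half = math.log(2) / lam if lam is not None else None
    auc_inf = None
    if extrapolate and lam is not None:
        auc_inf = auc + float(cc[-1]) / lam

    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc,
        t_end=float(t_end),
        t_half=t_half,
        lambda_z=lam,
        n_terminal_points=n_pts,
        terminal_fit_r2=r2,
        auc_inf=auc_inf,
    )


def _terminal_slope(t: np.ndarray, c: np.ndarray):
    """Best log-linear terminal window over the last k = 3..8 positive
    points after Tmax; returns (lambda_z, r2, n_points)."""
    pos = c > 0
    tp, cp = t[pos], c[pos]
    i_max = int(np.argmax(cp))
    tp, cp = tp[i_max:], cp[i_max:]
    best = None
    for k in range(3, min(8, len(tp)) + 1):
        x, y = tp[-k:], np.log(cp[-k:])
        res = stats.linregress(x, y)
        if res.slope >= 0:
            continue
        r2 = res.rvalue**2
        adj = 1 - (1 - r2) * (k - 1) / (k - 2)
        if best is None or adj > best[0]:
            best = (adj, -res.slope, r2, k)
    if best is None:
        return None, None, 0
    _, lam, r2, k = best
    return float(lam), float(r2), k


def exposure_ratio(serum: NCAResult, csf: NCAResult) -> tuple[float, float]:
    """CSF/serum exposure as percentages: (Cmax ratio, AUC(0-t) ratio).

    Both summaries must cover the same AUC interval so the ratio
    compares like with like.
    """
    if not math.isclose(serum.t_end, csf.t_end, rel_tol=1e-9):
        raise ValidationError(
            f"mismatched AUC intervals: serum t_end {serum.t_end}, csf t_end {csf.t_end}"
        )
    cmax_ratio = 100.0 * csf.cmax / serum.cmax
    auc_ratio = 100.0 * csf.auc_0_t / serum.auc_0_t
    return cmax_ratio, auc_ratio
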