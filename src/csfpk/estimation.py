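"""Parameter estimation from serum/CSF concentration data.

Two estimators are provided in place of a full nonlinear mixed-effects
engine (an explicit non-goal): a naive-pooled fit treating all
quantifiable observations as one subject-independent dataset, and a
two-stage population summary (per-subject fits, then geometric means
and between-subject CVs).

The objective is a Gaussian log-likelihood on log concentrations with
per-point variance  ln(1 + cv² + (additive_sd/pred)²) , which reduces to
ln(1+cv²) ≈ cv² for a pure proportional error.  Records flagged below
the LLOQ are excluded.  Optimization runs in log-parameter space under
box bounds with seeded multi-start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitError, ValidationError
from .pk_model import DoseEvent, LinearSystem, PKParameters

__all__ = [
    "PKDataset",
    "ErrorModel",
    "FitResult",
    "negative_log_likelihood",
    "fit_pooled",
    "fit_two_stage",
]

_OBS_COLUMNS = ["subject_id", "time_h", "conc", "matrix", "below_lloq"]


@dataclass
class PKDataset:
    """Observed (or synthetic) concentration records plus dosing.

    Parameters
    ----------
    observations : DataFrame
        Columns ``subject_id, time_h, conc, matrix, below_lloq`` with
        matrix in {'serum', 'csf'}.
    doses : dict
        subject_id -> sequence of DoseEvent.
    body_weights : dict
        subject_id -> kg.
    lloq : dict
        matrix -> µg/mL lower limit of quantification.
    """

    observations: pd.DataFrame
    doses: dict[str, tuple[DoseEvent, ...]]
    body_weights: dict[str, float]
    lloq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        obs = self.observations
        missing = [c for c in _OBS_COLUMNS if c not in obs.columns]
        if missing:
            raise ValidationError(f"observations missing columns: {missing}")
        if (obs["time_h"] < 0).any():
            raise ValidationError("observation times must be >= 0")
        bad_matrix = set(obs["matrix"].unique()) - {"serum", "csf"}
        if bad_matrix:
            raise ValidationError(f"unknown matrix labels: {sorted(bad_matrix)}")
        quantifiable = obs[~obs["below_lloq"].astype(bool)]
        if (quantifiable["conc"] <= 0).any():
            raise ValidationError("quantifiable concentrations must be > 0")
        for sid in obs["subject_id"].unique():
            if sid not in self.doses or len(self.doses[sid]) == 0:
                raise ValidationError(f"subject {sid!r} has no dose events")

    @property
    def subjects(self) -> list[str]:
        return list(self.observations["subject_id"].unique())

    def quantifiable(self) -> pd.DataFrame:
        return self.observations[~self.observations["below_lloq"].astype(bool)]

    def subset(self, subject_id: str) -> "PKDataset":
        obs = self.observations[self.observations["subject_id"] == subject_id]
        return PKDataset(
            observations=obs.reset_index(drop=True),
            doses={subject_id: self.doses[subject_id]},
            body_weights={subject_id: self.body_weights[subject_id]},
            lloq=dict(self.lloq),
        )

    @property
    def matrices(self) -> set[str]:
        return set(self.quantifiable()["matrix"].unique())


@dataclass(frozen=True)
class ErrorModel:
    """Combined proportional + additive residual error."""

    proportional_cv: float = 0.15
    additive_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValidationError("error components must be >= 0")
        if self.proportional_cv == 0 and self.additive_sd == 0:
            raise ValidationError("error model cannot be identically zero")

    def log_variance(self, pred: np.ndarray) -> np.ndarray:
        """Per-point variance on the log-concentration scale."""
        return np.log1p(self.proportional_cv**2 + (self.additive_sd / pred) ** 2)


def _predictions(params: PKParameters, dataset: PKDataset, obs: pd.DataFrame) -> np.ndarray:
    """Model-predicted concentrations at every observation row.

    One eigendecomposition per parameter vector, shared across subjects
    (the fitting hot path)."""
    system = LinearSystem(params)
    pred = np.empty(len(obs))
    pos = {sid: np.flatnonzero(obs["subject_id"].to_numpy() == sid) for sid in obs["subject_id"].unique()}
    times_arr = obs["time_h"].to_numpy()
    matrix_arr = obs["matrix"].to_numpy()
    for sid, idx in pos.items():
        t = times_arr[idx]
        order = np.argsort(t, kind="stable")
        t_sorted = t[order]
        grid, inverse = np.unique(t_sorted, return_inverse=True)
        amounts = system.amounts(dataset.doses[sid], grid)
        serum = amounts[:, 0] / params.V
        csf = amounts[:, 2] / params.Vcsf
        vals = np.where(matrix_arr[idx][order] == "serum", serum[inverse], csf[inverse])
        pred[idx[order]] = vals
    return pred


def negative_log_likelihood(
    params: PKParameters, dataset: PKDataset, error: ErrorModel
) -> float:
    """Gaussian NLL on log concentrations over quantifiable records.

    NLL = 0.5 * sum[ r_i²/v_i + ln v_i + ln 2π ]  with
    r_i = ln(obs_i) - ln(pred_i) and v_i = error.log_variance(pred_i).
    """
    obs = dataset.quantifiable()
    if len(obs) == 0:
        raise FitError("no quantifiable observations")
    pred = _predictions(params, dataset, obs)
    if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
        return float("inf")
    r = np.log(obs["conc"].to_numpy()) - np.log(pred)
    v = error.log_variance(pred)
    return float(0.5 * np.sum(r**2 / v + np.log(v) + math.log(2 * math.pi)))


@dataclass
class FitResult:
    """Estimates plus diagnostics from a pooled or two-stage fit."""

    estimates: PKParameters
    standard_errors: dict[str, float]
    objective: float
    converged: bool
    n_obs: int
    non_identifiable: tuple[str, ...] = ()
    per_subject: dict[str, PKParameters] | None = None
    summary: dict[str, dict[str, float]] | None = None
    settings: dict | None = None


_DEFAULT_BOUNDS = (1e-3, 1e7)


def _check_identifiability(dataset: PKDataset) -> tuple[str, ...]:
    """CSF-linked parameters are structurally non-identifiable without
    CSF observations; they are then held fixed at their initial values."""
    return () if "csf" in dataset.matrices else ("Vcsf", "Qcsf")


def fit_pooled(
    dataset: PKDataset,
    init: PKParameters,
    bounds: tuple[float, float] = _DEFAULT_BOUNDS,
    error: ErrorModel | None = None,
    seed: int | None = None,
    n_restarts: int = 8,
) -> FitResult:
    """Naive-pooled box-constrained NLL minimization in log space.

    Multi-start from the initial values plus log-normally jittered
    copies; ties broken by lowest objective, then lowest parameter-norm.
    Standard errors come from the inverse of a finite-difference Hessian
    of the NLL in log space (delta method back to natural scale).
    """
    error = error or ErrorModel()
    obs = dataset.quantifiable()
    if len(obs) < 6:
        raise FitError(f"need >= 6 quantifiable observations, got {len(obs)}")
    fixed = _check_identifiability(dataset)
    free_idx = [i for i, name in enumerate(PKParameters.names) if name not in fixed]
    init_arr = init.as_array()
    lo, hi = math.log(bounds[0]), math.log(bounds[1])

    def unpack(x_free: np.ndarray) -> PKParameters:
        full = init_arr.copy()  # fixed parameters stay bit-exact at init
        full[free_idx] = np.exp(x_free)
        return PKParameters.from_array(full)

    # large finite penalty (not inf) keeps finite-difference gradients usable
    _PENALTY = 1e12

    def objective(x_free: np.ndarray) -> float:
        try:
            value = negative_log_likelihood(unpack(x_free), dataset, error)
        except (ValidationError, FloatingPointError):
            return _PENALTY
        return value if math.isfinite(value) else _PENALTY

    rng = np.random.default_rng(seed)
    x0 = np.log(init_arr)[free_idx]
    starts = [x0] + [
        np.clip(x0 + rng.normal(scale=0.5, size=len(free_idx)), lo, hi)
        for _ in range(max(0, n_restarts - 1))
    ]
    results = []
    diagnostics = []
    for start in starts:
        res = optimize.minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * len(free_idx),
        )
        diagnostics.append((res.success, res.fun, res.message))
        if np.isfinite(res.fun):
            results.append(res)
    converged = [r for r in results if r.success]
    if not converged:
        raise FitError(f"no start converged; per-start diagnostics: {diagnostics}")
    best = min(converged, key=lambda r: (r.fun, float(np.linalg.norm(r.x))))

    estimates = unpack(best.x)
    ses = _standard_errors(objective, best.x, estimates, free_idx)
    for name in fixed:
        ses[name] = float("nan")
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        objective=float(best.fun),
        converged=True,
        n_obs=len(obs),
        non_identifiable=fixed,
        settings={
            "n_restarts": n_restarts,
            "bounds": bounds,
            "error": {"proportional_cv": error.proportional_cv, "additive_sd": error.additive_sd},
            "seed": seed,
        },
    )


def _standard_errors(objective, x_opt, estimates: PKParameters, free_idx) -> dict[str, float]:
    """Finite-difference Hessian of the NLL in log-parameter space;
    SE(theta) = theta * sqrt(diag(H^-1)) by the delta method."""
    n = len(x_opt)
    h = 1e-4
    H = np.zeros((n, n))
    f0 = objective(x_opt)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = objective(x_opt + ei + ej)
            fpm = objective(x_opt + ei - ej)
            fmp = objective(x_opt - ei + ej)
            fmm = objective(x_opt - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    names = PKParameters.names
    ses = {name: float("nan") for name in names}
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        for k, idx in enumerate(free_idx):
            name = names[idx]
            if diag[k] > 0:
                ses[name] = getattr(estimates, name) * math.sqrt(diag[k])
    except np.linalg.LinAlgError:
        pass
    return ses


def fit_two_stage(
    dataset: PKDataset,
    init: PKParameters,
    bounds: tuple[float, float] = _DEFAULT_BOUNDS,
    error: ErrorModel | None = None,
    seed: int | None = None,
    n_restarts: int = 4,
) -> FitResult:
    """Per-subject fits, then a population summary.

    Typical values are geometric means of the per-subject estimates;
    between-subject variability is reported as a log-normal CV,
    sqrt(exp(s²) - 1) with s the SD of the log estimates.  Subjects that
    fail to converge are dropped with a warning; fewer than 2 usable
    subjects is an error.
    """
    import warnings

    error = error or ErrorModel()
    subjects = dataset.subjects
    eligible = [
        sid for sid in subjects if len(dataset.subset(sid).quantifiable()) >= 4
    ]
    if len(eligible) < 2:
        raise FitError("two-stage estimation needs >= 2 subjects with >= 4 quantifiable observations")
    per_subject: dict[str, PKParameters] = {}
    rng = np.random.default_rng(seed)
    for sid in eligible:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            res = fit_pooled(
                dataset.subset(sid), init, bounds, error, seed=sub_seed, n_restarts=n_restarts
            )
            per_subject[sid] = res.estimates
        except FitError as exc:
            warnings.warn(f"subject {sid!r} excluded from two-stage summary: {exc}")
    if len(per_subject) < 2:
        raise FitError("fewer than 2 subjects converged in two-stage estimation")

    mat = np.log([p.as_array() for p in per_subject.values()])
    geo_mean = np.exp(mat.mean(axis=0))
    s = mat.std(axis=0, ddof=1)
    bsv_cv = np.sqrt(np.expm1(s**2))
    typical = PKParameters.from_array(geo_mean)
    summary = {
        name: {"geometric_mean": float(geo_mean[i]), "bsv_cv": float(bsv_cv[i])}
        for i, name in enumerate(PKParameters.names)
    }
    return FitResult(
        estimates=typical,
        standard_errors={name: float("nan") for name in PKParameters.names},
        objective=float("nan"),
        converged=True,
        n_obs=int(len(dataset.quantifiable())),
        per_subject=per_subject,
        summary=summary,
        settings={"n_restarts": n_restarts, "bounds": bounds, "seed": seed},
    )
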