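"""Synthetic monkey PK studies and assay plates.

Emulates the statistical structure the estimators assume: a two-dose
(100 and 1000 mg/kg, 30-min IV infusion, n = 3 per dose) cynomolgus
study with dense serum and sparse CSF sampling out to 1008 h, log-normal
between-subject variability on the structural parameters, log-normal
(proportional) residual error, LLOQ censoring with flags — and 4PL
standard-curve plates with multiplicative read noise over the reference
10-fold dilution series (10 down to 0.0001 µg/mL).

Reproducibility contract: every subject draws from its own stream
seeded by (master seed, subject index), so the same seed yields a
byte-identical dataset and adding subjects never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_quant import FourPL
from .errors import ValidationError
from .estimation import PKDataset
from .pk_model import DoseEvent, PKParameters, Regimen, simulate_profile

__all__ = [
    "StudyDesign",
    "VariabilityModel",
    "generate_monkey_study",
    "generate_assay_plate",
    "DEFAULT_STANDARD_SERIES",
]

#: 10-fold reference-antibody dilution series, µg/mL (10 -> 0.0001).
DEFAULT_STANDARD_SERIES = tuple(10.0 / 10**i for i in range(6))

_DEFAULT_SERUM_TIMES = (
    0.083, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 96.0, 168.0, 336.0, 504.0, 672.0, 840.0, 1008.0
)
_DEFAULT_CSF_TIMES = (24.0, 48.0, 96.0, 168.0, 336.0, 504.0, 672.0, 840.0, 1008.0)


@dataclass(frozen=True)
class StudyDesign:
    """Single-dose IV-infusion study layout.

    Defaults mirror the originating monkey study: 100 and 1000 mg/kg,
    three animals per dose, 30-min infusion, serum sampled densely from
    5 min to 1008 h, CSF sparsely from 24 h to 1008 h.
    """

    doses: tuple[tuple[float, int], ...] = ((100.0, 3), (1000.0, 3))
    infusion_h: float = 0.5
    body_weight_mean: float = 4.42
    body_weight_cv: float = 0.07
    serum_times: tuple[float, ...] = _DEFAULT_SERUM_TIMES
    csf_times: tuple[float, ...] = _DEFAULT_CSF_TIMES
    lloq: Mapping[str, float] = field(default_factory=lambda: {"serum": 1.0, "csf": 0.05})

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.doses):
            raise ValidationError("each dose group needs >= 1 subject")
        for times in (self.serum_times, self.csf_times):
            arr = np.asarray(times)
            if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
                raise ValidationError("sampling times must be >= 0 and sorted ascending")
        if self.body_weight_mean <= 0 or self.body_weight_cv < 0:
            raise ValidationError("body weight mean must be > 0 and CV >= 0")


@dataclass(frozen=True)
class VariabilityModel:
    """Between-subject and residual variability.

    ``bsv_cv`` may be a single CV applied to every structural parameter
    or a mapping parameter-name -> CV.  Residual error is log-normal
    multiplicative with the given proportional CV plus optional additive
    Gaussian noise.
    """

    bsv_cv: float | Mapping[str, float] = 0.30
    proportional_cv: float = 0.15
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        cvs = (
            self.bsv_cv.values() if isinstance(self.bsv_cv, Mapping) else [self.bsv_cv]
        )
        if any(cv < 0 for cv in cvs) or self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValidationError("variability components must be >= 0")

    def cv_for(self, name: str) -> float:
        if isinstance(self.bsv_cv, Mapping):
            return float(self.bsv_cv.get(name, 0.0))
        return float(self.bsv_cv)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _draw_subject_params(
    true_params: PKParameters, variability: VariabilityModel, rng: np.random.Generator
) -> PKParameters:
    values = []
    for name in PKParameters.names:
        tv = getattr(true_params, name)
        sigma = _lognormal_sigma(variability.cv_for(name))
        values.append(tv * np.exp(rng.normal(scale=sigma)) if sigma > 0 else tv)
    return PKParameters.from_array(values)


def _draw_body_weight(design: StudyDesign, rng: np.random.Generator) -> float:
    mean, sd = design.body_weight_mean, design.body_weight_mean * design.body_weight_cv
    if sd == 0:
        return mean
    while True:  # truncate at +/- 3 SD
        bw = rng.normal(mean, sd)
        if abs(bw - mean) <= 3 * sd:
            return bw


def generate_monkey_study(
    true_params: PKParameters,
    design: StudyDesign | None = None,
    variability: VariabilityModel | None = None,
) -> PKDataset:
    """Simulate a single-dose IV study as an observed-style dataset.

    Per subject: draw body weight and log-normal individual parameters,
    simulate the infusion, apply residual error at the sampling times,
    then flag records below the matrix LLOQ.  Deterministic given
    ``variability.seed``.
    """
    design = design or StudyDesign()
    variability = variability or VariabilityModel()
    rows = []
    doses: dict[str, tuple[DoseEvent, ...]] = {}
    weights: dict[str, float] = {}
    subject_index = 0
    for dose_mg_per_kg, n_subjects in design.doses:
        for _ in range(n_subjects):
            rng = np.random.default_rng([variability.seed, subject_index])
            sid = f"M{subject_index + 1:02d}"
            bw = _draw_body_weight(design, rng)
            indiv = _draw_subject_params(true_params, variability, rng)
            regimen = Regimen.single_iv_infusion(dose_mg_per_kg, bw, design.infusion_h, label=sid)
            grid = np.union1d(design.serum_times, design.csf_times)
            profile = simulate_profile(indiv, regimen, grid)
            sigma = _lognormal_sigma(variability.proportional_cv)
            for matrix, times in (("serum", design.serum_times), ("csf", design.csf_times)):
                series = profile.serum if matrix == "serum" else profile.csf
                idx = np.searchsorted(profile.times, times)
                pred = series[idx]
                eps = rng.normal(size=len(pred))
                obs = pred * np.exp(sigma * eps) if sigma > 0 else pred.copy()
                if variability.additive_sd > 0:
                    obs = obs + rng.normal(scale=variability.additive_sd, size=len(obs))
                lloq = design.lloq.get(matrix, 0.0)
                for t, value in zip(times, obs):
                    rows.append(
                        {
                            "subject_id": sid,
                            "time_h": float(t),
                            "conc": float(max(value, 0.0)),
                            "matrix": matrix,
                            "below_lloq": bool(value < lloq),
                        }
                    )
            doses[sid] = regimen.events
            weights[sid] = bw
            subject_index += 1
    observations = pd.DataFrame(rows, columns=["subject_id", "time_h", "conc", "matrix", "below_lloq"])
    return PKDataset(
        observations=observations,
        doses=doses,
        body_weights=weights,
        lloq=dict(design.lloq),
    )


def generate_assay_plate(
    true_curve: FourPL,
    sample_concentrations: Sequence[float] = (),
    noise_cv: float = 0.02,
    seed: int = 0,
    standards: Sequence[float] = DEFAULT_STANDARD_SERIES,
    background: float = 0.0,
    n_background_wells: int = 2,
) -> pd.DataFrame:
    """Simulate a calibration plate as a tidy table.

    Standards follow the reference dilution series; samples are placed
    at the requested true concentrations.  Measured responses are
    ``background + signal`` with log-normal multiplicative noise on the
    signal.  Columns: sample_id, role, concentration, response.
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(noise_cv)

    def measure(signal: float) -> float:
        noisy = signal * np.exp(rng.normal(scale=sigma)) if sigma > 0 else signal
        return float(background + noisy)

    rows = []
    for i, conc in enumerate(sorted(standards, reverse=True)):
        rows.append(
            {
                "sample_id": f"STD{i + 1}",
                "role": "standard",
                "concentration": float(conc),
                "response": measure(true_curve.response(conc)),
            }
        )
    for i, conc in enumerate(sample_concentrations):
        rows.append(
            {
                "sample_id": f"S{i + 1}",
                "role": "sample",
                "concentration": np.nan,
                "response": measure(true_curve.response(conc)),
            }
        )
    for i in range(n_background_wells):
        rows.append(
            {
                "sample_id": f"BKG{i + 1}",
                "role": "background",
                "concentration": np.nan,
                "response": float(background),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "role", "concentration", "response"])
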