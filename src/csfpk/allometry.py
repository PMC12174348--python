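"""Allometric interspecies scaling of compartmental PK parameters.

Volumes scale with body weight to the power 1; clearances and flows
(Cl, Cl2, Qcsf) scale with body weight to the power 0.8.  The defaults
reproduce the standard monkey-to-human projection for monoclonal
antibodies (4.42 kg cynomolgus -> 80 kg human).

Because all three clearance-like parameters share one exponent, every
dimensionless ratio built from them (e.g. Qcsf/Cl, and hence the
asymptotic CSF/serum AUC ratio) is invariant under scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .pk_model import PKParameters

__all__ = ["BodyScale", "scale_parameters", "invert_scale"]


@dataclass(frozen=True)
class BodyScale:
    """Source/target body weights (kg) and the scaling exponents."""

    source_weight: float
    target_weight: float
    volume_exponent: float = 1.0
    clearance_exponent: float = 0.8

    def __post_init__(self) -> None:
        if self.source_weight <= 0 or self.target_weight <= 0:
            raise ValidationError("body weights must be > 0")

    @property
    def volume_factor(self) -> float:
        return (self.target_weight / self.source_weight) ** self.volume_exponent

    @property
    def clearance_factor(self) -> float:
        return (self.target_weight / self.source_weight) ** self.clearance_exponent

    def inverted(self) -> "BodyScale":
        return BodyScale(
            source_weight=self.target_weight,
            target_weight=self.source_weight,
            volume_exponent=self.volume_exponent,
            clearance_exponent=self.clearance_exponent,
        )


def scale_parameters(params: PKParameters, scale: BodyScale) -> PKParameters:
    """Project typical-value parameters from source to target body weight."""
    fv, fc = scale.volume_factor, scale.clearance_factor
    return PKParameters(
        V=params.V * fv,
        Cl=params.Cl * fc,
        V2=params.V2 * fv,
        Cl2=params.Cl2 * fc,
        Vcsf=params.Vcsf * fv,
        Qcsf=params.Qcsf * fc,
    )


def invert_scale(params: PKParameters, scale: BodyScale) -> PKParameters:
    """Undo ``scale_parameters`` (source and target weights swapped).

    Needed when only the scaled parameter set is published and the
    source-species typical values must be recovered.
    """
    return scale_parameters(params, scale.inverted())
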