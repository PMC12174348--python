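"""Published reference inputs for the ART5803 serum--CSF PK analysis.

These constants are inputs to the analysis, reported by the originating
cynomolgus-monkey PopPK study and patient assay panel: the final
human-scaled model parameters, the body weights behind the allometric
projection, the CSF target concentration band, and the patient
serum/CSF 502-Ab-equivalent pseudo-concentration panel used for the
serum--CSF concordance analysis.
"""

from __future__ import annotations

from .allometry import BodyScale, invert_scale
from .assay_quant import ConcordancePair
from .pk_model import PKParameters
from .regimen_sim import TargetBand

__all__ = [
    "HUMAN_PARAMETERS",
    "HUMAN_BODY_WEIGHT_KG",
    "MONKEY_BODY_WEIGHT_KG",
    "MONKEY_HUMAN_SCALE",
    "monkey_typical_parameters",
    "CSF_TARGET_BAND",
    "PATIENT_PANEL",
]

#: Final human-scaled model parameters (mL and mL/h).
HUMAN_PARAMETERS = PKParameters(
    V=4570.0, Cl=29.8, V2=4340.0, Cl2=12.3, Vcsf=1910.0, Qcsf=0.0639
)

#: Mean human body weight assumed by the scaling, kg.
HUMAN_BODY_WEIGHT_KG = 80.0

#: Mean body weight of the six study monkeys, kg.
MONKEY_BODY_WEIGHT_KG = 4.42

#: Monkey -> human allometric scale (volumes ~ W^1, clearances ~ W^0.8).
MONKEY_HUMAN_SCALE = BodyScale(
    source_weight=MONKEY_BODY_WEIGHT_KG, target_weight=HUMAN_BODY_WEIGHT_KG
)


def monkey_typical_parameters() -> PKParameters:
    """Monkey typical values recovered by inverting the published
    human-scaled set through the allometric equations."""
    return invert_scale(HUMAN_PARAMETERS, MONKEY_HUMAN_SCALE)


#: CSF concentration band projected to block patient-autoantibody-driven
#: receptor internalization, µg/mL.
CSF_TARGET_BAND = TargetBand(low=0.6, high=2.5)

#: Patient 502-Ab-equivalent pseudo-concentrations (µg/mL): serum, CSF.
#: Patient #2's serum level was not determined (sample availability).
PATIENT_PANEL = (
    ConcordancePair(patient_id="#1", serum_value=2.2, csf_value=0.15),
    ConcordancePair(patient_id="#2", serum_value=None, csf_value=0.0078),
    ConcordancePair(patient_id="#3", serum_value=1.1, csf_value=0.082),
    ConcordancePair(patient_id="#4", serum_value=0.65, csf_value=0.078),
    ConcordancePair(patient_id="#5", serum_value=0.55, csf_value=0.018),
    ConcordancePair(patient_id="#6", serum_value=0.56, csf_value=0.015),
    ConcordancePair(patient_id="#7", serum_value=0.24, csf_value=0.015),
)
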