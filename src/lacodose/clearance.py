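"""Extracorporeal (CRRT) drug clearance and per-patient PK parameters.

Transmembrane clearance depends on the modality:

* CVVHD (diffusion): ``CL_HD = SA * Qd`` where Qd is the dialysate
  (effluent) flow and SA the saturation coefficient.
* CVVH, pre-dilution (convection): ``CL_HF = SC * Quf * Qp / (Qp + Qrep)``
  where Quf is the ultrafiltration (effluent) flow, Qrep the replacement
  fluid flow (equal to Quf in pre-dilution), and Qp the plasma flow,
  ``Qblood * (1 - hematocrit)``.  The dilution factor ``Qp/(Qp+Qrep) < 1``
  is why pre-dilution CVVH clears less than CVVHD at the same effluent rate.

Effluent rates are prescribed per kg of body weight per hour, so the
absolute effluent flow scales with patient weight.  All clearance
arithmetic is carried out in L/h; inputs in mL/min are converted on entry.
Native kidney clearance defaults to zero (anuric patients); total clearance
is CRRT plus non-renal, and the first-order elimination rate constant is
``k = CL_total / Vd`` with ``Vd = vd_per_kg * weight``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CRRTPrescription",
    "PKParameters",
    "effluent_flow",
    "transmembrane_clearance",
    "derive_pk",
    "ML_MIN_TO_L_H",
]

ML_MIN_TO_L_H = 60.0 / 1000.0

MODALITIES = ("CVVHD", "CVVH")


@dataclass(frozen=True)
class CRRTPrescription:
    """One CRRT machine setting.

    effluent_rate is in mL/kg/h, blood_flow in mL/min, hematocrit a
    fraction.  Only pre-dilution is supported for CVVH.
    """

    modality: str
    effluent_rate: float
    blood_flow: float = 200.0
    hematocrit: float = 0.30
    dilution: str = "pre"

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if not self.effluent_rate > 0:
            raise ValueError(f"effluent_rate must be > 0, got {self.effluent_rate}")
        if not self.blood_flow > 0:
            raise ValueError(f"blood_flow must be > 0, got {self.blood_flow}")
        if not 0 < self.hematocrit < 1:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        if self.modality == "CVVH" and self.dilution != "pre":
            raise ValueError("only pre-dilution CVVH is supported")

    @property
    def plasma_flow_l_h(self) -> float:
        """Qp = Qblood * (1 - hematocrit), converted to L/h."""
        return self.blood_flow * (1.0 - self.hematocrit) * ML_MIN_TO_L_H

    @property
    def label(self) -> str:
        return f"{self.modality}@{self.effluent_rate:g}"


@dataclass(frozen=True)
class PKParameters:
    """Per-patient disposition parameters, all in L/h, L and 1/h.

    Fields may be scalars or aligned numpy arrays (one entry per patient).
    """

    crrt_clearance: object
    clnr: object
    total_clearance: object
    vd: object
    k: object


def effluent_flow(prescription: CRRTPrescription, weight) -> object:
    """Absolute effluent flow in L/h for a weight-scaled prescription."""
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be > 0 kg")
    out = prescription.effluent_rate * weight / 1000.0
    return float(out) if out.ndim == 0 else out


def transmembrane_clearance(
    prescription: CRRTPrescription, weight, extraction_coefficient
) -> object:
    """CRRT clearance in L/h for one patient or an array of patients.

    ``extraction_coefficient`` is the saturation coefficient for CVVHD and
    the sieving coefficient for CVVH (the study uses one distribution for
    both).
    """
    q_effluent = effluent_flow(prescription, weight)
    sc = np.asarray(extraction_coefficient, dtype=float)
    if prescription.modality == "CVVHD":
        out = sc * q_effluent
    else:  # pre-dilution CVVH
        qp = prescription.plasma_flow_l_h
        out = sc * q_effluent * qp / (qp + q_effluent)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def derive_pk(
    patients: pd.DataFrame | pd.Series | dict,
    prescription: CRRTPrescription,
    renal_clearance_l_h: float = 0.0,
) -> PKParameters:
    """Assemble PK parameters for a cohort (or a single patient).

    Accepts a cohort DataFrame or any mapping with the cohort column names.
    Non-renal clearance arrives in mL/min and is converted; native renal
    clearance is zero by default (anuric assumption) but may be overridden
    for sensitivity analyses.
    """
    weight = np.asarray(patients["weight_kg"], dtype=float)
    vd = np.asarray(patients["vd_per_kg"], dtype=float) * weight
    clnr = np.asarray(patients["clnr_ml_min"], dtype=float) * ML_MIN_TO_L_H
    crrt = transmembrane_clearance(
        prescription, weight, patients["sieving_coefficient"]
    )
    total = np.asarray(crrt) + clnr + renal_clearance_l_h
    k = total / vd
    if k.ndim == 0:
        return PKParameters(float(np.asarray(crrt)), float(clnr), float(total), float(vd), float(k))
    return PKParameters(np.asarray(crrt), clnr, total, vd, k)
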