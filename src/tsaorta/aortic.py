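"""Turner-specific aortic morphometrics.

Aortic dilation in Turner syndrome cannot be judged against euploid nomograms
because longitudinal growth is altered; expected aortic-root (AR) and
ascending-aorta (AAO) diameters are instead modelled as quadratics in body
surface area fitted in a Turner-syndrome reference population.  A diameter is
expressed as a z-score on the square-root-cm scale,

    z = (sqrt(actual) - sqrt(expected)) / sqrt(MSE),

where MSE is the residual mean squared error of the reference regression.
Thoracic aortic dilation (TAD) is defined as any available z-score >= 1.9
after rounding to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "Vessel",
    "AorticMeasure",
    "SubjectRecord",
    "haycock_bsa",
    "expected_dimension",
    "aortic_z",
    "invert_z",
    "classify_tad",
    "classify_aortopathy",
    "round_half_up",
    "DEFAULT_MSE",
]

# Residual MSE (sqrt-cm scale) of the reference regressions.  The source
# regressions do not travel with this package; 0.01 is a placeholder so that
# structural identities hold — absolute z-scores against real echocardiograms
# require the published values, supplied via configuration.
DEFAULT_MSE = 0.01


class Vessel(str, Enum):
    AR = "AR"
    AAO = "AAO"


# expected diameter = |a + b*BSA + c*BSA^2| per vessel
_COEFFS = {
    Vessel.AR: (1.035, 0.589, -0.129),
    Vessel.AAO: (0.942, 0.593, -0.122),
}


def haycock_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Haycock power-law formula.

    BSA = 0.024265 * height^0.3964 * weight^0.5378 with height in cm and
    weight in kg.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError(
            f"height and weight must be positive, got {height_cm} cm / {weight_kg} kg"
        )
    return 0.024265 * height_cm**0.3964 * weight_kg**0.5378


def expected_dimension(
    bsa_m2: float, vessel: Vessel | str, *, absolute_value: bool = True
) -> float:
    """Expected vessel diameter (cm) at a given body surface area.

    The reference model publishes (expected)^2 = (a + b*BSA + c*BSA^2)^2;
    taking the square root leaves the absolute value of the quadratic, which
    is positive everywhere in the physiologic BSA range.  ``absolute_value``
    may be disabled to expose the raw polynomial.
    """
    if bsa_m2 < 0:
        raise ValueError(f"BSA must be non-negative, got {bsa_m2}")
    a, b, c = _COEFFS[Vessel(vessel)]
    poly = a + b * bsa_m2 + c * bsa_m2**2
    return abs(poly) if absolute_value else poly


def aortic_z(actual_cm: float, expected_cm: float, mse: float = DEFAULT_MSE) -> float:
    """z-score of an aortic diameter on the square-root scale."""
    if mse <= 0:
        raise ValueError(f"MSE must be positive, got {mse}")
    if actual_cm < 0 or expected_cm < 0:
        raise ValueError("diameters must be non-negative")
    return (math.sqrt(actual_cm) - math.sqrt(expected_cm)) / math.sqrt(mse)


def invert_z(z: float, expected_cm: float, mse: float = DEFAULT_MSE) -> float:
    """Actual diameter (cm) that yields z against an expected diameter.

    Exact inverse of :func:`aortic_z`: actual = (sqrt(expected) + z*sqrt(MSE))^2.
    Used by the cohort simulator so that re-scoring recovers the latent z.
    """
    if mse <= 0:
        raise ValueError(f"MSE must be positive, got {mse}")
    root = math.sqrt(expected_cm) + z * math.sqrt(mse)
    if root < 0:
        raise ValueError(f"z={z} drives the diameter negative at expected={expected_cm}")
    return root**2


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (half-up), e.g. 1.85 -> 1.9 at 1 d.p."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class AorticMeasure:
    """A single vessel measurement with its derived quantities."""

    vessel: Vessel
    actual_cm: float
    bsa_m2: float
    mse: float = DEFAULT_MSE
    expected_cm: float = field(init=False)
    z: float = field(init=False)

    def __post_init__(self) -> None:
        self.vessel = Vessel(self.vessel)
        if self.actual_cm <= 0:
            raise ValueError(f"actual diameter must be positive, got {self.actual_cm}")
        self.expected_cm = expected_dimension(self.bsa_m2, self.vessel)
        self.z = aortic_z(self.actual_cm, self.expected_cm, self.mse)


@dataclass
class SubjectRecord:
    """Per-subject phenotypes and inferred genotype groupings.

    Missing values are ``None`` and are dropped per-analysis (each report row
    carries its own N); nothing is imputed.
    """

    id: str
    bav: Optional[bool] = None
    coarctation: Optional[bool] = None
    lymphedema: Optional[bool] = None
    broad_chest: Optional[bool] = None
    webbed_neck: Optional[bool] = None
    poi: Optional[bool] = None
    hypertension: Optional[bool] = None
    dissection: Optional[bool] = None
    age_years: Optional[float] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    ar: Optional[AorticMeasure] = None
    aao: Optional[AorticMeasure] = None
    karyotype: Optional[str] = None
    timp1_copies: Optional[float] = None
    timp3_rs11547635_carrier: Optional[bool] = None

    @property
    def bsa_m2(self) -> Optional[float]:
        if self.height_cm is None or self.weight_kg is None:
            return None
        return haycock_bsa(self.height_cm, self.weight_kg)


class TadUndefined(Exception):
    """Raised when neither vessel has a measurement — exclude, don't guess."""


def classify_tad(ar_z: Optional[float] = None, aao_z: Optional[float] = None,
                 threshold: float = 1.9) -> bool:
    """TAD flag: max available z, rounded to one decimal, >= threshold.

    Rounding to tenths before comparison matches the one-decimal precision of
    the clinical threshold, so 1.85 counts as dilated and 1.84 does not.
    """
    zs = [z for z in (ar_z, aao_z) if z is not None]
    if not zs:
        raise TadUndefined("no AR or AAO z-score available; subject must be excluded")
    return round_half_up(max(zs), 1) >= threshold


def classify_aortopathy(subject: SubjectRecord, threshold: float = 1.9) -> dict:
    """Aortopathy flags for one subject.

    Returns ``{"bav", "tad", "bav_with_tad", "any_aortic_risk"}``; ``tad`` and
    ``bav_with_tad`` are ``None`` when no aortic measurement exists.  Any
    aortic risk = BAV or coarctation or TAD.
    """
    if subject.bav is None:
        raise ValueError(f"subject {subject.id}: BAV status unknown")
    ar_z = subject.ar.z if subject.ar is not None else None
    aao_z = subject.aao.z if subject.aao is not None else None
    try:
        tad: Optional[bool] = classify_tad(ar_z, aao_z, threshold)
    except TadUndefined:
        tad = None
    bav_with_tad = (subject.bav and tad) if tad is not None else None
    any_risk = bool(subject.bav) or bool(subject.coarctation) or bool(tad)
    return {
        "bav": bool(subject.bav),
        "tad": tad,
        "bav_with_tad": bav_with_tad,
        "any_aortic_risk": any_risk,
    }
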