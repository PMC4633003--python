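"""Core IVUS domain types and derived cross-sectional geometry.

An intravascular-ultrasound (IVUS) pullback yields one cross-sectional frame
every fraction of a millimetre along a coronary artery.  Each frame carries two
planimetric measurements:

* **lumen area** — the blood channel inside the intimal border (mm²), and
* **EEM area** — the area enclosed by the external elastic membrane, i.e. the
  whole vessel cross-section (mm²).

Everything else is derived: *plaque + media area* is EEM minus lumen, and
*plaque burden* is that difference as a percentage of the EEM area.  Optional
virtual-histology (VH) output splits the plaque into four tissue components
(fibrous, fibrolipidic, necrotic core, dense calcium).

This module holds the record types for patients and frames, the geometry
derivation, and body-surface-area (BSA) formulas used as a constitutional
covariate for normal vessel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: Vessel labels accepted throughout the package (uppercase canonical form).
VESSELS = ("LM", "LAD", "LCX", "RCA")

#: Coronary dominance levels; "left" and "balanced" share one model level.
DOMINANCE_LEVELS = ("right", "left", "balanced")

BSA_FORMULAS = ("mosteller", "dubois")

#: Canonical column order of a frames table.
FRAME_COLUMNS = [
    "patient_id",
    "artery_id",
    "vessel",
    "frame_index",
    "distance_mm",
    "lumen_area_mm2",
    "eem_area_mm2",
]

#: Optional VH tissue-component area columns (mm²), blank when VH is absent.
COMPOSITION_COLUMNS = [
    "fibrous_mm2",
    "fibrofatty_mm2",
    "necrotic_mm2",
    "dense_calcium_mm2",
]

PATIENT_COLUMNS = ["patient_id", "weight_kg", "height_cm", "bsa_m2", "dominance"]


class ValidationError(ValueError):
    """An input violated an IVUS domain invariant."""


def compute_bsa(weight_kg: float, height_cm: float, formula: str = "mosteller") -> float:
    """Body surface area in m² from weight (kg) and height (cm).

    The Mosteller formula ``sqrt(weight * height / 3600)`` is the default;
    Du Bois (``0.007184 * height^0.725 * weight^0.425``) is selectable.
    """
    if not (weight_kg > 0 and height_cm > 0):
        raise ValidationError(
            f"weight and height must be positive, got weight={weight_kg}, height={height_cm}"
        )
    if formula == "mosteller":
        return math.sqrt(weight_kg * height_cm / 3600.0)
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    raise ValueError(f"unknown BSA formula {formula!r}; expected one of {BSA_FORMULAS}")


def dominance_indicator(dominance: str) -> int:
    """Binary dominance code: 0 = right-dominant (reference), 1 = left or balanced."""
    if dominance not in DOMINANCE_LEVELS:
        raise ValidationError(
            f"unknown dominance {dominance!r}; expected one of {DOMINANCE_LEVELS}"
        )
    return 0 if dominance == "right" else 1


@dataclass(frozen=True)
class PatientProfile:
    """Per-patient constitutional covariates for normal vessel size."""

    patient_id: str
    weight_kg: float
    height_cm: float
    bsa_m2: float
    dominance: str

    def __post_init__(self) -> None:
        if not (self.weight_kg > 0 and self.height_cm > 0 and self.bsa_m2 > 0):
            raise ValidationError(
                f"patient {self.patient_id}: weight, height and BSA must be positive"
            )
        dominance_indicator(self.dominance)  # validates

    @property
    def dominance_indicator(self) -> int:
        return dominance_indicator(self.dominance)

    @classmethod
    def from_measurements(
        cls,
        patient_id: str,
        weight_kg: float,
        height_cm: float,
        dominance: str,
        bsa_m2: Optional[float] = None,
        bsa_formula: str = "mosteller",
    ) -> "PatientProfile":
        """Build a profile, computing BSA from weight/height when not supplied."""
        if bsa_m2 is None:
            bsa_m2 = compute_bsa(weight_kg, height_cm, bsa_formula)
        return cls(patient_id, weight_kg, height_cm, bsa_m2, dominance)


@dataclass(frozen=True)
class CompositionProfile:
    """VH plaque composition of one frame: four tissue-component areas (mm²).

    Percentages are expressed over the sum of the four component areas (the
    VH confluent-plaque convention).
    """

    fibrous_mm2: float
    fibrofatty_mm2: float
    necrotic_mm2: float
    dense_calcium_mm2: float

    def __post_init__(self) -> None:
        for name, value in self.areas().items():
            if value < 0:
                raise ValidationError(f"composition area {name} must be >= 0, got {value}")

    def areas(self) -> dict[str, float]:
        return {
            "fibrous": self.fibrous_mm2,
            "fibrofatty": self.fibrofatty_mm2,
            "necrotic": self.necrotic_mm2,
            "dense_calcium": self.dense_calcium_mm2,
        }

    @property
    def total_mm2(self) -> float:
        return sum(self.areas().values())

    def percentages(self) -> dict[str, float]:
        """Component percentages of the component sum; all zero when sum is 0."""
        total = self.total_mm2
        if total <= 0:
            return {name: 0.0 for name in self.areas()}
        return {name: 100.0 * area / total for name, area in self.areas().items()}


@dataclass(frozen=True)
class FrameMeasurement:
    """One IVUS cross-section with its raw planimetric measurements."""

    patient_id: str
    artery_id: str
    vessel: str
    frame_index: int
    distance_mm: float
    lumen_area_mm2: float
    eem_area_mm2: float
    composition: Optional[CompositionProfile] = None

    def __post_init__(self) -> None:
        if self.vessel not in VESSELS:
            raise ValidationError(
                f"{self.label}: unknown vessel {self.vessel!r}; expected one of {VESSELS}"
            )
        if self.distance_mm < 0:
            raise ValidationError(f"{self.label}: distance from ostium must be >= 0")
        if not self.lumen_area_mm2 > 0:
            raise ValidationError(f"{self.label}: lumen area must be positive")
        if self.lumen_area_mm2 > self.eem_area_mm2:
            raise ValidationError(
                f"{self.label}: lumen area {self.lumen_area_mm2} exceeds "
                f"EEM area {self.eem_area_mm2}"
            )

    @property
    def label(self) -> str:
        return f"frame {self.patient_id}/{self.artery_id}#{self.frame_index}"


@dataclass(frozen=True)
class DerivedGeometry:
    """Plaque + media area (mm²) and plaque burden (%) of one frame."""

    plaque_media_area_mm2: float
    plaque_burden_pct: float


def derive_geometry(frame: FrameMeasurement) -> DerivedGeometry:
    """Derived geometry of one frame.

    plaque + media area = EEM − lumen; plaque burden = 100·(EEM − lumen)/EEM.
    The frame's own invariants guarantee 0 <= burden < 100.
    """
    plaque = frame.eem_area_mm2 - frame.lumen_area_mm2
    burden = 100.0 * plaque / frame.eem_area_mm2
    return DerivedGeometry(plaque_media_area_mm2=plaque, plaque_burden_pct=burden)


def add_geometry(frames: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a frames table with derived-geometry columns appended.

    Adds ``plaque_media_area_mm2`` and ``plaque_burden_pct``.  Rows violating
    ``0 < lumen <= eem`` raise :class:`ValidationError` naming the offenders.
    """
    lumen = frames["lumen_area_mm2"].to_numpy(float)
    eem = frames["eem_area_mm2"].to_numpy(float)
    bad = ~((lumen > 0) & (lumen <= eem))
    if bad.any():
        rows = frames.index[bad].tolist()[:10]
        raise ValidationError(
            f"{int(bad.sum())} frame(s) violate 0 < lumen <= EEM (rows {rows})"
        )
    out = frames.copy()
    out["plaque_media_area_mm2"] = eem - lumen
    out["plaque_burden_pct"] = 100.0 * (eem - lumen) / eem
    return out
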