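"""The fractional vessel remodeling index (FVRI) and its frame classifier.

FVRI compares a frame's measured vessel size with the size it *should* have
if the inferred pre-disease vessel had enlarged exactly enough to accommodate
the plaque (complete Glagov compensation)::

    FVRI = EEM_actual / (EEM_predicted + plaque_area)          (default)

An index of 1 means the vessel grew by exactly the plaque load; values above
1 mean disproportionate (ectatic) expansion, below 1 incomplete compensation
or outright shrinkage.  An algebraically different variant with the same
fixed point, ``(EEM_actual - plaque) / EEM_predicted``, is selectable; both
equal 1 exactly when ``EEM_actual = EEM_predicted + plaque`` and agree on the
sign of FVRI - 1 everywhere.

Frames with established plaque (burden >= 20%) are classified into four
patterns using a symmetric band around 1 (default 0.83–1.17, one standard
deviation of the lesion-level index):

* ``ectatic`` — FVRI > 1.17;
* ``complete_compensatory`` — 0.83 <= FVRI <= 1.17 (inclusive);
* ``negative`` — FVRI < 0.83 with EEM_actual < EEM_predicted (absolute
  shrinkage of the vessel);
* ``incomplete_compensatory`` — FVRI < 0.83 with EEM_actual >=
  EEM_predicted (enlargement insufficient for the plaque).

Frames below 20% burden are labelled ``trivial_plaque`` and not classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from fvri.core import ValidationError
from fvri.io import Cohort, frames_with_covariates
from fvri.normal_model import LUMEN_RANGE, NormalModelSpec, design_matrix

logger = logging.getLogger("fvri")

FORMULA_VARIANTS = ("compensation_ratio", "lumen_ratio")

#: Remodeling classes assigned to frames with established plaque, plus the
#: label for frames below the trivial-plaque burden cutoff.
REMODELING_CLASSES = (
    "negative",
    "incomplete_compensatory",
    "complete_compensatory",
    "ectatic",
)
TRIVIAL_CLASS = "trivial_plaque"


@dataclass(frozen=True)
class FvriConfig:
    """Scoring thresholds: the complete-compensation band, the trivial-plaque
    burden cutoff (%) and the formula variant."""

    band_low: float = 0.83
    band_high: float = 1.17
    trivial_burden_cutoff: float = 20.0
    formula_variant: str = "compensation_ratio"

    def __post_init__(self) -> None:
        if not (0 < self.band_low < 1 < self.band_high):
            raise ValidationError(
                f"band must satisfy 0 < low < 1 < high, got "
                f"({self.band_low}, {self.band_high})"
            )
        if self.formula_variant not in FORMULA_VARIANTS:
            raise ValidationError(
                f"formula_variant must be one of {FORMULA_VARIANTS}, "
                f"got {self.formula_variant!r}"
            )


def derive_band_from_sd(sd: float) -> tuple[float, float]:
    """Complete-compensation band (1 - sd, 1 + sd) from a lesion-level FVRI
    standard deviation; ``sd`` must lie strictly between 0 and 1."""
    if not 0 < sd < 1:
        raise ValidationError(f"band SD must be in (0, 1), got {sd}")
    return (1.0 - sd, 1.0 + sd)


def compute_fvri(
    eem_actual,
    eem_predicted,
    plaque_area,
    config: Union[FvriConfig, str, None] = None,
):
    """FVRI of one frame (or arrays of frames).

    All inputs must be positive: a frame with no plaque has no defined index
    (the classifier routes such frames to ``trivial_plaque`` instead).
    """
    variant = (
        config.formula_variant
        if isinstance(config, FvriConfig)
        else (config or "compensation_ratio")
    )
    if variant not in FORMULA_VARIANTS:
        raise ValidationError(f"unknown formula variant {variant!r}")
    a = np.asarray(eem_actual, dtype=float)
    p = np.asarray(eem_predicted, dtype=float)
    pl = np.asarray(plaque_area, dtype=float)
    if np.any(a <= 0) or np.any(p <= 0) or np.any(pl <= 0):
        raise ValidationError(
            "compute_fvri requires positive EEM_actual, EEM_predicted and "
            "plaque area (plaque-free frames are classified as trivial_plaque "
            "without an index)"
        )
    if variant == "compensation_ratio":
        out = a / (p + pl)
    else:
        out = (a - pl) / p
    return out if out.ndim else float(out)


def classify_frame(
    fvri: Optional[float],
    plaque_burden_pct: float,
    eem_actual: float,
    eem_predicted: float,
    config: FvriConfig = FvriConfig(),
) -> str:
    """Remodeling pattern of one frame.

    Burden below the trivial cutoff short-circuits to ``trivial_plaque``
    (``fvri`` may then be None); otherwise the band and the sign of
    ``EEM_actual - EEM_predicted`` decide among the four patterns.
    """
    if plaque_burden_pct < config.trivial_burden_cutoff:
        return TRIVIAL_CLASS
    if fvri is None or np.isnan(fvri):
        raise ValidationError("classification above the burden cutoff needs an index")
    if fvri > config.band_high:
        return "ectatic"
    if fvri >= config.band_low:
        return "complete_compensatory"
    return "negative" if eem_actual < eem_predicted else "incomplete_compensatory"


def classify_frames(
    fvri: np.ndarray,
    plaque_burden_pct: np.ndarray,
    eem_actual: np.ndarray,
    eem_predicted: np.ndarray,
    config: FvriConfig = FvriConfig(),
) -> np.ndarray:
    """Vectorized :func:`classify_frame` (object array of class labels)."""
    fvri = np.asarray(fvri, dtype=float)
    trivial = np.asarray(plaque_burden_pct) < config.trivial_burden_cutoff
    if np.any(~trivial & np.isnan(fvri)):
        raise ValidationError("classification above the burden cutoff needs an index")
    with np.errstate(invalid="ignore"):
        return np.select(
            [
                trivial,
                fvri > config.band_high,
                fvri >= config.band_low,
                np.asarray(eem_actual) < np.asarray(eem_predicted),
            ],
            [TRIVIAL_CLASS, "ectatic", "complete_compensatory", "negative"],
            default="incomplete_compensatory",
        )


def score_frames(
    cohort: Cohort,
    model: NormalModelSpec,
    config: FvriConfig = FvriConfig(),
) -> pd.DataFrame:
    """Score every frame of a cohort: geometry, EEM_predicted, FVRI, class.

    Returns the frames table extended with ``plaque_media_area_mm2``,
    ``plaque_burden_pct``, ``eem_pred_mm2``, ``fvri`` (NaN for plaque-free
    frames), ``remodeling_class`` and ``formula_variant``.
    """
    frames = frames_with_covariates(cohort)
    X = design_matrix(frames, model.vessel_coding, model.log_clamp_mm)
    eem_pred = model.linear_predictor(X)
    out_of_range = int(np.sum((eem_pred < LUMEN_RANGE[0]) | (eem_pred > LUMEN_RANGE[1])))
    if out_of_range:
        logger.warning(
            "%d of %d predicted normal EEM areas fall outside the plausible "
            "range %s mm²",
            out_of_range,
            len(eem_pred),
            LUMEN_RANGE,
        )
    eem = frames["eem_area_mm2"].to_numpy(float)
    plaque = frames["plaque_media_area_mm2"].to_numpy(float)
    burden = frames["plaque_burden_pct"].to_numpy(float)

    has_plaque = plaque > 0
    fvri = np.full(len(frames), np.nan)
    if has_plaque.any():
        fvri[has_plaque] = compute_fvri(
            eem[has_plaque], eem_pred[has_plaque], plaque[has_plaque], config
        )

    scored = frames.drop(columns=["bsa_m2", "dominance_indicator"])
    scored["eem_pred_mm2"] = eem_pred
    scored["fvri"] = fvri
    scored["remodeling_class"] = classify_frames(fvri, burden, eem, eem_pred, config)
    scored["formula_variant"] = config.formula_variant
    n_classified = int((burden >= config.trivial_burden_cutoff).sum())
    logger.info(
        "scored %d frames (%d with established plaque >= %.0f%% burden)",
        len(scored),
        n_classified,
        config.trivial_burden_cutoff,
    )
    return scored
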