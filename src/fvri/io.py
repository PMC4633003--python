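"""Reading and writing pullback tables.

Two delimited tables describe a study:

``frames.csv``
    patient_id, artery_id, vessel, frame_index, distance_mm, lumen_area_mm2,
    eem_area_mm2 and four optional VH component-area columns (blank allowed).

``patients.csv``
    patient_id, weight_kg, height_cm, bsa_m2 (optional; computed when blank)
    and dominance (right / left / balanced).

Reading validates every domain invariant and reports offending file rows
(1-based, header included, i.e. the row number an editor would show).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from fvri.core import (
    COMPOSITION_COLUMNS,
    DOMINANCE_LEVELS,
    FRAME_COLUMNS,
    PATIENT_COLUMNS,
    ValidationError,
    VESSELS,
    add_geometry,
    compute_bsa,
    dominance_indicator,
)

logger = logging.getLogger("fvri")

PathLike = Union[str, Path]

#: Serialized precision of numeric fields in all CSV artifacts.
FLOAT_FORMAT = "%.6f"


@dataclass
class Cohort:
    """A validated study: frames grouped per (patient, artery) plus covariates.

    ``frames`` is sorted by (patient_id, artery_id, distance_mm); ``patients``
    carries ``bsa_m2`` (filled) and the binary ``dominance_indicator``.
    """

    frames: pd.DataFrame
    patients: pd.DataFrame

    def arteries(self):
        """Iterate over (patient_id, artery_id) -> per-artery frame table."""
        return self.frames.groupby(["patient_id", "artery_id"], sort=True)


def _file_row(df_index: int) -> int:
    # pandas row i of the data corresponds to file line i+2 (header is line 1)
    return df_index + 2


def read_patients(path: PathLike, bsa_formula: str = "mosteller") -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PATIENT_COLUMNS if c != "bsa_m2" and c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing patient column(s) {missing}")
    errors: list[str] = []
    if "bsa_m2" not in df.columns:
        df["bsa_m2"] = np.nan
    for i, row in df.iterrows():
        if not (row.weight_kg > 0 and row.height_cm > 0):
            errors.append(f"row {_file_row(i)}: nonpositive weight/height")
        if row.dominance not in DOMINANCE_LEVELS:
            errors.append(f"row {_file_row(i)}: unknown dominance {row.dominance!r}")
    if errors:
        raise ValidationError(f"{path}: invalid patients table:\n" + "\n".join(errors))
    blank = df["bsa_m2"].isna()
    df.loc[blank, "bsa_m2"] = [
        compute_bsa(w, h, bsa_formula)
        for w, h in zip(df.loc[blank, "weight_kg"], df.loc[blank, "height_cm"])
    ]
    df["dominance_indicator"] = [dominance_indicator(d) for d in df["dominance"]]
    return df


def validate_frames(frames: pd.DataFrame, patients: pd.DataFrame) -> list[str]:
    """Collect invariant violations of a frames table as row-tagged messages."""
    errors: list[str] = []
    known_patients = set(patients["patient_id"])
    lumen = frames["lumen_area_mm2"]
    eem = frames["eem_area_mm2"]
    for i in frames.index[~(lumen > 0)]:
        errors.append(f"row {_file_row(i)}: lumen area must be positive")
    for i in frames.index[lumen > eem]:
        errors.append(
            f"row {_file_row(i)}: lumen area {lumen[i]} exceeds EEM area {eem[i]}"
        )
    for i in frames.index[frames["distance_mm"] < 0]:
        errors.append(f"row {_file_row(i)}: negative distance from ostium")
    for i in frames.index[~frames["patient_id"].isin(known_patients)]:
        errors.append(f"row {_file_row(i)}: unknown patient {frames.patient_id[i]!r}")
    for (pid, aid), grp in frames.groupby(["patient_id", "artery_id"], sort=False):
        order = grp.sort_values("frame_index")
        if not order["distance_mm"].is_monotonic_increasing or order[
            "distance_mm"
        ].duplicated().any():
            errors.append(
                f"artery {pid}/{aid}: distances must increase strictly with frame index"
            )
        if order["frame_index"].duplicated().any():
            errors.append(f"artery {pid}/{aid}: duplicated frame_index")
    return errors


def read_pullbacks(
    frames_path: PathLike,
    patients_path: PathLike,
    bsa_formula: str = "mosteller",
) -> Cohort:
    """Read and validate the two study tables into a :class:`Cohort`.

    Frames in vessels other than LM/LAD/LCX/RCA are dropped with a warning
    (they carry no vessel code in the normal-dimension model).  Any other
    violation raises :class:`ValidationError` citing file rows.
    """
    patients = read_patients(patients_path, bsa_formula=bsa_formula)
    frames = pd.read_csv(frames_path)
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise ValidationError(f"{frames_path}: missing frame column(s) {missing}")
    for col in COMPOSITION_COLUMNS:
        if col not in frames.columns:
            frames[col] = np.nan

    frames["vessel"] = frames["vessel"].astype(str).str.upper()
    other = ~frames["vessel"].isin(VESSELS)
    if other.any():
        logger.warning(
            "dropping %d frame(s) in unsupported vessel(s) %s",
            int(other.sum()),
            sorted(frames.loc[other, "vessel"].unique()),
        )
        frames = frames[~other]

    errors = validate_frames(frames, patients)
    if errors:
        raise ValidationError(
            f"{frames_path}: invalid frames table:\n" + "\n".join(errors)
        )

    frames = frames.sort_values(
        ["patient_id", "artery_id", "distance_mm"], kind="mergesort"
    ).reset_index(drop=True)
    n_arteries = frames.groupby(["patient_id", "artery_id"]).ngroups
    logger.info(
        "read %d frames in %d arteries of %d patients",
        len(frames),
        n_arteries,
        len(patients),
    )
    return Cohort(frames=frames, patients=patients)


def write_frames(frames: pd.DataFrame, path: PathLike) -> None:
    """Write a frames table at the package's 6-decimal serialized precision."""
    cols = [c for c in FRAME_COLUMNS + COMPOSITION_COLUMNS if c in frames.columns]
    extra = [c for c in frames.columns if c not in cols]
    frames[cols + extra].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_patients(patients: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in PATIENT_COLUMNS if c in patients.columns]
    patients[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def frames_with_covariates(cohort: Cohort) -> pd.DataFrame:
    """Frames joined with patient covariates and derived geometry.

    Adds ``bsa_m2``, ``dominance_indicator``, ``plaque_media_area_mm2`` and
    ``plaque_burden_pct``; the covariate columns feed the design matrix of the
    normal-dimension model.
    """
    frames = add_geometry(cohort.frames)
    pat = cohort.patients.set_index("patient_id")
    frames = frames.merge(
        pat[["bsa_m2", "dominance_indicator"]],
        left_on="patient_id",
        right_index=True,
        how="left",
    )
    return frames
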