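"""Lesion detection, dual remodeling classification, and scheme agreement.

A lesion is any maximal run of at least three consecutive frames with plaque
burden above 40%.  Its representative cross-section is the minimal-lumen-area
(MLA) frame; ties break to the most proximal frame.  Two classifications are
assigned per lesion:

* the FVRI-based pattern, read off the MLA frame's score, and
* the classical remodeling index — MLA-frame EEM over the mean EEM of the
  immediately adjacent proximal and distal reference frames (burden <= 40% by
  maximality) — categorized as negative (< 0.88), intermediate (0.88–1.00,
  inclusive) or positive (> 1.00).

Lesions touching a pullback boundary lack a reference and are excluded from
the classical-index analysis (but still scored by FVRI).  The 4×3
cross-tabulation of the two schemes, with marginals, percent agreement and
Cohen's kappa, quantifies how far the two diagnostic vocabularies coincide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from fvri.core import COMPOSITION_COLUMNS, ValidationError
from fvri.engine import FvriConfig

logger = logging.getLogger("fvri")

#: Row (FVRI scheme) and column (classical scheme) orders of the agreement
#: table, matching the published presentation.
FVRI_CLASS_ORDER = (
    "negative",
    "incomplete_compensatory",
    "complete_compensatory",
    "ectatic",
)
CLASSICAL_CLASS_ORDER = ("negative", "intermediate", "positive")

#: Cells counted as concordant: the three named diagnostic pairs plus
#: ectatic/positive (both denote expansion).
NAMED_CONCORDANT_PAIRS = (
    ("negative", "negative"),
    ("incomplete_compensatory", "intermediate"),
    ("complete_compensatory", "positive"),
)
CONCORDANT_PAIRS = NAMED_CONCORDANT_PAIRS + (("ectatic", "positive"),)

#: Classical-index category cutoffs (negative below, positive above).
CLASSICAL_CUTS = (0.88, 1.00)

#: Lesion rule: minimum run length and burden threshold (%).
LESION_MIN_RUN = 3
LESION_BURDEN_PCT = 40.0

#: Composition percentage columns carried on the lesion table.
COMPOSITION_PCT_COLUMNS = [c.replace("_mm2", "_pct") for c in COMPOSITION_COLUMNS]


@dataclass(frozen=True)
class Lesion:
    """A maximal high-burden run within one artery.

    ``start``/``end`` are inclusive positional indices into the artery's
    distance-sorted frame table; ``length_mm`` spans first to last frame.
    """

    patient_id: str
    artery_id: str
    start: int
    end: int
    start_frame_index: int
    end_frame_index: int
    length_mm: float

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


def detect_lesion_spans(
    burdens: Sequence[float],
    burden_cutoff_pct: float = LESION_BURDEN_PCT,
    min_run: int = LESION_MIN_RUN,
) -> list[tuple[int, int]]:
    """All maximal runs of burden > cutoff with length >= ``min_run``.

    Returns inclusive (start, end) positional pairs in proximal-to-distal
    order; runs never overlap by construction.
    """
    spans: list[tuple[int, int]] = []
    start: Optional[int] = None
    burdens = np.asarray(burdens, dtype=float)
    for i, b in enumerate(burdens):
        if b > burden_cutoff_pct:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_run:
                spans.append((start, i - 1))
            start = None
    if start is not None and len(burdens) - start >= min_run:
        spans.append((start, len(burdens) - 1))
    return spans


def detect_lesions(
    artery_frames: pd.DataFrame,
    burden_cutoff_pct: float = LESION_BURDEN_PCT,
    min_run: int = LESION_MIN_RUN,
) -> list[Lesion]:
    """Lesions of one artery (frames must be sorted by distance)."""
    frames = artery_frames.reset_index(drop=True)
    spans = detect_lesion_spans(
        frames["plaque_burden_pct"].to_numpy(), burden_cutoff_pct, min_run
    )
    return [
        Lesion(
            patient_id=str(frames.at[0, "patient_id"]),
            artery_id=str(frames.at[0, "artery_id"]),
            start=s,
            end=e,
            start_frame_index=int(frames.at[s, "frame_index"]),
            end_frame_index=int(frames.at[e, "frame_index"]),
            length_mm=float(
                frames.at[e, "distance_mm"] - frames.at[s, "distance_mm"]
            ),
        )
        for s, e in spans
    ]


def select_mla_frame(artery_frames: pd.DataFrame, span: tuple[int, int]) -> int:
    """Positional index of the minimal-lumen-area frame within a span.

    Ties break to the smallest distance (most proximal frame).
    """
    s, e = span
    lumen = artery_frames["lumen_area_mm2"].to_numpy(float)[s : e + 1]
    return s + int(np.argmin(lumen))  # argmin returns the first minimum


def find_references(
    artery_frames: pd.DataFrame, span: tuple[int, int]
) -> tuple[Optional[int], Optional[int]]:
    """Positional indices of the proximal/distal reference frames.

    References are the immediate out-of-span neighbors (burden <= 40% by run
    maximality); ``None`` when the lesion touches a pullback boundary.
    """
    s, e = span
    prox = s - 1 if s > 0 else None
    dist = e + 1 if e < len(artery_frames) - 1 else None
    return prox, dist


def classical_index(eem_mla: float, eem_prox: float, eem_dist: float) -> float:
    """Classical remodeling index: MLA EEM over the mean reference EEM."""
    if not (eem_mla > 0 and eem_prox > 0 and eem_dist > 0):
        raise ValidationError("classical_index requires positive EEM areas")
    return eem_mla / ((eem_prox + eem_dist) / 2.0)


def classify_classical(index: float, cuts: tuple[float, float] = CLASSICAL_CUTS) -> str:
    """Categorize a classical index: < low → negative, [low, high] →
    intermediate (inclusive bounds), > high → positive."""
    if not index > 0:
        raise ValidationError(f"classical index must be positive, got {index}")
    low, high = cuts
    if index < low:
        return "negative"
    if index <= high:
        return "intermediate"
    return "positive"


def assess_lesions(
    scored_frames: pd.DataFrame,
    config: FvriConfig = FvriConfig(),
    burden_cutoff_pct: float = LESION_BURDEN_PCT,
    min_run: int = LESION_MIN_RUN,
    classical_cuts: tuple[float, float] = CLASSICAL_CUTS,
) -> pd.DataFrame:
    """Per-lesion assessment table from scored frames.

    One row per detected lesion: span, length, MLA-frame geometry and FVRI
    class, references, classical index and class (NaN when a reference is
    missing, with ``has_references`` False), and MLA-frame VH composition
    percentages when present.
    """
    rows: list[dict] = []
    lesion_id = 0
    for (pid, aid), artery in scored_frames.groupby(
        ["patient_id", "artery_id"], sort=True
    ):
        artery = artery.sort_values("distance_mm").reset_index(drop=True)
        for lesion in detect_lesions(artery, burden_cutoff_pct, min_run):
            span = (lesion.start, lesion.end)
            mla = select_mla_frame(artery, span)
            prox, dist = find_references(artery, span)
            m = artery.iloc[mla]
            lesion_id += 1
            row = {
                "lesion_id": lesion_id,
                "patient_id": pid,
                "artery_id": aid,
                "span_start_frame": lesion.start_frame_index,
                "span_end_frame": lesion.end_frame_index,
                "n_frames": lesion.n_frames,
                "length_mm": lesion.length_mm,
                "mla_frame_index": int(m["frame_index"]),
                "mla_lumen_mm2": float(m["lumen_area_mm2"]),
                "mla_eem_mm2": float(m["eem_area_mm2"]),
                "plaque_burden_pct": float(m["plaque_burden_pct"]),
                "eem_pred_mm2": float(m["eem_pred_mm2"]),
                "fvri": float(m["fvri"]),
                "fvri_class": m["remodeling_class"],
                "has_references": prox is not None and dist is not None,
                "eem_prox_mm2": np.nan,
                "eem_dist_mm2": np.nan,
                "classical_index": np.nan,
                "classical_class": None,
            }
            if row["has_references"]:
                ep = float(artery.at[prox, "eem_area_mm2"])
                ed = float(artery.at[dist, "eem_area_mm2"])
                ci = classical_index(row["mla_eem_mm2"], ep, ed)
                row.update(
                    eem_prox_mm2=ep,
                    eem_dist_mm2=ed,
                    classical_index=ci,
                    classical_class=classify_classical(ci, classical_cuts),
                )
            comp = m[COMPOSITION_COLUMNS].astype(float)
            total = comp.sum()
            for col, pct_col in zip(COMPOSITION_COLUMNS, COMPOSITION_PCT_COLUMNS):
                row[pct_col] = (
                    100.0 * float(comp[col]) / total if total > 0 else np.nan
                )
            rows.append(row)
    lesions = pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "patient_id", "artery_id", "span_start_frame",
            "span_end_frame", "n_frames", "length_mm", "mla_frame_index",
            "mla_lumen_mm2", "mla_eem_mm2", "plaque_burden_pct", "eem_pred_mm2",
            "fvri", "fvri_class", "has_references", "eem_prox_mm2",
            "eem_dist_mm2", "classical_index", "classical_class",
        ] + COMPOSITION_PCT_COLUMNS,
    )
    n_refs = int(lesions["has_references"].sum()) if len(lesions) else 0
    logger.info(
        "detected %d lesion(s), %d with both references", len(lesions), n_refs
    )
    return lesions


def _kappa_collapsed(counts: np.ndarray) -> float:
    """Cohen's kappa on the 3×3 collapse (ectatic merged with complete)."""
    collapsed = counts[:3].copy().astype(float)
    collapsed[2] += counts[3]
    y_fvri, y_classical, w = [], [], []
    for i in range(3):
        for j in range(3):
            if collapsed[i, j] > 0:
                y_fvri.append(i)
                y_classical.append(j)
                w.append(collapsed[i, j])
    return float(
        cohen_kappa_score(y_fvri, y_classical, labels=[0, 1, 2], sample_weight=w)
    )


@dataclass
class AgreementTable:
    """4×3 cross-tabulation of FVRI-based vs classical lesion classes.

    Rows follow :data:`FVRI_CLASS_ORDER`, columns
    :data:`CLASSICAL_CLASS_ORDER`.  ``overall_agreement_pct`` counts the four
    concordant cells (ectatic/positive included, both denoting expansion);
    ``named_pairs_agreement_pct`` counts only the three named diagnostic
    pairs.  ``kappa`` — an added diagnostic beyond simple percent agreement —
    is computed on the 3×3 collapse with ectatic merged into complete.
    """

    counts: np.ndarray
    n: int = field(init=False)
    mean_fvri_by_fvri_class: Optional[dict] = None
    mean_classical_by_fvri_class: Optional[dict] = None
    mean_fvri_by_classical_class: Optional[dict] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 3):
            raise ValidationError(
                f"agreement counts must be 4x3, got {self.counts.shape}"
            )
        self.n = int(self.counts.sum())
        if self.n == 0:
            raise ValidationError("agreement table needs at least one lesion")

    # -- marginals --------------------------------------------------------
    @property
    def row_counts(self) -> dict[str, int]:
        return dict(zip(FVRI_CLASS_ORDER, self.counts.sum(axis=1).tolist()))

    @property
    def col_counts(self) -> dict[str, int]:
        return dict(zip(CLASSICAL_CLASS_ORDER, self.counts.sum(axis=0).tolist()))

    @property
    def row_pct(self) -> dict[str, float]:
        return {k: 100.0 * v / self.n for k, v in self.row_counts.items()}

    @property
    def col_pct(self) -> dict[str, float]:
        return {k: 100.0 * v / self.n for k, v in self.col_counts.items()}

    @property
    def cell_pct(self) -> np.ndarray:
        return 100.0 * self.counts / self.n

    def _cell(self, fvri_class: str, classical_class: str) -> int:
        i = FVRI_CLASS_ORDER.index(fvri_class)
        j = CLASSICAL_CLASS_ORDER.index(classical_class)
        return int(self.counts[i, j])

    @property
    def named_pairs_agreement_pct(self) -> float:
        return 100.0 * sum(self._cell(*p) for p in NAMED_CONCORDANT_PAIRS) / self.n

    @property
    def overall_agreement_pct(self) -> float:
        return 100.0 * sum(self._cell(*p) for p in CONCORDANT_PAIRS) / self.n

    @property
    def kappa(self) -> float:
        return _kappa_collapsed(self.counts)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_counts(cls, counts) -> "AgreementTable":
        """Build from a printed/stored 4×3 count matrix."""
        return cls(counts=np.asarray(counts))

    @classmethod
    def from_assessments(cls, lesions: pd.DataFrame) -> "AgreementTable":
        """Cross-tabulate lesions that carry both classifications."""
        usable = lesions[lesions["has_references"] & lesions["classical_class"].notna()]
        if usable.empty:
            raise ValidationError(
                "no lesion has both references; agreement table undefined"
            )
        counts = np.zeros((4, 3), dtype=int)
        for i, fc in enumerate(FVRI_CLASS_ORDER):
            for j, cc in enumerate(CLASSICAL_CLASS_ORDER):
                counts[i, j] = int(
                    ((usable["fvri_class"] == fc) & (usable["classical_class"] == cc)).sum()
                )
        if counts.sum() != len(usable):
            raise ValidationError("unrecognized class label in lesion table")
        table = cls(counts=counts)
        table.mean_fvri_by_fvri_class = {
            fc: float(usable.loc[usable["fvri_class"] == fc, "fvri"].mean())
            for fc in FVRI_CLASS_ORDER
        }
        table.mean_classical_by_fvri_class = {
            fc: float(
                usable.loc[usable["fvri_class"] == fc, "classical_index"].mean()
            )
            for fc in FVRI_CLASS_ORDER
        }
        table.mean_fvri_by_classical_class = {
            cc: float(usable.loc[usable["classical_class"] == cc, "fvri"].mean())
            for cc in CLASSICAL_CLASS_ORDER
        }
        return table

    def to_dict(self) -> dict:
        return {
            "n_lesions": self.n,
            "fvri_class_order": list(FVRI_CLASS_ORDER),
            "classical_class_order": list(CLASSICAL_CLASS_ORDER),
            "counts": self.counts.tolist(),
            "cell_pct": np.round(self.cell_pct, 4).tolist(),
            "fvri_class_counts": self.row_counts,
            "fvri_class_pct": self.row_pct,
            "classical_class_counts": self.col_counts,
            "classical_class_pct": self.col_pct,
            "overall_agreement_pct": self.overall_agreement_pct,
            "named_pairs_agreement_pct": self.named_pairs_agreement_pct,
            "kappa_collapsed_3x3": self.kappa,
            "mean_fvri_by_fvri_class": self.mean_fvri_by_fvri_class,
            "mean_classical_by_fvri_class": self.mean_classical_by_fvri_class,
            "mean_fvri_by_classical_class": self.mean_fvri_by_classical_class,
        }


def agreement_table(lesions: pd.DataFrame) -> AgreementTable:
    """Agreement between the two schemes over lesions with both references."""
    return AgreementTable.from_assessments(lesions)


def composition_by_class(
    lesions: pd.DataFrame,
    grouping: str = "fvri",
    min_group_size: int = 2,
) -> dict[str, dict]:
    """Per-tissue composition means by remodeling class, with one-way ANOVA.

    ``grouping`` selects the FVRI-based or classical class labels.  For each
    tissue percentage, lesions with missing composition are dropped and
    classes with fewer than ``min_group_size`` lesions are excluded from the
    ANOVA; a tissue with fewer than two usable groups is skipped with a
    warning.  Returns ``{tissue: {"group_means": {...}, "group_n": {...},
    "f": F, "p": p}}``.
    """
    if grouping not in ("fvri", "classical"):
        raise ValidationError("grouping must be 'fvri' or 'classical'")
    class_col = "fvri_class" if grouping == "fvri" else "classical_class"
    order = FVRI_CLASS_ORDER if grouping == "fvri" else CLASSICAL_CLASS_ORDER
    results: dict[str, dict] = {}
    for pct_col in COMPOSITION_PCT_COLUMNS:
        tissue = pct_col.replace("_pct", "")
        usable = lesions[[class_col, pct_col]].dropna()
        groups = {
            cls: usable.loc[usable[class_col] == cls, pct_col].to_numpy(float)
            for cls in order
            if (usable[class_col] == cls).sum() > 0
        }
        anova_groups = {
            cls: vals for cls, vals in groups.items() if len(vals) >= min_group_size
        }
        if len(anova_groups) < 2:
            warnings.warn(
                f"composition ANOVA skipped for {tissue}: fewer than two "
                f"classes with >= {min_group_size} lesions",
                stacklevel=2,
            )
            continue
        f, p = stats.f_oneway(*anova_groups.values())
        results[tissue] = {
            "group_means": {cls: float(v.mean()) for cls, v in groups.items()},
            "group_n": {cls: int(len(v)) for cls, v in groups.items()},
            "f": float(f),
            "p": float(p),
        }
    return results
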