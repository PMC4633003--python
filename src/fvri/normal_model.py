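"""Estimation of the pre-disease ("normal") vessel dimension.

The remodeling index needs, for every frame, the EEM area the vessel would
have had *before* plaque formed.  That counterfactual is inferred from a
multivariable linear model of the normal lumen area.  The premise: in early
atherosclerosis the lumen is preserved (Glagov compensation), so frames with
plaque burden < 20% still show a near-normal lumen, and lumen and EEM
coincide on IVUS in the absence of plaque.  Those near-normal frames are
therefore used as training data, with the response restricted to lumen areas
between 3.1 and 19.6 mm² (average vessel diameter 2.0–5.0 mm) to stay within
clinically relevant calibers.

The model is linear in four constitutional/anatomical covariates::

    EEM_predicted = b0 + b_dom * dominance + b_ves * vessel_code
                       + b_dist * ln(distance_mm) + b_bsa * BSA

with a binary dominance indicator (right = 0, left/balanced = 1), an ordinal
vessel code (LM 0, LAD 1, LCx 2, RCA 3), the natural log of the distance from
the coronary ostium (clamped at 1 mm) and body surface area in m².  The final
equation is obtained by a bootstrap: coefficients are the means over
resampled replicates and confidence intervals the 2.5/97.5 percentiles.
Resampling whole patients is the default, respecting within-patient frame
clustering.

A published fitted model ships as the built-in ``falcao2015-default`` so
pullbacks can be scored without refitting.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from fvri.core import ValidationError
from fvri.io import Cohort, frames_with_covariates

logger = logging.getLogger("fvri")

#: Design-matrix term names, intercept first.
TERM_NAMES = ("intercept", "dominance", "vessel", "log_distance", "bsa")

#: Ordinal vessel coding behind the single "coronary vessel" coefficient.
DEFAULT_VESSEL_CODING: dict[str, int] = {"LM": 0, "LAD": 1, "LCX": 2, "RCA": 3}

#: Training-frame lumen-area window (mm²): vessel diameter 2.0–5.0 mm.
LUMEN_RANGE = (3.1, 19.6)

#: Plaque-burden cutoff (%) below which a frame counts as near-normal.
TRIVIAL_BURDEN_PCT = 20.0

RESAMPLE_UNITS = ("patient", "frame", "none")


@dataclass(frozen=True)
class NormalModelSpec:
    """A fitted (or packaged) normal-dimension prediction equation.

    Coefficients are in mm² per unit of each covariate; ``ci_low``/``ci_high``
    are 95% bootstrap confidence bounds keyed by term name.
    """

    intercept: float
    beta_dominance: float
    beta_vessel: float
    beta_log_distance: float
    beta_bsa: float
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    adjusted_r2: float
    n_bootstrap: int
    seed: Optional[int] = None
    vessel_coding: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VESSEL_CODING)
    )
    log_clamp_mm: float = 1.0
    bsa_formula: str = "mosteller"
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")
        for term, coef in zip(TERM_NAMES, self.coefficients):
            lo, hi = self.ci_low[term], self.ci_high[term]
            if not (lo <= coef <= hi):
                raise ValidationError(
                    f"coefficient {term}={coef} outside its CI [{lo}, {hi}]"
                )

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficient vector ordered as :data:`TERM_NAMES`."""
        return np.array(
            [
                self.intercept,
                self.beta_dominance,
                self.beta_vessel,
                self.beta_log_distance,
                self.beta_bsa,
            ]
        )

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """Predicted normal EEM area for design rows ``X`` (n×4, no intercept)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coefficients[1:]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "coefficients": dict(zip(TERM_NAMES, map(float, self.coefficients))),
            "ci_low": dict(self.ci_low),
            "ci_high": dict(self.ci_high),
            "adjusted_r2": self.adjusted_r2,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "vessel_coding": dict(self.vessel_coding),
            "log": {"base": "natural", "clamp_mm": self.log_clamp_mm},
            "bsa_formula": self.bsa_formula,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "NormalModelSpec":
        c = d["coefficients"]
        return cls(
            intercept=c["intercept"],
            beta_dominance=c["dominance"],
            beta_vessel=c["vessel"],
            beta_log_distance=c["log_distance"],
            beta_bsa=c["bsa"],
            ci_low=dict(d["ci_low"]),
            ci_high=dict(d["ci_high"]),
            adjusted_r2=d["adjusted_r2"],
            n_bootstrap=d["n_bootstrap"],
            seed=d.get("seed"),
            vessel_coding=dict(d.get("vessel_coding", DEFAULT_VESSEL_CODING)),
            log_clamp_mm=d.get("log", {}).get("clamp_mm", 1.0),
            bsa_formula=d.get("bsa_formula", "mosteller"),
            name=d.get("name", ""),
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "NormalModelSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Packaged default model: published bootstrap equation for the original EEM
#: area (coefficients and 95% CIs from Falcão et al. 2015,
#: doi:10.5935/abc.20150098; adjusted R² 0.46, 5000 bootstrap replicates).
#: The covariate encodings (vessel order, dominance levels, natural log) are
#: package conventions — the publication does not print them — so per-frame
#: numeric agreement with the original authors' predictions is not guaranteed.
FALCAO2015_DEFAULT = NormalModelSpec(
    intercept=12.20,
    beta_dominance=-1.14,
    beta_vessel=-1.73,
    beta_log_distance=-1.28,
    beta_bsa=2.60,
    ci_low={
        "intercept": 11.07,
        "dominance": -1.46,
        "vessel": -1.80,
        "log_distance": -1.39,
        "bsa": 1.99,
    },
    ci_high={
        "intercept": 13.33,
        "dominance": -0.82,
        "vessel": -1.66,
        "log_distance": -1.18,
        "bsa": 3.20,
    },
    adjusted_r2=0.46,
    n_bootstrap=5000,
    name="falcao2015-default",
)


def design_row(
    distance_mm: float,
    vessel: str,
    dominance_indicator: int,
    bsa_m2: float,
    vessel_coding: Mapping[str, int] = DEFAULT_VESSEL_CODING,
    log_clamp_mm: float = 1.0,
) -> np.ndarray:
    """Covariate vector (dominance, vessel code, ln distance, BSA) of one frame.

    Distance is clamped at ``log_clamp_mm`` (default 1 mm) before the natural
    log, so ostial frames contribute a zero log term.
    """
    if vessel not in vessel_coding:
        raise ValidationError(
            f"vessel {vessel!r} not in coding map {dict(vessel_coding)}"
        )
    if distance_mm < 0:
        raise ValidationError("distance from ostium must be >= 0")
    return np.array(
        [
            float(dominance_indicator),
            float(vessel_coding[vessel]),
            np.log(max(distance_mm, log_clamp_mm)),
            float(bsa_m2),
        ]
    )


def design_matrix(
    frames: pd.DataFrame,
    vessel_coding: Mapping[str, int] = DEFAULT_VESSEL_CODING,
    log_clamp_mm: float = 1.0,
) -> np.ndarray:
    """Vectorized :func:`design_row` for a frames table with covariates."""
    codes = frames["vessel"].map(vessel_coding)
    if codes.isna().any():
        bad = sorted(frames.loc[codes.isna(), "vessel"].unique())
        raise ValidationError(f"vessel(s) {bad} not in coding map")
    return np.column_stack(
        [
            frames["dominance_indicator"].to_numpy(float),
            codes.to_numpy(float),
            np.log(np.maximum(frames["distance_mm"].to_numpy(float), log_clamp_mm)),
            frames["bsa_m2"].to_numpy(float),
        ]
    )


def select_training_frames(
    cohort: Cohort,
    burden_cutoff_pct: float = TRIVIAL_BURDEN_PCT,
    lumen_range: tuple[float, float] = LUMEN_RANGE,
    vessel_coding: Mapping[str, int] = DEFAULT_VESSEL_CODING,
    log_clamp_mm: float = 1.0,
) -> pd.DataFrame:
    """Frames assumed to show normal lumen dimensions, with covariates.

    Selects frames with plaque burden strictly below ``burden_cutoff_pct`` and
    lumen area inside ``lumen_range`` (inclusive bounds), and materializes the
    model covariates.  The returned table has the response ``lumen_area_mm2``,
    the four covariate columns and ``patient_id`` for clustered resampling.
    """
    frames = frames_with_covariates(cohort)
    lo, hi = lumen_range
    mask = (
        (frames["plaque_burden_pct"] < burden_cutoff_pct)
        & (frames["lumen_area_mm2"] >= lo)
        & (frames["lumen_area_mm2"] <= hi)
    )
    selected = frames[mask].reset_index(drop=True)
    if selected.empty:
        raise ValidationError(
            "no training frames: no frame has plaque burden < "
            f"{burden_cutoff_pct}% with lumen in {lumen_range}; provide a larger "
            "pullback set or use the packaged default model"
        )
    X = design_matrix(selected, vessel_coding, log_clamp_mm)
    out = selected[["patient_id", "lumen_area_mm2"]].copy()
    out["dominance_indicator"] = X[:, 0]
    out["vessel_code"] = X[:, 1]
    out["log_distance"] = X[:, 2]
    out["bsa_m2"] = X[:, 3]
    logger.info(
        "selected %d of %d frames as near-normal training frames (%.1f%%)",
        len(out),
        len(frames),
        100.0 * len(out) / len(frames),
    )
    return out


@dataclass(frozen=True)
class OlsFit:
    """Least-squares solution with fit statistics."""

    coefficients: np.ndarray  # intercept first
    r2: float
    adjusted_r2: float
    n: int


def _check_rank(Xc: np.ndarray, term_names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        involved = [
            term_names[j] if j < len(term_names) else f"x{j}"
            for j in range(Xc.shape[1])
            if np.linalg.matrix_rank(np.delete(Xc, j, axis=1)) == rank
        ]
        raise ValidationError(
            f"rank-deficient design (rank {rank} < {Xc.shape[1]}); "
            f"collinear column(s): {involved}"
        )


def fit_ols(X: np.ndarray, y: np.ndarray) -> OlsFit:
    """Ordinary least squares of ``y`` on ``X`` (intercept added).

    Adjusted R² follows ``1 - (1 - R²)(n - 1)/(n - p - 1)``.  Rank-deficient
    designs raise, naming the collinear columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < max(p + 2, 6):
        raise ValidationError(f"need at least {max(p + 2, 6)} rows, got {n}")
    Xc = np.column_stack([np.ones(n), X])
    _check_rank(Xc, TERM_NAMES if p == 4 else [f"x{j}" for j in range(p + 1)])
    res = sm.OLS(y, Xc).fit()
    return OlsFit(
        coefficients=np.asarray(res.params),
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        n=n,
    )


def _training_arrays(training: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = training[["dominance_indicator", "vessel_code", "log_distance", "bsa_m2"]]
    return X.to_numpy(float), training["lumen_area_mm2"].to_numpy(float)


def bootstrap_fit(
    training: pd.DataFrame,
    n_bootstrap: int = 5000,
    seed: Optional[int] = None,
    resample_unit: str = "patient",
    vessel_coding: Mapping[str, int] = DEFAULT_VESSEL_CODING,
    log_clamp_mm: float = 1.0,
    bsa_formula: str = "mosteller",
    name: str = "fitted",
    max_redraw_frac: float = 0.10,
) -> NormalModelSpec:
    """Bootstrap the normal-dimension equation on selected training frames.

    The final coefficients are the means over ``n_bootstrap`` resampled OLS
    fits; 95% CIs are the 2.5/97.5 percentiles of the replicate coefficients.
    Adjusted R² is reported from the point fit on the full training set.
    ``resample_unit`` draws whole patients (default, respects within-patient
    clustering), single frames, or ``"none"`` (every replicate is the full
    sample — degenerate, for testing).  Replicates with rank-deficient designs
    are redrawn; more than ``max_redraw_frac`` redraws aborts.
    """
    if seed is None:
        raise ValidationError("bootstrap_fit requires an explicit seed")
    if resample_unit not in RESAMPLE_UNITS:
        raise ValidationError(
            f"resample_unit must be one of {RESAMPLE_UNITS}, got {resample_unit!r}"
        )
    X, y = _training_arrays(training)
    point = fit_ols(X, y)  # also validates the full design
    n = len(y)
    Xc = np.column_stack([np.ones(n), X])

    rng = np.random.default_rng(seed)
    if resample_unit == "patient":
        groups = [
            np.flatnonzero((training["patient_id"] == pid).to_numpy())
            for pid in training["patient_id"].unique()
        ]
    coefs = np.empty((n_bootstrap, 5))
    redraws = 0
    max_redraws = int(np.ceil(max_redraw_frac * n_bootstrap))
    i = 0
    while i < n_bootstrap:
        if resample_unit == "none":
            idx = np.arange(n)
        elif resample_unit == "frame":
            idx = rng.integers(0, n, n)
        else:
            chosen = rng.integers(0, len(groups), len(groups))
            idx = np.concatenate([groups[g] for g in chosen])
        sol, _, rank, _ = np.linalg.lstsq(Xc[idx], y[idx], rcond=None)
        if rank < 5:
            redraws += 1
            if redraws > max_redraws:
                raise ValidationError(
                    f"{redraws} rank-deficient bootstrap replicates exceed "
                    f"{max_redraw_frac:.0%} of n_bootstrap={n_bootstrap}"
                )
            continue
        coefs[i] = sol
        i += 1
    if redraws:
        logger.info("redrew %d rank-deficient bootstrap replicate(s)", redraws)

    mean = coefs.mean(axis=0)
    lo = np.percentile(coefs, 2.5, axis=0)
    hi = np.percentile(coefs, 97.5, axis=0)
    return NormalModelSpec(
        intercept=mean[0],
        beta_dominance=mean[1],
        beta_vessel=mean[2],
        beta_log_distance=mean[3],
        beta_bsa=mean[4],
        ci_low=dict(zip(TERM_NAMES, map(float, np.minimum(lo, mean)))),
        ci_high=dict(zip(TERM_NAMES, map(float, np.maximum(hi, mean)))),
        adjusted_r2=point.adjusted_r2,
        n_bootstrap=n_bootstrap,
        seed=seed,
        vessel_coding=dict(vessel_coding),
        log_clamp_mm=log_clamp_mm,
        bsa_formula=bsa_formula,
        name=name,
    )


def predict_eem(
    spec: NormalModelSpec,
    distance_mm: float,
    vessel: str,
    dominance_indicator: int,
    bsa_m2: float,
    plausible_range: tuple[float, float] = LUMEN_RANGE,
) -> float:
    """Predicted normal EEM area (mm²) of one frame.

    Values outside ``plausible_range`` — the caliber window the model was
    trained on — are flagged with a warning but returned unclamped.
    """
    row = design_row(
        distance_mm,
        vessel,
        dominance_indicator,
        bsa_m2,
        spec.vessel_coding,
        spec.log_clamp_mm,
    )
    value = float(spec.linear_predictor(row)[0])
    lo, hi = plausible_range
    if not lo <= value <= hi:
        warnings.warn(
            f"predicted normal EEM {value:.2f} mm² outside the plausible "
            f"range [{lo}, {hi}] mm²",
            stacklevel=2,
        )
    return value
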