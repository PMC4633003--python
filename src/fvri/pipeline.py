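"""End-to-end pipeline: read → model → score → lesions → agreement → report.

:class:`RunConfig` aggregates every stage threshold at its published default;
all outputs embed the configuration hash and seed so any artifact can be
traced back to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from fvri.core import ValidationError
from fvri.engine import FvriConfig, score_frames
from fvri.io import FLOAT_FORMAT, Cohort, read_pullbacks
from fvri.lesions import (
    AgreementTable,
    CLASSICAL_CUTS,
    LESION_BURDEN_PCT,
    LESION_MIN_RUN,
    agreement_table,
    assess_lesions,
)
from fvri.normal_model import (
    FALCAO2015_DEFAULT,
    LUMEN_RANGE,
    NormalModelSpec,
    TRIVIAL_BURDEN_PCT,
    bootstrap_fit,
    select_training_frames,
)
from fvri.report import render_report

logger = logging.getLogger("fvri")


@dataclass(frozen=True)
class RunConfig:
    """Every stage threshold of one pipeline run, at published defaults."""

    seed: Optional[int] = None
    model_source: str = "packaged"  # "packaged", "fit", or a model.json path
    n_bootstrap: int = 5000
    resample_unit: str = "patient"
    trivial_burden_pct: float = TRIVIAL_BURDEN_PCT
    lesion_burden_pct: float = LESION_BURDEN_PCT
    min_run: int = LESION_MIN_RUN
    band: tuple[float, float] = (0.83, 1.17)
    classical_cuts: tuple[float, float] = CLASSICAL_CUTS
    lumen_range: tuple[float, float] = LUMEN_RANGE
    formula_variant: str = "compensation_ratio"
    bsa_formula: str = "mosteller"

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < 1 < self.band[1]:
            raise ValidationError(f"band must straddle 1, got {self.band}")
        if not 0 < self.classical_cuts[0] <= self.classical_cuts[1]:
            raise ValidationError(f"bad classical cuts {self.classical_cuts}")
        if not 0 < self.trivial_burden_pct < self.lesion_burden_pct:
            raise ValidationError("burden cutoffs must satisfy 0 < trivial < lesion")

    @property
    def fvri_config(self) -> FvriConfig:
        return FvriConfig(
            band_low=self.band[0],
            band_high=self.band[1],
            trivial_burden_cutoff=self.trivial_burden_pct,
            formula_variant=self.formula_variant,
        )

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update(overrides)
        for key, value in list(d.items()):
            if isinstance(value, list):
                d[key] = tuple(value)
        return cls(**d)


@dataclass
class PipelineResult:
    """Everything one run produced, plus the stage-by-stage record counts."""

    config: RunConfig
    model: NormalModelSpec
    scored: pd.DataFrame
    lesions: pd.DataFrame
    agreement: Optional[AgreementTable]
    report: str
    counts: dict[str, int] = field(default_factory=dict)


def resolve_model(config: RunConfig, cohort: Optional[Cohort]) -> NormalModelSpec:
    """Packaged default, freshly fitted, or loaded from a model.json path."""
    if config.model_source == "packaged":
        return FALCAO2015_DEFAULT
    if config.model_source == "fit":
        if cohort is None:
            raise ValidationError("model_source='fit' needs input pullbacks")
        if config.seed is None:
            raise ValidationError("model_source='fit' needs a seed for the bootstrap")
        training = select_training_frames(
            cohort,
            burden_cutoff_pct=config.trivial_burden_pct,
            lumen_range=config.lumen_range,
        )
        return bootstrap_fit(
            training,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            resample_unit=config.resample_unit,
            bsa_formula=config.bsa_formula,
        )
    return NormalModelSpec.from_json(config.model_source)


def run_pipeline(
    cohort: Cohort,
    config: RunConfig = RunConfig(),
    outdir: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Score a cohort, assess its lesions, and report.

    When ``outdir`` is given, writes ``frames_scored.csv``, ``lesions.csv``,
    ``agreement.json``, ``model.json``, ``report.md`` and ``run_config.yaml``.
    Any stage failure propagates with the stage name prefixed.
    """
    counts: dict[str, int] = {"frames_read": len(cohort.frames)}
    stage = "model"
    try:
        model = resolve_model(config, cohort)
        stage = "score"
        scored = score_frames(cohort, model, config.fvri_config)
        counts["classified_frames"] = int(
            (scored["plaque_burden_pct"] >= config.trivial_burden_pct).sum()
        )
        stage = "lesions"
        lesions = assess_lesions(
            scored,
            config.fvri_config,
            burden_cutoff_pct=config.lesion_burden_pct,
            min_run=config.min_run,
            classical_cuts=config.classical_cuts,
        )
        counts["lesions"] = len(lesions)
        counts["lesions_with_references"] = int(lesions["has_references"].sum()) if len(lesions) else 0
        stage = "agreement"
        agreement = (
            agreement_table(lesions)
            if counts["lesions_with_references"] > 0
            else None
        )
        stage = "report"
        meta = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "model": model.name or "fitted",
            "formula_variant": config.formula_variant,
            **counts,
        }
        report = render_report(scored, lesions, agreement, meta)
    except Exception as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc

    logger.info("pipeline counts: %s", counts)
    result = PipelineResult(
        config=config,
        model=model,
        scored=scored,
        lesions=lesions,
        agreement=agreement,
        report=report,
        counts=counts,
    )
    if outdir is not None:
        write_pipeline_outputs(result, outdir)
    return result


def run_pipeline_from_files(
    frames_csv: Union[str, Path],
    patients_csv: Union[str, Path],
    config: RunConfig = RunConfig(),
    outdir: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    cohort = read_pullbacks(frames_csv, patients_csv, bsa_formula=config.bsa_formula)
    return run_pipeline(cohort, config, outdir)


def write_pipeline_outputs(result: PipelineResult, outdir: Union[str, Path]) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": result.config.config_hash(), "seed": result.config.seed}
    paths = {
        "frames_scored": outdir / "frames_scored.csv",
        "lesions": outdir / "lesions.csv",
        "agreement": outdir / "agreement.json",
        "model": outdir / "model.json",
        "report": outdir / "report.md",
        "run_config": outdir / "run_config.yaml",
    }
    result.scored.to_csv(paths["frames_scored"], index=False, float_format=FLOAT_FORMAT)
    result.lesions.to_csv(paths["lesions"], index=False, float_format=FLOAT_FORMAT)
    agreement_payload = {
        **meta,
        "counts_log": result.counts,
        "agreement": result.agreement.to_dict() if result.agreement else None,
    }
    paths["agreement"].write_text(json.dumps(agreement_payload, indent=2) + "\n")
    model_payload = result.model.to_dict()
    model_payload.update(meta)
    paths["model"].write_text(json.dumps(model_payload, indent=2) + "\n")
    paths["report"].write_text(result.report)
    result.config.to_yaml(paths["run_config"])
    return paths
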