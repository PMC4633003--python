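"""Human-readable Markdown reports over pipeline artifacts.

Every number in a report is recomputable from the emitted CSV/JSON artifacts
alone; the report is presentation, not analysis.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from fvri.engine import REMODELING_CLASSES, TRIVIAL_CLASS
from fvri.lesions import (
    AgreementTable,
    CLASSICAL_CLASS_ORDER,
    FVRI_CLASS_ORDER,
    composition_by_class,
)

#: Plaque-burden bins used for the index-vs-burden profile (%).
BURDEN_BIN_EDGES = (20.0, 30.0, 40.0, 50.0, 60.0)
BURDEN_BIN_LABELS = ("<20", "20-30", "30-40", "40-50", "50-60", ">60")


def fvri_by_burden_bins(scored: pd.DataFrame) -> pd.DataFrame:
    """Mean FVRI per plaque-burden bin over all frames with plaque.

    Bins: <20, 20-30, 30-40, 40-50, 50-60, >60 (%); frames without plaque
    carry no index and are excluded.
    """
    frames = scored[scored["fvri"].notna()]
    edges = [-np.inf, *BURDEN_BIN_EDGES, np.inf]
    binned = pd.cut(
        frames["plaque_burden_pct"], bins=edges, labels=BURDEN_BIN_LABELS, right=False
    )
    grouped = frames.groupby(binned, observed=False)["fvri"]
    return pd.DataFrame(
        {
            "burden_bin": BURDEN_BIN_LABELS,
            "n_frames": grouped.size().reindex(BURDEN_BIN_LABELS).fillna(0).astype(int).values,
            "mean_fvri": grouped.mean().reindex(BURDEN_BIN_LABELS).values,
            "sem_fvri": grouped.sem().reindex(BURDEN_BIN_LABELS).values,
        }
    )


def _freq_lines(labels, counts: pd.Series, total: int) -> list[str]:
    lines = ["| class | n | % |", "|---|---|---|"]
    for cls in labels:
        n = int(counts.get(cls, 0))
        lines.append(f"| {cls} | {n} | {100.0 * n / total:.1f} |")
    return lines


def render_report(
    scored: pd.DataFrame,
    lesions: pd.DataFrame,
    agreement: Optional[AgreementTable],
    meta: Optional[dict] = None,
) -> str:
    """Assemble the five-section Markdown report.

    Sections: frame-class frequencies, lesion-class frequencies, agreement
    matrix with marginals, mean FVRI by plaque-burden bin, and plaque
    composition by class with one-way ANOVA.  An empty lesion set collapses
    the lesion-dependent sections into a note.
    """
    out: list[str] = ["# Coronary remodeling report", ""]
    for key, value in (meta or {}).items():
        out.append(f"- {key}: {value}")
    if meta:
        out.append("")

    # 1 — frame classes
    out += ["## Frame remodeling classes", ""]
    classified = scored[scored["remodeling_class"] != TRIVIAL_CLASS]
    n_trivial = int((scored["remodeling_class"] == TRIVIAL_CLASS).sum())
    if len(classified):
        out += _freq_lines(
            REMODELING_CLASSES,
            classified["remodeling_class"].value_counts(),
            len(classified),
        )
    out += [
        "",
        f"{len(classified)} frames with established plaque; "
        f"{n_trivial} trivial-plaque frames (burden < 20%).",
        "",
    ]

    # 2 — lesion classes
    out += ["## Lesion remodeling classes", ""]
    if lesions.empty:
        out += ["No lesions detected (no run of 3+ frames above 40% burden).", ""]
    else:
        out += _freq_lines(
            FVRI_CLASS_ORDER, lesions["fvri_class"].value_counts(), len(lesions)
        )
        with_refs = lesions[lesions["has_references"]]
        out += ["", f"{len(lesions)} lesions, {len(with_refs)} with both references."]
        if len(with_refs):
            out += ["", "Classical classes (lesions with references):", ""]
            out += _freq_lines(
                CLASSICAL_CLASS_ORDER,
                with_refs["classical_class"].value_counts(),
                len(with_refs),
            )
        out.append("")

    # 3 — agreement
    out += ["## Scheme agreement (FVRI-based vs classical)", ""]
    if agreement is None:
        out += ["Not available: no lesion carries both classifications.", ""]
    else:
        header = "| FVRI class \\ classical | " + " | ".join(CLASSICAL_CLASS_ORDER) + " | total |"
        out += [header, "|" + "---|" * 5]
        for i, cls in enumerate(FVRI_CLASS_ORDER):
            cells = " | ".join(
                f"{agreement.counts[i, j]} ({agreement.cell_pct[i, j]:.1f}%)"
                for j in range(3)
            )
            out.append(f"| {cls} | {cells} | {agreement.row_counts[cls]} |")
        out.append(
            "| total | "
            + " | ".join(str(agreement.col_counts[c]) for c in CLASSICAL_CLASS_ORDER)
            + f" | {agreement.n} |"
        )
        out += [
            "",
            f"Overall agreement {agreement.overall_agreement_pct:.1f}% "
            f"(named concordant pairs only: {agreement.named_pairs_agreement_pct:.1f}%).",
            f"Cohen's kappa (3×3 collapse, extra diagnostic): {agreement.kappa:.3f}.",
            "",
        ]

    # 4 — FVRI vs burden
    out += ["## Mean FVRI by plaque-burden bin", ""]
    bins = fvri_by_burden_bins(scored)
    out += ["| burden (%) | n | mean FVRI | SEM |", "|---|---|---|---|"]
    for _, r in bins.iterrows():
        mean = "-" if np.isnan(r.mean_fvri) else f"{r.mean_fvri:.3f}"
        sem = "-" if not np.isfinite(r.sem_fvri or np.nan) else f"{r.sem_fvri:.4f}"
        out.append(f"| {r.burden_bin} | {int(r.n_frames)} | {mean} | {sem} |")
    out.append("")

    # 5 — composition
    out += ["## Plaque composition by remodeling class", ""]
    if lesions.empty or lesions[[c for c in lesions.columns if c.endswith("_pct") and c != "plaque_burden_pct"]].dropna(how="all").empty:
        out += ["Not available: no VH composition on the lesion set.", ""]
    else:
        for grouping, order in (("fvri", FVRI_CLASS_ORDER), ("classical", CLASSICAL_CLASS_ORDER)):
            try:
                results = composition_by_class(lesions, grouping=grouping)
            except Exception:
                results = {}
            if not results:
                continue
            out += [f"### Grouped by {grouping} class", ""]
            out += [
                "| tissue | " + " | ".join(order) + " | F | p |",
                "|" + "---|" * (len(order) + 3),
            ]
            for tissue, res in results.items():
                means = " | ".join(
                    (
                        f"{res['group_means'][cls]:.1f}"
                        if cls in res["group_means"]
                        else "-"
                    )
                    for cls in order
                )
                out.append(
                    f"| {tissue} | {means} | {res['f']:.2f} | {res['p']:.3g} |"
                )
            out.append("")
    return "\n".join(out) + "\n"
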