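"""End-to-end pipeline: virtual study -> comparisons -> DVH evaluation ->
action-level report, fully reproducible from a config and a master seed.

Outputs written to the target directory:

* ``comparisons.tsv`` — one row per (roi, deformation, plan, mode, fraction)
  with Dice and mSSD versus the group consensus.
* ``dose_metrics.tsv`` — per-fraction achieved values of the nine planning
  constraints.
* ``anova.tsv`` — deformation-effect ANOVA per ROI/mode and plan-type ANOVA
  per constraint.
* ``action_levels.tsv`` / ``dose_action_levels.tsv`` — the 95% action-level
  intervals (Dice/mSSD per ROI and mode; constraint values per plan type).
* ``report.md`` and ``figures/*.png`` — a human-readable summary.
* ``provenance.json`` — config, seed, and package version.

Every random draw descends from the master seed, so repeated runs produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dvh import default_constraints, evaluate_constraints
from .metrics import compare_repetitions, comparisons_to_frame
from .report import ActionLevelAnalysis, ActionLevelResults
from .surrogate import PhantomConfig, StudyConfig, default_phantom_geometry, run_virtual_study
from .volumes import REPORT_ROIS

logger = logging.getLogger(__name__)

DOSE_METRIC_COLUMNS = [
    "constraint",
    "roi",
    "plan_type",
    "mode",
    "deformation_id",
    "fraction",
    "achieved",
    "unit",
    "passed",
]


def study_config_from_dict(data: dict) -> StudyConfig:
    """Build a StudyConfig from a plain dict (YAML-friendly)."""
    data = dict(data or {})
    phantom_kwargs = dict(data.pop("phantom", {}) or {})
    geom = phantom_kwargs.pop("geometry", None)
    if geom is not None:
        phantom_kwargs["geometry"] = default_phantom_geometry(
            spacing_mm=float(geom.get("spacing_mm", 2.0)), size=geom.get("size", (128, 128, 96))
        )
    phantom = PhantomConfig(**phantom_kwargs)
    return StudyConfig(phantom=phantom, **data)


def load_study_config(path: str | Path | None) -> StudyConfig:
    if path is None:
        return StudyConfig()
    with open(path) as fh:
        return study_config_from_dict(yaml.safe_load(fh) or {})


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(
    config: StudyConfig | None = None,
    seed: int = 0,
    out_dir: str | Path = "results",
    make_figures: bool = True,
) -> ActionLevelResults:
    """Run the full QA analysis and write the report bundle."""
    config = config or StudyConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    study = run_virtual_study(config, master_seed=seed)
    timings["phantom_and_layout_s"] = time.perf_counter() - t0

    constraints = default_constraints(rx_gy=config.rx_gy)
    comparisons_parts: list[pd.DataFrame] = []
    dose_rows: list[dict] = []
    t0 = time.perf_counter()
    for d in range(1, config.n_deformations + 1):
        records = list(study.fraction_records(deformation_id=d))
        comparisons_parts.append(comparisons_to_frame(compare_repetitions(records, rois=REPORT_ROIS)))
        for rec in records:
            for res in evaluate_constraints(rec.dose, rec.masks, constraints):
                dose_rows.append(
                    {
                        "constraint": f"{res.spec.roi} {res.spec.label}",
                        "roi": res.spec.roi,
                        "plan_type": rec.plan_type,
                        "mode": rec.mode,
                        "deformation_id": rec.deformation_id,
                        "fraction": rec.fraction,
                        "achieved": res.achieved,
                        "unit": res.spec.unit,
                        "passed": res.passed,
                    }
                )
        logger.info("deformation %d simulated and scored", d)
    timings["simulation_and_metrics_s"] = time.perf_counter() - t0

    comparisons = pd.concat(comparisons_parts, ignore_index=True)
    dose_metrics = pd.DataFrame(dose_rows, columns=DOSE_METRIC_COLUMNS)

    t0 = time.perf_counter()
    results = ActionLevelAnalysis(comparisons, dose_metrics).fit()
    timings["statistics_s"] = time.perf_counter() - t0

    _write_tsv(comparisons, out / "comparisons.tsv")
    _write_tsv(dose_metrics, out / "dose_metrics.tsv")
    _write_tsv(results.anova_table, out / "anova.tsv")
    _write_tsv(results.contour_action_levels, out / "action_levels.tsv")
    _write_tsv(results.dose_action_levels, out / "dose_action_levels.tsv")

    provenance = {
        "package": "e2eqa",
        "version": __version__,
        "master_seed": int(seed),
        "config": _config_to_jsonable(config),
        "deformations": [spec.to_dict() for spec in study.deformations],
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)

    if make_figures:
        try:
            _make_figures(comparisons, dose_metrics, out / "figures")
        except Exception:  # figures are best-effort; tables are the record
            logger.exception("figure generation failed")

    (out / "report.md").write_text(_report_markdown(results, provenance))
    return results


def _config_to_jsonable(config: StudyConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return convert(config)


def _report_markdown(results: ActionLevelResults, provenance: dict) -> str:
    flagged = results.contour_action_levels.query("pooling == 'stratified'")["roi"].unique()
    lines = [
        "# End-to-end QA action-level report",
        "",
        f"Package e2eqa {provenance['version']}, master seed {provenance['master_seed']}.",
        "",
        "## Contour reproducibility",
        "",
        "Per-ROI 95% intervals of Dice and mean symmetric surface distance vs the",
        "STAPLE consensus of each repetition group. Deformations are pooled when the",
        f"one-way ANOVA deformation effect has p >= {results.alpha:g}.",
        "",
        "```",
        results.contour_action_levels.to_string(index=False),
        "```",
        "",
        f"ROIs stratified by deformation (significant deformation effect): "
        + (", ".join(flagged) if len(flagged) else "none"),
        "",
        "## Dose-volume action levels",
        "",
        "95% intervals of achieved constraint values, stratified by plan type.",
        "",
        "```",
        results.dose_action_levels.to_string(index=False),
        "```",
        "",
        "## ANOVA",
        "",
        "```",
        results.anova_table.to_string(index=False),
        "```",
        "",
    ]
    return "\n".join(lines)


def _make_figures(comparisons: pd.DataFrame, dose_metrics: pd.DataFrame, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    for metric, label, fname in (
        ("dsc", "Dice similarity coefficient", "contour_dsc.png"),
        ("mssd_mm", "mean symmetric surface distance (mm)", "contour_mssd.png"),
    ):
        fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
        for ax, mode in zip(axes, ("corrected", "ai")):
            sub = comparisons[comparisons["mode"] == mode]
            rois = sorted(sub["roi"].unique())
            ax.boxplot([sub[sub.roi == r][metric] for r in rois], tick_labels=rois)
            ax.set_title(f"{mode} contours")
            ax.tick_params(axis="x", rotation=60)
        axes[0].set_ylabel(label)
        fig.tight_layout()
        fig.savefig(fig_dir / fname, dpi=120)
        plt.close(fig)

    if not dose_metrics.empty:
        fig, ax = plt.subplots(figsize=(9, 4))
        constraints = sorted(dose_metrics["constraint"].unique())
        positions, data, colors = [], [], []
        for i, c in enumerate(constraints):
            for j, (plan, color) in enumerate((("IMRT", "tab:red"), ("VMAT", "tab:green"))):
                vals = dose_metrics.query("constraint == @c and plan_type == @plan")["achieved"]
                data.append(vals)
                positions.append(i * 3 + j)
                colors.append(color)
        bp = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
        for patch, color in zip(bp["boxes"], colors):
            patch.set_facecolor(color)
        ax.set_xticks([i * 3 + 0.5 for i in range(len(constraints))])
        ax.set_xticklabels(constraints, rotation=60, ha="right")
        ax.set_ylabel("achieved value (unit per constraint)")
        ax.set_title("Adapted-plan constraint values (IMRT red, VMAT green)")
        fig.tight_layout()
        fig.savefig(fig_dir / "dose_metrics.png", dpi=120)
        plt.close(fig)
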