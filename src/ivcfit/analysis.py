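"""Full agreement analysis of a pre/post measurement table.

Runs the validation pipeline on a cohort: per-subject equivalent
diameters from the circle-fitting model, cohort summaries, the complete
agreement matrix (every pre-placement predictor against every
post-placement diameter, plus the post-max/post-min circularity check),
bootstrap comparisons of the dependent CCCs, and paired mean-difference
tests.  Reports serialize losslessly to canonical JSON and can be
re-rendered as CSV or text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    DegenerateStatisticError,
    PairedSample,
    ccc_confidence_interval,
    classify_agreement,
    compare_dependent_ccc,
    lin_ccc,
    mean_diff_test,
)
from .cohort import summarize_cohort
from .geometry import ValidationError, equivalent_diameter_simplified
from .io import MeasurementTable

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "render_report", "load_report"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA = "ivcfit-report/1"

#: variable labels used in the report (post-placement carries the -IVCF suffix)
_LABELS = {
    "dmax_mm": "D_max",
    "dmin_mm": "D_min",
    "deq_mm": "D_eq",
    "post_dmax_mm": "D_max-IVCF",
    "post_dmin_mm": "D_min-IVCF",
}

#: the agreement matrix: every pre-placement predictor against each
#: post-placement diameter, plus the post-vs-post circularity pair
AGREEMENT_PAIRS = [
    ("dmax_mm", "post_dmax_mm"),
    ("dmax_mm", "post_dmin_mm"),
    ("dmin_mm", "post_dmax_mm"),
    ("dmin_mm", "post_dmin_mm"),
    ("deq_mm", "post_dmax_mm"),
    ("deq_mm", "post_dmin_mm"),
    ("post_dmax_mm", "post_dmin_mm"),
]

#: dependent-CCC contrasts: (common, candidate_a, candidate_b)
CCC_CONTRASTS = [
    ("post_dmax_mm", "deq_mm", "dmax_mm"),
    ("post_dmax_mm", "deq_mm", "dmin_mm"),
    ("post_dmin_mm", "deq_mm", "dmax_mm"),
    ("post_dmin_mm", "deq_mm", "dmin_mm"),
    ("deq_mm", "post_dmax_mm", "post_dmin_mm"),
]

#: paired mean-difference contrasts
MEAN_DIFF_PAIRS = [
    ("dmax_mm", "dmin_mm"),
    ("deq_mm", "post_dmax_mm"),
    ("deq_mm", "post_dmin_mm"),
    ("post_dmax_mm", "post_dmin_mm"),
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Seed and statistical settings of one analysis run."""

    seed: int
    n_boot: int = 2000
    ci_level: float = 0.95
    auto_sort: bool = False


@dataclass
class AnalysisReport:
    """Everything one analysis run computed, JSON-serializable."""

    subjects: list  # per-subject derived values (records)
    summary: list  # cohort summary rows (records)
    agreement: dict  # pair label -> agreement entry
    comparisons: dict  # contrast label -> comparison entry
    mean_diffs: dict  # pair label -> t-test entry
    metadata: dict = field(default_factory=dict)

    def to_dict(self, stable: bool = False) -> dict:
        d = {
            "schema": REPORT_SCHEMA,
            "subjects": self.subjects,
            "summary": self.summary,
            "agreement": self.agreement,
            "comparisons": self.comparisons,
            "mean_diffs": self.mean_diffs,
            "metadata": dict(self.metadata),
        }
        if stable:
            d["metadata"].pop("created", None)
        return d

    def to_json(self, stable: bool = False) -> str:
        """Canonical JSON: sorted keys, fixed separators, full precision."""
        return json.dumps(
            self.to_dict(stable=stable),
            sort_keys=True,
            indent=1,
            default=lambda o: o.item() if hasattr(o, "item") else str(o),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        if d.get("schema") != REPORT_SCHEMA:
            raise ValidationError(f"unsupported report schema {d.get('schema')!r}")
        return cls(
            subjects=d["subjects"],
            summary=d["summary"],
            agreement=d["agreement"],
            comparisons=d["comparisons"],
            mean_diffs=d["mean_diffs"],
            metadata=d.get("metadata", {}),
        )


def _pair_label(a: str, b: str) -> str:
    return f"{_LABELS[a]} vs {_LABELS[b]}"


def _agreement_entry(x, y, level: float) -> dict:
    sample = PairedSample(np.asarray(x), np.asarray(y))
    try:
        ccc = lin_ccc(sample)
    except DegenerateStatisticError as exc:
        logger.warning("agreement undefined: %s", exc)
        return {"status": "undefined", "reason": str(exc), "n": sample.n}
    try:
        res = ccc_confidence_interval(sample, level=level)
    except DegenerateStatisticError as exc:
        logger.warning("degenerate CI: %s", exc)
        return {
            "status": "degenerate_ci",
            "ccc": ccc,
            "agreement_class": classify_agreement(ccc),
            "note": str(exc),
            "n": sample.n,
        }
    return {
        "status": "ok",
        "ccc": res.ccc,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pearson": res.pearson,
        "n": res.n,
        "agreement_class": res.agreement_class,
        "level": res.level,
    }


def run_analysis(
    table: Union[MeasurementTable, pd.DataFrame], config: AnalysisConfig
) -> AnalysisReport:
    """Run the full agreement/comparison pipeline on a measurement table.

    Degenerate statistics (identical vectors, zero variances) become
    structured ``"undefined"`` / ``"degenerate_ci"`` entries and a warning
    in the log — never a silent omission.  Fully seeded: the same table,
    config and seed reproduce the report bit for bit.
    """
    df = table.data.copy() if isinstance(table, MeasurementTable) else table.copy()
    if len(df) < 3:
        raise ValidationError(f"analysis requires n >= 3 subjects, got {len(df)}")

    df["deq_mm"] = equivalent_diameter_simplified(
        df["dmax_mm"].to_numpy(), df["dmin_mm"].to_numpy()
    )

    agreement = {}
    for a, b in AGREEMENT_PAIRS:
        agreement[_pair_label(a, b)] = _agreement_entry(df[a], df[b], config.ci_level)

    comparisons = {}
    for k, (common, cand_a, cand_b) in enumerate(CCC_CONTRASTS):
        label = f"{_LABELS[cand_a]} minus {_LABELS[cand_b]} (target {_LABELS[common]})"
        try:
            res = compare_dependent_ccc(
                df[common].to_numpy(),
                df[cand_a].to_numpy(),
                df[cand_b].to_numpy(),
                n_boot=config.n_boot,
                seed=config.seed + k,
            )
            comparisons[label] = {"status": "ok", **asdict(res)}
        except (DegenerateStatisticError, ValidationError) as exc:
            logger.warning("comparison undefined (%s): %s", label, exc)
            comparisons[label] = {"status": "undefined", "reason": str(exc)}

    mean_diffs = {}
    for a, b in MEAN_DIFF_PAIRS:
        label = _pair_label(a, b)
        try:
            res = mean_diff_test(df[a].to_numpy(), df[b].to_numpy(), paired=True)
            mean_diffs[label] = {"status": "ok", **asdict(res)}
        except DegenerateStatisticError as exc:
            logger.warning("t test undefined (%s): %s", label, exc)
            mean_diffs[label] = {"status": "undefined", "reason": str(exc)}

    summary_input = df[["dmax_mm", "dmin_mm", "post_dmax_mm", "post_dmin_mm"]].copy()
    summary_input["true_deq_mm"] = df["deq_mm"]
    if "group" in df.columns:
        summary_input["group"] = df["group"]
    summary_df = summarize_cohort(
        summary_input, group="group" if "group" in df.columns else None
    )

    subject_cols = ["subject_id", "dmax_mm", "dmin_mm", "deq_mm", "post_dmax_mm", "post_dmin_mm"]
    if "group" in df.columns:
        subject_cols.append("group")
    subjects = df[subject_cols].to_dict(orient="records")

    return AnalysisReport(
        subjects=subjects,
        summary=summary_df.to_dict(orient="records"),
        agreement=agreement,
        comparisons=comparisons,
        mean_diffs=mean_diffs,
        metadata={
            "version": __version__,
            "config": asdict(config),
            "n_subjects": int(len(df)),
            "created": datetime.now(timezone.utc).isoformat(),
        },
    )


def _render_text(report: AnalysisReport) -> str:
    lines = ["Agreement analysis", "=" * 60]
    lines.append(f"subjects: {report.metadata.get('n_subjects')}")
    lines.append("")
    lines.append("Cohort summary (mean ± SD, mm)")
    for row in report.summary:
        label = {"true_deq_mm": "D_eq"}.get(
            row["variable"], _LABELS.get(row["variable"], row["variable"])
        )
        lines.append(f"  {label:<12} {row['mean']:6.2f} ± {row['sd']:.2f}  (n={row['n']})")
        if "p_between_groups" in row:
            lines[-1] += f"  between-group p={row['p_between_groups']:.3f}"
    lines.append("")
    lines.append("Agreement matrix (Lin's CCC, 95% CI; poor / fair to good / excellent)")
    for label, entry in report.agreement.items():
        if entry["status"] == "ok":
            lines.append(
                f"  {label:<28} CCC={entry['ccc']:+.3f} "
                f"(95% CI {entry['ci_low']:+.3f} to {entry['ci_high']:+.3f}), "
                f"Pearson ρ={entry['pearson']:+.3f} -> {entry['agreement_class']}"
            )
        elif entry["status"] == "degenerate_ci":
            lines.append(
                f"  {label:<28} CCC={entry['ccc']:+.3f} (CI degenerate: {entry['note']}) "
                f"-> {entry['agreement_class']}"
            )
        else:
            lines.append(f"  {label:<28} undefined: {entry['reason']}")
    lines.append("")
    lines.append("CCC comparisons (bootstrap difference of dependent CCCs)")
    for label, entry in report.comparisons.items():
        if entry["status"] == "ok":
            lines.append(
                f"  {label:<42} ΔCCC={entry['delta']:+.3f} "
                f"(95% CI {entry['ci_low']:+.3f} to {entry['ci_high']:+.3f}), p={entry['p_value']:.4f} "
                f"[Fisher-z p={entry['fisher_z_p']:.2e}]"
            )
        else:
            lines.append(f"  {label:<42} undefined: {entry['reason']}")
    lines.append("")
    lines.append("Mean differences (paired Student's t)")
    for label, entry in report.mean_diffs.items():
        if entry["status"] == "ok":
            lines.append(
                f"  {label:<28} {entry['mean_x']:6.2f} vs {entry['mean_y']:6.2f} mm, "
                f"t={entry['t_statistic']:+.2f}, p={entry['p_value']:.4f}"
            )
        else:
            lines.append(f"  {label:<28} undefined: {entry['reason']}")
    return "\n".join(lines) + "\n"


def _render_csv(report: AnalysisReport) -> str:
    rows = []
    for label, entry in report.agreement.items():
        rows.append({"pair": label, **entry})
    return pd.DataFrame(rows).to_csv(index=False)


def render_report(
    report: AnalysisReport,
    path: Union[str, Path],
    fmt: str = "json",
    stable: bool = False,
    plot: bool = False,
) -> Path:
    """Write a report as JSON (canonical), CSV (agreement rows) or text.

    ``stable=True`` omits the creation timestamp so identical runs give
    byte-identical files.  ``plot=True`` additionally attempts a paired
    raincloud-style figure next to the report; plotting failures are
    logged and never change the exit status.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path.write_text(report.to_json(stable=stable))
    elif fmt == "csv":
        path.write_text(_render_csv(report))
    elif fmt == "text":
        path.write_text(_render_text(report))
    else:
        raise ValidationError(f"unknown report format {fmt!r}; use json, csv or text")
    if plot:
        try:
            plot_paired_diameters(report, path.with_suffix(".png"))
        except Exception as exc:  # plotting is best-effort by contract
            logger.warning("plot generation failed: %s", exc)
    return path


def load_report(path: Union[str, Path]) -> AnalysisReport:
    """Load a JSON report written by :func:`render_report`."""
    return AnalysisReport.from_dict(json.loads(Path(path).read_text()))


def plot_paired_diameters(report: AnalysisReport, path: Union[str, Path]) -> Path:
    """Raincloud-style plot of D_eq, post D_max and post D_min distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame(report.subjects)
    cols = [("deq_mm", "D_eq"), ("post_dmax_mm", "D_max-IVCF"), ("post_dmin_mm", "D_min-IVCF")]
    fig, ax = plt.subplots(figsize=(6, 4))
    rng = np.random.default_rng(0)
    for i, (col, label) in enumerate(cols):
        vals = df[col].to_numpy()
        ax.violinplot([vals], positions=[i], showextrema=False, widths=0.7)
        ax.boxplot([vals], positions=[i], widths=0.12, showfliers=False)
        ax.scatter(
            np.full_like(vals, i) + rng.uniform(0.1, 0.25, size=len(vals)),
            vals,
            s=12,
            alpha=0.6,
        )
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels([label for _, label in cols])
    ax.set_ylabel("diameter (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
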