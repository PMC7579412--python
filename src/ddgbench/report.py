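"""Rendering of evaluation reports as TSV or Markdown tables.

Rows appear in the fixed category order (directional pairs first, then the
aggregates, ending with Buried, Surface, Everything).  Correlations are
printed to 2 decimals, percentages to 1; with several replicates the
cross-replicate spread is shown as "mean ± sd".  Undefined metrics render
as "NA", never as 0.
"""

from __future__ import annotations

import math

from .core import ConfigurationError
from .metrics import EvaluationReport, MetricRow
from .taxonomy import TABLE_ORDER

__all__ = ["render_report"]

_COLUMNS = [
    ("Mutation Type", None),
    ("Pearson's R", "pearson_r"),
    ("Pearson's R Filtered", "pearson_r_filtered"),
    ("Predictive Index", "predictive_index"),
    ("MCC", "mcc"),
    ("Same class (%)", "pct_same_class"),
    ("Off by one (%)", "pct_off_by_one"),
    ("Off by two (%)", "pct_off_by_two"),
    ("Total entries", "n_entries"),
]


def _fmt(value: float, decimals: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.{decimals}f}"


def _cell(field: str, mean_row: MetricRow, sd_row: MetricRow | None, n_reps: int) -> str:
    decimals = 1 if field.startswith("pct") else 2
    if field == "n_entries":
        return str(mean_row.n_entries)
    mean = getattr(mean_row, field)
    if isinstance(mean, float) and math.isnan(mean):
        return "NA"
    if n_reps > 1 and sd_row is not None:
        sd = getattr(sd_row, field)
        return f"{_fmt(mean, decimals)} ± {_fmt(sd, 4 if decimals == 2 else 2)}"
    return _fmt(mean, decimals)


def render_report(report: EvaluationReport, format: str = "tsv") -> str:
    """Render the cross-replicate summary of an evaluation as text."""
    if format not in ("tsv", "markdown"):
        raise ConfigurationError(f"unknown report format {format!r}")
    if not report.summary.mean:
        raise ConfigurationError("report is empty")
    header = [name for name, _ in _COLUMNS]
    rows: list[list[str]] = []
    for label in TABLE_ORDER:
        if label not in report.summary.mean:
            continue
        mean_row = report.summary.mean[label]
        sd_row = report.summary.sd.get(label)
        cells = [label.value]
        for _, field in _COLUMNS[1:]:
            cells.append(_cell(field, mean_row, sd_row, report.summary.n_replicates))
        rows.append(cells)

    if format == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    widths = [max(len(header[i]), *(len(r[i]) for r in rows)) for i in range(len(header))]
    def mk(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [mk(header), "|" + "|".join("-" * (w + 2) for w in widths) + "|"]
    lines += [mk(r) for r in rows]
    return "\n".join(lines) + "\n"
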