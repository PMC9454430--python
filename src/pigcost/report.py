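"""Rendering the ledger and indicator suite to CSV, JSON or text.

CSV and JSON carry every number at full floating precision and
round-trip exactly; the plain-text report is for reading and rounds to
two decimals. Percent-style indicators (ROI) are rendered as
percentages only in the text format; machine formats keep fractions.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

from .indicators import BatchReport
from .ledger import CostLedger

#: Indicator fields in report order, with human labels and units.
_INDICATOR_ROWS: tuple[tuple[str, str], ...] = (
    ("operating_cost", "operating cost (A + B), per week"),
    ("total_cost", "total cost (A + B + D), per week"),
    ("cost_per_head", "total cost per finished head"),
    ("cost_per_arroba", "total cost per arroba (18.75 kg)"),
    ("cost_per_kg", "total cost per kg live weight"),
    ("revenue", "weekly revenue (batch + culls)"),
    ("revenue_per_head", "revenue per finished head"),
    ("revenue_per_kg", "revenue per kg of batch"),
    ("profit", "weekly profit"),
    ("leveling_point", "leveling point, head"),
    ("benefit_cost_ratio", "benefit-cost ratio"),
    ("roi", "return on investment (fraction)"),
    ("producer_income", "producer total weekly income"),
    ("producer_income_per_kg", "producer income per kg of batch"),
)


def _fmt_full(x: Optional[float]) -> str:
    return "" if x is None else repr(float(x))


def _fmt2(x: Optional[float]) -> str:
    return "n/a" if x is None else f"{x:,.2f}"


def indicator_dict(report: BatchReport) -> dict[str, Optional[float]]:
    return dataclasses.asdict(report)


def write_report(
    report: BatchReport,
    ledger: CostLedger,
    path: str | Path,
    format: str = "csv",
) -> Path:
    """Write the full batch report (ledger groups A-E then indicators)."""
    path = Path(path)
    if format == "csv":
        _write_csv(report, ledger, path)
    elif format == "json":
        _write_json(report, ledger, path)
    elif format == "text":
        path.write_text(render_text(report, ledger))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def _write_csv(report: BatchReport, ledger: CostLedger, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "section", "label", "level", "amount"])
        for line in ledger.lines:
            writer.writerow(
                [line.group, line.section, line.label, line.level,
                 _fmt_full(line.amount)]
            )
        for name, label in _INDICATOR_ROWS:
            writer.writerow(
                ["R", "indicators", label, name,
                 _fmt_full(getattr(report, name))]
            )


def _write_json(report: BatchReport, ledger: CostLedger, path: Path) -> None:
    payload: dict[str, Any] = {
        "ledger": [dataclasses.asdict(line) for line in ledger.lines],
        "indicators": indicator_dict(report),
    }
    path.write_text(json.dumps(payload, indent=2))


def read_report_csv(path: str | Path) -> list[dict[str, Any]]:
    """Parse a CSV report back into rows with float amounts."""
    rows: list[dict[str, Any]] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rec["amount"] = float(rec["amount"]) if rec["amount"] else None
            rows.append(rec)
    return rows


def render_text(report: BatchReport, ledger: CostLedger) -> str:
    """Human-readable two-decimal report."""
    out: list[str] = []
    width = 58
    group_titles = {
        "A": "A - VARIABLE COSTS",
        "B": "B - FIXED OPERATING COSTS",
        "C": "C - OPERATING COST (A + B)",
        "D": "D - CAPITAL AND LAND REMUNERATION",
        "E": "E - TOTAL COST (C + D)",
    }
    for group in "ABCDE":
        out.append(group_titles[group])
        for line in ledger.group_lines(group):
            if line.level in ("group", "total"):
                out.append("  " + "-" * (width + 14))
                out.append(f"  {line.label:<{width}}{_fmt2(line.amount):>14}")
            elif line.level == "subtotal":
                out.append(f"    {line.label:<{width - 2}}{_fmt2(line.amount):>14}")
            else:
                out.append(f"      {line.label:<{width - 4}}{_fmt2(line.amount):>14}")
        out.append("")
    out.append("ECONOMIC INDICATORS")
    for name, label in _INDICATOR_ROWS:
        value = getattr(report, name)
        if name == "roi" and value is not None:
            shown = f"{value * 100:,.2f}%"
        else:
            shown = _fmt2(value)
        out.append(f"  {label:<{width}}{shown:>14}")
    out.append("")
    return "\n".join(out)
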