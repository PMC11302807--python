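"""Report emitters: cost grids and savings tables as DataFrames, CSV,
JSON-ready dicts, and plain markdown.

Money is carried at full precision everywhere else in the package;
rounding to cents happens here.  Markdown gets thousands separators,
CSV/JSON stay bare so the three formats carry identical numbers.
"""

from __future__ import annotations

import pandas as pd

from .fmea import Register, display_round, format_score
from .scenario import CombinedResult, SavingsBreakdown
from .tdabc import CostBreakdown

__all__ = [
    "breakdown_frame",
    "category_summary",
    "savings_frame",
    "register_frame",
    "frame_to_markdown",
]

TOTAL = "Total"


def breakdown_frame(bd: CostBreakdown, category: str | None = None) -> pd.DataFrame:
    """Resource-by-stage cost grid with a Total row and column (cents).

    ``category`` restricts to one resource category (e.g. the personnel
    block of a published cost table).
    """
    if category is not None:
        bd = bd.restrict(category)
    resources = sorted({rid for rid, _ in bd.cell_costs})
    stages = [s for s in bd.stages]
    data = {
        stage: [round(bd.cell_costs.get((rid, stage), 0.0), 2) for rid in resources]
        for stage in stages
    }
    df = pd.DataFrame(data, index=resources)
    df[TOTAL] = [round(v, 2) for v in df.sum(axis=1)]
    df.loc[TOTAL] = [round(v, 2) for v in df.sum(axis=0)]
    # recompute marginals from full precision so totals match the engine
    totals = bd.resource_totals
    df.loc[resources, TOTAL] = [round(totals[r], 2) for r in resources]
    stage_totals = bd.stage_totals
    df.loc[TOTAL, stages] = [round(stage_totals[s], 2) for s in stages]
    df.loc[TOTAL, TOTAL] = round(bd.grand_total, 2)
    return df


def category_summary(bd: CostBreakdown) -> pd.DataFrame:
    cats = bd.category_totals
    rows = {k: round(v, 2) for k, v in cats.items()}
    rows["grand_total"] = round(bd.grand_total, 2)
    return pd.DataFrame({"cost_usd": rows})


def savings_frame(result: CombinedResult) -> pd.DataFrame:
    """Per-intervention and combined savings, with the reduced total."""

    def row(sb: SavingsBreakdown) -> dict:
        return {
            "personnel": round(sb.personnel, 2),
            "equipment": round(sb.equipment, 2),
            "space": round(sb.space, 2),
            "total": round(sb.total, 2),
            "time_saved_min": round(sb.time_saved, 2),
        }

    rows = {name: row(sb) for name, sb in result.per_intervention.items()}
    rows["combined"] = row(result.combined)
    df = pd.DataFrame(rows).T
    df.attrs["baseline_total"] = round(result.baseline_total, 2)
    df.attrs["reduced_total"] = round(result.reduced_total, 2)
    return df


def register_frame(register: Register) -> pd.DataFrame:
    rows = []
    for fm in register:
        rows.append(
            {
                "id": fm.id,
                "step": fm.process_step_label,
                "role": fm.role,
                "description": fm.description,
                "O": format_score(fm.O),
                "S": format_score(fm.S),
                "D": format_score(fm.D),
                "rpn": display_round(fm.rpn),
                "risk_level": fm.risk_level or "",
                "top_rpn": fm.top_rpn_flag,
                "top_severity": fm.top_severity_flag,
            }
        )
    return pd.DataFrame(rows)


def _fmt_cell(v, money: bool) -> str:
    if isinstance(v, float) and money:
        return f"{v:,.2f}"
    return str(v)


def frame_to_markdown(df: pd.DataFrame, money: bool = True, index_name: str = "") -> str:
    """Minimal GitHub-style pipe table (no external table dependency)."""
    header = [index_name] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |"]
    lines.append("|" + "|".join("---" for _ in header) + "|")
    for idx, row in df.iterrows():
        cells = [str(idx)] + [_fmt_cell(v, money) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
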