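"""TG-100-style failure modes and effects analysis.

Failure modes carry occurrence (O), severity (S), and detectability (D)
scores on the 1-10 TG-100 scales.  Scores are exact rationals
(:class:`fractions.Fraction`): when several raters score independently the
consensus is the exact mean, so three raters give thirds (16/3 prints as
5.33) and the risk priority number RPN = O x S x D is computed on the
unrounded values.  This matters: 4 x 16/3 x 13/3 = 832/9 prints as 92.44,
whereas multiplying the rounded displays would give 92.32.

Risk levels come from a configurable (severity, occurrence) matrix that
must be monotone and must map severity 9-10 to high risk regardless of
occurrence — the severity override.  Top-fraction selection (the "top 20%
RPNs", globally or per responsible role) uses a ceiling cutoff and keeps
ties at the boundary.

``audit_register`` recomputes every published RPN from its scores and
lists the rows that disagree beyond a tolerance — a data-quality check on
printed tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "LEVELS",
    "display_round",
    "parse_score",
    "format_score",
    "consensus",
    "rpn",
    "RiskMatrix",
    "default_matrix",
    "FailureMode",
    "Register",
    "classify",
    "classify_register",
    "top_fraction",
    "summarize",
    "audit_register",
    "AuditRow",
    "read_register",
    "write_register",
]

LEVELS = ("low", "medium", "high")
_LEVEL_RANK = {lvl: i for i, lvl in enumerate(LEVELS)}


def display_round(x: Fraction | float, ndigits: int = 2) -> float:
    """Round half away from zero, exactly for rationals.

    Bankers' rounding would print 832/9 as 92.44 either way, but
    half-cases like 5/2 must display 2.5 -> 2.50 and -5/2 -> -2.50.
    """
    q = Fraction(x).limit_denominator(10**9) if isinstance(x, float) else Fraction(x)
    scale = 10**ndigits
    sign = -1 if q < 0 else 1
    return sign * float(math.floor(abs(q) * scale + Fraction(1, 2))) / scale


def _thirds(text: str) -> Fraction | None:
    """Interpret a printed two-decimal value as an exact third if it is the
    standard rounding of one (x.33 -> x + 1/3, x.67 -> x + 2/3)."""
    if "." not in text:
        return None
    whole, frac = text.split(".", 1)
    if frac == "33":
        return Fraction(int(whole)) + Fraction(1, 3)
    if frac == "67":
        return Fraction(int(whole)) + Fraction(2, 3)
    return None


def parse_score(cell: object, mode: str = "thirds") -> Fraction:
    """Parse a score cell: integer, decimal, fraction "16/3", or a
    semicolon-separated rater list "5;5;6" (averaged exactly).

    ``mode="thirds"`` (default) reads printed decimals like 5.33 as the
    exact third they round from; ``mode="decimal"`` takes them literally.
    """
    if isinstance(cell, Fraction):
        value = cell
    elif isinstance(cell, int):
        value = Fraction(cell)
    elif isinstance(cell, float):
        value = parse_score(repr(cell), mode=mode)
    elif isinstance(cell, str):
        text = cell.strip()
        if ";" in text:
            return consensus([int(t) for t in text.split(";") if t.strip()])
        if "/" in text:
            value = Fraction(text)
        else:
            value = None
            if mode == "thirds":
                value = _thirds(text)
            if value is None:
                value = Fraction(text)
    else:
        raise ValueError(f"cannot parse score from {cell!r}")
    if not Fraction(1) <= value <= Fraction(10):
        raise ValueError(f"score {cell!r} outside the 1-10 scale")
    return value


def format_score(value: Fraction) -> str:
    if value.denominator == 1:
        return str(value.numerator)
    return f"{display_round(value):.2f}"


def consensus(
    rater_scores: Sequence[int], method: str = "mean_exact"
) -> Fraction:
    """Consensus score from individual rater scores.

    ``mean_exact`` averages independent integer scores exactly (the
    physicist-panel path); ``agreed_value`` is the discussion-consensus
    path and requires a single mutually agreed value.
    """
    if len(rater_scores) == 0:
        raise ValueError("consensus requires at least one rater score")
    for s in rater_scores:
        if not 1 <= s <= 10:
            raise ValueError(f"rater score {s} outside the 1-10 scale")
    if method == "agreed_value":
        if len(rater_scores) != 1:
            raise ValueError("agreed_value consensus takes exactly one value")
        return Fraction(rater_scores[0])
    if method != "mean_exact":
        raise ValueError(f"unknown consensus method {method!r}")
    return Fraction(sum(rater_scores), len(rater_scores))


def rpn(O: Fraction, S: Fraction, D: Fraction) -> Fraction:
    """Risk priority number O x S x D, exact."""
    return Fraction(O) * Fraction(S) * Fraction(D)


class RiskMatrix:
    """A monotone (severity, occurrence) -> level grid on 1..10 x 1..10.

    Rejected at construction unless the level never decreases with S or O
    and the severity-override rows (S = 9, 10) are entirely high.
    """

    def __init__(self, grid: Sequence[Sequence[str]]):
        g = [list(row) for row in grid]
        if len(g) != 10 or any(len(row) != 10 for row in g):
            raise ValueError("risk matrix must be 10 rows (S) x 10 columns (O)")
        for row in g:
            for lvl in row:
                if lvl not in LEVELS:
                    raise ValueError(f"unknown risk level {lvl!r}")
        for s in range(10):
            for o in range(10):
                if o > 0 and _LEVEL_RANK[g[s][o]] < _LEVEL_RANK[g[s][o - 1]]:
                    raise ValueError(
                        f"non-monotone in occurrence at S={s+1}, O={o+1}"
                    )
                if s > 0 and _LEVEL_RANK[g[s][o]] < _LEVEL_RANK[g[s - 1][o]]:
                    raise ValueError(
                        f"non-monotone in severity at S={s+1}, O={o+1}"
                    )
        for s in (8, 9):
            if any(lvl != "high" for lvl in g[s]):
                raise ValueError(
                    f"severity override violated: row S={s+1} must be all high"
                )
        self.grid = g

    def level(self, S: Fraction | float | int, O: Fraction | float | int) -> str:
        """Level at (S, O); non-integer scores are ceiled (conservative) and
        values are clamped to the 1-10 grid."""
        s = min(10, max(1, math.ceil(S)))
        o = min(10, max(1, math.ceil(O)))
        if s >= 9:
            return "high"
        return self.grid[s - 1][o - 1]

    # -- file form: 10 lines of 10 {L,M,H} letters --------------------------

    _LETTER = {"L": "low", "M": "medium", "H": "high"}

    @classmethod
    def from_file(cls, path: str | Path) -> "RiskMatrix":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip().replace(" ", "")
            if not line or line.startswith("#"):
                continue
            rows.append([cls._LETTER.get(ch, ch) for ch in line])
        return cls(rows)

    def to_file(self, path: str | Path) -> None:
        inv = {v: k for k, v in self._LETTER.items()}
        Path(path).write_text(
            "\n".join("".join(inv[lvl] for lvl in row) for row in self.grid) + "\n"
        )


def default_matrix() -> RiskMatrix:
    """The packaged default risk matrix.

    High: S >= 9 (any O), or S >= 7 and O >= 6, or S >= 5 and O >= 8.
    Low:  S <= 2, or S <= 4 and O <= 3.  Medium elsewhere.  Monotone and
    TG-100-scale compatible; an institutional assumption, configurable.
    """
    grid = []
    for s in range(1, 11):
        row = []
        for o in range(1, 11):
            if s >= 9 or (s >= 7 and o >= 6) or (s >= 5 and o >= 8):
                row.append("high")
            elif s <= 2 or (s <= 4 and o <= 3):
                row.append("low")
            else:
                row.append("medium")
        grid.append(row)
    return RiskMatrix(grid)


@dataclass
class FailureMode:
    id: str
    process_step_label: str = ""
    role: str = ""
    description: str = ""
    cause: str = ""
    effect: str = ""
    O: Fraction = Fraction(1)
    S: Fraction = Fraction(1)
    D: Fraction = Fraction(1)
    printed_rpn: float | None = None
    printed_top_severity: bool | None = None
    # derived
    risk_level: str | None = None
    top_rpn_flag: bool = False
    top_severity_flag: bool = False

    @property
    def rpn(self) -> Fraction:
        return rpn(self.O, self.S, self.D)


@dataclass
class Register:
    """A failure-mode register with free-form provenance metadata."""

    modes: list[FailureMode] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [fm.id for fm in self.modes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate failure-mode ids: {dupes}")

    def __iter__(self):
        return iter(self.modes)

    def __len__(self) -> int:
        return len(self.modes)


def classify(fm: FailureMode, matrix: RiskMatrix) -> str:
    return matrix.level(fm.S, fm.O)


def classify_register(register: Register, matrix: RiskMatrix) -> Register:
    for fm in register.modes:
        fm.risk_level = classify(fm, matrix)
    return register


def top_fraction(
    register: Register,
    fraction: float = 0.2,
    key: str = "rpn",
    group_by: str = "none",
) -> Register:
    """Flag the top ``fraction`` of modes by RPN or severity.

    Within each group, k = ceil(fraction x group size) modes are selected
    and every mode tied with the k-th value is included.  ``group_by="role"``
    ranks each responsible-personnel group independently (the per-role
    top-20% of TG-100 practice).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if key not in ("rpn", "severity"):
        raise ValueError(f"unknown ranking key {key!r}")
    if group_by not in ("none", "role"):
        raise ValueError(f"unknown grouping {group_by!r}")
    flag = "top_rpn_flag" if key == "rpn" else "top_severity_flag"
    keyfun: Callable[[FailureMode], Fraction] = (
        (lambda fm: fm.rpn) if key == "rpn" else (lambda fm: fm.S)
    )
    groups: dict[str, list[FailureMode]] = {}
    for fm in register.modes:
        groups.setdefault(fm.role if group_by == "role" else "", []).append(fm)
    for members in groups.values():
        k = math.ceil(fraction * len(members))
        threshold = sorted((keyfun(fm) for fm in members), reverse=True)[k - 1]
        for fm in members:
            setattr(fm, flag, keyfun(fm) >= threshold)
    return register


def summarize(register: Register, matrix: RiskMatrix | None = None) -> dict:
    """Count modes by risk level and top-fraction flags.

    Classifies on the fly when a matrix is given; otherwise uses the
    levels already present.
    """
    if matrix is not None:
        classify_register(register, matrix)
    counts = {"total": len(register.modes), "high": 0, "medium": 0, "low": 0}
    for fm in register.modes:
        if fm.risk_level is not None:
            counts[fm.risk_level] += 1
    counts["n_top_rpn"] = sum(fm.top_rpn_flag for fm in register.modes)
    counts["n_top_severity"] = sum(fm.top_severity_flag for fm in register.modes)
    return counts


@dataclass(frozen=True)
class AuditRow:
    id: str
    printed_rpn: float
    recomputed_rpn: float
    discrepancy: float


def audit_register(register: Register, tolerance_abs: float = 0.1) -> list[AuditRow]:
    """Rows whose published RPN disagrees with exact recomputation.

    The recomputed value is the display rounding of the exact product, so
    legitimate rounding (92.44 for 832/9) never trips the audit; genuine
    errata (e.g. a printed 51.13 against an exact 51.33) do.
    """
    out = []
    for fm in register.modes:
        if fm.printed_rpn is None:
            continue
        recomputed = display_round(fm.rpn)
        gap = abs(fm.printed_rpn - recomputed)
        if gap > tolerance_abs:
            out.append(AuditRow(fm.id, fm.printed_rpn, recomputed, gap))
    return out


# ---------------------------------------------------------------------------
# CSV register I/O

_IN_COLUMNS = ["id", "step", "role", "description", "cause", "effect", "O", "S", "D"]


def read_register(path: str | Path, score_mode: str = "thirds") -> Register:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _IN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: register CSV missing columns {missing}")
    modes = []
    for _, row in df.iterrows():
        try:
            O = parse_score(row["O"], mode=score_mode)
            S = parse_score(row["S"], mode=score_mode)
            D = parse_score(row["D"], mode=score_mode)
        except ValueError as exc:
            raise ValueError(f"row {row['id']!r}: {exc}") from exc
        printed = row.get("printed_rpn", "")
        top_sev = row.get("printed_top_severity", "")
        modes.append(
            FailureMode(
                id=row["id"],
                process_step_label=row["step"],
                role=row["role"],
                description=row["description"],
                cause=row["cause"],
                effect=row["effect"],
                O=O,
                S=S,
                D=D,
                printed_rpn=float(printed) if printed else None,
                printed_top_severity={"yes": True, "no": False}.get(
                    str(top_sev).strip().lower()
                ),
            )
        )
    return Register(modes=modes, metadata={"source": str(path)})


def write_register(register: Register, path: str | Path) -> None:
    rows = []
    for fm in register.modes:
        rows.append(
            {
                "id": fm.id,
                "step": fm.process_step_label,
                "role": fm.role,
                "description": fm.description,
                "cause": fm.cause,
                "effect": fm.effect,
                "O": format_score(fm.O),
                "S": format_score(fm.S),
                "D": format_score(fm.D),
                "printed_rpn": "" if fm.printed_rpn is None else fm.printed_rpn,
                "rpn": f"{display_round(fm.rpn):.2f}",
                "risk_level": fm.risk_level or "",
                "top_rpn": fm.top_rpn_flag,
                "top_severity": fm.top_severity_flag,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
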