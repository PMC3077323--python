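"""Stable TSV/JSON serialization of analysis results.

All writers emit deterministic, byte-stable output for identical
inputs: fixed column orders, repr-precision floats, LF line endings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .consistency import ForestTable
from .robustness import EliminationPath, LocoResult
from .surrogacy import CountryEffect, SurrogacyFit


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_tsv(
    rows: Iterable[Mapping], path: str | Path, columns: Sequence[str] | None = None
) -> None:
    rows = list(rows)
    if columns is None:
        columns = list(rows[0]) if rows else []
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(_fmt(row.get(c)) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# -- result-specific row shapes ---------------------------------------------


def forest_rows(table: ForestTable) -> list[dict]:
    """Forest-plot columns: subset label, O/N per arm, HR with CI, P."""
    rows = []
    for r in table.rows:
        rows.append(
            {
                "label": r.label,
                "o_n_treat": f"{r.events_treat}/{r.n_treat}",
                "o_n_control": f"{r.events_control}/{r.n_control}",
                "hr": r.fit.hr,
                "ci_low": r.fit.ci_low,
                "ci_high": r.fit.ci_high,
                "p": r.fit.p_two_sided,
            }
        )
    return rows


def loco_rows(loco: LocoResult) -> list[dict]:
    return [r.to_dict() for r in loco.rows]


def histogram_rows(bins: list[tuple[float, float, int]]) -> list[dict]:
    return [{"bin_low": lo, "bin_high": hi, "count": c} for lo, hi, c in bins]


def elimination_rows(path_obj: EliminationPath) -> list[dict]:
    return [s.to_dict() for s in path_obj.steps]


def effect_rows(effects: Sequence[CountryEffect]) -> list[dict]:
    return [e.to_dict() for e in effects]


def surrogacy_report(
    fit: SurrogacyFit,
    effects: Sequence[CountryEffect],
    excluded: Sequence[tuple[str, str]],
) -> dict:
    return {
        "fit": fit.to_dict(),
        "effects": [e.to_dict() for e in effects],
        "excluded": [{"country": c, "reason": r} for c, r in excluded],
    }
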