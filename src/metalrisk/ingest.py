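"""Reading, preprocessing and daily aggregation of detection records.

The preprocessing rules applied before any index is computed:

1. results reported below the limit of detection ("not detected") are
   replaced by half of the LOD rather than zero (the standard credible
   treatment of low pollutant levels);
2. results carrying an extra ``<`` marker keep their numeric value with the
   symbol stripped;
3. total-arsenic results are converted to inorganic arsenic at a fixed ratio
   (70% by default), applied exactly once per record.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import DailyMetalSummary, DetectionRecord, Metal, parse_metal

#: Canonical field → default input column header (matching the national
#: sampling-inspection export layout).
DEFAULT_DIALECT: dict[str, str] = {
    "metal": "Heavy Metal Elements",
    "date": "Date of Inspection",
    "result": "Inspection Result",
    "province": "Province",
    "food_category": "Food Category",
    "lod": "Limit of Detection",  # optional column
}

#: Lowercased markers treated as a below-LOD (censored) result.
_ND_MARKERS = {"not detected", "nd", "n.d.", "undetected", "未检出"}


@dataclass(frozen=True)
class IngestReport:
    """Row accounting for one table read."""

    n_rows: int
    n_parsed: int
    n_rejected: int
    reasons: dict[str, int]


def _parse_result(text: str) -> tuple[float | None, bool]:
    """Parse an inspection-result cell → (value, censored).

    ``<``-prefixed results are returned with value=None, censored=False; the
    symbol is stripped later, in :func:`preprocess`, so the raw text survives
    in the record.
    """
    s = str(text).strip()
    if s.lower() in _ND_MARKERS:
        return None, True
    if s.startswith("<"):
        float(s[1:])  # must at least be numeric
        return None, False
    return float(s), False


def read_detection_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str = ",",
) -> tuple[list[DetectionRecord], IngestReport]:
    """Read a delimiter-separated detection table into records.

    Rows whose metal, date or result cannot be parsed are rejected and
    counted in the returned :class:`IngestReport`.  Raises if the file is
    missing, a mandatory mapped column is absent, or no row parses at all.
    """
    cols = {**DEFAULT_DIALECT, **(dialect or {})}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for key in ("metal", "date", "result"):
        if cols[key] not in df.columns:
            raise ValueError(f"missing mandatory column {cols[key]!r} (for {key})")

    records: list[DetectionRecord] = []
    reasons: dict[str, int] = {}

    def _reject(reason: str) -> None:
        reasons[reason] = reasons.get(reason, 0) + 1

    for _, row in df.iterrows():
        try:
            metal = parse_metal(row[cols["metal"]])
        except (ValueError, TypeError):
            _reject("unparseable metal")
            continue
        ts = pd.to_datetime(row[cols["date"]], errors="coerce")
        if pd.isna(ts):
            _reject("unparseable date")
            continue
        raw = row[cols["result"]]
        try:
            value, censored = _parse_result(raw)
        except (ValueError, TypeError):
            _reject("unparseable result")
            continue
        lod = None
        if cols.get("lod") in df.columns:
            lod_cell = row[cols["lod"]]
            if lod_cell is not None and not pd.isna(lod_cell):
                lod = float(lod_cell)
        records.append(
            DetectionRecord(
                metal=metal,
                date=ts.date(),
                raw_result=str(raw).strip(),
                value=value,
                censored=censored,
                lod=lod,
                province=str(row.get(cols.get("province"), "") or ""),
                food_category=str(
                    row.get(cols.get("food_category"), "Grain processing products")
                    or "Grain processing products"
                ),
            )
        )

    report = IngestReport(
        n_rows=len(df),
        n_parsed=len(records),
        n_rejected=len(df) - len(records),
        reasons=reasons,
    )
    if not records:
        raise ValueError(f"zero parseable rows in {path}")
    return records, report


def preprocess(
    records: Iterable[DetectionRecord],
    inorganic_as_ratio: float = 0.70,
    lod_table: Mapping[Metal, float] | None = None,
) -> list[DetectionRecord]:
    """Apply the substitution / symbol-stripping / arsenic-conversion rules.

    Order per record: strip a leading ``<``; substitute half-LOD for censored
    results (per-record LOD first, then ``lod_table``); finally convert
    arsenic to its inorganic fraction.  The conversion is guarded by the
    ``processed`` flag so re-running preprocess is a no-op.
    """
    out: list[DetectionRecord] = []
    for rec in records:
        value = rec.value
        censored = rec.censored
        lod = rec.lod
        if value is None and not censored and rec.raw_result.startswith("<"):
            value = float(rec.raw_result[1:])
        if censored:
            if lod is None and lod_table is not None:
                lod = lod_table.get(rec.metal)
            if lod is None or not lod > 0:
                raise ValueError(
                    f"censored {rec.metal.value} record on {rec.date} has no resolvable LOD"
                )
            value = lod / 2.0
            censored = False
        if value is None:
            raise ValueError(f"record on {rec.date} has no parseable value: {rec.raw_result!r}")
        if rec.metal is Metal.ARSENIC and not rec.processed:
            value = value * inorganic_as_ratio
        if not value > 0:
            raise ValueError(f"non-positive value after preprocessing: {value}")
        out.append(replace(rec, value=value, censored=censored, lod=lod, processed=True))
    return out


def summarize_daily(
    records: Sequence[DetectionRecord],
    limits: Mapping[Metal, float],
    quantile_rule: str = "linear",
) -> list[DailyMetalSummary]:
    """Aggregate preprocessed records into per-(date, metal) summaries.

    For each group the per-record pollution index P = X/S is computed against
    the national limit S; the summary carries max(P), mean(P) and the 50th /
    95th concentration quantiles (interpolation scheme ``quantile_rule``,
    linear by default).  Groups are emitted sorted by (date, metal).
    """
    rows = []
    for rec in records:
        if rec.value is None or not rec.processed:
            raise ValueError("summarize_daily requires preprocessed records")
        if rec.metal not in limits:
            raise KeyError(f"missing national limit for {rec.metal.value}")
        if not limits[rec.metal] > 0:
            raise ValueError(f"non-positive limit for {rec.metal.value}")
        rows.append((rec.date, rec.metal, rec.value))
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["date", "metal", "value"])
    summaries: list[DailyMetalSummary] = []
    for (date, metal), grp in sorted(
        df.groupby(["date", "metal"], sort=False),
        key=lambda kv: (kv[0][0], kv[0][1].value),
    ):
        # sorted values make the aggregates exactly invariant to row order
        x = np.sort(grp["value"].to_numpy(dtype=float))
        p = x / limits[metal]
        summaries.append(
            DailyMetalSummary(
                date=date,
                metal=metal,
                n_samples=len(x),
                p_max=float(p.max()),
                p_avg=float(p.mean()),
                x_q50=float(np.quantile(x, 0.5, method=quantile_rule)),
                x_q95=float(np.quantile(x, 0.95, method=quantile_rule)),
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[DailyMetalSummary]) -> pd.DataFrame:
    """Tabular view of summaries (one row per date × metal)."""
    return pd.DataFrame(
        {
            "date": [s.date for s in summaries],
            "metal": [s.metal.value for s in summaries],
            "n_samples": [s.n_samples for s in summaries],
            "p_max": [s.p_max for s in summaries],
            "p_avg": [s.p_avg for s in summaries],
            "x_q50": [s.x_q50 for s in summaries],
            "x_q95": [s.x_q95 for s in summaries],
        }
    )
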