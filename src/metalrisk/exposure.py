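"""Daily risk-assessment indexes: NIPI, TCR and THQ.

For each day and metal, three indexes are computed from the daily summary:

* NIPI, the Nemerow integrated pollution index
  ``sqrt((Pmax² + Pavg²) / 2)`` over the day's pollution indexes P = X/S —
  a quadratic mean that emphasises peak contamination;
* TCR, the target cancer risk ``EF·ED·CSF·EDI50 / ATC`` with the estimated
  daily intake at the day's median concentration,
  ``EDI50 = FC·X50 / W``;
* THQ, the target hazard quotient ``EF·ED·EDI95 / (ATC·RfD)`` with the
  intake at the day's 95th-percentile concentration.

Under the default chronic-exposure constants (EF = 365 d/yr, ED = 70 yr,
ATC = 365·ED d) the prefactor EF·ED/ATC is exactly 1, so TCR = CSF·EDI50 and
THQ = EDI95/RfD.  All three indexes are homogeneous of degree one in the
concentration scale.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

from .config import ConsumptionTable, ToxicologyParams
from .records import (
    INDEX_TYPES,
    METAL_ORDER,
    DailyMetalSummary,
    IndexTriple,
    Metal,
)


def nipi(p_max: float, p_avg: float) -> float:
    """Nemerow integrated pollution index of one day's pollution indexes.

    Quadratic mean of the day's maximum and average pollution index; lies
    between ``p_avg`` and ``p_max``.
    """
    if p_avg < 0 or p_max < p_avg:
        raise ValueError(f"need p_max >= p_avg >= 0, got {p_max}, {p_avg}")
    return math.sqrt((p_max * p_max + p_avg * p_avg) / 2.0)


def edi(fc_kg_per_day: float, x_mg_per_kg: float, body_mass_kg: float = 60.0) -> float:
    """Estimated daily intake, mg/(kg·d): consumption × concentration / body mass."""
    if not body_mass_kg > 0:
        raise ValueError("body mass must be positive")
    if fc_kg_per_day < 0 or x_mg_per_kg < 0:
        raise ValueError("consumption and concentration must be non-negative")
    return fc_kg_per_day * x_mg_per_kg / body_mass_kg


def tcr(summary: DailyMetalSummary, params: ToxicologyParams, fc_kg_per_day: float) -> float:
    """Target cancer risk for one day/metal, from the median concentration."""
    try:
        csf = params.csf[summary.metal]
    except KeyError:
        raise KeyError(f"no cancer slope factor for {summary.metal.value}") from None
    e = edi(fc_kg_per_day, summary.x_q50, params.body_mass_w)
    return params.chronic_prefactor * csf * e


def thq(summary: DailyMetalSummary, params: ToxicologyParams, fc_kg_per_day: float) -> float:
    """Target hazard quotient for one day/metal, from the 95th percentile."""
    try:
        rfd = params.rfd[summary.metal]
    except KeyError:
        raise KeyError(f"no reference dose for {summary.metal.value}") from None
    if not rfd > 0:
        raise ValueError(f"reference dose for {summary.metal.value} must be positive")
    e = edi(fc_kg_per_day, summary.x_q95, params.body_mass_w)
    return params.chronic_prefactor * e / rfd


def assess_day(
    summaries: Mapping[Metal, DailyMetalSummary],
    params: ToxicologyParams,
    consumption: ConsumptionTable,
) -> dict[Metal, IndexTriple]:
    """NIPI/TCR/THQ for every metal of one fully-observed day.

    Requires a summary for each of the three metals; days with partial metal
    coverage are dropped upstream because the fusion step needs all nine
    indexes.
    """
    missing = [m.value for m in METAL_ORDER if m not in summaries]
    if missing:
        raise KeyError(f"missing metals for this day: {missing}")
    fc = consumption.national_fc_kg_per_day
    out: dict[Metal, IndexTriple] = {}
    for m in METAL_ORDER:
        s = summaries[m]
        out[m] = IndexTriple(
            nipi=nipi(s.p_max, s.p_avg),
            tcr=tcr(s, params, fc),
            thq=thq(s, params, fc),
        )
    return out


def assess_series(
    summaries: Sequence[DailyMetalSummary],
    params: ToxicologyParams,
    consumption: ConsumptionTable,
) -> pd.DataFrame:
    """Per-day 9-column index matrix (metal × index type), fully-observed days only.

    Columns are a MultiIndex (metal, index) in canonical order; the row index
    is the calendar day.  Days missing any of the three metals are dropped.
    """
    by_date: dict = {}
    for s in summaries:
        by_date.setdefault(s.date, {})[s.metal] = s
    cols = pd.MultiIndex.from_tuples(
        [(m.value, t) for m in METAL_ORDER for t in INDEX_TYPES],
        names=["metal", "index"],
    )
    rows, dates = [], []
    for date in sorted(by_date):
        day = by_date[date]
        if any(m not in day for m in METAL_ORDER):
            continue
        triples = assess_day(day, params, consumption)
        rows.append(
            [getattr(triples[m], t) for m in METAL_ORDER for t in INDEX_TYPES]
        )
        dates.append(date)
    return pd.DataFrame(rows, index=pd.Index(dates, name="date"), columns=cols)
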