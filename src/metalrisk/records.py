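"""Domain records for heavy-metal detection data.

A :class:`DetectionRecord` is one laboratory measurement of one metal in one
product on one day, possibly left-censored at the assay's limit of detection
(LOD).  A :class:`DailyMetalSummary` holds the per-day, per-metal aggregates
that all downstream risk indexes are computed from: the maximum and mean
pollution index (concentration over national limit) and the 50th / 95th
concentration quantiles.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass


class Metal(str, enum.Enum):
    """The three supported heavy metals (closed enum)."""

    CHROMIUM = "chromium"
    CADMIUM = "cadmium"
    ARSENIC = "arsenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Accepted spellings in input tables, lowercase, punctuation-insensitive.
_METAL_ALIASES: dict[str, Metal] = {
    "chromium": Metal.CHROMIUM,
    "cr": Metal.CHROMIUM,
    "chromium(cr)": Metal.CHROMIUM,
    "cadmium": Metal.CADMIUM,
    "cd": Metal.CADMIUM,
    "cadmium(cd)": Metal.CADMIUM,
    "arsenic": Metal.ARSENIC,
    "as": Metal.ARSENIC,
    "arsenic(as)": Metal.ARSENIC,
    "inorganic arsenic": Metal.ARSENIC,
    "inorganic arsenic(as)": Metal.ARSENIC,
    "total arsenic": Metal.ARSENIC,
}


def parse_metal(text: str) -> Metal:
    """Map a free-text metal label (e.g. ``"Cadmium(Cd)"``) to a :class:`Metal`.

    Raises :class:`ValueError` for unknown labels.
    """
    key = text.strip().lower().replace("（", "(").replace("）", ")")
    try:
        return _METAL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognised metal label: {text!r}") from None


@dataclass
class DetectionRecord:
    """One detection result for one metal on one day.

    ``value`` is the concentration in mg/kg and is absent while the record is
    censored (reported below the LOD) or still carries an unstripped ``<``
    marker in ``raw_result``.  ``processed`` guards one-shot preprocessing
    steps (the inorganic-arsenic conversion in particular) against being
    applied twice.
    """

    metal: Metal
    date: datetime.date
    raw_result: str
    value: float | None
    censored: bool
    lod: float | None = None
    province: str = ""
    food_category: str = "Grain processing products"
    processed: bool = False

    def __post_init__(self) -> None:
        if self.value is not None and self.value < 0:
            raise ValueError(f"negative concentration {self.value!r}")
        if self.censored and self.lod is not None and self.lod <= 0:
            raise ValueError("censored record requires a positive LOD")


@dataclass(frozen=True)
class DailyMetalSummary:
    """Per-day, per-metal aggregates feeding the risk indexes.

    ``p_max`` / ``p_avg`` are the maximum and mean pollution index
    (dimensionless, concentration divided by the national limit) over the
    day's samples; ``x_q50`` / ``x_q95`` are concentration quantiles in mg/kg.
    """

    date: datetime.date
    metal: Metal
    n_samples: int
    p_max: float
    p_avg: float
    x_q50: float
    x_q95: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("summary needs at least one sample")
        if not (self.p_max >= self.p_avg >= 0):
            raise ValueError(f"need p_max >= p_avg >= 0, got {self.p_max}, {self.p_avg}")
        if not (self.x_q95 >= self.x_q50 >= 0):
            raise ValueError(f"need x_q95 >= x_q50 >= 0, got {self.x_q95}, {self.x_q50}")


@dataclass(frozen=True)
class IndexTriple:
    """The three daily risk indexes: NIPI, TCR and THQ (all dimensionless)."""

    nipi: float
    tcr: float
    thq: float

    def __post_init__(self) -> None:
        for name in ("nipi", "tcr", "thq"):
            v = getattr(self, name)
            if not (v >= 0) or v != v or v in (float("inf"),):
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.nipi, self.tcr, self.thq)


#: Canonical ordering of the index types in 9-column matrices.
INDEX_TYPES: tuple[str, ...] = ("nipi", "tcr", "thq")

#: Canonical metal ordering in 9-column matrices (matches reporting order).
METAL_ORDER: tuple[Metal, ...] = (Metal.CHROMIUM, Metal.CADMIUM, Metal.ARSENIC)
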