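"""Toxicology constants, consumption data and configuration handling.

Defaults follow the standard oral-exposure parameterisation used in dietary
risk assessment of heavy metals in grain products:

* reference doses (RfD, mg per kg body weight per day): Cr(III) 0.003,
  Cd 0.001, inorganic As 0.0003;
* cancer slope factors (CSF, (kg·d)/mg): Cr 0.5, Cd 6.3, As 1.5;
* exposure frequency EF = 365 d/yr, exposure duration ED = 70 yr, averaging
  time ATC = 365·ED d, so the chronic prefactor EF·ED/ATC equals 1;
* average adult body mass W = 60 kg;
* total arsenic converted to inorganic arsenic at a 70% ratio.

National limit standards S (mg/kg in grain processing products) default to
the GB 2762 values for Cr (1.0), Cd (0.2) and inorganic As (0.2) and are
configurable, as are all constants above, through a YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .records import Metal

#: Provincial per-capita consumption of grain processing products, g/day
#: (Fifth Chinese Total Diet Study survey values, 20 provinces).
PROVINCE_CONSUMPTION_G_PER_DAY: dict[str, float] = {
    "Heilongjiang": 673.70,
    "Jilin": 1201.02,
    "Liaoning": 1131.27,
    "Beijing": 825.20,
    "Hebei": 935.58,
    "Henan": 1517.90,
    "Ningxia": 1002.35,
    "Shaanxi": 783.86,
    "Inner Mongolia": 1038.39,
    "Qinghai": 1681.60,
    "Fujian": 920.55,
    "Zhejiang": 1126.50,
    "Jiangsu": 620.64,
    "Shanghai": 566.96,
    "Jiangxi": 641.55,
    "Hubei": 916.16,
    "Sichuan": 806.08,
    "Hunan": 905.68,
    "Guangxi": 765.55,
    "Guangdong": 431.90,
}


@dataclass(frozen=True)
class ConsumptionTable:
    """Province → daily consumption (g/day) with a derived national figure.

    The national per-capita consumption used in the exposure equations is, by
    default, the unweighted arithmetic mean of the provincial values converted
    to kg/day; per-province assessment simply passes the provincial value
    instead.
    """

    g_per_day: dict[str, float] = field(
        default_factory=lambda: dict(PROVINCE_CONSUMPTION_G_PER_DAY)
    )

    def __post_init__(self) -> None:
        if not self.g_per_day:
            raise ValueError("consumption table is empty")
        bad = {p: v for p, v in self.g_per_day.items() if not v > 0}
        if bad:
            raise ValueError(f"non-positive consumption entries: {bad}")

    @property
    def national_fc_kg_per_day(self) -> float:
        vals = list(self.g_per_day.values())
        return sum(vals) / len(vals) / 1000.0

    def fc_kg_per_day(self, province: str | None = None) -> float:
        """kg/day for a province, or the national mean when ``province`` is None."""
        if province is None:
            return self.national_fc_kg_per_day
        try:
            return self.g_per_day[province] / 1000.0
        except KeyError:
            raise KeyError(f"province {province!r} not in consumption table") from None


@dataclass(frozen=True)
class ToxicologyParams:
    """Toxicology constants and exposure-model parameters.

    rfd        oral reference dose, mg/(kg·d), per metal
    csf        cancer slope factor, (kg·d)/mg, per metal
    limit_s    national limit standard in grain products, mg/kg, per metal
    ef         exposure frequency, days/year
    ed         exposure duration, years
    atc        averaging time, days (defaults to 365·ed)
    body_mass_w  average resident body mass, kg
    inorganic_as_ratio  fraction of total As counted as inorganic
    """

    rfd: dict[Metal, float] = field(
        default_factory=lambda: {
            Metal.CHROMIUM: 0.003,
            Metal.CADMIUM: 0.001,
            Metal.ARSENIC: 0.0003,
        }
    )
    csf: dict[Metal, float] = field(
        default_factory=lambda: {
            Metal.CHROMIUM: 0.5,
            Metal.CADMIUM: 6.3,
            Metal.ARSENIC: 1.5,
        }
    )
    limit_s: dict[Metal, float] = field(
        default_factory=lambda: {
            Metal.CHROMIUM: 1.0,
            Metal.CADMIUM: 0.2,
            Metal.ARSENIC: 0.2,
        }
    )
    ef: float = 365.0
    ed: float = 70.0
    atc: float | None = None
    body_mass_w: float = 60.0
    inorganic_as_ratio: float = 0.70

    def __post_init__(self) -> None:
        if self.atc is None:
            object.__setattr__(self, "atc", 365.0 * self.ed)
        for name in ("ef", "ed", "atc", "body_mass_w", "inorganic_as_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for table in (self.rfd, self.csf, self.limit_s):
            for m, v in table.items():
                if not v > 0:
                    raise ValueError(f"non-positive constant for {m}: {v}")

    @property
    def chronic_prefactor(self) -> float:
        """EF·ED/ATC — exactly 1 under the default 365 d/yr over 70 yr."""
        return self.ef * self.ed / self.atc


def default_config() -> dict:
    """The full default configuration as a plain mapping (YAML-serialisable)."""
    tox = ToxicologyParams()
    return {
        "toxicology": {
            "rfd": {m.value: v for m, v in tox.rfd.items()},
            "csf": {m.value: v for m, v in tox.csf.items()},
            "limit_s": {m.value: v for m, v in tox.limit_s.items()},
            "ef": tox.ef,
            "ed": tox.ed,
            "atc": tox.atc,
            "body_mass_w": tox.body_mass_w,
            "inorganic_as_ratio": tox.inorganic_as_ratio,
        },
        "consumption": {
            "g_per_day": dict(PROVINCE_CONSUMPTION_G_PER_DAY),
            "fc_policy": "national-mean",
        },
        "quantile_interpolation": "linear",
    }


def load_config(path: str | Path) -> tuple[ToxicologyParams, ConsumptionTable, dict]:
    """Read a YAML config file, filling unspecified keys from the defaults.

    Returns the toxicology params, the consumption table and the raw merged
    mapping (for keys such as ``quantile_interpolation``).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    merged = default_config()
    for section, values in raw.items():
        if isinstance(values, dict) and section in merged:
            for k, v in values.items():
                if isinstance(v, dict) and k in merged[section]:
                    merged[section][k] = {**merged[section][k], **v}
                else:
                    merged[section][k] = v
        else:
            merged[section] = values
    t = merged["toxicology"]

    def _per_metal(d: dict) -> dict[Metal, float]:
        return {Metal(k): float(v) for k, v in d.items()}

    tox = ToxicologyParams(
        rfd=_per_metal(t["rfd"]),
        csf=_per_metal(t["csf"]),
        limit_s=_per_metal(t["limit_s"]),
        ef=float(t["ef"]),
        ed=float(t["ed"]),
        atc=float(t["atc"]) if t.get("atc") is not None else None,
        body_mass_w=float(t["body_mass_w"]),
        inorganic_as_ratio=float(t["inorganic_as_ratio"]),
    )
    cons = ConsumptionTable(
        g_per_day={k: float(v) for k, v in merged["consumption"]["g_per_day"].items()}
    )
    return tox, cons, merged


def dump_default_config() -> str:
    """Default configuration rendered as YAML (for ``metalrisk config``)."""
    return yaml.safe_dump(default_config(), sort_keys=False)
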