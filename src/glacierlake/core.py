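"""Shared schemas, units, detection-limit handling and I/O.

All stages of the pipeline exchange water-chemistry observations through a
single long-format table (:class:`SampleTable`). Concentrations are stored in
each species' canonical units (mg/L for major constituents, µg/L for trace
constituents such as TFe and TDP); readers auto-scale between the two.
Censored observations (below the analytical detection limit) carry the
registered detection limit as their reported bound and are substituted by
half the detection limit by :func:`apply_detection_limits`, the convention
used for all downstream statistics.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("glacierlake")

#: Compartments along the land-to-ocean continuum sampled by the pipeline.
COMPARTMENTS = (
    "snowpack",
    "snowmelt",
    "glacial_terminus",
    "glacial_delta",
    "lake_shoreline",
    "lake_column",
    "outflow",
)

#: 1 km³ of water at 1 mg/L holds exactly 1000 metric tons of solute.
TONS_PER_KM3_MGL = 1000.0


class ConfigurationError(ValueError):
    """Raised for missing registry entries, areas or constants."""


@dataclass(frozen=True)
class ChemSpecies:
    """A chemical species tracked by the pipeline.

    Parameters
    ----------
    name
        Identifier, e.g. ``NH4``, ``NO3NO2``, ``SO4``, ``DOC``.
    phase
        ``dissolved``, ``particulate`` or ``bulk``.
    canonical_units
        ``mg/L`` or ``ug/L``; every stored value for this species is in
        these units.
    detection_limit
        Method detection limit in canonical units, if known.
    """

    name: str
    phase: str = "dissolved"
    canonical_units: str = "mg/L"
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("dissolved", "particulate", "bulk"):
            raise ValueError(f"unknown phase {self.phase!r} for {self.name}")
        if self.canonical_units not in ("mg/L", "ug/L"):
            raise ValueError(f"unsupported units {self.canonical_units!r}")
        if self.detection_limit is not None and self.detection_limit <= 0:
            raise ValueError(f"detection limit must be > 0 for {self.name}")


class SpeciesRegistry:
    """Mapping of species name -> :class:`ChemSpecies` with unit helpers.

    Derived quantities follow the field conventions: DIN = NH4 + NO3NO2 and
    TC = DIC + DOC + PC.
    """

    def __init__(self, species: Iterable[ChemSpecies] = ()) -> None:
        self._species: dict[str, ChemSpecies] = {}
        for sp in species:
            self.add(sp)

    def add(self, sp: ChemSpecies) -> None:
        if sp.name in self._species:
            raise ValueError(f"duplicate species {sp.name!r}")
        self._species[sp.name] = sp

    def __contains__(self, name: str) -> bool:
        return name in self._species

    def __getitem__(self, name: str) -> ChemSpecies:
        try:
            return self._species[name]
        except KeyError:
            raise ConfigurationError(f"species {name!r} not registered") from None

    def __iter__(self):
        return iter(self._species.values())

    def names(self) -> list[str]:
        return list(self._species)

    def to_canonical(self, name: str, value: float, units: str) -> float:
        """Convert ``value`` given in ``units`` to the species' canonical units."""
        sp = self[name]
        if units == sp.canonical_units:
            return value
        if units == "ug/L" and sp.canonical_units == "mg/L":
            return value / 1000.0
        if units == "mg/L" and sp.canonical_units == "ug/L":
            return value * 1000.0
        raise ConfigurationError(f"cannot convert {units!r} for species {name!r}")


def default_registry() -> SpeciesRegistry:
    """Registry covering the constituents of a glacierized-watershed survey.

    Trace constituents measured in µg/L carry their published method
    detection limits (TFe 7 µg/L, TDP 1.8 µg/L, TP 3 µg/L).
    """
    mg = [("NO3NO2", "dissolved"), ("NH4", "dissolved"), ("SO4", "dissolved"),
          ("dSiO2", "dissolved"), ("DIC", "dissolved"), ("DOC", "dissolved"),
          ("TN", "bulk"), ("PN", "particulate"), ("PC", "particulate"),
          ("TSS", "particulate")]
    species = [ChemSpecies(n, phase=p, canonical_units="mg/L") for n, p in mg]
    species += [
        ChemSpecies("TP", phase="bulk", canonical_units="ug/L", detection_limit=3.0),
        ChemSpecies("TDP", phase="dissolved", canonical_units="ug/L", detection_limit=1.8),
        ChemSpecies("TFe", phase="bulk", canonical_units="ug/L", detection_limit=7.0),
        ChemSpecies("CHLA", phase="particulate", canonical_units="ug/L"),
    ]
    return SpeciesRegistry(species)


@dataclass
class WaterSample:
    """One bottle: a dated, located set of analyte concentrations."""

    compartment: str
    site: str
    date: str
    depth_m: float | None = None
    #: species -> (value in canonical units, censored flag)
    analytes: dict[str, tuple[float, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.depth_m is not None and self.depth_m < 0:
            raise ValueError("depth_m must be >= 0 (positive down)")
        # dates must parse as ISO-8601
        pd.Timestamp(self.date)


#: Column order of the long-format samples.csv schema.
SAMPLE_COLUMNS = ["compartment", "site", "date", "depth_m", "species",
                  "value", "units", "censored", "substituted"]


class SampleTable:
    """Long-format collection of water samples plus a species registry."""

    def __init__(self, df: pd.DataFrame, registry: SpeciesRegistry | None = None):
        self.registry = registry if registry is not None else default_registry()
        df = df.copy()
        for col in ("censored", "substituted"):
            if col not in df.columns:
                df[col] = False
            df[col] = df[col].astype(bool)
        if "units" not in df.columns:
            df["units"] = [self.registry[s].canonical_units for s in df["species"]]
        unknown = set(df["species"]) - set(self.registry.names())
        if unknown:
            raise ConfigurationError(f"species not in registry: {sorted(unknown)}")
        bad = set(df["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartments: {sorted(bad)}")
        pd.to_datetime(df["date"])  # ISO-8601 validation
        # normalise values to canonical units
        df["value"] = [
            self.registry.to_canonical(s, v, u)
            for s, v, u in zip(df["species"], df["value"], df["units"])
        ]
        df["units"] = [self.registry[s].canonical_units for s in df["species"]]
        if "depth_m" not in df.columns:
            df["depth_m"] = np.nan
        self.df = df[SAMPLE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_samples(cls, samples: Iterable[WaterSample],
                     registry: SpeciesRegistry | None = None) -> "SampleTable":
        registry = registry if registry is not None else default_registry()
        rows = []
        for s in samples:
            for name, (value, censored) in s.analytes.items():
                rows.append({
                    "compartment": s.compartment, "site": s.site, "date": s.date,
                    "depth_m": np.nan if s.depth_m is None else s.depth_m,
                    "species": name, "value": value,
                    "units": registry[name].canonical_units,
                    "censored": censored, "substituted": False,
                })
        return cls(pd.DataFrame(rows, columns=SAMPLE_COLUMNS), registry)

    @classmethod
    def read_csv(cls, path: str | Path,
                 registry: SpeciesRegistry | None = None) -> "SampleTable":
        """Read a samples.csv.

        Lenient on censoring: a value written as ``<7`` is parsed as
        value 7 with ``censored=True`` even without a flag column.
        """
        df = pd.read_csv(path, dtype={"value": str})
        censored = df.get("censored")
        cens = (pd.Series(False, index=df.index) if censored is None
                else censored.astype(str).str.lower().isin(["true", "1", "yes"]))
        raw = df["value"].astype(str).str.strip()
        lt = raw.str.startswith("<")
        df["value"] = pd.to_numeric(raw.str.lstrip("<"), errors="raise")
        df["censored"] = cens | lt
        if "substituted" in df.columns:
            df["substituted"] = df["substituted"].astype(str).str.lower().isin(
                ["true", "1", "yes"])
        return cls(df, registry)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def subset(self, **filters) -> pd.DataFrame:
        """Rows matching equality filters, e.g. ``subset(compartment="snowpack")``."""
        df = self.df
        for col, val in filters.items():
            df = df[df[col] == val]
        return df


def apply_detection_limits(table: SampleTable) -> SampleTable:
    """Replace censored values by half the registered detection limit.

    Idempotent: rows already flagged ``substituted`` are left untouched, so
    applying the convention twice never halves a value twice.

    Raises
    ------
    ConfigurationError
        If a censored value belongs to a species without a registered
        detection limit.
    """
    df = table.df.copy()
    todo = df["censored"] & ~df["substituted"]
    for idx in df.index[todo]:
        name = df.at[idx, "species"]
        dl = table.registry[name].detection_limit
        if dl is None:
            raise ConfigurationError(
                f"censored value for species {name!r} but no detection limit registered")
        df.at[idx, "value"] = dl / 2.0
        df.at[idx, "substituted"] = True
    return SampleTable(df, table.registry)


def convert_load(concentration_mgL: float, volume_km3: float) -> float:
    """Annual load in metric tons from a concentration and a water volume.

    1 km³ at 1 mg/L is exactly 1000 t.
    """
    if concentration_mgL < 0 or volume_km3 < 0:
        raise ValueError("concentration and volume must be non-negative")
    return concentration_mgL * volume_km3 * TONS_PER_KM3_MGL


# ---------------------------------------------------------------------------
# configuration and logging

#: Watershed constants. Lake and watershed geometry are survey inputs; the
#: landscape (non-glacierized, non-lake) area follows by subtraction.
DEFAULT_CONFIG: dict = {
    "areas": {
        "watershed_km2": 7516.0,
        "glacierized_fraction": 0.409,
        "lake_km2": 544.0,
    },
    "snow": {"tracer_species": "SO4", "runoff_fraction": None},
    "loads": {"n_boot": 500, "centering": "orthogonal"},
    "budget": {"k_sigma": 1.0, "se_combination": "linear"},
    "stoich": {
        "secchi_constant": 1.7,
        "din_tp_thresholds": [1.5, 3.4],
        "atm_co2_ppm": 400.0,
    },
    "sediment": {"alpha": 0.05, "max_zones": 4,
                 "tube_inner_diameter_cm": 8.6},
}


def landscape_area_km2(config: Mapping | None = None) -> float:
    """Non-glacierized, non-lake watershed area receiving seasonal snowpack."""
    cfg = (config or DEFAULT_CONFIG)["areas"]
    area = cfg["watershed_km2"] * (1.0 - cfg["glacierized_fraction"]) - cfg["lake_km2"]
    if area <= 0:
        raise ConfigurationError("landscape area must be positive; check areas config")
    return area


def _merge(base: dict, extra: Mapping) -> dict:
    out = dict(base)
    for key, val in extra.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a TOML config file merged over the defaults."""
    if path is None:
        return _merge(DEFAULT_CONFIG, {})
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    return _merge(DEFAULT_CONFIG, user)


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(int(verbosity), 2)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")


def asdict(obj) -> dict:
    """JSON-friendly dict view of any pipeline dataclass."""
    return dataclasses.asdict(obj)
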