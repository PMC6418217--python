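"""Snowpack hydrology: areal water volumes and tracer melt partitioning.

Integrated snow cores weighed in the field give the areal water volume
(AWV, L/m²) of the snowpack assuming 1 kg of snow is 1 L of water:

    AWV = weight / (pi * r**2)

Snow on the lake surface melts in place, so its full AWV enters the lake.
On the surrounding landscape most of the shallow polar-desert snowpack
sublimates before it can run off; the fraction that does leave as overland
flow is inferred from a conservative tracer (sulfate): if all tracer mass is
conserved during melt while water is lost to sublimation, the snowmelt
stream is enriched relative to the snowpack exactly by the inverse of the
runoff fraction, so

    f_runoff = c_snowpack / c_snowmelt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from glacierlake.core import ConfigurationError, convert_load

__all__ = [
    "SnowCore", "SnowSurvey", "ArealWaterVolume",
    "areal_water_volume", "tracer_runoff_fraction",
    "snow_input_volumes", "snow_loads",
]

#: 1 L/m² of water over 1 km² is 1e-6 km³.
KM3_PER_LM2_KM2 = 1e-6


@dataclass(frozen=True)
class SnowCore:
    """One weighed snow core (1 kg snow = 1 L water)."""

    site: str
    replicate: int
    weight_kg: float
    corer_radius_m: float

    def __post_init__(self) -> None:
        if self.weight_kg < 0:
            raise ValueError("snow core weight must be >= 0")
        if self.corer_radius_m <= 0:
            raise ValueError("corer radius must be > 0")

    @property
    def awv(self) -> float:
        """Areal water volume of this core, L/m²."""
        return self.weight_kg / (math.pi * self.corer_radius_m ** 2)


@dataclass
class SnowSurvey:
    """A snow survey: cores plus mean snow chemistry and the areas it feeds."""

    cores: list[SnowCore]
    snow_chemistry: dict[str, tuple[float, float]] = field(default_factory=dict)
    """species -> (mean mg/L, SE mg/L) of snowpack (or snowmelt) chemistry."""
    lake_area_km2: float = 544.0
    landscape_area_km2: float = 3898.0
    tracer_species: str = "SO4"

    def __post_init__(self) -> None:
        if self.lake_area_km2 <= 0 or self.landscape_area_km2 <= 0:
            raise ConfigurationError("areas must be positive")
        if not self.cores:
            raise ValueError("a snow survey needs at least one core")


@dataclass(frozen=True)
class ArealWaterVolume:
    """Survey-level AWV: mean over sites with SE over sites."""

    mean: float        # L/m²
    se: float          # L/m²
    per_site: dict[str, float]

    @property
    def n_sites(self) -> int:
        return len(self.per_site)


def areal_water_volume(cores: Iterable[SnowCore]) -> ArealWaterVolume:
    """Survey AWV: replicate cores average within site, then SE over sites.

    Aggregating replicates per site first reflects the sampling design
    (three cores per site); the survey SE is the standard error of the
    site means.
    """
    per_site: dict[str, list[float]] = {}
    for core in cores:
        per_site.setdefault(core.site, []).append(core.awv)
    if not per_site:
        raise ValueError("no cores supplied")
    site_means = {site: float(np.mean(vals)) for site, vals in per_site.items()}
    values = np.array(list(site_means.values()))
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
    return ArealWaterVolume(mean=mean, se=se, per_site=site_means)


def tracer_runoff_fraction(c_snowpack: float, c_snowmelt: float) -> float:
    """Fraction of landscape snowpack water leaving as overland flow.

    Assumes the tracer is fully conserved in the pack during melt, so the
    only way the melt stream concentrates relative to the pack is loss of
    water to sublimation. The sublimated fraction is ``1 - f``.

    Scale-invariant: depends only on the concentration ratio.
    """
    if c_snowpack < 0 or c_snowmelt <= 0:
        raise ValueError("tracer concentrations must be positive")
    if c_snowmelt < c_snowpack:
        raise ValueError(
            "snowmelt tracer concentration below snowpack concentration: "
            "enrichment-by-sublimation assumption violated")
    return c_snowpack / c_snowmelt


def snow_input_volumes(survey: SnowSurvey,
                       fraction: float | None = None,
                       awv: ArealWaterVolume | None = None,
                       ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Meltwater volumes entering the lake from snow, km³ ± SE.

    Returns ``((on_lake, se), (landscape, se))``. Snow on the lake surface
    contributes its full AWV (no sublimation correction); landscape snow
    contributes AWV x area x runoff fraction. SEs scale linearly with the
    AWV SE.
    """
    if awv is None:
        awv = areal_water_volume(survey.cores)
    if fraction is None:
        raise ConfigurationError("runoff fraction required (tracer-derived or config)")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("runoff fraction must be in [0, 1]")
    on_lake = awv.mean * survey.lake_area_km2 * KM3_PER_LM2_KM2
    on_lake_se = awv.se * survey.lake_area_km2 * KM3_PER_LM2_KM2
    land = awv.mean * survey.landscape_area_km2 * fraction * KM3_PER_LM2_KM2
    land_se = awv.se * survey.landscape_area_km2 * fraction * KM3_PER_LM2_KM2
    return (on_lake, on_lake_se), (land, land_se)


def snow_loads(volume_km3: tuple[float, float],
               chemistry: Mapping[str, tuple[float, float]],
               species: Iterable[str] | None = None,
               ) -> dict[str, tuple[float, float]]:
    """Per-species snow loads in metric tons ± SE for one melt volume.

    ``chemistry`` maps species to (mean mg/L, SE mg/L): snowpack chemistry
    for snow melting on the lake surface, snowmelt-stream chemistry for
    landscape runoff. SEs combine linearly from the concentration SE and
    the volume SE (consistent with the budget convention).
    """
    vol, vol_se = volume_km3
    names = list(species) if species is not None else list(chemistry)
    out: dict[str, tuple[float, float]] = {}
    for name in names:
        if name not in chemistry:
            raise KeyError(f"no snow chemistry for species {name!r}")
        conc, conc_se = chemistry[name]
        load = convert_load(conc, vol)
        se = convert_load(conc_se, vol) + convert_load(conc, vol_se)
        out[name] = (load, se)
    return out
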