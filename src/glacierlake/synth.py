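"""Seeded synthetic-watershed generator with serialized ground truth.

Generates a complete field season for a glacierized Arctic watershed —
melt-season hydrographs, concentration-discharge chemistry, snow surveys
with a conservative sulfate tracer, sediment O2 microprofiles from known
consumption zones, and plankton communities structured along a DIN:TP
gradient — so that every pipeline stage has a parameter-recovery test
without any field data.

The stated world mirrors the study design it emulates: seven glacial
rivers flowing mid-June to end-August, two summers with weekly sampling of
the two rivers within hiking distance (11 calibration samplings per river x
species across the two years), snow surveys of 20 lake-surface and 13
landscape sites with three replicate cores each, an 87.8% / 12.2%
sublimation / runoff split of landscape snow, and five sediment cores.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawns, so components can be regenerated
independently and reproducibly. Multiplicative concentration noise is
mean-one lognormal (the log-noise has mean -sigma²/2), so the observed
concentrations are unbiased for the underlying concentration-discharge
relation and the realized annual truth is the noise-free integral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from glacierlake import sediment as sed
from glacierlake.loads import (CalibrationSet, DischargeSeries,
                               SECONDS_PER_DAY)
from glacierlake.snow import SnowCore, SnowSurvey

__all__ = [
    "ScenarioConfig", "SpeciesCQ",
    "gen_melt_hydrograph", "gen_chemistry", "gen_snow_survey",
    "gen_o2_profile", "gen_community", "simulate",
]


@dataclass(frozen=True)
class SpeciesCQ:
    """Concentration-discharge relation c = c0 (q/q0)^exponent.

    Dissolved constituents dilute (exponent <= 0), particulates amplify
    (exponent > 0). ``noise_sd`` is the SD of the multiplicative
    (mean-one lognormal) sampling noise on observed concentrations.
    """

    c0_mgL: float
    exponent: float
    noise_sd: float = 0.3
    phase: str = "dissolved"


#: Default concentration-discharge parameters, scaled to glacial rivers
#: draining carbonate terrain (dissolved species dilute gently; particulate
#: carbon amplifies strongly at peak flow).
DEFAULT_SPECIES: dict[str, SpeciesCQ] = {
    "SO4": SpeciesCQ(14.0, -0.30),
    "NO3NO2": SpeciesCQ(0.037, -0.20),
    "NH4": SpeciesCQ(0.024, -0.20),
    "dSiO2": SpeciesCQ(0.19, -0.25),
    "DIC": SpeciesCQ(6.7, -0.30),
    "DOC": SpeciesCQ(0.30, -0.10),
    "PC": SpeciesCQ(8.0, 0.80, phase="particulate"),
    "TSS": SpeciesCQ(300.0, 0.90, phase="particulate"),
}


@dataclass
class ScenarioConfig:
    """The stated world of one synthetic field season."""

    seed: int = 0
    n_rivers: int = 7
    years: tuple[int, ...] = (2015, 2016)
    # hydrograph
    melt_start: str = "06-15"           # mid-June
    melt_end: str = "08-31"             # end of August
    peak_doy_offset: int = 30           # peak ~mid-July
    peak_q_m3s: float = 40.0
    pulse_width_days: float = 16.0
    event_noise_sd: float = 0.15        # day-to-day lognormal flow noise
    q0_m3s: float = 10.0                # reference discharge of the c-q laws
    species: dict[str, SpeciesCQ] = field(default_factory=lambda: dict(DEFAULT_SPECIES))
    n_calibration: int = 11             # samplings per river x species
    # snow survey (polar desert: thin wind-packed snow, ~145 L/m²)
    n_lake_sites: int = 20
    n_land_sites: int = 13
    cores_per_site: int = 3
    awv_mean_Lm2: float = 145.0
    awv_site_sd_Lm2: float = 25.0
    core_rel_sd: float = 0.05
    corer_radius_m: float = 0.0215
    snowpack_so4_mgL: float = 1.82
    true_runoff_fraction: float = 0.122
    lake_area_km2: float = 544.0
    landscape_area_km2: float = 3898.0
    # sediment microprofile
    sediment_zone_boundaries_mm: tuple[float, ...] = (0.0, 15.0, 30.0)
    sediment_rates: tuple[float, ...] = (1.5e-3, 3.0e-4)  # nmol/cm³/s
    sediment_phi: float = 0.93
    sediment_temp_C: float = 3.76
    sediment_noise_umolL: float = 2.0
    profile_top_mm: float = -10.0
    # community gradient
    n_community_samples: int = 24
    din_tp_range: tuple[float, float] = (2.0, 60.0)
    community_mean_count: float = 200.0


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named per-component generators spawned from the master seed."""
    names = ["hydro", "chem", "snow", "sediment", "community"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# hydrographs and chemistry

def gen_melt_hydrograph(config: ScenarioConfig, year: int,
                        rng: np.random.Generator | None = None,
                        river: str = "river1",
                        peak_q: float | None = None) -> DischargeSeries:
    """Daily hydrograph for one melt season: Gaussian pulse x event noise.

    Discharge is zero outside the melt window. With ``event_noise_sd = 0``
    the series is a deterministic bell shape; otherwise day-to-day mean-one
    lognormal noise modulates it.
    """
    start = np.datetime64(f"{year}-01-01")
    dates = start + np.arange(365)
    doy = np.arange(365)
    t0 = (np.datetime64(f"{year}-{config.melt_start}") - start).astype(int)
    t1 = (np.datetime64(f"{year}-{config.melt_end}") - start).astype(int)
    peak = t0 + config.peak_doy_offset
    qp = config.peak_q_m3s if peak_q is None else peak_q
    q = qp * np.exp(-0.5 * ((doy - peak) / config.pulse_width_days) ** 2)
    window = (doy >= t0) & (doy <= t1)
    q = np.where(window, q, 0.0)
    if config.event_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        s = config.event_noise_sd
        noise = np.exp(rng.normal(-0.5 * s * s, s, size=365))
        q = q * np.where(window, noise, 1.0)
    return DischargeSeries(river=river, dates=dates, q=q)


def gen_chemistry(q_series: DischargeSeries, config: ScenarioConfig,
                  species: str, rng: np.random.Generator | None = None,
                  n_calibration: int | None = None,
                  ) -> tuple[CalibrationSet, pd.DataFrame, float]:
    """Daily concentrations, noisy calibration samplings and the true load.

    Daily true concentrations follow the noise-free concentration-discharge
    law; the recorded true annual load is their direct summation against the
    hydrograph. Calibration observations on ``n_calibration`` evenly spaced
    flowing days carry multiplicative mean-one lognormal noise.

    Returns ``(calibration, daily, true_tons)`` where ``daily`` has columns
    date, q, c.
    """
    par = config.species[species]
    n_cal = config.n_calibration if n_calibration is None else n_calibration
    q = q_series.q
    flowing = np.flatnonzero(q > 0)
    if len(flowing) < n_cal:
        raise ValueError("not enough flowing days for the calibration design")
    c_true = np.zeros_like(q)
    c_true[flowing] = par.c0_mgL * (q[flowing] / config.q0_m3s) ** par.exponent
    true_tons = float(np.sum(c_true * q) * 1000.0 * SECONDS_PER_DAY / 1e9)

    pick = flowing[np.linspace(0, len(flowing) - 1, n_cal).round().astype(int)]
    if rng is None:
        rng = np.random.default_rng(config.seed)
    s = par.noise_sd
    noise = np.exp(rng.normal(-0.5 * s * s, s, size=n_cal)) if s > 0 else np.ones(n_cal)
    calib = CalibrationSet(river=q_series.river, species=species,
                           dates=q_series.dates[pick], q=q[pick],
                           c=c_true[pick] * noise)
    daily = pd.DataFrame({"date": q_series.dates, "q": q, "c": c_true})
    return calib, daily, true_tons


# ---------------------------------------------------------------------------
# snow

def gen_snow_survey(config: ScenarioConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[SnowSurvey, dict]:
    """Snow survey with known AWV and tracer truth.

    Site AWVs are normal around the target mean; replicate core weights add
    relative noise. The snowmelt tracer concentration is exactly
    ``snowpack / true_runoff_fraction``, so a noiseless survey recovers the
    runoff fraction identically.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cores: list[SnowCore] = []
    area = np.pi * config.corer_radius_m ** 2
    site_awv = rng.normal(config.awv_mean_Lm2, config.awv_site_sd_Lm2,
                          size=config.n_lake_sites)
    site_awv = np.clip(site_awv, 1.0, None)
    for i, awv in enumerate(site_awv):
        for rep in range(config.cores_per_site):
            w = awv * area * max(1.0 + rng.normal(0, config.core_rel_sd), 0.0)
            cores.append(SnowCore(site=f"S{i:02d}", replicate=rep,
                                  weight_kg=float(w),
                                  corer_radius_m=config.corer_radius_m))
    c_pack = config.snowpack_so4_mgL
    c_melt = c_pack / config.true_runoff_fraction
    survey = SnowSurvey(cores=cores,
                        snow_chemistry={"SO4": (c_pack, 0.0)},
                        lake_area_km2=config.lake_area_km2,
                        landscape_area_km2=config.landscape_area_km2)
    truth = {"awv_mean_Lm2": float(site_awv.mean()),
             "snowpack_so4_mgL": c_pack,
             "snowmelt_so4_mgL": c_melt,
             "runoff_fraction": config.true_runoff_fraction}
    return survey, truth


# ---------------------------------------------------------------------------
# sediment

def gen_o2_profile(config: ScenarioConfig,
                   rng: np.random.Generator | None = None,
                   core: str = "core1") -> tuple[sed.MicroProfile, sed.ZoneModel]:
    """Forward-solved O2 microprofile plus the generating zone truth.

    The profile spans from ``profile_top_mm`` above the SWI (bottom water at
    the SWI concentration of the steady solution) to the bottom of the
    deepest zone, on a 0.1-mm grid, with additive Gaussian noise.
    """
    bounds_mm = np.asarray(config.sediment_zone_boundaries_mm, float)
    rates = np.asarray(config.sediment_rates, float)
    if len(rates) != len(bounds_mm) - 1:
        raise ValueError("need one rate per zone interval")
    d0 = sed.o2_free_diffusivity(config.sediment_temp_C)
    w = config.sediment_phi * sed.sediment_diffusivity(d0, config.sediment_phi)
    L_cm = bounds_mm[-1] / 10.0
    z_sed_mm = np.arange(0.0, bounds_mm[-1] + 1e-9, 0.1)
    c_sed, flux_top, flux_bottom = sed.solve_steady_profile(
        z_sed_mm / 10.0, np.full_like(z_sed_mm, w), bounds_mm / 10.0, rates,
        bc="bottomzero")
    z_above = np.arange(config.profile_top_mm, 0.0, 0.1)
    c_above = np.full_like(z_above, c_sed[0])
    z_mm = np.concatenate([z_above, z_sed_mm])
    c = np.concatenate([c_above, c_sed])
    if config.sediment_noise_umolL > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        c = c + rng.normal(0.0, config.sediment_noise_umolL, size=len(c))
    c = np.clip(c, 0.0, None)
    profile = sed.MicroProfile(core=core, z_mm=z_mm, c_umolL=c,
                               temperature_C=config.sediment_temp_C,
                               phi=config.sediment_phi, d0=d0)
    truth = sed.ZoneModel(core=core, boundaries_mm=bounds_mm, rates=rates,
                          rate_se=np.zeros_like(rates), bc="bottomzero",
                          swi_flux=flux_top, bottom_flux=flux_bottom)
    return profile, truth


# ---------------------------------------------------------------------------
# community

#: group -> (direction along DIN:TP, taxa). Mixotroph-capable flagellate
#: groups decline as DIN:TP rises (they dominate turbid low-ratio summer
#: water); diatoms, chlorophytes and cyanobacteria increase with the high
#: under-ice ratios.
COMMUNITY_GROUPS = {
    "chrysophyte": (-1, ["Dinobryon", "Uroglena", "Mallomonas"]),
    "cryptophyte": (-1, ["Rhodomonas", "Cryptomonas", "Kateblepharis"]),
    "dinoflagellate": (-1, ["Gymnodinium", "Peridinium"]),
    "diatom": (+1, ["Cyclotella", "Fragilaria", "Achnanthes"]),
    "chlorophyte": (+1, ["Chlamydomonas", "Oocystis", "Monoraphidium"]),
    "cyanobacteria": (+1, ["Aphanothece", "Synechococcus"]),
}


def gen_community(config: ScenarioConfig,
                  rng: np.random.Generator | None = None,
                  env_gradient: np.ndarray | None = None,
                  flat: bool = False,
                  ) -> tuple[np.ndarray, list[str], dict[str, str], pd.DataFrame]:
    """Sample x taxon counts along a DIN:TP gradient plus environment table.

    Group responses are logistic in log(DIN:TP) with the signs above;
    counts are Poisson around the response. ``flat=True`` removes the
    gradient (all taxa respond to nothing — the null world for selection
    tests). Returns ``(counts, taxa, taxon_group, env)`` where env has
    columns din_tp, tp, temperature, so4, co2_sat and season.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if env_gradient is None:
        lo, hi = config.din_tp_range
        ratio = np.exp(np.linspace(np.log(lo), np.log(hi),
                                   config.n_community_samples))
    else:
        ratio = np.asarray(env_gradient, dtype=float)
    n = len(ratio)
    if n < 6:
        raise ValueError("community gradient needs at least 6 samples")
    x = np.log(ratio)
    xc = (x - x.mean()) / x.std()
    taxa, groups, cols = [], {}, []
    for group, (sign, members) in COMMUNITY_GROUPS.items():
        for i, taxon in enumerate(members):
            taxa.append(taxon)
            groups[taxon] = group
            shift = (i - 1) * 0.4        # stagger optima within the group
            if flat:
                mean = np.full(n, 0.3 * config.community_mean_count)
            else:
                mean = config.community_mean_count * expit(sign * 2.5 * (xc - shift))
            cols.append(rng.poisson(np.clip(mean, 0.0, None)))
    counts = np.column_stack(cols).astype(float)
    season = np.where(ratio > 10.0, "under_ice", "open_water")
    env = pd.DataFrame({
        "din_tp": ratio,
        "tp": 3.0 + 50.0 / ratio + rng.normal(0, 0.5, n),
        "temperature": np.where(season == "under_ice", 0.5, 3.4)
        + rng.normal(0, 0.2, n),
        "so4": 6.0 + 0.02 * ratio + rng.normal(0, 0.3, n),
        "co2_sat": 95.0 + rng.normal(0, 4.0, n),
        "season": season,
    })
    return counts, taxa, groups, env


# ---------------------------------------------------------------------------
# full scenario bundle

def simulate(seed: int, out_dir: str | Path,
             config: ScenarioConfig | None = None) -> dict:
    """Write the complete synthetic CSV bundle plus ``truth.json``.

    Produces discharge.csv (daily, all rivers x years), samples.csv
    (calibration chemistry as glacial-delta samples, plus snowpack and
    snowmelt chemistry), snowcores.csv, sediment_profiles.csv, sections.csv,
    community.csv and env.csv, all conforming to the pipeline schemas, and a
    truth.json holding every generating parameter and realized true load.
    """
    config = config if config is not None else ScenarioConfig(seed=seed)
    rngs = _substreams(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth: dict = {"seed": seed, "true_loads_tons": {}}
    discharge_rows, sample_rows = [], []
    for year in config.years:
        scale = 1.0 if year == config.years[0] else 0.45  # low-melt second year
        for r in range(config.n_rivers):
            river = f"river{r + 1}"
            qs = gen_melt_hydrograph(config, year, rngs["hydro"], river=river,
                                     peak_q=config.peak_q_m3s * scale
                                     * (0.5 + r / config.n_rivers))
            discharge_rows.append(pd.DataFrame(
                {"river": river, "date": qs.dates.astype(str), "q_m3s": qs.q}))
            truth.setdefault("annual_volume_km3", {}).setdefault(
                str(year), {})[river] = qs.annual_volume_km3()
            if r >= 2:       # only the two hikable rivers get weekly chemistry
                continue
            for species, par in config.species.items():
                if par.phase != "dissolved":
                    continue
                calib, _, tons = gen_chemistry(qs, config, species, rngs["chem"])
                truth["true_loads_tons"].setdefault(str(year), {}).setdefault(
                    river, {})[species] = tons
                for d, q, c in zip(calib.dates, calib.q, calib.c):
                    sample_rows.append({
                        "compartment": "glacial_delta", "site": river,
                        "date": str(d), "depth_m": "", "species": species,
                        "value": c, "units": "mg/L",
                        "censored": False, "substituted": False})
    pd.concat(discharge_rows).to_csv(out / "discharge.csv", index=False)

    survey, snow_truth = gen_snow_survey(config, rngs["snow"])
    truth["snow"] = snow_truth
    pd.DataFrame([{"site": c.site, "replicate": c.replicate,
                   "weight_kg": c.weight_kg, "corer_radius_m": c.corer_radius_m}
                  for c in survey.cores]).to_csv(out / "snowcores.csv", index=False)
    for comp, conc in (("snowpack", snow_truth["snowpack_so4_mgL"]),
                       ("snowmelt", snow_truth["snowmelt_so4_mgL"])):
        sample_rows.append({
            "compartment": comp, "site": comp, "date": f"{config.years[0]}-06-01",
            "depth_m": "", "species": "SO4", "value": conc, "units": "mg/L",
            "censored": False, "substituted": False})
    pd.DataFrame(sample_rows).to_csv(out / "samples.csv", index=False)

    profile, zone_truth = gen_o2_profile(config, rngs["sediment"])
    pd.DataFrame({"core": profile.core, "depth_mm": profile.z_mm,
                  "o2_umolL": profile.c_umolL}).to_csv(
        out / "sediment_profiles.csv", index=False)
    phi = config.sediment_phi
    wet = 40.0
    dry = wet - phi * sed.SECTION_VOLUME_CM3
    pd.DataFrame([{"core": profile.core, "top_cm": i, "bottom_cm": i + 1,
                   "wet_g": wet, "dry_g": dry} for i in range(3)]).to_csv(
        out / "sections.csv", index=False)
    truth["sediment"] = {
        "boundaries_mm": list(zone_truth.boundaries_mm),
        "rates_nmol_cm3_s": list(zone_truth.rates),
        "integrated_rate_nmol_cm2_s": zone_truth.integrated_rate,
        "phi": phi, "temperature_C": config.sediment_temp_C,
    }

    counts, taxa, groups, env = gen_community(config, rngs["community"])
    comm_rows = []
    for i in range(counts.shape[0]):
        for j, taxon in enumerate(taxa):
            comm_rows.append({"sample": f"P{i:02d}", "taxon": taxon,
                              "group": groups[taxon],
                              "density_cells_mL": counts[i, j],
                              "biomass_ugL": counts[i, j] * 0.01})
    pd.DataFrame(comm_rows).to_csv(out / "community.csv", index=False)
    env_long = env.drop(columns="season").melt(ignore_index=False,
                                               var_name="variable")
    env_long.insert(0, "sample", [f"P{i:02d}" for i in env_long.index])
    env_long.to_csv(out / "env.csv", index=False)
    truth["community"] = {"n_samples": int(counts.shape[0]),
                          "din_tp": list(map(float, env["din_tp"]))}

    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
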