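"""Water-column summaries, light extinction, carbonate system, stoichiometry.

Covers the descriptive limnology that frames the mass-balance work:
depth-weighted water-column means, Secchi-disk light extinction
(k = 1.7 / z_SD, the Poole-Atkins constant), nutrient-limitation classes
from DIN:TP mass ratios, percent CO2 saturation from DIC/pH/temperature via
freshwater carbonate equilibrium constants, and ordered mean ± SE summary
tables along the land-to-ocean aquatic continuum (LOAC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ATOMIC_MASS", "LOAC_ORDER", "DepthProfile",
    "depth_integrated_mean", "extinction_from_secchi", "nutrient_limitation",
    "mass_to_molar_ratio", "co2_saturation", "loac_summary",
]

ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974, "S": 32.06, "Si": 28.085,
               "Fe": 55.845}

#: Compartment order along the land-to-ocean aquatic continuum.
LOAC_ORDER = ("glacial_terminus", "glacial_delta", "lake_shoreline",
              "lake_surface", "lake_bottom", "outflow", "fjord_inflow")


@dataclass
class DepthProfile:
    """One vertical profile of a single analyte."""

    site: str
    date: str
    season: str                # under_ice | open_water
    depths_m: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.depths_m = np.asarray(self.depths_m, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.depths_m) <= 0):
            raise ValueError("depths must be strictly increasing")


def depth_integrated_mean(depths_m: np.ndarray, values: np.ndarray,
                          replicate_values: np.ndarray | None = None,
                          ) -> tuple[float, float]:
    """Depth-weighted mean of a profile: trapezoidal integral / depth range.

    With ``replicate_values`` (replicate profiles on the same depth grid,
    one row per profile), the SE is the standard error of the replicate
    depth-weighted means. A single-depth profile returns the value with
    SE 0 (flagged upstream).
    """
    z = np.asarray(depths_m, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(z) < 2:
        return float(v[0]), 0.0
    span = z[-1] - z[0]
    mean = float(np.trapezoid(v, z) / span)
    se = 0.0
    if replicate_values is not None:
        reps = np.asarray(replicate_values, dtype=float)
        means = np.trapezoid(reps, z, axis=1) / span
        if len(means) > 1:
            se = float(means.std(ddof=1) / np.sqrt(len(means)))
    return mean, se


def extinction_from_secchi(z_sd_m: float, constant: float = 1.7) -> float:
    """Light extinction coefficient k (1/m) from a Secchi depth.

    Uses the Poole-Atkins relation k = constant / z_SD; 1.7 is the classic
    clear-lake value.
    """
    if z_sd_m <= 0:
        raise ValueError("Secchi depth must be > 0")
    return constant / z_sd_m


def nutrient_limitation(din_tp_mass_ratio: float,
                        thresholds: tuple[float, float] = (1.5, 3.4)) -> str:
    """Classify nutrient limitation from the DIN:TP mass ratio.

    Below the lower threshold the system is N-limited, above the upper
    P-limited, in between (boundaries inclusive) N and P co-limited.
    """
    lower, upper = thresholds
    if din_tp_mass_ratio < 0:
        raise ValueError("DIN:TP ratio must be >= 0")
    if din_tp_mass_ratio < lower:
        return "N_limited"
    if din_tp_mass_ratio <= upper:
        return "co_limited"
    return "P_limited"


def mass_to_molar_ratio(ratio_mass: float, element_pair: str) -> float:
    """Convert a mass ratio (e.g. N:P) to the corresponding molar ratio.

    ``element_pair`` is "num:den", e.g. ``"N:P"``; molar = mass x M_den/M_num.
    """
    try:
        num, den = element_pair.split(":")
        m_num, m_den = ATOMIC_MASS[num], ATOMIC_MASS[den]
    except (ValueError, KeyError):
        raise ValueError(f"unknown element pair {element_pair!r}") from None
    return ratio_mass * m_den / m_num


# -- freshwater carbonate system --------------------------------------------

def _carbonate_constants(temp_C: float) -> tuple[float, float, float]:
    """(K1, K2, KH) for freshwater at 1 atm.

    K1, K2 from the classical conductance determinations for pure water
    (Harned & Davis; Harned & Scholes); KH (mol/L/atm) from the
    temperature polynomial of Plummer & Busenberg. Validity ~0-50 °C.
    """
    T = temp_C + 273.15
    pk1 = 3404.71 / T + 0.032786 * T - 14.8435
    pk2 = 2902.39 / T + 0.02379 * T - 6.4980
    log_kh = (108.3865 + 0.01985076 * T - 6919.53 / T
              - 40.45154 * np.log10(T) + 669365.0 / T ** 2)
    return 10.0 ** -pk1, 10.0 ** -pk2, 10.0 ** log_kh


def co2_saturation(dic_mgC_L: float, ph: float, temp_C: float,
                   atm_co2_ppm: float = 400.0) -> float:
    """Percent CO2 saturation of a freshwater sample relative to the atmosphere.

    DIC (mg-C/L) is speciated into CO2*, HCO3- and CO3-- at the measured pH
    and temperature; the dissolved CO2 concentration is compared with the
    Henry's-law equilibrium for the given atmospheric mixing ratio.
    100% = equilibrium; >100% = supersaturated (a CO2 source to the air).
    """
    if not 4.0 <= ph <= 10.0:
        raise ValueError("pH outside supported range [4, 10]")
    if dic_mgC_L <= 0:
        raise ValueError("DIC must be > 0")
    k1, k2, kh = _carbonate_constants(temp_C)
    h = 10.0 ** -ph
    dic_molL = dic_mgC_L / 1000.0 / ATOMIC_MASS["C"]
    co2 = dic_molL / (1.0 + k1 / h + k1 * k2 / h ** 2)
    co2_eq = kh * atm_co2_ppm * 1e-6
    return float(100.0 * co2 / co2_eq)


# -- land-to-ocean summary tables -------------------------------------------

def loac_summary(samples: pd.DataFrame,
                 concentration_species: tuple[str, ...] = (
                     "DIC", "DOC", "PC", "TN", "TP", "TFe", "dSiO2", "SO4"),
                 order: tuple[str, ...] = LOAC_ORDER) -> pd.DataFrame:
    """Ordered mean ± SE table of concentrations and ratios along the LOAC.

    ``samples`` is a wide per-sample table with a ``compartment`` column and
    one column per species (canonical units). Derived columns are added
    when their parents exist: DIN = NH4 + NO3NO2, TC = DIC + DOC + PC,
    DIN:TP (mass, TP in mg/L), and molar TC:TP and TN:TP. Compartments
    absent from the data are omitted.
    """
    df = samples.copy()
    if {"NH4", "NO3NO2"} <= set(df.columns) and "DIN" not in df.columns:
        df["DIN"] = df["NH4"] + df["NO3NO2"]
    if {"DIC", "DOC", "PC"} <= set(df.columns) and "TC" not in df.columns:
        df["TC"] = df["DIC"] + df["DOC"] + df["PC"]
    if {"DIN", "TP"} <= set(df.columns):
        df["DIN_TP_mass"] = df["DIN"] / (df["TP"] / 1000.0)  # TP stored µg/L
    if {"TC", "TP"} <= set(df.columns):
        df["TC_TP_molar"] = [
            mass_to_molar_ratio(r, "C:P") for r in df["TC"] / (df["TP"] / 1000.0)]
    if {"TN", "TP"} <= set(df.columns):
        df["TN_TP_molar"] = [
            mass_to_molar_ratio(r, "N:P") for r in df["TN"] / (df["TP"] / 1000.0)]

    value_cols = [c for c in list(concentration_species)
                  + ["DIN", "TC", "DIN_TP_mass", "TC_TP_molar", "TN_TP_molar"]
                  if c in df.columns]
    rows = []
    for comp in order:
        sub = df[df["compartment"] == comp]
        if sub.empty:
            continue
        row: dict = {"compartment": comp, "n": len(sub)}
        for col in value_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_se"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                                if len(vals) > 1 else 0.0)
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["compartment"] = pd.Categorical(out["compartment"], categories=order,
                                            ordered=True)
        out = out.sort_values("compartment").reset_index(drop=True)
    return out
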