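"""Published reference values for the Lake Hazen watershed (Ellesmere Island).

The 2015/2016 annual mass-balance table for the world's largest High Arctic
lake is the standard worked example for this package: it provides printed
component loads (metric tons/yr ± SE; water in km³/yr) for the three
hydrological inputs (snowmelt on the lake surface, snowmelt runoff from the
landscape, glacial rivers) and the single outflow (Ruggles River), for the
six dissolved species whose budgets could be closed. These numbers are used
as *inputs* for cross-checks and examples — the package never tunes against
them.

``starred`` records whether the published table flagged the budget as a
significant source/sink; ``pct_diff_printed`` is the printed percent
difference column, which is not reproducible from the printed loads by any
simple formula and is retained for reference only.
"""

from __future__ import annotations

import pandas as pd

from glacierlake.budget import BudgetComponent

__all__ = ["hazen_budget_table", "hazen_components", "HAZEN_CONSTANTS"]

#: Survey constants for the reference watershed.
HAZEN_CONSTANTS = {
    "watershed_km2": 7516.0,
    "glacierized_fraction": 0.409,
    "lake_km2": 544.0,
    "lake_max_depth_m": 267.0,
    "snowpack_so4_mgL": 1.82,      # mean snowpack sulfate
    "snowmelt_so4_mgL": 14.9,      # mean snowmelt-stream sulfate
    "glacial_runoff_km3": {2015: 0.979, 2016: 0.291},
    "tfe_detection_limit_ugL": 7.0,
    "tfe_deep_summer_ugL": 495.0,
    "secchi_depths_m": {"spring_pre_melt": 27.0, "summer_centre": 16.0},
}

# columns: species, year, compartment, load, se
# loads in metric tons/yr except the water rows (km³/yr); se as printed.
_ROWS = [
    # water (km³)
    ("water", 2015, "snow_on_lake", 0.069, 0.015),
    ("water", 2015, "snow_from_land", 0.055, 0.012),
    ("water", 2015, "glacial_rivers", 0.948, 0.0),
    ("water", 2015, "total_inputs", 1.07, 0.027),
    ("water", 2015, "outflow", 1.07, 0.027),
    ("water", 2016, "snow_on_lake", 0.060, 0.008),
    ("water", 2016, "snow_from_land", 0.059, 0.089),
    ("water", 2016, "glacial_rivers", 0.281, 0.0),
    ("water", 2016, "total_inputs", 0.400, 0.097),
    ("water", 2016, "outflow", 0.400, 0.097),
    # NH4
    ("NH4", 2015, "snow_on_lake", 0.584, 0.115),
    ("NH4", 2015, "snow_from_land", 1.67, 0.454),
    ("NH4", 2015, "glacial_rivers", 22.9, 15.9),
    ("NH4", 2015, "total_inputs", 25.2, 16.5),
    ("NH4", 2015, "outflow", 3.79, 1.38),
    ("NH4", 2016, "snow_on_lake", 0.551, 0.092),
    ("NH4", 2016, "snow_from_land", 1.48, 0.371),
    ("NH4", 2016, "glacial_rivers", 5.42, 2.15),
    ("NH4", 2016, "total_inputs", 7.45, 2.61),
    ("NH4", 2016, "outflow", 1.13, 0.411),
    # NO3NO2
    ("NO3NO2", 2015, "snow_on_lake", 2.81, 0.611),
    ("NO3NO2", 2015, "snow_from_land", 5.63, 1.89),
    ("NO3NO2", 2015, "glacial_rivers", 35.1, 4.84),
    ("NO3NO2", 2015, "total_inputs", 43.6, 7.34),
    ("NO3NO2", 2015, "outflow", 12.0, 7.59),
    ("NO3NO2", 2016, "snow_on_lake", 2.22, 0.361),
    ("NO3NO2", 2016, "snow_from_land", 4.98, 1.59),
    ("NO3NO2", 2016, "glacial_rivers", 12.0, 1.34),
    ("NO3NO2", 2016, "total_inputs", 19.2, 3.29),
    ("NO3NO2", 2016, "outflow", 3.57, 2.26),
    # SO4
    ("SO4", 2015, "snow_on_lake", 73.0, 0.01),
    ("SO4", 2015, "snow_from_land", 993.0, 235.0),
    ("SO4", 2015, "glacial_rivers", 13400.0, 2420.0),
    ("SO4", 2015, "total_inputs", 14420.0, 2661.0),
    ("SO4", 2015, "outflow", 9400.0, 1440.0),
    ("SO4", 2016, "snow_on_lake", 77.8, 0.01),
    ("SO4", 2016, "snow_from_land", 879.0, 188.0),
    ("SO4", 2016, "glacial_rivers", 3580.0, 411.0),
    ("SO4", 2016, "total_inputs", 4540.0, 599.0),
    ("SO4", 2016, "outflow", 2790.0, 428.0),
    # dSiO2
    ("dSiO2", 2015, "snow_on_lake", 5.88, 0.001),
    ("dSiO2", 2015, "snow_from_land", 16.0, 3.21),
    ("dSiO2", 2015, "glacial_rivers", 181.0, 59.2),
    ("dSiO2", 2015, "total_inputs", 203.0, 62.4),
    ("dSiO2", 2015, "outflow", 246.0, 75.8),
    ("dSiO2", 2016, "snow_on_lake", 5.09, 0.001),
    ("dSiO2", 2016, "snow_from_land", 14.2, 2.44),
    ("dSiO2", 2016, "glacial_rivers", 56.9, 11.0),
    ("dSiO2", 2016, "total_inputs", 76.2, 13.5),
    ("dSiO2", 2016, "outflow", 73.2, 22.5),
    # DIC
    ("DIC", 2015, "snow_on_lake", 139.0, 0.028),
    ("DIC", 2015, "snow_from_land", 102.0, 21.0),
    ("DIC", 2015, "glacial_rivers", 6310.0, 474.0),
    ("DIC", 2015, "total_inputs", 6550.0, 495.0),
    ("DIC", 2015, "outflow", 9700.0, 2470.0),
    ("DIC", 2016, "snow_on_lake", 117.0, 0.019),
    ("DIC", 2016, "snow_from_land", 88.0, 15.4),
    ("DIC", 2016, "glacial_rivers", 1920.0, 117.0),
    ("DIC", 2016, "total_inputs", 2120.0, 132.0),
    ("DIC", 2016, "outflow", 2880.0, 735.0),
    # DOC
    ("DOC", 2015, "snow_on_lake", 6.92, 0.002),
    ("DOC", 2015, "snow_from_land", 0.087, 0.023),
    ("DOC", 2015, "glacial_rivers", 364.0, 59.6),
    ("DOC", 2015, "total_inputs", 371.0, 59.6),
    ("DOC", 2015, "outflow", 203.0, 55.9),
    ("DOC", 2016, "snow_on_lake", 13.3, 0.003),
    ("DOC", 2016, "snow_from_land", 0.077, 0.018),
    ("DOC", 2016, "glacial_rivers", 109.0, 14.5),
    ("DOC", 2016, "total_inputs", 123.0, 14.6),
    ("DOC", 2016, "outflow", 60.6, 16.6),
]

#: (species, year) -> (starred significant?, printed percent difference)
_FLAGS = {
    ("NH4", 2015): (True, -71.1), ("NH4", 2016): (True, -63.6),
    ("NO3NO2", 2015): (True, -33.7), ("NO3NO2", 2016): (True, -40.4),
    ("SO4", 2015): (False, -15.5), ("SO4", 2016): (False, -6.66),
    ("dSiO2", 2015): (False, 15.4), ("dSiO2", 2016): (False, 15.5),
    ("DIC", 2015): (True, 24.9), ("DIC", 2016): (True, 31.7),
    ("DOC", 2015): (True, -23.7), ("DOC", 2016): (False, -17.6),
}

DISSOLVED_SPECIES = ("NH4", "NO3NO2", "SO4", "dSiO2", "DIC", "DOC")


def hazen_budget_table() -> pd.DataFrame:
    """The published budget table as a tidy DataFrame.

    Columns: species, year, compartment, load, se, starred, pct_diff_printed.
    The water rows are km³/yr; everything else metric tons/yr.
    """
    df = pd.DataFrame(_ROWS, columns=["species", "year", "compartment", "load", "se"])
    df["starred"] = [
        _FLAGS.get((s, y), (False, float("nan")))[0]
        for s, y in zip(df["species"], df["year"])
    ]
    df["pct_diff_printed"] = [
        _FLAGS.get((s, y), (False, float("nan")))[1]
        for s, y in zip(df["species"], df["year"])
    ]
    return df


def hazen_components(species: str, year: int):
    """Input components and outflow for one species x year as budget objects.

    Returns ``(inputs, outflow)`` ready for :func:`glacierlake.budget.assemble_budget`.
    """
    df = hazen_budget_table()
    sel = df[(df.species == species) & (df.year == year)].set_index("compartment")
    inputs = [
        BudgetComponent(comp, species, year, float(sel.at[comp, "load"]),
                        float(sel.at[comp, "se"]))
        for comp in ("snow_on_lake", "snow_from_land", "glacial_rivers")
    ]
    outflow = BudgetComponent("outflow", species, year,
                              float(sel.at["outflow", "load"]),
                              float(sel.at["outflow", "se"]))
    return inputs, outflow
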