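"""Sediment O2 microprofile diagenesis: porosity, diffusivity, inverse model.

A steady-state oxygen microprofile below the sediment-water interface (SWI)
obeys the diffusion-reaction balance

    d/dz ( phi * Ds * dC/dz ) = R(z)

with R(z) >= 0 the volumetric net consumption rate (nmol/cm³/s; note that
1 µmol/L is numerically 1 nmol/cm³). The inverse model fits a
piecewise-constant R over a small number of equal-thickness zones: because
the forward solution is linear in the zone rates, fitting is linear least
squares, and the number of zones is reduced stepwise with an F-test until
the simpler model is significantly worse. This mirrors the classical
numerical procedure used for microprofile interpretation, except that zone
boundaries stay at fixed equal partitions rather than being optimized.

Porosity comes from 1-cm core sections weighed wet and freeze-dried
(all voids water-filled, density 1 g/cm³), and the sediment diffusivity
from the tortuosity correction Ds = D0 / (1 + 3 (1 - phi)).

Boundary conditions: either measured top and bottom concentrations
("conc-conc"), or zero concentration and zero flux at the bottom of the
profile ("bottomzero") for cores in which O2 is fully consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "SedimentSection", "MicroProfile", "ZoneModel",
    "porosity", "o2_free_diffusivity", "sediment_diffusivity",
    "solve_steady_profile", "fit_fixed_zones", "fit_consumption_zones",
    "depth_integrated_rate",
    "SECTION_VOLUME_CM3",
]

#: Core tube inner diameter (cm) and the volume of a 1-cm slice.
TUBE_INNER_DIAMETER_CM = 8.6
SECTION_VOLUME_CM3 = np.pi * (TUBE_INNER_DIAMETER_CM / 2.0) ** 2 * 1.0  # 58.088...

#: Free-solution diffusion coefficient of O2 in water, cm²/s, by temperature.
#: Compiled from standard microsensor reference tabulations; linear
#: interpolation between entries.
_D0_TEMPS_C = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0])
_D0_CM2S = np.array([1.12e-5, 1.30e-5, 1.49e-5, 1.70e-5, 1.92e-5, 2.16e-5])


def o2_free_diffusivity(temperature_C: float) -> float:
    """D0 of O2 in water at the given temperature, cm²/s (table interpolation)."""
    if not -2.0 <= temperature_C <= 30.0:
        raise ValueError("temperature outside tabulated range")
    return float(np.interp(temperature_C, _D0_TEMPS_C, _D0_CM2S))


@dataclass(frozen=True)
class SedimentSection:
    """A 1-cm core slice weighed wet and after freeze-drying."""

    core: str
    top_cm: float
    bottom_cm: float
    wet_g: float
    dry_g: float

    def __post_init__(self) -> None:
        if self.dry_g > self.wet_g:
            raise ValueError("dry weight exceeds wet weight")
        if self.bottom_cm <= self.top_cm:
            raise ValueError("section interval must have positive thickness")


def porosity(section: SedimentSection,
             section_volume_cm3: float = SECTION_VOLUME_CM3) -> float:
    """Porosity of a section: water-filled void volume over total volume.

    Water lost on freeze-drying (wet - dry, at 1 g/cm³) is the void volume.
    Values outside [0, 1] are clipped with a warning-worthy tolerance.
    """
    thickness = section.bottom_cm - section.top_cm
    vol = section_volume_cm3 * thickness
    phi = (section.wet_g - section.dry_g) / 1.0 / vol
    return float(min(max(phi, 0.0), 1.0))


def sediment_diffusivity(d0: float, phi: float) -> float:
    """Tortuosity-corrected diffusivity Ds = D0 / (1 + 3 (1 - phi))."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("porosity must be within [0, 1]")
    if d0 <= 0:
        raise ValueError("D0 must be > 0")
    return d0 / (1.0 + 3.0 * (1.0 - phi))


@dataclass
class MicroProfile:
    """An O2 microprofile with the physical properties needed for inversion.

    Depths are mm below the SWI (negative above; the profile typically
    starts 10-20 mm up in the bottom water). ``phi`` may be a scalar or an
    array of per-interval porosities for ``phi_intervals`` = (top_cm,
    bottom_cm) pairs.
    """

    core: str
    z_mm: np.ndarray
    c_umolL: np.ndarray
    temperature_C: float = 3.76
    phi: float | np.ndarray = 0.9
    phi_intervals: np.ndarray | None = None
    d0: float | None = None

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.c_umolL = np.asarray(self.c_umolL, dtype=float)
        if np.any(np.diff(self.z_mm) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        if np.any(self.c_umolL < -1e-9):
            raise ValueError("O2 concentrations must be >= 0")
        if self.d0 is None:
            self.d0 = o2_free_diffusivity(self.temperature_C)

    def phi_at(self, z_cm: np.ndarray) -> np.ndarray:
        """Porosity at sediment depths (cm); constant extrapolation at ends."""
        if np.isscalar(self.phi) or np.ndim(self.phi) == 0:
            return np.full_like(np.asarray(z_cm, dtype=float), float(self.phi))
        phis = np.asarray(self.phi, dtype=float)
        ints = np.asarray(self.phi_intervals, dtype=float)
        mids = ints.mean(axis=1)
        return np.interp(np.asarray(z_cm, dtype=float), mids, phis)

    def w_at(self, z_cm: np.ndarray) -> np.ndarray:
        """phi * Ds at sediment depths (cm), cm²/s."""
        phi = self.phi_at(z_cm)
        ds = np.array([sediment_diffusivity(self.d0, p) for p in np.atleast_1d(phi)])
        return phi * ds


@dataclass
class ZoneModel:
    """Piecewise-constant consumption zones fitted to a microprofile."""

    core: str
    boundaries_mm: np.ndarray          # k+1 breakpoints, SWI to bottom
    rates: np.ndarray                  # nmol/cm³/s, positive = consumption
    rate_se: np.ndarray
    grid_z_mm: np.ndarray = field(repr=False, default=None)
    grid_c: np.ndarray = field(repr=False, default=None)
    fitted_c: np.ndarray = field(repr=False, default=None)
    sse: float = np.nan
    n_obs: int = 0
    f_tests: list = field(default_factory=list)
    bc: str = "bottomzero"
    swi_flux: float = np.nan           # downward flux into sediment, nmol/cm²/s
    bottom_flux: float = np.nan

    @property
    def n_zones(self) -> int:
        return len(self.rates)

    @property
    def integrated_rate(self) -> float:
        """Depth-integrated consumption, nmol/cm²/s (sum R_i x thickness_i)."""
        thick_cm = np.diff(self.boundaries_mm) / 10.0
        return float(np.sum(self.rates * thick_cm))


def _zone_cumulative(z: np.ndarray, boundaries: np.ndarray,
                     rates: np.ndarray) -> np.ndarray:
    """Exact cumulative integral of piecewise-constant R from 0 to each z (cm)."""
    F = np.zeros_like(z)
    for (lo, hi), r in zip(zip(boundaries[:-1], boundaries[1:]), rates):
        F += r * np.clip(np.minimum(z, hi) - lo, 0.0, None)
    return F


def solve_steady_profile(z_cm: np.ndarray, w: np.ndarray,
                         boundaries_cm: np.ndarray, rates: np.ndarray,
                         bc: str = "bottomzero",
                         c_top: float | None = None,
                         c_bottom: float | None = None,
                         ) -> tuple[np.ndarray, float, float]:
    """Steady-state O2 profile for piecewise-constant consumption.

    Integrates d/dz(w dC/dz) = R twice:

        w C'(z) = J0 + F(z),   F(z) = int_0^z R,
        C(z) = C(0) + J0 H(z) + G(z),
        H = int dz/w,  G = int F/w dz,

    with J0 = w C'(0) the (signed) diffusive flux at the SWI. For
    ``bc="bottomzero"`` (O2 fully consumed) C(L) = 0 and w C'(L) = 0 fix
    J0 = -F(L) and C(0); for ``bc="conc-conc"`` the measured end
    concentrations fix C(0) and J0.

    Returns ``(C, flux_top, flux_bottom)`` with fluxes positive downward
    into the sediment (so ``flux_top - flux_bottom`` equals the
    depth-integrated consumption).
    """
    z = np.asarray(z_cm, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), z.shape)
    if np.any(w <= 0):
        raise ValueError("phi*Ds must be > 0 everywhere")
    F = _zone_cumulative(z, np.asarray(boundaries_cm, float), np.asarray(rates, float))
    inv_w = 1.0 / w
    H = cumulative_trapezoid(inv_w, z, initial=0.0)
    G = cumulative_trapezoid(F * inv_w, z, initial=0.0)
    FL, HL, GL = F[-1], H[-1], G[-1]
    if bc == "bottomzero":
        J0 = -FL
        C0 = FL * HL - GL
    elif bc == "conc-conc":
        if c_top is None or c_bottom is None:
            raise ValueError("conc-conc boundary conditions need c_top and c_bottom")
        C0 = float(c_top)
        if HL <= 0:
            raise ValueError("degenerate grid for conc-conc boundary conditions")
        J0 = (float(c_bottom) - C0 - GL) / HL
    else:
        raise ValueError("bc must be 'bottomzero' or 'conc-conc'")
    C = C0 + J0 * H + G
    flux_top = -J0                    # downward positive
    flux_bottom = -(J0 + FL)
    return C, float(flux_top), float(flux_bottom)


def fit_fixed_zones(profile: MicroProfile, n_zones: int, bc: str = "bottomzero",
                    grid_per_mm: int = 10) -> ZoneModel:
    """Linear least-squares zone rates for a fixed zone count."""
    below = profile.z_mm >= 0.0
    z_obs_mm = profile.z_mm[below]
    c_obs = profile.c_umolL[below]
    if len(z_obs_mm) < 10:
        raise ValueError("need at least 10 measurements below the SWI")
    L_mm = float(z_obs_mm.max())
    # solver grid: fine, includes zone boundaries by construction
    n_nodes = max(int(round(L_mm * grid_per_mm)), 50 * n_zones)
    n_nodes = n_nodes - n_nodes % n_zones + n_zones   # boundaries on nodes
    grid_mm = np.linspace(0.0, L_mm, n_nodes + 1)
    z_cm = grid_mm / 10.0
    w = profile.w_at(z_cm)
    boundaries_cm = np.linspace(0.0, L_mm / 10.0, n_zones + 1)

    if bc == "conc-conc":
        c_top = float(np.interp(0.0, z_obs_mm, c_obs))
        c_bot = float(np.interp(L_mm, z_obs_mm, c_obs))
        hom, *_ = solve_steady_profile(z_cm, w, boundaries_cm,
                                       np.zeros(n_zones), bc=bc,
                                       c_top=c_top, c_bottom=c_bot)
    else:
        c_top = c_bot = None
        hom = np.zeros_like(z_cm)

    # unit-rate responses per zone, homogeneous boundary values
    cols = []
    for j in range(n_zones):
        unit = np.zeros(n_zones)
        unit[j] = 1.0
        cj, *_ = solve_steady_profile(
            z_cm, w, boundaries_cm, unit, bc=bc,
            c_top=0.0 if bc == "conc-conc" else None,
            c_bottom=0.0 if bc == "conc-conc" else None)
        cols.append(np.interp(z_obs_mm, grid_mm, cj))
    A = np.column_stack(cols)
    b = c_obs - np.interp(z_obs_mm, grid_mm, hom)
    rates, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ rates
    sse = float(resid @ resid)
    dof = len(b) - n_zones
    s2 = sse / dof if dof > 0 else np.nan
    try:
        cov = s2 * np.linalg.inv(A.T @ A)
        rate_se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular zone design for {n_zones} zones: {exc}") from exc

    grid_c, flux_top, flux_bottom = solve_steady_profile(
        z_cm, w, boundaries_cm, rates, bc=bc, c_top=c_top, c_bottom=c_bot)
    fitted = np.interp(z_obs_mm, grid_mm, grid_c)
    return ZoneModel(core=profile.core, boundaries_mm=boundaries_cm * 10.0,
                     rates=rates, rate_se=rate_se, grid_z_mm=grid_mm,
                     grid_c=grid_c, fitted_c=fitted, sse=sse, n_obs=len(b),
                     bc=bc, swi_flux=flux_top, bottom_flux=flux_bottom)


def fit_consumption_zones(profile: MicroProfile, max_zones: int = 4,
                          alpha: float = 0.05,
                          bc: str = "bottomzero") -> ZoneModel:
    """Fit zone rates, then reduce the zone count while statistically safe.

    Starting from ``max_zones`` equal-thickness zones, the model with one
    zone fewer is accepted whenever the nested F-test comparing the two
    sums of squared errors is non-significant at ``alpha`` (i.e. the extra
    zone does not buy a significantly better fit). Negative fitted rates
    (net production) are allowed but should be treated as diagnostic.
    """
    if max_zones < 1:
        raise ValueError("max_zones must be >= 1")
    fits = {k: fit_fixed_zones(profile, k, bc) for k in range(1, max_zones + 1)}
    current = fits[max_zones]
    # SSE floor at solver-discretization level: a reduced model fitting this
    # well is "perfect" and the F-statistic would only compare round-off
    c_scale = float(np.max(np.abs(profile.c_umolL))) or 1.0
    floor = fits[max_zones].n_obs * (1e-4 * c_scale) ** 2
    f_tests = []
    for k in range(max_zones, 1, -1):
        full, reduced = fits[k], fits[k - 1]
        df_num = full.n_zones - reduced.n_zones
        df_den = full.n_obs - full.n_zones
        if reduced.sse <= floor or reduced.sse <= full.sse:
            accept, f_stat, p_val = True, 0.0, 1.0
        elif full.sse <= 0:
            accept, f_stat, p_val = False, np.inf, 0.0
        else:
            f_stat = ((reduced.sse - full.sse) / df_num) / (full.sse / df_den)
            p_val = float(stats.f.sf(f_stat, df_num, df_den))
            accept = p_val > alpha
        f_tests.append({"zones_full": k, "zones_reduced": k - 1,
                        "F": float(f_stat), "p": float(p_val), "accepted": bool(accept)})
        if not accept:
            current = fits[k]
            break
        current = fits[k - 1]
    current.f_tests = f_tests
    return current


def depth_integrated_rate(model: ZoneModel) -> float:
    """Depth-integrated O2 consumption, nmol/cm²/s.

    At steady state this equals the net diffusive supply
    ``swi_flux - bottom_flux`` (and the SWI flux itself when the bottom
    flux is zero).
    """
    return model.integrated_rate
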