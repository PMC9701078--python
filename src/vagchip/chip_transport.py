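"""Oxygen transport in a two-channel organ chip.

The chip is a PDMS device with two parallel channels separated by a porous
membrane: a stratified vaginal epithelium grows on top of the membrane in the
apical channel and a fibroblast stroma hangs below it in the basal channel.
Oxygen-saturated medium is perfused through both channels while the
incubator-side PDMS faces stay in equilibrium with ambient pO2; the tissue
layers consume oxygen with Michaelis-Menten kinetics, so a hypoxic gradient
develops over the epithelial lumen.

This module solves the 2D (length x vertical stack) advection-diffusion-
reaction problem with a cell-centered finite-volume scheme:

    d c/dt = div(D grad c) - u dc/dx - Vmax c/(Km + c)   [tissue only]

* flow is the fully developed plane-Poiseuille profile over each open channel
  gap (Re << 1 at 40 uL/h, so the Navier-Stokes solution reduces to it),
* face diffusivities are harmonic means across material interfaces,
* advection is first-order upwind,
* the Michaelis-Menten sink is Picard-linearized (steady) or lagged one step
  (backward-Euler transient).

Units are SI internally (m, s, mol/m^3); constructors accept the bench units
used in the lab (mm, um, uL/h, mmHg).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

logger = logging.getLogger(__name__)

__all__ = [
    "ChipGeometry",
    "TransportParams",
    "DomainGrid",
    "ConcentrationField",
    "CalibrationResult",
    "MATERIALS",
    "DEFAULT_VMAX_EPI",
    "henry_concentration",
    "pO2_of",
    "oxygen_percent",
    "mean_velocity",
    "poiseuille_profile",
    "build_grid",
    "build_column_grid",
    "mm_sink",
    "solve_steady",
    "solve_transient",
    "probe",
    "probe_labels",
    "calibrate_uptake",
    "field_to_dataframe",
]

#: vertical stack order, bottom -> top
MATERIALS = (
    "basal_pdms",
    "basal_medium",
    "stroma",
    "membrane",
    "epithelium",
    "apical_medium",
    "apical_pdms",
)

MEDIUM_MATERIALS = frozenset({"apical_medium", "basal_medium"})
TISSUE_MATERIALS = frozenset({"epithelium", "stroma"})

#: Maximal volumetric epithelial O2 uptake (mol m^-3 s^-1). Calibrated once
#: (bisection on the steady model, nx=200 ny=120, default geometry/transport)
#: so that the epithelium apical surface at mid-length sits at 0.11 mol/m^3,
#: the lumen oxygen level this chip is designed to reproduce.
DEFAULT_VMAX_EPI = 2.642059e-03

MMHG_PER_ATM = 760.0


# --------------------------------------------------------------------------
# unit bridges
# --------------------------------------------------------------------------

def henry_concentration(pO2_mmHg: float, henry_k: float) -> float:
    """Dissolved O2 concentration (mol/m^3) in equilibrium with a partial
    pressure, via Henry's law ``c = k * pO2``.

    ``henry_k`` is the solubility in mol m^-3 mmHg^-1.
    """
    if pO2_mmHg < 0:
        raise ValueError(f"partial pressure must be >= 0, got {pO2_mmHg}")
    if henry_k <= 0:
        raise ValueError(f"Henry solubility must be > 0, got {henry_k}")
    return pO2_mmHg * henry_k


def pO2_of(conc: float, henry_k: float) -> float:
    """Inverse of :func:`henry_concentration`: partial pressure (mmHg)."""
    if henry_k <= 0:
        raise ValueError(f"Henry solubility must be > 0, got {henry_k}")
    return conc / henry_k


def oxygen_percent(conc: float, henry_k: float) -> float:
    """Express a dissolved O2 concentration as percent of one standard
    atmosphere (760 mmHg), the convention used for incubator gas mixes."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return 100.0 * (conc / henry_k) / MMHG_PER_ATM


def mean_velocity(Q_uL_per_h: float, width_mm: float, height_mm: float) -> float:
    """Cross-section mean velocity (m/s) for a volumetric flow in uL/h through
    a rectangular section given in mm."""
    if Q_uL_per_h < 0:
        raise ValueError(f"flow rate must be >= 0, got {Q_uL_per_h}")
    if width_mm <= 0 or height_mm <= 0:
        raise ValueError("channel width and height must be > 0")
    q_m3_s = Q_uL_per_h * 1e-9 / 3600.0
    area_m2 = width_mm * 1e-3 * height_mm * 1e-3
    return q_m3_s / area_m2


def mm_sink(c: float | np.ndarray, Vmax: float, Km: float) -> float | np.ndarray:
    """Michaelis-Menten consumption rate ``Vmax * c / (Km + c)``.

    Monotone non-decreasing in ``c`` and bounded above by ``Vmax``.
    """
    if Km <= 0:
        raise ValueError(f"Km must be > 0, got {Km}")
    if np.any(np.asarray(c) < 0):
        raise ValueError("concentration must be >= 0")
    return Vmax * c / (Km + c)


# --------------------------------------------------------------------------
# geometry and parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChipGeometry:
    """Dimensions of the two-channel chip (commercial organ-chip layout).

    The apical channel is 1 mm high with an 80 um epithelium on the membrane;
    the basal channel is 0.2 mm high with a 50 um stroma hanging from the
    membrane's lower face. PDMS blocks close the device above and below.
    """

    length_mm: float = 16.7
    apical_channel_height_mm: float = 1.0
    apical_channel_width_mm: float = 1.0
    basal_channel_height_mm: float = 0.2
    basal_channel_width_mm: float = 1.0
    membrane_thickness_um: float = 50.0
    epithelium_thickness_um: float = 80.0
    stroma_thickness_um: float = 50.0
    apical_pdms_thickness_mm: float = 3.5
    basal_pdms_thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.epithelium_thickness_um * 1e-3 >= self.apical_channel_height_mm:
            raise ValueError("epithelium must be thinner than the apical channel")
        if self.stroma_thickness_um * 1e-3 >= self.basal_channel_height_mm:
            raise ValueError("stroma must be thinner than the basal channel")

    @property
    def bands_mm(self) -> list[tuple[str, float]]:
        """(material, thickness_mm) bottom -> top."""
        return [
            ("basal_pdms", self.basal_pdms_thickness_mm),
            ("basal_medium",
             self.basal_channel_height_mm - self.stroma_thickness_um * 1e-3),
            ("stroma", self.stroma_thickness_um * 1e-3),
            ("membrane", self.membrane_thickness_um * 1e-3),
            ("epithelium", self.epithelium_thickness_um * 1e-3),
            ("apical_medium",
             self.apical_channel_height_mm - self.epithelium_thickness_um * 1e-3),
            ("apical_pdms", self.apical_pdms_thickness_mm),
        ]

    @property
    def total_height_mm(self) -> float:
        return sum(t for _, t in self.bands_mm)


@dataclass(frozen=True)
class TransportParams:
    """Transport and uptake parameters.

    Diffusivities are literature-sourced defaults for 37 C (m^2/s); the
    membrane is modeled as PDMS with a porosity-weighted effective
    diffusivity. ``Vmax_epi`` defaults to the shipped calibrated value
    (:data:`DEFAULT_VMAX_EPI`); ``Vmax_stroma`` defaults to the same value.
    """

    D_medium: float = 3.0e-9
    D_pdms: float = 3.4e-9
    D_epithelium: float = 1.5e-9
    D_stroma: float = 1.5e-9
    membrane_porosity: float = 0.05
    D_membrane_effective: float | None = None
    Vmax_epi: float = DEFAULT_VMAX_EPI
    Vmax_stroma: float | None = None
    Km: float = 1.0e-3
    Q_apical_uL_per_h: float = 40.0
    Q_basal_uL_per_h: float = 40.0
    pO2_ambient_mmHg: float = 145.0
    temperature_C: float = 37.0
    henry_k: float = 1.3e-3

    def __post_init__(self) -> None:
        for name in ("D_medium", "D_pdms", "D_epithelium", "D_stroma",
                     "Km", "henry_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Vmax_epi < 0:
            raise ValueError("Vmax_epi must be >= 0")
        if self.Vmax_stroma is not None and self.Vmax_stroma < 0:
            raise ValueError("Vmax_stroma must be >= 0")
        if not (0.0 <= self.membrane_porosity <= 1.0):
            raise ValueError("membrane_porosity must be in [0, 1]")
        if self.Q_apical_uL_per_h < 0 or self.Q_basal_uL_per_h < 0:
            raise ValueError("flow rates must be >= 0")

    @property
    def D_membrane(self) -> float:
        if self.D_membrane_effective is not None:
            return self.D_membrane_effective
        phi = self.membrane_porosity
        return phi * self.D_medium + (1.0 - phi) * self.D_pdms

    @property
    def vmax_stroma(self) -> float:
        return self.Vmax_epi if self.Vmax_stroma is None else self.Vmax_stroma

    @property
    def c_sat(self) -> float:
        """Saturation concentration at ambient pO2 (mol/m^3)."""
        return henry_concentration(self.pO2_ambient_mmHg, self.henry_k)

    def diffusivity_of(self, material: str) -> float:
        return {
            "apical_pdms": self.D_pdms,
            "basal_pdms": self.D_pdms,
            "apical_medium": self.D_medium,
            "basal_medium": self.D_medium,
            "epithelium": self.D_epithelium,
            "stroma": self.D_stroma,
            "membrane": self.D_membrane,
        }[material]

    def vmax_of(self, material: str) -> float:
        if material == "epithelium":
            return self.Vmax_epi
        if material == "stroma":
            return self.vmax_stroma
        return 0.0


# --------------------------------------------------------------------------
# grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainGrid:
    """Structured cell-centered grid.

    Material bands are horizontal, so each row has a single material; per-cell
    labels are the row label broadcast along x. ``dirichlet_top``/``bottom``
    flag saturation boundaries on the outer PDMS faces (disabled for 1D
    verification columns).
    """

    nx: int
    ny: int
    dx: float                       # m, uniform
    dy: np.ndarray                  # m, per row, bottom -> top
    row_material: tuple[str, ...]   # per row
    u: np.ndarray                   # m/s, x-velocity per row
    length_m: float
    dirichlet_top: bool = True
    dirichlet_bottom: bool = True

    def __post_init__(self) -> None:
        if len(self.row_material) != self.ny or len(self.dy) != self.ny:
            raise ValueError("row arrays must have length ny")
        if np.any((np.asarray(self.u) != 0)
                  & ~np.isin(self.row_material, list(MEDIUM_MATERIALS))):
            raise ValueError("velocity must be zero outside medium rows")

    @property
    def y_faces(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.dy)])

    @property
    def y_centers(self) -> np.ndarray:
        f = self.y_faces
        return 0.5 * (f[:-1] + f[1:])

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def materials(self) -> np.ndarray:
        """(ny, nx) per-cell material labels."""
        return np.repeat(np.array(self.row_material)[:, None], self.nx, axis=1)

    def rows_of(self, material: str) -> np.ndarray:
        return np.flatnonzero(np.array(self.row_material) == material)

    def band_face_y(self, material: str, face: str) -> float:
        """y (m) of the bottom/top face of a material band."""
        rows = self.rows_of(material)
        if rows.size == 0:
            raise ValueError(f"grid has no '{material}' band")
        yf = self.y_faces
        return yf[rows[0]] if face == "bottom" else yf[rows[-1] + 1]


def poiseuille_profile(grid_or_heights, channel: str, Q_uL_per_h: float,
                       width_mm: float = 1.0,
                       geometry: ChipGeometry | None = None) -> np.ndarray:
    """Plane-Poiseuille x-velocity per row for one channel's open gap.

    The parabolic profile ``u(y) = 6 u_bar (y/h)(1 - y/h)`` is sampled at cell
    centers over the open (medium) gap; ``u_bar`` is the mean velocity through
    that gap (flow rate divided by gap cross-section). Returns a full (ny,)
    array, zero outside the gap.
    """
    grid: DomainGrid = grid_or_heights
    medium = {"apical": "apical_medium", "basal": "basal_medium"}.get(channel)
    if medium is None:
        raise ValueError(f"channel must be 'apical' or 'basal', got {channel!r}")
    rows = grid.rows_of(medium)
    if rows.size == 0:
        raise ValueError(f"no open gap: tissue fills the {channel} channel")
    if geometry is not None:
        width_mm = (geometry.apical_channel_width_mm if channel == "apical"
                    else geometry.basal_channel_width_mm)
    y0 = grid.y_faces[rows[0]]
    h = grid.y_faces[rows[-1] + 1] - y0
    u_bar = mean_velocity(Q_uL_per_h, width_mm, h * 1e3)
    u = np.zeros(grid.ny)
    xi = (grid.y_centers[rows] - y0) / h
    u[rows] = 6.0 * u_bar * xi * (1.0 - xi)
    return u


def _allocate_rows(bands_mm: Sequence[tuple[str, float]], ny: int) -> list[int]:
    """Largest-remainder allocation of ny rows across bands, >= 1 per band."""
    total = sum(t for _, t in bands_mm)
    ideal = [ny * t / total for _, t in bands_mm]
    if min(ideal) < 0.5:
        worst = min(bands_mm, key=lambda b: b[1])
        need = math.ceil(0.5 * total / worst[1])
        raise ValueError(
            f"band '{worst[0]}' ({worst[1]:.3g} mm) is thinner than half a "
            f"cell at ny={ny}; use ny >= {need}")
    counts = [max(1, int(v)) for v in ideal]
    rem = sorted(range(len(ideal)), key=lambda i: ideal[i] - int(ideal[i]),
                 reverse=True)
    i = 0
    while sum(counts) < ny:
        counts[rem[i % len(rem)]] += 1
        i += 1
    while sum(counts) > ny:
        j = max(range(len(counts)), key=lambda m: counts[m] - ideal[m])
        if counts[j] <= 1:
            raise ValueError("ny too small for the band structure")
        counts[j] -= 1
    return counts


def build_grid(geometry: ChipGeometry, nx: int = 200, ny: int = 120,
               params: TransportParams | None = None) -> DomainGrid:
    """Discretize the chip cross-section (length x vertical stack).

    Rows are allocated to material bands proportionally to band thickness
    (at least one row per band); each band is internally uniform, so band
    heights match the geometry exactly. If ``params`` is given, Poiseuille
    velocities for both channels are installed.
    """
    if nx < 2:
        raise ValueError("nx must be >= 2")
    bands = geometry.bands_mm
    counts = _allocate_rows(bands, ny)
    dy: list[float] = []
    row_material: list[str] = []
    for (mat, t_mm), n in zip(bands, counts):
        dy.extend([t_mm * 1e-3 / n] * n)
        row_material.extend([mat] * n)
    grid = DomainGrid(
        nx=nx, ny=ny, dx=geometry.length_mm * 1e-3 / nx,
        dy=np.array(dy), row_material=tuple(row_material),
        u=np.zeros(ny), length_m=geometry.length_mm * 1e-3,
    )
    if params is not None:
        u = (poiseuille_profile(grid, "apical", params.Q_apical_uL_per_h,
                                geometry=geometry)
             + poiseuille_profile(grid, "basal", params.Q_basal_uL_per_h,
                                  geometry=geometry))
        grid = replace(grid, u=u)
    return grid


def build_column_grid(L_m: float, ny: int, material: str = "epithelium",
                      nx: int = 3) -> DomainGrid:
    """Single-material 1D verification column (no flow, Dirichlet top only).

    Used to check the solver against the closed-form diffusion-consumption
    slab solution.
    """
    return DomainGrid(
        nx=nx, ny=ny, dx=L_m / nx, dy=np.full(ny, L_m / ny),
        row_material=(material,) * ny, u=np.zeros(ny), length_m=L_m,
        dirichlet_top=True, dirichlet_bottom=False,
    )


# --------------------------------------------------------------------------
# finite-volume solver
# --------------------------------------------------------------------------

@dataclass
class ConcentrationField:
    """O2 concentration on a grid. ``time_s`` is None for steady solutions."""

    grid: DomainGrid
    values: np.ndarray              # (ny, nx), mol/m^3
    time_s: float | None = None
    diagnostics: dict = field(default_factory=dict)


class _System:
    """Assembled FV operator: A c = b + (transient/sink terms added later)."""

    def __init__(self, grid: DomainGrid, params: TransportParams):
        self.grid, self.params = grid, params
        nx, ny = grid.nx, grid.ny
        dx, dy = grid.dx, grid.dy
        c_sat = params.c_sat
        D = np.array([params.diffusivity_of(m) for m in grid.row_material])
        vmax = np.array([params.vmax_of(m) for m in grid.row_material])
        u = grid.u
        idx = np.arange(nx * ny).reshape(ny, nx)

        rows, cols, data = [], [], []
        b = np.zeros(nx * ny)

        def add(r, c, v):
            rows.append(np.asarray(r).ravel())
            cols.append(np.asarray(c).ravel())
            data.append(np.asarray(v).ravel())

        # x-direction faces (same material along a row)
        Gx = (D * dy / dx)[:, None] * np.ones((ny, nx - 1))
        F = u * dy                                   # advective flux per row
        Fx = F[:, None] * np.ones((ny, nx - 1))
        left, right = idx[:, :-1], idx[:, 1:]
        add(left, left, Gx + Fx)        # upwind: u >= 0 everywhere
        add(left, right, -Gx)
        add(right, right, Gx)
        add(right, left, -(Gx + Fx))

        # y-direction faces (harmonic-mean diffusivity across the interface)
        res = dy[:-1] / (2 * D[:-1]) + dy[1:] / (2 * D[1:])
        Gy = (dx / res)[:, None] * np.ones((ny - 1, nx))
        lo, hi = idx[:-1, :], idx[1:, :]
        add(lo, lo, Gy)
        add(lo, hi, -Gy)
        add(hi, hi, Gy)
        add(hi, lo, -Gy)

        self._boundary_links: list[tuple[np.ndarray, np.ndarray]] = []

        # top/bottom Dirichlet (incubator-equilibrated PDMS faces)
        if grid.dirichlet_top:
            g = D[-1] * dx / (dy[-1] / 2)
            cells = idx[-1, :]
            add(cells, cells, np.full(nx, g))
            b[cells] += g * c_sat
            self._boundary_links.append((cells, np.full(nx, g)))
        if grid.dirichlet_bottom:
            g = D[0] * dx / (dy[0] / 2)
            cells = idx[0, :]
            add(cells, cells, np.full(nx, g))
            b[cells] += g * c_sat
            self._boundary_links.append((cells, np.full(nx, g)))

        # inlets (x=0, flowing medium rows): saturated Dirichlet, advective +
        # diffusive; with Q=0 there is no inlet and the face is zero-flux
        medium = np.isin(grid.row_material, list(MEDIUM_MATERIALS))
        jin = np.flatnonzero(medium & (F > 0))
        if jin.size:
            g_in = D[jin] * dy[jin] / (dx / 2)
            cells = idx[jin, 0]
            add(cells, cells, g_in)
            b[cells] += (g_in + F[jin]) * c_sat
            self._boundary_links.append((cells, g_in))
            # outlets (x=L): advective outflow, zero diffusive flux
            out = idx[jin, -1]
            add(out, out, F[jin])

        self.A = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nx * ny, nx * ny))
        self.b = b
        self.vol = (dy[:, None] * dx * np.ones((ny, nx))).ravel()
        self.vmax_cell = (vmax[:, None] * np.ones((ny, nx))).ravel()
        self.F = F
        self.medium_rows = jin
        self.c_sat = c_sat
        self.idx = idx

    def sink_coeff(self, c_flat: np.ndarray) -> np.ndarray:
        """Picard-linearized sink: rate = coeff * c, coeff per unit volume."""
        return self.vmax_cell / (self.params.Km + np.maximum(c_flat, 0.0))

    def mass_balance(self, c_flat: np.ndarray) -> dict:
        """Steady O2 budget (per unit chip width, mol/s/m).

        Influx = advective inflow at the inlets + net diffusive influx through
        every saturation boundary (incubator faces and inlet faces); outflow is
        advective at the outlets; consumption is the Michaelis-Menten total.
        """
        jin = self.medium_rows
        adv_in = float(np.sum(self.F[jin]) * self.c_sat)
        adv_out = float(np.sum(self.F[jin] * c_flat[self.idx[jin, -1]]))
        diff_in = 0.0
        for cells, g in self._boundary_links:
            diff_in += float(np.sum(g * (self.c_sat - c_flat[cells])))
        consumption = float(np.sum(
            self.vol * mm_sink(np.maximum(c_flat, 0.0),
                               self.vmax_cell, self.params.Km)))
        influx = adv_in + diff_in
        residual = influx - adv_out - consumption
        return {
            "advective_in": adv_in, "diffusive_in": diff_in,
            "advective_out": adv_out, "consumption": consumption,
            "residual": residual,
            "relative_residual": abs(residual) / influx if influx > 0 else 0.0,
        }


def solve_steady(grid: DomainGrid, params: TransportParams,
                 tol: float = 1e-8, max_iter: int = 200) -> ConcentrationField:
    """Steady finite-volume solution with Picard iteration on the MM sink.

    Converges when the max concentration update falls below ``tol`` (mol/m^3).
    The mass-balance budget is attached to ``diagnostics``.
    """
    sys_ = _System(grid, params)
    c = np.full(grid.nx * grid.ny, sys_.c_sat)
    history = []
    for it in range(max_iter):
        A = sys_.A + sp.diags(sys_.sink_coeff(c) * sys_.vol)
        c_new = spla.spsolve(A.tocsc(), sys_.b)
        delta = float(np.max(np.abs(c_new - c)))
        history.append(delta)
        c = c_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"steady solver did not converge in {max_iter} Picard iterations; "
            f"residual history tail: {history[-5:]}")
    if np.min(c) < -tol:
        raise RuntimeError(f"negative concentration {np.min(c):.3e} (solver bug)")
    mb = sys_.mass_balance(c)
    logger.info("steady solve: %d Picard iterations, mass-balance residual "
                "%.3e (%.4f%% of influx)", it + 1, mb["residual"],
                100 * mb["relative_residual"])
    diag = {"picard_iterations": it + 1, "picard_history": history,
            "mass_balance": mb}
    return ConcentrationField(grid=grid, values=c.reshape(grid.ny, grid.nx),
                              time_s=None, diagnostics=diag)


def solve_transient(grid: DomainGrid, params: TransportParams,
                    t_end_min: float = 200.0, dt_s: float = 10.0,
                    n_frames: int = 21) -> list[ConcentrationField]:
    """Backward-Euler transient from uniform saturation (the chip starts in
    equilibrium with the incubator, then flow and consumption switch on).

    Returns ~``n_frames`` snapshots including t=0 and t_end. The MM sink is
    linearized about the previous step, which preserves positivity and the
    monotone relaxation toward steady state.
    """
    if dt_s <= 0:
        raise ValueError(f"dt_s must be > 0, got {dt_s}")
    sys_ = _System(grid, params)
    n_steps = int(round(t_end_min * 60.0 / dt_s))
    store_every = max(1, n_steps // max(1, n_frames - 1))
    c = np.full(grid.nx * grid.ny, sys_.c_sat)
    m = sys_.vol / dt_s
    frames = [ConcentrationField(grid=grid,
                                 values=c.reshape(grid.ny, grid.nx).copy(),
                                 time_s=0.0)]
    for step in range(1, n_steps + 1):
        A = sys_.A + sp.diags(m + sys_.sink_coeff(c) * sys_.vol)
        c = spla.spsolve(A.tocsc(), sys_.b + m * c)
        if step % store_every == 0 or step == n_steps:
            frames.append(ConcentrationField(
                grid=grid, values=c.reshape(grid.ny, grid.nx).copy(),
                time_s=step * dt_s))
    frames[-1].diagnostics["mass_balance"] = sys_.mass_balance(c)
    return frames


# --------------------------------------------------------------------------
# probes and calibration
# --------------------------------------------------------------------------

_PROBE_BASE = {
    "epithelium_apical_surface": ("epithelium", "top"),
    "epithelium_basal_surface": ("epithelium", "bottom"),
    "stroma_basal_surface": ("stroma", "bottom"),
    "membrane_top": ("membrane", "top"),
    "apical_channel_mid": ("apical_medium", "mid"),
    "basal_channel_mid": ("basal_medium", "mid"),
}


def probe_labels() -> list[str]:
    """Available probe labels (append ``_midlength`` or ``_mean`` to pick x)."""
    out = []
    for base in _PROBE_BASE:
        out.extend([base + "_midlength", base + "_mean"])
    return out


def _resolve_y(grid: DomainGrid, base: str) -> float:
    material, face = _PROBE_BASE[base]
    if face == "mid":
        return 0.5 * (grid.band_face_y(material, "bottom")
                      + grid.band_face_y(material, "top"))
    return grid.band_face_y(material, face)


def _interp(field: ConcentrationField, x: float, y: float) -> float:
    """Bilinear interpolation at (x, y) in meters, clamped at boundaries."""
    g = field.grid

    def axis_weights(centers: np.ndarray, p: float) -> tuple[int, int, float]:
        if p <= centers[0]:
            return 0, 0, 0.0
        if p >= centers[-1]:
            return len(centers) - 1, len(centers) - 1, 0.0
        k = int(np.searchsorted(centers, p)) - 1
        w = (p - centers[k]) / (centers[k + 1] - centers[k])
        return k, k + 1, w

    j0, j1, wy = axis_weights(g.y_centers, y)
    i0, i1, wx = axis_weights(g.x_centers, x)
    v = field.values
    return float((1 - wy) * ((1 - wx) * v[j0, i0] + wx * v[j0, i1])
                 + wy * ((1 - wx) * v[j1, i0] + wx * v[j1, i1]))


def probe(field: ConcentrationField, label: str,
          x_mm: float | None = None) -> float:
    """Concentration at a named location.

    Labels are ``<surface>_midlength`` (x = L/2), ``<surface>_mean``
    (average along the channel length), or a bare surface name with an
    explicit ``x_mm``. ``epithelium_apical_surface`` is the top face of the
    epithelium band.
    """
    base, mode = label, None
    for suffix in ("_midlength", "_mean"):
        if label.endswith(suffix):
            base, mode = label[: -len(suffix)], suffix
            break
    if base not in _PROBE_BASE:
        raise KeyError(
            f"unknown probe label {label!r}; available: {probe_labels()}")
    g = field.grid
    y = _resolve_y(g, base)
    if mode == "_mean":
        xs = g.x_centers
        return float(np.mean([_interp(field, x, y) for x in xs]))
    if mode == "_midlength":
        x = g.length_m / 2
    elif x_mm is not None:
        x = x_mm * 1e-3
    else:
        raise ValueError("bare probe labels need x_mm")
    return _interp(field, x, y)


@dataclass(frozen=True)
class CalibrationResult:
    Vmax_epi: float
    achieved: float
    target: float
    iterations: int
    history: tuple[tuple[float, float], ...]   # (Vmax, probe value)


def calibrate_uptake(grid: DomainGrid, params: TransportParams,
                     target_conc: float,
                     location: str = "epithelium_apical_surface_midlength",
                     bounds: tuple[float, float] = (0.0, 0.1),
                     stroma_ratio: float = 1.0,
                     rel_tol: float = 1e-3,
                     max_iter: int = 60) -> CalibrationResult:
    """Bisection on ``Vmax_epi`` (stroma scaled by ``stroma_ratio``) so the
    steady probe at ``location`` hits ``target_conc``.

    The probe is monotone decreasing in Vmax, so a sign change over ``bounds``
    brackets the root. Raises if the target is outside the achievable range.
    """
    if not (0.0 < target_conc < params.c_sat):
        raise ValueError(
            f"target must be in (0, saturation={params.c_sat:.4g}), "
            f"got {target_conc}")

    history: list[tuple[float, float]] = []

    def f(vmax: float) -> float:
        p = replace(params, Vmax_epi=vmax, Vmax_stroma=vmax * stroma_ratio)
        value = probe(solve_steady(grid, p), location)
        history.append((vmax, value))
        return value

    lo, hi = bounds
    f_lo, f_hi = f(lo), f(hi)
    if not (f_hi <= target_conc <= f_lo):
        raise ValueError(
            f"target {target_conc} unreachable in bounds {bounds}: achievable "
            f"probe range is [{f_hi:.4g}, {f_lo:.4g}]")
    for it in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val - target_conc) <= rel_tol * target_conc:
            return CalibrationResult(mid, val, target_conc, it + 1,
                                     tuple(history))
        if val > target_conc:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(0.5 * (lo + hi), history[-1][1], target_conc,
                             max_iter, tuple(history))


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

def field_to_dataframe(field: ConcentrationField) -> pd.DataFrame:
    """Long-form table (x_mm, y_mm, material, c_mol_per_m3)."""
    g = field.grid
    xs, ys = np.meshgrid(g.x_centers, g.y_centers)
    return pd.DataFrame({
        "x_mm": xs.ravel() * 1e3,
        "y_mm": ys.ravel() * 1e3,
        "material": g.materials.ravel(),
        "c_mol_per_m3": field.values.ravel(),
    })


def plot_field(field: ConcentrationField, path: str) -> None:
    """Save a heatmap of the concentration field (aspect-stretched)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = field.grid
    fig, ax = plt.subplots(figsize=(8, 4))
    m = ax.pcolormesh(g.x_centers * 1e3, g.y_centers * 1e3, field.values,
                      shading="nearest", cmap="viridis")
    fig.colorbar(m, ax=ax, label="O2 (mol/m3)")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
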