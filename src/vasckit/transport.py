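"""Reduced-order flow and solute transport in a channel-in-hydrogel construct.

The physical picture: culture medium is pumped through a cylindrical
vascular channel (radius R) embedded in a porous GelMA annulus (outer
radius R_out).  Flow in the channel obeys Stokes/Navier-Stokes; seepage in
the hydrogel obeys the Brinkman equation (Darcy drag ``mu_f/kappa`` plus an
effective viscous term).  At the creeping-flow regimes of perfusion culture
(Re << 1) the axial momentum balance is fully developed, so the velocity
reduces to a 1-D radial two-domain problem,

    channel (r < R):        mu_f (1/r) d/dr(r du/dr)              = -G
    matrix  (R < r < R_out): mu_e (1/r) d/dr(r du/dr) - mu_f/kappa u = -G

with symmetry at r = 0, no slip at R_out, and continuity of velocity and
viscous stress at the interface.  The axial pressure gradient G is scaled
so the channel carries the prescribed flow rate Q; wall shear stress is
``tau_w = mu_f |du/dr|`` at r = R.  With the high GelMA effective viscosity
the matrix is essentially stagnant and the channel solution collapses onto
Poiseuille flow, which serves as the closed-form oracle.

Solute transport (oxygen / nutrients, normalized to inlet concentration)
combines upwind axial advection inside the channel with Fickian diffusion,
using the free diffusivity D_s in the channel lumen and the
porosity-scaled effective diffusivity ``D_eff = eps * D_s`` in the matrix.
The reported readout is t*, the first time the volume-averaged matrix
concentration reaches a target fraction of the inlet value.

The Forchheimer inertial drag correction is deliberately omitted: at
Re << 1 its quadratic term is negligible and no inertial coefficient is
available for this hydrogel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

__all__ = [
    "PorousDomainParams",
    "ChannelGeometry",
    "FlowConditions",
    "FlowResult",
    "TransportResult",
    "solve_channel_flow",
    "sweep_flow_rates",
    "calibrate_radius",
    "solve_species_transport",
    "poiseuille_wall_shear",
    "UL_PER_MIN_TO_M3_PER_S",
]

UL_PER_MIN_TO_M3_PER_S = 1e-9 / 60.0


@dataclass
class PorousDomainParams:
    """GelMA porous-domain constants.

    Defaults are the modeling constants of the study this package
    reimplements: density 1150 kg/m³, water content 1058 kg/m³, Young's
    modulus 8 kPa, hydrogel dynamic viscosity 100 Pa·s, porosity 0.7,
    Darcy permeability 1e-7 m², oxygen diffusivity 3e-9 m²/s.
    """

    density: float = 1150.0  # kg/m^3
    water_content: float = 1058.0  # kg/m^3
    youngs_modulus: float = 8.0  # kPa
    dynamic_viscosity_matrix: float = 100.0  # Pa s (effective Brinkman viscosity)
    porosity: float = 0.7
    permeability: float = 1e-7  # m^2
    species_diffusivity: float = 3e-9  # m^2/s

    def __post_init__(self) -> None:
        for name in (
            "density",
            "water_content",
            "youngs_modulus",
            "dynamic_viscosity_matrix",
            "porosity",
            "permeability",
            "species_diffusivity",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.porosity < 1:
            raise ValueError("porosity must be < 1")

    @property
    def effective_diffusivity(self) -> float:
        """Porosity-scaled species diffusivity in the matrix, m²/s."""
        return self.porosity * self.species_diffusivity

    @classmethod
    def from_config(cls, cfg: dict) -> "PorousDomainParams":
        """Build from a flat config dict; missing keys keep defaults."""
        known = {
            k: float(v)
            for k, v in cfg.items()
            if k in cls.__dataclass_fields__
        }
        return cls(**known)


@dataclass
class ChannelGeometry:
    """Axisymmetric channel-in-annulus geometry.

    ``n_r`` cells span [0, R_out] (split between the two domains so that a
    cell face falls exactly on the interface r = R); ``n_r_matrix``
    optionally pins the number of matrix cells for thin-annulus studies.
    """

    radius: float = 5.5e-4  # m
    length: float = 1.0e-2  # m
    matrix_outer_radius: float = 3.0e-3  # m
    n_r: int = 64
    n_z: int = 32
    n_r_matrix: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.radius < self.matrix_outer_radius:
            raise ValueError("need 0 < radius < matrix_outer_radius")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.n_r < 16 or self.n_z < 16:
            raise ValueError("grid resolution must be at least 16 x 16")

    def radial_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        """Piecewise-uniform cell-centered radial grid aligned to r = R.

        Returns (cell centers, cell widths, face radii, n_channel_cells).
        """
        frac = self.radius / self.matrix_outer_radius
        if self.n_r_matrix is not None:
            n_in = self.n_r
            n_out = int(self.n_r_matrix)
        else:
            n_in = int(round(self.n_r * frac))
            n_in = min(max(n_in, 8), self.n_r - 8)
            n_out = self.n_r - n_in
        dr_in = self.radius / n_in
        dr_out = (self.matrix_outer_radius - self.radius) / n_out
        widths = np.concatenate([np.full(n_in, dr_in), np.full(n_out, dr_out)])
        faces = np.concatenate([[0.0], np.cumsum(widths)])
        centers = 0.5 * (faces[:-1] + faces[1:])
        return centers, widths, faces, n_in


@dataclass
class FlowConditions:
    """Perfusion operating point: flow rate (µL/min) and medium properties."""

    flow_rate: float = 10.0  # uL/min
    fluid_viscosity: float = 0.7e-3  # Pa s, aqueous medium at 37 C
    fluid_density: float = 1000.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise ValueError("flow_rate must be >= 0")
        if not self.fluid_viscosity > 0:
            raise ValueError("fluid_viscosity must be > 0")

    @property
    def flow_rate_si(self) -> float:
        return self.flow_rate * UL_PER_MIN_TO_M3_PER_S


@dataclass
class FlowResult:
    """Steady axisymmetric flow solution."""

    r: np.ndarray  # cell centers, m
    z: np.ndarray  # cell centers, m
    u: np.ndarray  # axial velocity, (n_r, n_z), m/s
    p: np.ndarray  # pressure, (n_r, n_z), Pa
    wall_shear_stress: float  # Pa
    reynolds: float
    pressure_gradient: float  # Pa/m
    channel_flux: float  # m^3/s, integral of u over the channel section
    n_channel_cells: int
    u_profile: np.ndarray = field(repr=False, default=None)  # u(r), m/s


@dataclass
class TransportResult:
    """Transient solute transport solution."""

    times: np.ndarray  # s
    bulk_average: np.ndarray  # mean matrix concentration (normalized)
    time_to_target: float  # s; +inf if target not reached by t_max
    target_fraction: float
    c_final: np.ndarray  # (n_r, n_z) at the last computed time
    r: np.ndarray
    z: np.ndarray
    n_channel_cells: int
    method: dict = field(default_factory=dict)


def poiseuille_wall_shear(Q_ul_min: float, radius: float, mu: float) -> float:
    """Closed-form laminar-tube wall shear stress, 4 mu Q / (pi R^3), Pa."""
    return 4.0 * mu * Q_ul_min * UL_PER_MIN_TO_M3_PER_S / (math.pi * radius**3)


def solve_channel_flow(
    geom: ChannelGeometry,
    porous: PorousDomainParams,
    cond: FlowConditions,
) -> FlowResult:
    """Solve the coupled channel/Brinkman fully developed flow.

    The linear two-domain radial problem is discretized with a
    flux-conservative finite-volume scheme on the piecewise-uniform grid of
    ``geom`` (interface exactly on a face, harmonic-mean viscosity at the
    face) and solved for a unit pressure gradient; by linearity the solution
    is rescaled so the channel cross-section carries ``cond.flow_rate``.

    Wall shear stress is evaluated as ``mu_f du/dr`` at r = R from a
    quadratic fit through the three channel cells nearest the wall (exact
    for the piecewise-quadratic channel profile).
    """
    mu_f = cond.fluid_viscosity
    mu_e = porous.dynamic_viscosity_matrix
    centers, widths, faces, n_in = geom.radial_grid()
    n = centers.size
    mu_cell = np.where(np.arange(n) < n_in, mu_f, mu_e)
    beta = np.where(np.arange(n) < n_in, 0.0, mu_f / porous.permeability)

    # interior face transmissibilities T = r_f / (h_L/(2 mu_L) + h_R/(2 mu_R))
    T = faces[1:-1] / (
        widths[:-1] / (2 * mu_cell[:-1]) + widths[1:] / (2 * mu_cell[1:])
    )
    # outer face: no-slip ghost
    T_out = faces[-1] / (widths[-1] / (2 * mu_cell[-1]))

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    lower[1:] = T
    upper[:-1] = T
    diag[:-1] -= T
    diag[1:] -= T
    diag[-1] -= T_out
    diag -= beta * centers * widths
    rhs = -1.0 * centers * widths  # unit pressure gradient G = 1

    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    u_unit = solve_banded((1, 1), ab, rhs)

    flux_unit = float(
        2 * math.pi * np.sum(centers[:n_in] * u_unit[:n_in] * widths[:n_in])
    )
    Q_si = cond.flow_rate_si
    if Q_si == 0.0:
        u_r = np.zeros(n)
        G = 0.0
        tau_w = 0.0
    else:
        G = Q_si / flux_unit
        u_r = u_unit * G
        # quadratic fit through the three channel cells nearest the wall
        rr = centers[n_in - 3 : n_in]
        uu = u_r[n_in - 3 : n_in]
        coef = np.polyfit(rr, uu, 2)
        dudr = 2 * coef[0] * geom.radius + coef[1]
        tau_w = abs(mu_f * dudr)

    channel_flux = float(
        2 * math.pi * np.sum(centers[:n_in] * u_r[:n_in] * widths[:n_in])
    )
    u_mean = channel_flux / (math.pi * geom.radius**2) if geom.radius else 0.0
    reynolds = cond.fluid_density * abs(u_mean) * 2 * geom.radius / mu_f
    if reynolds >= 100:
        warnings.warn(
            f"Re = {reynolds:.1f} >= 100: outside the creeping-flow regime "
            "this reduced-order model assumes",
            stacklevel=2,
        )

    z = (np.arange(geom.n_z) + 0.5) * geom.length / geom.n_z
    u = np.tile(u_r[:, None], (1, geom.n_z))
    p = np.tile((G * (geom.length - z))[None, :], (n, 1))
    return FlowResult(
        r=centers,
        z=z,
        u=u,
        p=p,
        wall_shear_stress=tau_w,
        reynolds=reynolds,
        pressure_gradient=G,
        channel_flux=channel_flux,
        n_channel_cells=n_in,
        u_profile=u_r,
    )


def sweep_flow_rates(
    geom: ChannelGeometry,
    porous: PorousDomainParams,
    q_list: list[float],
    cond: FlowConditions | None = None,
) -> dict:
    """Parametric wall-shear sweep over flow rates (µL/min).

    Returns a dict with a ``table`` DataFrame of (Q, tau_w), the slope of
    the least-squares fit through the origin (Pa per µL/min) and the R² of
    that fit — the linearity check for Stokes flow.
    """
    if not q_list:
        raise ValueError("q_list must be nonempty")
    if any(q < 0 for q in q_list):
        raise ValueError("flow rates must be >= 0")
    cond = cond or FlowConditions()
    rows = []
    for q in q_list:
        res = solve_channel_flow(geom, porous, replace(cond, flow_rate=q))
        rows.append({"flow_rate_ul_min": q, "wall_shear_stress_pa": res.wall_shear_stress})
    table = pd.DataFrame(rows)
    qv = table["flow_rate_ul_min"].to_numpy(float)
    tv = table["wall_shear_stress_pa"].to_numpy(float)
    slope = float(np.sum(qv * tv) / np.sum(qv * qv)) if np.any(qv > 0) else 0.0
    resid = tv - slope * qv
    ss_tot = float(np.sum((tv - tv.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return {"table": table, "slope": slope, "r_squared": r2}


def calibrate_radius(
    target_tau: float,
    flow_rate: float,
    cond: FlowConditions | None = None,
    porous: PorousDomainParams | None = None,
    geom_template: ChannelGeometry | None = None,
    rel_tol: float = 0.005,
) -> ChannelGeometry:
    """Invert the shear-flow relation: find R giving ``target_tau`` at Q.

    Bisection on R in [10 µm, 5 mm] against the numerical solver (wall
    shear decreases monotonically with R at fixed Q).  The matrix annulus
    thickness of the template geometry is preserved.
    """
    if not target_tau > 0:
        raise ValueError("target_tau must be > 0")
    cond = cond or FlowConditions()
    cond = replace(cond, flow_rate=flow_rate)
    porous = porous or PorousDomainParams()
    template = geom_template or ChannelGeometry()
    thickness = template.matrix_outer_radius - template.radius

    def tau_of(r: float) -> float:
        geom = replace(
            template, radius=r, matrix_outer_radius=r + thickness, n_r_matrix=None
        )
        return solve_channel_flow(geom, porous, cond).wall_shear_stress

    lo, hi = 1e-5, 5e-3
    tau_lo, tau_hi = tau_of(lo), tau_of(hi)
    if not (tau_hi <= target_tau <= tau_lo):
        raise ValueError(
            f"target tau_w = {target_tau:g} Pa unreachable for R in "
            f"[{lo:g}, {hi:g}] m (attainable range [{tau_hi:g}, {tau_lo:g}])"
        )
    for _ in range(100):
        mid = math.sqrt(lo * hi)  # geometric bisection: tau ~ R^-3
        tau_mid = tau_of(mid)
        if abs(tau_mid - target_tau) / target_tau < rel_tol:
            return replace(
                template,
                radius=mid,
                matrix_outer_radius=mid + thickness,
                n_r_matrix=None,
            )
        if tau_mid > target_tau:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("calibration bisection did not converge")


def solve_species_transport(
    geom: ChannelGeometry,
    porous: PorousDomainParams,
    cond: FlowConditions,
    inlet_concentration: float = 1.0,
    target_fraction: float = 0.9,
    t_max: float = 3600.0,
    channel_model: str = "advect",
    cfl_safety: float = 0.8,
) -> TransportResult:
    """Transient solute transport from the channel into the matrix.

    Axisymmetric explicit finite-volume scheme: upwind axial advection in
    the channel (velocity profile from :func:`solve_channel_flow`), Fickian
    diffusion everywhere (free diffusivity ``D_s`` in the lumen, effective
    diffusivity ``eps * D_s`` in the matrix).  The inlet (z = 0, channel) is
    held at ``inlet_concentration``; all outer boundaries are no-flux, the
    channel outlet is zero-gradient.  Time stepping substeps internally to
    honor the diffusive and CFL stability bounds.

    ``channel_model="saturated"`` holds the whole lumen at the inlet
    concentration from t = 0 (the no-flow / fast-perfusion idealization
    used for closed-form benchmarks).

    ``time_to_target`` is the first time the volume-averaged matrix
    concentration crosses ``target_fraction`` (linear interpolation between
    steps); ``+inf`` with a warning when not reached by ``t_max``.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    if channel_model not in ("advect", "saturated"):
        raise ValueError("channel_model must be 'advect' or 'saturated'")

    centers, widths, faces, n_in = geom.radial_grid()
    n_r = centers.size
    n_z = geom.n_z
    dz = geom.length / n_z
    D_s = porous.species_diffusivity
    D_eff = porous.effective_diffusivity
    D_cell = np.where(np.arange(n_r) < n_in, D_s, D_eff)

    if channel_model == "advect" and cond.flow_rate > 0:
        flow = solve_channel_flow(geom, porous, cond)
        u_r = np.clip(flow.u_profile, 0.0, None)
        u_r[n_in:] = 0.0
    else:
        u_r = np.zeros(n_r)

    # radial face transmissibilities (per unit axial length), divided later
    # by the cell volume factor r_i * dr_i
    T_r = faces[1:-1] / (
        widths[:-1] / (2 * D_cell[:-1]) + widths[1:] / (2 * D_cell[1:])
    )
    if channel_model == "saturated":
        # lumen held at the inlet value: the Dirichlet condition acts at the
        # interface face itself, so only the matrix half-cell resists
        T_r[n_in - 1] = faces[n_in] / (widths[n_in] / (2 * D_cell[n_in]))
    vol_r = centers * widths

    # stability: combined explicit bound, dt <= 1/(2D(1/dr^2+1/dz^2) + u/dz)
    u_max = float(np.max(u_r))
    rate = 2.0 * np.max(D_cell * (1.0 / widths**2 + 1.0 / dz**2)) + u_max / dz
    dt = cfl_safety / rate
    n_steps = int(math.ceil(t_max / dt))
    dt = t_max / n_steps

    c = np.zeros((n_r, n_z))
    matrix_w = vol_r[n_in:]
    matrix_wsum = matrix_w.sum() * n_z

    times = np.empty(n_steps + 1)
    cbar = np.empty(n_steps + 1)
    times[0], cbar[0] = 0.0, 0.0

    alpha_z = D_cell[:, None] / dz**2
    for step in range(1, n_steps + 1):
        if channel_model == "saturated":
            c[:n_in, :] = inlet_concentration

        # radial diffusion
        flux_r = T_r[:, None] * (c[1:, :] - c[:-1, :])
        div = np.zeros_like(c)
        div[:-1, :] += flux_r / vol_r[:-1, None]
        div[1:, :] -= flux_r / vol_r[1:, None]

        # axial diffusion (no-flux ends; inlet Dirichlet handled with ghost
        # for channel rows)
        div[:, 1:] += alpha_z * (c[:, :-1] - c[:, 1:])
        div[:, :-1] += alpha_z * (c[:, 1:] - c[:, :-1])
        if channel_model == "advect":
            div[:n_in, 0] += alpha_z[:n_in, 0] * (
                2.0 * (inlet_concentration - c[:n_in, 0])
            )

        # upwind axial advection in the channel
        if u_max > 0:
            adv = np.zeros_like(c)
            adv[:n_in, 0] = -u_r[:n_in] * (c[:n_in, 0] - inlet_concentration) / dz
            adv[:n_in, 1:] = (
                -u_r[:n_in, None] * (c[:n_in, 1:] - c[:n_in, :-1]) / dz
            )
            div += adv

        c += dt * div
        if channel_model == "saturated":
            c[:n_in, :] = inlet_concentration
        times[step] = step * dt
        cbar[step] = float(np.sum(c[n_in:, :] * matrix_w[:, None]) / matrix_wsum)

    target = target_fraction * inlet_concentration
    idx = np.argmax(cbar >= target)
    if cbar[idx] >= target and idx > 0:
        # linear interpolation across the crossing step
        t0, t1 = times[idx - 1], times[idx]
        c0, c1 = cbar[idx - 1], cbar[idx]
        t_star = t0 + (target - c0) / (c1 - c0) * (t1 - t0)
    elif cbar[0] >= target:
        t_star = 0.0
    else:
        t_star = math.inf
        warnings.warn(
            f"target fraction {target_fraction} not reached by t_max = "
            f"{t_max:g} s (final mean concentration {cbar[-1]:.4f})",
            stacklevel=2,
        )

    return TransportResult(
        times=times,
        bulk_average=cbar,
        time_to_target=t_star,
        target_fraction=target_fraction,
        c_final=c,
        r=centers,
        z=(np.arange(n_z) + 0.5) * dz,
        n_channel_cells=n_in,
        method={
            "scheme": "explicit finite volume, upwind advection",
            "dt_s": dt,
            "n_steps": n_steps,
            "channel_model": channel_model,
            "effective_diffusivity_m2_s": D_eff,
        },
    )
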