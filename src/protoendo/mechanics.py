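"""Reduced dynamics of a growing, water-permeable elastic vesicle.

The membrane is a Helfrich sheet with bending modulus K_b (in k_B*T),
spontaneous curvature c0 and water permeability P_f.  Instead of resolving
the surrounding incompressible flow, the contour follows an overdamped
gradient flow of the bending energy with the Stokes membrane mobility:
the velocity response to a normal force density of arclength wavenumber q
is 1/(4*mu*q), so long-wavelength deformations are hydrodynamically slow
while local dimpling is fast — the mode competition that selects inward
invagination over global elongation.  Shape relaxation (milliseconds at
these parameters) is fast compared to the osmotic and growth forcing
(seconds), so the trajectory tracks the constrained energy-minimizing
branch as the constraints move.

Constraints: surface area is driven toward an exponential growth target
A(t) = min(A0*exp(gamma*t), cap*A0) through a stiff quadratic penalty
(membrane inextensibility with micelle incorporation), and enclosed volume
follows dV/dt = -P_f*v_w*A*dc (water efflux under a hyperosmotic bath)
through a second penalty whose force is the uniform-pressure normal force
on the surface.

Numerics: forces are exact gradients of the discretized energy obtained by
complex-step differentiation; the mobility and the IMEX stabilizer for the
stiff bending flow are diagonal in the sine basis over the arclength
parameterization, and the slow rank-one penalty ("breathing") modes are
made implicit through a Woodbury correction, so the step size is set by
the forcing rather than the bending stiffness.  Markers are periodically
redistributed in arclength.  Topological changes are outside the model: a
self-intersecting contour or a neck narrower than a configurable fraction
of the equivalent radius terminates the run with status "pre_pinch".
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from . import constants as K
from .errors import InvalidShapeError, StepSizeError
from .shapes import (
    AxisymShape,
    enclosed_volume,
    node_areas,
    principal_curvatures,
    resample,
    segment_lengths,
    surface_area,
)

__all__ = [
    "MembraneParams",
    "EnvironmentParams",
    "SimulationConfig",
    "Trajectory",
    "bending_energy",
    "target_area",
    "osmotic_volume_rate",
    "vant_hoff_pressure",
    "simulate",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MembraneParams:
    """Membrane material and growth parameters.

    bending_modulus : K_b in units of k_B*T
    spontaneous_curvature : c0 in um^-1 (negative favors inward budding)
    area_growth_rate : gamma in s^-1 (relative exponential growth)
    water_permeability : P_f in cm/s
    water_molar_volume : v_w in cm^3/mol
    area_cap_factor : growth saturates at this multiple of the initial area
    """

    bending_modulus: float = 10.0
    spontaneous_curvature: float = 0.0
    area_growth_rate: float = 0.0
    water_permeability: float = 14e-3
    water_molar_volume: float = 20.0
    area_cap_factor: float = 2.0

    def __post_init__(self):
        if self.bending_modulus <= 0:
            raise ValueError("bending_modulus must be > 0")
        if self.water_permeability < 0:
            raise ValueError("water_permeability must be >= 0")
        if self.water_molar_volume <= 0:
            raise ValueError("water_molar_volume must be > 0")
        if self.area_growth_rate < 0:
            raise ValueError("area_growth_rate must be >= 0")
        if self.area_cap_factor < 1:
            raise ValueError("area_cap_factor must be >= 1")


@dataclass
class EnvironmentParams:
    """Bath properties: viscosity mu (dyn s/cm^2), density rho (g/cm^3),
    osmolarity difference dc = c_out - c_in (mM, constant in time) and
    temperature (K)."""

    viscosity: float = 0.01
    density: float = 1.0
    osmolarity_difference: float = 0.0
    temperature_K: float = K.DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")


@dataclass
class SimulationConfig:
    """Integrator knobs.

    timestep : initial physical step in s (adapted during the run)
    total_time : simulated time in s
    marker_count : contour resolution
    area_penalty / volume_penalty : penalty stiffnesses in k_B*T against
        the squared relative constraint mismatch
    area_tolerance : relative area mismatch the run is expected to hold;
        the worst mismatch occurs transiently before buckling, while a
        near-sphere cannot yet store excess area in deformation
    mobility_scale : dimensionless prefactor on the hydrodynamic
        mobility 1/(4*mu*q); default 1
    area_mode : "target" enforces the growth law; "free" leaves area
        unconstrained (used to verify the volume-flux law on a sphere)
    neck_fraction : neck radius below this fraction of the equivalent
        radius terminates the run as "pre_pinch"
    """

    timestep: float = 1e-4
    total_time: float = 2.0
    marker_count: int = 64
    area_penalty: float = 2.0e5
    volume_penalty: float = 2.0e5
    area_tolerance: float = 0.05
    mobility_scale: float | None = None
    area_mode: str = "target"
    neck_fraction: float = 0.15
    seed: int = 0
    remesh_interval: int = 15
    n_frames: int = 61
    max_timestep: float = 2e-3
    max_steps: int = 400_000

    def __post_init__(self):
        if self.timestep <= 0 or self.total_time <= 0:
            raise ValueError("timestep and total_time must be > 0")
        if self.marker_count < 8:
            raise ValueError("marker_count must be >= 8")
        if self.area_mode not in ("target", "free"):
            raise ValueError("area_mode must be 'target' or 'free'")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def target_area(t: float, A0: float, params: MembraneParams) -> float:
    """Membrane area target A(t) = min(A0*exp(gamma*t), cap*A0), um^2."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return float(min(A0 * np.exp(params.area_growth_rate * t),
                     params.area_cap_factor * A0))


def osmotic_volume_rate(shape: AxisymShape, params: MembraneParams,
                        env: EnvironmentParams) -> float:
    """Water-efflux rate dV/dt = -P_f*v_w*A*dc in um^3/s.

    Positive dc (hyperosmotic bath) shrinks the vesicle.
    """
    return _volume_rate_from_area(shape.area, params, env)


def _volume_rate_from_area(area_um2: float, params: MembraneParams,
                           env: EnvironmentParams) -> float:
    # P_f[cm/s] * v_w[cm^3/mol] * dc[mol/cm^3] is a velocity in cm/s;
    # convert to um/s (1e4) and multiply by area (um^2); the mM->mol/cm^3
    # factor 1e-6 nets to 1e-2.
    dc = env.osmolarity_difference
    return float(-params.water_permeability * params.water_molar_volume
                 * dc * 1e-2 * area_um2)


def vant_hoff_pressure(dc_mM: float, T_K: float = K.DEFAULT_TEMPERATURE_K) -> float:
    """Osmotic pressure p = c*k_B*T for concentration difference c, in Pa."""
    if T_K <= 0:
        raise ValueError("temperature must be > 0")
    c_per_m3 = dc_mM * K.MOL_PER_M3_PER_MM * K.AVOGADRO
    return float(c_per_m3 * K.BOLTZMANN_J_PER_K * T_K)


def bending_energy(shape: AxisymShape, params: MembraneParams) -> float:
    """Discretized Helfrich energy (K_b/2) * Int (2H - c0)^2 dA in k_B*T."""
    return float(_bending_energy_arr(shape.markers,
                                     params.bending_modulus,
                                     params.spontaneous_curvature))


def _bending_energy_arr(x, Kb, c0):
    c_m, c_phi = principal_curvatures(x)
    a = node_areas(x)
    return 0.5 * Kb * np.sum(a * (c_m + c_phi - c0) ** 2, axis=-1)


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time series of contours with per-frame diagnostics.

    status is "completed", "pre_pinch" (self-intersection or narrow neck
    reached; topological change is outside the model) or "step_error".
    """

    frames: list = field(default_factory=list)
    times: list = field(default_factory=list)
    status: str = "completed"
    params: MembraneParams | None = None
    env: EnvironmentParams | None = None
    config: SimulationConfig | None = None

    @property
    def final_shape(self) -> AxisymShape:
        return self.frames[-1]

    @property
    def diagnostics(self) -> pd.DataFrame:
        from .morphology import classify, reduced_volume

        rows = []
        for t, sh in zip(self.times, self.frames):
            rows.append({
                "time_s": t,
                "area_um2": sh.area,
                "volume_um3": sh.volume,
                "reduced_volume": reduced_volume(sh),
                "E_bend_kBT": bending_energy(sh, self.params),
                "morphology": classify(sh).value,
            })
        df = pd.DataFrame(rows)
        if self.status == "pre_pinch" and len(df):
            df.loc[df.index[-1], "morphology"] = "pre_pinch"
        return df

    def plot(self, ax=None, every: int = 10):
        """Overlay contour snapshots (mirrored across the axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i in range(0, len(self.frames), max(1, every)):
            m = self.frames[i].markers
            ax.plot(m[:, 0], m[:, 1], color="C0", alpha=0.3 + 0.7 * i / max(1, len(self.frames) - 1))
            ax.plot(-m[:, 0], m[:, 1], color="C0", alpha=0.3 + 0.7 * i / max(1, len(self.frames) - 1))
        ax.set_aspect("equal")
        ax.set_xlabel("r (um)")
        ax.set_ylabel("z (um)")
        return ax


# ---------------------------------------------------------------------------
# gradient-flow integrator
# ---------------------------------------------------------------------------

_CSTEP = 1e-30  # complex-step size; exact to machine precision
_DEBUG = False


def _pack(x):
    """DOF vector: interleaved (r_i, z_i) for the interior markers.

    Pole markers are not degrees of freedom; they are reconstructed from
    the adjacent interior markers (see _unpack), which removes the stiff,
    nearly-massless pole modes from the flow.
    """
    return x[1:-1].reshape(-1).copy()


def _pole_z(r1, z1, r2, z2):
    """Axis intercept of the even parabola z = c0 + c2 r^2 through two
    near-pole markers; analytic in all arguments."""
    return (z1 * r2 ** 2 - z2 * r1 ** 2) / (r2 ** 2 - r1 ** 2)


def _unpack(q, n):
    # q may be a batch (..., ndof); poles are even-extrapolated
    shape = q.shape[:-1] + (n, 2)
    x = np.zeros(shape, dtype=q.dtype)
    interior = q.reshape(q.shape[:-1] + (n - 2, 2))
    x[..., 1:-1, :] = interior
    x[..., 0, 1] = _pole_z(x[..., 1, 0], x[..., 1, 1],
                           x[..., 2, 0], x[..., 2, 1])
    x[..., -1, 1] = _pole_z(x[..., -2, 0], x[..., -2, 1],
                            x[..., -3, 0], x[..., -3, 1])
    return x


def _total_energy(x, Kb, c0, A_t, V_t, kA, kV, A0, V0):
    E = _bending_energy_arr(x, Kb, c0)
    if A_t is not None:
        E = E + 0.5 * kA * ((surface_area(x) - A_t) / A0) ** 2
    if V_t is not None:
        E = E + 0.5 * kV * ((enclosed_volume(x) - V_t) / V0) ** 2
    return E


def _gradients(q, n, args):
    """Exact gradients of the total energy, area and volume w.r.t. the
    DOF vector via complex-step differentiation (one batched sweep)."""
    ndof = q.shape[0]
    qc = q[None, :].astype(complex) + 1j * _CSTEP * np.eye(ndof)
    x = _unpack(qc, n)
    E = _total_energy(x, *args)
    gA = surface_area(x).imag / _CSTEP
    gV = enclosed_volume(x).imag / _CSTEP
    return E.imag / _CSTEP, gA, gV


def _neck_and_validity(x, neck_fraction):
    """Return (valid, pre_pinch) geometric checks on the real contour."""
    if np.any(~np.isfinite(x)):
        return False, False
    if np.any(x[1:-1, 0] <= 0):
        return False, False
    if not LineString(x).is_simple:
        return False, True  # crossed itself between checks: pre-pinch
    from scipy.signal import find_peaks

    from .morphology import cavity_metrics

    v = enclosed_volume(x)
    r_eq = (3.0 * abs(v) / (4.0 * np.pi)) ** (1.0 / 3.0)
    n_cav, neck = cavity_metrics(x)
    if n_cav > 0 and neck is not None and neck <= neck_fraction * r_eq:
        return True, True
    # outer waist pinching toward the axis (pearling / division attempt)
    waists, _ = find_peaks(-x[1:-1, 0], prominence=0.05 * r_eq)
    if waists.size and x[1:-1, 0][waists].min() <= neck_fraction * r_eq:
        return True, True
    return True, False


def _safe_resample(x, n):
    """Arclength redistribution; falls back to shape-preserving linear
    interpolation when the cubic spline overshoots near a tight neck."""
    sh = AxisymShape(x.copy())
    try:
        out = resample(sh, n)
        if LineString(out.markers).is_simple:
            return out.markers
    except InvalidShapeError:
        pass
    s = sh.arclengths()
    s_new = np.linspace(0.0, s[-1], n)
    r_new = np.interp(s_new, s, x[:, 0])
    z_new = np.interp(s_new, s, x[:, 1])
    r_new[0] = r_new[-1] = 0.0
    tiny = 1e-9 * max(s[-1], 1.0)
    r_new[1:-1] = np.maximum(r_new[1:-1], tiny)
    return AxisymShape(np.column_stack([r_new, z_new])).markers


def simulate(shape0: AxisymShape, params: MembraneParams,
             env: EnvironmentParams, config: SimulationConfig) -> Trajectory:
    """Integrate the constrained overdamped gradient flow.

    Deterministic given its inputs.  Returns a Trajectory whose frames are
    evenly spaced in time (last frame earlier if the run terminated
    "pre_pinch").
    """
    from scipy.fft import dst, idst

    n = config.marker_count
    sh = resample(shape0, n) if shape0.n_markers != n else shape0
    x = sh.markers.copy()

    A0 = surface_area(x)
    V0 = enclosed_volume(x)

    # membrane mobility in Stokes flow: velocity response 1/(4*mu*q) per
    # unit normal force density at arclength wavenumber q
    kbt = K.thermal_energy_erg(env.temperature_K)
    mu_star = env.viscosity / (kbt * 1e12)  # kBT s / um^3
    mob_pref = 1.0 if config.mobility_scale is None else float(config.mobility_scale)

    Kb = params.bending_modulus
    c0 = params.spontaneous_curvature
    kA = config.area_penalty
    kV = config.volume_penalty

    V_t = V0
    dt = config.timestep
    t = 0.0
    T = config.total_time

    frame_times = np.linspace(0.0, T, config.n_frames)
    traj = Trajectory(params=params, env=env, config=config)

    def record(t_now, x_now):
        traj.frames.append(AxisymShape(x_now.copy()))
        traj.times.append(float(t_now))

    record(0.0, x)
    next_frame = 1

    steps_since_remesh = 0
    h = float(np.mean(segment_lengths(x)))
    max_rejects = 60
    n_steps = 0

    while t < T - 1e-12:
        n_steps += 1
        if n_steps > config.max_steps:
            traj.status = "step_error"
            return traj
        if _DEBUG and n_steps % 2000 == 0:
            print(f"[simulate] step {n_steps} t={t:.4f} dt={dt:.2e}")

        A_t = target_area(t, A0, params) if config.area_mode == "target" else None
        args = (Kb, c0, A_t, V_t, kA, kV, A0, V0)

        E0 = float(_total_energy(x, *args))
        if not np.isfinite(E0):
            # a kink reached the turning-angle limit; redistribute markers
            try:
                x = _safe_resample(x, n)
            except InvalidShapeError:
                traj.status = "pre_pinch"
                return traj
            h = float(np.mean(segment_lengths(x)))
            steps_since_remesh = 0
            E0 = float(_total_energy(x, *args))
            if not np.isfinite(E0):
                traj.status = "step_error"
                return traj
            continue

        q = _pack(x)
        g, gA, gV = _gradients(q, n, args)
        # force density (energy gradient per node area, floored near the
        # poles), projected on the local normal: membrane motion is
        # normal, tangential motion only reparameterizes
        a = node_areas(x)[1:-1].copy()
        a = np.maximum(a, 0.3 * np.mean(a))
        a_dof = np.repeat(a, 2)
        f = (-g / a_dof).reshape(n - 2, 2)
        d = x[1:, :] - x[:-1, :]
        tn = d[:-1] + d[1:]
        tn /= np.hypot(tn[:, 0], tn[:, 1])[:, None]
        normals = np.column_stack([tn[:, 1], -tn[:, 0]])
        f = np.sum(f * normals, axis=1)[:, None] * normals

        # spectral mobility and IMEX stabilizer, diagonal in the sine
        # basis over the interior chain
        L_tot = float(segment_lengths(x).sum())
        qk = np.pi * np.arange(1, n - 1) / L_tot
        Mq = mob_pref / (4.0 * mu_star * qk)
        r_min = max(float(x[1:-1, 0].min()), 2.0 * h)
        sigma = kA * (abs(surface_area(x) - (A_t if A_t is not None else A0))
                      / A0 + 0.02) / A0
        lam = 1.5 * mob_pref * (Kb * qk ** 3 + (Kb / r_min ** 2 + sigma
                                + Kb * c0 ** 2) * qk) / (4.0 * mu_star)

        def mob_apply(vec):
            out = np.empty_like(vec)
            for c_ in range(2):
                out[c_::2] = idst(Mq * dst(vec[c_::2], type=1), type=1)
            return out

        v_dof = np.empty(2 * (n - 2))
        v_dof[0::2] = idst(Mq * dst(f[:, 0], type=1), type=1)
        v_dof[1::2] = idst(Mq * dst(f[:, 1], type=1), type=1)

        # rank-one curvatures of the two penalties (slow breathing modes),
        # folded into the implicit solve by the Woodbury identity
        u_cols, w_cols = [], []
        if A_t is not None:
            u_cols.append(mob_apply(gA / a_dof) * (kA / A0 ** 2))
            w_cols.append(gA)
        u_cols.append(mob_apply(gV / a_dof) * (kV / V0 ** 2))
        w_cols.append(gV)
        U = np.column_stack(u_cols)
        W = np.column_stack(w_cols)

        accepted = False
        for _ in range(max_rejects):
            dt_eff = min(dt, T - t)

            def solve_B(vec):
                out = np.empty_like(vec)
                for c_ in range(2):
                    vh = dst(vec[c_::2], type=1)
                    out[c_::2] = idst(vh / (1.0 + dt_eff * lam), type=1)
                return out

            y = solve_B(dt_eff * v_dof)
            BU = np.column_stack([solve_B(dt_eff * U[:, j])
                                  for j in range(U.shape[1])])
            cap = np.eye(U.shape[1]) + W.T @ BU
            delta = y - BU @ np.linalg.solve(cap, W.T @ y)
            x_new = _unpack(q + delta, n)

            disp = np.max(np.hypot(*(x_new - x).T))
            ok = (bool(np.all(np.isfinite(x_new)))
                  and bool(np.all(x_new[1:-1, 0] > 0))
                  and disp <= 0.35 * h)
            if ok:
                E1 = float(_total_energy(x_new, *args))
                ok = E1 <= E0 + 1e-3 * abs(E0) + 1e-9
            if ok:
                accepted = True
                break
            dt *= 0.5
            if dt < 1e-12:
                if _DEBUG:
                    print(f"[simulate] step collapse at t={t:.4f} "
                          f"disp={disp:.3e} h={h:.3e} E0={E0:.3f}")
                traj.status = "step_error"
                return traj
        if not accepted:
            raise StepSizeError("integrator failed to find a stable step")

        # advance the volume target with the actual area (trapezoid over
        # the step)
        V_t += 0.5 * (_volume_rate_from_area(surface_area(x), params, env)
                      + _volume_rate_from_area(surface_area(x_new), params, env)
                      ) * dt_eff
        V_t = max(V_t, 1e-6 * V0)

        x = x_new
        t += dt_eff
        dt = min(dt * 1.3, config.max_timestep)
        steps_since_remesh += 1

        if steps_since_remesh >= config.remesh_interval:
            try:
                x = _safe_resample(x, n)
            except InvalidShapeError:
                traj.status = "pre_pinch"
                record(t, traj.frames[-1].markers)
                return traj
            h = float(np.mean(segment_lengths(x)))
            steps_since_remesh = 0
            valid, pinch = _neck_and_validity(x, config.neck_fraction)
            if not valid or pinch:
                traj.status = "pre_pinch"
                record(t, x if valid else traj.frames[-1].markers)
                return traj

        while (next_frame < len(frame_times)
               and t >= frame_times[next_frame] - 1e-12):
            valid, pinch = _neck_and_validity(x, config.neck_fraction)
            if not valid or pinch:
                traj.status = "pre_pinch"
                record(t, x if valid else traj.frames[-1].markers)
                return traj
            record(frame_times[next_frame], x)
            next_frame += 1

    return traj
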