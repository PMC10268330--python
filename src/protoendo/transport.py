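"""Passive-permeation calculus and compartment-release kinetics.

Transmembrane solute transport is diffusive: the flux across a membrane
is J = P_s * dC, with P_s the solute permeability (cm/s) and dC the
concentration difference.  For a vesicle of membrane area A this gives a
molecular crossing rate dN/dt = J*A*N_A and a mean single-molecule
crossing time 1/(dN/dt).  For a nested compartment-in-vesicle geometry
(endocytic compartment -> lumen -> bath) the same law yields a linear
two-membrane exchange system solved here in closed form.

Units at the interface: concentrations in mM, lengths in um,
permeabilities in cm/s, times in seconds (fits in hours, matching how
release experiments are reported).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import linregress

from .constants import AVOGADRO, CM_PER_UM, MOL_PER_CM3_PER_MM

__all__ = [
    "SoluteSpec",
    "VesicleGeometry",
    "CompartmentSystem",
    "molecular_flux",
    "crossing_rate",
    "crossing_time",
    "release_timecourse",
    "time_to_fraction",
    "sink_release_time",
    "fit_release_rate",
    "ReleaseKineticsModel",
    "ReleaseKineticsResults",
]


@dataclass
class SoluteSpec:
    """A solute and its membrane permeability P_s in cm/s."""

    name: str
    permeability: float

    def __post_init__(self):
        if self.permeability < 0:
            raise ValueError("permeability must be >= 0")


@dataclass
class VesicleGeometry:
    """Spherical vesicle geometry; diameter in um."""

    diameter: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")

    @property
    def area_cm2(self) -> float:
        d_cm = self.diameter * CM_PER_UM
        return float(np.pi * d_cm ** 2)

    @property
    def volume_cm3(self) -> float:
        d_cm = self.diameter * CM_PER_UM
        return float(np.pi * d_cm ** 3 / 6.0)


@dataclass
class CompartmentSystem:
    """Nested release geometry: an endocytic compartment inside the
    vesicle lumen, which in turn exchanges with an infinite bath.

    Radii in um, concentrations in mM.  A non-finite lumen_radius (or
    bath_is_lumen sink limit via `sink_limit`) is not allowed; use a very
    large lumen to approximate a sink.
    """

    compartment_radius: float
    lumen_radius: float
    solute: SoluteSpec
    compartment_concentration: float = 1.0
    lumen_concentration: float = 0.0
    bath_concentration: float = 0.0
    bath_exchange: bool = True

    def __post_init__(self):
        if not 0 < self.compartment_radius < self.lumen_radius:
            raise ValueError(
                "need 0 < compartment_radius < lumen_radius")
        for c in (self.compartment_concentration, self.lumen_concentration,
                  self.bath_concentration):
            if c < 0:
                raise ValueError("concentrations must be >= 0")

    # first-order exchange rates, s^-1
    @property
    def rates(self):
        ps = self.solute.permeability  # cm/s
        r_c = self.compartment_radius * CM_PER_UM
        r_l = self.lumen_radius * CM_PER_UM
        a_c = 4.0 * np.pi * r_c ** 2
        v_c = 4.0 * np.pi * r_c ** 3 / 3.0
        a_l = 4.0 * np.pi * r_l ** 2
        v_l = 4.0 * np.pi * r_l ** 3 / 3.0 - v_c
        k1 = ps * a_c / v_c            # compartment loss
        k2 = ps * a_c / v_l            # lumen gain from compartment
        k3 = ps * a_l / v_l if self.bath_exchange else 0.0  # lumen<->bath
        return k1, k2, k3


def molecular_flux(solute: SoluteSpec, dc_mM: float) -> float:
    """Diffusive flux J = P_s * dC in mol cm^-2 s^-1; sign follows dC."""
    return float(solute.permeability * dc_mM * MOL_PER_CM3_PER_MM)


def crossing_rate(solute: SoluteSpec, dc_mM: float,
                  geom: VesicleGeometry) -> float:
    """Molecules per second crossing the vesicle membrane,
    dN/dt = J*A*N_A."""
    return float(molecular_flux(solute, dc_mM) * geom.area_cm2 * AVOGADRO)


def crossing_time(solute: SoluteSpec, dc_mM: float,
                  geom: VesicleGeometry) -> float:
    """Mean seconds per molecule crossing; inf when the rate is zero."""
    rate = crossing_rate(solute, dc_mM, geom)
    if rate == 0.0:
        return float("inf")
    return 1.0 / abs(rate)


def _system_matrix(system: CompartmentSystem):
    k1, k2, k3 = system.rates
    M = np.array([[-k1, k1], [k2, -(k2 + k3)]])
    return M


def release_timecourse(system: CompartmentSystem, times_s) -> pd.DataFrame:
    """Closed-form concentrations of compartment and lumen over time.

    Solves dC_c/dt = -k1 (C_c - C_l),
           dC_l/dt = k2 (C_c - C_l) - k3 (C_l - C_b)
    by eigendecomposition around the fixed point C = C_b (which is also a
    fixed point of the closed system, where k3 = 0 and total solute is
    conserved).  Columns: time_s, C_compartment_mM, C_lumen_mM.
    """
    t = np.asarray(times_s, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be a sorted, non-negative 1-D array")
    M = _system_matrix(system)
    c0 = np.array([system.compartment_concentration,
                   system.lumen_concentration])
    cb = system.bath_concentration
    evals, evecs = np.linalg.eig(M)
    coeff = np.linalg.solve(evecs, c0 - cb)
    c_t = (evecs @ (coeff[:, None] * np.exp(np.outer(evals, t)))).real + cb
    return pd.DataFrame({
        "time_s": t,
        "C_compartment_mM": c_t[0],
        "C_lumen_mM": c_t[1],
    })


def _equilibrium_compartment(system: CompartmentSystem) -> float:
    k1, k2, k3 = system.rates
    if k3 > 0:
        return system.bath_concentration
    # closed system: conserved total over compartment + lumen volumes
    w_c = k2
    w_l = k1  # proportional to V_c, V_l after dividing by ps*a_c
    return ((system.compartment_concentration * w_c
             + system.lumen_concentration * w_l) / (w_c + w_l))


def time_to_fraction(system: CompartmentSystem, fraction: float) -> float:
    """Smallest t with released fraction >= `fraction`, where the released
    fraction is (C_c(0) - C_c(t)) / (C_c(0) - C_eq)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return 0.0
    c_start = system.compartment_concentration
    c_eq = _equilibrium_compartment(system)
    if c_start == c_eq:
        return 0.0

    def released(t):
        cc = float(release_timecourse(system, [t]).C_compartment_mM.iloc[0])
        return (c_start - cc) / (c_start - c_eq) - fraction

    t_hi = 1.0
    while released(t_hi) < 0:
        t_hi *= 4.0
        if t_hi > 1e16:
            raise RuntimeError("release fraction not reached")
    return float(brentq(released, 0.0, t_hi, xtol=1e-9, rtol=1e-12))


def sink_release_time(radius_um: float, solute: SoluteSpec,
                      fraction: float) -> float:
    """Single-membrane sink limit: the surrounding volume is an infinite
    sink, so C_c decays with rate k = 3*P_s/r and
    t = -ln(1 - fraction) * r / (3*P_s), in seconds."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if solute.permeability == 0.0:
        return float("inf") if fraction > 0 else 0.0
    r_cm = radius_um * CM_PER_UM
    return float(-np.log1p(-fraction) * r_cm / (3.0 * solute.permeability))


def fit_release_rate(times_h, ratios, model: str = "least_squares") -> float:
    """First-order release rate k (per hour) from an intensity-ratio decay.

    "two_point" uses the first and last points, k = ln(r0/rt)/(t - t0);
    "least_squares" is the slope of -ln(ratio) against t.
    """
    t = np.asarray(times_h, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two points")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    if model == "two_point":
        if t[-1] == t[0]:
            raise ValueError("first and last times must differ")
        return float(np.log(r[0] / r[-1]) / (t[-1] - t[0]))
    if model == "least_squares":
        if np.allclose(t, t[0]):
            raise ValueError("times are degenerate")
        res = linregress(t, -np.log(r))
        return float(res.slope)
    raise ValueError(f"unknown model {model!r}")


class ReleaseKineticsModel:
    """First-order release model for intensity-ratio time series.

    The observed ratio is modeled as r(t) = r0 * exp(-k t) with
    multiplicative noise, fitted as a linear regression of log(ratio) on
    time.  Construct from arrays or a DataFrame; fit() returns a
    ReleaseKineticsResults with the rate, its standard error and a
    summary table.
    """

    def __init__(self, times_h, ratios):
        self.times_h = np.asarray(times_h, dtype=float)
        self.ratios = np.asarray(ratios, dtype=float)
        if self.times_h.size != self.ratios.size:
            raise ValueError("times and ratios must have equal length")
        if self.times_h.size < 2:
            raise ValueError("need at least two points")
        if np.any(self.ratios <= 0):
            raise ValueError("ratios must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time_h",
                       ratio_col: str = "ratio") -> "ReleaseKineticsModel":
        return cls(df[time_col].to_numpy(), df[ratio_col].to_numpy())

    def fit(self) -> "ReleaseKineticsResults":
        res = linregress(self.times_h, np.log(self.ratios))
        return ReleaseKineticsResults(
            model=self,
            rate_per_h=-res.slope,
            rate_stderr=res.stderr if np.isfinite(res.stderr) else np.nan,
            initial_ratio=float(np.exp(res.intercept)),
            intercept_stderr=res.intercept_stderr,
            rvalue=res.rvalue,
        )


@dataclass
class ReleaseKineticsResults:
    """Fit results for the first-order release model."""

    model: ReleaseKineticsModel
    rate_per_h: float
    rate_stderr: float
    initial_ratio: float
    intercept_stderr: float
    rvalue: float

    @property
    def halflife_h(self) -> float:
        return float(np.log(2.0) / self.rate_per_h) if self.rate_per_h > 0 \
            else float("inf")

    def predict(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        return self.initial_ratio * np.exp(-self.rate_per_h * t)

    def summary(self) -> str:
        lines = [
            "First-order release fit",
            "=" * 39,
            f"n points            {self.model.times_h.size:>18d}",
            f"rate k (1/h)        {self.rate_per_h:>18.5f}",
            f"  std err           {self.rate_stderr:>18.5f}",
            f"initial ratio r0    {self.initial_ratio:>18.3f}",
            f"half-life (h)       {self.halflife_h:>18.2f}",
            f"R^2                 {self.rvalue ** 2:>18.4f}",
        ]
        return "\n".join(lines)
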