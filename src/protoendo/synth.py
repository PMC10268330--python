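"""Seeded generators emulating the statistical structure of the study data.

Three generators stand in for the microscopy-derived inputs: per-vesicle
internal-compartment count tables over (dC_V, dC_A) conditions, intensity
-ratio time series decaying by first-order release with multiplicative
noise, and perturbed near-spherical initial membrane contours.  All are
bit-reproducible under a fixed seed.

The count law is a zero-inflated zero-truncated Poisson: a vesicle forms
at least one compartment with probability p1 (driven mainly by micelle
addition dC_A) and, conditional on that, carries a zero-truncated
Poisson(lambda) number of compartments (lambda rising with the osmotic
shock dC_V).  Default (p1, lambda) grids are anchored to the reported
fractions at the corners of the condition table: p1 ~ 7% at the weakest
micelle dose and ~70-88% at the strongest, with the multi-compartment
share roughly tripling from the mildest to the strongest shock.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import legval

from .errors import InvalidShapeError
from .shapes import AxisymShape

__all__ = [
    "CountGeneratorParams",
    "SeriesGeneratorParams",
    "DEFAULT_P1",
    "DEFAULT_LAMBDA",
    "gen_counts",
    "gen_ratio_series",
    "gen_initial_shape",
]

# default condition grid mirrors the 3 shocks x 4 micelle doses of the
# stimulus table; p1 increases with dC_A, lambda with dC_V
DEFAULT_P1 = {
    (25.0, 0.5): 0.06, (25.0, 1.0): 0.12, (25.0, 2.5): 0.35, (25.0, 5.0): 0.70,
    (50.0, 0.5): 0.07, (50.0, 1.0): 0.15, (50.0, 2.5): 0.45, (50.0, 5.0): 0.80,
    (100.0, 0.5): 0.073, (100.0, 1.0): 0.18, (100.0, 2.5): 0.55, (100.0, 5.0): 0.885,
}
DEFAULT_LAMBDA = {25.0: 0.37, 50.0: 0.60, 100.0: 0.97}


@dataclass
class CountGeneratorParams:
    """Parameters of the compartment-count generator.

    p1 maps condition (dC_V mM, dC_A mM) -> probability of >= 1
    compartment; lam maps dC_V -> conditional zero-truncated Poisson mean.
    """

    p1: dict = field(default_factory=lambda: dict(DEFAULT_P1))
    lam: dict = field(default_factory=lambda: dict(DEFAULT_LAMBDA))
    replicates: int = 5
    vesicles_per_replicate: int = 300
    seed: int = 0

    def __post_init__(self):
        for v in self.p1.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("p1 values must lie in [0, 1]")
        for v in self.lam.values():
            if v <= 0:
                raise ValueError("lambda values must be > 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class SeriesGeneratorParams:
    """Parameters of the intensity-ratio series generator."""

    rate_per_h: float = 0.0388
    initial_ratio: float = 36.3
    times_h: tuple = tuple(np.linspace(0.0, 24.0, 9))
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.rate_per_h < 0:
            raise ValueError("rate must be >= 0")
        if self.initial_ratio <= 0:
            raise ValueError("initial ratio must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _sample_ztp(rng, lam, size):
    """Zero-truncated Poisson via resampling of zeros."""
    out = rng.poisson(lam, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def gen_counts(params: CountGeneratorParams) -> pd.DataFrame:
    """Per-vesicle compartment counts over the condition grid.

    Columns: dcv_mM, dca_mM, replicate, n_compartments.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for (dcv, dca), p1 in sorted(params.p1.items()):
        lam = params.lam.get(dcv)
        if lam is None:
            raise ValueError(f"no lambda for dC_V = {dcv}")
        for rep in range(params.replicates):
            n = params.vesicles_per_replicate
            counts = np.zeros(n, dtype=int)
            has = rng.random(n) < p1
            if has.any():
                counts[has] = _sample_ztp(rng, lam, int(has.sum()))
            rows.append(pd.DataFrame({
                "dcv_mM": dcv, "dca_mM": dca, "replicate": rep,
                "n_compartments": counts,
            }))
    return pd.concat(rows, ignore_index=True)


def gen_ratio_series(params: SeriesGeneratorParams) -> pd.DataFrame:
    """Intensity-ratio decay r0*exp(-k t) with multiplicative log-normal
    noise; columns time_h, ratio."""
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.times_h, dtype=float)
    ratio = params.initial_ratio * np.exp(-params.rate_per_h * t)
    if params.noise_sigma > 0:
        ratio = ratio * np.exp(rng.normal(0.0, params.noise_sigma, t.size))
    return pd.DataFrame({"time_h": t, "ratio": ratio})


def gen_initial_shape(mode: str = "sphere", amplitude: float = 0.0,
                      seed: int = 0, marker_count: int = 64,
                      diameter: float = 1.0) -> AxisymShape:
    """Initial contour for the membrane simulation.

    "sphere": exact sphere of the given diameter (um).
    "prolate": 3:2 prolate spheroid of equal volume.
    "perturbed_sphere": sphere with a low-order axisymmetric perturbation
    rho(u) = R*(1 + sum a_l P_l(cos u)), the Legendre amplitudes a_l
    (l = 2..5) drawn from the seeded generator and scaled to `amplitude`.
    "dimpled_sphere": deterministic oblate-side seed rho = R*(1 - a*(P2 +
    0.35*P3)), the descending direction of the deflation instability for
    negative spontaneous curvature; the small odd component lets one pole
    lead.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    R = diameter / 2.0
    u = np.linspace(0.0, np.pi, marker_count)
    if mode == "sphere":
        rho = np.full_like(u, R)
    elif mode == "prolate":
        s = (2.0 / 3.0) ** (1.0 / 3.0)
        return AxisymShape(np.column_stack([
            R * s * np.sin(u), -1.5 * R * s * np.cos(u)]))
    elif mode == "dimpled_sphere":
        xg = np.cos(u)
        pert = -(legval(xg, [0, 0, 1]) + 0.35 * legval(xg, [0, 0, 0, 1]))
        scale = amplitude / max(np.max(np.abs(pert)), 1e-12)
        rho = R * (1.0 + scale * pert)
    elif mode == "perturbed_sphere":
        rng = np.random.default_rng(seed)
        coeffs = np.zeros(6)
        raw = rng.uniform(0.5, 1.0, size=4) * rng.choice([-1.0, 1.0], size=4)
        coeffs[2:] = raw
        x = np.cos(u)
        pert = legval(x, coeffs)
        scale = amplitude / max(np.max(np.abs(pert)), 1e-12) if amplitude else 0.0
        rho = R * (1.0 + scale * pert)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    markers = np.column_stack([rho * np.sin(u), -rho * np.cos(u)])
    try:
        return AxisymShape(markers)
    except InvalidShapeError as exc:
        raise InvalidShapeError(
            f"perturbation amplitude {amplitude} produced an invalid "
            f"contour") from exc
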