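"""Shape classification and (growth rate, osmotic shock) phase scans.

The morphology vocabulary follows the observed transformation sequence of
osmotically deflated, growing vesicles: sphere -> prolate/oblate ->
stomatocyte (an inner cavity open through a wide mouth) -> invaginated
(cavity nearly closed off by a narrow neck), with multiple disjoint
cavities possible at low bending modulus and weak spontaneous curvature.

Cavity detection works on the generating contour: an inner cavity exists
iff some plane normal to the symmetry axis cuts the full cross-section in
four or more points, which for the pole-to-pole contour means the axial
coordinate z(s) is non-monotonic.  Cavities are counted as interior
extrema of z(s) with prominence above a fraction of the equivalent
radius, which distinguishes genuine inversions from discretization
wiggles.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .shapes import AxisymShape

__all__ = [
    "MorphologyLabel",
    "ClassifyThresholds",
    "PhaseScanResult",
    "reduced_volume",
    "cavity_metrics",
    "classify",
    "phase_scan",
    "VESICULATED_LABELS",
]


class MorphologyLabel(str, enum.Enum):
    sphere = "sphere"
    prolate = "prolate"
    oblate = "oblate"
    stomatocyte = "stomatocyte"
    invaginated = "invaginated"
    multi_invaginated = "multi_invaginated"
    pre_pinch = "pre_pinch"


VESICULATED_LABELS = frozenset({
    MorphologyLabel.stomatocyte,
    MorphologyLabel.invaginated,
    MorphologyLabel.multi_invaginated,
    MorphologyLabel.pre_pinch,
})


@dataclass
class ClassifyThresholds:
    """Tunable decision thresholds for classify().

    sphere_nu : reduced volume above which a cavity-free shape is a sphere
    neck_fraction : neck radius below this fraction of the equivalent
        radius upgrades a stomatocyte to "invaginated"
    cavity_depth_fraction : minimum inversion depth (prominence of an
        interior extremum of z(s)) as a fraction of the equivalent radius
    """

    sphere_nu: float = 0.98
    neck_fraction: float = 0.15
    cavity_depth_fraction: float = 0.15


def reduced_volume(shape: AxisymShape) -> float:
    """nu = 6*sqrt(pi)*V*A^(-3/2); 1 for a sphere, < 1 otherwise."""
    return float(6.0 * np.sqrt(np.pi) * shape.volume / shape.area ** 1.5)


def max_plane_crossings(markers: np.ndarray, n_levels: int = 200) -> int:
    """Largest number of contour crossings of any plane z = const.

    Counted on the half-plane contour; the full cross-section doubles it.
    """
    z = markers[:, 1]
    lo, hi = z.min(), z.max()
    levels = np.linspace(lo, hi, n_levels + 2)[1:-1]
    sign = np.sign(z[None, :] - levels[:, None])
    crossings = np.sum(np.abs(np.diff(sign, axis=1)) > 0, axis=1)
    return int(crossings.max(initial=0))


def cavity_metrics(markers: np.ndarray,
                   thresholds: ClassifyThresholds | None = None):
    """Count inner cavities and measure the narrowest neck.

    Returns (n_cavities, neck_radius_um or None).  Cavities are interior
    extrema of z(s) with prominence above cavity_depth_fraction * R_eq;
    the neck radius is the smallest opening radius among fold points and
    interior local minima of r(s).
    """
    th = thresholds or ClassifyThresholds()
    r = markers[:, 0]
    z = markers[:, 1]
    from .shapes import enclosed_volume

    v = abs(float(enclosed_volume(markers)))
    r_eq = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
    prom = th.cavity_depth_fraction * r_eq

    peaks_max, _ = find_peaks(z, prominence=prom)
    peaks_min, _ = find_peaks(-z, prominence=prom)
    folds = np.sort(np.concatenate([peaks_max, peaks_min]))
    n_cav = folds.size
    if n_cav == 0:
        return 0, None

    neck_candidates = list(r[folds])
    r_necks, _ = find_peaks(-r[1:-1], prominence=0.05 * r_eq)
    if r_necks.size:
        neck_candidates.extend(r[1:-1][r_necks])
    return int(n_cav), float(min(neck_candidates))


def classify(shape: AxisymShape,
             thresholds: ClassifyThresholds | None = None) -> MorphologyLabel:
    """Deterministic morphology label for a contour.

    sphere if nu > sphere_nu with no cavity; prolate/oblate by polar vs
    equatorial extent; stomatocyte/invaginated by cavity presence and neck
    width; multi_invaginated for two or more disjoint cavities.
    """
    th = thresholds or ClassifyThresholds()
    m = shape.markers
    n_cav, neck = cavity_metrics(m, th)

    if n_cav == 0:
        if reduced_volume(shape) > th.sphere_nu:
            return MorphologyLabel.sphere
        polar_extent = m[:, 1].max() - m[:, 1].min()
        equatorial_extent = 2.0 * m[:, 0].max()
        if polar_extent > equatorial_extent:
            return MorphologyLabel.prolate
        return MorphologyLabel.oblate

    if n_cav >= 2:
        return MorphologyLabel.multi_invaginated
    if neck is not None and neck <= th.neck_fraction * shape.equivalent_radius:
        return MorphologyLabel.invaginated
    return MorphologyLabel.stomatocyte


# ---------------------------------------------------------------------------
# phase scan
# ---------------------------------------------------------------------------

@dataclass
class PhaseScanResult:
    """Grid of final morphologies over (gamma, dc).

    labels[i, j] is the final label for gamma_values[i], dc_values[j];
    failed cells carry None and an entry in errors.
    """

    gamma_values: np.ndarray
    dc_values: np.ndarray
    labels: np.ndarray
    reduced_volumes: np.ndarray
    n_invaginations: np.ndarray
    errors: dict = field(default_factory=dict)

    def threshold_gamma(self, dc: float) -> float:
        """Smallest gamma whose cell vesiculated at this dc; inf if none."""
        j = int(np.argmin(np.abs(self.dc_values - dc)))
        for i, g in enumerate(self.gamma_values):
            lab = self.labels[i, j]
            if lab is not None and lab in VESICULATED_LABELS:
                return float(g)
        return float("inf")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gamma_values):
            for j, dc in enumerate(self.dc_values):
                lab = self.labels[i, j]
                rows.append({
                    "gamma_per_s": g,
                    "delta_c_mM": dc,
                    "label": lab.value if lab is not None else "error",
                    "reduced_volume": self.reduced_volumes[i, j],
                    "n_invaginations": self.n_invaginations[i, j],
                })
        return pd.DataFrame(rows)


def phase_scan(gamma_values, dc_values, params, env, config,
               thresholds: ClassifyThresholds | None = None,
               initial_shape: AxisymShape | None = None) -> PhaseScanResult:
    """simulate + classify on each (gamma, dc) grid cell.

    Axes must be strictly increasing.  A failed cell is recorded and the
    scan continues.
    """
    from dataclasses import replace

    from .mechanics import simulate
    from .synth import gen_initial_shape

    gammas = np.asarray(gamma_values, dtype=float)
    dcs = np.asarray(dc_values, dtype=float)
    if np.any(np.diff(gammas) <= 0) or np.any(np.diff(dcs) <= 0):
        raise ValueError("grid axes must be strictly increasing")
    if np.any(gammas < 0):
        raise ValueError("growth rates must be non-negative")

    if initial_shape is None:
        # negative spontaneous curvature makes the inward (oblate) side of
        # the deflation instability the descending one; seed it
        # deterministically so every cell follows the same branch family
        mode = ("dimpled_sphere" if params.spontaneous_curvature < 0
                else "perturbed_sphere")
        initial_shape = gen_initial_shape(
            mode, amplitude=0.02, seed=config.seed,
            marker_count=config.marker_count)

    shape = (gammas.size, dcs.size)
    labels = np.empty(shape, dtype=object)
    nus = np.full(shape, np.nan)
    ninv = np.zeros(shape, dtype=int)
    errors = {}

    for i, g in enumerate(gammas):
        for j, dc in enumerate(dcs):
            p = replace(params, area_growth_rate=float(g))
            e = replace(env, osmolarity_difference=float(dc))
            try:
                traj = simulate(initial_shape, p, e, config)
                final = traj.final_shape
                if traj.status == "pre_pinch":
                    labels[i, j] = MorphologyLabel.pre_pinch
                else:
                    labels[i, j] = classify(final, thresholds)
                nus[i, j] = reduced_volume(final)
                n_cav, _ = cavity_metrics(final.markers, thresholds)
                ninv[i, j] = n_cav
            except Exception as exc:  # failure is per-cell, scan continues
                labels[i, j] = None
                errors[(float(g), float(dc))] = repr(exc)

    return PhaseScanResult(gammas, dcs, labels, nus, ninv, errors)
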