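"""Plan-evaluation computations: DVH parameters and 2D global gamma.

DVH conventions
---------------
``Dq%`` is the dose received by at least q% of the structure volume, i.e.
the (100 - q)th percentile of the masked doses with linear interpolation
between order statistics. ``VxGy`` is the percentage of the volume
receiving at least x Gy (threshold inclusive). The homogeneity index
follows the ICRU-83-style definition HI = (D2% - D98%) / D50%.

Gamma analysis
--------------
2D global gamma: the dose-difference criterion is a percentage of the
maximum of the *reference* distribution; points below the low-dose
threshold (default 10% of that maximum) are excluded. For each scored
point, gamma is minimised over a disc of radius 3x DTA sampled every
DTA/10, with bilinear interpolation of the evaluated distribution at
sub-pixel offsets. gamma <= 1 counts as a pass (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class DoseGrid:
    """Dose values (Gy) on a regular 2D/3D grid."""

    dose: np.ndarray
    spacing_mm: tuple
    prescription_gy: float | None = None

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.float64)
        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing_mm))
        if len(spacing) == 1:
            spacing = spacing * self.dose.ndim
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing_mm must be strictly positive")
        self.spacing_mm = spacing
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")


@dataclass
class StructureMask:
    """Binary region mask congruent with a DoseGrid."""

    mask: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class GammaParams:
    dose_criterion_pct: float = 2.0
    distance_criterion_mm: float = 2.0
    low_dose_threshold_pct_of_max: float = 10.0
    search_radius_factor: float = 3.0
    interp_step_fraction: float = 0.1  # step = DTA * fraction

    def __post_init__(self):
        for v in (self.dose_criterion_pct, self.distance_criterion_mm,
                  self.low_dose_threshold_pct_of_max, self.search_radius_factor,
                  self.interp_step_fraction):
            if v <= 0:
                raise ValueError("GammaParams entries must be strictly positive")


def _masked_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if dose.dose.shape != mask.mask.shape:
        raise ValueError("dose grid and structure mask are not congruent")
    vals = dose.dose[mask.mask]
    if vals.size == 0:
        raise ValueError(f"structure {mask.name!r} is empty")
    return vals


def dvh(dose: DoseGrid, mask: StructureMask, n_bins: int = 1000):
    """Cumulative dose-volume histogram.

    Returns ``(dose_axis_gy, volume_pct)`` where ``volume_pct[i]`` is the
    percentage of the structure receiving at least ``dose_axis_gy[i]``;
    the curve is monotone non-increasing from 100%.
    """
    vals = _masked_doses(dose, mask)
    top = max(float(vals.max()), 1e-12)
    axis = np.linspace(0.0, top, n_bins + 1)
    volume = (vals[None, :] >= axis[:, None]).mean(axis=1) * 100.0
    return axis, volume


def dvh_parameters(dose: DoseGrid, mask: StructureMask, v_gy=(20.0, 10.0, 5.0)) -> dict:
    """Dmean, D2%, D50%, D98%, VxGy (in %) and HI for one structure."""
    vals = _masked_doses(dose, mask)
    d = {f"D{q}": float(np.percentile(vals, 100.0 - q)) for q in (2, 50, 98)}
    out = {
        "Dmean": float(vals.mean()),
        "D2": d["D2"],
        "D50": d["D50"],
        "D98": d["D98"],
    }
    for x in v_gy:
        out[f"V{x:g}Gy"] = float((vals >= x).mean() * 100.0)
    out["HI"] = (d["D2"] - d["D98"]) / d["D50"] if d["D50"] != 0 else float("nan")
    return out


def gamma_2d(ref: DoseGrid, evl: DoseGrid, params: GammaParams | None = None):
    """2D global gamma map and pass rate between two congruent dose planes.

    Returns ``(gamma_map, pass_rate_pct)``; excluded (low-dose) points are
    NaN in the map and do not count toward the pass rate.
    """
    params = params or GammaParams()
    if ref.dose.ndim != 2 or evl.dose.ndim != 2:
        raise ValueError("gamma_2d operates on 2D dose planes")
    if ref.dose.shape != evl.dose.shape or ref.spacing_mm != evl.spacing_mm:
        raise ValueError("reference and evaluated grids must be congruent")

    max_ref = float(ref.dose.max())
    if max_ref <= 0:
        raise ValueError("reference dose is identically zero")
    dd = params.dose_criterion_pct / 100.0 * max_ref
    dta = params.distance_criterion_mm
    include = ref.dose >= params.low_dose_threshold_pct_of_max / 100.0 * max_ref

    sy, sx = ref.spacing_mm[-2], ref.spacing_mm[-1]
    step = dta * params.interp_step_fraction
    radius = params.search_radius_factor * dta
    n_steps = int(np.floor(radius / step))
    offsets_mm = np.arange(-n_steps, n_steps + 1) * step
    ny, nx = ref.dose.shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(np.float64)

    gamma_sq = np.full(ref.dose.shape, np.inf)
    for dy in offsets_mm:
        for dx in offsets_mm:
            r2 = dy * dy + dx * dx
            if r2 > radius * radius:
                continue
            rr = rows + dy / sy
            cc = cols + dx / sx
            inside = (rr >= 0) & (rr <= ny - 1) & (cc >= 0) & (cc <= nx - 1)
            ev = ndimage.map_coordinates(evl.dose, [rr, cc], order=1, mode="nearest")
            dose_term = (ev - ref.dose) / dd
            cand = r2 / (dta * dta) + dose_term * dose_term
            cand = np.where(inside, cand, np.inf)
            np.minimum(gamma_sq, cand, out=gamma_sq)

    gamma_map = np.sqrt(gamma_sq)
    gamma_map[~include] = np.nan
    scored = gamma_map[include]
    pass_rate = float((scored <= 1.0 + 1e-12).mean() * 100.0) if scored.size else float("nan")
    return gamma_map, pass_rate
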