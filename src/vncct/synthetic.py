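"""Synthetic inputs for the whole pipeline: a digital electron-density
phantom, paired CE/VNC patient-like slices with a known additive iodine
model, couch/body fixtures, and toy dose grids.

The phantom emulates a CIRS-style electron-density phantom: a water-
equivalent body disc carrying 15 mm-radius tissue plugs whose per-scanner
mean CT numbers and noise SDs default to measured values for a planning
scanner / dual-layer spectral scanner pair. The paired-slice generator
produces elliptical patient anatomy where iodine enhancement is a known
additive HU perturbation confined to vessel and organ regions, with bone
left untouched — so network residuals can be scored against an exact
ground truth. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dosimetry import DoseGrid, StructureMask
from .image import HU_MIN, CTImage, ROISpec, clamp_hu
from .transfer import DECT_SPACING_MM, PCT_SPACING_MM
from .vncnet import PairedSliceDataset, normalize_hu

#: Measured plug statistics per scanner domain: (planning mean, sd),
#: (spectral mean, sd), (pseudo-spectral mean, sd) for the all-plugs setup.
PHANTOM_PLUGS = [
    ("Lung (Inhale) 1", (-785, 15), (-798, 13), (-792, 13)),
    ("Lung (Inhale) 2", (-799, 12), (-804, 13), (-807, 10)),
    ("Lung (Exhale) 1", (-457, 12), (-461, 10), (-464, 9)),
    ("Lung (Exhale) 2", (-452, 15), (-457, 14), (-458, 11)),
    ("Adipose 1", (-67, 12), (-70, 11), (-73, 10)),
    ("Adipose 2", (-63, 15), (-70, 14), (-68, 12)),
    ("Breast 1", (-31, 15), (-34, 12), (-36, 11)),
    ("Breast 2", (-26, 14), (-35, 13), (-31, 11)),
    ("Muscle 1", (48, 11), (47, 10), (56, 9)),
    ("Muscle 2", (44, 17), (41, 15), (52, 14)),
    ("Liver 1", (57, 11), (56, 11), (66, 10)),
    ("Liver 2", (53, 15), (50, 15), (62, 13)),
    ("Trabecular bone 1", (179, 14), (228, 12), (203, 12)),
    ("Trabecular bone 2", (180, 14), (228, 14), (204, 13)),
    ("Dense bone 1", (833, 17), (929, 15), (933, 17)),
    ("Dense bone 2", (820, 20), (913, 17), (917, 17)),
]

_DOMAIN_COLUMN = {"planning": 1, "dect": 2, "pseudo_dect": 3}


@dataclass
class PhantomSpec:
    """Layout and statistics of the digital phantom.

    ``plugs`` maps plug name -> per-domain (mean, sd); defaults to the
    bundled measured table. ``noise_scale`` multiplies every plug SD
    (0 disables noise).
    """

    plugs: list = field(default_factory=lambda: list(PHANTOM_PLUGS))
    plug_radius_mm: float = 15.0
    roi_radius_mm: float = 12.0  # 80% of the plug radius
    body_radius_mm: float = 130.0
    body_hu: float = 0.0
    body_sd: float = 8.0
    noise_scale: float = 1.0
    n_slices: int = 3
    grid: int = 512
    rng_seed: int = 0
    include_dense_bone: bool = True


def _plug_positions(n: int, outer_r: float, inner_r: float):
    """Plug centres (mm offsets from the body centre): outer then inner ring."""
    n_outer = min(n, 10)
    pos = []
    for i in range(n_outer):
        a = 2 * np.pi * i / n_outer
        pos.append((outer_r * np.cos(a), outer_r * np.sin(a)))
    for i in range(n - n_outer):
        a = 2 * np.pi * i / max(n - n_outer, 1) + np.pi / 6
        pos.append((inner_r * np.cos(a), inner_r * np.sin(a)))
    return pos


def make_digital_phantom(spec: PhantomSpec | None = None, domain: str = "planning"):
    """Render the phantom for one scanner domain.

    Returns ``(CTImage, list of ROISpec)`` — a body disc with tissue plugs
    at the domain's mean HU plus seeded Gaussian noise at the plug SDs, and
    matching circular ROIs (default 12 mm radius over all slices).
    """
    spec = spec or PhantomSpec()
    if domain not in _DOMAIN_COLUMN:
        raise ValueError(f"domain must be one of {sorted(_DOMAIN_COLUMN)}")
    col = _DOMAIN_COLUMN[domain]
    plugs = [p for p in spec.plugs
             if spec.include_dense_bone or not p[0].startswith("Dense bone")]

    spacing = PCT_SPACING_MM if domain == "planning" else DECT_SPACING_MM
    n = spec.grid
    fov = n * spacing
    cx = cy = fov / 2.0
    y_mm = (np.arange(n) + 0.5) * spacing
    x_mm = (np.arange(n) + 0.5) * spacing
    yy, xx = np.meshgrid(y_mm, x_mm, indexing="ij")

    positions = _plug_positions(len(plugs), outer_r=90.0, inner_r=45.0)
    for i, (xa, ya) in enumerate(positions):
        for xb, yb in positions[i + 1:]:
            if np.hypot(xa - xb, ya - yb) < 2 * spec.plug_radius_mm:
                raise ValueError("plug layout overlaps")
        if np.hypot(xa, ya) + spec.plug_radius_mm > spec.body_radius_mm:
            raise ValueError("plug extends outside the body disc")

    rng = np.random.default_rng(spec.rng_seed)
    body = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.body_radius_mm ** 2
    base = np.where(body, spec.body_hu, HU_MIN).astype(np.float64)
    sd_map = np.where(body, spec.body_sd, 0.0)
    rois = []
    for (name, *cols), (px, py) in zip(plugs, positions):
        mean, sd = cols[col - 1]
        plug_mask = (yy - (cy + py)) ** 2 + (xx - (cx + px)) ** 2 <= spec.plug_radius_mm ** 2
        base[plug_mask] = mean
        sd_map[plug_mask] = sd
        rois.append(ROISpec(center_mm=(cx + px, cy + py), radius_mm=spec.roi_radius_mm,
                            slice_range=tuple(range(spec.n_slices)), label=name))

    slices = []
    for _ in range(spec.n_slices):
        noise = rng.normal(0.0, 1.0, base.shape) * sd_map * spec.noise_scale
        slices.append(clamp_hu(base + noise))
    voxels = np.stack(slices) if spec.n_slices > 1 else slices[0]
    spacing_t = (3.0, spacing, spacing) if spec.n_slices > 1 else (spacing, spacing)
    tag = "planning" if domain == "planning" else ("dect" if domain == "dect" else "pseudo_dect")
    return CTImage(voxels=voxels, spacing_mm=spacing_t, domain_tag=tag), rois


# ---------------------------------------------------------------------------
# Paired CE / VNC slices
# ---------------------------------------------------------------------------

@dataclass
class EnhancementModel:
    """Additive iodine-enhancement model.

    Per slice, vessel regions receive a dHU drawn uniformly from
    ``vessel_delta_range`` (heart/great-vessel regime) and organ regions
    from ``organ_delta_range``; bone regions receive exactly 0 (the
    non-contrast ground truth preserves bone).
    """

    vessel_delta_range: tuple = (110.0, 250.0)
    organ_delta_range: tuple = (30.0, 120.0)
    rng_seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.vessel_delta_range, self.organ_delta_range):
            if lo < 0 or hi < lo:
                raise ValueError("enhancement ranges must satisfy 0 <= lo <= hi")


def _ellipse(yy, xx, cy, cx, ry, rx):
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_paired_ce_vnc(n_slices: int, enh: EnhancementModel | None = None,
                       geometry_seed: int = 0, size: int = 128,
                       noise_sd: float = 10.0, smooth_sigma: float = 1.0):
    """Generate paired contrast-enhanced / non-contrast slices.

    Each slice holds an elliptical body (soft tissue), two lung fields,
    an abdominal organ blob, rib-like bone nodules, and two mediastinal
    vessels. The non-contrast slice is the base anatomy; the enhanced slice
    adds the drawn dHU inside vessel/organ regions (sharp-edged, so the
    returned masks partition the enhancement exactly); independent Gaussian
    noise is then added to both.

    Returns ``(PairedSliceDataset, truth)`` where ``truth`` maps
    ``vessel``/``organ``/``bone``/``body`` to ``(n, size, size)`` boolean
    stacks, the drawn deltas to ``vessel_delta``/``organ_delta``, and the
    noise-free HU slices to ``vnc_clean``/``ce_clean`` (for residual
    scoring against exact ground truth).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    enh = enh or EnhancementModel()
    rng_geo = np.random.default_rng(geometry_seed)
    rng_enh = np.random.default_rng(enh.rng_seed)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    ce, vnc = [], []
    clean_ce, clean_vnc = [], []
    masks = {k: [] for k in ("vessel", "organ", "bone", "body")}
    vessel_deltas, organ_deltas = [], []
    for _ in range(n_slices):
        cy, cx = size / 2 + rng_geo.uniform(-3, 3), size / 2 + rng_geo.uniform(-3, 3)
        ry, rx = size * rng_geo.uniform(0.34, 0.42), size * rng_geo.uniform(0.40, 0.47)
        body = _ellipse(yy, xx, cy, cx, ry, rx)
        base = np.where(body, 40.0, HU_MIN)

        lung_r = size * rng_geo.uniform(0.11, 0.15)
        for sign in (-1, 1):
            lung = _ellipse(yy, xx, cy - 0.25 * ry, cx + sign * 0.45 * rx,
                            lung_r, lung_r * 0.8) & body
            base[lung] = -800.0

        organ = _ellipse(yy, xx, cy + 0.35 * ry, cx - 0.15 * rx,
                         size * rng_geo.uniform(0.08, 0.12),
                         size * rng_geo.uniform(0.10, 0.14)) & body
        base[organ] = 55.0

        # iodine-enhancing blood pool: a cardiac-chamber disc plus a
        # descending-aorta disc (the 110-250 HU regime covers both)
        vessel = np.zeros_like(body)
        ch_r = size * rng_geo.uniform(0.060, 0.090)
        vessel |= _ellipse(yy, xx, cy - 0.15 * ry + rng_geo.uniform(-2, 2),
                           cx + rng_geo.uniform(-3, 3), ch_r, ch_r)
        ao_r = size * rng_geo.uniform(0.030, 0.045)
        vessel |= _ellipse(yy, xx, cy + 0.05 * ry + rng_geo.uniform(-2, 2),
                           cx - 0.18 * rx + rng_geo.uniform(-2, 2), ao_r, ao_r)
        vessel &= body
        base[vessel] = 50.0
        organ &= ~vessel  # enhancement regions are disjoint by construction

        # bone: a vertebral body (large, mostly interior pixels) plus a few
        # rib cross-sections along the posterior margin
        bone = np.zeros_like(body)
        bone |= _ellipse(yy, xx, cy + 0.72 * ry, cx + rng_geo.uniform(-2, 2),
                         size * 0.07, size * 0.07)
        for a in (0.25, 0.75, 1.25, 2.25, 2.75):
            bcy = cy + 0.85 * ry * np.sin(a + np.pi / 2)
            bcx = cx + 0.85 * rx * np.cos(a + np.pi / 2)
            bone |= _ellipse(yy, xx, bcy, bcx, size * 0.025, size * 0.025)
        bone &= body & ~vessel & ~organ
        base[bone] = 700.0

        if smooth_sigma > 0:
            base = ndimage.gaussian_filter(base, smooth_sigma)

        dv = rng_enh.uniform(*enh.vessel_delta_range)
        do = rng_enh.uniform(*enh.organ_delta_range)
        delta = np.zeros_like(base)
        delta[vessel] = dv
        delta[organ] = do
        vessel_deltas.append(dv)
        organ_deltas.append(do)

        vnc_hu = base
        ce_hu = base + delta
        noise = rng_enh.normal(0.0, noise_sd, (2,) + base.shape) if noise_sd > 0 else np.zeros((2,) + base.shape)
        ce.append(clamp_hu(ce_hu + noise[0]))
        vnc.append(clamp_hu(vnc_hu + noise[1]))
        clean_ce.append(clamp_hu(ce_hu))
        clean_vnc.append(clamp_hu(vnc_hu))
        masks["vessel"].append(vessel)
        masks["organ"].append(organ)
        masks["bone"].append(bone)
        masks["body"].append(body)

    dataset = PairedSliceDataset(normalize_hu(np.stack(ce)), normalize_hu(np.stack(vnc)))
    out_masks = {k: np.stack(v) for k, v in masks.items()}
    out_masks["vessel_delta"] = np.asarray(vessel_deltas)
    out_masks["organ_delta"] = np.asarray(organ_deltas)
    out_masks["ce_clean"] = np.stack(clean_ce)
    out_masks["vnc_clean"] = np.stack(clean_vnc)
    return dataset, out_masks


# ---------------------------------------------------------------------------
# Couch fixture and planning-frame patient
# ---------------------------------------------------------------------------

def make_couch_fixture(body_pixels: int = 15000, couch_pixels: int = 4000,
                       seed: int = 0, grid: int = 512, gap_px: int = 6,
                       body_hu: float = 20.0, couch_hu: float = -100.0):
    """A body blob plus a detached couch arc with exact pixel counts.

    The body is the ``body_pixels`` grid points closest (in an elliptical
    metric) to the body centre — a connected, convex-ish blob of exactly
    that size. The couch is an annulus band below the body trimmed to
    ``couch_pixels``. Returns ``(CTImage, truth)`` where ``truth`` holds
    the exact ``body``/``couch`` masks. ``gap_px=0`` fuses couch and body.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:grid, 0:grid].astype(np.float64)
    cy, cx = grid * 0.45 + rng.uniform(-2, 2), grid * 0.5 + rng.uniform(-2, 2)
    metric = ((yy - cy) / 1.0) ** 2 + ((xx - cx) / 1.35) ** 2
    order = np.argsort(metric, axis=None, kind="stable")
    body = np.zeros(grid * grid, dtype=bool)
    body[order[:body_pixels]] = True
    body = body.reshape(grid, grid)

    body_bottom = np.max(np.nonzero(body.any(axis=1))[0])
    # wide shallow arc (large-radius circle) below the body, like a couch shell
    arc_r = grid * 0.55
    arc_cy = body_bottom + gap_px + 12.0 - arc_r
    ring = np.abs(np.hypot(yy - arc_cy, xx - cx) - arc_r)
    width = 10.0
    while True:
        band = (yy > body_bottom + gap_px) & (ring < width)
        if int(band.sum()) >= couch_pixels or width > grid:
            break
        width *= 1.5
    avail = int(band.sum())
    if avail < couch_pixels:
        raise ValueError(f"couch band holds only {avail} px < {couch_pixels}")
    idx = np.argsort(np.where(band, ring, np.inf), axis=None, kind="stable")
    couch = np.zeros(grid * grid, dtype=bool)
    couch[idx[:couch_pixels]] = True
    couch = couch.reshape(grid, grid)
    if (couch & body).any():
        raise ValueError("couch overlaps the body")

    hu = np.full((grid, grid), HU_MIN, dtype=np.float64)
    hu[body] = body_hu
    hu[couch] = couch_hu
    img = CTImage(voxels=hu, spacing_mm=(PCT_SPACING_MM, PCT_SPACING_MM),
                  domain_tag="planning")
    return img, {"body": body, "couch": couch}


def make_planning_patient(seed: int = 0, grid: int = 512, with_arms: bool = True,
                          with_couch: bool = True, smooth_sigma: float = 3.0,
                          site: str = "abdomen"):
    """A smooth patient-like planning-frame slice (700 mm FOV).

    Interior anatomy is Gaussian-smoothed while the body-air boundary stays
    sharp (so it coincides with the couch-removal threshold contour); the
    optional arms sit outside the central 350 mm window and the optional
    couch is a detached arc. ``site='abdomen'`` gives soft-tissue-only
    contrast (liver/kidneys/fat, amplitudes within ~150 HU);
    ``site='thorax'`` adds air-filled lungs, whose steep gradients the
    edge-preserving filter of the forward conversion smooths measurably.
    Returns ``(CTImage, truth_masks)``.
    """
    if site not in ("abdomen", "thorax"):
        raise ValueError("site must be 'abdomen' or 'thorax'")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:grid, 0:grid].astype(np.float64)
    cy, cx = grid / 2 + rng.uniform(-4, 4), grid / 2 + rng.uniform(-4, 4)
    ry, rx = grid * rng.uniform(0.16, 0.19), grid * rng.uniform(0.20, 0.24)
    body = _ellipse(yy, xx, cy, cx, ry, rx)
    inner = np.full((grid, grid), 45.0)
    if site == "thorax":
        for sign in (-1, 1):
            lung = _ellipse(yy, xx, cy - 0.2 * ry, cx + sign * 0.45 * rx,
                            0.5 * ry, 0.35 * rx)
            inner[lung] = -780.0
        inner[_ellipse(yy, xx, cy + 0.4 * ry, cx, 0.3 * ry, 0.35 * rx)] = 60.0
    else:
        # liver and kidneys well inside a uniform soft-tissue background, so
        # the near-rim zone is flat and the rim itself stays sharp
        inner[_ellipse(yy, xx, cy - 0.1 * ry, cx - 0.3 * rx, 0.4 * ry, 0.35 * rx)] = 60.0
        for sign in (-1, 1):
            inner[_ellipse(yy, xx, cy + 0.4 * ry, cx + sign * 0.35 * rx,
                           0.16 * ry, 0.13 * rx)] = 30.0
    if smooth_sigma > 0:
        inner = ndimage.gaussian_filter(inner, smooth_sigma)
    base = np.where(body, inner, HU_MIN)

    arms = np.zeros_like(body)
    if with_arms:
        # 350 mm window = 256 px; arms centred ~190 px from the body centre
        for sign in (-1, 1):
            arm = _ellipse(yy, xx, cy, cx + sign * 190.0, 14.0, 14.0)
            arms |= arm
        base[arms] = 35.0
    couch = np.zeros_like(body)
    if with_couch:
        band = (yy > cy + ry + 15) & (yy < cy + ry + 25) & (np.abs(xx - cx) < rx * 1.1)
        couch = band
        base[couch] = -150.0
    img = CTImage(voxels=base, spacing_mm=(PCT_SPACING_MM, PCT_SPACING_MM),
                  domain_tag="planning")
    return img, {"body": body, "arms": arms, "couch": couch}


# ---------------------------------------------------------------------------
# Toy dose grids
# ---------------------------------------------------------------------------

def make_toy_dose(shape=(64, 64), model: str = "uniform", params: dict | None = None,
                  seed: int = 0, spacing_mm: float = 1.0):
    """Analytic dose fields with known DVH/gamma properties.

    ``model`` is ``uniform`` (params: value), ``ramp`` (params: max, axis)
    or ``gaussian`` (params: amplitude, sigma_mm, center_mm). Returns
    ``(DoseGrid, StructureMask)`` with a full-frame structure.
    """
    params = params or {}
    ny, nx = shape
    if model == "uniform":
        dose = np.full(shape, float(params.get("value", 10.0)))
    elif model == "ramp":
        top = float(params.get("max", 20.0))
        axis = int(params.get("axis", 1))
        ramp = np.linspace(0.0, top, shape[axis])
        dose = np.broadcast_to(ramp if axis == 1 else ramp[:, None], shape).copy()
    elif model == "gaussian":
        amp = float(params.get("amplitude", 10.0))
        sigma = float(params.get("sigma_mm", 10.0))
        cy, cx = params.get("center_mm", (ny * spacing_mm / 2, nx * spacing_mm / 2))
        y = (np.arange(ny) + 0.5) * spacing_mm
        x = (np.arange(nx) + 0.5) * spacing_mm
        yyg, xxg = np.meshgrid(y, x, indexing="ij")
        dose = amp * np.exp(-((yyg - cy) ** 2 + (xxg - cx) ** 2) / (2 * sigma ** 2))
    else:
        raise ValueError(f"unknown dose model {model!r}")
    grid = DoseGrid(dose=dose, spacing_mm=(spacing_mm, spacing_mm))
    mask = StructureMask(mask=np.ones(shape, dtype=bool), name="frame")
    return grid, mask
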