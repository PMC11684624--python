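"""Deterministic planning-CT <-> pseudo-DECT domain transfer.

The forward conversion makes a planning-CT slice look like it came from the
spectral scanner: remove the couch, crop/resample the 700 mm planning frame
onto the 350 mm spectral-scanner grid, smooth with an edge-preserving
bilateral filter, map CT numbers through the piecewise calibration, and add
white Gaussian noise to the spectral scanner's noise level (40 dB SNR on the
0-4095 offset scale). The inverse transfer undoes the calibration, resamples
back to the planning grid, and reinserts the result into a copy of the
original planning image so that everything outside the 350 mm crop window
(e.g. raised arms) is bit-identical to the input.

Every stage is a pure function of (input, parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import PiecewiseCalibration, apply_calibration, invert_calibration
from .image import HU_MIN, BodyMask, CTImage, clamp_hu

#: Spectral-scanner in-plane grid: 512 px spanning exactly 350 mm.
DECT_GRID = 512
DECT_FOV_MM = 350.0
DECT_SPACING_MM = DECT_FOV_MM / DECT_GRID  # 0.68359375, printed as "0.68"

#: Planning-scanner in-plane pixel size (700 mm FOV on a 512 grid).
PCT_SPACING_MM = 1.3672


@dataclass
class DenoiseParams:
    """Bilateral-filter parameters (MATLAB ``imbilatfilt`` convention).

    ``degree_of_smoothing`` is the *variance* of the intensity-range
    Gaussian (HU^2); ``spatial_sigma`` the spatial kernel sigma in pixels.
    The neighbourhood is ``2*ceil(2*spatial_sigma)+1`` pixels square.
    """

    degree_of_smoothing: float = 109.2218
    spatial_sigma: float = 2.0

    def __post_init__(self):
        if self.degree_of_smoothing <= 0 or self.spatial_sigma <= 0:
            raise ValueError("DenoiseParams must be strictly positive")

    @property
    def window(self) -> int:
        return 2 * int(np.ceil(2 * self.spatial_sigma)) + 1


@dataclass
class NoiseModel:
    """Additive white Gaussian noise targeting a given SNR in dB.

    Signal power is the mean squared intensity on the 0-4095 offset scale
    (HU + 1024), so noise variance = P_signal / 10^(snr/10). A target of
    ``None`` or ``inf`` disables the stage.
    """

    target_snr_db: float | None = 40.0
    rng_seed: int = 0

    @property
    def enabled(self) -> bool:
        return self.target_snr_db is not None and np.isfinite(self.target_snr_db)


@dataclass
class CouchRemovalParams:
    """Couch removal by thresholding + connected-component size filtering."""

    air_threshold_hu: float = -430.0
    min_component_pixels: int = 7000
    connectivity: int = 8

    def __post_init__(self):
        if self.min_component_pixels <= 0:
            raise ValueError("min_component_pixels must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class TransferRecord:
    """Provenance needed to invert a forward conversion losslessly.

    ``crop_window`` is ``(row0, col0, size)`` in planning-frame pixels;
    ``original`` keeps the untouched input image so the inverse transfer can
    reinsert the converted region into it.
    """

    crop_window: tuple
    in_spacing_mm: float
    out_spacing_mm: float
    out_shape: tuple
    original: CTImage | None = None
    body_mask: BodyMask | None = None
    params: dict = field(default_factory=dict)

    def map_point_mm(self, xy: tuple) -> tuple:
        """Map an in-plane (x, y) mm position from the planning frame into
        the cropped/resampled output frame."""
        r0, c0, _ = self.crop_window
        x, y = xy
        return (x - c0 * self.in_spacing_mm, y - r0 * self.in_spacing_mm)

    def to_json(self, path) -> None:
        doc = {
            "crop_window": list(self.crop_window),
            "in_spacing_mm": self.in_spacing_mm,
            "out_spacing_mm": self.out_spacing_mm,
            "out_shape": list(self.out_shape),
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def remove_couch(image: CTImage, params: CouchRemovalParams | None = None):
    """Mask out the treatment couch, keeping only the patient body.

    Binarise at the air threshold, label connected components (8-connected
    by default), delete components smaller than ``min_component_pixels``
    (the couch shell), fill internal holes (lungs), and set everything
    outside the surviving mask to -1024 HU.

    Returns ``(image_without_couch, BodyMask)``; raises ``ValueError`` if no
    component survives ("no body found").
    """
    params = params or CouchRemovalParams()
    structure = (np.ones((3, 3)) if params.connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))

    def one_slice(sl):
        binary = sl >= params.air_threshold_hu
        labels, n = ndimage.label(binary, structure=structure)
        if n == 0:
            raise ValueError("no body found: nothing above the air threshold")
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= params.min_component_pixels) + 1
        if keep.size == 0:
            raise ValueError(
                f"no body found: largest component has {int(sizes.max())} px "
                f"< {params.min_component_pixels}"
            )
        mask = np.isin(labels, keep)
        mask = ndimage.binary_fill_holes(mask)
        return mask, keep.size

    if image.ndim == 2:
        mask, ncomp = one_slice(image.voxels)
        mask_arr = mask
    else:
        per = [one_slice(sl) for sl in image.voxels]
        mask_arr = np.stack([m for m, _ in per])
        ncomp = max(c for _, c in per)
    out = np.where(mask_arr, image.voxels, np.float32(HU_MIN))
    return image.with_voxels(out), BodyMask(mask=mask_arr, component_count=int(ncomp), filled=True)


def _resample_plane(plane, row_coords, col_coords):
    rr, cc = np.meshgrid(row_coords, col_coords, indexing="ij")
    return ndimage.map_coordinates(
        plane.astype(np.float64), [rr, cc], order=1, mode="nearest"
    ).astype(np.float32)


def resample_to_dect_frame(pct: CTImage, body_mask: BodyMask | None = None,
                           couch_params: CouchRemovalParams | None = None):
    """Bilinear resample of a planning image onto the spectral-scanner grid.

    A 350 mm square window, centred on the body-mask centroid (clamped to
    the image bounds), is cropped from the planning frame and resampled to
    the 512 x 512 spectral grid. Returns ``(CTImage, TransferRecord)``.
    """
    if body_mask is None:
        _, body_mask = remove_couch(pct, couch_params)
    if body_mask.n_pixels == 0:
        raise ValueError("body mask is empty")
    s_in = pct.inplane_spacing
    win = int(round(DECT_FOV_MM / s_in))  # 256 px at 1.3672 mm
    ny, nx = pct.voxels.shape[-2:]
    r_c, c_c = body_mask.centroid()
    r0 = int(np.clip(round(r_c) - win // 2, 0, max(ny - win, 0)))
    c0 = int(np.clip(round(c_c) - win // 2, 0, max(nx - win, 0)))

    s_out = DECT_SPACING_MM
    # output pixel-centre i maps to input row r0 + ((i+0.5)*s_out)/s_in - 0.5
    idx = np.arange(DECT_GRID)
    rows = r0 + (idx + 0.5) * s_out / s_in - 0.5
    cols = c0 + (idx + 0.5) * s_out / s_in - 0.5

    if pct.ndim == 2:
        out = _resample_plane(pct.voxels, rows, cols)
        spacing = (s_out, s_out)
    else:
        out = np.stack([_resample_plane(sl, rows, cols) for sl in pct.voxels])
        spacing = (pct.spacing_mm[0], s_out, s_out)
    record = TransferRecord(
        crop_window=(r0, c0, win),
        in_spacing_mm=s_in,
        out_spacing_mm=s_out,
        out_shape=out.shape,
        original=pct,
        body_mask=body_mask,
    )
    img = CTImage(voxels=out, spacing_mm=spacing, domain_tag=pct.domain_tag,
                  fov_mm=DECT_FOV_MM)
    return img, record


def bilateral_denoise(image: CTImage, params: DenoiseParams | None = None) -> CTImage:
    """Edge-preserving bilateral smoothing, slice-wise in 2D.

    Weight of neighbour at offset (di, dj) with intensity difference d:
    ``exp(-(di^2+dj^2)/(2*sigma_s^2)) * exp(-d^2/(2*DoS))``, normalised per
    pixel; borders use replicate padding.
    """
    params = params or DenoiseParams()
    half = params.window // 2
    offsets = range(-half, half + 1)
    two_ss2 = 2.0 * params.spatial_sigma ** 2
    two_sr2 = 2.0 * params.degree_of_smoothing

    def one_slice(sl):
        sl = sl.astype(np.float64)
        padded = np.pad(sl, half, mode="edge")
        num = np.zeros_like(sl)
        den = np.zeros_like(sl)
        h, w = sl.shape
        for di in offsets:
            for dj in offsets:
                w_s = np.exp(-(di * di + dj * dj) / two_ss2)
                shifted = padded[half + di:half + di + h, half + dj:half + dj + w]
                diff = shifted - sl
                wgt = w_s * np.exp(-(diff * diff) / two_sr2)
                num += wgt * shifted
                den += wgt
        return (num / den).astype(np.float32)

    if image.ndim == 2:
        return image.with_voxels(one_slice(image.voxels))
    return image.with_voxels(np.stack([one_slice(sl) for sl in image.voxels]))


def add_noise_to_snr(image: CTImage, model: NoiseModel | None = None) -> CTImage:
    """Add seeded white Gaussian noise so the image reaches the target SNR.

    Noise variance is ``mean((HU + 1024)^2) / 10^(snr_db/10)``; the result
    is clamped back to the HU window.
    """
    model = model or NoiseModel()
    if not model.enabled:
        return image.with_voxels(image.voxels.copy())
    rng = np.random.default_rng(model.rng_seed)
    offset = image.voxels.astype(np.float64) + 1024.0
    p_signal = float(np.mean(offset ** 2))
    sigma = np.sqrt(p_signal / 10.0 ** (model.target_snr_db / 10.0))
    noisy = image.voxels + rng.normal(0.0, sigma, size=image.voxels.shape)
    return image.with_voxels(clamp_hu(noisy))


def convert_pct_to_pseudo_dect(
    pct: CTImage,
    calib: PiecewiseCalibration | None = None,
    denoise: DenoiseParams | None = None,
    noise: NoiseModel | None = None,
    couch: CouchRemovalParams | None = None,
    remove_couch_stage: bool = True,
):
    """Full planning-CT -> pseudo-DECT conversion.

    Stage order: couch removal -> resample/crop to the 350 mm spectral grid
    -> bilateral denoise -> piecewise HU calibration -> noise injection.
    Returns ``(pseudo_dect_image, TransferRecord)`` with full provenance.
    """
    calib = calib or PiecewiseCalibration.default()
    denoise = denoise or DenoiseParams()
    noise = noise or NoiseModel()
    couch = couch or CouchRemovalParams()

    if remove_couch_stage:
        body_img, body_mask = remove_couch(pct, couch)
    else:
        body_img, body_mask = pct, None
    resampled, record = resample_to_dect_frame(body_img, body_mask=body_mask,
                                               couch_params=couch)
    record.original = pct  # reinsert into the *untouched* input on inversion
    smoothed = bilateral_denoise(resampled, denoise)
    calibrated = apply_calibration(smoothed, calib)
    final = add_noise_to_snr(calibrated, noise)
    final.domain_tag = "pseudo_dect"
    record.params = {
        "denoise": {"degree_of_smoothing": denoise.degree_of_smoothing,
                    "spatial_sigma": denoise.spatial_sigma},
        "noise": {"target_snr_db": noise.target_snr_db if noise.enabled else None,
                  "rng_seed": noise.rng_seed},
        "couch": {"air_threshold_hu": couch.air_threshold_hu,
                  "min_component_pixels": couch.min_component_pixels,
                  "connectivity": couch.connectivity,
                  "applied": remove_couch_stage},
        "calibration": calib.to_dict(),
    }
    return final, record


def invert_to_planning_ct(vnc_dect: CTImage, record: TransferRecord,
                          calib: PiecewiseCalibration | None = None) -> CTImage:
    """Map a (pseudo) VNC spectral image back into the planning frame.

    Inverts the HU calibration, resamples bilinearly back to the planning
    pixel size, and pastes the result into a copy of the original planning
    image at the recorded crop window; pixels outside the window are
    bit-identical to the original.
    """
    calib = calib or PiecewiseCalibration.default()
    if tuple(vnc_dect.voxels.shape) != tuple(record.out_shape):
        raise ValueError(
            f"geometry mismatch: image shape {vnc_dect.voxels.shape} != "
            f"recorded {tuple(record.out_shape)}"
        )
    if record.original is None:
        raise ValueError("TransferRecord does not carry the original planning image")

    hu = invert_calibration(vnc_dect, calib)
    r0, c0, win = record.crop_window
    s_in, s_out = record.in_spacing_mm, record.out_spacing_mm
    idx = np.arange(win)
    # planning pixel-centre i (within the window) in spectral-grid pixel coords
    coords = (idx + 0.5) * s_in / s_out - 0.5

    def paste(plane_dect, plane_orig):
        block = _resample_plane(plane_dect, coords, coords)
        out = plane_orig.copy()
        out[r0:r0 + win, c0:c0 + win] = block
        return out

    if vnc_dect.ndim == 2:
        out = paste(hu.voxels, record.original.voxels)
    else:
        out = np.stack([paste(sl, osl) for sl, osl in
                        zip(hu.voxels, record.original.voxels)])
    img = record.original.with_voxels(out)
    img.domain_tag = "vnc"
    return img
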