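"""Body-masked image-similarity metrics and paired nonparametric tests.

MSE, PSNR, SSIM and the Pearson correlation coefficient, evaluated over an
optional body mask so that only the patient interior contributes, plus ROI
CT-number reporting and the two-sided Wilcoxon signed-rank test used for
paired ROI comparisons.

By default the metrics operate on whatever scale the images carry; the
network representation is min-max-normalised [0, 1], and ``peakval``
defaults to the maximum of the target image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .image import CTImage, ROISpec
from .calibration import extract_plug_stats

PSNR_INF = float("inf")


@dataclass
class MetricConfig:
    """Constants shared by the similarity metrics.

    ``peakval``: maximal value in the data (None -> max of the target).
    ``data_range``: dynamic range L used for the SSIM stabilising constants
    eps1 = (0.01 L)^2 and eps2 = (0.03 L)^2 (None -> observed range).
    ``ssim_window``: side of the local Gaussian window; None means a single
    global window (the direct formula on the whole masked region).
    """

    peakval: float | None = None
    data_range: float | None = None
    ssim_window: int | None = 7

    @property
    def eps1(self) -> float:
        if self.data_range is None:
            raise ValueError("data_range is unset")
        return (0.01 * self.data_range) ** 2

    @property
    def eps2(self) -> float:
        if self.data_range is None:
            raise ValueError("data_range is unset")
        return (0.03 * self.data_range) ** 2


@dataclass
class ImagePair:
    """Two congruent images plus an optional evaluation mask."""

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape:
            raise ValueError(f"shape mismatch: {self.x.shape} vs {self.y.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.x.shape:
                raise ValueError("mask must be congruent with the images")
            if not self.mask.any():
                raise ValueError("mask selects no pixels")

    def vectors(self):
        if self.mask is None:
            return self.x.ravel(), self.y.ravel()
        return self.x[self.mask], self.y[self.mask]

    @property
    def n_pixels(self) -> int:
        return self.x.size if self.mask is None else int(self.mask.sum())


def mse(pair: ImagePair) -> float:
    """Mean squared difference over the masked pixels."""
    xv, yv = pair.vectors()
    return float(np.mean((yv - xv) ** 2))


def psnr(pair: ImagePair, cfg: MetricConfig | None = None) -> float:
    """10 log10(peakval^2 / MSE); identical images give +inf."""
    cfg = cfg or MetricConfig()
    err = mse(pair)
    peak = cfg.peakval if cfg.peakval is not None else float(np.max(pair.y))
    if peak <= 0:
        raise ValueError("peakval must be > 0")
    if err == 0:
        return PSNR_INF
    return float(10.0 * np.log10(peak * peak / err))


def _ssim_global(xv, yv, eps1, eps2) -> float:
    mx, my = xv.mean(), yv.mean()
    vx, vy = xv.var(), yv.var()
    cov = float(np.mean((xv - mx) * (yv - my)))
    lum = (2 * mx * my + eps1) / (mx * mx + my * my + eps1)
    cs = (2 * cov + eps2) / (vx + vy + eps2)
    return float(lum * cs)


def ssim(pair: ImagePair, cfg: MetricConfig | None = None) -> float:
    """Structural similarity over the masked region.

    With ``ssim_window`` set, the windowed map (Gaussian weights) is
    averaged over the mask; with ``ssim_window=None`` the luminance/
    contrast/structure product is evaluated once on the whole masked
    pixel set.
    """
    cfg = cfg or MetricConfig()
    drange = cfg.data_range
    if drange is None:
        drange = float(max(pair.x.max(), pair.y.max()) - min(pair.x.min(), pair.y.min()))
        if drange == 0:
            drange = 1.0
    if cfg.ssim_window is None:
        xv, yv = pair.vectors()
        return _ssim_global(xv, yv, (0.01 * drange) ** 2, (0.03 * drange) ** 2)
    if min(pair.x.shape[-2:]) < cfg.ssim_window:
        raise ValueError("image smaller than the SSIM window")
    _, smap = structural_similarity(
        pair.x, pair.y, win_size=cfg.ssim_window, data_range=drange,
        gaussian_weights=True, use_sample_covariance=False, full=True,
    )
    if pair.mask is None:
        return float(smap.mean())
    return float(smap[pair.mask].mean())


def pcc(pair: ImagePair) -> float:
    """Pearson correlation over the masked pixels."""
    xv, yv = pair.vectors()
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("undefined correlation: an image is constant on the mask")
    return float(np.corrcoef(xv, yv)[0, 1])


def metric_report(pair: ImagePair, cfg: MetricConfig | None = None) -> dict:
    """All four similarity metrics plus the pixel count, as a dict."""
    cfg = cfg or MetricConfig()
    return {
        "mse": mse(pair),
        "psnr_db": psnr(pair, cfg),
        "ssim": ssim(pair, cfg),
        "pcc": pcc(pair),
        "n_pixels": pair.n_pixels,
    }


def per_slice_report(x, y, mask=None, cfg: MetricConfig | None = None) -> pd.DataFrame:
    """Metrics computed per slice of congruent 3D stacks, plus their mean.

    The alternative aggregation to voxel pooling: each slice contributes
    one value per metric and the ``mean`` row averages them (slices whose
    mask is empty are skipped).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("per_slice_report expects 3D (slice, row, col) stacks")
    rows = []
    for k in range(x.shape[0]):
        m = None if mask is None else np.asarray(mask)[k].astype(bool)
        if m is not None and not m.any():
            continue
        rep = metric_report(ImagePair(x=x[k], y=y[k], mask=m), cfg)
        rep["slice"] = k
        rows.append(rep)
    if not rows:
        raise ValueError("no slice has evaluable pixels")
    df = pd.DataFrame(rows).set_index("slice")
    df.loc["mean"] = df.mean(axis=0)
    return df


def roi_report(images: dict, rois) -> pd.DataFrame:
    """Mean (SD) per ROI per image, plus pairwise mean differences.

    Parameters
    ----------
    images : dict of name -> CTImage (congruent geometry)
    rois : sequence of ROISpec

    Returns a DataFrame indexed by ROI label with ``<name>_mean``,
    ``<name>_sd`` and ``<a>-<b>_diff`` columns, mirroring the layout of a
    per-region CT-number comparison table.
    """
    names = list(images)
    rows = {}
    for name in names:
        stats_ = extract_plug_stats(images[name], rois)
        for st in stats_:
            row = rows.setdefault(st.plug_id, {})
            row[f"{name}_mean"] = st.mean_hu
            row[f"{name}_sd"] = st.sd_hu
            row["n_pixels"] = st.n_pixels
    df = pd.DataFrame.from_dict(rows, orient="index")
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            df[f"{a}-{b}_diff"] = df[f"{a}_mean"] - df[f"{b}_mean"]
    df.index.name = "roi"
    return df


def wilcoxon_signed_rank(a, b) -> tuple:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original treatment), ties are
    mid-ranked; the exact null distribution is used for n <= 25 when there
    are no rank ties, the normal approximation otherwise. All differences
    zero returns ``(0.0, 1.0)`` with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("a and b must be equal-length 1D samples, n >= 1")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        import warnings

        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(ranks)) != len(ranks)
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def roi_comparison_table(images: dict, rois, pairs=None) -> pd.DataFrame:
    """ROI table with Wilcoxon p-values between named image groups.

    ``images`` maps a name to a *list* of CTImages (one per subject);
    ``pairs`` lists ``(name_a, name_b)`` comparisons (default: all pairs).
    Per ROI, each subject contributes its ROI mean; the paired test runs
    across subjects.
    """
    names = list(images)
    n_subjects = {k: len(v) for k, v in images.items()}
    if len(set(n_subjects.values())) != 1:
        raise ValueError(f"image groups differ in size: {n_subjects}")
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    per_roi = {}
    for name in names:
        means = []
        for img in images[name]:
            stats_ = extract_plug_stats(img, rois)
            means.append([s.mean_hu for s in stats_])
        per_roi[name] = np.asarray(means)  # (subjects, rois)
    labels = [r.label or f"roi_{i}" for i, r in enumerate(rois)]
    rows = []
    for j, label in enumerate(labels):
        row = {"roi": label}
        for name in names:
            vals = per_roi[name][:, j]
            row[f"{name}_mean"] = vals.mean()
            row[f"{name}_sd"] = vals.std(ddof=0)
        for a, b in pairs:
            _, p = wilcoxon_signed_rank(per_roi[a][:, j], per_roi[b][:, j])
            row[f"p_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("roi")
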