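"""Two-branch piecewise-linear CT-number calibration between scanner domains.

A planning scanner and a dual-layer spectral scanner assign slightly
different CT numbers to the same material. The cross-calibration used here
is a pair of independent ordinary-least-squares lines relating mean plug CT
numbers of an electron-density phantom imaged on both scanners, split at
0 HU (roughly the water point, where detector response changes regime):

    y = a_neg * x + b_neg   for x <= 0
    y = a_pos * x + b_pos   for x >  0

No continuity constraint is imposed at the boundary: the two branches are
fitted separately and the measured coefficients shipped as defaults are in
fact discontinuous there (a few HU jump), which an enforced joint would
destroy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .image import CTImage, ROISpec, circle_mask

#: Default cross-calibration coefficients (planning scanner -> dual-layer
#: spectral scanner), measured on a CIRS-style electron-density phantom.
DEFAULT_COEFFS = {
    "slope_neg": 1.0021,
    "intercept_neg": -5.3595,
    "slope_pos": 1.1148,
    "intercept_pos": 2.7053,
}


@dataclass
class PlugStats:
    """ROI statistics of one tissue-equivalent plug."""

    plug_id: str
    mean_hu: float
    sd_hu: float
    n_pixels: int
    scanner_tag: str = ""

    def __post_init__(self):
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be > 0")


def extract_plug_stats(image: CTImage, rois, labels=None, scanner_tag: str = "") -> list:
    """Mean/SD of HU over each circular ROI, pooled across its slice range.

    Parameters
    ----------
    image : CTImage
    rois : sequence of ROISpec
    labels : sequence of str, optional
        Plug names in ROI order; defaults to each ROI's own label.
    """
    labels = list(labels) if labels is not None else [r.label or f"roi_{i}" for i, r in enumerate(rois)]
    if len(labels) != len(rois):
        raise ValueError("labels and rois must have equal length")
    out = []
    for label, roi in zip(labels, rois):
        m = circle_mask(image, roi)
        vals = []
        for k in roi.slice_range:
            vals.append(image.get_slice(k)[m])
        vals = np.concatenate(vals)
        if vals.size == 0:
            raise ValueError(f"ROI {label!r} selects no pixels")
        out.append(
            PlugStats(
                plug_id=label,
                mean_hu=float(vals.mean()),
                sd_hu=float(vals.std(ddof=0)),
                n_pixels=int(vals.size),
                scanner_tag=scanner_tag or image.domain_tag,
            )
        )
    return out


def _ols(x: np.ndarray, y: np.ndarray):
    """Slope, intercept and R^2 of an ordinary least-squares line."""
    if x.size < 2:
        raise ValueError(f"branch needs >= 2 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("branch has zero variance in the source values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


class PiecewiseCalibration(BaseEstimator, TransformerMixin):
    """Piecewise-linear HU mapping with a branch boundary at 0 HU.

    The estimator can be fitted to ``(source, target)`` mean-HU pairs or
    instantiated directly from known coefficients (``from_coeffs`` /
    ``default``). ``transform`` maps source-domain HU to target-domain HU;
    ``inverse_transform`` applies the exact algebraic inverse per branch.

    Fitted attributes
    -----------------
    slope_neg_, intercept_neg_ : coefficients of the ``x <= 0`` branch
    slope_pos_, intercept_pos_ : coefficients of the ``x > 0`` branch
    r2_neg_, r2_pos_ : per-branch coefficients of determination

    Notes
    -----
    Target values falling in the discontinuity gap between the two forward
    branch images (for the default coefficients, ``(-5.3595, 2.7053]``) are
    mapped back to 0 HU, the closest pre-image boundary; this keeps the
    inverse monotone and affects only a handful of integer HU values.
    """

    def __init__(self, boundary_hu: float = 0.0):
        self.boundary_hu = boundary_hu

    # -- construction ---------------------------------------------------

    @classmethod
    def from_coeffs(cls, slope_neg, intercept_neg, slope_pos, intercept_pos,
                    boundary_hu: float = 0.0, r2_neg=None, r2_pos=None) -> "PiecewiseCalibration":
        if slope_neg <= 0 or slope_pos <= 0:
            raise ValueError("both slopes must be > 0 for an invertible calibration")
        model = cls(boundary_hu=boundary_hu)
        model.slope_neg_ = float(slope_neg)
        model.intercept_neg_ = float(intercept_neg)
        model.slope_pos_ = float(slope_pos)
        model.intercept_pos_ = float(intercept_pos)
        model.r2_neg_ = r2_neg
        model.r2_pos_ = r2_pos
        return model

    @classmethod
    def default(cls) -> "PiecewiseCalibration":
        """The bundled planning-scanner -> spectral-scanner calibration."""
        return cls.from_coeffs(**DEFAULT_COEFFS)

    # -- sklearn surface ------------------------------------------------

    def fit(self, X, y):
        """Fit both branches by independent OLS on (source, target) pairs.

        Parameters
        ----------
        X : array-like, shape (n,) or (n, 1)
            Source-domain mean HU values.
        y : array-like, shape (n,)
            Target-domain mean HU values.
        """
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have equal length")
        neg = x <= self.boundary_hu
        self.slope_neg_, self.intercept_neg_, self.r2_neg_ = _ols(x[neg], y[neg])
        self.slope_pos_, self.intercept_pos_, self.r2_pos_ = _ols(x[~neg], y[~neg])
        if self.slope_neg_ <= 0 or self.slope_pos_ <= 0:
            raise ValueError("fitted calibration is not strictly increasing on each branch")
        return self

    def _check_fitted(self):
        if not hasattr(self, "slope_neg_"):
            raise AttributeError("calibration is not fitted; call fit() or use default()")

    def transform(self, X):
        """Map source-domain HU to target-domain HU, element-wise."""
        self._check_fitted()
        x = np.asarray(X, dtype=np.float64)
        neg = x <= self.boundary_hu
        out = np.where(
            neg,
            self.slope_neg_ * x + self.intercept_neg_,
            self.slope_pos_ * x + self.intercept_pos_,
        )
        return out if out.ndim else float(out)

    def inverse_transform(self, Y):
        """Exact per-branch inverse; gap values map to the boundary (0 HU)."""
        self._check_fitted()
        y = np.asarray(Y, dtype=np.float64)
        y_neg_max = self.slope_neg_ * self.boundary_hu + self.intercept_neg_
        y_pos_min = self.slope_pos_ * self.boundary_hu + self.intercept_pos_
        x_neg = (y - self.intercept_neg_) / self.slope_neg_
        x_pos = (y - self.intercept_pos_) / self.slope_pos_
        out = np.where(y <= y_neg_max, x_neg, np.where(y > y_pos_min, x_pos, self.boundary_hu))
        return out if out.ndim else float(out)

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "slope_neg": self.slope_neg_,
            "intercept_neg": self.intercept_neg_,
            "slope_pos": self.slope_pos_,
            "intercept_pos": self.intercept_pos_,
            "boundary_hu": self.boundary_hu,
            "r2_neg": getattr(self, "r2_neg_", None),
            "r2_pos": getattr(self, "r2_pos_", None),
            "provenance": "vncct piecewise HU calibration",
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PiecewiseCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls.from_coeffs(
            d["slope_neg"], d["intercept_neg"], d["slope_pos"], d["intercept_pos"],
            boundary_hu=d.get("boundary_hu", 0.0),
            r2_neg=d.get("r2_neg"), r2_pos=d.get("r2_pos"),
        )


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def fit_piecewise_calibration(pairs) -> PiecewiseCalibration:
    """Fit a calibration from ``(source_mean_hu, target_mean_hu)`` pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    return PiecewiseCalibration().fit(arr[:, 0], arr[:, 1])


def apply_calibration(image_or_value, model: PiecewiseCalibration):
    """Apply the forward HU mapping to a scalar, array or CTImage."""
    if isinstance(image_or_value, CTImage):
        return image_or_value.with_voxels(model.transform(image_or_value.voxels))
    return model.transform(image_or_value)


def invert_calibration(image_or_value, model: PiecewiseCalibration):
    """Apply the inverse HU mapping to a scalar, array or CTImage."""
    if isinstance(image_or_value, CTImage):
        return image_or_value.with_voxels(model.inverse_transform(image_or_value.voxels))
    return model.inverse_transform(image_or_value)
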