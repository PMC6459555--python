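"""Empty-field background calibration and cell masking.

Cell-containing regions are found by fitting a Gaussian to the intensity
distribution of a smoothed green-channel z-stack acquired from an empty
field, then assigning to the cells every voxel of the (identically
smoothed) sample stack whose upper-tail background probability is below
``alpha`` (default 1e-5). The mask is cleaned by removing small connected
components (debris specks) and zeroing planes classified out of focus.

The tail test is one-sided and upper: fluorescence foreground is strictly
brighter than the empty-field background, so p(background) for a voxel of
intensity v is P(X >= v) under Normal(mu_bg, sigma_bg). Masking via the
per-voxel p-value is exactly equivalent to the closed-form intensity
cutoff mu_bg + z_{1-alpha} * sigma_bg, which is what the implementation
uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .errors import (
    DegenerateModelError,
    InvalidInputError,
    InvalidParameterError,
    NotReadyError,
)
from .stacks import CellMask, ImageStack

DEFAULT_ALPHA = 1e-5
DEFAULT_SMOOTHING_SIGMA = (1.0, 2.0, 2.0)  # (z, y, x) voxels
DEFAULT_MIN_SPECK_VOXELS = 100_000


def smooth_stack(stack: ImageStack, sigma) -> ImageStack:
    """Gaussian-filter a stack (per-axis sigma, voxels); sigma 0 is the identity."""
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if sigma.size == 1:
        sigma = np.repeat(sigma, 3)
    if sigma.size != 3 or (sigma < 0).any():
        raise InvalidParameterError(f"sigma must be 3 nonnegative values, got {sigma}")
    if np.all(sigma == 0):
        return stack.copy_with(stack.voxels.copy())
    out = ndi.gaussian_filter(stack.voxels.astype(np.float32), sigma=sigma, mode="nearest")
    return stack.copy_with(out)


@dataclass
class BackgroundModel:
    """Gaussian background fit plus the tail-probability mask rule."""

    mu_bg: float
    sigma_bg: float
    alpha: float = DEFAULT_ALPHA
    smoothing_sigma: tuple = DEFAULT_SMOOTHING_SIGMA

    def __post_init__(self) -> None:
        if self.sigma_bg <= 0:
            raise DegenerateModelError("sigma_bg must be > 0")
        if not (0.0 < self.alpha < 0.5):
            raise InvalidParameterError("alpha must be in (0, 0.5)")

    @property
    def threshold(self) -> float:
        """Closed-form intensity cutoff mu + z_{1-alpha} * sigma."""
        return self.mu_bg + stats.norm.isf(self.alpha) * self.sigma_bg

    def p_background(self, values: np.ndarray) -> np.ndarray:
        """Upper-tail probability of each intensity under the background fit."""
        return stats.norm.sf(values, loc=self.mu_bg, scale=self.sigma_bg)


def fit_background_gaussian(
    empty_field: ImageStack,
    smoothing_sigma=DEFAULT_SMOOTHING_SIGMA,
    alpha: float = DEFAULT_ALPHA,
    robust: bool = False,
) -> BackgroundModel:
    """Fit Normal(mu, sigma) to smoothed empty-field voxel intensities.

    Sample mean/SD by default (method of moments = the Gaussian MLE); the
    robust option uses median and 1.4826*MAD for calibration fields that
    may contain stray debris.
    """
    if empty_field.voxels.size < 1000:
        raise InvalidInputError("empty field must contain at least 10^3 voxels")
    smoothed = smooth_stack(empty_field, smoothing_sigma).voxels.ravel()
    if robust:
        mu = float(np.median(smoothed))
        sigma = float(1.4826 * np.median(np.abs(smoothed - mu)))
    else:
        mu = float(smoothed.mean())
        sigma = float(smoothed.std())
    if sigma <= 0:
        raise DegenerateModelError("zero-variance empty field: background tail undefined")
    sm = tuple(np.atleast_1d(np.asarray(smoothing_sigma, dtype=float)).tolist())
    return BackgroundModel(mu_bg=mu, sigma_bg=sigma, alpha=alpha, smoothing_sigma=sm)


def compute_cell_mask(stack: ImageStack, model: BackgroundModel) -> CellMask:
    """Mask voxels with p(background) < alpha, via the closed-form cutoff.

    ``stack`` must already be smoothed with ``model.smoothing_sigma`` (the
    calibration and sample stacks are filtered identically).
    """
    if not np.all(np.isfinite(stack.voxels)):
        raise InvalidInputError("stack contains non-finite intensities")
    mask = stack.voxels > model.threshold
    return CellMask(
        mask,
        provenance={
            "mu_bg": model.mu_bg,
            "sigma_bg": model.sigma_bg,
            "alpha": model.alpha,
            "threshold": model.threshold,
            "filters": [],
        },
    )


def remove_small_specks(
    mask: CellMask, min_voxels: int = DEFAULT_MIN_SPECK_VOXELS, connectivity: int = 3
) -> CellMask:
    """Delete 3D connected components smaller than ``min_voxels`` (strict <).

    26-connectivity by default. Components of exactly ``min_voxels`` are
    retained, matching the strict "< 100,000 voxel" debris rule.
    """
    structure = ndi.generate_binary_structure(3, connectivity)
    labels, n = ndi.label(mask.mask, structure=structure)
    if n == 0:
        cleaned = mask.mask.copy()
    else:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_voxels
        keep[0] = False
        cleaned = keep[labels]
    prov = dict(mask.provenance)
    prov.setdefault("filters", [])
    prov["filters"] = list(prov["filters"]) + [f"specks<{min_voxels}"]
    return CellMask(cleaned, provenance=prov)


# ---------------------------------------------------------------------------
# Out-of-focus plane filtering


def plane_features(mask: CellMask, stack: ImageStack) -> np.ndarray:
    """Per-plane focus features: masked fraction, mean in-mask intensity, mean |gradient|.

    Planes with an empty mask get zero mean in-mask intensity.
    """
    nz = stack.shape[0]
    feats = np.zeros((nz, 3), dtype=float)
    for z in range(nz):
        m = mask.mask[z]
        plane = stack.voxels[z].astype(float)
        frac = m.mean()
        mean_in = plane[m].mean() if m.any() else 0.0
        gy, gx = np.gradient(plane)
        grad = float(np.hypot(gy, gx).mean())
        feats[z] = (frac, mean_in, grad)
    return feats


class FocusClassifier:
    """Per-plane in-focus/out-of-focus decision.

    Two modes: a linear max-margin classifier (standardized features +
    LinearSVC) trained on labeled synthetic planes, or a rule-based
    fallback that calls a plane out of focus when its masked-voxel
    fraction falls below ``f_min`` (default 1e-3). The original plane
    filter's features and training data live in external prior work, so
    this classifier is trained on this package's own synthetic scenes.
    """

    def __init__(self, mode: str = "svm", f_min: float = 1e-3):
        if mode not in ("svm", "rule"):
            raise InvalidParameterError(f"unknown focus-classifier mode {mode!r}")
        self.mode = mode
        self.f_min = f_min
        self._pipeline = None

    @classmethod
    def rule_based(cls, f_min: float = 1e-3) -> "FocusClassifier":
        return cls(mode="rule", f_min=f_min)

    @property
    def trained(self) -> bool:
        return self._pipeline is not None

    def fit(self, features: np.ndarray, in_focus: np.ndarray) -> "FocusClassifier":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import LinearSVC

        self._pipeline = make_pipeline(StandardScaler(), LinearSVC(C=1.0))
        self._pipeline.fit(np.asarray(features), np.asarray(in_focus, dtype=int))
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        """True = in focus."""
        features = np.asarray(features)
        if self.mode == "rule":
            return features[:, 0] >= self.f_min
        if not self.trained:
            raise NotReadyError("focus classifier not trained and rule fallback not selected")
        return self._pipeline.predict(features).astype(bool)


def filter_out_of_focus_planes(
    mask: CellMask, stack: ImageStack, classifier: FocusClassifier
):
    """Zero the mask on planes the classifier calls out of focus.

    Returns ``(filtered_mask, decisions)`` where decisions is a per-plane
    DataFrame logging the feature vector and the call.
    """
    feats = plane_features(mask, stack)
    in_focus = classifier.predict(feats)
    out = mask.mask.copy()
    out[~in_focus] = False
    decisions = pd.DataFrame(
        {
            "plane": np.arange(stack.shape[0]),
            "masked_fraction": feats[:, 0],
            "mean_in_mask_intensity": feats[:, 1],
            "mean_gradient": feats[:, 2],
            "in_focus": in_focus,
        }
    )
    prov = dict(mask.provenance)
    prov.setdefault("filters", [])
    prov["filters"] = list(prov["filters"]) + ["focus"]
    return CellMask(out, provenance=prov), decisions


__all__ = [
    "DEFAULT_ALPHA", "DEFAULT_SMOOTHING_SIGMA", "DEFAULT_MIN_SPECK_VOXELS",
    "BackgroundModel", "smooth_stack", "fit_background_gaussian",
    "compute_cell_mask", "remove_small_specks",
    "plane_features", "FocusClassifier", "filter_out_of_focus_planes",
]
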