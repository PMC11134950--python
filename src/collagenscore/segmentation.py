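"""Gaussian-mixture segmentation of SHG images into collagen and background.

The intensity histogram of an SHG tile is modelled as a mixture of Gaussians
(default two: dim background, bright collagen).  Pixels are assigned to the
component with the highest posterior probability; every component except the
dimmest one counts as collagen.  With two components this is equivalent to a
single intensity threshold at the posterior crossing, but the mixture fit
chooses that threshold from the data rather than from a fixed rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .synthetic import MAX_INTENSITY

__all__ = ["IntensityImage", "CollagenMask", "GMMModel",
           "fit_gmm", "segment_collagen", "read_image"]


@dataclass
class IntensityImage:
    """A 2D 12-bit SHG tile with optional physical pixel size (length/px)."""
    pixels: np.ndarray
    pixel_size: float | None = None
    id: str | None = None

    def validate(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or min(px.shape) < 16:
            raise ValueError("image must be 2D with both dimensions >= 16")
        if px.min() < 0 or px.max() > MAX_INTENSITY:
            raise ValueError(f"pixel values must lie in [0, {MAX_INTENSITY}]")


@dataclass
class CollagenMask:
    mask: np.ndarray
    source_id: str | None = None


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, IntensityImage):
        return np.asarray(image.pixels)
    return np.asarray(image)


def _as_mask(mask) -> np.ndarray:
    if isinstance(mask, CollagenMask):
        return np.asarray(mask.mask, dtype=bool)
    return np.asarray(mask, dtype=bool)


@dataclass
class GMMModel:
    """Fitted intensity mixture, components sorted by ascending mean."""
    n_components: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    converged: bool
    seed: int

    def posterior_log_prob(self, values: np.ndarray) -> np.ndarray:
        """Unnormalised per-component log posterior at each intensity."""
        v = np.asarray(values, dtype=float)[..., None]
        return (np.log(self.weights)
                + norm.logpdf(v, self.means, np.sqrt(self.variances)))

    def predict_component(self, values: np.ndarray) -> np.ndarray:
        """Maximum-posterior component index (0 = dimmest)."""
        return np.argmax(self.posterior_log_prob(values), axis=-1)


def fit_gmm(image, n_components: int = 2, seed: int = 0,
            tol: float = 1e-4, max_iter: int = 200) -> GMMModel:
    """Fit a Gaussian mixture to the flattened intensity distribution.

    EM is initialised by k-means with a fixed seed, so identical
    (image, seed) pairs give identical models.  Components are reported
    sorted by ascending mean.

    Raises
    ------
    ValueError
        If the image is constant (a mixture over intensities is degenerate)
        or ``n_components`` < 2.
    """
    px = _as_pixels(image)
    if isinstance(image, IntensityImage):
        image.validate()
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    flat = px.reshape(-1, 1).astype(float)
    if np.unique(flat).size < 2:
        raise ValueError("degenerate input: constant image, cannot separate "
                         "collagen from background")
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         tol=tol, max_iter=max_iter, n_init=1,
                         init_params="kmeans", random_state=seed)
    gm.fit(flat)
    if not gm.converged_:
        warnings.warn("EM did not converge within max_iter; model returned "
                      "with converged=False", RuntimeWarning)
    order = np.argsort(gm.means_.ravel())
    return GMMModel(
        n_components=n_components,
        means=gm.means_.ravel()[order],
        variances=gm.covariances_.reshape(n_components)[order],
        weights=gm.weights_[order],
        converged=bool(gm.converged_),
        seed=seed,
    )


def segment_collagen(image, model: GMMModel,
                     min_object_px: int = 5) -> np.ndarray:
    """Maximum-posterior collagen mask.

    Foreground is the union of all components except the lowest-mean
    (background) one.  Objects smaller than ``min_object_px`` pixels are
    removed (set 0 to disable); this stabilises fiber tracing against
    single-pixel noise.
    """
    px = _as_pixels(image)
    if px.ndim != 2:
        raise ValueError("image must be 2D")
    # posterior depends only on intensity: classify each distinct value once
    values, inverse = np.unique(px, return_inverse=True)
    fg_value = model.predict_component(values) > 0
    mask = fg_value[inverse].reshape(px.shape)
    if min_object_px > 0 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_object_px)
        mask &= ~np.isin(labels, small[small > 0])
    return mask


def read_image(path) -> np.ndarray:
    """Read a grayscale TIFF/PNG as a 2D integer array."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile
        arr = tifffile.imread(path)
    else:
        from PIL import Image
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel image: {path}")
    return arr
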