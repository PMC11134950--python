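"""The eight collagen morphological features.

Per region of interest (ROI):

==== ======================================= =========================
fea1 collagen proportionate area              fraction of pixels [0, 1]
fea2 fiber number                             count per tile
fea3 mean fiber length                        px
fea4 mean fiber width                         px
fea5 mean fiber straightness                  (0, 1]
fea6 cross-link density                       cross-links per fiber
fea7 mean cross-link spacing                  px (geodesic, along fiber)
fea8 orientation / alignment index            [0, 1]
==== ======================================= =========================

A feature that is undefined for an ROI (no fibers, fewer than two
cross-links on any fiber, constant image) is NaN, never zero: zero-filling
would bias patient means toward "less collagen" where the pipeline simply
found nothing to measure.  Patient-level values are unweighted arithmetic
means over the ROIs where the feature is defined.

fea8 is the axial order parameter of the FFT angular power distribution:
R = |sum_theta p(theta) exp(2i*theta)| / sum_theta p(theta), computed over a
band-limited annulus of the centred power spectrum with the DC term
removed.  Doubling the angle makes the statistic insensitive to the 180-deg
ambiguity of fiber direction; R = 1 for perfectly parallel fibers, R -> 0
for an isotropic scene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

from .network import FiberNetwork, Skeleton
from .segmentation import _as_mask

__all__ = ["FeatureVector", "PatientFeatures", "FEATURE_NAMES",
           "area_fraction", "fiber_count", "fiber_length_mean",
           "fiber_width_mean", "fiber_straightness_mean",
           "crosslink_density", "crosslink_spacing_mean",
           "orientation_index", "compute_feature_vector",
           "aggregate_patient"]

FEATURE_NAMES = [f"fea{i}" for i in range(1, 9)]


@dataclass
class FeatureVector:
    fea1: float = np.nan
    fea2: float = np.nan
    fea3: float = np.nan
    fea4: float = np.nan
    fea5: float = np.nan
    fea6: float = np.nan
    fea7: float = np.nan
    fea8: float = np.nan

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])

    def validate(self) -> None:
        a = self.to_array()
        def ok(v, lo, hi):
            return np.isnan(v) or lo <= v <= hi
        checks = [
            ok(a[0], 0, 1), a[1] >= 0 or np.isnan(a[1]),
            ok(a[2], 0, np.inf), ok(a[3], 0, np.inf),
            np.isnan(a[4]) or 0 < a[4] <= 1 + 1e-9,
            ok(a[5], 0, np.inf), ok(a[6], 0, np.inf), ok(a[7], 0, 1 + 1e-9),
        ]
        if not all(checks):
            raise ValueError(f"feature vector violates range invariants: {a}")


@dataclass
class PatientFeatures:
    patient_id: str
    roi_features: list
    aggregate: FeatureVector


def area_fraction(mask) -> float:
    """fea1: fraction of pixels classified as collagen."""
    m = _as_mask(mask)
    return float(m.mean())


def fiber_count(network: FiberNetwork, pixel_size: float | None = None,
                per_mm2: bool = False) -> float:
    """fea2: number of retained fibers (optionally per mm^2 when the
    physical pixel size, in micrometres, is known)."""
    n = float(len(network.fibers))
    if per_mm2:
        if pixel_size is None:
            raise ValueError("per-area fiber count requires pixel_size")
        area_mm2 = network.image_area * (pixel_size / 1000.0) ** 2
        return n / area_mm2
    return n


def fiber_length_mean(network: FiberNetwork) -> float:
    """fea3: mean fiber path length (px); NaN for an empty network."""
    if not network.fibers:
        return np.nan
    return float(np.mean([f.path_length for f in network.fibers]))


def fiber_width_mean(network: FiberNetwork, skel: Skeleton = None) -> float:
    """fea4: mean fiber width (px), from the distance transform sampled
    along each fiber; NaN for an empty network."""
    if not network.fibers:
        return np.nan
    return float(np.mean([f.mean_width for f in network.fibers]))


def fiber_straightness_mean(network: FiberNetwork) -> float:
    """fea5: mean endpoint-distance / path-length over fibers, in (0, 1].

    Closed loops (coincident endpoints, straightness 0) are excluded with a
    warning since the ratio is meaningless for them.
    """
    if not network.fibers:
        return np.nan
    vals = [f.straightness() for f in network.fibers]
    kept = [v for v in vals if v > 0]
    if len(kept) < len(vals):
        warnings.warn(f"excluded {len(vals) - len(kept)} closed-loop "
                      "fiber(s) from straightness", RuntimeWarning)
    return float(np.mean(kept)) if kept else np.nan


def crosslink_density(network: FiberNetwork) -> float:
    """fea6: cross-links per fiber; NaN for an empty network."""
    if not network.fibers:
        return np.nan
    return len(network.crosslinks) / len(network.fibers)


def _crosslink_positions_on_fiber(fiber, members: dict) -> list:
    """Along-fiber path positions of the cross-links the fiber touches.

    Consecutive vertices in the same cross-link cluster collapse to one
    position (the mean of the run).
    """
    verts = np.asarray(fiber.vertices, dtype=float)
    steps = np.r_[0.0, np.sqrt((np.diff(verts, axis=0) ** 2).sum(axis=1))]
    arc = np.cumsum(steps)
    positions = []
    run_cluster, run_pos = None, []
    for i, v in enumerate(map(tuple, fiber.vertices)):
        cid = members.get(v)
        if cid is not None and cid == run_cluster:
            run_pos.append(arc[i])
        else:
            if run_pos:
                positions.append((run_cluster, float(np.mean(run_pos))))
            run_cluster, run_pos = cid, ([arc[i]] if cid is not None else [])
    if run_pos:
        positions.append((run_cluster, float(np.mean(run_pos))))
    # collapse repeat visits of the same cluster at distant arc positions
    return [p for _, p in positions]


def crosslink_spacing_mean(network: FiberNetwork) -> float:
    """fea7: mean geodesic gap between consecutive cross-links along a
    fiber, pooled over all fibers with >= 2 cross-links; NaN if none."""
    gaps = []
    for fiber in network.fibers:
        pos = _crosslink_positions_on_fiber(fiber, network.crosslink_members)
        if len(pos) >= 2:
            gaps.extend(np.diff(sorted(pos)))
    return float(np.mean(gaps)) if gaps else np.nan


def orientation_index(image_or_mask, r_min: float | None = None,
                      r_max: float | None = None) -> float:
    """fea8: axial order parameter of the FFT angular power distribution.

    The power spectrum is centred and restricted to an annulus of radii
    ``[r_min, r_max]``, by default 3% and 25% of the smaller image
    dimension.  The inner cut removes the DC term and the near-DC
    frequencies whose angular resolution is too coarse to carry
    orientation; the outer cut drops the high frequencies dominated by
    edge pixelation, which are isotropic and would dilute the index.  The
    annulus lies inside the inscribed disc so every direction is sampled
    equally.  Returns NaN for a constant input.
    """
    a = np.asarray(image_or_mask, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2D array")
    if np.ptp(a) == 0:
        return np.nan
    f = np.fft.fftshift(np.fft.fft2(a - a.mean()))
    power = np.abs(f) ** 2
    h, w = a.shape
    rows = np.arange(h) - h // 2
    cols = np.arange(w) - w // 2
    vv, uu = np.meshgrid(rows, cols, indexing="ij")
    r = np.hypot(vv, uu)
    if r_min is None:
        r_min = max(3.0, 0.03 * min(h, w))
    if r_max is None:
        r_max = 0.25 * min(h, w)
    band = (r >= r_min) & (r <= r_max)
    p = power[band]
    total = p.sum()
    if total <= 0:
        return np.nan
    theta = np.arctan2(vv[band], uu[band])
    z = np.sum(p * np.exp(2j * theta)) / total
    return float(np.abs(z))


def compute_feature_vector(image, mask, network: FiberNetwork,
                           skel: Skeleton,
                           orientation_source: str = "mask") -> FeatureVector:
    """Assemble fea1..fea8 for one ROI.

    ``orientation_source`` selects the input of the FFT alignment index:
    ``"mask"`` (default; intensity-scale invariant) or ``"intensity"``.
    Undefined components propagate as NaN.
    """
    if orientation_source not in ("mask", "intensity"):
        raise ValueError(f"unknown orientation_source {orientation_source!r}")
    m = _as_mask(mask)
    fea8_input = m.astype(float) if orientation_source == "mask" \
        else np.asarray(image, dtype=float)
    fv = FeatureVector(
        fea1=area_fraction(m),
        fea2=fiber_count(network),
        fea3=fiber_length_mean(network),
        fea4=fiber_width_mean(network, skel),
        fea5=fiber_straightness_mean(network),
        fea6=crosslink_density(network),
        fea7=crosslink_spacing_mean(network),
        fea8=orientation_index(fea8_input),
    )
    fv.validate()
    return fv


def aggregate_patient(roi_features: list,
                      patient_id: str = "") -> PatientFeatures:
    """Average ROI feature vectors into one per-patient vector.

    Per feature, the mean is taken over the ROIs where it is defined; the
    patient-level value is NaN only when the feature is missing in every
    ROI.  An empty ROI list is an error.
    """
    if not roi_features:
        raise ValueError("at least one ROI is required")
    stack = np.vstack([fv.to_array() for fv in roi_features])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        agg = np.nanmean(stack, axis=0)
    return PatientFeatures(
        patient_id=patient_id,
        roi_features=list(roi_features),
        aggregate=FeatureVector(*agg),
    )
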