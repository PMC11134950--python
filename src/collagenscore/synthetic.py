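"""Synthetic SHG-like fibrous images and simulated survival cohorts.

Second-harmonic-generation (SHG) microscopy of tumour stroma shows fibrillar
collagen as bright curvilinear structures on a dim background.  This module
draws such scenes with a known ground truth (centerlines, widths, crossings,
orientations) so that every downstream morphometric can be checked against
the generating parameters, and simulates patient cohorts whose overall
survival follows a proportional-hazards model on the eight collagen features
plus the usual clinical covariates.

All generators are pure functions of their spec (which carries the seed):
the same spec always yields byte-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FiberSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_fiber_image",
    "generate_cohort",
    "write_image",
    "write_ground_truth",
    "CLINICAL_PREVALENCES",
    "CLINICAL_COVARIATE_COLUMNS",
]

MAX_INTENSITY = 4095  # 12-bit detector

#: Marginal frequencies of the clinical covariates in a PDAC resection cohort,
#: used as sampling probabilities for simulated patients.
CLINICAL_PREVALENCES = {
    "age_gt50": 0.805,
    "male": 0.631,
    "tnm_high": 0.584,          # stage >= IIB
    "differentiation": (0.188, 0.416, 0.396),  # grades I, II, III
    "pni": 0.765,               # perineural invasion
    "lvi": 0.161,               # lymphovascular invasion
    "location": (0.718, 0.248, 0.034),  # head, body/tail, other
}

CLINICAL_COVARIATE_COLUMNS = [
    "age_group", "sex", "tnm", "differentiation", "pni", "lvi", "location",
]

FEATURE_COLUMNS = [f"fea{i}" for i in range(1, 9)]


@dataclass(frozen=True)
class FiberSpec:
    """Parameters of a synthetic fibrous scene.

    Fibers are smoothed random-walk polylines (step ~2 px, per-step heading
    perturbation with standard deviation ``waviness`` radians) dilated to the
    sampled width.  Orientations are axial (period 180 deg) and drawn from a
    von Mises distribution with concentration ``orientation_kappa``; kappa=0
    is isotropic, large kappa approaches perfect alignment.
    """

    n_fibers: int
    length_mean: float = 120.0
    length_sd: float = 20.0
    width_mean: float = 5.0
    width_sd: float = 1.0
    waviness: float = 0.1
    orientation_mean: float = 90.0
    orientation_kappa: float = 2.0
    crossing_allowed: bool = True
    fg_intensity_mean: float = 1500.0
    bg_intensity_mean: float = 150.0
    noise_sd: float = 80.0
    seed: int = 0
    shape: tuple[int, int] = (512, 512)

    def validate(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.length_mean <= 0:
            raise ValueError("length_mean must be > 0")
        if self.width_mean < 1:
            raise ValueError("width_mean must be >= 1")
        if self.waviness < 0:
            raise ValueError("waviness must be >= 0")
        if not (0.0 <= self.orientation_mean < 180.0):
            raise ValueError("orientation_mean must lie in [0, 180)")
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be >= 0")
        if self.fg_intensity_mean <= self.bg_intensity_mean:
            raise ValueError(
                "fg_intensity_mean must exceed bg_intensity_mean")
        for name in ("fg_intensity_mean", "bg_intensity_mean"):
            v = getattr(self, name)
            if not (0 <= v <= MAX_INTENSITY):
                raise ValueError(f"{name} must lie in [0, {MAX_INTENSITY}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.shape) < 16:
            raise ValueError("image dimensions must be >= 16")


@dataclass
class GroundTruth:
    """What was actually drawn: the oracle for the morphometric pipeline."""

    fiber_centerlines: list  # list of (k, 2) float arrays, (row, col)
    fiber_widths: list       # drawn width per fiber, px
    true_mask: np.ndarray    # boolean foreground
    true_crossings: list     # (row, col) tuples where centerlines intersect
    true_orientations: list  # drawn base orientation per fiber, degrees

    def to_json(self) -> str:
        return json.dumps({
            "fiber_centerlines": [c.tolist() for c in self.fiber_centerlines],
            "fiber_widths": list(map(float, self.fiber_widths)),
            "true_crossings": [list(map(int, c)) for c in self.true_crossings],
            "true_orientations": list(map(float, self.true_orientations)),
            "shape": list(self.true_mask.shape),
        })


def _sample_axial_orientation(rng: np.random.Generator,
                              mean_deg: float, kappa: float) -> float:
    """Draw an axial orientation in [0, 180) from a von Mises on 2*theta."""
    if np.isinf(kappa):
        return mean_deg % 180.0
    angle = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa)
    return (np.rad2deg(angle) / 2.0) % 180.0


def _walk_centerline(rng: np.random.Generator, start: np.ndarray,
                     heading: float, length: float, waviness: float,
                     shape: tuple[int, int], step: float = 2.0) -> np.ndarray:
    """Random-walk polyline of total path length ~``length`` starting at
    ``start`` with initial ``heading`` (radians, image convention: row grows
    with sin, col with cos).  Stops early at the image border."""
    n_steps = max(2, int(round(length / step)))
    pts = [start.astype(float)]
    h = heading
    for _ in range(n_steps):
        if waviness > 0:
            h += rng.normal(0.0, waviness)
        nxt = pts[-1] + step * np.array([np.sin(h), np.cos(h)])
        if not (1 <= nxt[0] <= shape[0] - 2 and 1 <= nxt[1] <= shape[1] - 2):
            break
        pts.append(nxt)
    return np.array(pts)


def _rasterize_centerline(centerline: np.ndarray,
                          shape: tuple[int, int]) -> np.ndarray:
    """Boolean image of the pixels traversed by the polyline."""
    from skimage.draw import line as _line
    out = np.zeros(shape, dtype=bool)
    pix = np.rint(centerline).astype(int)
    for a, b in zip(pix[:-1], pix[1:]):
        rr, cc = _line(a[0], a[1], b[0], b[1])
        out[rr, cc] = True
    return out


def _thicken(centerline_mask: np.ndarray, width: float) -> np.ndarray:
    """Dilate a 1-px centerline to the requested width via the distance
    transform (stadium-shaped caps): pixels within width/2 of the
    rasterized centerline are foreground."""
    if not centerline_mask.any():
        return centerline_mask.copy()
    d = ndimage.distance_transform_edt(~centerline_mask)
    return d <= max(0.0, width / 2.0)


def generate_fiber_image(spec: FiberSpec) -> tuple[np.ndarray, GroundTruth]:
    """Draw a synthetic SHG tile and its ground truth.

    Returns
    -------
    image : uint16 array of ``spec.shape``, values in [0, 4095]
    truth : :class:`GroundTruth`
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)

    mask = np.zeros(shape, dtype=bool)
    centerline_union = np.zeros(shape, dtype=bool)
    centerlines: list[np.ndarray] = []
    widths: list[float] = []
    orientations: list[float] = []
    crossings: list[tuple[int, int]] = []

    placed = 0
    attempts = 0
    max_attempts = 500 * max(1, spec.n_fibers)
    while placed < spec.n_fibers:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place all fibers without crossings; "
                "reduce n_fibers or allow crossings")
        theta = _sample_axial_orientation(
            rng, spec.orientation_mean, spec.orientation_kappa)
        length = max(8.0, rng.normal(spec.length_mean, spec.length_sd))
        width = max(1.0, rng.normal(spec.width_mean, spec.width_sd))
        heading = np.deg2rad(theta)
        direction = np.array([np.sin(heading), np.cos(heading)])
        margin = width / 2.0 + 2.0
        # centre the straight-line extent inside the image so the drawn
        # length is not clipped at the border
        lo = np.full(2, margin) + np.abs(direction) * length / 2.0
        hi = np.array(shape) - 1 - lo
        if np.any(hi <= lo):
            lo = np.full(2, margin)
            hi = np.array(shape) - 1 - margin
        center = rng.uniform(lo, hi)
        start = center - direction * length / 2.0
        start = np.clip(start, 1, np.array(shape) - 2)

        centerline = _walk_centerline(
            rng, start, heading, length, spec.waviness, shape)
        if len(centerline) < 3:
            continue
        cl_mask = _rasterize_centerline(centerline, shape)
        fiber_mask = _thicken(cl_mask, width)

        if not spec.crossing_allowed:
            # enforce a 2-px clearance so fibers stay individually traceable
            clearance = ndimage.binary_dilation(
                fiber_mask, structure=np.ones((5, 5), bool))
            if (clearance & mask).any():
                continue
        else:
            # record where this centerline meets previously drawn ones
            touch = ndimage.binary_dilation(cl_mask) & centerline_union
            if touch.any():
                lab, n = ndimage.label(
                    ndimage.binary_dilation(touch), structure=np.ones((3, 3)))
                for com in ndimage.center_of_mass(touch, lab, range(1, n + 1)):
                    crossings.append((int(round(com[0])), int(round(com[1]))))

        mask |= fiber_mask
        centerline_union |= cl_mask
        centerlines.append(centerline)
        widths.append(width)
        orientations.append(theta)
        placed += 1

    image = np.full(shape, spec.bg_intensity_mean, dtype=float)
    image[mask] = spec.fg_intensity_mean
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, shape)
    image = np.clip(np.rint(image), 0, MAX_INTENSITY).astype(np.uint16)

    truth = GroundTruth(
        fiber_centerlines=centerlines,
        fiber_widths=widths,
        true_mask=mask,
        true_crossings=crossings,
        true_orientations=orientations,
    )
    return image, truth


def write_image(path, image: np.ndarray) -> None:
    """Write a 16-bit grayscale TIFF (values stay <= 4095)."""
    import tifffile
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint16))


def write_ground_truth(path, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated survival cohort.

    Event times follow an exponential proportional-hazards model:
    hazard_i = baseline_hazard * exp(lp_i), with lp_i the linear predictor
    over the eight collagen features (``feature_betas``) and any clinical
    effects (``clinical_betas``, keyed by indicator name, e.g. ``tnm_high``).
    Censoring is independent uniform on [0, T_max] with T_max tuned so the
    realised censoring fraction approximates ``censoring_rate``.
    """

    n_patients: int
    rois_per_patient: int = 1
    feature_means: tuple = (0.3, 40.0, 80.0, 6.0, 0.9, 0.8, 40.0, 0.3)
    feature_sds: tuple = (0.1, 10.0, 15.0, 1.0, 0.05, 0.3, 10.0, 0.1)
    feature_betas: tuple = (0.0,) * 8
    clinical_betas: tuple = ()  # pairs (indicator_name, beta)
    baseline_hazard: float = 0.05  # events per month
    censoring_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if len(self.feature_means) != 8 or len(self.feature_sds) != 8:
            raise ValueError("feature_means and feature_sds must have length 8")
        if len(self.feature_betas) != 8:
            raise ValueError("feature_betas must have length 8")


def _sample_clinical(rng: np.random.Generator, n: int) -> pd.DataFrame:
    p = CLINICAL_PREVALENCES
    diff = rng.choice(["I", "II", "III"], size=n, p=p["differentiation"])
    loc = rng.choice(["head", "body-tail", "other"], size=n, p=p["location"])
    return pd.DataFrame({
        "age_group": np.where(rng.random(n) < p["age_gt50"], ">50", "<=50"),
        "sex": np.where(rng.random(n) < p["male"], "male", "female"),
        "tnm": np.where(rng.random(n) < p["tnm_high"], ">=IIB", "<=IIA"),
        "differentiation": diff,
        "pni": np.where(rng.random(n) < p["pni"], "yes", "no"),
        "lvi": np.where(rng.random(n) < p["lvi"], "yes", "no"),
        "location": loc,
    })


def clinical_indicators(clinical: pd.DataFrame) -> pd.DataFrame:
    """0/1 design columns for the clinical covariates (reference levels:
    age <=50, female, TNM <=IIA, differentiation I, no PNI, no LVI, head)."""
    return pd.DataFrame({
        "age_gt50": (clinical["age_group"] == ">50").astype(float),
        "male": (clinical["sex"] == "male").astype(float),
        "tnm_high": (clinical["tnm"] == ">=IIB").astype(float),
        "diff_II": (clinical["differentiation"] == "II").astype(float),
        "diff_III": (clinical["differentiation"] == "III").astype(float),
        "pni": (clinical["pni"] == "yes").astype(float),
        "lvi": (clinical["lvi"] == "yes").astype(float),
        "loc_body_tail": (clinical["location"] == "body-tail").astype(float),
        "loc_other": (clinical["location"] == "other").astype(float),
    }, index=clinical.index)


def _tune_censoring_tmax(event_times: np.ndarray, uniforms: np.ndarray,
                         rate: float) -> float:
    """Find T_max such that censoring times C = u * T_max (u ~ U(0,1))
    censor approximately the requested fraction of the drawn event times.
    The censored fraction is monotone decreasing in T_max, so bisect."""
    lo, hi = 1e-6, float(event_times.max()) * 10 + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(uniforms * mid < event_times))
        if frac > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a patient cohort.

    Returns a DataFrame with columns ``patient_id``, ``fea1``..``fea8``, the
    clinical covariates, ``os_months`` and ``event`` (1 = death observed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    feats = rng.normal(np.asarray(spec.feature_means),
                       np.asarray(spec.feature_sds), size=(n, 8))
    clinical = _sample_clinical(rng, n)
    indicators = clinical_indicators(clinical)

    lp = feats @ np.asarray(spec.feature_betas, dtype=float)
    for name, beta in spec.clinical_betas:
        if name not in indicators.columns:
            raise ValueError(f"unknown clinical indicator {name!r}")
        lp = lp + beta * indicators[name].to_numpy()

    rates = spec.baseline_hazard * np.exp(lp)
    event_times = rng.exponential(1.0 / rates)

    if spec.censoring_rate > 0:
        u = rng.random(n)
        tmax = _tune_censoring_tmax(event_times, u, spec.censoring_rate)
        censor_times = u * tmax
        os_months = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        os_months = event_times
        event = np.ones(n, dtype=int)

    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    for j, col in enumerate(FEATURE_COLUMNS):
        df[col] = feats[:, j]
    df = pd.concat([df, clinical], axis=1)
    df["os_months"] = os_months
    df["event"] = event
    return df
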