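"""Detect vesicle-like blobs in tomograms and classify their maturation.

Bright compact features in a water-window tomogram are candidate secretory
granules.  They are found by multi-scale Laplacian-of-Gaussian (LoG)
detection inside a validity mask, pruned by overlap and by a response
threshold tuned on a small labelled set, and then interpreted by matching
each blob's radial LAC profile against a library of simulated profiles:
the coefficient of determination R^2 over the first six radial points scores
the vesicle itself, over fifteen points it also scores the surrounding
cytoplasm, and the best-matching library entry's maturation step assigns the
blob to the immature / transitional / mature class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .xray import LacVolume, RadialProfile, radial_profile

#: Sphere-overlap (IoU) above which the weaker of two detections is dropped.
OVERLAP_IOU = 0.3

N_SHORT = 6  # radial points scoring the vesicle
N_LONG = 15  # radial points including surrounding cytoplasm


@dataclass(frozen=True)
class Blob:
    """One detection: centre in voxel indices, radius in nm, LoG response."""

    center: tuple  # (ix, iy, iz)
    radius_nm: float
    response: float


@dataclass
class VolumeMask:
    """Boolean validity grid with provenance."""

    mask: np.ndarray
    provenance: str = "manual"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


def cylinder_mask(
    shape: tuple,
    axis_point: Sequence[float],
    axis_direction: Sequence[float],
    radius_voxels: float,
    margin_voxels: float = 8.5,
) -> VolumeMask:
    """Exclusion mask for the sample capillary: a cylinder plus margin.

    Voxels within ``radius + margin`` of the cylinder axis are masked out
    (the margin defaults to the middle of the 7-10 voxel range).
    """
    p = np.asarray(axis_point, dtype=float)
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    rel = idx - p
    along = rel @ d
    perp = rel - np.outer(along, d)
    dist = np.linalg.norm(perp, axis=1).reshape(shape)
    keep = dist > (radius_voxels + margin_voxels)
    return VolumeMask(mask=keep, provenance="tube-exclusion")


def _sphere_iou(b1: Blob, b2: Blob, voxel_nm: float) -> float:
    c1 = np.asarray(b1.center, float) * voxel_nm
    c2 = np.asarray(b2.center, float) * voxel_nm
    d = float(np.linalg.norm(c1 - c2))
    r1, r2 = b1.radius_nm, b2.radius_nm
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        inter = 4.0 / 3.0 * np.pi * min(r1, r2) ** 3
    else:
        # lens volume of two intersecting spheres
        inter = (
            np.pi
            * (r1 + r2 - d) ** 2
            * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
            / (12 * d)
        )
    v1 = 4.0 / 3.0 * np.pi * r1**3
    v2 = 4.0 / 3.0 * np.pi * r2**3
    return inter / (v1 + v2 - inter)


def log_responses(volume: LacVolume, scales_nm: Sequence[float]) -> np.ndarray:
    """Scale-normalised negative LoG response stack, one layer per scale.

    Scales are blob radii (nm); the filter sigma is ``r / sqrt(3)`` (the 3D
    scale-selection optimum for a solid sphere).
    """
    from scipy.ndimage import gaussian_laplace

    # remove the mean so the small DC leakage of the truncated LoG kernel
    # cannot masquerade as a response on flat regions
    centred = volume.data - volume.data.mean()
    stack = np.empty((len(scales_nm),) + volume.shape)
    for i, r_nm in enumerate(scales_nm):
        sigma = r_nm / np.sqrt(3.0) / volume.voxel_nm
        stack[i] = -(sigma**2) * gaussian_laplace(centred, sigma, truncate=5.0)
    return stack


def detect_blobs(
    volume: LacVolume,
    mask: VolumeMask | None = None,
    scales_nm: Sequence[float] | None = None,
    threshold: float = 0.0,
) -> list:
    """Multi-scale LoG maxima within the mask, pruned by overlap.

    Local maxima over space and scale with response above ``threshold`` are
    kept; of two detections whose spheres overlap with IoU > 0.3 the
    stronger survives.  Deterministic given its inputs.
    """
    from scipy.ndimage import maximum_filter

    if scales_nm is None:
        scales_nm = np.geomspace(60.0, 260.0, 8)
    scales_nm = np.asarray(scales_nm, dtype=float)
    if len(scales_nm) == 0:
        raise ValueError("at least one scale required")
    if mask is not None and not mask.mask.any():
        raise ValueError("empty mask")

    stack = log_responses(volume, scales_nm)
    footprint = np.ones((3, 3, 3, 3))
    local_max = stack == maximum_filter(stack, footprint=footprint, mode="nearest")
    candidates = np.argwhere(local_max & (stack > threshold))
    blobs = []
    for s, ix, iy, iz in candidates:
        if mask is not None and not mask.mask[ix, iy, iz]:
            continue
        blobs.append(
            Blob(
                center=(int(ix), int(iy), int(iz)),
                radius_nm=float(scales_nm[s]),
                response=float(stack[s, ix, iy, iz]),
            )
        )
    blobs.sort(key=lambda b: (-b.response, b.center))
    kept = []
    for b in blobs:
        if all(_sphere_iou(b, k, volume.voxel_nm) <= OVERLAP_IOU for k in kept):
            kept.append(b)
    return kept


def tune_threshold(
    positive_responses: Sequence[float], negative_responses: Sequence[float]
) -> float:
    """Detection threshold maximising accuracy on a labelled response set.

    A feature is detected when its response is >= the threshold.  Candidate
    thresholds are the observed response values; ties in accuracy are broken
    towards the higher threshold (fewer false positives).
    """
    pos = np.asarray(positive_responses, dtype=float)
    neg = np.asarray(negative_responses, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both labelled classes must be nonempty")
    candidates = np.unique(np.concatenate([pos, neg]))
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = ((pos >= t).sum() + (neg < t).sum()) / (len(pos) + len(neg))
        if acc >= best_acc:  # >= moves ties to the higher threshold
            best_acc, best_t = acc, t
    return float(best_t)


# ---------------------------------------------------------------------------
# Profile fitting
# ---------------------------------------------------------------------------

class DegenerateProfileError(ValueError):
    """Raised when the experimental profile has zero variance (R^2 undefined)."""


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination of ``predicted`` against ``observed``."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("length mismatch between profiles")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    # constant profiles leave only floating-point dust in the total variance
    if ss_tot <= 1e-18 * max(1.0, float(np.sum(observed**2))):
        raise DegenerateProfileError("constant experimental profile")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def maturity_class(step: int) -> str:
    if step == 1:
        return "immature"
    if step == 6:
        return "mature"
    return "transitional"


@dataclass
class FitResult:
    """Best library match for one blob."""

    blob: Blob
    entry_id: str
    r2_short: float
    r2_long: float
    maturity: str
    error: str = ""


def _resample(profile: RadialProfile, radii_nm: np.ndarray) -> np.ndarray:
    return np.interp(radii_nm, profile.radii_nm, np.nan_to_num(profile.values))


def fit_blob(
    experimental: RadialProfile,
    library: Sequence[tuple],
    blob: Blob | None = None,
    n_short: int = N_SHORT,
    n_long: int = N_LONG,
) -> FitResult:
    """Match an experimental radial profile against the simulated library.

    ``library`` is a sequence of ``(entry, profile)`` where ``entry`` has a
    ``maturation_step`` attribute.  Library profiles are resampled onto the
    experimental radii; the best entry maximises R^2 over the first
    ``n_short`` bins, ties broken by the ``n_long``-bin score.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    n_long = min(n_long, len(experimental.values))
    obs_long = np.nan_to_num(experimental.values[:n_long])
    obs_short = obs_long[:n_short]
    radii = experimental.radii_nm[:n_long]

    best = None
    for entry, profile in library:
        pred = _resample(profile, radii)
        r2s = r_squared(obs_short, pred[:n_short])
        r2l = r_squared(obs_long, pred)
        key = (r2s, r2l)
        if best is None or key > best[0]:
            best = (key, entry)
    (r2s, r2l), entry = best
    return FitResult(
        blob=blob if blob is not None else Blob((0, 0, 0), 0.0, 0.0),
        entry_id=getattr(entry, "entry_id", str(entry)),
        r2_short=r2s,
        r2_long=r2l,
        maturity=maturity_class(entry.maturation_step),
    )


def blob_profile(
    volume: LacVolume, blob: Blob, n_bins: int = N_LONG + 1,
    center_smooth_voxels: float = 1.0,
) -> RadialProfile:
    """Radial profile of a blob from the central slice through its centre.

    The slice is taken perpendicular to the y axis at the blob's y index and
    recentred on the brightest pixel within the blob radius.  The centre
    search runs on a lightly smoothed copy of the slice so single-voxel
    noise spikes do not displace the profile origin; the profile values come
    from the raw slice.
    """
    from scipy.ndimage import gaussian_filter

    ix, iy, iz = blob.center
    y0, y1 = max(0, iy - 1), min(volume.data.shape[1], iy + 2)
    sl = volume.data[:, y0:y1, :].mean(axis=1)  # 3-slice average tames noise
    search = gaussian_filter(sl, center_smooth_voxels) if center_smooth_voxels else sl
    r_vox = max(1, int(round(blob.radius_nm / volume.voxel_nm)))
    x0, x1 = max(0, ix - r_vox), min(sl.shape[0], ix + r_vox + 1)
    z0, z1 = max(0, iz - r_vox), min(sl.shape[1], iz + r_vox + 1)
    window = search[x0:x1, z0:z1]
    local = np.unravel_index(np.argmax(window), window.shape)
    center = (x0 + local[0], z0 + local[1])
    return radial_profile(sl, voxel_nm=volume.voxel_nm, center=center, n_bins=n_bins)


def classify_map(
    volume: LacVolume,
    mask: VolumeMask | None,
    library: Sequence[tuple],
    scales_nm: Sequence[float] | None = None,
    threshold: float = 0.0,
) -> tuple:
    """Detect, profile and fit every blob in a tomogram.

    Returns ``(results, summary)`` where summary holds per-class counts and
    the mean and standard deviation of the short R^2 scores.
    """
    blobs = detect_blobs(volume, mask, scales_nm, threshold)
    results = []
    for blob in blobs:
        profile = blob_profile(volume, blob)
        try:
            results.append(fit_blob(profile, library, blob=blob))
        except DegenerateProfileError as exc:
            results.append(
                FitResult(
                    blob=blob, entry_id="", r2_short=np.nan, r2_long=np.nan,
                    maturity="unassigned", error=str(exc),
                )
            )
    counts = {"immature": 0, "transitional": 0, "mature": 0, "unassigned": 0}
    for res in results:
        counts[res.maturity] += 1
    r2s = [r.r2_short for r in results if not r.error]
    summary = {
        "counts": counts,
        "r2_mean": float(np.mean(r2s)) if r2s else np.nan,
        "r2_sd": float(np.std(r2s)) if r2s else np.nan,
        "n_blobs": len(results),
    }
    return results, summary


def results_to_tsv(results: Sequence[FitResult], path) -> None:
    import pandas as pd

    rows = [
        {
            "x": r.blob.center[0], "y": r.blob.center[1], "z": r.blob.center[2],
            "radius_nm": r.blob.radius_nm, "response": r.blob.response,
            "entry": r.entry_id, "r2_short": r.r2_short, "r2_long": r.r2_long,
            "class": r.maturity,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
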