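"""End-to-end study conditions for the idealised mature/immature granules.

These functions tie the pipeline together under the reference conditions:
a 320 nm vesicle with a 200 nm (mature) insulin crystal, surrounded by
cytoplasm with an average LAC of 0.35 um^-1, imaged at 37.42 nm voxels.
They are what the command-line demos, the test suite and the acceptance
script all call, so the measured quantities come from one code path.

Problem sizes: the granule volume is embedded in a 181 x 17 x 181 voxel
cytoplasm box (6.8 um wide, 17-voxel thickness as in the library protocol)
rather than the full experimental-map width; the 181-angle tilt series and
10-replicate averaging follow the simulated-imaging protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import SphereSDF, build_granule_model
from .recipe import VesicleGeometry
from .synthetic import PhantomSpec, _Everywhere, analytic_granule_lac
from .util import rng_for
from .xray import (
    LacVolume,
    ProjectionOperator,
    RadialProfile,
    concentration_for_lac,
    membrane_share,
    radial_profile,
    simulate_tomogram,
    voxelize,
)

#: Average cytoplasmic LAC surrounding the idealised vesicles (um^-1).
CYTOPLASM_LAC_UM = 0.35

DEFAULT_NX = 181  # embedding width in voxels (tilt plane)
DEFAULT_NY = 17  # embedding thickness (tilt axis), as in the library boxes

#: Blob-radius scale grid (nm) for multi-scale detection.
DETECTION_SCALES_NM = np.geomspace(60.0, 261.0, 16)


def reference_geometry() -> VesicleGeometry:
    return VesicleGeometry(vesicle_diameter=320.0, crystal_diameter=200.0)


def embedded_granule_volume(
    vesicles,
    seed: int = 0,
    with_lipids: bool = True,
    nx: int = DEFAULT_NX,
    ny: int = DEFAULT_NY,
    cyto_lac: float = CYTOPLASM_LAC_UM,
    voxel_nm: float = 37.42,
) -> LacVolume:
    """Voxelise built granules embedded in homogeneous cytoplasm.

    ``vesicles`` is a list of ``(step, center_nm)``.  Each granule is built
    as placed instances (crystal lattice, packed lumen, anchored membrane
    proteins, lipid leaflets); the cytoplasm is a uniform protein solution
    whose concentration reproduces ``cyto_lac``.
    """
    geometry = reference_geometry()
    model = None
    for i, (step, center) in enumerate(vesicles):
        m = build_granule_model(
            geometry, step=step, seed=seed + i, with_lipids=with_lipids,
            center=center,
        )
        if model is None:
            model = m
        else:
            for iid, pl in m.placements.items():
                model.add(m.ingredients[iid], pl)
    cyto_conc = concentration_for_lac(cyto_lac)
    outside = _Everywhere()
    for step, center in vesicles:
        outside = outside.difference(
            SphereSDF(np.asarray(center, float), geometry.vesicle_radius)
        )
    model.uniform_regions.append((outside, cyto_conc, None))
    return voxelize(model, (nx, ny, nx), voxel_nm=voxel_nm)


def _central_profile(
    recon: LacVolume, center_xz_vox=None, search_halfwidth: int = 8, n_bins: int = 16
) -> RadialProfile:
    """Radial profile of the central slice, centred on the brightest pixel.

    The brightest-pixel search is restricted to a window around the nominal
    blob position to avoid reconstruction-boundary artefacts.
    """
    sl = recon.central_slice(axis=1)
    if center_xz_vox is None:
        center_xz_vox = (sl.shape[0] // 2, sl.shape[1] // 2)
    cx, cz = center_xz_vox
    h = search_halfwidth
    window = sl[cx - h:cx + h + 1, cz - h:cz + h + 1]
    local = np.unravel_index(np.argmax(window), window.shape)
    center = (cx - h + local[0], cz - h + local[1])
    return radial_profile(sl, voxel_nm=recon.voxel_nm, center=center, n_bins=n_bins)


@dataclass
class PeakStudyResult:
    step: int
    profile: RadialProfile
    peak_um: float
    volume: LacVolume
    recon: LacVolume


def vesicle_peak_study(
    step: int,
    seed: int = 0,
    with_lipids: bool = True,
    op: ProjectionOperator | None = None,
    nx: int = DEFAULT_NX,
    ny: int = DEFAULT_NY,
) -> PeakStudyResult:
    """Simulate one idealised vesicle tomogram and measure its profile peak.

    The peak is the maximum of the 2D radial profile computed on the central
    slice of the replicate-averaged reconstruction, centred on the brightest
    pixel of the blob.
    """
    op = op or ProjectionOperator()
    volume = embedded_granule_volume(
        [(step, (0.0, 0.0, 0.0))], seed=seed, with_lipids=with_lipids, nx=nx, ny=ny
    )
    recon = simulate_tomogram(volume, op, seed=seed)
    profile = _central_profile(recon)
    return PeakStudyResult(
        step=step, profile=profile, peak_um=profile.peak, volume=volume, recon=recon
    )


def membrane_contribution_study(
    step: int,
    seed: int = 0,
    mode: str = "integrated",
    reconstructed: bool = False,
    op: ProjectionOperator | None = None,
) -> float:
    """Membrane share of a vesicle's absorbance from paired builds.

    The same granule (shared seed, identical protein placements) is
    voxelised with and without its lipid bilayer; the share is computed from
    the paired radial profiles.  By default the noise-free voxelised models
    are compared (the imaging chain conserves the absorbance integrals);
    ``reconstructed=True`` runs both volumes through the full simulated
    imaging chain instead.
    """
    geometry = reference_geometry()
    profiles = {}
    for with_lipids in (True, False):
        volume = embedded_granule_volume(
            [(step, (0.0, 0.0, 0.0))], seed=seed, with_lipids=with_lipids
        )
        if reconstructed:
            volume = simulate_tomogram(volume, op or ProjectionOperator(), seed=seed)
        # profile about the known model centre (paired model volumes)
        profiles[with_lipids] = _central_profile(volume, search_halfwidth=0)
    # integrate one voxel past the vesicle radius to keep the partial-volume
    # spill of the membrane ring inside the footprint
    return membrane_share(
        profiles[True],
        profiles[False],
        r_max_nm=geometry.vesicle_radius + volume.voxel_nm,
        mode=mode,
    )


def cytoplasm_lac_study(
    concentration: float = 0.2,
    seed: int = 0,
    op: ProjectionOperator | None = None,
    nx: int = 99,
    ny: int = 9,
) -> float:
    """Average reconstructed LAC of a homogeneous cytoplasm volume.

    The mean is taken over the central region (inside half the inscribed
    circle), away from reconstruction-boundary effects.
    """
    from .xray import protein_solution_lac

    op = op or ProjectionOperator()
    lac = protein_solution_lac(concentration)
    volume = LacVolume(np.full((nx, ny, nx), lac), voxel_nm=37.42)
    recon = simulate_tomogram(volume, op, seed=seed)
    sl = recon.central_slice(axis=1)
    yy, xx = np.indices(sl.shape)
    r = np.hypot(yy - nx // 2, xx - nx // 2)
    return float(sl[r < nx / 4].mean())


# ---------------------------------------------------------------------------
# Detection study
# ---------------------------------------------------------------------------

def _multi_phantom_volume(
    entries,
    nx: int,
    ny: int,
    cyto_lac: float,
    voxel_nm: float = 37.42,
) -> LacVolume:
    """Analytic multi-granule volume: closed-form shells pasted in cytoplasm.

    ``entries`` is a list of ``(PhantomSpec, center_nm)``.  Used for the
    labelled tuning set, where many idealised features are needed cheaply.
    """
    data = np.full((nx, ny, nx), None, dtype=float)
    from .xray import protein_solution_lac

    data[:] = protein_solution_lac(concentration_for_lac(cyto_lac))
    origin = -0.5 * (np.array([nx, ny, nx]) - 1) * voxel_nm
    for spec, center in entries:
        r_out = spec.vesicle_diameter / 2.0
        # paste the analytic granule into its bounding sub-box
        lo_vox = np.floor((np.asarray(center) - r_out - origin) / voxel_nm).astype(int) - 1
        hi_vox = np.ceil((np.asarray(center) + r_out - origin) / voxel_nm).astype(int) + 2
        lo_vox = np.maximum(lo_vox, 0)
        hi_vox = np.minimum(hi_vox, [nx, ny, nx])
        shape = tuple(hi_vox - lo_vox)
        sub_origin = origin + lo_vox * voxel_nm
        local = analytic_granule_lac(
            PhantomSpec(
                vesicle_diameter=spec.vesicle_diameter,
                crystal_diameter=spec.crystal_diameter,
                maturation_step=spec.maturation_step,
                cyto_concentration=concentration_for_lac(cyto_lac),
                voxel_nm=voxel_nm,
                box_shape=shape,
            ),
            center_nm=center,
            origin_nm=sub_origin,
        )
        data[lo_vox[0]:hi_vox[0], lo_vox[1]:hi_vox[1], lo_vox[2]:hi_vox[2]] = local.data
    return LacVolume(data=data, voxel_nm=voxel_nm, origin_nm=origin)


@dataclass
class DetectionStudyResult:
    threshold: float
    mature_detected: bool
    immature_detected: bool
    contour_diameter_nm: float
    blobs: list
    tuning_accuracy: float


def detection_study(
    seed: int = 0,
    op: ProjectionOperator | None = None,
    nx: int = DEFAULT_NX,
    ny: int = DEFAULT_NY,
    n_labelled: int = 30,
) -> DetectionStudyResult:
    """Blob-segmentation protocol on the simulated two-vesicle tomogram.

    The detection threshold is tuned on a simulated tomogram containing
    ``n_labelled`` idealised mature granules of varied size (positives) and
    ``n_labelled`` faint diffuse density bumps (negative decoys), maximising
    classification accuracy.  Detection then runs on the tomogram containing
    the idealised mature and immature vesicles; reported are the tuned
    threshold, the detection status of both vesicles and the contour
    diameter of the mature detection.
    """
    from .blobs import VolumeMask, detect_blobs, log_responses, tune_threshold

    op = op or ProjectionOperator()
    voxel_nm = 37.42
    rng = rng_for(seed, "detection")

    # --- labelled tuning volume -------------------------------------------
    n_side = int(np.ceil(np.sqrt(2 * n_labelled))) + 2
    pitch = (nx - 24) // n_side
    sites = []
    for i in range(n_side):
        for j in range(n_side):
            sites.append(
                (
                    (i - (n_side - 1) / 2.0) * pitch * voxel_nm,
                    0.0,
                    (j - (n_side - 1) / 2.0) * pitch * voxel_nm,
                )
            )
    # keep sites well inside the cylindrical sample boundary
    sites = [
        s for s in sites if np.hypot(s[0], s[2]) < (nx / 2 - 12) * voxel_nm
    ]
    if len(sites) < 2 * n_labelled:
        raise ValueError("tuning volume too small for the labelled set")
    order = rng.permutation(len(sites))
    pos_sites = [sites[k] for k in order[:n_labelled]]
    neg_sites = [sites[k] for k in order[n_labelled:2 * n_labelled]]

    diameters = rng.uniform(280.0, 400.0, size=n_labelled)
    entries = [
        (
            PhantomSpec(
                vesicle_diameter=d, crystal_diameter=0.625 * d, maturation_step=6
            ),
            c,
        )
        for d, c in zip(diameters, pos_sites)
    ]
    tuning = _multi_phantom_volume(entries, nx, ny, CYTOPLASM_LAC_UM)
    # decoys: faint diffuse bumps a human annotator would reject
    axes = [np.arange(s) * voxel_nm for s in tuning.shape]
    axes = [a - a.mean() for a in axes]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    for c in neg_sites:
        bump = 0.02 * np.exp(
            -((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) / (2 * 80.0**2)
        )
        tuning.data += bump
    tuning_recon = simulate_tomogram(tuning, op, seed=seed)

    stack = log_responses(tuning_recon, DETECTION_SCALES_NM)
    response_map = stack.max(axis=0)

    def site_response(center_nm):
        idx = np.round(
            (np.asarray(center_nm) - tuning.origin_nm) / voxel_nm
        ).astype(int)
        lo = np.maximum(idx - 3, 0)
        hi = np.minimum(idx + 4, response_map.shape)
        return float(response_map[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].max())

    pos_resp = [site_response(c) for c in pos_sites]
    neg_resp = [site_response(c) for c in neg_sites]
    threshold = tune_threshold(pos_resp, neg_resp)
    acc = (
        (np.asarray(pos_resp) >= threshold).sum()
        + (np.asarray(neg_resp) < threshold).sum()
    ) / (len(pos_resp) + len(neg_resp))

    # --- two-vesicle tomogram ---------------------------------------------
    offset_nm = 45 * voxel_nm
    volume = embedded_granule_volume(
        [(6, (-offset_nm, 0.0, 0.0)), (1, (offset_nm, 0.0, 0.0))], seed=seed,
        nx=nx, ny=ny,
    )
    recon = simulate_tomogram(volume, op, seed=seed)
    # cytoplasm validity mask: keep away from the reconstruction boundary
    idx = np.indices(recon.shape)
    r_inplane = np.hypot(idx[0] - nx // 2, idx[2] - nx // 2)
    mask = VolumeMask(r_inplane < nx / 2 - 10, provenance="cytoplasm")
    blobs = detect_blobs(recon, mask, DETECTION_SCALES_NM, threshold=threshold)

    def nearest(center_nm, radius_vox):
        tgt = np.round((np.asarray(center_nm) - recon.origin_nm) / voxel_nm)
        found = [
            b
            for b in blobs
            if np.linalg.norm(np.asarray(b.center) - tgt) <= radius_vox
        ]
        return max(found, key=lambda b: b.response) if found else None

    mature = nearest((-offset_nm, 0.0, 0.0), 5)
    immature = nearest((offset_nm, 0.0, 0.0), 5)
    return DetectionStudyResult(
        threshold=threshold,
        mature_detected=mature is not None,
        immature_detected=immature is not None,
        contour_diameter_nm=2.0 * mature.radius_nm if mature else float("nan"),
        blobs=blobs,
        tuning_accuracy=float(acc),
    )


# ---------------------------------------------------------------------------
# Library profiles and planted-phantom classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryEntry:
    entry_id: str
    vesicle_diameter: float
    crystal_diameter: float
    maturation_step: int
    cyto_concentration: float


def library_profile(
    entry: LibraryEntry,
    op: ProjectionOperator | None = None,
    n_bins: int = 16,
    nx: int = 99,
    ny: int = DEFAULT_NY,
) -> RadialProfile:
    """Noise-free reference profile of one library entry.

    The analytic phantom is embedded in cytoplasm and passed through the
    same projection / filtered-back-projection operator as the data, without
    noise (replicate-averaged noisy reconstructions converge to this
    reference, as the imaging chain is linear and unbiased in the line
    integrals).
    """
    from .xray import protein_solution_lac

    op = op or ProjectionOperator()
    spec = PhantomSpec(
        vesicle_diameter=entry.vesicle_diameter,
        crystal_diameter=entry.crystal_diameter,
        maturation_step=entry.maturation_step,
        cyto_concentration=entry.cyto_concentration,
    )
    from scipy.ndimage import gaussian_filter

    cyto_lac = protein_solution_lac(entry.cyto_concentration)
    volume = _multi_phantom_volume(
        [(spec, (0.0, 0.0, 0.0))], nx, ny, cyto_lac
    )
    recon = simulate_tomogram(volume, op, noise=False)
    # expected blur of the averaged registration jitter (uniform +/- a: a/sqrt(3))
    jitter_sigma = op.jitter_voxels / np.sqrt(3.0)
    iy = ny // 2
    sl = recon.data[:, iy - 1:iy + 2, :].mean(axis=1)  # match 3-slice averaging
    sl = gaussian_filter(sl, jitter_sigma)
    return radial_profile(
        sl, voxel_nm=volume.voxel_nm, center=(nx // 2, nx // 2), n_bins=n_bins
    )


def default_library(
    diameters=(260.0, 320.0, 380.0, 440.0),
    steps=(1, 2, 3, 4, 5, 6),
    crystal_fraction: float = 0.625,
    cyto_concentration: float | None = None,
) -> list:
    """Small profile library spanning size and maturation."""
    if cyto_concentration is None:
        cyto_concentration = concentration_for_lac(CYTOPLASM_LAC_UM)
    library = []
    for d in diameters:
        for s in steps:
            entry = LibraryEntry(
                entry_id=f"d{int(d)}_s{s}",
                vesicle_diameter=d,
                crystal_diameter=crystal_fraction * d,
                maturation_step=s,
                cyto_concentration=cyto_concentration,
            )
            library.append((entry, library_profile(entry)))
    return library


def planted_phantom_study(
    seed: int = 0,
    diameters=(280.0, 320.0, 380.0),
    steps=(1, 3, 6),
    op: ProjectionOperator | None = None,
    nx: int = DEFAULT_NX,
    ny: int = DEFAULT_NY,
) -> dict:
    """Plant a size x maturation grid of granules, recover their classes.

    Uses a permissive detection threshold (classification, not detection, is
    under test) and the default profile library.  Returns the per-plant
    truth/assignment table and the recovery fraction.
    """
    from .blobs import VolumeMask, classify_map, maturity_class

    op = op or ProjectionOperator()
    voxel_nm = 37.42
    pitch_nm = (nx // (len(diameters) + 1)) * voxel_nm
    entries, truth = [], []
    for i, d in enumerate(diameters):
        for j, s in enumerate(steps):
            center = (
                (i - (len(diameters) - 1) / 2.0) * pitch_nm,
                0.0,
                (j - (len(steps) - 1) / 2.0) * pitch_nm,
            )
            entries.append(
                (PhantomSpec(vesicle_diameter=d, crystal_diameter=0.625 * d,
                             maturation_step=s), center)
            )
            truth.append((center, maturity_class(s)))
    volume = _multi_phantom_volume(entries, nx, ny, CYTOPLASM_LAC_UM)
    recon = simulate_tomogram(volume, op, seed=seed)
    idx = np.indices(recon.shape)
    r_inplane = np.hypot(idx[0] - nx // 2, idx[2] - nx // 2)
    mask = VolumeMask(r_inplane < nx / 2 - 10, provenance="cytoplasm")
    library = default_library()
    results, summary = classify_map(
        recon, mask, library, DETECTION_SCALES_NM, threshold=0.02
    )
    correct, assigned = 0, []
    for center, true_class in truth:
        tgt = np.round((np.asarray(center) - recon.origin_nm) / voxel_nm)
        near = [
            r
            for r in results
            if np.linalg.norm(np.asarray(r.blob.center) - tgt) <= 5
        ]
        got = max(near, key=lambda r: r.blob.response).maturity if near else "missed"
        assigned.append((true_class, got))
        correct += got == true_class
    return {
        "assignments": assigned,
        "recovery": correct / len(truth),
        "summary": summary,
    }
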