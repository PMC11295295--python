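"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: retinotopic aperture
movies (rotating wedges, expanding/contracting rings, sweeping bars confined to
a circular field), BOLD series produced by running the CSS pRF model in the
generative direction, toy streamline bundles terminating at labelled cortical
patches, and block-design working-memory runs with known condition effects.

The generators are deliberately simple relative to real data: noise is
additive white Gaussian (an AR(1) option exists), there is no physiological or
vascular structure, and the toy anatomy is a flat sheet rather than a folded
cortex.  What recovery tests on this data show is that the estimators are
correct, not that real white-matter SNR suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm_wm import TaskDesign, convolve_regressor
from .io_formats import LabelMap, StimulusApertureMovie, StreamlineSet, VolumeGrid
from .prf import BaselineModel, HRFSpec, PRFParams, forward_model

APERTURE_KINDS = ("wedge_cw", "wedge_ccw", "ring_expand", "ring_contract", "bar")

# stimulus geometry defaults: 45 deg wedge, ring thickness 25% of field radius,
# bar width 1/8 of field diameter
WEDGE_WIDTH_DEG = 45.0
RING_DUTY = 0.25
BAR_WIDTH_FRACTION = 0.125
BAR_N_ORIENTATIONS = 8


@dataclass
class GroundTruthRecord:
    """True generative parameters behind one synthetic bundle's series."""

    prf: PRFParams
    noise_sd: float = 0.0
    seed: int = 0
    baseline_coefficients: np.ndarray | None = None
    design: TaskDesign | None = None
    condition_effects: dict | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_aperture_movie(
    kind: str, n_frames: int, size_px: int, field_diameter_deg: float
) -> StimulusApertureMovie:
    """Binary aperture movie confined to the central circular field.

    wedge_cw / wedge_ccw sweep a 45 deg wedge through 360 deg over the run;
    ring_expand / ring_contract sweep an annulus over the eccentricity range;
    bar sweeps a strip across the field at 8 successive orientations.
    """
    if kind not in APERTURE_KINDS:
        raise ValueError(f"unknown aperture kind {kind!r}")
    if n_frames < 1 or size_px < 8:
        raise ValueError("need n_frames >= 1 and size_px >= 8")
    scale = field_diameter_deg / size_px  # deg per pixel
    radius_deg = field_diameter_deg / 2.0
    x = (np.arange(size_px) - (size_px - 1) / 2.0) * scale
    y = ((size_px - 1) / 2.0 - np.arange(size_px)) * scale
    xx, yy = np.meshgrid(x, y)
    rr = np.hypot(xx, yy)
    disc = rr <= radius_deg
    theta = np.rad2deg(np.arctan2(yy, xx)) % 360.0
    frames = np.zeros((n_frames, size_px, size_px))
    if kind.startswith("wedge"):
        direction = -1.0 if kind == "wedge_cw" else 1.0
        for f in range(n_frames):
            start = (direction * 360.0 * f / n_frames) % 360.0
            diff = (theta - start) % 360.0
            frames[f] = disc & (diff < WEDGE_WIDTH_DEG)
    elif kind.startswith("ring"):
        # annulus between two radius quantiles of the disc: sweeps eccentricity
        # outward with pixel area growing monotonically (no quantization jitter)
        flat_idx = np.flatnonzero(disc.ravel())
        order = flat_idx[np.argsort(rr.ravel()[flat_idx], kind="stable")]
        n_disc = len(order)
        m0 = max(1, round(0.5 * RING_DUTY * n_disc))
        m1 = max(m0, round(RING_DUTY * n_disc))
        for f in range(n_frames):
            u = f / (n_frames - 1) if n_frames > 1 else 0.0
            if kind == "ring_contract":
                u = 1.0 - u
            m = m0 + round(u * (m1 - m0))
            lo = round(u * (n_disc - m1))
            frame = np.zeros(size_px * size_px)
            frame[order[lo : lo + m]] = 1.0
            frames[f] = frame.reshape(size_px, size_px)
    else:  # bar
        width = BAR_WIDTH_FRACTION * field_diameter_deg
        per = max(1, n_frames // BAR_N_ORIENTATIONS)
        for f in range(n_frames):
            ori = (f // per) % BAR_N_ORIENTATIONS
            ang = np.deg2rad(180.0 * ori / BAR_N_ORIENTATIONS)
            step = (f % per) / max(1, per - 1) if per > 1 else 0.5
            offset = -radius_deg + 2.0 * radius_deg * step
            dist = xx * np.cos(ang) + yy * np.sin(ang) - offset
            frames[f] = disc & (np.abs(dist) <= width / 2.0)
    return StimulusApertureMovie(frames=frames.astype(float), deg_per_pixel=scale)


def simulate_bundle_bold(
    movie: StimulusApertureMovie,
    truth: GroundTruthRecord,
    hrf: HRFSpec,
    tr: float = 1.0,
    n_frames_per_tr: int = 1,
    ar1: float = 0.0,
) -> np.ndarray:
    """CSS forward prediction + polynomial baseline + Gaussian noise.

    The stimulus-related component is exactly the model the fitting stage
    assumes, so at noise_sd = 0 the series equals the forward prediction and
    parameter recovery is limited only by the fit itself.
    """
    import warnings

    field_radius_px = movie.shape_px[0] / 2.0
    if np.hypot(truth.prf.x0_px, truth.prf.y0_px) > 2.0 * field_radius_px:
        warnings.warn("pRF center lies outside twice the field radius", stacklevel=2)
    n_tr = movie.n_frames // n_frames_per_tr
    coeffs = truth.baseline_coefficients
    baseline = None
    if coeffs is not None:
        baseline = BaselineModel(max_poly_degree=len(np.atleast_1d(coeffs)) - 1)
    series = forward_model(
        truth.prf, movie, hrf, coeffs, tr=tr, n_frames_per_tr=n_frames_per_tr,
        baseline=baseline,
    )
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        eps = rng.normal(0.0, truth.noise_sd, n_tr)
        if ar1:
            for t in range(1, n_tr):
                eps[t] += ar1 * eps[t - 1]
        series = series + eps
    return series


@dataclass
class ToyAnatomy:
    """Flat-sheet stand-in for tract geometry: streamlines from a thalamic
    seed point to three labelled cortical patches (FVF / PUVF / PLVF)."""

    streamlines: StreamlineSet
    labels: LabelMap
    gm_mask: VolumeGrid
    wm_mask: VolumeGrid
    designed_subfield: np.ndarray  # per-streamline index into subfield_names
    subfield_names: tuple = ("FVF", "PLVF", "PUVF")
    endpoint_jitter_mm: np.ndarray | None = None


def make_toy_anatomy(
    n_streamlines_per_subfield: int = 20,
    jitter_mm: float = 0.0,
    seed: int = 0,
    n_points_per_patch: int = 25,
) -> ToyAnatomy:
    """Build three labelled target patches on a cortical sheet plus streamlines.

    Patches sit on the plane x = 30 mm in a 40 mm cube, 10 mm apart; each
    streamline runs from a common seed region at x = 5 mm to one designated
    labelled location, displaced by a random vector of length <= jitter_mm.
    The retinotopic coordinates at each patch follow the subfield rules
    (FVF: ecc <= 3; PUVF: 3 < ecc <= 30, angle < 90; PLVF: 3 < ecc <= 30,
    angle >= 90), so designed assignments are recoverable by construction.
    """
    if n_streamlines_per_subfield < 1:
        raise ValueError("need at least one streamline per subfield")
    rng = np.random.default_rng(seed)
    names = ("FVF", "PLVF", "PUVF")
    centers = {"FVF": (30.0, 10.0, 20.0), "PLVF": (30.0, 20.0, 20.0),
               "PUVF": (30.0, 30.0, 20.0)}
    coords, eccs, angs = [], [], []
    for name in names:
        c = np.asarray(centers[name])
        offs = rng.uniform(-3.0, 3.0, (n_points_per_patch, 2))
        pts = np.column_stack([np.full(n_points_per_patch, c[0]),
                               c[1] + offs[:, 0], c[2] + offs[:, 1]])
        coords.append(pts)
        if name == "FVF":
            eccs.append(rng.uniform(0.0, 3.0, n_points_per_patch))
            angs.append(rng.uniform(0.0, 180.0, n_points_per_patch))
        elif name == "PUVF":
            eccs.append(rng.uniform(3.5, 25.0, n_points_per_patch))
            angs.append(rng.uniform(0.0, 89.0, n_points_per_patch))
        else:
            eccs.append(rng.uniform(3.5, 25.0, n_points_per_patch))
            angs.append(rng.uniform(90.0, 180.0, n_points_per_patch))
    labels = LabelMap(
        coordinates=np.vstack(coords),
        eccentricity_deg=np.concatenate(eccs),
        polar_angle_deg=np.concatenate(angs),
    )
    seed_point = np.array([5.0, 20.0, 20.0])
    streamlines, designed, jitters = [], [], []
    for si, name in enumerate(names):
        patch_lo = si * n_points_per_patch
        for _ in range(n_streamlines_per_subfield):
            target_idx = patch_lo + rng.integers(n_points_per_patch)
            target = labels.coordinates[target_idx]
            if jitter_mm > 0:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                r = rng.uniform(0.0, jitter_mm)
                endpoint = target + r * direction
            else:
                r = 0.0
                endpoint = target
            t = np.linspace(0.0, 1.0, 20)[:, None]
            path = seed_point * (1 - t) + endpoint * t
            # gentle out-of-plane arc so paths are not all collinear
            path[:, 2] += 3.0 * np.sin(np.pi * t[:, 0]) * rng.uniform(0.5, 1.0)
            path[-1] = endpoint
            streamlines.append(path)
            designed.append(si)
            jitters.append(r)
    affine = np.eye(4)  # 1 mm isotropic, voxel centers at integer mm
    shape = (41, 41, 41)
    gm = np.zeros(shape, dtype=np.uint8)
    for p in labels.coordinates:
        i, j, k = np.round(p).astype(int)
        gm[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2, max(k - 1, 0): k + 2] = 1
    wm = np.zeros(shape, dtype=np.uint8)
    for s in streamlines:
        ijk = np.round(s).astype(int)
        ijk = ijk[(ijk >= 0).all(axis=1) & (ijk < 41).all(axis=1)]
        wm[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = 1
    wm &= ~gm.astype(bool)
    return ToyAnatomy(
        streamlines=StreamlineSet(streamlines=streamlines),
        labels=labels,
        gm_mask=VolumeGrid(data=gm, affine=affine),
        wm_mask=VolumeGrid(data=wm, affine=affine),
        designed_subfield=np.asarray(designed),
        subfield_names=names,
        endpoint_jitter_mm=np.asarray(jitters),
    )


def simulate_task_bold(
    design: TaskDesign,
    effects: dict,
    hrf: HRFSpec,
    tr: float,
    n_vol: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    drift_coefficients: tuple = (0.0, 0.0),
) -> np.ndarray:
    """Block-design series: sum of condition boxcars convolved with the HRF,
    scaled by per-condition effects, plus linear drift and white noise."""
    conditions = sorted(set(design.condition))
    for cond in conditions:
        rows = [i for i, c in enumerate(design.condition) if c == cond]
        iv = sorted((design.onsets_s[i], design.onsets_s[i] + design.durations_s[i])
                    for i in rows)
        for (s0, e0), (s1, _) in zip(iv, iv[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping blocks for condition {cond!r}")
    for cond in conditions:
        if cond not in effects:
            raise ValueError(f"no effect amplitude for condition {cond!r}")
        if not np.isfinite(effects[cond]):
            raise ValueError("effect amplitudes must be finite")
    series = np.zeros(n_vol)
    for cond in conditions:
        reg = convolve_regressor(
            [o for o, c in zip(design.onsets_s, design.condition) if c == cond],
            [d for d, c in zip(design.durations_s, design.condition) if c == cond],
            tr, n_vol, hrf,
        )
        series += effects[cond] * reg
    t = np.linspace(-1.0, 1.0, n_vol)
    series += drift_coefficients[0] + drift_coefficients[1] * t
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sd, n_vol)
    return series


def default_wm_design(tr: float = 1.0, n_vol: int = 200,
                      block_s: float = 25.0, rest_s: float = 15.0) -> TaskDesign:
    """Alternating 0-back / 2-back blocks separated by rest."""
    onsets, durations, conditions = [], [], []
    t, toggle = rest_s, 0
    while t + block_s <= n_vol * tr - rest_s:
        onsets.append(t)
        durations.append(block_s)
        conditions.append("0bk" if toggle == 0 else "2bk")
        toggle ^= 1
        t += block_s + rest_s
    return TaskDesign(onsets_s=onsets, durations_s=durations, condition=conditions,
                      tr=tr, n_vol=n_vol)
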