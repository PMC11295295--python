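"""Streamline subdivision into retinotopically defined sub-bundles.

A tract's streamlines are assigned to cortical subfields (foveal FVF,
peripheral upper PUVF, peripheral lower PLVF) by the retinotopic labels nearest
their cortical termination; each sub-bundle becomes a track-weighted volume
(per-voxel streamline counts), overlapping voxels are reallocated to the
sub-bundle with the most streamlines there, and standard/strict white-matter
masks trim voxels bordering gray matter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import LabelMap, StreamlineSet, VolumeGrid


@dataclass(frozen=True)
class SubfieldRule:
    """Eccentricity/polar-angle box defining one V1 subfield."""

    name: str
    ecc_min_deg: float
    ecc_max_deg: float
    angle_min_deg: float
    angle_max_deg: float

    def contains(self, ecc: np.ndarray, angle: np.ndarray) -> np.ndarray:
        # eccentricity lower bound open, upper bound closed; angle half-open
        # except at the hemifield edge (180 closes the last bin)
        ok = (ecc > self.ecc_min_deg) | (
            (self.ecc_min_deg == 0) & (ecc == 0)
        )
        ok &= ecc <= self.ecc_max_deg
        if self.angle_max_deg >= 180.0:
            ok &= (angle >= self.angle_min_deg) & (angle <= self.angle_max_deg)
        else:
            ok &= (angle >= self.angle_min_deg) & (angle < self.angle_max_deg)
        return ok


# foveal field takes the full hemifield of angles; peripheral split at 90 deg;
# locations beyond 30 deg eccentricity stay unlabelled
DEFAULT_RULES = (
    SubfieldRule("FVF", 0.0, 3.0, 0.0, 180.0),
    SubfieldRule("PUVF", 3.0, 30.0, 0.0, 90.0),
    SubfieldRule("PLVF", 3.0, 30.0, 90.0, 180.0),
)


@dataclass
class SubBundle:
    """Streamlines of one subfield plus its volumetric representations."""

    subfield: str
    streamlines: StreamlineSet | None
    track_weight: VolumeGrid | None = None
    mask_standard: VolumeGrid | None = None
    mask_strict: VolumeGrid | None = None


def label_subfields(label_map: LabelMap, rules=DEFAULT_RULES) -> LabelMap:
    """Attach a subfield id to every labelled location (-1 = unlabelled).

    Rules are applied in order; the first match wins (with the default rules
    the boxes are disjoint, so order does not matter).
    """
    ecc = label_map.eccentricity_deg
    angle = label_map.polar_angle_deg
    if np.any((angle < 0) | (angle > 180)):
        raise ValueError("polar angle must lie in [0, 180] (hemifield convention)")
    ids = np.full(len(label_map), -1, dtype=int)
    for i, rule in enumerate(rules):
        hit = (ids == -1) & rule.contains(ecc, angle)
        ids[hit] = i
    return replace(
        label_map, subfield_id=ids, subfield_names=tuple(r.name for r in rules)
    )


def assign_streamlines(
    tract: StreamlineSet, label_map: LabelMap, max_dist_mm: float = 2.0
) -> tuple[dict, StreamlineSet | None, np.ndarray]:
    """Assign each streamline to the subfield of the labelled location nearest
    its cortical termination, if that distance is below max_dist_mm.

    The cortical termination is whichever streamline endpoint lies closer to
    the labelled map.  Returns (per-subfield StreamlineSet dict, unassigned
    StreamlineSet or None, per-streamline subfield index with -1 = unassigned).
    """
    if tract.count == 0:
        raise ValueError("empty tract")
    if label_map.subfield_id is None:
        raise ValueError("label map has no subfield ids; run label_subfields first")
    labelled = label_map.subfield_id >= 0
    if not labelled.any():
        raise ValueError("no labelled locations")
    tree = cKDTree(label_map.coordinates[labelled])
    labelled_ids = label_map.subfield_id[labelled]
    assigned = np.full(tract.count, -1, dtype=int)
    for i, s in enumerate(tract):
        d_ends, i_ends = tree.query(np.array([s[0], s[-1]]))
        end = int(np.argmin(d_ends))  # cortical end = endpoint nearer the map
        if d_ends[end] < max_dist_mm:
            assigned[i] = labelled_ids[i_ends[end]]
    per_subfield = {}
    for si, name in enumerate(label_map.subfield_names):
        sls = [s for s, a in zip(tract, assigned) if a == si]
        if sls:
            per_subfield[name] = StreamlineSet(streamlines=sls)
    rest = [s for s, a in zip(tract, assigned) if a == -1]
    unassigned = StreamlineSet(streamlines=rest) if rest else None
    return per_subfield, unassigned, assigned


def track_weight_map(
    bundle: StreamlineSet, grid: VolumeGrid, step_mm: float = 0.1
) -> VolumeGrid:
    """Per-voxel count of distinct streamlines (each counted once per voxel).

    Streamlines are resampled at step_mm along each segment and the visited
    voxel set of each streamline is accumulated.
    """
    shape = grid.data.shape[:3]
    counts = np.zeros(shape, dtype=np.int32)
    for s in bundle:
        seg = np.diff(s, axis=0)
        lengths = np.linalg.norm(seg, axis=1)
        pts = [s[0][None]]
        for p0, d, ln in zip(s[:-1], seg, lengths):
            n = max(1, int(np.ceil(ln / step_mm)))
            t = np.arange(1, n + 1) / n
            pts.append(p0 + t[:, None] * d)
        dense = np.vstack(pts)
        ijk = np.round(grid.world_to_voxel(dense)).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.array(shape)), axis=1)
        ijk = ijk[inside]
        if len(ijk) == 0:
            continue
        flat = np.unique(np.ravel_multi_index(ijk.T, shape))
        counts.flat[flat] += 1
    return VolumeGrid(data=counts, affine=grid.affine)


def reallocate_overlaps(bundles: list) -> list:
    """Make sub-bundle masks pairwise disjoint.

    Every voxel claimed by more than one sub-bundle is kept only by the bundle
    whose track-weight (streamline count) there is largest; exact ties go to
    the lexicographically smallest subfield name, for determinism.
    """
    if not bundles:
        return []
    order = np.argsort([b.subfield for b in bundles])  # lexicographic tie-break
    weights = np.stack([bundles[i].track_weight.data for i in order])
    claimed = weights > 0
    winner = np.argmax(weights, axis=0)  # first (lexicographically smallest) max
    any_claim = claimed.any(axis=0)
    out = [None] * len(bundles)
    for rank, i in enumerate(order):
        b = bundles[i]
        mask = (any_claim & (winner == rank)).astype(np.uint8)
        out[i] = replace(
            b, mask_standard=VolumeGrid(data=mask, affine=b.track_weight.affine)
        )
    return out


def make_wm_masks(
    gm: VolumeGrid, wm: VolumeGrid, connectivity: int = 1
) -> tuple[VolumeGrid, VolumeGrid]:
    """Standard and strict white-matter masks.

    standard = WM minus the once-dilated GM mask; strict = WM minus the
    twice-dilated GM mask (dilation one voxel at a time, face-adjacent by
    default; ``connectivity=3`` gives the 26-connected variant).
    """
    for vol in (gm, wm):
        vals = np.unique(vol.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("masks must be binary")
    structure = ndimage.generate_binary_structure(3, connectivity)
    g = gm.data.astype(bool)
    dil1 = ndimage.binary_dilation(g, structure=structure, iterations=1)
    dil2 = ndimage.binary_dilation(g, structure=structure, iterations=2)
    w = wm.data.astype(bool)
    standard = (w & ~dil1).astype(np.uint8)
    strict = (w & ~dil2).astype(np.uint8)
    return (
        VolumeGrid(data=standard, affine=wm.affine),
        VolumeGrid(data=strict, affine=wm.affine),
    )


def apply_wm_constraint(bundle: SubBundle, standard: VolumeGrid,
                        strict: VolumeGrid) -> SubBundle:
    """Intersect the reallocated sub-bundle mask with the WM masks."""
    base = bundle.mask_standard.data.astype(bool)
    return replace(
        bundle,
        mask_standard=VolumeGrid(
            data=(base & standard.data.astype(bool)).astype(np.uint8),
            affine=standard.affine,
        ),
        mask_strict=VolumeGrid(
            data=(base & strict.data.astype(bool)).astype(np.uint8),
            affine=strict.affine,
        ),
    )


def finalize_subject(bundles: list, min_voxels: int = 10) -> tuple[bool, dict]:
    """Subject inclusion: every sub-bundle mask (standard and strict evaluated
    separately) must contain strictly more than min_voxels voxels."""
    report = {}
    included = True
    for b in bundles:
        n_std = int(b.mask_standard.data.sum()) if b.mask_standard is not None else 0
        n_strict = int(b.mask_strict.data.sum()) if b.mask_strict is not None else 0
        report[b.subfield] = {"standard_voxels": n_std, "strict_voxels": n_strict}
        if n_std <= min_voxels or n_strict <= min_voxels:
            included = False
    return included, report
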