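"""File formats and shared coordinate conventions.

All volumes carry a 4x4 voxel-to-world affine; voxel indexing is 0-based and a
voxel index maps to the world-mm coordinate of its *center*.  Streamline
coordinates are always world mm after reading, regardless of the on-disk
convention (TRK voxel-space data is converted through its header).  Visual-field
quantities are degrees of visual angle; distances are mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram


@dataclass
class VolumeGrid:
    """A 3-D or 4-D image on a regular voxel grid.

    Parameters
    ----------
    data : ndarray
        3-D (spatial) or 4-D (spatial x time) array.
    affine : (4, 4) ndarray
        Voxel-to-world (mm) map; must be invertible.
    tr : float, optional
        Repetition time in seconds; required (and > 0) for 4-D data.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3-D or 4-D data, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if self.data.ndim == 4 and not (self.tr is not None and self.tr > 0):
            raise ValueError("4-D volume requires tr > 0")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be strictly positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per voxel along each spatial axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points to (float) voxel indices."""
        pts = np.atleast_2d(points_mm)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class StreamlineSet:
    """Ordered 3-D point sequences in world mm."""

    streamlines: list

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise ValueError("each streamline needs >= 2 points of 3 coordinates")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline coordinates must be finite")

    @property
    def count(self) -> int:
        return len(self.streamlines)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class LabelMap:
    """Labelled cortical locations with retinotopic coordinates.

    ``polar_angle_deg`` follows the within-hemifield convention [0, 180]
    (0 = upper vertical meridian side of the horizontal axis); ``subfield_id``
    is filled by :func:`tractprf.subdivision.label_subfields` (-1 = unlabelled).
    """

    coordinates: np.ndarray
    eccentricity_deg: np.ndarray
    polar_angle_deg: np.ndarray
    subfield_id: np.ndarray | None = None
    subfield_names: tuple = ()

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        self.eccentricity_deg = np.asarray(self.eccentricity_deg, dtype=float)
        self.polar_angle_deg = np.asarray(self.polar_angle_deg, dtype=float)
        n = len(self.coordinates)
        if self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3) world mm")
        if len(self.eccentricity_deg) != n or len(self.polar_angle_deg) != n:
            raise ValueError("per-location arrays must match coordinate count")
        if np.any(self.eccentricity_deg < 0):
            raise ValueError("eccentricity must be >= 0")

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class StimulusApertureMovie:
    """Time-ordered stack of 2-D aperture frames with a pixel scale.

    frames: (n_frames, height, width) array with values in [0, 1];
    deg_per_pixel converts pixel units to degrees of visual angle.
    """

    frames: np.ndarray
    deg_per_pixel: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("aperture movie must be frames x height x width")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("aperture values must lie in [0, 1]")
        if self.deg_per_pixel <= 0:
            raise ValueError("deg_per_pixel must be positive")
        if self.frames.shape[1] != self.frames.shape[2]:
            warnings.warn("non-square aperture frames", stacklevel=2)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_px(self) -> tuple:
        return self.frames.shape[1:]


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI volume into a :class:`VolumeGrid`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3-D or 4-D volume, got {data.ndim}-D")
    tr = None
    if data.ndim == 4:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if tr <= 0:
            tr = 1.0  # headers written without timing info
    return VolumeGrid(data=data, affine=np.asarray(img.affine), tr=tr)


def write_volume(grid: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(grid.data, grid.affine)
    if grid.data.ndim == 4 and grid.tr:
        zooms = list(img.header.get_zooms())
        zooms[3] = grid.tr
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_streamlines(path) -> StreamlineSet:
    """Read a TCK or TRK tractogram; coordinates come back in world mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tf = nib.streamlines.load(str(path))  # applies header transform to RAS+ mm
    sls = list(tf.tractogram.streamlines)
    if len(sls) == 0:
        raise ValueError(f"tractogram {path} contains no streamlines")
    return StreamlineSet(streamlines=sls)


def write_streamlines(sls: StreamlineSet, path) -> None:
    """Write world-mm streamlines to TCK or TRK (by extension)."""
    tractogram = Tractogram(list(sls), affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def read_aperture_movie(path, deg_per_pixel: float) -> StimulusApertureMovie:
    """Load a frames x H x W array (``.npy``) as an aperture movie."""
    arr = np.load(str(path))
    return StimulusApertureMovie(frames=arr, deg_per_pixel=float(deg_per_pixel))


def write_aperture_movie(movie: StimulusApertureMovie, path) -> None:
    np.save(str(path), movie.frames)
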