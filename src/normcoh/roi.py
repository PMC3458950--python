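"""Region-of-interest signal extraction and normalization.

Representative signals for a brain region are obtained by averaging all
voxel time series inside a spherical mask defined in world (mm)
coordinates, then z-normalizing to mean zero and unit variance.  The
default pipeline uses two regions: the posterior cingulate cortex (PCC)
and the dorsal anterior cingulate cortex (dACC), core nodes in
resting-state default-mode-network studies.

Table (TSV) input bypasses this module entirely, so the downstream
pipeline is fully testable without any imaging file.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ROISpec",
    "ROITimeSeries",
    "PCC",
    "DACC",
    "build_spherical_mask",
    "extract_mean_signal",
    "znormalize",
]


@dataclasses.dataclass(frozen=True)
class ROISpec:
    """A spherical region of interest in world (MNI mm) coordinates."""

    name: str
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"ROI {self.name!r}: radius must be > 0, got {self.radius}")
        if len(self.center) != 3:
            raise ValueError(f"ROI {self.name!r}: center must be a 3-vector")


#: Default regions: 7.5 mm spheres at standard MNI coordinates.
PCC = ROISpec("PCC", (-5.0, -49.0, 40.0), 7.5)
DACC = ROISpec("dACC", (8.0, 7.0, 38.0), 7.5)


@dataclasses.dataclass
class ROITimeSeries:
    """A single region's representative signal sampled every ``dt`` seconds."""

    subject_id: str
    region: str
    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    def __len__(self) -> int:
        return self.values.size


def build_spherical_mask(
    spec: ROISpec, affine: np.ndarray, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Voxels whose center lies within ``spec.radius`` mm of the ROI center.

    Parameters
    ----------
    spec
        Sphere definition (world-space center and radius in mm).
    affine
        4x4 voxel-to-world map (e.g. a NIfTI affine).  The affine is
        authoritative: no assumption about RAS/LPS axis conventions.
    grid_shape
        The (i, j, k) extent of the voxel grid.

    Returns
    -------
    ndarray of shape (n_voxels, 3)
        Integer voxel indices, sorted lexicographically.

    Raises
    ------
    ValueError
        If the affine is singular or the resulting mask is empty
        (center outside the field of view).
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    if any(s <= 0 for s in grid_shape):
        raise ValueError("grid_shape entries must be positive")

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    dist2 = np.sum((world - np.asarray(spec.center)) ** 2, axis=1)
    mask = vox[dist2 <= spec.radius**2]
    if mask.size == 0:
        raise ValueError(
            f"ROI {spec.name!r}: spherical mask is empty — center {spec.center} "
            "is outside the field of view at this radius"
        )
    return mask


def extract_mean_signal(
    volumes: np.ndarray,
    mask: np.ndarray,
    *,
    subject_id: str = "",
    region: str = "",
    dt: float = 2.0,
) -> ROITimeSeries:
    """Average the voxel time series inside ``mask`` into one signal.

    ``volumes`` is a 4D array indexed (i, j, k, t); ``mask`` is an
    (n_voxels, 3) integer index array as produced by
    :func:`build_spherical_mask`.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise ValueError("volumes must be 4D (i, j, k, t)")
    mask = np.asarray(mask, dtype=int)
    if mask.ndim != 2 or mask.shape[1] != 3 or mask.shape[0] == 0:
        raise ValueError("mask must be a nonempty (n, 3) index array")
    if (mask < 0).any() or (mask >= np.array(volumes.shape[:3])).any():
        raise ValueError("mask voxel indices fall outside the volume grid")
    series = volumes[mask[:, 0], mask[:, 1], mask[:, 2], :].mean(axis=0)
    return ROITimeSeries(subject_id=subject_id, region=region, values=series, dt=dt)


def znormalize(series: ROITimeSeries) -> ROITimeSeries:
    """Normalize to mean zero and variance one (population 1/T variance).

    Raises ``ValueError`` for constant input (zero variance).
    """
    v = series.values
    sd = v.std()  # population (1/T) denominator: "variance one" holds exactly
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError(
            f"cannot z-normalize constant or non-finite series "
            f"({series.subject_id}/{series.region})"
        )
    return ROITimeSeries(
        subject_id=series.subject_id,
        region=series.region,
        values=(v - v.mean()) / sd,
        dt=series.dt,
    )
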