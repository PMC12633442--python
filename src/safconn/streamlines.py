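"""Streamline and bundle data model, TCK/NIfTI I/O, voxelization, and bundle cleaning.

Coordinates live in a world RAS frame in millimetres.  Density maps use
isotropic, axis-aligned grids with 0-based voxel indices and half-open voxel
intervals: a point belongs to the voxel whose interval
``[origin + i*voxel_size, origin + (i+1)*voxel_size)`` contains it.
Voxelization counts *streamline visitation*: a voxel's count is the number of
distinct streamlines whose polyline passes through it (track-density imaging
convention), determined by exact segment traversal rather than point sampling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile

from .atlas import ConnectionKey

__all__ = [
    "Streamline",
    "Bundle",
    "GridSpec",
    "DensityMap",
    "TractSpec",
    "StreamlineError",
    "TckFormatError",
    "GridBoundsError",
    "as_streamline",
    "read_tck",
    "write_tck",
    "streamline_length",
    "filter_by_length",
    "resample_streamline",
    "reject_outliers",
    "compute_density_map",
    "write_density_nifti",
    "read_density_nifti",
]

Streamline = np.ndarray  # (n_points, 3) float64, world mm


class StreamlineError(ValueError):
    """Invalid streamline geometry."""


class TckFormatError(IOError):
    """Malformed or truncated TCK file."""


class GridBoundsError(ValueError):
    """A streamline point falls outside the density grid."""


def as_streamline(points: Sequence[Sequence[float]] | np.ndarray) -> Streamline:
    """Validate and coerce *points* into an (n, 3) float64 streamline array."""
    arr = np.asarray(points, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise StreamlineError(f"streamline must be an (n, 3) array, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise StreamlineError("streamline needs at least 2 points")
    if not np.all(np.isfinite(arr)):
        raise StreamlineError("streamline contains non-finite coordinates")
    if streamline_length(arr) <= 0:
        raise StreamlineError("streamline has zero length")
    return arr


@dataclass
class Bundle:
    """A set of streamlines for one connection in one subject (may be empty)."""

    streamlines: list[Streamline]
    connection: ConnectionKey | None = None
    subject_id: str = ""
    session: str = "n/a"  # {"test", "retest", "n/a"}

    def __len__(self) -> int:
        return len(self.streamlines)

    def with_streamlines(self, streamlines: list[Streamline]) -> "Bundle":
        return replace(self, streamlines=streamlines)


@dataclass(frozen=True)
class GridSpec:
    """Isotropic, axis-aligned voxel grid.

    ``origin`` is the world coordinate of the corner of voxel (0, 0, 0);
    voxel centres sit at ``origin + (index + 0.5) * voxel_size``.
    """

    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape: tuple[int, int, int] = (120, 120, 120)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError("grid shape must be 3 positive integers")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world points to integer voxel indices (floor after origin shift)."""
        return np.floor(
            (np.asarray(points, dtype=np.float64) - np.asarray(self.origin))
            / self.voxel_size
        ).astype(np.int64)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return (np.asarray(indices, dtype=np.float64) + 0.5) * self.voxel_size + np.asarray(
            self.origin
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = self.world_to_voxel(points)
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)


@dataclass
class DensityMap:
    """Per-voxel streamline visitation counts on a :class:`GridSpec`."""

    grid: GridSpec
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match grid {self.grid.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("density counts must be non-negative")

    @property
    def support(self) -> np.ndarray:
        """(n, 3) voxel indices with non-zero counts."""
        return np.argwhere(self.counts > 0)

    @property
    def n_support(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class TractSpec:
    """Per-connection tracking budget: length cap and streamline ceiling.

    The maximum streamline length is tract-specific, between 38 and 125 mm,
    chosen to favour short-range fibres over deep white matter.  Two runs of
    1,000 streamlines give a per-tract ceiling of 2,000.
    """

    connection: ConnectionKey | None = None
    max_length_mm: float = 125.0
    streamlines_per_run: int = 1000
    runs: int = 2
    min_streamlines_present: int = 5

    def __post_init__(self) -> None:
        if not 38.0 <= self.max_length_mm <= 125.0:
            raise ValueError("max_length_mm must lie in [38, 125]")
        if self.streamlines_per_run <= 0 or self.runs <= 0:
            raise ValueError("streamline budget must be positive")

    @property
    def max_total_streamlines(self) -> int:
        return self.runs * self.streamlines_per_run


# ---------------------------------------------------------------------------
# TCK I/O (MRtrix track format) via nibabel
# ---------------------------------------------------------------------------

def write_tck(bundle: Bundle, path: str | Path) -> Path:
    """Write *bundle* to an MRtrix TCK file (world/RAS mm coordinates)."""
    path = Path(path)
    tractogram = Tractogram(
        [np.asarray(s, dtype=np.float32) for s in bundle.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    TckFile(tractogram).save(str(path))
    return path


def read_tck(path: str | Path) -> Bundle:
    """Read an MRtrix TCK file into a :class:`Bundle`.

    Raises :class:`TckFormatError` for files without the ``mrtrix tracks``
    magic or with truncated/corrupt payloads.
    """
    path = Path(path)
    try:
        if not TckFile.is_correct_format(str(path)):
            raise TckFormatError(f"{path}: not a TCK file (missing 'mrtrix tracks' magic)")
        tck = TckFile.load(str(path), lazy_load=False)
    except TckFormatError:
        raise
    except Exception as exc:  # nibabel raises several header/data error types
        raise TckFormatError(f"{path}: malformed TCK file ({exc})") from exc
    streamlines = [np.asarray(s, dtype=np.float64) for s in tck.tractogram.streamlines]
    return Bundle(streamlines=streamlines)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def streamline_length(s: Streamline) -> float:
    """Arc length in mm: sum of Euclidean segment lengths."""
    arr = np.asarray(s, dtype=np.float64)
    return float(np.linalg.norm(np.diff(arr, axis=0), axis=1).sum())


def filter_by_length(bundle: Bundle, spec: TractSpec) -> Bundle:
    """Retain streamlines with arc length <= ``spec.max_length_mm``, order preserved."""
    kept = [s for s in bundle.streamlines if streamline_length(s) <= spec.max_length_mm]
    return bundle.with_streamlines(kept)


def resample_streamline(s: Streamline, n_points: int) -> Streamline:
    """Resample to *n_points* equidistant points along the arc."""
    arr = np.asarray(s, dtype=np.float64)
    seg = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n_points)
    out = np.empty((n_points, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, arr[:, d])
    return out


def _mean_closest_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetrized mean closest-point distance between two resampled streamlines."""
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def reject_outliers(
    bundle: Bundle, threshold_factor: float = 3.0, n_resample: int = 20
) -> Bundle:
    """Remove streamlines geometrically far from the bundle's medoid.

    Each streamline is resampled to ``n_resample`` equidistant points and its
    symmetrized mean closest-point distance to every other streamline is
    computed (orientation-invariant by construction).  The medoid minimises the
    summed distance to the rest of the bundle.  Streamlines whose distance to
    the medoid exceeds ``median + threshold_factor * MAD`` are removed; the
    medoid itself is never removed.  Deterministic; bundles with fewer than two
    streamlines are returned unchanged.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    n = len(bundle)
    if n < 2:
        return bundle
    pts = np.stack([resample_streamline(s, n_resample) for s in bundle.streamlines])
    # pairwise symmetrized mean closest-point distances, row by row
    dist = np.zeros((n, n))
    for i in range(n):
        d = np.linalg.norm(pts[i][None, :, None, :] - pts[:, None, :, :], axis=3)
        dist[i] = 0.5 * (d.min(axis=2).mean(axis=1) + d.min(axis=1).mean(axis=1))
    medoid = int(np.argmin(dist.sum(axis=1)))
    d_med = dist[medoid]
    med = float(np.median(d_med))
    mad = float(np.median(np.abs(d_med - med)))
    cutoff = med + threshold_factor * mad
    kept = [
        s
        for i, s in enumerate(bundle.streamlines)
        if i == medoid or d_med[i] <= cutoff
    ]
    return bundle.with_streamlines(kept)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def _segment_voxels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxel indices traversed by the segment a->b, in continuous voxel units.

    Splits [0, 1] at every crossing of an integer grid plane and assigns each
    open sub-interval to the voxel containing its midpoint; this enumerates
    every voxel the segment passes through, in order.
    """
    ts = [0.0, 1.0]
    delta = b - a
    for d in range(3):
        if delta[d] != 0.0:
            lo, hi = sorted((a[d], b[d]))
            first = math.floor(lo) + 1
            last = math.ceil(hi) - 1
            for k in range(first, last + 1):
                t = (k - a[d]) / delta[d]
                if 0.0 < t < 1.0:
                    ts.append(t)
    ts = np.unique(np.asarray(ts))
    mids = 0.5 * (ts[:-1] + ts[1:])
    vox = np.floor(a[None, :] + mids[:, None] * delta[None, :]).astype(np.int64)
    # endpoint voxels are covered by the first/last sub-interval midpoints
    return vox


def streamline_voxels(s: Streamline, grid: GridSpec) -> np.ndarray:
    """Unique voxel indices visited by streamline *s* (exact segment traversal)."""
    arr = (np.asarray(s, dtype=np.float64) - np.asarray(grid.origin)) / grid.voxel_size
    chunks = [_segment_voxels(arr[i], arr[i + 1]) for i in range(len(arr) - 1)]
    vox = np.concatenate(chunks, axis=0)
    return np.unique(vox, axis=0)


def compute_density_map(bundle: Bundle, grid: GridSpec) -> DensityMap:
    """Voxel-wise streamline visitation counts for *bundle* on *grid*.

    Each streamline contributes at most 1 to each voxel it traverses.  Raises
    :class:`GridBoundsError` (naming the offending streamline) if any point
    falls outside the grid.
    """
    counts = np.zeros(grid.shape, dtype=np.int32)
    for i, s in enumerate(bundle.streamlines):
        inside = grid.contains(np.asarray(s))
        if not np.all(inside):
            raise GridBoundsError(
                f"streamline {i} has {int((~inside).sum())} point(s) outside the grid"
            )
        vox = streamline_voxels(s, grid)
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return DensityMap(grid=grid, counts=counts)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_density_nifti(dmap: DensityMap, path: str | Path) -> Path:
    """Write a density map as a NIfTI-1 volume; the affine encodes the grid.

    The affine diagonal is the (isotropic) voxel size and the translation is
    the world coordinate of the centre of voxel (0, 0, 0).
    """
    path = Path(path)
    vs = dmap.grid.voxel_size
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = vs
    affine[:3, 3] = np.asarray(dmap.grid.origin) + 0.5 * vs
    img = nib.Nifti1Image(dmap.counts.astype(np.int32), affine)
    nib.save(img, str(path))
    return path


def read_density_nifti(path: str | Path) -> DensityMap:
    """Read a density volume written by :func:`write_density_nifti`.

    Only isotropic, axis-aligned affines are accepted.
    """
    img = nib.load(str(path))
    affine = img.affine
    diag = np.diag(affine)[:3]
    off_diag = affine[:3, :3] - np.diag(diag)
    if np.any(np.abs(off_diag) > 1e-6):
        raise ValueError("only axis-aligned density volumes are supported")
    if not np.allclose(diag, diag[0], atol=1e-6):
        raise ValueError("only isotropic density volumes are supported")
    vs = float(diag[0])
    origin = tuple(affine[:3, 3] - 0.5 * vs)
    counts = np.asarray(img.dataobj).astype(np.int32)
    return DensityMap(grid=GridSpec(voxel_size=vs, origin=origin, shape=counts.shape), counts=counts)
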