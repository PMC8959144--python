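"""Shared domain containers.

All physical quantities are in micrometres (µm); image coordinates are
(row, col) pixels.  3D atlas coordinates follow a CCFv3-style ordering:
x increases rostral→caudal, y dorsal→ventral, z left→right.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class SectionImage:
    """One registered 2D grayscale section.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Intensity grid, uint8 or uint16.
    bit_depth : {8, 16}
    pixel_size : float
        Physical size of one pixel in µm.
    section_index : int
        Serial index in the medio-lateral series.
    medio_lateral_pos : float
        Position of the section plane along the medio-lateral axis, µm.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size: float = 1.0
    section_index: int = 0
    medio_lateral_pos: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("section image must be 2D grayscale")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.size and self.pixels.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities exceed the stated bit range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "SectionImage":
        """Copy of this section carrying new pixel data, same metadata."""
        return replace(self, pixels=pixels)


@dataclass
class AtlasPlate:
    """Colour-coded atlas segmentation plate paired with a section image."""

    pixels: np.ndarray  # (H, W, 3) uint8 RGB

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("atlas plate must be an RGB (H, W, 3) image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class RegionMap:
    """Colour → region lookup: rows of (region_id, name, (r, g, b)).

    Region ids and colours must both be unique; colour matching downstream is
    exact (plates are label images, not photographs).
    """

    entries: list[tuple[int, str, tuple[int, int, int]]]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        colours = [tuple(e[2]) for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids must be unique")
        if len(set(colours)) != len(colours):
            raise ValueError("region colours must be unique")

    @property
    def region_ids(self) -> list[int]:
        return [e[0] for e in self.entries]

    def colour_of(self, region_id: int) -> tuple[int, int, int]:
        for rid, _, colour in self.entries:
            if rid == region_id:
                return tuple(colour)
        raise KeyError(region_id)

    def name_of(self, region_id: int) -> str:
        for rid, name, _ in self.entries:
            if rid == region_id:
                return name
        raise KeyError(region_id)

    def colour_lookup(self) -> dict[tuple[int, int, int], int]:
        return {tuple(e[2]): e[0] for e in self.entries}


@dataclass
class DetectedObject:
    """A detected labelled soma with its shape descriptors.

    circularity = 4π·area/perimeter², clamped to ≤ 1.0 (rasterization can
    push the raw value above 1 for small objects, as in ImageJ).
    """

    centroid: tuple[float, float]  # (row, col) px
    area: float  # px²
    perimeter: float  # px
    circularity: float
    mean_intensity: float
    region_id: int | None = None

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("object area must be ≥ 1 px")
        if not 0 < self.circularity <= 1.0:
            raise ValueError("circularity must lie in (0, 1]")


@dataclass
class PointCloud3D:
    """Labelled 3D points in atlas µm coordinates.

    ``xyz`` is an (n, 3) float array; ``density_class`` an ordinal per-point
    label ≥ 1; ``source_section`` the serial section each point came from.
    """

    xyz: np.ndarray
    density_class: np.ndarray | None = None
    group: str = ""
    source_section: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.size == 0:
            self.xyz = self.xyz.reshape(0, 3)
        if self.xyz.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        n = len(self.xyz)
        if self.density_class is None:
            self.density_class = np.ones(n, dtype=int)
        else:
            self.density_class = np.asarray(self.density_class, dtype=int)
            if self.density_class.shape != (n,):
                raise ValueError("density_class must have one entry per point")
            if n and self.density_class.min() < 1:
                raise ValueError("density_class is ordinal, must be ≥ 1")
        if self.source_section is None:
            self.source_section = np.zeros(n, dtype=int)
        else:
            self.source_section = np.asarray(self.source_section, dtype=int)
            if self.source_section.shape != (n,):
                raise ValueError("source_section must have one entry per point")

    def __len__(self) -> int:
        return len(self.xyz)

    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise ValueError("centroid of an empty cloud is undefined")
        return self.xyz.mean(axis=0)

    def subset(self, mask: np.ndarray) -> "PointCloud3D":
        """Row subset preserving all per-point attributes."""
        return PointCloud3D(
            xyz=self.xyz[mask],
            density_class=self.density_class[mask],
            group=self.group,
            source_section=self.source_section[mask],
        )


_SLAB_AXES = {"sagittal": 2, "frontal": 0, "horizontal": 1}


@dataclass
class SlabSpec:
    """A digital slice through a point cloud.

    ``axis`` names the anatomical cutting plane; its normal is z for
    sagittal, x for frontal, y for horizontal slices.  Membership is the
    half-open interval [centre − t/2, centre + t/2) along that normal, so
    tiling slabs partition a cloud.
    """

    axis: str
    centre: float  # µm along the slab normal
    thickness: float = 100.0  # µm

    def __post_init__(self) -> None:
        if self.axis not in _SLAB_AXES:
            raise ValueError(f"axis must be one of {sorted(_SLAB_AXES)}")
        if self.thickness <= 0:
            raise ValueError("slab thickness must be positive")

    @property
    def normal_axis(self) -> int:
        """Index (0=x, 1=y, 2=z) of the coordinate normal to the slab."""
        return _SLAB_AXES[self.axis]

    @property
    def bounds(self) -> tuple[float, float]:
        half = self.thickness / 2.0
        return self.centre - half, self.centre + half


@dataclass
class RegionVolume:
    """Voxelized binary mask of an atlas region (e.g. the pontine nuclei).

    ``mask`` is indexed (ix, iy, iz); voxel centre of index (i, j, k) sits at
    ``origin + (i + 0.5, j + 0.5, k + 0.5) * voxel_size`` µm.
    """

    mask: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("volume mask must be 3D")
        if not self.mask.any():
            raise ValueError("volume mask must be non-empty")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    def voxel_index(self, xyz: np.ndarray) -> np.ndarray:
        """Integer voxel indices of µm points (floor; may fall outside)."""
        return np.floor((np.atleast_2d(xyz) - self.origin) / self.voxel_size).astype(int)

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean membership of µm points in the masked volume."""
        idx = self.voxel_index(xyz)
        inside = np.all((idx >= 0) & (idx < self.mask.shape), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out
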