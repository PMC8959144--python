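"""Semi-quantitative 3D point recording and topography comparison.

Points are recorded per section at a density reflecting the labelling seen
in the image, placed in atlas µm coordinates, spread along z by a random
displacement within the inter-section gap, and compared across groups by
digital slab slicing, centroid shifts and density-overlap scores.
"""

from __future__ import annotations

import numpy as np

from ponsquant.types import PointCloud3D, RegionVolume, SlabSpec


def record_points(
    density_map: np.ndarray,
    points_per_unit: float,
    *,
    pixel_size: float = 1.0,
    section_index: int = 0,
    section_spacing: float = 100.0,
    density_class_edges: tuple[float, ...] = (),
    group: str = "",
    seed: int = 0,
) -> PointCloud3D:
    """Sample points from a per-section labelling-density map.

    Each pixel contributes Poisson(points_per_unit · density) points placed
    uniformly within the pixel; (row, col) map to (y, x)·pixel_size µm and
    the section index maps to the section mid-plane
    z = (section_index + 0.5)·section_spacing.  ``density_class_edges``
    optionally bins pixel density into ordinal classes 1..k+1 (low→high).
    """
    dmap = np.asarray(density_map, dtype=float)
    if dmap.ndim != 2:
        raise ValueError("density_map must be 2D")
    if (dmap < 0).any():
        raise ValueError("density_map must be non-negative")
    if points_per_unit < 0:
        raise ValueError("points_per_unit must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(points_per_unit * dmap)
    rows, cols = np.nonzero(counts)
    reps = counts[rows, cols]
    if reps.sum() == 0:
        return PointCloud3D(
            xyz=np.empty((0, 3)),
            group=group,
            source_section=np.empty(0, dtype=int),
            density_class=np.empty(0, dtype=int),
        )
    rr = np.repeat(rows, reps).astype(float)
    cc = np.repeat(cols, reps).astype(float)
    jitter = rng.random((len(rr), 2))  # uniform within the pixel
    x = (cc + jitter[:, 1]) * pixel_size
    y = (rr + jitter[:, 0]) * pixel_size
    z = np.full(len(rr), (section_index + 0.5) * section_spacing)
    dens = np.repeat(dmap[rows, cols], reps)
    if density_class_edges:
        cls = 1 + np.searchsorted(np.asarray(density_class_edges), dens, side="right")
    else:
        cls = np.ones(len(rr), dtype=int)
    return PointCloud3D(
        xyz=np.column_stack([x, y, z]),
        density_class=cls.astype(int),
        group=group,
        source_section=np.full(len(rr), section_index, dtype=int),
    )


def jitter_z(
    cloud: PointCloud3D, gap: float, seed: int = 0, *, mode: str = "centred"
) -> PointCloud3D:
    """Randomly displace each point's z within the inter-section gap.

    ``centred`` (default) draws uniform offsets on (−gap/2, +gap/2) around
    the section plane; ``forward`` draws on (0, gap), for the reading in
    which the whole gap lies to one side of the section.  x and y are
    untouched; gap = 0 is the identity.  Deterministic given ``seed``.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    if mode not in ("centred", "forward"):
        raise ValueError("mode must be 'centred' or 'forward'")
    if gap == 0:
        return cloud.subset(np.ones(len(cloud), dtype=bool))
    rng = np.random.default_rng(seed)
    if mode == "centred":
        dz = rng.uniform(-gap / 2.0, gap / 2.0, size=len(cloud))
    else:
        dz = rng.uniform(0.0, gap, size=len(cloud))
    xyz = cloud.xyz.copy()
    xyz[:, 2] += dz
    return PointCloud3D(
        xyz=xyz,
        density_class=cloud.density_class.copy(),
        group=cloud.group,
        source_section=cloud.source_section.copy(),
    )


def slice_points(cloud: PointCloud3D, slab: SlabSpec) -> PointCloud3D:
    """Points within a digital slab: half-open [centre − t/2, centre + t/2).

    The half-open convention makes adjacent slabs a partition of the cloud.
    All per-point attributes are preserved.
    """
    lo, hi = slab.bounds
    coord = cloud.xyz[:, slab.normal_axis]
    return cloud.subset((coord >= lo) & (coord < hi))


def centroid_shift(
    cloud_a: PointCloud3D,
    cloud_b: PointCloud3D,
    *,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Component-wise centroid difference B − A with a bootstrap CI.

    Returns ``(shift, ci)`` where shift is (Δx, Δy, Δz) in µm and ci is a
    (2, 3) array of percentile bootstrap bounds (default 95%, 1000
    resamples of each cloud, seeded).
    """
    if len(cloud_a) == 0 or len(cloud_b) == 0:
        raise ValueError("centroid shift of an empty cloud is undefined")
    shift = cloud_b.centroid() - cloud_a.centroid()
    rng = np.random.default_rng(seed)
    na, nb = len(cloud_a), len(cloud_b)
    boots = np.empty((n_boot, 3))
    # resample in chunks: full (n_boot, n) index matrices for large clouds
    # would not fit comfortably in memory
    chunk = max(1, int(2_000_000 // max(na, nb)))
    for s in range(0, n_boot, chunk):
        e = min(n_boot, s + chunk)
        ia = rng.integers(0, na, size=(e - s, na))
        ib = rng.integers(0, nb, size=(e - s, nb))
        boots[s:e] = cloud_b.xyz[ib].mean(axis=1) - cloud_a.xyz[ia].mean(axis=1)
    alpha = (1.0 - ci_level) / 2.0
    ci = np.quantile(boots, [alpha, 1.0 - alpha], axis=0)
    return shift, ci


def voxelize(
    cloud: PointCloud3D, volume: RegionVolume
) -> np.ndarray:
    """Normalized per-voxel point density restricted to the volume mask.

    Points outside the mask are ignored; the returned histogram sums to 1
    (all zeros if no point falls inside).
    """
    hist = np.zeros(volume.mask.shape, dtype=float)
    idx = volume.voxel_index(cloud.xyz)
    inside = np.all((idx >= 0) & (idx < volume.mask.shape), axis=1)
    idx = idx[inside]
    keep = volume.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    idx = idx[keep]
    np.add.at(hist, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    total = hist.sum()
    if total > 0:
        hist /= total
    return hist


def density_overlap(
    cloud_a: PointCloud3D,
    cloud_b: PointCloud3D,
    volume: RegionVolume,
) -> float:
    """Histogram-intersection overlap of voxelized densities, in [0, 1].

    1.0 for identical normalized densities, 0.0 for disjoint support.
    """
    if len(cloud_a) == 0 or len(cloud_b) == 0:
        raise ValueError("density overlap of an empty cloud is undefined")
    ha = voxelize(cloud_a, volume)
    hb = voxelize(cloud_b, volume)
    return float(np.minimum(ha, hb).sum())
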