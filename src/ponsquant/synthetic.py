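"""Synthetic fixtures with planted ground truth.

Three generators emulate the three kinds of data the quantification
pipelines consume:

* ``make_section_set`` — serial sagittal cortical sections with
  region-graded planted fluorescent somata, paired with colour-coded atlas
  plates and a colour→region lookup, so per-region counting has an exact
  planted-count oracle.
* ``make_tract_image`` / ``make_tract_series`` — binary fibre-tract images
  with known bundle envelopes and inter-fascicle gaps, so width and
  fasciculation measurements have analytic ground truth.
* ``make_pointclouds`` — clustered corticopontine point clouds inside a
  pontine-nuclei-like ellipsoidal volume, with a group-dependent planted
  shift, sectioned at a known z-spacing.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from ponsquant.types import (
    AtlasPlate,
    PointCloud3D,
    RegionMap,
    RegionVolume,
    SectionImage,
)

# ---------------------------------------------------------------------------
# Cortical section sets
# ---------------------------------------------------------------------------

#: Seven cortical areas carrying the labelled layer V population, ordered
#: anterior→posterior: prefrontal, motor, somatosensory, auditory, visual,
#: retrosplenial, gustatory.
DEFAULT_REGION_NAMES = ("PFC", "M", "S", "A", "V", "RSC", "GC")

#: Distinct label colours (pure hues, exact-match friendly).
DEFAULT_REGION_COLOURS = (
    (230, 25, 75),
    (60, 180, 75),
    (0, 130, 200),
    (245, 130, 48),
    (145, 30, 180),
    (70, 240, 240),
    (240, 50, 230),
)

#: Control-like count profile across the seven areas — motor-dominant with a
#: graded fall-off towards posterior areas — and the flattened profile
#: emulating a mutant in which the areal gradient is lost.
CONTROL_GRADIENT = {i + 1: c for i, c in enumerate((60, 160, 80, 50, 40, 30, 20))}
FLAT_GRADIENT = {i + 1: 63 for i in range(7)}


@dataclass
class SectionSpec:
    """Recipe for one serial set of synthetic cortical sections.

    ``regions`` entries are ``(region_id, colour, geometry)`` where geometry
    is either a boolean mask of shape ``image_shape`` or a polygon given as
    an (k, 2) array of (row, col) vertices.  ``planted_counts`` maps
    region_id → somata per section.  Blobs are isotropic Gaussians of
    σ = blob_radius/3 truncated at 3σ (= blob_radius), with centroids kept
    ≥ min_separation_factor·blob_radius apart (default 3×, so neighbouring
    thresholded blobs cannot merge even under noise) and ≥ blob_radius +
    2 px inside their region so detected centroids cannot leak across a
    boundary.
    """

    image_shape: tuple[int, int] = (640, 700)
    pixel_size: float = 1.29  # µm/px
    n_sections: int = 2
    section_spacing: float = 100.0  # µm
    regions: list[tuple[int, tuple[int, int, int], object]] = field(default_factory=list)
    planted_counts: dict[int, int] = field(default_factory=dict)
    blob_radius_px: float = 3.0
    min_separation_factor: float = 3.0
    blob_peak: float = 20000.0
    background_level: float = 2000.0
    background_gradient: float = 0.0  # intensity per px along columns
    noise_sd: float = 0.0
    bit_depth: int = 16
    animal_id: str = "synthetic"
    genotype: str = "Ctrl"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            self.regions = default_regions(self.image_shape)
        if not self.planted_counts:
            self.planted_counts = dict(CONTROL_GRADIENT)
        if any(c < 0 for c in self.planted_counts.values()):
            raise ValueError("planted counts must be non-negative")
        colours = [tuple(r[1]) for r in self.regions]
        if len(set(colours)) != len(colours):
            raise ValueError("region colours must be unique")
        unknown = set(self.planted_counts) - {r[0] for r in self.regions}
        if unknown:
            raise ValueError(f"planted counts for unknown regions: {sorted(unknown)}")


def default_regions(
    image_shape: tuple[int, int],
    names: tuple[str, ...] = DEFAULT_REGION_NAMES,
    colours: tuple[tuple[int, int, int], ...] = DEFAULT_REGION_COLOURS,
) -> list[tuple[int, tuple[int, int, int], np.ndarray]]:
    """Vertical strips of equal width spanning the plate, one per area."""
    h, w = image_shape
    n = len(names)
    edges = np.linspace(0, w, n + 1).astype(int)
    regions = []
    for i in range(n):
        mask = np.zeros(image_shape, dtype=bool)
        mask[:, edges[i] : edges[i + 1]] = True
        regions.append((i + 1, colours[i], mask))
    return regions


def _region_mask(geometry: object, image_shape: tuple[int, int]) -> np.ndarray:
    if isinstance(geometry, np.ndarray) and geometry.dtype == bool:
        if geometry.shape != tuple(image_shape):
            raise ValueError("region mask shape must match image_shape")
        return geometry
    verts = np.asarray(geometry, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValueError("region polygon must be (k, 2) (row, col) vertices")
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=tuple(image_shape))
    mask = np.zeros(image_shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _place_centroids(
    allowed: np.ndarray,
    count: int,
    min_sep: float,
    occupied: list[np.ndarray],
    rng: np.random.Generator,
    max_attempts_per_point: int = 200,
) -> np.ndarray:
    """Rejection-sample `count` centroids on `allowed` pixels, ≥ min_sep apart."""
    rows, cols = np.nonzero(allowed)
    if count == 0:
        return np.empty((0, 2))
    if len(rows) == 0:
        raise ValueError("region too small for the requested blob radius")
    placed: list[np.ndarray] = []
    existing = np.array(occupied).reshape(-1, 2) if occupied else np.empty((0, 2))
    sep2 = min_sep**2
    attempts = 0
    budget = count * max_attempts_per_point
    while len(placed) < count:
        if attempts >= budget:
            raise ValueError(
                f"could not place {count} blobs at min separation {min_sep} px; "
                "planted count exceeds region capacity at this blob radius"
            )
        attempts += 1
        i = rng.integers(len(rows))
        cand = np.array([rows[i], cols[i]], dtype=float) + rng.random(2) - 0.5
        neighbours = np.vstack([existing, np.array(placed).reshape(-1, 2)])
        if len(neighbours) and np.min(np.sum((neighbours - cand) ** 2, axis=1)) < sep2:
            continue
        placed.append(cand)
    return np.array(placed)


def _render_blobs(
    img: np.ndarray, centroids: np.ndarray, radius: float, amplitude: float
) -> None:
    """Add truncated-Gaussian blobs (σ = radius/3, cut at 3σ) in place."""
    sigma = radius / 3.0
    r_int = int(np.ceil(radius))
    h, w = img.shape
    for cr, cc in centroids:
        r0, r1 = int(np.floor(cr)) - r_int, int(np.floor(cr)) + r_int + 1
        c0, c1 = int(np.floor(cc)) - r_int, int(np.floor(cc)) + r_int + 1
        r0c, r1c = max(r0, 0), min(r1, h)
        c0c, c1c = max(c0, 0), min(c1, w)
        yy, xx = np.mgrid[r0c:r1c, c0c:c1c]
        d2 = (yy - cr) ** 2 + (xx - cc) ** 2
        prof = amplitude * np.exp(-d2 / (2 * sigma**2))
        prof[d2 > radius**2] = 0.0
        img[r0c:r1c, c0c:c1c] += prof


def make_section_set(
    spec: SectionSpec,
) -> tuple[list[SectionImage], list[AtlasPlate], RegionMap, pd.DataFrame]:
    """Generate a serial section set with planted per-region cell counts.

    Returns the grayscale sections, their atlas plates, the colour→region
    lookup, and a ground-truth table with columns
    (animal_id, genotype, section_index, region_id, raw_count) recording the
    exact planted counts.
    """
    h, w = spec.image_shape
    masks = {rid: _region_mask(geom, spec.image_shape) for rid, _, geom in spec.regions}
    margin = spec.blob_radius_px + 2
    # distance-to-outside per region: centroids stay `margin` inside their region
    allowed = {
        rid: ndimage.distance_transform_edt(m) > margin for rid, m in masks.items()
    }

    plate_pixels = np.zeros((h, w, 3), dtype=np.uint8)
    for rid, colour, _ in spec.regions:
        plate_pixels[masks[rid]] = colour
    region_map = RegionMap(
        entries=[
            (rid, DEFAULT_REGION_NAMES[i] if i < len(DEFAULT_REGION_NAMES) else f"R{rid}", tuple(colour))
            for i, (rid, colour, _) in enumerate(spec.regions)
        ]
    )

    rng = np.random.default_rng(spec.seed)
    max_val = 2**spec.bit_depth - 1
    sections: list[SectionImage] = []
    plates: list[AtlasPlate] = []
    truth_rows = []
    for s in range(spec.n_sections):
        img = np.full((h, w), float(spec.background_level))
        if spec.background_gradient:
            img += spec.background_gradient * np.arange(w)[None, :]
        occupied: list[np.ndarray] = []
        for rid, _, _ in spec.regions:
            count = int(spec.planted_counts.get(rid, 0))
            cents = _place_centroids(
                allowed[rid],
                count,
                spec.min_separation_factor * spec.blob_radius_px,
                occupied,
                rng,
            )
            occupied.extend(list(cents))
            _render_blobs(
                img, cents, spec.blob_radius_px, spec.blob_peak - spec.background_level
            )
            truth_rows.append(
                {
                    "animal_id": spec.animal_id,
                    "genotype": spec.genotype,
                    "section_index": s,
                    "region_id": rid,
                    "raw_count": count,
                }
            )
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        pixels = np.clip(np.rint(img), 0, max_val)
        dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
        sections.append(
            SectionImage(
                pixels=pixels.astype(dtype),
                bit_depth=spec.bit_depth,
                pixel_size=spec.pixel_size,
                section_index=s,
                medio_lateral_pos=s * spec.section_spacing,
            )
        )
        plates.append(AtlasPlate(pixels=plate_pixels.copy()))
    ground_truth = pd.DataFrame(truth_rows)
    return sections, plates, region_map, ground_truth


def make_cohort_specs(
    gradient: dict[int, float],
    n_animals: int,
    genotype: str,
    *,
    n_sections: int = 2,
    noise_sd: float = 1000.0,
    seed: int = 0,
) -> list[SectionSpec]:
    """Section specs for a cohort of animals sharing a count profile.

    Each animal's planted per-region counts are an independent Poisson draw
    around the profile means (between-animal biological variability); the
    profile itself is the group's expected anterior→posterior gradient
    (``CONTROL_GRADIENT``) or its flattened mutant counterpart
    (``FLAT_GRADIENT``).
    """
    specs = []
    for a in range(n_animals):
        rng = np.random.default_rng([seed, a])
        counts = {rid: max(1, int(rng.poisson(mu))) for rid, mu in gradient.items()}
        specs.append(
            SectionSpec(
                planted_counts=counts,
                noise_sd=noise_sd,
                n_sections=n_sections,
                seed=int(rng.integers(2**31)),
                animal_id=f"{genotype}_{a}",
                genotype=genotype,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Fibre-tract images
# ---------------------------------------------------------------------------


@dataclass
class TractSpec:
    """Recipe for one binary fibre-tract image.

    ``fascicles`` maps column x → list of inclusive (row_start, row_end)
    intervals, the fibre bundles crossing that column.  Columns not listed
    are empty.  The bundle envelope at a column is the hull of its
    intervals.  ``measurement_columns`` labels the x-positions at which the
    morphometry module measures (rostral, caudal, c250, c500).
    """

    image_shape: tuple[int, int] = (300, 400)
    pixel_size: float = 1.29  # µm/px
    n_sections: int = 1
    fascicles: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    measurement_columns: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        h, w = self.image_shape
        for x, intervals in self.fascicles.items():
            if not 0 <= x < w:
                raise ValueError(f"fascicle column {x} outside image")
            ordered = sorted(intervals)
            for r0, r1 in ordered:
                if r0 > r1 or r0 < 0 or r1 >= h:
                    raise ValueError(f"invalid row interval ({r0}, {r1}) at column {x}")
            for (a0, a1), (b0, _) in zip(ordered, ordered[1:]):
                if b0 <= a1:
                    raise ValueError(f"overlapping fascicle intervals at column {x}")
        for label, x in self.measurement_columns.items():
            if not 0 <= x < w:
                raise ValueError(f"measurement column {label}={x} outside image")


def column_truth(intervals: list[tuple[int, int]]) -> tuple[int, int, int]:
    """Analytic (total, fibre, gap) widths in px of disjoint row intervals."""
    if not intervals:
        return 0, 0, 0
    total = max(r1 for _, r1 in intervals) - min(r0 for r0, _ in intervals) + 1
    fibre = sum(r1 - r0 + 1 for r0, r1 in intervals)
    return total, fibre, total - fibre


def make_tract_image(spec: TractSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize a tract spec to a binary image plus analytic ground truth.

    The ground-truth table has one row per fascicle-bearing or measurement
    column: (column, total_px, fibre_px, gap_px, total_um, fibre_um, gap_um).
    """
    img = np.zeros(spec.image_shape, dtype=bool)
    for x, intervals in spec.fascicles.items():
        for r0, r1 in intervals:
            img[r0 : r1 + 1, x] = True
    columns = sorted(set(spec.fascicles) | set(spec.measurement_columns.values()))
    rows = []
    for x in columns:
        total, fibre, gap = column_truth(spec.fascicles.get(x, []))
        rows.append(
            {
                "column": x,
                "total_px": total,
                "fibre_px": fibre,
                "gap_px": gap,
                "total_um": total * spec.pixel_size,
                "fibre_um": fibre * spec.pixel_size,
                "gap_um": gap * spec.pixel_size,
            }
        )
    return img, pd.DataFrame(rows)


def band_fascicles(
    columns: range | list[int], bands: list[tuple[int, int]]
) -> dict[int, list[tuple[int, int]]]:
    """Constant horizontal bands across a column span (helper for specs)."""
    return {x: [tuple(b) for b in bands] for x in columns}


def make_tract_series(
    spec: TractSpec, seed: int = 0, max_jitter_px: int = 2
) -> tuple[list[SectionImage], pd.DataFrame]:
    """A medio-lateral series of tract sections with per-section jitter.

    Each section shifts every fascicle vertically by a deterministic random
    offset ≤ ``max_jitter_px`` (whole-column rigid shift, so per-column
    widths are unchanged but positions vary as across real serial sections).
    Ground truth is recomputed per section.
    """
    rng = np.random.default_rng(seed)
    h, _ = spec.image_shape
    sections = []
    truth_frames = []
    for s in range(spec.n_sections):
        shift = int(rng.integers(-max_jitter_px, max_jitter_px + 1)) if s else 0
        shifted = {}
        for x, intervals in spec.fascicles.items():
            moved = [(r0 + shift, r1 + shift) for r0, r1 in intervals]
            if any(r0 < 0 or r1 >= h for r0, r1 in moved):
                moved = intervals  # jitter would clip: keep original rows
            shifted[x] = moved
        img, truth = make_tract_image(
            TractSpec(
                image_shape=spec.image_shape,
                pixel_size=spec.pixel_size,
                n_sections=1,
                fascicles=shifted,
                measurement_columns=spec.measurement_columns,
            )
        )
        truth["section_index"] = s
        truth_frames.append(truth)
        sections.append(
            SectionImage(
                pixels=img.astype(np.uint8),
                bit_depth=8,
                pixel_size=spec.pixel_size,
                section_index=s,
                medio_lateral_pos=s * 100.0,
            )
        )
    return sections, pd.concat(truth_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Corticopontine point clouds
# ---------------------------------------------------------------------------


@dataclass
class ClusterSpec:
    """One Gaussian cluster of labelled-axon points."""

    centre: tuple[float, float, float]  # µm
    cov: object  # scalar variance, (3,) diagonal, or (3, 3) covariance
    n_points: int
    density_class: int = 2

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.density_class < 1:
            raise ValueError("density_class is ordinal, must be ≥ 1")

    def cov_matrix(self) -> np.ndarray:
        c = np.asarray(self.cov, dtype=float)
        if c.ndim == 0:
            return np.eye(3) * float(c)
        if c.ndim == 1:
            return np.diag(c)
        return c


@dataclass
class CloudSpec:
    """Recipe for paired control/shifted corticopontine point clouds."""

    volume: RegionVolume
    clusters: list[ClusterSpec]
    group_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    section_spacing: float = 100.0  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("at least one cluster required")
        centres = np.array([c.centre for c in self.clusters])
        if not self.volume.contains(centres).all():
            raise ValueError("cluster centres must lie inside the volume")
        if self.section_spacing <= 0:
            raise ValueError("section_spacing must be positive")


def make_pontine_volume(
    semi_axes: tuple[float, float, float] = (900.0, 500.0, 700.0),
    voxel_size: float = 25.0,
    margin_voxels: int = 2,
) -> RegionVolume:
    """Ellipsoidal pontine-nuclei-like volume mask on a µm voxel grid."""
    a = np.asarray(semi_axes, dtype=float)
    shape = np.ceil(2 * a / voxel_size).astype(int) + 2 * margin_voxels
    centre_um = (shape * voxel_size) / 2.0
    idx = np.indices(shape) + 0.5
    coords = idx * voxel_size  # voxel centres, origin at 0
    d2 = sum(((coords[i] - centre_um[i]) / a[i]) ** 2 for i in range(3))
    return RegionVolume(mask=d2 <= 1.0, voxel_size=voxel_size, origin=np.zeros(3))


def _sample_cluster_in_volume(
    cluster: ClusterSpec,
    shift: np.ndarray,
    volume: RegionVolume,
    section_spacing: float,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> np.ndarray:
    """Gaussian samples inside the volume; z snapped to section planes.

    Out-of-volume draws (including after the group shift) are rejected and
    resampled so both groups remain point processes on the same support.
    """
    centre = np.asarray(cluster.centre, dtype=float) + shift
    cov = cluster.cov_matrix()
    accepted: list[np.ndarray] = []
    need = cluster.n_points
    for _ in range(max_rounds):
        batch = rng.multivariate_normal(centre, cov, size=max(2 * need, 32))
        # snap z to the nearest section mid-plane before the membership test
        k = np.floor(batch[:, 2] / section_spacing)
        batch[:, 2] = (k + 0.5) * section_spacing
        keep = volume.contains(batch)
        accepted.extend(batch[keep])
        if len(accepted) >= cluster.n_points:
            return np.array(accepted[: cluster.n_points])
        need = cluster.n_points - len(accepted)
    raise ValueError(
        "rejection sampling failed: cluster (after group shift) does not fit "
        "inside the volume"
    )


def make_pointclouds(
    spec: CloudSpec,
) -> tuple[PointCloud3D, PointCloud3D, np.ndarray]:
    """Generate a control and a group-shifted cloud plus the true shift.

    The shifted cloud is the control generative process translated by
    ``group_shift`` and re-drawn under the same seed policy; all returned
    points lie inside the volume, with z snapped to section mid-planes at
    the spec's section spacing (as recorded points sit on section planes
    before z-jitter).
    """
    shift = np.asarray(spec.group_shift, dtype=float)
    clouds = []
    for gi, (group, offset) in enumerate(
        [("control", np.zeros(3)), ("shifted", shift)]
    ):
        xyz_parts, cls_parts = [], []
        for ci, cluster in enumerate(spec.clusters):
            rng = np.random.default_rng([spec.seed, gi, ci])
            pts = _sample_cluster_in_volume(
                cluster, offset, spec.volume, spec.section_spacing, rng
            )
            xyz_parts.append(pts)
            cls_parts.append(np.full(len(pts), cluster.density_class, dtype=int))
        xyz = np.vstack(xyz_parts)
        source = np.floor(xyz[:, 2] / spec.section_spacing).astype(int)
        clouds.append(
            PointCloud3D(
                xyz=xyz,
                density_class=np.concatenate(cls_parts),
                group=group,
                source_section=source,
            )
        )
    return clouds[0], clouds[1], shift
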