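"""Atlas-masked counting of labelled somata per cortical area.

Mirrors the classic particle-analysis recipe: delineate regions of interest
from a colour-coded atlas plate, subtract the image background, binarize,
keep objects with circularity in 0.5–1, and tabulate counts per region per
section, with the two count normalizations used for cohort comparison
(per-section counts, and motor/somatosensory percentages).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter as ndi_gaussian
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, white_tophat

from ponsquant.types import AtlasPlate, DetectedObject, RegionMap, SectionImage

UNASSIGNED = -1  # bucket for objects on background or unmapped colours


def extract_rois(
    plate: AtlasPlate, region_map: RegionMap
) -> tuple[dict[int, np.ndarray], np.ndarray, int]:
    """Delineate per-region binary masks from a plate's unique colour codes.

    Returns ``(masks, unassigned_mask, n_unassigned_px)``.  Masks are
    pairwise disjoint (each pixel has one colour) and together with the
    black background and the unassigned set they cover the plate.  A colour
    present in the plate but absent from the map is not fatal: its pixels
    land in the unassigned mask and their count is reported.
    """
    px = plate.pixels
    masks: dict[int, np.ndarray] = {}
    matched = np.zeros(px.shape[:2], dtype=bool)
    for colour, rid in region_map.colour_lookup().items():
        m = np.all(px == np.array(colour, dtype=px.dtype), axis=2)
        masks[rid] = m
        matched |= m
    background = np.all(px == 0, axis=2)
    unassigned = ~matched & ~background
    n_unassigned = int(unassigned.sum())
    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} plate pixels have colours absent from the region map",
            stacklevel=2,
        )
    return masks, unassigned, n_unassigned


def subtract_background(img: SectionImage, radius_px: int = 15) -> SectionImage:
    """Remove slowly varying background with a white top-hat transform.

    The structuring element is a disk of ``radius_px``; structures smaller
    than the disk (the somata) survive, flat or slowly graded background
    maps to ~0.  Output is non-negative by construction.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be ≥ 1")
    if radius_px >= min(img.shape):
        raise ValueError("background radius larger than the image")
    # crosses decomposition is an exact factorisation of the disk and much
    # faster than the monolithic footprint
    corrected = white_tophat(
        img.pixels, footprint=disk(radius_px, decomposition="crosses")
    )
    return img.with_pixels(corrected)


# Moore neighbourhood, clockwise starting north
_NBRS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_DIR_INDEX = {d: i for i, d in enumerate(_NBRS)}


def _boundary_perimeter(mask: np.ndarray) -> float:
    """Contour length by Moore boundary following (√2 for diagonal steps).

    ``mask`` is a cropped binary patch holding a single 8-connected object.
    The walk starts at the first foreground pixel in raster order (its west
    neighbour is background) and stops when the initial transition out of
    the start pixel repeats (Jacob's criterion).  A single pixel has no
    closed walk and gets the unit-square perimeter 4.
    """
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    start = tuple(np.argwhere(padded)[0])
    cur = start
    last_bg = (start[0], start[1] - 1)  # background we "entered" from
    sqrt2 = float(np.sqrt(2.0))
    perim = 0.0
    first_transition = None
    while True:
        b = _DIR_INDEX[(last_bg[0] - cur[0], last_bg[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            d = (b + k) % 8
            cand = (cur[0] + _NBRS[d][0], cur[1] + _NBRS[d][1])
            if padded[cand]:
                nxt = cand
                step_dir = d
                break
            last_bg = cand
        if nxt is None:
            return 4.0  # isolated pixel
        if first_transition is None:
            first_transition = (cur, nxt)
        elif (cur, nxt) == first_transition:
            return perim
        perim += sqrt2 if _NBRS[step_dir][0] and _NBRS[step_dir][1] else 1.0
        cur = nxt


def circularity(area: float, perimeter: float) -> float:
    """4π·area/perimeter², clamped to 1.0 (rasterization can exceed 1)."""
    if perimeter <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


def detect_objects(
    img: SectionImage,
    threshold: float | str = "otsu",
    min_area: int = 4,
) -> list[DetectedObject]:
    """Binarize a background-corrected section and measure its particles.

    Objects are 8-connected components of ``pixels > threshold``; each
    carries area, boundary-following perimeter, circularity and mean
    intensity.  ``min_area`` (px) drops sub-somatic specks; an all-zero
    image yields an empty list.
    """
    pixels = img.pixels
    if threshold == "otsu":
        if pixels.max() == pixels.min():
            return []
        thresh = threshold_otsu(pixels)
    else:
        thresh = float(threshold)
    binary = pixels > thresh
    if not binary.any():
        return []
    labels = label(binary, connectivity=2)
    objects: list[DetectedObject] = []
    for prop in regionprops(labels, intensity_image=pixels):
        if prop.area < min_area:
            continue
        perim = _boundary_perimeter(prop.image)
        objects.append(
            DetectedObject(
                centroid=tuple(prop.centroid),
                area=float(prop.area),
                perimeter=perim,
                circularity=circularity(prop.area, perim),
                mean_intensity=float(prop.intensity_mean),
            )
        )
    return objects


def filter_by_circularity(
    objects: list[DetectedObject], lo: float = 0.5, hi: float = 1.0
) -> list[DetectedObject]:
    """Keep objects with lo ≤ circularity ≤ hi (defaults 0.5–1)."""
    if not 0 <= lo <= hi <= 1:
        raise ValueError("require 0 ≤ lo ≤ hi ≤ 1")
    return [o for o in objects if lo <= o.circularity <= hi]


def count_per_region(
    objects: list[DetectedObject],
    rois: dict[int, np.ndarray],
    unassigned_mask: np.ndarray | None = None,
    *,
    animal_id: str = "",
    genotype: str = "",
    section_index: int = 0,
) -> pd.DataFrame:
    """Assign objects to regions by centroid pixel and tabulate counts.

    Returns one row per region plus an ``UNASSIGNED`` (-1) bucket for
    objects whose centroid falls on background or unmapped colours; the
    bucket totals always conserve the number of input objects.
    """
    shapes = {m.shape for m in rois.values()}
    if unassigned_mask is not None:
        shapes.add(unassigned_mask.shape)
    if len(shapes) > 1:
        raise ValueError("ROI masks have inconsistent shapes")
    counts = {rid: 0 for rid in rois}
    counts[UNASSIGNED] = 0
    for obj in objects:
        r, c = (int(round(v)) for v in obj.centroid)
        assigned = UNASSIGNED
        for rid, mask in rois.items():
            if mask[r, c]:
                assigned = rid
                break
        obj.region_id = None if assigned == UNASSIGNED else assigned
        counts[assigned] += 1
    rows = [
        {
            "animal_id": animal_id,
            "genotype": genotype,
            "section_index": section_index,
            "region_id": rid,
            "raw_count": n,
        }
        for rid, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def count_section(
    img: SectionImage,
    plate: AtlasPlate,
    region_map: RegionMap,
    *,
    background_radius_px: int = 15,
    threshold: float | str = "otsu",
    circ: tuple[float, float] = (0.5, 1.0),
    min_area: int = 4,
    smooth_sigma: float = 1.0,
    animal_id: str = "",
    genotype: str = "",
) -> pd.DataFrame:
    """Full counting pipeline for one section/plate pair.

    Gaussian noise suppression (σ = ``smooth_sigma`` px, the counterpart
    of find-maxima's noise tolerance; 0 disables) → top-hat background
    subtraction → threshold → circularity gate → per-region centroid
    assignment.
    """
    if img.shape != plate.shape:
        raise ValueError("section image and atlas plate shapes differ")
    rois, unassigned, _ = extract_rois(plate, region_map)
    if smooth_sigma > 0:
        smoothed = ndi_gaussian(img.pixels.astype(float), smooth_sigma)
        img = img.with_pixels(np.rint(smoothed).astype(img.pixels.dtype))
    corrected = subtract_background(img, background_radius_px)
    objects = detect_objects(corrected, threshold=threshold, min_area=min_area)
    kept = filter_by_circularity(objects, *circ)
    return count_per_region(
        kept,
        rois,
        unassigned,
        animal_id=animal_id,
        genotype=genotype,
        section_index=img.section_index,
    )


def normalize_counts(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Derive normalized count columns from raw per-section region counts.

    ``per_section``: per-animal per-region total divided by the number of
    sections analysed for that animal.  ``MS_percentage``: per animal,
    counts in the motor (M) and somatosensory (S) areas as percentages of
    their sum, so %M + %S = 100 exactly.  Region ids follow the synthetic
    convention M=2, S=3 unless the table carries a ``region_name`` column.
    """
    t = table[table["region_id"] != UNASSIGNED]
    if mode == "per_section":
        if t.empty:
            raise ValueError("per_section normalization needs at least one section")
        out = []
        for (animal, rid), grp in t.groupby(["animal_id", "region_id"]):
            n_sections = t[t["animal_id"] == animal]["section_index"].nunique()
            out.append(
                {
                    "animal_id": animal,
                    "region_id": rid,
                    "total_count": int(grp["raw_count"].sum()),
                    "n_sections": n_sections,
                    "per_section": grp["raw_count"].sum() / n_sections,
                }
            )
        return pd.DataFrame(out)
    if mode == "MS_percentage":
        if "region_name" in t.columns:
            m_ids = set(t.loc[t["region_name"] == "M", "region_id"])
            s_ids = set(t.loc[t["region_name"] == "S", "region_id"])
        else:
            m_ids, s_ids = {2}, {3}
        out = []
        for animal, grp in t.groupby("animal_id"):
            m = int(grp.loc[grp["region_id"].isin(m_ids), "raw_count"].sum())
            s = int(grp.loc[grp["region_id"].isin(s_ids), "raw_count"].sum())
            if m + s == 0:
                raise ValueError(
                    f"animal {animal!r}: M+S total is zero, percentages undefined"
                )
            out.append(
                {
                    "animal_id": animal,
                    "M_count": m,
                    "S_count": s,
                    "pct_M": 100.0 * m / (m + s),
                    "pct_S": 100.0 * s / (m + s),
                }
            )
        return pd.DataFrame(out)
    raise ValueError(f"unknown normalization mode {mode!r}")
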