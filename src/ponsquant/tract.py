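"""Corticospinal-tract width profiling and fasciculation morphometry.

On registered sagittal sections the descending tract runs roughly
horizontally, so the dorso-ventral extent of the labelled bundle at a given
medio-lateral measurement site is read off a single image column: the
*total* width spans from the first to the last signal row, the *fibre*
width counts only signal rows, and their difference is the summed gap
between fascicles.  The fasciculation index is fibre/total — 1.0 for a
fully fasciculated bundle, lower when fibres spread apart.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ponsquant.types import SectionImage

#: Canonical measurement labels: rostral/caudal to the pontine nuclei and
#: 250/500 µm caudal to their terminal edge.
MEASUREMENT_LABELS = ("rostral", "caudal", "c250", "c500")


def offset_to_columns(
    edge_column: int, offsets_um: tuple[float, ...], pixel_size: float
) -> dict[str, int]:
    """Convert caudal µm offsets from the tract's reference edge to columns.

    Offsets are rounded half-away-from-zero to whole columns.
    """
    cols = {}
    for off in offsets_um:
        px = int(np.sign(off) * np.floor(abs(off) / pixel_size + 0.5))
        cols[f"c{int(off)}"] = edge_column + px
    return cols


def _as_binary(img: SectionImage | np.ndarray, threshold: float | None) -> np.ndarray:
    pixels = img.pixels if isinstance(img, SectionImage) else np.asarray(img)
    if pixels.dtype == bool:
        return pixels
    if threshold is None:
        return pixels > 0
    return pixels > threshold


def width_at_column(
    img: SectionImage | np.ndarray,
    x: int,
    pixel_size: float = 1.0,
    *,
    threshold: float | None = None,
    halfwidth: int = 0,
) -> tuple[float, float, float]:
    """(total, fibre, gap) dorso-ventral widths in µm at one column.

    total = (last signal row − first signal row + 1) · pixel_size,
    fibre = number of signal rows · pixel_size, gap = total − fibre.
    An empty column yields (0, 0, 0).  With ``halfwidth`` k > 0 the column
    profile is the per-row median over columns x−k..x+k, for robustness to
    single-column dropouts.
    """
    binary = _as_binary(img, threshold)
    h, w = binary.shape
    if not 0 <= x < w:
        raise ValueError(f"column {x} outside image of width {w}")
    if halfwidth:
        lo, hi = max(0, x - halfwidth), min(w, x + halfwidth + 1)
        col = np.median(binary[:, lo:hi], axis=1) >= 0.5
    else:
        col = binary[:, x]
    rows = np.nonzero(col)[0]
    if len(rows) == 0:
        return 0.0, 0.0, 0.0
    total_px = int(rows[-1] - rows[0] + 1)
    fibre_px = int(len(rows))
    return (
        total_px * pixel_size,
        fibre_px * pixel_size,
        (total_px - fibre_px) * pixel_size,
    )


def profile_series(
    images: list[SectionImage],
    columns: dict[str, int] | list[dict[str, int]],
    *,
    threshold: float | None = None,
    halfwidth: int = 0,
) -> pd.DataFrame:
    """Width profile across a medio-lateral series of sections.

    ``columns`` maps measurement label → column, either one mapping shared
    by all sections or one per section.  Returns one row per section per
    label with total/fibre/gap widths in µm, ordered lateral→medial
    (ascending ``medio_lateral_pos``).  A label whose column is missing for
    a section is flagged ``missing`` rather than failing.
    """
    if not images:
        raise ValueError("at least one section required")
    per_section = columns if isinstance(columns, list) else [columns] * len(images)
    if len(per_section) != len(images):
        raise ValueError("need one column mapping per section")
    labels = sorted({lbl for m in per_section for lbl in m})
    rows = []
    for img, colmap in zip(images, per_section):
        for lbl in labels:
            if lbl not in colmap:
                rows.append(
                    {
                        "section_index": img.section_index,
                        "medio_lateral_pos": img.medio_lateral_pos,
                        "measurement_label": lbl,
                        "total_width": np.nan,
                        "fibre_width": np.nan,
                        "gap_width": np.nan,
                        "missing": True,
                    }
                )
                continue
            total, fibre, gap = width_at_column(
                img,
                colmap[lbl],
                img.pixel_size,
                threshold=threshold,
                halfwidth=halfwidth,
            )
            rows.append(
                {
                    "section_index": img.section_index,
                    "medio_lateral_pos": img.medio_lateral_pos,
                    "measurement_label": lbl,
                    "total_width": total,
                    "fibre_width": fibre,
                    "gap_width": gap,
                    "missing": False,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["medio_lateral_pos", "measurement_label"])
        .reset_index(drop=True)
    )


def area_under_profile(profile: pd.DataFrame, label: str) -> float:
    """Trapezoidal integral (µm²) of total width over medio-lateral position.

    Entries flagged missing are skipped with a warning; fewer than two
    valid entries is an error.
    """
    sel = profile[profile["measurement_label"] == label]
    if sel["missing"].any():
        warnings.warn(
            f"{int(sel['missing'].sum())} missing entries skipped for {label!r}",
            stacklevel=2,
        )
        sel = sel[~sel["missing"]]
    sel = sel.sort_values("medio_lateral_pos")
    if len(sel) < 2:
        raise ValueError(f"need ≥2 valid entries with label {label!r} for AUC")
    return float(
        np.trapezoid(sel["total_width"].to_numpy(), sel["medio_lateral_pos"].to_numpy())
    )


def fasciculation_index(
    total_width: float, fibre_width: float, *, reciprocal: bool = False
) -> float:
    """Fibre-to-total width ratio; 1.0 means fully fasciculated.

    Returns NaN when total_width is 0 (no bundle to measure).  With
    ``reciprocal=True`` returns total/fibre instead, for the opposite
    reading of the width ratio.
    """
    if total_width == 0:
        return float("nan")
    if fibre_width < 0 or fibre_width > total_width:
        raise ValueError("require 0 ≤ fibre_width ≤ total_width")
    if reciprocal:
        if fibre_width == 0:
            return float("nan")
        return total_width / fibre_width
    return fibre_width / total_width


def fasciculation_table(
    profile: pd.DataFrame, labels: tuple[str, ...] = ("c250", "c500")
) -> pd.DataFrame:
    """Per-section fasciculation indices at the caudal offset labels."""
    sel = profile[profile["measurement_label"].isin(labels) & ~profile["missing"]]
    out = sel.copy()
    out["index"] = [
        fasciculation_index(t, f)
        for t, f in zip(sel["total_width"], sel["fibre_width"])
    ]
    return out[["section_index", "medio_lateral_pos", "measurement_label", "index"]].reset_index(
        drop=True
    )
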