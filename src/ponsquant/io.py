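"""Readers and writers for the pipeline's on-disk formats.

Grayscale sections travel as 16-bit TIFF (tifffile), atlas plates as RGB
PNG (imageio), region lookups and count tables as CSV, point clouds as
JSON-lines records with explicit axis names, volume masks as .npy with a
JSON sidecar (voxel_size, origin).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from ponsquant.types import AtlasPlate, PointCloud3D, RegionMap, RegionVolume, SectionImage


def write_section(path: str | Path, img: SectionImage) -> None:
    tifffile.imwrite(str(path), img.pixels)


def read_section(
    path: str | Path,
    pixel_size: float = 1.0,
    section_index: int = 0,
    medio_lateral_pos: float = 0.0,
) -> SectionImage:
    p = Path(path)
    pixels = tifffile.imread(str(p)) if p.suffix.lower() in (".tif", ".tiff") else iio.imread(p)
    if pixels.ndim == 3:  # grayscale stored with redundant channels
        pixels = pixels[..., 0]
    bit_depth = 8 if pixels.dtype == np.uint8 else 16
    return SectionImage(
        pixels=pixels,
        bit_depth=bit_depth,
        pixel_size=pixel_size,
        section_index=section_index,
        medio_lateral_pos=medio_lateral_pos,
    )


def write_plate(path: str | Path, plate: AtlasPlate) -> None:
    iio.imwrite(Path(path), plate.pixels.astype(np.uint8))


def read_plate(path: str | Path) -> AtlasPlate:
    pixels = iio.imread(Path(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return AtlasPlate(pixels=pixels)


def write_region_map(path: str | Path, region_map: RegionMap) -> None:
    pd.DataFrame(
        [
            {"region_id": rid, "name": name, "r": c[0], "g": c[1], "b": c[2]}
            for rid, name, c in region_map.entries
        ]
    ).to_csv(path, index=False)


def read_region_map(path: str | Path) -> RegionMap:
    df = pd.read_csv(path)
    return RegionMap(
        entries=[
            (int(r.region_id), str(r.name), (int(r.r), int(r.g), int(r.b)))
            for r in df.itertuples()
        ]
    )


def write_pointcloud(path: str | Path, cloud: PointCloud3D) -> None:
    """JSON-lines records {x_um, y_um, z_um, density_class, group, source_section}."""
    with open(path, "w") as fh:
        for (x, y, z), cls, sec in zip(
            cloud.xyz, cloud.density_class, cloud.source_section
        ):
            fh.write(
                json.dumps(
                    {
                        "x_um": float(x),
                        "y_um": float(y),
                        "z_um": float(z),
                        "density_class": int(cls),
                        "group": cloud.group,
                        "source_section": int(sec),
                    }
                )
                + "\n"
            )


def read_pointcloud(path: str | Path) -> PointCloud3D:
    records = [json.loads(line) for line in Path(path).read_text().splitlines() if line]
    if not records:
        return PointCloud3D(xyz=np.empty((0, 3)))
    return PointCloud3D(
        xyz=np.array([[r["x_um"], r["y_um"], r["z_um"]] for r in records]),
        density_class=np.array([r.get("density_class", 1) for r in records]),
        group=records[0].get("group", ""),
        source_section=np.array([r.get("source_section", 0) for r in records]),
    )


def write_volume(path_stem: str | Path, volume: RegionVolume) -> None:
    """Raster to <stem>.npy plus a <stem>.json sidecar with the µm geometry."""
    stem = Path(path_stem)
    np.save(stem.with_suffix(".npy"), volume.mask)
    stem.with_suffix(".json").write_text(
        json.dumps(
            {"voxel_size": volume.voxel_size, "origin": list(map(float, volume.origin))}
        )
    )


def read_volume(path_stem: str | Path) -> RegionVolume:
    stem = Path(path_stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return RegionVolume(
        mask=np.load(stem.with_suffix(".npy")),
        voxel_size=meta["voxel_size"],
        origin=np.array(meta["origin"]),
    )
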