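"""Readers and writers for the package's on-disk formats.

* Hyperspectral cubes: multi-page TIFF (page order = channel order of the
  spectral axis) plus a YAML sidecar with the axis regions, zoom, per-region
  laser powers and bit depth.
* Reference sets: CSV with a wavenumber column and one column per component;
  the round trip is bit-exact (floats serialized with ``repr``).
* Label images: 16-bit TIFF; weight images: multi-page 32-bit float TIFF
  (pages TAG, CE, cellular_bg, water_bg) plus a saturation-mask TIFF.
* False-color renderings: 8-bit PNG.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .spectral import (
    COMPONENTS,
    AcquisitionSettings,
    HyperCube,
    ReferenceSet,
    SpectralAxis,
    build_spectral_axis,
)
from .unmixing import WeightImage

__all__ = [
    "write_cube",
    "read_cube",
    "write_reference_set",
    "read_reference_set",
    "write_label_image",
    "read_label_image",
    "write_weight_image",
    "read_weight_image",
    "write_falsecolor_png",
    "write_pore_coords",
    "read_pore_coords",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".yaml")


def write_cube(path: str | Path, cube: HyperCube) -> None:
    """Write a cube as channel-paged TIFF + YAML settings sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.data, 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "regions": [list(r) for r in cube.axis.regions],
        "zoom": cube.settings.zoom,
        "pump_power": list(cube.settings.pump_power)
        if isinstance(cube.settings.pump_power, tuple)
        else cube.settings.pump_power,
        "stokes_power": list(cube.settings.stokes_power)
        if isinstance(cube.settings.stokes_power, tuple)
        else cube.settings.stokes_power,
        "bit_depth": cube.settings.bit_depth,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_cube(path: str | Path) -> HyperCube:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    axis = build_spectral_axis([tuple(r) for r in meta["regions"]])
    settings = AcquisitionSettings(
        zoom=meta["zoom"],
        pump_power=tuple(meta["pump_power"])
        if isinstance(meta["pump_power"], list)
        else meta["pump_power"],
        stokes_power=tuple(meta["stokes_power"])
        if isinstance(meta["stokes_power"], list)
        else meta["stokes_power"],
        bit_depth=meta["bit_depth"],
    )
    return HyperCube(np.moveaxis(pages, 0, 2), axis, settings)


def write_reference_set(path: str | Path, refs: ReferenceSet) -> None:
    """CSV writer; floats use ``repr`` so the round trip is bit-exact."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavenumber_cm", *COMPONENTS])
        for i, wn in enumerate(refs.axis.wavenumbers):
            writer.writerow([repr(float(wn)), *(repr(float(v)) for v in refs.S[i])])


def read_reference_set(path: str | Path, axis: SpectralAxis) -> ReferenceSet:
    df = pd.read_csv(path, float_precision="round_trip")
    if not np.array_equal(df["wavenumber_cm"].to_numpy(), axis.wavenumbers):
        raise ValueError("reference CSV wavenumbers do not match the axis")
    return ReferenceSet(df[list(COMPONENTS)].to_numpy(), axis)


def write_label_image(path: str | Path, labels: np.ndarray) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label image exceeds 16-bit range")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_label_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_weight_image(path: str | Path, wi: WeightImage) -> None:
    path = Path(path)
    pages = np.moveaxis(wi.W.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    tifffile.imwrite(
        path.with_name(path.stem + "_saturation.tif"),
        wi.saturation_mask.astype(np.uint8),
    )


def read_weight_image(
    path: str | Path,
    axis: SpectralAxis,
    settings: AcquisitionSettings | None = None,
) -> WeightImage:
    path = Path(path)
    pages = tifffile.imread(path)
    sat_path = path.with_name(path.stem + "_saturation.tif")
    sat = tifffile.imread(sat_path).astype(bool) if sat_path.exists() else None
    if settings is None:
        settings = AcquisitionSettings()
    return WeightImage(np.moveaxis(pages, 0, 2), axis, settings, saturation_mask=sat)


def write_falsecolor_png(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.clip(rgb, 0, 1) * 255).astype(np.uint8))


def write_pore_coords(path: str | Path, coords: np.ndarray) -> None:
    """Coordinates CSV: columns x_um, y_um and, for 3D sets, z_um."""
    coords = np.atleast_2d(coords)
    cols = ["x_um", "y_um", "z_um"][: coords.shape[1]]
    pd.DataFrame(coords, columns=cols).to_csv(path, index=False)


def read_pore_coords(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = [c for c in ("x_um", "y_um", "z_um") if c in df.columns]
    if len(cols) < 2:
        raise ValueError("pore CSV must contain x_um and y_um columns")
    return df[cols].to_numpy(dtype=float)
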