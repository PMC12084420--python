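"""Subcellular-distribution metrics.

Four small measurements of where signal sits within a cell:

* **nuclear proximity** -- the intensity-weighted average of the normalized
  distance d_PM / (d_N + d_PM), where d_N is the shortest distance to the
  nucleus and d_PM the shortest distance to the cell-mask contour (the
  plasma-membrane proxy).  The score is 1 for signal in the nucleus and 0
  for signal at the edge of the cell mask.
* **nuclear/cytoplasmic translocation ratio** -- mean nuclear over mean
  cytoplasmic (cell minus nucleus) intensity, both after subtracting the
  well-level outside-cell background; the standard readout of
  transcription-factor (e.g. NF-kB p65) nuclear entry.
* **focus-slice selection** -- pick the z slice with the highest total
  reference-channel (nuclear stain) intensity, or maximum-intensity project.
* **Dendra2 photoconversion ratio** -- nuclear red fluorescence over the
  pre-conversion green fluorescence at the photoconverted region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "ProximityInputs",
    "TranslocationRecord",
    "proximity_inputs",
    "nuclear_proximity",
    "outside_cell_background",
    "nuccyto_translocation",
    "select_focus_slice",
    "dendra2_ratio",
]


@dataclass
class ProximityInputs:
    """Intensity and distance fields for the nuclear-proximity score."""

    intensity: np.ndarray
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    d_n: np.ndarray
    d_pm: np.ndarray


def _contour(cell_mask: np.ndarray) -> np.ndarray:
    """Cell pixels adjacent to background (the outer contour)."""
    eroded = ndi.binary_erosion(cell_mask, border_value=0)
    return cell_mask & ~eroded


def proximity_inputs(
    intensity: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
) -> ProximityInputs:
    """Compute the Euclidean distance fields for one cell.

    ``d_n`` is 0 inside the nucleus; ``d_pm`` is 0 on the cell-mask contour
    (background-adjacent cell pixels), the convention under which contour
    signal scores 0.
    """
    intensity = np.asarray(intensity, dtype=float)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not (intensity.shape == nucleus_mask.shape == cell_mask.shape):
        raise ValueError("intensity and mask shapes differ")
    if np.any(nucleus_mask & ~cell_mask):
        raise ValueError("nucleus mask must be contained in the cell mask")
    d_n = ndi.distance_transform_edt(~nucleus_mask)
    d_pm = ndi.distance_transform_edt(~_contour(cell_mask))
    return ProximityInputs(intensity, nucleus_mask, cell_mask, d_n, d_pm)


def nuclear_proximity(inputs: ProximityInputs) -> float:
    """Intensity-weighted nuclear-proximity score in [0, 1].

    score = sum_k (i_k / I) * d_PM,k / (d_N,k + d_PM,k) over cell pixels k,
    where I is the total intensity in the cell.  Pixels with
    d_N = d_PM = 0 are nuclear and contribute weight 1.
    """
    cell = inputs.cell_mask
    i = np.where(cell, inputs.intensity, 0.0)
    total = i.sum()
    if total <= 0:
        raise ValueError("total intensity in the cell must be > 0")
    d_n, d_pm = inputs.d_n, inputs.d_pm
    denom = d_n + d_pm
    ratio = np.ones_like(denom)
    nz = denom > 0
    ratio[nz] = d_pm[nz] / denom[nz]
    return float((i / total * ratio)[cell].sum())


def outside_cell_background(
    intensity: np.ndarray,
    cells: np.ndarray,
    mode: str = "mean",
    percentile: float = 50.0,
) -> float:
    """Well-level background: statistic of all pixels outside every cell.

    Default is the plain mean of outside-cell pixels; ``mode="percentile"``
    offers a robust alternative.
    """
    intensity = np.asarray(intensity, dtype=float)
    outside = np.asarray(cells) == 0
    if not outside.any():
        raise ValueError("no pixels outside the cell masks")
    vals = intensity[outside]
    if mode == "mean":
        return float(vals.mean())
    if mode == "percentile":
        return float(np.percentile(vals, percentile))
    raise ValueError(f"unknown background mode {mode!r}")


@dataclass
class TranslocationRecord:
    """Background-subtracted nuclear/cytoplasmic intensity ratio for a cell."""

    cell_id: int
    nuc_mean: float
    cyto_mean: float
    background: float
    ratio: float
    ratio_rel_baseline: float
    valid: bool = True


def nuccyto_translocation(
    intensity: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    background: float,
    baseline_mean: float | None = None,
    cell_id: int = 0,
) -> TranslocationRecord:
    """Nuclear/cytoplasmic translocation ratio for one cell.

    ratio = (mean_nuc - bg) / (mean_cyto - bg), with the cytoplasm defined
    as cell minus nucleus.  A non-positive background-subtracted cytoplasmic
    mean flags the record invalid (ratio NaN) rather than raising.
    ``ratio_rel_baseline`` divides by the mean ratio of the designated
    baseline condition (e.g. the 0-min treatment), when given.
    """
    intensity = np.asarray(intensity, dtype=float)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    cyto = cell_mask & ~nucleus_mask
    if not nucleus_mask.any() or not cyto.any():
        raise ValueError("cell must have non-empty nuclear and cytoplasmic areas")
    nuc_mean = float(intensity[nucleus_mask].mean())
    cyto_mean = float(intensity[cyto].mean())
    denom = cyto_mean - background
    valid = denom > 0
    ratio = (nuc_mean - background) / denom if valid else float("nan")
    rel = ratio / baseline_mean if (valid and baseline_mean) else (
        ratio if valid and baseline_mean is None else float("nan")
    )
    return TranslocationRecord(
        cell_id=cell_id,
        nuc_mean=nuc_mean,
        cyto_mean=cyto_mean,
        background=float(background),
        ratio=ratio,
        ratio_rel_baseline=rel,
        valid=valid,
    )


def select_focus_slice(
    stack3d: np.ndarray,
    reference_stack3d: np.ndarray,
    mode: str = "best_slice",
) -> np.ndarray:
    """Collapse a z stack to 2D.

    ``mode="best_slice"`` picks the slice whose reference channel (e.g. the
    nuclear stain) has the highest total intensity and returns that slice of
    ``stack3d`` (ties break to the lowest index); ``mode="max_project"``
    returns the per-pixel maximum-intensity projection of ``stack3d``.
    """
    stack3d = np.asarray(stack3d)
    reference = np.asarray(reference_stack3d)
    if stack3d.ndim != 3 or reference.ndim != 3:
        raise ValueError("stacks must be Z x H x W")
    if stack3d.shape[0] == 0:
        raise ValueError("empty stack")
    if stack3d.shape[0] != reference.shape[0]:
        raise ValueError("stacks have different slice counts")
    if mode == "max_project":
        return stack3d.max(axis=0)
    if mode == "best_slice":
        totals = reference.reshape(reference.shape[0], -1).sum(axis=1)
        return stack3d[int(np.argmax(totals))]
    raise ValueError(f"unknown mode {mode!r}")


def dendra2_ratio(red_nuc_roi_mean: float, green_preconv_roi_mean: float) -> float:
    """Nuclear red fluorescence normalized by pre-conversion green.

    Quantifies the arrival of cytoplasm-photoconverted Dendra2 in a nuclear
    region relative to the amount of convertible protein at the conversion
    site; invariant under joint rescaling of both channels.
    """
    if green_preconv_roi_mean <= 0:
        raise ValueError("pre-conversion green mean must be > 0")
    return float(red_nuc_roi_mean) / float(green_preconv_roi_mean)
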