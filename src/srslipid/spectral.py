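"""Spectral-axis construction, background spectra and reference-set assembly.

Hyperspectral stimulated Raman scattering (SRS) acquisitions tile a set of
Raman-shift regions (e.g. the fingerprint carbonyl region 1625-1775 cm^-1 and
the C-H stretch regions 2800-2950 and 2950-3100 cm^-1) at a fixed wavenumber
step.  Everything downstream -- cover-glass background estimation, reference
spectra for triacylglycerol (TAG) and cholesteryl ester (CE), and per-pixel
non-negative unmixing -- is expressed on this channel axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Fixed component order used throughout the package.
COMPONENTS = ("TAG", "CE", "cellular_bg", "water_bg")

SPECTRUM_KINDS = frozenset(
    {"TAG", "CE", "cellular_bg", "water_bg", "raw", "cover_glass"}
)

#: The canonical three-region acquisition at 3 cm^-1 step (153 channels).
DEFAULT_REGIONS = ((1625.0, 1775.0, 3.0), (2800.0, 2950.0, 3.0), (2950.0, 3100.0, 3.0))


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered wavenumber grid assembled from acquisition regions.

    A wavenumber shared by two adjacent regions (2950 cm^-1 in the canonical
    three-region layout) is retained as two distinct channels, one per
    region, because each region is a separate acquisition: the canonical
    layout therefore has 3 x 51 = 153 channels.
    """

    regions: tuple[tuple[float, float, float], ...]
    wavenumbers: np.ndarray
    region_index: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def step_cm(self) -> float:
        """Step of the first region (all-region steps are usually equal)."""
        return self.regions[0][2]

    def region_slice(self, region: int) -> slice:
        idx = np.flatnonzero(self.region_index == region)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def channel_at(self, wavenumber_cm: float) -> int:
        """Index of the channel closest to ``wavenumber_cm``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber_cm)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.regions == other.regions

    def __hash__(self) -> int:
        return hash(self.regions)


def build_spectral_axis(
    regions: Iterable[tuple[float, float, float]],
) -> SpectralAxis:
    """Assemble a :class:`SpectralAxis` from ``(start, end, step)`` regions.

    Each region must satisfy ``end > start``, ``step > 0`` and an integer
    number of steps between the endpoints; both endpoints are included.

    >>> build_spectral_axis([(1625, 1775, 3), (2800, 2950, 3), (2950, 3100, 3)]).n_channels
    153
    """
    regions = tuple((float(s), float(e), float(st)) for s, e, st in regions)
    if not regions:
        raise ValueError("at least one spectral region is required")
    grids = []
    index = []
    for i, (start, end, step) in enumerate(regions):
        if step <= 0:
            raise ValueError(f"region {i} ({start}-{end}): step must be > 0, got {step}")
        if end <= start:
            raise ValueError(f"region {i}: end ({end}) must exceed start ({start})")
        n_steps = (end - start) / step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"region {i} ({start}-{end} cm^-1): range not divisible by step {step}"
            )
        n = int(round(n_steps)) + 1
        grids.append(start + step * np.arange(n))
        index.append(np.full(n, i, dtype=np.int32))
    wavenumbers = np.concatenate(grids)
    wavenumbers.setflags(write=False)
    region_index = np.concatenate(index)
    region_index.setflags(write=False)
    return SpectralAxis(regions, wavenumbers, region_index)


@dataclass(frozen=True)
class AcquisitionSettings:
    """Per-acquisition imaging settings.

    Powers may be scalars (one laser setting for the whole spectrum) or
    per-region sequences matching the axis regions.  SRS signal is linear in
    pump x Stokes power, which is what weight normalization relies on.
    """

    zoom: float = 1.0
    pump_power: float | tuple[float, ...] = 1.0
    stokes_power: float | tuple[float, ...] = 1.0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.zoom <= 0:
            raise ValueError("zoom must be > 0")
        if self.bit_depth < 8:
            raise ValueError("bit_depth must be >= 8")
        for name in ("pump_power", "stokes_power"):
            val = getattr(self, name)
            if isinstance(val, (list, tuple, np.ndarray)):
                object.__setattr__(self, name, tuple(float(v) for v in val))
                val = getattr(self, name)
                if any(v <= 0 for v in val):
                    raise ValueError(f"{name} entries must be > 0")
            elif float(val) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def power_product(self, region: int) -> float:
        """pump x Stokes power for ``region`` (scalars broadcast)."""

        def pick(p):
            return p[region] if isinstance(p, tuple) else p

        return float(pick(self.pump_power)) * float(pick(self.stokes_power))


@dataclass
class Spectrum:
    """A single spectrum on a :class:`SpectralAxis`."""

    values: np.ndarray
    axis: SpectralAxis
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.axis.n_channels:
            raise ValueError(
                f"spectrum length {self.values.size} does not match axis "
                f"channel count {self.axis.n_channels}"
            )
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")


@dataclass
class HyperCube:
    """Raw H x W x C hyperspectral SRS image with acquisition settings."""

    data: np.ndarray
    axis: SpectralAxis
    settings: AcquisitionSettings = field(default_factory=AcquisitionSettings)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x C")
        if self.data.shape[2] != self.axis.n_channels:
            raise ValueError(
                f"cube has {self.data.shape[2]} channels, axis has "
                f"{self.axis.n_channels}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def flattened(self) -> np.ndarray:
        """Pixels row-wise collected into an N x C float matrix."""
        return self.data.reshape(-1, self.axis.n_channels).astype(float)


@dataclass
class ReferenceSet:
    """The C x 4 matrix S of component spectra in :data:`COMPONENTS` order.

    TAG and CE columns are stored after capped subtraction of the cellular
    background, so all entries are non-negative.  Spectra are kept on the raw
    intensity scale -- no per-spectrum normalization -- because the unmixing
    weights serve as absolute lipid-amount proxies.
    """

    S: np.ndarray
    axis: SpectralAxis
    provenance: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (self.axis.n_channels, len(COMPONENTS)):
            raise ValueError(
                f"S must be {self.axis.n_channels} x {len(COMPONENTS)}, "
                f"got {self.S.shape}"
            )
        if np.any(self.S < 0):
            raise ValueError("reference spectra must be non-negative")

    def column(self, component: str) -> np.ndarray:
        return self.S[:, COMPONENTS.index(component)]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.S))


def cover_glass_background(cube: HyperCube, n_lowest: int = 2000) -> Spectrum:
    """Per-image cover-glass background spectrum.

    The background is the mean spectrum of the ``n_lowest`` pixels with the
    lowest per-pixel channel-mean intensity.  For images with fewer pixels
    than ``n_lowest`` the count is clamped to 10% of the pixels (at least
    one) and a warning is logged; this keeps the estimator meaningful on
    small crops while matching the per-experiment default on full frames.
    """
    if n_lowest < 1:
        raise ValueError("n_lowest must be >= 1")
    flat = cube.flattened()
    n_pix = flat.shape[0]
    if n_pix == 0:
        raise ValueError("cube has no pixels")
    if n_pix < n_lowest:
        clamped = max(1, n_pix // 10)
        logger.warning(
            "cube has %d pixels < n_lowest=%d; clamping to %d (10%% of pixels)",
            n_pix, n_lowest, clamped,
        )
        n_lowest = clamped
    means = flat.mean(axis=1)
    order = np.argsort(means, kind="stable")[:n_lowest]
    return Spectrum(flat[order].mean(axis=0), cube.axis, kind="cover_glass")


def _check_same_axis(a: Spectrum, b: Spectrum) -> None:
    if a.axis != b.axis:
        raise ValueError("spectra are defined on different spectral axes")


def subtract_capped(a: Spectrum, b: Spectrum) -> Spectrum:
    """Elementwise ``max(a - b, 0)``: subtraction capped at zero.

    Capping keeps spectra in the space of non-negative numbers, as required
    by the non-negative mixing model.
    """
    _check_same_axis(a, b)
    return Spectrum(np.maximum(a.values - b.values, 0.0), a.axis, kind=a.kind)


def mean_collapse(cube: HyperCube, background: Spectrum | None = None) -> np.ndarray:
    """Mean-project a cube to 2D after capped per-pixel background subtraction.

    Used for segmentation and visualization only; unmixing always runs on the
    raw (unsubtracted) spectra.
    """
    data = cube.data.astype(float)
    if background is not None:
        if background.axis != cube.axis:
            raise ValueError("background spectrum is on a different axis")
        data = np.maximum(data - background.values, 0.0)
    return data.mean(axis=2)


RoiSpec = np.ndarray | Sequence[Sequence[tuple[int, int]]]


def _roi_pixel_sets(rois: RoiSpec, shape: tuple[int, int]) -> list[np.ndarray]:
    """Normalize ROI input to a list of flat pixel-index arrays.

    Accepts an integer label image (one ROI per positive label) or a sequence
    of ``(row, col)`` coordinate collections.
    """
    if isinstance(rois, np.ndarray) and rois.ndim == 2 and rois.dtype != object:
        if rois.shape != shape:
            raise ValueError(f"ROI label image shape {rois.shape} != image {shape}")
        labels = np.unique(rois)
        labels = labels[labels > 0]
        flat = rois.ravel()
        return [np.flatnonzero(flat == lab) for lab in labels]
    sets = []
    for roi in rois:
        coords = np.atleast_2d(np.asarray(roi, dtype=int))
        if coords.shape[1] != 2:
            raise ValueError("coordinate ROIs must be sequences of (row, col) pairs")
        if np.any(coords < 0) or np.any(coords[:, 0] >= shape[0]) or np.any(
            coords[:, 1] >= shape[1]
        ):
            raise ValueError("ROI coordinates fall outside the image")
        sets.append(coords[:, 0] * shape[1] + coords[:, 1])
    return sets


def _roi_mean_spectrum(cube: HyperCube, pixel_sets: list[np.ndarray]) -> np.ndarray:
    flat = cube.flattened()
    all_idx = np.concatenate(pixel_sets)
    return flat[all_idx].mean(axis=0)


def extract_reference_set(
    tag_cube: HyperCube,
    tag_rois: RoiSpec,
    ce_cube: HyperCube,
    ce_rois: RoiSpec,
    starved_cube: HyperCube,
    cyto_rois: RoiSpec,
    water_rois: RoiSpec,
    water_cube: HyperCube | None = None,
) -> ReferenceSet:
    """Build the 4-component :class:`ReferenceSet` from annotated ROIs.

    TAG and CE references are the mean spectra over manually selected lipid
    droplets of singly loaded cells (oleic-acid load for TAG, cholesterol
    load for CE); the cellular background is the mean over cytoplasmic
    regions of lipid-starved cells; the water background is taken from
    cell-free regions (of ``water_cube`` if given, else of the starved cube).
    The cellular background is subtracted (capped at 0) from the TAG and CE
    columns to remove the membrane contribution that overlaps droplets.
    """
    axes = {tag_cube.axis, ce_cube.axis, starved_cube.axis}
    if water_cube is not None:
        axes.add(water_cube.axis)
    if len(axes) != 1:
        raise ValueError("all reference cubes must share one spectral axis")
    axis = tag_cube.axis
    wcube = water_cube if water_cube is not None else starved_cube

    roi_sets = {}
    for name, cube, rois in (
        ("TAG", tag_cube, tag_rois),
        ("CE", ce_cube, ce_rois),
        ("cellular_bg", starved_cube, cyto_rois),
        ("water_bg", wcube, water_rois),
    ):
        sets = _roi_pixel_sets(rois, cube.data.shape[:2])
        if not sets or all(s.size == 0 for s in sets):
            raise ValueError(f"no ROI pixels provided for component {name!r}")
        roi_sets[name] = (cube, sets)

    expected = {"TAG": (5, 12), "CE": (5, 12), "cellular_bg": (4, 7), "water_bg": (2, 4)}
    for name, (_, sets) in roi_sets.items():
        lo, hi = expected[name]
        if not lo <= len(sets) <= hi:
            logger.warning(
                "%s reference built from %d ROIs (typical range %d-%d)",
                name, len(sets), lo, hi,
            )

    means = {name: _roi_mean_spectrum(c, s) for name, (c, s) in roi_sets.items()}
    cellular = means["cellular_bg"]
    S = np.column_stack(
        [
            np.maximum(means["TAG"] - cellular, 0.0),
            np.maximum(means["CE"] - cellular, 0.0),
            cellular,
            means["water_bg"],
        ]
    )
    provenance = {name: len(sets) for name, (_, sets) in roi_sets.items()}
    return ReferenceSet(S, axis, provenance)
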