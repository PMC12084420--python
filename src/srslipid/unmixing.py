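"""Per-pixel non-negative least-squares unmixing of SRS spectra.

Each pixel spectrum d (length C) is decomposed against the reference matrix
S (C x 4, components TAG / CE / cellular background / water background) by
solving

    min_w ||S w - d||_2   subject to  w >= 0,

stacked over pixels this minimizes the Frobenius norm ||W S^T - D||_F.  The
raw pixel spectra are NOT background-subtracted before unmixing: including
the cellular-background column in the model performs a pixel-wise scaled
background subtraction implicitly.  The TAG and CE weight planes are the
"SRS lipid intensities" used for all quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .spectral import (
    COMPONENTS,
    AcquisitionSettings,
    HyperCube,
    ReferenceSet,
    SpectralAxis,
)

__all__ = [
    "WeightImage",
    "nnls_pixel",
    "decompose_cube",
    "detect_saturation",
    "normalize_weights",
    "render_falsecolor",
]


@dataclass
class WeightImage:
    """Per-pixel component weights W (H x W x 4) plus saturation mask."""

    W: np.ndarray
    axis: SpectralAxis
    settings: AcquisitionSettings
    saturation_mask: np.ndarray | None = None
    normalized_to: AcquisitionSettings | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 3 or self.W.shape[2] != len(COMPONENTS):
            raise ValueError("W must be H x W x 4")
        if np.any(self.W < 0):
            raise ValueError("component weights must be non-negative")
        if self.saturation_mask is None:
            self.saturation_mask = np.zeros(self.W.shape[:2], dtype=bool)
        self.saturation_mask = np.asarray(self.saturation_mask, dtype=bool)
        if self.saturation_mask.shape != self.W.shape[:2]:
            raise ValueError("saturation mask shape mismatch")

    def plane(self, component: str) -> np.ndarray:
        return self.W[:, :, COMPONENTS.index(component)]

    @property
    def tag(self) -> np.ndarray:
        return self.plane("TAG")

    @property
    def ce(self) -> np.ndarray:
        return self.plane("CE")


def _check_reference(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2:
        raise ValueError("reference matrix must be 2D")
    norms = np.linalg.norm(S, axis=0)
    if np.any(norms == 0):
        dead = [COMPONENTS[i] if i < len(COMPONENTS) else str(i)
                for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"degenerate reference: all-zero column(s) {dead}")
    return S


def nnls_pixel(d: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Non-negative least squares for a single pixel spectrum.

    Solves ``min ||S w - d||`` with ``w >= 0`` using the Lawson-Hanson
    active-set algorithm (:func:`scipy.optimize.nnls`).
    """
    S = _check_reference(S)
    d = np.asarray(d, dtype=float)
    if d.shape != (S.shape[0],):
        raise ValueError(f"spectrum length {d.size} != reference rows {S.shape[0]}")
    w, _ = scipy.optimize.nnls(S, d)
    return w


def decompose_cube(cube: HyperCube, refs: ReferenceSet) -> WeightImage:
    """Unmix every pixel of ``cube`` against ``refs``.

    Pixels are processed independently (the result is order-independent).
    Repeated spectra -- common in synthetic or background-dominated images --
    are solved once through a unique-row cache.
    """
    if cube.axis != refs.axis:
        raise ValueError("cube and reference set are on different spectral axes")
    S = _check_reference(refs.S)
    D = cube.flattened()
    uniq, inverse = np.unique(D, axis=0, return_inverse=True)
    W_uniq = np.empty((uniq.shape[0], S.shape[1]))
    for i, d in enumerate(uniq):
        W_uniq[i], _ = scipy.optimize.nnls(S, d)
    W = W_uniq[inverse].reshape(cube.data.shape[0], cube.data.shape[1], S.shape[1])
    sat = detect_saturation(cube)
    return WeightImage(W, cube.axis, cube.settings, saturation_mask=sat)


def detect_saturation(
    cube: HyperCube,
    window_cm: float = 12.0,
    std_thresh: float = 50.0,
    value_thresh: float = 3500.0,
) -> np.ndarray:
    """Flag lock-in-saturated pixels.

    A pixel is saturated if any sliding window of ``window_cm`` wavenumbers
    (5 consecutive channels at the 3 cm^-1 step) has a sample standard
    deviation below ``std_thresh`` while all its values exceed
    ``value_thresh``.  Windows never span acquisition-region boundaries: a
    12 cm^-1 window across the 1775 -> 2800 cm^-1 gap has no physical
    meaning.  The default 3500 threshold is ~85% of the 12-bit maximum 4095.
    """
    flat = cube.flattened()
    mask = np.zeros(flat.shape[0], dtype=bool)
    for r in range(cube.axis.n_regions):
        sl = cube.axis.region_slice(r)
        step = cube.axis.regions[r][2]
        win = int(round(window_cm / step)) + 1
        seg = flat[:, sl]
        if win < 2 or seg.shape[1] < win:
            continue
        # sliding windows over channel axis
        sw = np.lib.stride_tricks.sliding_window_view(seg, win, axis=1)
        std = sw.std(axis=2, ddof=1)
        high = sw.min(axis=2) > value_thresh
        mask |= np.any((std < std_thresh) & high, axis=1)
    return mask.reshape(cube.data.shape[:2])


def _component_regions(axis: SpectralAxis) -> tuple[int, ...]:
    """Dominant acquisition region per component for power normalization.

    The lipid components and the cellular background are dominated by the
    CH-stretch region around 2857 cm^-1; the water background by the highest
    wavenumber region (O-H tail).
    """
    ch = int(axis.region_index[axis.channel_at(2857.0)])
    hi = int(axis.region_index[int(np.argmax(axis.wavenumbers))])
    return (ch, ch, ch, hi)


def normalize_weights(
    wi: WeightImage,
    settings: AcquisitionSettings | None = None,
    target: AcquisitionSettings | None = None,
    *,
    zoom_exponent: float = 0.0,
    component_regions: tuple[int, ...] | None = None,
) -> WeightImage:
    """Linearly rescale weights to a target acquisition setting.

    SRS signal is linear in pump x Stokes laser power, so each component
    plane is multiplied by ``(pump_t * stokes_t) / (pump * stokes)``
    evaluated for the acquisition region that dominates that component,
    together with a zoom correction ``(zoom_t / zoom) ** zoom_exponent``
    (default exponent 0: zoom alters sampling geometry, not per-pixel
    signal).
    """
    if settings is None:
        settings = wi.settings
    if target is None:
        raise ValueError("target settings are required")
    if component_regions is None:
        component_regions = _component_regions(wi.axis)
    factors = np.empty(len(COMPONENTS))
    for c, region in enumerate(component_regions):
        denom = settings.power_product(region)
        if denom == 0:
            raise ValueError("source settings have zero laser power")
        factors[c] = target.power_product(region) / denom
    factors *= (target.zoom / settings.zoom) ** zoom_exponent
    return WeightImage(
        wi.W * factors,
        wi.axis,
        settings,
        saturation_mask=wi.saturation_mask.copy(),
        normalized_to=target,
    )


def render_falsecolor(
    wi: WeightImage,
    segmentation: np.ndarray | None = None,
    clip_fraction: float = 0.3,
    gray_level: float = 0.5,
) -> np.ndarray:
    """False-color RGB rendering: magenta = TAG, green = CE.

    Lipid intensities are linearly mapped to ``[0, 1]`` with the top of the
    range at ``clip_fraction`` x the maximum lipid intensity of the rendered
    planes (values above clip to full color); this keeps a few aberrantly
    bright pixels from crushing the display range.  Pixels outside the
    segmented area and saturated pixels are colored gray.
    """
    if clip_fraction <= 0:
        raise ValueError("clip_fraction must be > 0")
    tag, ce = wi.tag, wi.ce
    peak = max(tag.max(), ce.max())
    scale = clip_fraction * peak if peak > 0 else 1.0
    t = np.clip(tag / scale, 0.0, 1.0)
    c = np.clip(ce / scale, 0.0, 1.0)
    rgb = np.stack([t, c, t], axis=-1)  # magenta = R+B, green = G
    gray = wi.saturation_mask.copy()
    if segmentation is not None:
        gray |= np.asarray(segmentation) == 0
    rgb[gray] = gray_level
    return rgb
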