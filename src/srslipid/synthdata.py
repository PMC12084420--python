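"""Synthetic hyperspectral SRS scenes with known ground truth.

Every pipeline stage (unmixing, segmentation, droplet quantification,
NE-vs-cytoplasmic statistics) can be exercised without external data:
scenes are built from four Lorentzian-sum component spectra -- TAG
(dominant CH2 symmetric stretch at 2857 cm^-1 plus an ester carbonyl band
near 1745 cm^-1), CE (sterol-ring CH2 stretch at 2875 cm^-1 plus a sterol
band in the 1670 cm^-1 region), a broad low cellular background and a water
background rising above 3000 cm^-1 (O-H tail) -- mixed per pixel with
non-negative concentrations over a cell layout of dark elliptical nuclei,
bright lipid-droplet disks and an optional diffuse cytoplasmic CE pool.
NE droplets are placed overlapping the nucleus boundary and draw their CE
fraction from a distribution offset above the cytoplasmic one.

The peak tables beyond the two anchored CH-stretch peaks are a declared
model, versioned here so tests are stable; they are not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .spectral import (
    COMPONENTS,
    AcquisitionSettings,
    HyperCube,
    ReferenceSet,
    SpectralAxis,
    Spectrum,
)

__all__ = [
    "COMPONENT_PEAKS",
    "SceneLayout",
    "SceneTruth",
    "make_component_spectra",
    "reference_set_from_spectra",
    "render_scene",
    "corrupt_cube",
]

#: Lorentzian peak model per component: (center cm^-1, HWHM cm^-1, amplitude),
#: plus a constant baseline.  Amplitudes are relative; see ``scale`` below.
COMPONENT_PEAKS: dict[str, dict] = {
    "TAG": {
        "peaks": [(2857.0, 14.0, 1.00), (2895.0, 25.0, 0.40), (1745.0, 12.0, 0.35),
                  (3008.0, 20.0, 0.12)],
        "baseline": 0.02,
    },
    "CE": {
        "peaks": [(2875.0, 14.0, 1.00), (2930.0, 22.0, 0.45), (1672.0, 12.0, 0.40),
                  (3042.0, 25.0, 0.15)],
        "baseline": 0.02,
    },
    "cellular_bg": {
        "peaks": [(2850.0, 60.0, 0.22), (2930.0, 60.0, 0.28), (1660.0, 50.0, 0.10)],
        "baseline": 0.05,
    },
    "water_bg": {
        "peaks": [(3250.0, 150.0, 1.10), (1640.0, 40.0, 0.15)],
        "baseline": 0.03,
    },
}


def _lorentzian_sum(wavenumbers: np.ndarray, model: dict, scale: float) -> np.ndarray:
    vals = np.full(wavenumbers.shape, model["baseline"], dtype=float)
    for center, hwhm, amp in model["peaks"]:
        vals += amp * hwhm**2 / ((wavenumbers - center) ** 2 + hwhm**2)
    return vals * scale


def make_component_spectra(
    axis: SpectralAxis,
    seed: int | None = None,
    scale: float = 800.0,
    jitter: float = 0.0,
) -> dict[str, Spectrum]:
    """Evaluate the four component spectra on ``axis``.

    ``scale`` converts relative amplitudes to detector counts per unit
    concentration.  ``jitter`` > 0 perturbs peak amplitudes by that relative
    Gaussian factor (seeded) for robustness experiments; the default 0 keeps
    the declared model exactly.  The four spectra are linearly independent
    by construction.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name in COMPONENTS:
        model = COMPONENT_PEAKS[name]
        if jitter > 0:
            peaks = [
                (c, w, a * max(0.0, 1.0 + jitter * rng.standard_normal()))
                for c, w, a in model["peaks"]
            ]
            model = {"peaks": peaks, "baseline": model["baseline"]}
        out[name] = Spectrum(
            _lorentzian_sum(axis.wavenumbers, model, scale), axis, kind=name
        )
    return out


def reference_set_from_spectra(spectra: dict[str, Spectrum]) -> ReferenceSet:
    """Stack generator spectra into a :class:`ReferenceSet` (ground truth)."""
    axis = spectra[COMPONENTS[0]].axis
    S = np.column_stack([spectra[name].values for name in COMPONENTS])
    return ReferenceSet(S, axis, provenance={name: 0 for name in COMPONENTS})


@dataclass
class SceneLayout:
    """Layout and statistical parameters of a synthetic scene.

    Defaults describe a desk-scale field: 256 x 256 pixels, 6 cells, 8
    droplets per cell with a quarter of them nuclear-envelope associated,
    cytoplasmic CE fraction ~ N(0.35, 0.05) and NE droplets offset +0.10
    (clipped to [0, 1]) -- the direction and order of the compositional
    difference the pipeline is meant to resolve.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 6
    droplets_per_cell: int = 8
    ne_fraction: float = 0.25
    droplet_radius_px: tuple[float, float] = (2.0, 5.0)
    droplet_amplitude: tuple[float, float] = (1.5, 3.0)
    cyto_ce_mean: float = 0.35
    ce_sigma: float = 0.05
    ne_ce_offset: float = 0.10
    nucleus_cellular_factor: float = 0.55
    water_in_cell: float = 0.35
    diffuse_ce: float = 0.0
    shell_contrast: float = 0.0
    pixel_size_um: float = 0.2
    max_placement_retries: int = 400


@dataclass
class SceneTruth:
    """Ground truth of a rendered scene.

    ``concentrations`` is H x W x 4 in :data:`COMPONENTS` order; the droplet
    table holds per-droplet centers, radii, NE flags and the true TAG / CE
    amounts (sums of the concentration maps over the droplet's pixels, i.e.
    exactly what a perfect unmixing + perfect segmentation would recover).
    """

    concentrations: np.ndarray
    droplets: pd.DataFrame
    nuclei: np.ndarray
    cells: np.ndarray
    droplet_labels: np.ndarray
    nuclear_stain: np.ndarray
    pixel_size_um: float


def _cell_grid(shape: tuple[int, int], n_cells: int) -> list[tuple[float, float, float]]:
    """Cell centers and radii on a near-square grid covering the frame."""
    cols = int(np.ceil(np.sqrt(n_cells)))
    rows = int(np.ceil(n_cells / cols))
    ch, cw = shape[0] / rows, shape[1] / cols
    radius = 0.44 * min(ch, cw)
    centers = []
    for i in range(n_cells):
        r, c = divmod(i, cols)
        centers.append(((r + 0.5) * ch, (c + 0.5) * cw, radius))
    return centers


def render_scene(
    layout: SceneLayout,
    spectra: dict[str, Spectrum],
    seed: int | None = None,
    quantize: bool = True,
    settings: AcquisitionSettings | None = None,
) -> tuple[HyperCube, SceneTruth]:
    """Render a hyperspectral scene and its ground truth.

    Pixel spectra are the non-negative mixture ``sum_c conc_c * spectrum_c``;
    with ``quantize`` the cube is rounded and clipped to the 12-bit range
    (the acquisition model), otherwise kept as exact floats (useful for
    numerically tight recovery checks).  NE droplets are centered on randomly
    chosen nucleus-boundary pixels so their masks partially overlap the
    nuclear mask; cytoplasmic droplets are placed inside the cell clear of
    the nucleus; droplets never overlap each other.  Raises if placement
    fails after the configured retries.
    """
    rng = np.random.default_rng(seed)
    axis = spectra[COMPONENTS[0]].axis
    if settings is None:
        settings = AcquisitionSettings()
    h, w = layout.shape
    rr, cc = np.mgrid[0:h, 0:w]

    nuclei = np.zeros((h, w), dtype=np.int32)
    cells = np.zeros((h, w), dtype=np.int32)
    cell_geom = []
    for lab, (cy, cx, radius) in enumerate(_cell_grid(layout.shape, layout.n_cells), 1):
        cy += rng.uniform(-2, 2)
        cx += rng.uniform(-2, 2)
        cells[(rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2] = lab
        a = radius * rng.uniform(0.38, 0.46)  # nucleus semi-axes
        b = radius * rng.uniform(0.28, 0.36)
        nuclei[((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0] = lab
        cell_geom.append((cy, cx, radius, a, b))

    conc = np.zeros((h, w, len(COMPONENTS)))
    i_tag, i_ce, i_cell, i_water = (COMPONENTS.index(k) for k in COMPONENTS)
    conc[:, :, i_water] = np.where(cells > 0, layout.water_in_cell, 1.0)
    conc[:, :, i_cell] = np.where(
        nuclei > 0, layout.nucleus_cellular_factor, np.where(cells > 0, 1.0, 0.0)
    )
    if layout.diffuse_ce > 0:
        conc[:, :, i_ce] += np.where((cells > 0) & (nuclei == 0), layout.diffuse_ce, 0.0)

    droplet_labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    occupied = np.zeros((h, w), dtype=bool)
    n_ne_target = int(round(layout.ne_fraction * layout.droplets_per_cell))
    failures = 0
    next_label = 1
    for cell_lab, (cy, cx, radius, a, b) in enumerate(cell_geom, 1):
        boundary = _nucleus_boundary(nuclei == cell_lab)
        for k in range(layout.droplets_per_cell):
            want_ne = k < n_ne_target
            placed = False
            for _ in range(layout.max_placement_retries):
                dr = rng.uniform(*layout.droplet_radius_px)
                if want_ne:
                    if boundary.shape[0] == 0:
                        break
                    py, px = boundary[rng.integers(boundary.shape[0])]
                    py, px = float(py), float(px)
                else:
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0, 1) ** 0.5 * (radius - dr - 2)
                    py, px = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                    # keep cytoplasmic droplets clear of the nucleus
                    if ((py - cy) / (a + dr + 1)) ** 2 + ((px - cx) / (b + dr + 1)) ** 2 <= 1.0:
                        continue
                disk = (rr - py) ** 2 + (cc - px) ** 2 <= dr**2
                if not disk.any() or (occupied & _dilate(disk)).any():
                    continue
                if not (cells[disk] == cell_lab).all():
                    continue
                ce_mean = layout.cyto_ce_mean + (layout.ne_ce_offset if want_ne else 0.0)
                f = float(np.clip(rng.normal(ce_mean, layout.ce_sigma), 0.0, 1.0))
                amp = rng.uniform(*layout.droplet_amplitude)
                cef_px = np.full(int(disk.sum()), f)
                if layout.shell_contrast > 0:
                    rho = np.sqrt((rr - py) ** 2 + (cc - px) ** 2)[disk] / dr
                    cef_px = np.clip(
                        f + layout.shell_contrast * (rho**2 - 0.5), 0.0, 1.0
                    )
                conc_tag = amp * (1.0 - cef_px)
                conc_ce = amp * cef_px
                conc[:, :, i_tag][disk] += conc_tag
                conc[:, :, i_ce][disk] += conc_ce
                droplet_labels[disk] = next_label
                occupied |= disk
                is_ne = bool((disk & (nuclei > 0)).any())
                rows.append(
                    dict(
                        droplet_id=next_label,
                        cell_id=cell_lab,
                        center_row=py,
                        center_col=px,
                        radius_px=dr,
                        is_ne=is_ne,
                        tag_amount=float(conc_tag.sum()),
                        ce_amount=float(conc_ce.sum()),
                        ce_fraction=float(conc_ce.sum() / (amp * disk.sum())),
                        pixel_count=int(disk.sum()),
                    )
                )
                next_label += 1
                placed = True
                break
            if not placed:
                failures += 1
    if failures:
        raise RuntimeError(
            f"could not place {failures} of "
            f"{layout.n_cells * layout.droplets_per_cell} droplets without overlap; "
            "reduce droplet count/radius or enlarge the scene"
        )

    S = np.column_stack([spectra[name].values for name in COMPONENTS])
    data = conc.reshape(-1, len(COMPONENTS)) @ S.T
    data = data.reshape(h, w, axis.n_channels)
    if quantize:
        data = np.clip(np.round(data), 0, settings.max_value).astype(np.uint16)
    cube = HyperCube(data, axis, settings)

    stain = np.where(nuclei > 0, 1000.0, 50.0)
    stain = ndi.gaussian_filter(stain, 1.0)
    droplets_df = pd.DataFrame(
        rows,
        columns=[
            "droplet_id", "cell_id", "center_row", "center_col", "radius_px",
            "is_ne", "tag_amount", "ce_amount", "ce_fraction", "pixel_count",
        ],
    )
    truth = SceneTruth(
        concentrations=conc,
        droplets=droplets_df,
        nuclei=nuclei,
        cells=cells,
        droplet_labels=droplet_labels,
        nuclear_stain=stain,
        pixel_size_um=layout.pixel_size_um,
    )
    return cube, truth


def _nucleus_boundary(mask: np.ndarray) -> np.ndarray:
    edge = mask & ~ndi.binary_erosion(mask, border_value=0)
    return np.argwhere(edge)


def _dilate(mask: np.ndarray) -> np.ndarray:
    return ndi.binary_dilation(mask)


def corrupt_cube(
    cube: HyperCube,
    noise_sigma_frac: float = 0.0,
    saturate: bool = False,
    seed: int | None = None,
    saturate_mask: np.ndarray | None = None,
) -> HyperCube:
    """Add acquisition artifacts: Gaussian noise and lock-in saturation.

    Noise is additive with sigma = ``noise_sigma_frac`` x the cube maximum,
    then clipped to the bit-depth range.  With ``saturate``, the pixels of
    ``saturate_mask`` (e.g. selected droplets from the scene truth) are
    scaled up until their spectral peaks clip flat at the detector maximum,
    which the saturation detector (flat window above 3500) then flags.
    """
    if not 0.0 <= noise_sigma_frac <= 0.2:
        raise ValueError("noise_sigma_frac must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    data = cube.data.astype(float)
    maxval = cube.settings.max_value
    if saturate:
        if saturate_mask is None:
            raise ValueError("saturate=True requires a saturate_mask")
        mask = np.asarray(saturate_mask, dtype=bool)
        spec = data[mask]
        # scale so >= 5 channels (the peak top) exceed the detector ceiling
        v5 = np.sort(spec, axis=1)[:, -5]
        factor = np.where(v5 > 0, 1.1 * maxval / np.maximum(v5, 1e-9), 1.0)
        data[mask] = spec * factor[:, None]
    if noise_sigma_frac > 0:
        sigma = noise_sigma_frac * data.max()
        data = data + rng.normal(0.0, sigma, size=data.shape)
    if noise_sigma_frac > 0 or saturate:
        data = np.clip(np.round(data), 0, maxval)
    if np.issubdtype(cube.data.dtype, np.integer):
        data = data.astype(cube.data.dtype)
    return HyperCube(data, cube.axis, cube.settings)
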