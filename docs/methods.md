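# Methods

## Spectral model and axis

An acquisition is a list of Raman-shift regions `(start, end, step)` in
cm⁻¹; each region contributes `(end − start)/step + 1` channels including
both endpoints. A wavenumber shared by adjacent regions (2950 cm⁻¹ in the
default 1625–1775 / 2800–2950 / 2950–3100 cm⁻¹ layout) is kept as two
distinct channels because each region is acquired separately — the default
axis therefore has 3 × 51 = 153 channels. No smoothing, baseline
correction or wavelength calibration is applied anywhere: weights are meant
to be absolute lipid-amount proxies, so spectra stay on the raw intensity
scale.

## Reference spectra

TAG and CE references are mean spectra over manually selected droplet ROIs
of singly loaded cells (typically 5–12 droplets per load; counts outside
that range are accepted with a logged warning); the cellular background is
the mean over cytoplasmic ROIs of lipid-starved cells (typically 4–7), the
water background over cell-free regions (2–4). Because droplet spectra
include overlapping membrane signal, the cellular background is subtracted
from the TAG and CE columns, capped at 0 to stay non-negative. ROIs are
accepted as integer label images or lists of (row, col) coordinates.

The per-image cover-glass background — used only for the mean-collapsed 2D
image that feeds segmentation and display, never for unmixing — is the mean
spectrum of the 2000 pixels with the lowest channel-mean intensity. On
images smaller than the requested count the count clamps to 10% of the
pixels with a logged warning. The collapse uses all channels; restricting
it to the C–H region is possible upstream by building a narrower axis.

## Unmixing

Per pixel we solve `min ‖S w − d‖₂, w ≥ 0` with `scipy.optimize.nnls`
(Lawson–Hanson active set; with 4 components the cost per pixel is
trivial). Pixels are independent, so results are order-independent and a
unique-spectrum cache accelerates quantized or background-dominated cubes.
The raw spectra are not background-subtracted first: the background columns
inside the model subtract per pixel with a fitted scale. Tests check the
solution against an exhaustive oracle that enumerates all 16 support
subsets, solves each unconstrained, keeps feasible candidates and takes the
minimum residual — for a 4-column S the NNLS optimum is always among these.

Saturation: lock-in clipping produces flat, high spectral plateaus. A pixel
is flagged if any sliding window of 12 cm⁻¹ (5 channels at the 3 cm⁻¹ step)
has sample standard deviation (ddof = 1) below 50 counts while all window
values exceed 3500 counts (~85% of the 12-bit maximum 4095). Windows never
span region boundaries — a window across the 1775 → 2800 cm⁻¹ gap has no
physical meaning. Both thresholds are parameters.

Normalization: SRS signal is linear in pump × Stokes power, so weights are
rescaled by `(pump_t·stokes_t)/(pump·stokes)` per acquisition region, each
component following its dominant region (lipids and cellular background the
CH-stretch region containing 2857 cm⁻¹; water the highest-wavenumber
region). Zoom enters as `(zoom_t/zoom)^zoom_exponent` with exponent 0 by
default — zoom changes sampling geometry, and whether it should rescale
per-pixel intensity is instrument-dependent, so it is left configurable
rather than assumed.

## Segmentation

Nuclei: Gaussian smoothing, Otsu threshold, hole filling, distance-
transform watershed seeded at distance maxima (minimum separation
`min_sep_px`), small objects removed. This classical route replaces
learned nucleus segmentation; externally produced nucleus label images are
accepted wherever nuclei are consumed, preserving fidelity on real data
where nuclei are low-contrast.

Cells: propagation-style seeded growing on the collapsed SRS image — a
multi-source Dijkstra where a 4-neighbor step costs
`λ + |I(p) − I(q)|`. With flat intensity the partition is geodesic-Voronoi
(λ dominates); dark ridges between cells are expensive to cross, so
boundaries snap to them. λ defaults to 0.05. Nucleus pixels always keep
their label.

Droplets: undecimated ("à trous") B3-spline wavelet decomposition
(kernel [1,4,6,4,1]/16 with 2^(j−1) holes, mirror boundaries). Planes
2..levels are thresholded at `k_mad ×` the plane's median absolute
deviation (plane 1 carries mostly single-pixel noise); the pixelwise AND of
the thresholded planes, split into 8-connected components of ≥ `min_px`
pixels, is the droplet label image. Defaults: levels 4, k_mad 3, min_px 4 —
declared values, tuned to the synthetic scene scale; two spots closer than
the wavelet support merge (documented limitation).

NE-LDs: a droplet is nuclear-envelope associated iff ≥ 1 of its pixels lies
on the nuclear mask (partial overlap counts); a droplet overlapping several
nuclei is NE if it overlaps any. Droplet→cell assignment is by majority
pixel overlap, with orphans rescued to the nearest cell within 5 px, else
dropped and logged. The equivalent radius is `√(area/π) × pixel size`.

## Quantification

Per droplet: TAG/CE sums over droplet pixels, CE fraction
CE/(CE + TAG) (NaN when both are zero), saturated-pixel fraction; droplets
with ≥ 20% saturated pixels are excluded. Pooling across acquisitions
requires weights normalized to one target setting (enforced; can be waived
for single acquisitions). Per cell: droplet-pixel totals and all-cell-pixel
totals (the latter capture the diffuse, non-droplet CE pool), NE-droplet
fraction and the fraction of droplet CE held in NE-LDs; cells without
droplets emit NaN for ratio metrics and are excluded from ratio means.
Group statistics mirror common figure usage: Welch t-tests for CE fractions
and intensities, Mann–Whitney U for droplet counts; fully degenerate
zero-variance groups get a tiny variance floor instead of NaN. SRS and
biochemical (TLC) tables are placed on a common artificial scale by
dividing each by its own CE mean in an anchor condition (conventionally the
double cholesterol + oleate load); the operation is idempotent and
preserves within-table ratios.

## Localization metrics

Distances are Euclidean distance transforms on the pixel grid. `d_N` is 0
inside the nucleus; `d_PM` is 0 on the cell-mask outer contour
(background-adjacent cell pixels), which realizes the boundary convention
that contour signal scores exactly 0 and nuclear signal exactly 1 (pixels
with `d_N = d_PM = 0` count as nuclear, weight 1). All cell pixels are
included — the formula itself assigns nuclear pixels weight 1, so no
cytoplasm-only restriction is needed. The nuc/cyto translocation ratio
subtracts the well-level background (mean of all pixels outside every cell
mask; a percentile alternative is available) from both the nuclear and the
cytoplasmic (cell minus nucleus) mean; non-positive cytoplasmic means flag
the record invalid rather than raising. Focus handling offers
highest-total-reference slice selection (ties to the lowest index) and
maximum-intensity projection.

## Pore clustering

Edges join pores strictly closer than the threshold (kd-tree pair query);
clusters are connected components. In 3D the threshold is scaled by
`(nucleus_measure / ref_measure)^(1/dim)` — the exponent turns a volume (or
area) ratio into a length-scale ratio and is configurable since only
"adjusted with the volume" is specified; the 2D fluorescence path uses the
fixed base threshold. Base threshold and reference measure are user
configuration, not inferred constants. Spot detection for 2D pore maps
reuses the wavelet detector and accepts externally produced pixel-
classification probability images.

## Synthetic scenes

Component spectra are Lorentzian sums anchored at the two CH₂ symmetric-
stretch peaks (TAG 2857 cm⁻¹ from open acyl chains, CE 2875 cm⁻¹ from the
sterol ring) with secondary bands (TAG carbonyl ~1745 cm⁻¹, CE band in the
1670 cm⁻¹ region, broad low cellular background, water O–H tail rising
above 3000 cm⁻¹), scaled to 800 counts per unit concentration so default
scenes stay below the 12-bit ceiling. The default scene is 256×256 px, 6
cells on a jittered grid, dark elliptical nuclei (cellular concentration
0.55 of cytoplasm), water 1.0 outside / 0.35 inside cells, 8 droplets per
cell of radius 2–5 px and amplitude U(1.5, 3), cytoplasmic CE fraction
N(0.35, 0.05) and NE droplets offset +0.10 — NE droplets are centered on
nucleus-boundary pixels so their masks partially overlap the nuclear mask.
Optional features: diffuse cytoplasmic CE (membrane pool analog) and a
radial CE-shell/TAG-core profile. Cubes are rounded and clipped to the bit
depth by default (`quantize=False` gives exact floats for tight numerical
checks). Corruption adds Gaussian noise (σ as a fraction of the cube
maximum, capped at 0.2) and can saturate chosen droplets by scaling their
spectra until the peak tops clip flat at the detector maximum.

What the generator does *not* emulate: optical blur and spectral-focusing
chirp, detector shot-noise statistics, cell-to-cell reference-spectrum
variability, droplets out of focus, and irregular cell/nucleus shapes.
Passing tests therefore demonstrate correctness of the computational
pipeline under its stated model, not robustness to every property of real
acquisitions; the module boundaries accept externally produced masks and
probability images precisely so real-data idiosyncrasies can be handled
upstream.

## Problem sizes, tolerances and determinism

The test suite uses the default 256×256×153 scene for recovery and
detection checks (rendered once per session) and 128×128 scenes for
end-to-end determinism — scales at which the full suite runs in well under
a minute while keeping ≥ 30 droplets per comparison group where statistics
are asserted. Numerical expectations: noise-free per-droplet recovery
within 1% (quantization-limited), oracle agreement to 1e−9 in residual,
detection recall/precision ≥ 0.9 at IoU ≥ 0.3. All randomness flows through
`numpy.random.default_rng(seed)`; identical configuration + seed produce
byte-identical CSV outputs, which the suite asserts literally.
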