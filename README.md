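# srslipid

Neutral-lipid quantification for hyperspectral stimulated Raman scattering
(SRS) microscopy: reference-spectrum non-negative unmixing of triacylglycerol
(TAG) and cholesteryl ester (CE) signal per pixel, lipid-droplet (LD)
segmentation with nuclear-envelope (NE-LD) classification, per-droplet and
per-cell lipid statistics, subcellular-distribution metrics (nuclear
proximity, nuclear/cytoplasmic translocation, Dendra2 photoconversion
ratios) and nuclear-pore cluster analysis. A built-in synthetic scene
generator with known ground truth makes every stage testable without
microscope data.

It is written for cell biologists and image analysts quantifying where cells
store CEs vs TAGs — e.g. whether droplets touching the nuclear envelope are
CE-enriched relative to cytoplasmic droplets — from label-free hyperspectral
image cubes.

## The model

A hyperspectral SRS acquisition tiles Raman-shift regions (by default
1625–1775, 2800–2950 and 2950–3100 cm⁻¹ at a 3 cm⁻¹ step: 153 channels) so
each pixel carries a spectrum. Because stimulated Raman loss is linear in
analyte concentration, a pixel spectrum *d* ∈ ℝᶜ is modeled as a
non-negative mixture of four reference spectra — TAG, CE, cellular
background, water background — stacked into S ∈ ℝᶜˣ⁴:

    min over w ≥ 0 of ‖S w − d‖₂      (stacked over pixels: ‖W Sᵀ − D‖_F)

solved per pixel with Lawson–Hanson active-set NNLS. The TAG and CE weight
planes are the *SRS lipid intensities*, used directly as lipid-amount
proxies. Raw pixel spectra are never background-subtracted before unmixing:
the cellular-background column performs a pixel-wise scaled subtraction
implicitly. Lock-in-saturated pixels (a 12 cm⁻¹ window with sample standard
deviation < 50 and all values > 3500, ~85% of the 12-bit maximum) are
masked, and droplets with ≥ 20% saturated pixels are excluded. Per droplet,
composition is the CE fraction CE_LD / (CE_LD + TAG_LD); NE-LDs are droplets
whose mask overlaps the nuclear mask by at least one pixel.

The nuclear-proximity score of a fluorescence channel is
Σₖ (iₖ/I) · d_PM,k / (d_N,k + d_PM,k), with d_N and d_PM the Euclidean
distances to the nucleus and to the cell-mask contour: 1 for nuclear signal,
0 for signal at the cell edge. Nuclear pores are clustered as connected
components of a neighborhood graph with edges between pores closer than a
(optionally nucleus-size-adjusted) distance threshold.

## Worked example

```sh
python examples/01_unmix_synthetic_scene.py
```

prints

```
153 channels; reference condition number 6.4
48 droplets; worst per-droplet relative error 6.91e-04
```

i.e. on the default noise-free 256×256×153 synthetic scene, per-droplet TAG
and CE sums recovered by pixel-wise NNLS agree with the generator's ground
truth to < 0.1% despite 12-bit quantization. The full pipeline with
segmentation and statistics:

```sh
python examples/02_segment_and_quantify.py
```

```
detected droplets: 101 (NE 35, cytoplasmic 66)
mean CE fraction: NE 0.426 vs cytoplasmic 0.340 (Welch p = 8.99e-14)
```

The scene's NE droplets are generated with a +0.10 CE-fraction offset; the
pipeline detects droplets on the collapsed image, classifies them by nuclear
overlap and recovers the enrichment direction with high confidence. The
other examples cover saturation masking + false-color rendering,
translocation/proximity metrics, and pore clustering. A thin CLI mirrors the
library (`srslipid all`, `synth`, `decompose`, `segment`, `pores`).

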