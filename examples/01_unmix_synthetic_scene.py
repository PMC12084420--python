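"""Unmix a synthetic hyperspectral SRS scene and check lipid recovery.

Renders the default 256 x 256 x 153 scene (known per-pixel TAG/CE/background
concentrations), decomposes every pixel against the generator's own
reference spectra with non-negative least squares, and compares the
per-droplet TAG and CE sums with the ground truth.
"""

import numpy as np

import srslipid as sl

axis = sl.build_spectral_axis(sl.DEFAULT_REGIONS)
spectra = sl.make_component_spectra(axis)
refs = sl.reference_set_from_spectra(spectra)
print(f"{axis.n_channels} channels; reference condition number "
      f"{refs.condition_number:.1f}")

cube, truth = sl.render_scene(sl.SceneLayout(), spectra, seed=1)
weights = sl.decompose_cube(cube, refs)

rel_errors = []
for row in truth.droplets.itertuples():
    mask = truth.droplet_labels == row.droplet_id
    est_tag = weights.tag[mask].sum()
    est_ce = weights.ce[mask].sum()
    rel_errors.append(max(abs(est_tag - row.tag_amount) / row.tag_amount,
                          abs(est_ce - row.ce_amount) / row.ce_amount))

print(f"{len(truth.droplets)} droplets; worst per-droplet relative error "
      f"{max(rel_errors):.2e}")
print("A value well below 1e-2 means the per-pixel NNLS decomposition "
      "recovers the generator's lipid amounts despite 12-bit quantization.")
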