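"""Full pipeline: segment a noisy scene and test NE-LD CE enrichment.

Runs axis -> references -> scene -> unmixing -> segmentation -> droplet
records -> NE-vs-cytoplasmic statistics on a synthetic scene whose
nuclear-envelope droplets carry a +0.10 CE-fraction offset, and prints the
Welch t-test the pipeline reports.
"""

import srslipid as sl

config = sl.RunConfig(
    out_dir="scratch_example_run",
    seed=7,
    scene=dict(droplets_per_cell=20, ne_fraction=0.35,
               droplet_radius_px=(2.0, 4.0)),
)
result = sl.run_pipeline(config)

stats = result["ne_vs_cyto"]
print(f"detected droplets: {len(result['records'])} "
      f"(NE {stats['n_ne']}, cytoplasmic {stats['n_cyto']})")
print(f"mean CE fraction: NE {stats['mean_a']:.3f} vs cytoplasmic "
      f"{stats['mean_b']:.3f} (Welch p = {stats['p_value']:.2e})")
print("The NE group mean exceeding the cytoplasmic mean at p < 0.05 "
      "reproduces the direction of the generator's configured offset.")
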