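"""Render a synthetic two-channel scene and quantify its chromocenters.

Builds a field of nuclei whose DNA channel contains bright DNA-dense foci,
then runs segmentation, per-nucleus foci detection and measurement, and
prints the foci/nucleoplasm enrichment ratio per nucleus.  On a noise-free
scene the measured ratios equal the generator's contrast exactly.
"""

import chromofoci as cf

params = cf.SceneParams(nucleus_count=4, foci_per_nucleus_mean=5.0,
                        dna_foci_to_nucleoplasm_contrast=3.0, noise_sd=0.05,
                        seed=1)
channels, truth = cf.simulate_scene(params)

labels = cf.segment_nuclei(channels["dna"], cf.SegmentationConfig(),
                           params.pixel_size_um)
foci = cf.detect_foci(channels["dna"], labels, cf.FociConfig(),
                      params.pixel_size_um)
measurements = cf.measure_nuclei(channels, labels, foci, params.pixel_size_um)

print(f"{'nucleus':>7} {'area um2':>9} {'foci':>5} {'foci area':>9} "
      f"{'DNA ratio':>9} {'call':>8}")
for m in measurements:
    call = cf.classify_distribution(m, "reporter")
    print(f"{m.nucleus_id:>7} {m.nucleus_area_um2:>9.1f} {m.foci_count:>5} "
          f"{m.foci_area_um2:>9.2f} {m.ratio.get('dna', float('nan')):>9.2f} "
          f"{call.label:>8}")

print("\nThe DNA ratio is mean intensity inside foci over mean intensity in")
print("the nucleoplasm; ratios near the generating contrast (3.0) and a")
print("'spotty' call indicate strong chromocenter enrichment.")
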