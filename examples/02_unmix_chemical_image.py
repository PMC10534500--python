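"""Preprocess a chemical image and unmix it into an HPMC concentration map.

The NIR recipe (Savitzky-Golay first derivative) keeps the pipeline linear,
so on a noiseless image classical least squares recovers the generator's
ground-truth HPMC map essentially exactly; the printed error is numerical
noise only.
"""

import numpy as np

from dissomap import concentration_map, fit_cls, full_design_table, mean_concentration
from dissomap.preprocess import preprocess_nir
from dissomap.synth import generate_particle_map, generate_pure_spectra, render_cube

design = next(d for d in full_design_table() if d.name == "DR13")  # 20% HPMC, <45 µm
library = generate_pure_spectra("nir", n_bands=240, similarity_target=0.9, seed=1)
pmap = generate_particle_map(design, (48, 48), pixel_pitch_um=25.0, seed=3)
cube = render_cube(pmap, library, noise_sd=0.0)

operator = fit_cls(preprocess_nir(library))
print(f"CLS operator condition number: {operator.condition_number:.1f}")

cmap = concentration_map(operator, preprocess_nir(cube), "HPMC")
truth = 100.0 * pmap.component_fraction("HPMC")
print(f"map shape: {cmap.shape}, mean HPMC: {mean_concentration(cmap):.2f} w/w% "
      f"(ground truth {truth.mean():.2f})")
print(f"max |recovered - truth|: {np.max(np.abs(cmap.values - truth)):.2e} w/w%")
print("-> noiseless NIR unmixing is exact to numerical precision")
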