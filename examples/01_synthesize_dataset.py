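"""Generate a small synthetic tablet dataset and inspect one record.

Each record emulates one HPMC sustained-release tablet: its composition
(with tablet-to-tablet jitter), Raman and NIR chemical images of the tablet
surface, and the in vitro dissolution profile measured over 16 h.
"""

import numpy as np

from dissomap import full_design_table
from dissomap.synth import SynthConfig, generate_dataset

designs = full_design_table()[:4]  # four calibration compositions
records = generate_dataset(designs, replicates=2, master_seed=7, cfg=SynthConfig())

print(f"{len(records)} records ({len(designs)} designs x 2 replicates)\n")
rec = records[0]
print(f"record {rec.record_id}: {100 * rec.design.hpmc_frac:.2f} w/w% HPMC, "
      f"sieve fraction {rec.design.hpmc_size_fraction} µm")
print(f"  Raman cube: {rec.cube_raman.shape} at {rec.cube_raman.pixel_pitch_um} µm/pixel")
print(f"  NIR cube:   {rec.cube_nir.shape} at {rec.cube_nir.pixel_pitch_um} µm/pixel")
print(f"  realized HPMC area fraction (Raman map): {rec.map_raman.hpmc_area_fraction:.3f}")
print(f"  dissolution: {len(rec.profile)} points, "
      f"{rec.profile.released[-1]:.1f}% released at {rec.profile.times[-1]:.0f} min")

# replicates share a design but differ in realized composition and texture
a, b = records[0], records[1]
print(f"\nreplicate jitter: {100 * a.design.hpmc_frac:.3f} vs "
      f"{100 * b.design.hpmc_frac:.3f} w/w% HPMC")
print("cubes identical?", np.array_equal(a.cube_raman.data, b.cube_raman.data))
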