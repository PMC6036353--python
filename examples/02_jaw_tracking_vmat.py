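"""Jaw-tracking dynamic collimation driven by fractional-MU sampling.

Builds a two-segment plan in which the jaws shrink from 10x10 to 4x4 while
the MLC gap sweeps across the field, collimates it dynamically (each
recycled copy samples its own fractional MU, which sets both the jaws and
the leaves — that coupling IS jaw-tracking), and shows how the collimation
counters change when jaw-tracking is disabled.
"""

import numpy as np

from fajtrace import (Beam, CollimationConfig, ControlPoint, CyclicReader,
                      SourceModel, collimate_dynamic, default_geometry,
                      generate_phspA)
from fajtrace.phasespace import fluence_map

geom = default_geometry()
phspA = generate_phspA(SourceModel(seed=11, cone_half_angle=0.1), 400_000)

mlc = ([-5.0, -3.0, -1.0, 1.0, 3.0, 5.0],  # leaf boundaries (y, cm at iso)
       [-3.0] * 5, [-1.0] * 5)             # 2 cm gap, bankA/bankB (x, cm)
mlc_end = (mlc[0], [1.0] * 5, [3.0] * 5)   # gap swept to the other side

for jaw_tracking in (True, False):
    beam = Beam([ControlPoint(0, 0.0, (-5, 5, -5, 5), mlc, 0.0),
                 ControlPoint(1, 1.0, (-2, 2, -2, 2), mlc_end, 0.0)],
                total_mu=100.0, modality="imrt_dynamic",
                jaw_tracking=jaw_tracking)
    cfg = CollimationConfig(n_requested=200_000, n_recycle=20, seed=3,
                            mlc_transmission=0.015)
    phspB, rep = collimate_dynamic(CyclicReader(phspA, 4), geom, cfg, beam)
    h, _, _ = fluence_map(phspB, 6.0, 24, z_plane=100.0)
    print(f"jaw_tracking={jaw_tracking}: read {rep.n_read}, "
          f"jaws absorbed {rep.n_absorbed_jaws}, "
          f"MLC attenuated {rep.n_attenuated}, scored {rep.n_scored}")

print("With tracking on, the jaws follow the small late-delivery aperture")
print("and absorb more particles; with tracking off they park at the")
print("maximum opening and the MLC alone shapes the fluence.")
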