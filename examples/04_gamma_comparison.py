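"""Dose-distribution comparison: 3D gamma, chi, RMSD and isodose bands.

Builds a smooth reference dose, perturbs it with a small spatial shift plus
noise, and runs the full evaluation stack, including the per-isodose-band
breakdown used to report clinical verification results.
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from fajtrace import ComparisonCriteria, DoseGrid, band_report
from fajtrace.compare import compare

rng = np.random.default_rng(0)
base = gaussian_filter(rng.random((30, 30, 30)), 4.0)
base = (base - base.min()) / (base.max() - base.min())
ref = DoseGrid(base, np.zeros_like(base), 1, (0.25,) * 3, (0, 0, 0))

shifted = np.roll(base, 1, axis=0)                 # 2.5 mm shift
noisy = shifted * (1 + 0.005 * rng.standard_normal(base.shape))
ev = DoseGrid(noisy, np.zeros_like(base), 1, (0.25,) * 3, (0, 0, 0))

crit = ComparisonCriteria(dose_tol=2, dta=2, threshold=10, bands=(80, 40, 20))
res = compare(ref, ev, crit)
print(f"gamma 2%/2mm pass: {res.gamma_pass:.1f}%   chi pass: {res.chi_pass:.1f}%")
print(f"RMSD: {res.rmsd:.2f}% of max over {res.n_voxels_evaluated} voxels")
for band, r in res.per_band.items():
    print(f"  isodose {band:>6}%: gamma {r.gamma_pass:6.2f}%  "
          f"chi {r.chi_pass:6.2f}%  ({r.n_voxels_evaluated} voxels)")
print("The 2 mm distance-to-agreement absorbs the 2.5 mm shift wherever the")
print("gradient is steep; flat regions rely on the 2% dose tolerance alone.")
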