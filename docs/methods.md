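# Methods

## The collimator model

`fajtrace` models the two pairs of linac secondary collimators (jaws) as
perfectly absorbing planes located at the **top surface** of each pair
(closest to the target).  A particle is ray-traced in vacuum to each plane
in beam order; if its coordinate along the pair's axis falls outside the
projected opening `e · z_top / SAD` it is terminated, otherwise it continues
with direction, energy and weight unchanged.  There is no transmission
through and no scatter from jaw material.  The top surface, rather than the
vertical midpoint, is chosen because it rejects both diverging and
downward-aimed particles most effectively; the difference is invisible for
a near-point source but measurable for a parallel beam, and a regression
test pins this semantics against a mid-plane variant.

Consequences of the approximation, by construction:

- the lateral fluence below the collimator is a step function at the
  projected edge (no transmission tail); out-of-field dose is therefore
  *underestimated*, which for a realistic jaw stack amounts to a few tenths
  of a percent of the maximum dose;
- monitor-chamber backscatter from the jaws cannot be simulated, which is
  why the absolute-dose conversion carries a measurement-style `S_b`
  lookup table (below);
- particles with `w <= 0` can never reach the phantom in a
  forward-ray-trace model and are discarded (counted in the report).

A particle exactly on a projected edge is absorbed — the closed-jaw
tie-break, chosen so edge round-off never over-doses out of field.  The
event has measure zero for continuous sources.

## Phase-space recycling and azimuthal redistribution

The source phase space PhspA (scored on a plane above the jaws, default
z = 26 cm) is held in RAM as a columnar table.  A cyclic reader starts at a
uniformly random index (so parallel runs with different seeds consume
independent portions) and reads sequentially with wraparound.  Particles
whose lateral radius exceeds `r_max` — by default the largest jaw-opening
corner projected to the source plane plus 10% — are discarded at read time
but still counted in `n_read`.

Each delivered particle is recycled `n_recycle` times (default 20); every
copy is rotated by an independent uniform azimuth about the beam axis,
rotating `(x, y)` and `(u, v)` through the same angle, which preserves
radius, polar angle, energy and weight exactly while making the azimuth
uniform.  This azimuthal particle redistribution (APR) suppresses the
latent variance of reusing a finite phase space — except near the beam
axis, where all copies of a source particle land in the same voxel column
regardless of azimuth.  The residual near-axis latent variance decreases
only with the number of *distinct* source particles read, which is what
drives the problem sizes chosen below.  If downstream demand exceeds one
pass over the store the reader wraps and a warning is logged, because
wrapped reads add no new information near the axis.

The output phase space PhspB (scored below the MLC, default z = 55 cm)
contains **exactly** `n_requested` particles; `n_read` is determined on the
fly from the rejection rate.  The accounting identity
`examined = upward + absorbed_jaws + absorbed_mlc + scored` is asserted on
every run.

Two seeded RNG streams are derived from the collimation seed (one for
azimuths, one for fractional-MU draws); combined with the fixed
2048-source-particle chunk size of the vectorized pipeline this makes every
collimation bit-reproducible from `(store, reader seed, config)`.

## Jaw-tracking and the MLC stage

Dynamic plans are cumulative-MU-indexed control-point lists.  Each APR copy
draws its own fractional MU; jaws, MLC banks and gantry angle are
interpolated **linearly in cumulative MU** between the bounding control
points (a `nearest` mode exists).  Linear interpolation of jaw edges and
per-leaf positions preserves `X1 < X2` and `bankA <= bankB` automatically.
Because one draw sets both jaws and leaves, collimator and leaf motion are
synchronized — that coupling is jaw-tracking.  With `jaw_tracking=False`
the jaws are parked at the per-beam maximum opening while the MLC still
moves.  Sampling is per copy rather than per source particle: it maximizes
aperture decorrelation between copies and costs nothing.

The MLC stage is deliberately first-order: project to a single plane
(default z = 50 cm), locate the leaf pair by the cross-leaf coordinate,
pass unmodified inside the (tip-offset-widened) opening, multiply the
weight by a bulk transmission factor under a leaf (or absorb when the
factor is 0), absorb outside the leaf-boundary span.  Tongue-and-groove,
interleaf leakage and in-leaf hardening are out of scope; the module
boundary allows a richer leaf model to drop in.

VMAT arcs are split into one sub-field per adjacent control-point pair,
each renormalized to `[0, 1]` and carrying its MU share and gantry span;
IMRT fields can be split into `nsplit` identical copies with seeds derived
via `SeedSequence(base, spawn_key=(i,))` folded below 2^31.  Scored
particles from dynamic collimation carry their sampled gantry angle so the
dose engine can rotate each one into the phantom frame.

## Dose engine

The engine is a kerma-level stand-in for a full phantom Monte Carlo code:
photons are traced through the voxel grid with the exact incremental
grid-crossing walk (ties at voxel faces assign the path to the voxel being
exited), energy fluence attenuates as `exp(-mu(E) rho l)` along the
radiological path, and each traversed voxel receives the track-length kerma
deposit `w · E · (mu_en/rho)(E) · exp(-(tau + mu rho dl / 2)) · dl / V`
(mid-segment attenuation; the closed-form exponential depth curve is
reproduced to < 0.5%).  There is no electron transport and no scatter dose
— no buildup, no penumbra blur beyond the focal spot — so the engine's
claims concern collimation geometry and bookkeeping, not transport physics.
Charged particles deposit their full energy in the entry voxel.  Water
`mu/rho` and `mu_en/rho` tables (coarse, NIST-like fixture values) are
interpolated log-log.

Dose is normalized per primary-history-equivalent with
`N = n_read · n_recycle · (n_original_histories / |PhspA|)`, which keeps
"Gy per initial history" semantics consistent under recycling and radius
rejection; a doubling-invariance test asserts the contract.  Per-voxel
variance accumulates per scored particle (copies are treated as
independent, so the estimate understates near-axis latent variance; the
acceptance experiments therefore size runs empirically, see below).
Gantry rotation is a frame transform about the couch axis through the
isocenter; collimator/couch rotations are unsupported.

## Absolute dose and Sb

`D' = Do · TMR(d_ref, 10×10) · D_cal(d_max, 10×10) / D_MC(d_ref, 10×10) · MU · S_b`,
applied voxelwise with the variance scaled by the square of the constant.
The calibration constants reflect SAD conditions (10×10, SSD 90,
d_ref = 10 cm); only the `(d_ref, 10×10)` TMR entry enters the relation but
a full TMR table is kept.  The shipped `S_b` table is a smooth synthetic
fixture normalized to `S_b(10,10) = 1` with range ≈ 0.991–1.002 (larger
openings expose less jaw area to the monitor chamber); real measured tables
are user-supplied CSV.  For IMRT, `S_b` is the MU-weighted mean over
control-point segments, each segment evaluated at its **midpoint** jaw
opening (consistent with linear-in-MU interpolation; a node mode exists);
for VMAT, `S_b` is computed and applied separately per sub-field.  The
weighted mean is convex, so `S_b` always lies between the per-segment
extremes.

## Comparison stack

Gamma uses global normalization (percent of maximum reference dose), a
voxel-above-threshold evaluation set, and a search pruned per reference
voxel to evaluation points whose pure distance term cannot beat the current
best — an exact pruning, asserted equal to exhaustive brute force to 1e-9.
No sub-voxel interpolation is performed (voxel-center search only): a
conservative bias, accepted so the pruned search is provably equivalent to
its oracle; at 5 mm voxels with 2 mm DTA the distance term rarely rescues a
voxel, making gamma noticeably noise-susceptible — one reason the signed
chi index is always reported alongside.  Chi is the gradient-weighted dose
difference `(D_e - D_r) / sqrt((tol·Dmax)^2 + dta^2 |grad D_r|^2)` with
central-difference gradients; it equals gamma on zero-gradient fields.
RMSD is reported in percent of the maximum reference dose.  Band reports
slice pass rates by reference isodose ranges (e.g. >80 / 40–80 / 20–40).

## Synthetic source and what passing tests show

Vendor phase spaces are proprietary, so the package ships a parameterized
stand-in: photons from a Gaussian focal spot (default sigma 1 mm) at the
target plane, directions uniform in solid angle within a cone, energies
from a 10-bin 6 MV-like spectrum fixture.  The emission cone default
(0.29 rad) covers a 40×40 cm field; per-field experiments use a cone
covering the field diagonal with 15% margin, which is what the radius
pre-filter would discard anyway and keeps the in-RAM store small.  The
synthetic source has no electron contamination, no off-axis softening and
no flattening-filter shape; tests passing against it demonstrate the
correctness of collimation geometry, sampling, bookkeeping and evaluation
machinery — not agreement with a real beam.

The analytic open-field oracle integrates the same point-source fluence
through the same aperture projections directly:
`D = sum_E p_E E (mu_en/rho) exp(-mu t) / (Omega r^2)` per voxel, with
exact per-voxel lateral coverage fractions (the admitted rays form a
rectangle at every depth for jaws-only apertures) because the Monte Carlo
estimator measures voxel-averaged dose; with an MLC aperture it falls back
to midpoint supersampling.  The oracle shares no code with the collimation
or deposition path.

## Problem sizes

End-to-end open-field comparisons use the 82³, 5 mm water cube at SSD 90
and are sized so the in-field per-voxel statistical uncertainty (including
the near-axis latent component, measured empirically from independent
repeats) is about 1%: 1.5 M scored particles for 4×4, 8 M for 10×10 and
48 M for 30×30 (scored counts scale with field area; the 30×30 run is
partitioned into six summed sub-runs, mirroring clinical parallel
splitting).  Source stores hold 1–6 M particles so no run wraps the phase
space.  Distributional tests (KS, binomial) use 1e5 samples at alpha 0.01
or 4-sigma bounds.

## Known limitations

- No jaw transmission/scatter (deliberate), no electron/scatter transport
  in the phantom, no monitor-chamber or flattening-filter simulation.
- The MLC stage is first-order; clinical leaf-end and tongue-and-groove
  effects are absent.
- CT-derived phantoms are stubbed (uniform water cube / water cylinder
  generators only); couch rotations unsupported.
- Gamma without sub-voxel interpolation is conservative on coarse grids.
- The per-voxel variance estimator treats recycled copies as independent
  and therefore underestimates uncertainty near the beam axis.
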