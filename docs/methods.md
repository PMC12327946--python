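# Methods

This note documents the models and procedures implemented in `flipscan`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data validation does and does not demonstrate.  All lengths are
in angstrom and all times in nanoseconds; trajectories are assumed to be
sampled at about one frame per nanosecond, as is typical for
coarse-grained bilayer production runs.

## Lipid orientation and flip-flop detection

Each phosphatidylcholine lipid is reduced to the angle θ(t) between the
average of its NC3→C4A and NC3→C4B vectors and the +z axis.  Resting
upper-leaflet lipids sit near 150°, lower-leaflet lipids near 30° — the
~30° offset from the poles reflects the average chain tilt of CG lipids.
The raw angle is denoised with a centered 100 ns running average, with
the window truncated at the series edges.  A trailing window was
considered and rejected: it shifts every detected completion time late by
half a window, which would bias the event-vs-groove-state correlation.

Events are detected by a two-state hysteresis machine on the smoothed
angle.  The initial leaflet state is taken from the first smoothed value
relative to 90°; an upper-state lipid emits an `upper_to_lower` event at
the first frame below θ_low = 35° (state flips), and symmetrically a
lower-state lipid emits `lower_to_upper` above θ_high = 145°.  These
stringent thresholds (rather than, say, 55°/125°) mean a partial
excursion that reaches the middle of the band and returns emits nothing;
with the default 1 Å bead jitter, resting-lipid noise on the smoothed
angle is ≈ 0.5°, so false positives are absent in practice.  Each
completed crossing counts as one event; a lipid that flips back later
contributes a second event in the opposite direction.

`t_enter_band` — the last frame the lipid spent in its origin band
(θ > 145° for upper, < 35° for lower) before the completing excursion —
defines the transit window used for pathway classification.

Rates are computed over non-overlapping 1 μs blocks (trailing partial
block discarded) as mean ± population SD of per-block counts.  Poisson
behavior is diagnosed with two complementary statistics: a
Kolmogorov–Smirnov test of inter-event gaps against an exponential with
rate n/duration, and the dispersion index (variance/mean) of the 1 μs
block counts.  The verdict is "consistent" when the KS p-value is ≥ 0.05;
with the rate estimated from the same data the test is slightly
conservative, which is acceptable for a diagnostic.  Fewer than two
events give no verdict.

## Leaflet surfaces and minimal thickness

Lipids are assigned to leaflets **per frame** using the hysteresis state
from event detection — not the sign of z — so a lipid mid-transit keeps
its origin label until the crossing completes, and never contributes to
both leaflets in one frame.

The two surfaces are built from the glycerol beads (GL1/GL2) on a 1 Å
(x, y) grid.  The default estimator scatters each frame's beads into
cells, takes per-frame cell means, and averages those over frames.  Cells
occupied in fewer than 2% of frames are discarded, then everything but
the largest 8-connected component.  Two properties of this estimator are
worth knowing:

- At physiological lipid density (~70 Å² per lipid) a 1 Å cell is hit in
  roughly 3% of frames, so the 2% cutoff removes only genuinely rare
  cells.  Sparse systems (> ~90 Å² per lipid) push typical occupancy
  *below* the cutoff and shred the mask; the validation fixtures
  therefore use ~70 Å² per lipid.
- The minimum over many noisy cell means is biased low by roughly
  2·σ_cell·√(2 ln N_cells).  With 1 Å positional noise this demands long
  averaging; the thickness validations use 8 μs of frames, where the
  flat-bilayer recovery is 29.6 Å against a true 30 Å.

An alternative estimator (`method="interpolate"`) builds a per-frame
Delaunay linear interpolation of the scattered glycerol positions (with
periodic images near the box edges) onto the grid.  It covers every
in-hull cell every frame and averages to a very quiet field, but linear
interpolation rides above curved dips by ~(inter-lipid spacing²/8) ×
curvature and therefore under-reports deep narrow pinches by 2–3 Å at
CG lipid densities.  It is kept for smooth-surface work and is not the
default.

Minimal membrane thickness is the **exact minimum 3D distance** between
retained cell centers of the two surfaces (k-d tree nearest neighbors;
verified against the all-pairs brute force).  The distinction from
vertical thickness matters at pinches, where the closest approach is
oblique.  Both the global minimum and a groove-local minimum (within a
configurable radius of the groove center) are reported, since a remote
undulation can otherwise dominate the global value.

## Groove geometry and competence

Groove width is the frame-wise minimum distance over all bead pairs
between the TM4 and TM6 residue ranges (all beads, not only backbone —
the most inclusive reading).  Default residue ranges per homolog:
nhTMEM16 327–339/430–452, afTMEM16 319–331/426–438, TMEM16K
365–377/434–446, TMEM16F 512–524/613–625, TMEM16A 541–553/635–647.  The
TMEM16F TM4 range is printed as "512–424" in the source material — an
apparent transposition; 512–524 is used here and is configurable.

The raw series feeds the median and quartiles; a recursive EWMA
(s_t = 0.1·x_t + 0.9·s_{t−1}, s₀ = x₀) feeds the open/closed flag at
6 Å.  The EWMA reaches 95% of a step in ⌈ln 0.05/ln 0.9⌉ = 29 frames;
because the lag is symmetric on opening and closing, the open-fraction
estimate of a breathing groove is unbiased (validated to within 0.02 of
a programmed 50% duty cycle).

Scrambling competence is a quadrant gate: competent iff minimal
thickness < 14 Å **and** median width > 6 Å.  Boundary values are
classified non-competent (strict inequalities; arbitrary but documented
and configurable).

## Densities and the maximum-density pathway

Bead densities are histogrammed on a 0.5 Å grid (default extents
100 × 100 × 150 Å) centered on the groove, in the protein-fixed frame
(each subunit rigid-body aligned to its starting coordinates; the
accumulator refuses unaligned trajectories).  Per-subunit grids can be
averaged in a common groove-local frame, or a single chain used for
asymmetric structures.  Grids round-trip through OpenDX.

The membrane-spanning pathway is traced per z slab: the candidate cell is
the density argmax within a 15 Å tube of the previous node, refined to
the density-weighted centroid of its 3×3 in-plane neighborhood, giving a
connected z-monotone polyline.  Empty slabs are linearly interpolated
(with a warning); more than 20% empty slabs is an error.  A Dijkstra
widest-path construction was considered as an alternative; the
constrained argmax was chosen for determinism and robustness on noisy
grids and recovers straight and helical synthetic tubes to within one
cell.

An event is **in-groove** when, during its transit window, the PO4 bead
comes within 4.7 Å of any pathway node while its z lies within the
middle half of the membrane span; otherwise out-of-groove.  With
per-subunit pathways the nearest subunit is recorded.

## Contacts and dwell times

A contact is a distance strictly below 7 Å between a residue's outermost
side-chain bead and a lipid's NC3 or PO4 bead.  "Outermost" is defined
operationally as the side-chain bead with the largest mean distance from
the residue's backbone bead over the trajectory; glycine falls back to
its backbone bead.  Dwells merge contact runs separated by gaps of at
most 6 ns, and the duration counts both endpoint frames
((last − first + 1)·dt), so a planted interval [a, b] is recovered as
b − a + dt.  Per residue, the headgroup bead with the higher mean dwell
is kept; contact frequency is the fraction of frames with ≥ 1 lipid in
contact, averaged over monomers; the top-50% summary averages the
⌈n/2⌉ longest dwells.

## Permeation and selectivity

Each water bead or ion is tracked through three zones — below
(z < z_lower − 5 Å), inside, above (z > z_upper + 5 Å), with z bounds
from the leaflet surfaces.  A directed event is recorded when a particle
that entered the middle zone from one side exits to the opposite side
while within 8 Å of the pathway at its midplane crossing.  Re-crossings
count separately; particles that enter and retreat — even past the
midplane — count nothing, and time reversal exactly swaps the up and
down counts.  Selectivity P_Na/P_Cl is the ratio of total counts, with
an infinity marker when only cations permeate and an undefined marker
when neither species does.  Martini water beads represent four waters;
counts are reported per bead event without rescaling.  Both total and
net (up − down) water flux are reported, since either convention may be
wanted.

## Transit energetics and kinetics

The free-energy profile along the groove is the Boltzmann inversion
G(s) = −kT·ln(ρ(s)/max ρ) of the in-tube PO4 density, binned at 1 Å on
the pathway's z coordinate, normalized to min G = 0, with empty bins
flagged rather than silently interpolated.  The barrier is read off the
membrane-spanning region only.  kT = 1 by default (thermal units).

The per-event transit dwell is the contiguous stretch of frames the PO4
bead spends inside the pathway tube around its midplane crossing.  The
diffusion coefficient along the groove is fit from the pooled MSD of the
projected coordinate over lag times of 1–10 frames, as a least-squares
line through the origin (MSD = 2Dτ).  On planted 1D Brownian motion with
D = 12 Å²/ns the estimator is unbiased to well within 20% over 50 seeds.
These two constructions are deliberately minimal standard choices; other
estimators (e.g. covariance-based or Bayesian D estimators) could differ
systematically on strongly confined motion.

## The synthetic generator

`flipscan.synth` emulates the statistical structure the analyses assume,
not membrane physics: lipids and tracers follow kinematic scripts with no
force field, solvent, or excluded volume.  Specifically it provides:

- two lipid lattices at ±15 Å (glycerol anchor) with 15 Å head-to-tail
  span, 30° resting tilt, isotropic per-bead Gaussian jitter (default
  σ = 1 Å) and a lateral random walk (default 1 Å²/ns, a typical CG lipid
  lateral diffusivity);
- a rigid two-column TM4/TM6 scaffold with BB/SC1 beads (every fourth
  residue glycine), optional mirrored second subunit, and an optional
  "breathing" mode that switches the column separation between 4 and 8 Å
  with a programmable duty cycle;
- flips whose headgroup follows a pathway polyline while the orientation
  angle sweeps 150° → 30° (or back), with partial excursions turning
  around near 55°; Poisson scheduling with exponential gaps, or explicit
  schedules;
- analytic deformation fields (Gaussian pinch, sinusoid) applied to the
  leaflet anchor heights, with closed-form minimal thickness
  (bulk − 2·amplitude for a centered symmetric pinch);
- tracer beads with planted directed transits, non-crossing decoys that
  may reach past the midplane before retreating, and groove-resident
  waters for density/pathway construction;
- planted protein–lipid contact intervals on dedicated lipids.

Everything is drawn from a single seeded generator, so identical specs
give bitwise-identical trajectories and ground truth.

Passing the validation suite on this generator demonstrates that the
estimators recover known answers under realistic noise, density and
sampling conditions.  It does **not** demonstrate robustness to features
the generator lacks: membrane undulations with long spatial correlations,
protein flexibility, lipid crowding/excluded volume, force-field
artifacts, or scrambling kinetics coupled to groove conformation.  One
interaction worth noting: on fixtures where flips are planted, the
scrambling lipids themselves pull the measured surfaces inward near the
pathway — as dilated-groove systems do in real simulations — so the
analytic deformation minimum is an upper bound, not an equality, and the
ground-truth validator treats it as such in that case.

## Numerical choices and degenerate inputs

- Internal units are fixed to Å/ns; file readers convert on load.  DCD
  files carry no reliable clock, so an explicit `dt` always wins over
  file time stamps.
- Alignment uses least-squares rigid superposition (SVD); collinear
  reference selections are rejected.  Alignment is idempotent to 1e-9 Å.
- Equilibration trimming is relative to the trajectory start, so
  trimming t₁ then t₂ equals trimming t₁ + t₂.
- The smoothing window is clipped to the series length; series shorter
  than the window are averaged whole.
- Quartiles use linear interpolation (numpy default).
- `block_rate` errors when the duration is shorter than one block; the
  pipeline clamps the block length to the retained duration instead.
- Zero-density slabs in pathway extraction are interpolated up to a 20%
  budget, then it is an error.  Empty leaflets, empty surface masks and
  empty free-energy histograms are errors, not NaNs.

## Problem sizes used in validation

The shipped validation (tests and `scripts/acceptance.py`) uses 10 μs
trajectories with 64–128 lipids per leaflet for event detection and
classification, 8 μs with 205 lipids per leaflet (70 Å² each) for
thickness recovery, 10 μs breathing-groove runs for duty-cycle recovery,
and 1.2 μs mixed fixtures for the end-to-end pipeline — sizes chosen so
each stage's statistical tolerance is met with margin while the whole
suite completes in a few minutes on one CPU.
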