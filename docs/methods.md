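# Methods

## The phantom

The phantom replaces a fixed, fluid-displacement-measured rat lung with a
miniature reference volume: a cube whose volume equals the "measured" lung
volume, filled with a suspension of AE2-like cells. Everything downstream
only ever sees profiles and a reference volume, so alveolar architecture
(septa, capillaries, air space) is deliberately absent; the "lung" is the
cube, and non-cell space plays the role of all other tissue compartments.

**Periodicity.** The tissue is periodic: cell centres are uniform over the
whole cube and any solid crossing a face wraps to the opposite face.
Sampling probes (counting frames, test lines, disector planes) that reach
beyond a face see the wrapped images (`Phantom.packed(margin)` materialises
every image a probe with that excursion can touch). This is what makes the
content density *exactly* uniform: with a bounded phantom, cells need a
wall margin, the resulting cell-free shell is covered less often by frames
anchored inside the tissue, and number estimates referencing the lung
volume acquire a genuine edge-effect bias of several percent. With
periodicity every estimator here is edge-free, and the exhaustive-disector
identity (below) holds exactly.

**Cells.** Ellipsoids of one shape (default semi-axis ratios
1.2 : 1 : 1/1.2, so the rotator is exercised beyond the sphere) scaled by a
lognormal volume (mean 500 μm³, CV 0.15), with Haar-random orientation.
Bounding spheres of different cells do not overlap (minimum-image metric).
Each cell contains

- a spherical nucleus (volume fraction 0.15 of the cell, placed at a small
  random offset),
- exactly one spherical nucleolus (radius 1.6 μm) inside the nucleus — the
  unique counting unit of the light-microscopic disector. Its diameter
  (3.2 μm) deliberately exceeds the 3 μm disector height: a particle
  shorter than the disector height would be undercounted, so the phantom
  encodes the assumption the bench protocol makes implicitly;
- a luminal surface patch: the set of surface points whose parameter
  direction lies within a cap around the local +z axis, with the cap angle
  solved by quadrature so the patch area fraction equals the configured
  luminal fraction to 1e-6 (for a sphere this is the geodesic cap with
  fraction (1−cos θ)/2);
- non-overlapping spherical lamellar bodies outside the nucleus. Counts per
  cell are negative binomial (mean 120, dispersion 50); individual volumes
  are lognormal (σ_log = 0.6), radii clipped below 0.08 μm so every Lb is
  taller than the EM disector. Placement is sequential largest-first over a
  pre-drawn candidate pool; a candidate admits a sphere of radius r if it
  lies in the cell scaled by 1 − r/c (c the smallest semi-axis) — a
  sufficient containment criterion by convexity — and clears the nucleus.
  A cell that cannot host its draw raises an explicit overpacked error.

**Magnitudes.** The study the pipeline emulates reports no absolute Lb
counts or sizes in print, so the defaults were chosen once to land the
derived surfaces in the reported range: 120 Lb per cell with mean volume
0.21 μm³ gives a sphere-model Lb membrane surface of ≈ 205 μm² per cell,
and a luminal fraction of 0.49 on a ≈ 307 μm² cell surface gives
≈ 150 μm² of luminal membrane. The lung is scaled down to 300 cells in
1.5 × 10⁻⁶ cm³ (10% cell packing) so that replicate-heavy studies run in
minutes; the calibration study uses a further reduced lung (100 cells).
All of this is configuration, not a claim about rat lungs.

**Scenarios.** `ir-shift` (default): the I/R group keeps cell number and
size but has the Lb count mean reduced from 120 to 80 with the mean Lb
volume raised ×1.5, conserving the expected total Lb volume per cell, and
the luminal fraction raised by exactly the expected sphere-model membrane
release divided by the expected cell surface — so the configured truth has
"fewer, larger Lb; larger luminal surface; conserved membrane". `null`:
identical distributions, different seeds (negative control).

## The virtual microtome

Slabs perpendicular to a fixed axis with a random start spanning one full
period of the kept-slab pattern (2T, since every other slab is processed),
and exactly the cut faces falling within one period of the (periodic)
tissue are used; a square point grid with random offset on each kept cut
face; each hit yields a cubic block, and blocks are processed in random
order. The plan is scaled to the phantom so a lung yields about 5–11
blocks (the bench yield) without truncation; a hard maximum exists but is
sized never to bind, because truncation thinning correlates with the slab
phase and would bias fixed-phantom estimates. Sections are allocated as an
equal number per block (complete round-robin rounds until the cell quota is
met): a fixed per-lung section total would weight tissue by the inverse
block yield, which also correlates with the sampling phase. Each of these
choices was driven by the fixed-phantom bias suite: with any of them
relaxed, coverage of the reference volume is measurably non-uniform and
number estimates acquire biases of a few tenths of a percent to a few
percent. Sections are zero-thickness planes carrying a
nominal thickness (1 μm semithin, 0.1 μm ultrathin); a pair shares an
isotropic (IUR) normal and sits at a uniform random position in the block.
The light-microscopic pair has plane separation exactly 3 μm (first and
fourth serial semithin section); the electron-microscopic pair is two
consecutive ultrathin sections, h = thickness, optionally "measured" by the
fold rule (half the fold thickness, a noisy measurement of 2t — with zero
noise it equals the true thickness; the default noise is zero because a
noisy h enters the estimator as 1/h and would add a small documented bias).
Tangency of a solid to a plane counts as non-intersecting (a measure-zero
convention). Profiles are exact conics: sphere ∩ plane → disc, ellipsoid ∩
plane → ellipse in closed form.

Counting uses an unbiased 2D frame (forbidden line down the left edge,
along the bottom, then down from the bottom-right corner; acceptance on top
and right). The frame-rule acceptance region of a disc has exactly the
frame's area, and a tessellation of frames counts every disc exactly once —
both are asserted in the test suite. Because the phantom is analytic, no
guard region is needed for visibility: the rule is evaluated exactly even
for profiles reaching beyond the block.

## Estimators

- `physical_disector`: marker present in the reference plane (frame rule on
  its profile) and absent in the look-up plane; both directions; the
  estimator divides by 2 · h · a(p) · ΣP_ref. Exhaustively tiling one
  period of the phantom with consecutive disectors and a frame equal to the
  period cross-section counts every Lb exactly twice — an exact identity
  used as an oracle.
- `planar_rotator`: axis through the reference point at a uniform random
  angle in the section; lines perpendicular to the axis at spacing t
  (default 1 μm ≈ mean cell radius / 5, a variance–cost compromise) with
  random start; each side contributes half the squared distance from the
  axis to the far boundary minus the near boundary (the general convex-
  profile form, which reduces to (ℓ₊² + ℓ₋²)/2 when the axis crosses the
  chord). Unbiased over isotropic sections through the reference point.
- point counting and intersection counting on a coherent square lattice
  whose rows double as test lines (a(p) = d², l(p) = d), randomly
  translated and rotated per section; `S_V = 2ΣI/ΣL` with
  ΣL = l(p) · ΣP_ref. Luminal intersections are classified by the exact
  patch-membership test at the 3D crossing point.
- the cascade to absolute values uses the noisy measured lung volume
  (default CV 2%) and the rotator mean cell volume; the number-weighted
  mean Lb volume is total Lb volume per lung over total Lb number per lung;
  the sphere-model Lb surface follows from it. Undefined densities (empty
  reference counts) make the lung a logged missing value, never a zero.
- V_V(mito) is not estimated: mitochondria are not modelled geometrically
  and their configured volume fraction rides through the density tables as
  a pass-through.

## Statistics

Two-sided throughout. Gate: Shapiro–Wilk at α = 0.10 per group; both pass →
unpaired pooled-variance t-test, otherwise exact Mann–Whitney U (exact
distribution for group sizes ≤ 8, mid-ranks). At n = 5 the gate has very
little power — an honest reflection of any "Gaussian approximation present"
judgement on five animals. Means ± SEM and t-based 95% CIs are always
reported; two identical constant groups get p = 1 by convention (logged).
Pearson r with the t-distributed test statistic and least-squares slope and
intercept; in the experiment the regression is S(Lb, AE2) on S(lumen, AE2)
across all ten lungs.

One terminological note: the source protocol once calls the rotator output
a volume-weighted mean volume, but the rotator applied to disector-sampled
cells yields the *number-weighted* mean volume, which is also what the rest
of its own cascade uses. This package computes and labels the
number-weighted mean everywhere.

## Known biases and limitations

- **Rotator on disector sections.** In the pipeline the rotator runs on the
  actual section in which the nucleolus appeared, so the plane misses the
  nucleolus centre by up to its radius (1.6 μm). This is exactly what
  happens at the bench and costs about −5% on the mean cell volume for the
  default geometry (cell radius ≈ 5 μm), propagating into the absolute
  cascade. The estimator itself is validated in its contract setting —
  isotropic planes through the reference point — where it is unbiased.
- **Sphere-model Lb surface vs true surface.** The sphere model evaluates
  s̄ at the mean volume; for lognormal sizes this overestimates the true
  mean Lb surface by exp(σ_r²) ≈ 4% at the default σ. Both groups are
  affected equally, so the balance logic is unaffected.
- The phantom's cells are a monodisperse shape family in suspension; real
  AE2 cells are polarised, apposed to septa, and multi-nucleolar cells
  exist but are out of scope (one nucleolus is the counting unit).
  Passing tests therefore demonstrate correctness of the estimators and
  pipeline on geometry satisfying the method's assumptions, not robustness
  to real-tissue deviations (shrinkage, overprojection, lost caps).
- Sampling variance is not corrected; the coefficient of error per
  estimator is reported descriptively by the validation suite.
- The validation suite resolves residual estimator biases down to roughly
  0.3–0.5% (3 standard errors at 200 replicate sessions); the mean-of-
  sessions ratio estimators carry a small-sample bias below that
  resolution, kept negligible by pooling three independent block draws of
  three section rounds each per replicate session.

## Study sizes and counting intensities

Defaults per lung: 5–11 blocks, 8 semithin pairs per block (≈ 60–90
nucleolus disector events, each triggering one rotator measurement), EM
pairs until ≈ 100 AE2 profiles are seen (≈ 200–300 Lb disector events,
≈ 1500 reference points, ≈ 900 boundary intersections). The
effect-recovery study raises the EM quota to 160 profiles with a finer
grid and more semithin pairs (`REGRESSION_STUDY_SETTINGS`): the
conserved-membrane scenario moves only ≈ 22 μm² of membrane per cell —
about a third of the contrast the published group means display — and
resolving the *sign* of the S(Lb)-vs-S(lumen) regression reliably across
replicates needs a lower per-lung coefficient of error than the bench
session provides. The type-I calibration runs 200 replicates on half-size
lungs with a lighter session; the effect study runs 50 replicates at full
size. These sizes were chosen once as the package's study conditions.
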