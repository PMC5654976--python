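# Methods

## Geometry and data model

All computation happens in a right-handed millimetre frame: `z` is the
axial (depth) direction, `x`–`y` the en-face plane. A star scan is the set
of radial B-scans through the ONH centre; each B-scan contributes two
*spokes* (half-scans), each carrying one BMO point and the ILM
segmentation polyline of that half. The standard acquisition (24 radial
scans at 15°) therefore yields 48 spokes at 7.5° spacing. Spoke angles are
measured counterclockwise from the temporal horizontal axis in right-eye
(OD) orientation; OS scans are mirrored about the vertical en-face axis on
load so that a single internal convention suffices, while the recorded
laterality still drives the chirality of the surface discretization
(OD → diagonal A, OS → diagonal B).

ILM polylines are parametrized by cumulative arclength with linear
interpolation, which makes every downstream quantity invariant to vertex
resampling density. Exact vertex parameters return the vertex coordinates
bitwise, so degenerate configurations (ILM passing through a BMO point)
produce exactly zero areas rather than rounding noise.

The inter-spoke quad between spokes i and i+1 has vertex order
(bmo_i, bmo_{i+1}, ilm_{i+1}, ilm_i). Chirality A splits it along the
bmo_i–ilm_{i+1} diagonal into triangles (bmo_i, bmo_{i+1}, ilm_{i+1}) and
(bmo_i, ilm_{i+1}, ilm_i); chirality B uses the other diagonal. For planar
quads the two splits agree; for non-planar quads they differ, which is why
the convention is an explicit, testable parameter rather than a hidden
choice.

"BMO area" is defined here as the area of the BMO point polygon projected
onto its least-squares best-fit plane; how commercial devices compute
their reported BMO area is not documented, so this projected-polygon
definition is the package's own.

## Sequential minimization (BMO-MRA)

Each of the n cyclic quads is minimized on its own, *jointly* over both
ILM endpoint parameters — a true 2-D minimization per trapezoid. (An
alternative found in some descriptions — anchoring trapezoid corners to
per-spoke minimum-rim-width endpoints — is a different algorithm and is
deliberately not what this package implements.) The candidate set per
spoke is the full ILM polyline: every vertex plus a uniform arclength
densification grid (default step 10 µm). The grid winner is then refined
continuously by alternating bounded scalar minimization (Brent within one
candidate spacing of the incumbent, `xatol` mapped from the 1e-7 mm²
area tolerance), accepting a move only if it decreases the area. Ties on
the grid go to the smallest arclength pair, making results deterministic.

## Global minimization (BMO-gMRA)

One ILM vertex per spoke is shared by the two adjacent sectors, so the
n-degree-of-freedom problem cannot be decomposed. On the candidate grid it
is solved *exactly* by cyclic dynamic programming: fix each candidate of
spoke 0 in turn, run a linear min-plus DP over spokes 1…n−1, close the
cycle, and keep the best anchor — O(n·m²·m₀) for m candidates per spoke,
vectorized over anchors in chunks. Tie-breaking returns the
lexicographically smallest index vector (smallest anchor first, then a
forward greedy pass against a backward cost-to-go table, with a 1e-12
relative tolerance on float equality so that exact ties behave as in the
all-constant-cost case).

Optional continuous refinement then runs cyclic coordinate descent: for
each spoke in turn, the shared vertex is moved continuously along its ILM
curve to minimize the sum of its two adjacent quads (bounded Brent within
one candidate spacing), sweeping until a full sweep improves the total by
less than 1e-7 mm² (max 100 sweeps; non-convergence warns and returns the
last iterate, which is never worse than the grid optimum). Every accepted
move decreases the total, so refinement is monotone.

Because both strategies consume the same cost tables, the relaxation
bound `MRA_total ≤ gMRA_total` is a float-exact theorem on the grid: the
per-table minimum can never exceed the table value at the DP selection.
With independent continuous refinement on both sides the bound is only
approximate, which is why bound assertions in the tests run with
refinement disabled.

## Sector aggregation

The default sector scheme is the Garway-Heath layout in the OD frame,
temporal axis at 0°: temporal [315°, 45°), temporal superior [45°, 85°),
nasal superior [85°, 125°), nasal [125°, 235°), nasal inferior
[235°, 275°), temporal inferior [275°, 315°). The exact boundaries used by
commercial software are not public, so the scheme is configurable (names +
half-open intervals partitioning the circle, optional axis rotation). A
quad belongs to the sector containing the circular midpoint of its two
spoke angles, which is unambiguous for boundary-straddling quads. Sector
sums partition the global total exactly (same additions, grouped).

## Synthetic phantoms and cohorts

The generator emulates the scan pattern and the magnitudes of real ONH
morphometry, not retinal anatomy. Per eye:

- BMO ring: ellipse with semi-axes (a, b), default (0.85, 0.71) mm →
  area ≈ 1.90 mm², optionally tilted about the y-axis.
- ILM surface per spoke angle θ, sampled at `radial_samples` radii in
  [0, r_max] (the BMO radius is always inserted into the grid):
  `z(r, θ) = −cup_depth + (h(θ) + cup_depth) · σ((r − ρ(θ)) / w)`
  with σ the logistic function, ρ(θ) the BMO radius, w the slope width,
  and `h(θ) = rim_height · thinning(sector θ)` — a smooth ramp from cup
  floor to rim plateau with piecewise-constant sector thinning.
- independent Gaussian axial noise (default sd 5 µm, a typical
  segmentation jitter scale) on every ILM sample; deterministic given the
  spec seed.

Defaults `rim_height = 1.00 mm`, `cup_depth = 0.15 mm`, `w = 0.25 mm`
were calibrated once so that the *measured* global BMO-MRA lands near
1.2 mm² for the control configuration; the glaucoma group of
`study_like_cohort` (rim_height mean 0.84, cup 0.25, preferential
temporal-inferior thinning 0.70) lands near 0.8 mm². These are the
magnitudes a study-shaped evaluation needs; no anatomical fidelity is
claimed for the logistic profile itself.

Cohorts draw per-eye parameters from per-group normal distributions using
counter-derived substreams of one master seed (`default_rng([seed, k])`),
so cohorts are reproducible and order-independent. A visual-field mean
deviation is linked linearly to an analytic rim-area proxy (the noise-free
per-spoke minimum BMO-to-ILM distance integrated around the ring):
`MD = −16.4 + 11.0 · proxy + N(0, 1.7) dB`, giving control MD ≈ −0.5 dB,
glaucoma ≈ −6 dB and a Spearman correlation between MD and measured rim
area in the 0.7–0.85 range.

What the phantoms do *not* model: image-level OCT physics (speckle,
A-scan rendering), ocular magnification/axial length, inter-eye
correlation within patients, segmentation failures, and disc-size/age
confounding. Passing tests therefore demonstrate the correctness of the
optimization and statistics machinery under controlled geometry, not
clinical performance.

## Evaluation statistics

Rim areas shrink in disease, so the default ROC direction is
`lower_is_case`. AUC is the Mann-Whitney pair-ordering estimator (ties
count 1/2). The DeLong structural-components test compares the two
correlated AUCs measured on the same eyes; a zero-variance difference
(identical parameters) returns z = 0, p = 1 by convention. Partial AUC is
reported unnormalized over specificity [0.9, 1.0] (maximum 0.1),
integrating the empirical ROC polyline segment-wise with linear
interpolation only at the window endpoints — over the full range this
reproduces the Mann-Whitney AUC exactly. Sensitivity at fixed specificity
uses the conservative step-function convention (largest threshold with
specificity ≥ the target; no interpolation).

Bootstrap comparisons resample cases and controls separately while
preserving the per-eye pairing of the two parameters, and report a
two-sided normal-approximation p from the bootstrap standard error of the
difference (pAUC difference, or Spearman-correlation difference for the
MD analysis); measured type-I error at nominal 0.05 is ≈ 0.03. Resampling
is per eye, not per patient — inter-eye correlation is ignored, matching
the per-eye analysis the pipeline performs. Benjamini-Hochberg adjustment
(step-up, statsmodels) accompanies every family of p-values, and the
reported significance threshold is the largest raw p passing the step-up
criterion.

## Known limitations

- The DP grid optimum is exact, but continuous refinement is coordinate
  descent and can stall at non-grid local optima of the 48-dimensional
  problem; the frustum oracle shows the practical error is ≪ 1 µm² on
  smooth inputs.
- With heavy densification (step ≪ 10 µm) the DP cost grows as m³; the
  intended operating range is m ≲ 300 candidates per spoke.
- The bootstrap p-values use a normal approximation on the resampled
  difference, which is slightly conservative for the discrete pAUC
  statistic at small n.
- Problem sizes in the test-suite and acceptance runs (cohorts of 200
  eyes, 40 µm candidate steps without refinement) were chosen to keep the
  pipeline's full verification in the minutes range; they reproduce the
  bound, correlation and discrimination structure at reduced resolution.
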