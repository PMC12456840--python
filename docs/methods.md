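# Methods

## Problem

At ultrahigh field (7 T) the RF wavelength in tissue is comparable to the
head, so the transmit field B1+ of a coil array interferes destructively
inside the subject and the flip-angle distribution becomes non-uniform.
Slice-wise static RF shimming chooses one complex drive weight per transmit
channel so the combined field magnitude approximates a uniform target over
a region of interest. With `A ∈ C^{V×C}` the per-channel complex field
values at the V in-mask voxels, `b ∈ C^C` the weights, `m` the target
magnitude and `w` the mask, the package minimizes the magnitude-least-
squares (MLS) objective

    J(b) = || |A b| − m ||²_w + λ ||b||²

and reports field homogeneity as

    RMSE [% of target FA] = 100 / mean_w(m) · sqrt( || |A b| − m ||²_w / V ).

With the uniform unit target used throughout, the normalization by
`mean_w(m)` is a no-op and the figure is exactly the masked RMS error ×100.
The magnitude-only data term makes J non-convex (a phase-retrieval
relative): local search can stall, which motivates both the multi-restart
strategy and the learned screen below.

## Shim optimizers

**Multi-restart Adam (`adam_shim`, the reference arm).** J is minimized
over the 2C real parameters (Re b, Im b) — smooth everywhere, unlike a
magnitude/phase parameterization which is singular at zero — with the Adam
update rule (β = 0.9/0.999, ε = 1e-8, learning rate 0.05, up to 500
iterations, absolute objective-change tolerance 1e-8). The gradient is the
Wirtinger expression `2(Aᴴ r + λ b)` with residual
`r = (|Ab| − m)·Ab/|Ab|`; it is verified against finite differences in the
test suite. `n_restarts` independent trajectories (300 at reference scale;
desk-scale runs use 8–50) start from random weights — magnitudes uniform on
(0,1], phases uniform on [0,360)° — and advance in lockstep as one batched
array computation. The best objective value *visited* by each restart is
retained; the restart with the lowest final best wins, ties broken by the
lowest restart index. One additional deterministic restart starts at the
quadrature drive (configurable, on by default), which makes "never worse
than the baseline" structural rather than statistical: the initial point
itself is a candidate solution.

**Variable exchange (`mls_variable_exchange`, the conventional arm).**
The classic alternation for magnitude-only fitting: adopt the current
combined field's per-voxel phase onto the target
(`z = m · exp(i·angle(Ab))`), then solve the regularized linear problem
`min_b ||Ab − z||² + λ||b||²` in closed form via the normal equations
(pseudo-inverse fallback when λ = 0 and AᴴA is singular). Both half-steps
are non-increasing in J, so the objective sequence is monotone — to a
*local* fixed point that depends on the start. The default start is the
quadrature drive; `n_random_starts` extra seeded starts (best final
objective wins) are available because single-start variable exchange
demonstrably stalls in poor basins on a noticeable fraction of small random
systems. The tiny-system oracle comparison runs it with 8 random starts.

**Quadrature baseline.** Unit magnitudes, phases −k·(360/C)° — the
circularly-polarized mode, which is also how the simulated fields are
normalized (below).

**Coherent reference stacks.** The MLS argmin is basin-degenerate: many
weight vectors reach near-equal cost, and independently optimized slices
pick among them arbitrarily — rotated copies of one slice, whose
landscapes are identical up to voxel re-indexing, can receive weight
vectors differing by ~0.4 in phase-aligned relative norm. When the
solutions serve as regression targets this matters: the field-to-weights
mapping must exist as a continuous function. `shim_volume(...,
coherent=True)` therefore warm-starts each slice from the previous
slice's solution and keeps that basin whenever it is within 2 % relative
objective of the best random restart — a continuation rule selecting one
continuous branch of the multi-valued argmin, at negligible cost in RMSE.
The default remains fully independent per-slice optimization.

**Exhaustive reference (`exhaustive_shim`).** For 2-channel systems only:
a full scan over per-channel magnitude ∈ [0,2] step 0.01 and relative
phase ∈ [0,360)° step 1°, with channel 0's phase fixed at 0 to remove the
global-phase invariance. It is exponential in C and exists purely as an
independent check on the iterative optimizers.

**λ default.** The objective as usually written leaves λ free; the package
defaults to `1e-3 · V / C`, which puts the power term and the error term on
comparable footing for unit-magnitude weights regardless of mask size.
λ = 0 is used wherever a test compares against the exhaustive reference.

## Synthetic transmit fields

No electromagnetic solver is used (and none is emulated numerically): each
channel is a quasi-static circular current loop whose exact Biot–Savart
field is evaluated with complete elliptic integrals, softened only on the
wire ring itself. On the loop axis this reduces to the textbook
`a²/(2(a²+z²)^{3/2})` expression, which the tests verify to 1e-6 relative.
Wave behaviour at 298 MHz is emulated by a phase ramp
`−2π·dist/λ_eff` from each coil center, with `λ_eff` = 0.55·grid-extent
(≈13 cm at a 2.4 mm voxel pitch — an in-tissue wavelength at 7 T), plus the
geometric phase e^{iθ} of a loop rotated to azimuth θ. The geometric phase
is what makes the −45°-step quadrature drive the constructive (CP) mode;
the drive phases themselves are *not* baked into the stored fields.

Default geometry (8 coils at 45° spacing on a ring of radius 0.58·grid,
loop radius 0.16·grid) scales proportionally with the grid so the 101×101
reference layout and the cheaper 64×64 option produce comparable
interference structure. The phantom is a jittered tilted ellipse
(semi-axes ≈ 0.40/0.32·grid ±15 %, center offset ±5 % of the grid, tilt
±30°) whose cross-section shrinks ellipsoidally with the axial slice
offset; the mass-density surrogate is 1 inside with 5 % smooth
multiplicative texture, 0 outside, and the region-of-interest mask is
`density > 0.5`. Fields are normalized per slice so the quadrature-mode
in-mask mean magnitude is exactly 1.0, making the percent-of-target metric
comparable across slices. Rotation augmentation rotates fields, density
and mask jointly (bilinear on real/imaginary parts, nearest-neighbor plus
re-binarization for the mask).

A consequence worth stating: joint rotation only re-indexes the rows of A,
and the objective is invariant under voxel permutation, so rotated copies
of a slice share the same optimal weights (up to interpolation error).
Rotation augmentation therefore diversifies the *inputs* the regressor
sees while keeping targets fixed — it teaches rotation invariance, not new
shim solutions.

What the generator does **not** model: tissue dielectric structure and
eddy currents (true EM wave propagation), coil coupling, SAR, measurement
noise in B1+ mapping, and 3-D (through-slice) field curvature. Passing
tests on these synthetic fields therefore demonstrates the correctness and
the relative behaviour of the algorithms — not absolute performance on
human-model EM simulations, whose error levels differ.

## The shim-weight regressor

A residual CNN maps an encoded field slice directly to shim weights.
Encodings: `realimag16` (default; the 2C real/imaginary planes, lossless)
and `rimp32` (real, imaginary, magnitude, phase per channel — 32 planes
for 8 channels, redundant but giving the first convolution direct access to magnitude and phase). The
encoder zeroes the fields outside the region of interest when given the
mask — the network then sees exactly the masked slices the objective is
defined on. This matters enormously in practice: with unmasked inputs the
network must learn to infer the ROI and ignore the strong irrelevant
field structure near the coils, and at desk scale it fails to fit even
its training set; with masked inputs the same network reaches
reference-level error. The head emits 16 reals by default, paired as
(Re, Im) per channel; a 32-wide head is allowed, surplus entries ignored.

Architecture: initial 3×3 stride-2 convolution, four stages of two
residual basic blocks (two 3×3 convolutions + batch norm + ReLU each),
stride-2 entries with 1×1 projections from stage 2 on, global average
pooling, fully connected head. Reference widths are 64/128/256/512;
desk-scale runs use 16/32/64/128. The head bias is initialized to the
quadrature weights (and the head weights shrunk ×0.1) so the untrained
network starts at the physical baseline rather than at noise.

Training minimizes the physics-informed loss: the predicted weights are
pushed through the actual field combination of each slice, and the
resulting RMSE is compared with the RMSE of a strong multi-restart Adam
reference. Two forms are selectable — the plain mean of
`RMSE_pred − RMSE_ref` (default) and the mean squared difference — with
identical gradient direction per example; both are exercised by tests.
Gradients flow analytically through |Ab| (same Wirtinger expression as the
optimizer).

Two additions make the physics loss trainable at desk scale, both
diagnosed on the synthetic task and on by default:

* **Global amplitude calibration** (`calibrate_scale`): the closed-form
  optimal drive amplitude `α* = Σ m|Ab| / Σ|Ab|²` is applied to the
  predicted pattern before the RMSE (envelope-theorem gradient). On real
  systems the transmit voltage is calibrated separately from the shim
  pattern anyway; learning it burns network capacity for nothing.
* **Weight supervision** (`weight_supervision`, default 10): a
  global-phase-aligned squared distance to the (coherent) reference
  weights is added to the loss. The per-slice physics term inherits the
  non-convexity of the magnitude objective, and a network descending it
  from a shared initialization parks every slice in the local basin
  reachable from that start — empirically the same plateau as a
  single-start local optimizer. Anchoring on the reference weights — the
  mapping the regressor is meant to learn in the first place — is convex
  in the outputs and pulls predictions into the reference basin, where
  the physics term takes over.

Optimization uses the Adam rule with the reference protocol's schedule
(initial 1e-3, halved every 50 epochs, 200 epochs, batch 16) as defaults;
desk-scale runs shorten this to 60 epochs.
Splits are 8:1:1 by *source slice*, so all rotated copies of a slice land
on one side of the train/test boundary — otherwise rotation augmentation
would leak test anatomy into training. The best-validation parameter state
is checkpointed and restored.

Validation, checkpoint selection and saved models use batch-norm
statistics recomputed exactly over the training population (a calibration
pass per epoch): momentum-averaged running statistics lag the feature
distribution while it drifts during training and make eval-mode inference
erratic.

Everything is plain numpy (float32, im2col convolutions with explicit
backward passes), so training is bit-reproducible given the seed; there is
no GPU path.

## Non-uniformity detector

RMSE is a slice-average and can look acceptable while a local field void
ruins the excitation. The detector is a DCGAN-discriminator-style binary
classifier: strided 4×4 convolutions doubling widths (reference 32→256,
desk scale 8→32), leaky ReLU (0.2), batch norm on interior layers, global
average pooling and a sigmoid scalar — the confidence that the map is
uniform, thresholded at 0.5. Its input is the single combined-magnitude
map (zeroed outside the mask), not the per-channel stack.

Training pairs are constructed programmatically rather than curated by
eye, so labels are objective and reproducible: well-shimmed magnitude maps
(variable-exchange output, RMSE below 35 % of target FA at desk scale) are
the uniform class; the same maps with 1–2 smooth multiplicative Gaussian
voids (`1 − depth·exp(−r²/2σ²)`, σ = radius/2, depth 0.5–0.95, radius
8–25 % of the map extent — anatomy-scaled so artifact visibility does not
depend on grid resolution — centers uniform over the mask) are the
non-uniform class, exactly balanced. Binary cross-entropy, Adam at 5e-3,
20 epochs at desk scale, with the checkpoint chosen by validation
cross-entropy (the confidence margin keeps widening after the accuracy
saturates).

## Problem sizes used by the tests and the acceptance script

Chosen once as the package's desk-scale study conditions: oracle
comparisons on 20 random 2-channel/6-voxel systems; the method-ordering
population is 128 slices (4 volumes × 8 slices × 4 rotations, 64×64 grid,
12 Adam restarts); regressor training uses 512 slices (16 volumes × 8
slices × 4 rotations, 64×64, coherent 8-restart references, narrow
8/16/32/64 widths, 60 epochs); the detector draws its maps from 8 volumes
× 8 slices × 7 rotations and
uses 400 examples per class with a 200-example held-out set; the pipeline
determinism check runs a 32×32 smoke configuration. Reference-scale
values (101×101×71×8 volumes, 300 restarts, 24,576 augmented slices =
64×32×12, 200 epochs, 384×64 detector slices per class) remain available
through configuration.

## Numerical choices and degenerate inputs

* Tie-breaking among equal-objective restarts: lowest restart index.
* |Ab| = 0 voxels: the residual phase factor is set to 0 (a valid
  subgradient) in the optimizer, and phase 1 in variable exchange.
* Empty masks are flagged at generation and rejected with a specific
  error by every consumer; batch drivers record failed slices as flagged
  rows instead of aborting.
* Non-finite objectives discard the offending restart with a warning; an
  all-restart failure raises. Non-finite training losses abort with the
  last good checkpoint.
* The elliptic-integral loop field softens `(a−ρ)²+z²` by 1e-9 only on
  the wire ring; the modulus is clipped below 1 by 1e-12.
* HDF5 containers carry `layout_version`; readers refuse unknown versions
  and name missing groups. Complex fields are stored as separate
  real/imaginary float64 arrays for lossless round trips.

## Known limitations

* Quasi-static loop fields with a heuristic phase ramp reproduce the
  interference *structure* of ultrahigh-field transmit arrays, not their
  absolute error levels; numbers here are not comparable to EM-simulated
  or measured B1+ data.
* Shimming is strictly slice-wise and unconstrained: no SAR or hardware
  power limits, no joint multi-slice design, no pulse waveform design.
* The regressor reaches reference-level held-out error on the synthetic
  family, whose anatomy varies along a handful of latent parameters
  (ellipse jitter, offset, tilt, slice position); real head-model
  populations are far more diverse, and desk-scale success here does not
  predict the data volume needed in that setting. Reference-scale data
  and training budgets are configurable but not exercised by the tests.
* The detector is trained on synthetic Gaussian voids; real artifact
  morphologies (coil failures, motion ghosts) are out of scope.
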