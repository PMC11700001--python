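# Methods

This note documents the models, algorithms and numerical choices behind the
`ctvi` toolkit: what each component computes, the assumptions it rests on,
and what the synthetic validation does and does not demonstrate.

## The problem

Functional lung avoidance radiotherapy needs a map of regional lung
ventilation so treatment plans can spare well-ventilated tissue. Dedicated
ventilation scans (Galligas PET, DTPA-SPECT) are low-resolution, motion
blurred, and rarely acquired. CT ventilation imaging (CTVI) estimates the
map from respiratory-correlated CT (4DCT) that is acquired anyway: breathing
motion encodes where the lung inflates. The toolkit implements the two
classical surrogate families, a supervoxel variant, and a dual-input
convolutional synthesis network that fuses anatomy (the time-averaged CT)
with motion (the Jacobian map of the breathing deformation), together with
the evaluation metrics and a fully synthetic test bed.

The toolkit deliberately does **not** perform deformable image registration;
a peak-exhale to peak-inhale displacement field on the image grid is an
input. Lung masks are likewise inputs (or phantom-provided).

## Ventilation surrogates

**Jacobian (motion) surrogate.** For a displacement field `u(x)` in mm with
the exhale-to-inhale convention, the local volume ratio of the deformation
`x + u(x)` is `J(x) = det(I + grad u)`, and the ventilation surrogate is
`J - 1`, the fractional volume change per voxel. Derivatives are taken with
respect to physical coordinates (central differences in the interior,
one-sided at the grid border), so the map is dimensionless and independent
of voxel size. For affine fields the finite differences are exact.

**Density (HU) surrogate.** Lung HU is an air-fraction meter: a voxel at
`HU` contains air fraction `-HU/1000`. After pulling the inhale phase back
onto exhale geometry through the field, the specific air-volume change

    SAVC = 1000 (HU_in - HU_ex) / (HU_ex (1000 + HU_in))

estimates ventilation per unit exhale air volume. Under exact tissue-mass
conservation the identity `SAVC = 1000 (J - 1) / |HU_ex|` holds, which makes
explicit that the density surrogate is *not* rank-identical to the Jacobian
surrogate wherever the air fraction `|HU_ex|/1000` varies — vessels and the
partial-volume shell at the pleura. This is the structural reason its
recovery correlation on the phantom (≈0.91) sits below the Jacobian
surrogate's (≈1.0), and it mirrors the weaker clinical performance of
density-based methods. Voxels where the formula degenerates (exhale HU
above -10, i.e. no air; warped inhale HU at the air floor) are replaced by
the masked median and counted in a log message.

**Supervoxel surrogate.** Simple linear iterative clustering (SLIC) on the
exhale lung (intensity + position, compactness 0.1, 500 clusters by
default) partitions the lung into supervoxels; each receives the mean of
the density-change signal (`D_mean` aggregation), producing a
piecewise-constant, noise-robust map. A switch aggregates raw exhale
density instead, since the literature is ambiguous about which quantity is
averaged. When the requested cluster count equals the lung voxel count the
clustering degenerates to one voxel per cluster by construction and the
estimate coincides with the density surrogate exactly.

All classical estimates are min-max normalised over the lung mask and set
to zero outside, so every method shares the `[0, 1]` scale the evaluation
threshold assumes.

## Preprocessing

Inputs to the synthesis network follow a fixed chain: crop to the smallest
axis-aligned box containing the lung mask (origin updated so world
coordinates are preserved; half-open boxes, 0-based indices) → resample to
a fixed cubic grid (trilinear for scalars, nearest for masks; the physical
extent is preserved exactly, spacing rescales) → normalise. CT is clamped
to the `[-1000, 0]` HU window and mapped linearly to `[0, 1]` (clamping
keeps bone/vessel voxels rather than discarding them); Jacobian maps are
min-max normalised per volume (per-volume rather than cohort-wide so that
inference works one case at a time); reference ventilation is median
filtered (kernel 3), capped at the 90th percentile of its non-zero voxels
(hotspot suppression), and divided by the cap. The percentile is computed
over non-zero voxels because the zero background would otherwise drag the
cap toward zero; whether it should be restricted to the lung mask is not
settled, so the evaluation region is configurable.

## The dual-path fusion network

Two independent feature-extraction branches (one per input volume) each
apply three conv blocks — 3×3×3 convolution, batch normalisation, rectifier
— with two max-poolings, yielding features at full, half and quarter
resolution with 64/128/256 channels at full scale. At **each** of the three
scales the branches are fused voxel-wise: their sum, product and maximum
are concatenated along channels and projected back to the branch width by a
1×1×1 convolution. A four-block encoder (128/256/256/512) with two
poolings digests the fused pyramid to a quarter-resolution bottleneck; a
decoder with two trilinear upsamplings interleaved with conv layers
(256/128/64) merges each upsampled map with the matching-scale fused
features and a final 1-channel convolution plus sigmoid produces the
ventilation map.

Design choices made where the architecture was genuinely open:

- *Fusion mechanics*: sum/product/maximum are concatenated and projected,
  rather than picking one; this retains all three interaction types with a
  defined channel budget. (The three ops all commute, so the fusion value is
  symmetric in its two arguments; input asymmetry comes from the branches'
  separate weights.)
- *Multi-scale fusion*: fusion happens at all three branch scales, not only
  the deepest, so the decoder's skip connections carry fused rather than
  single-branch features.
- *Pooling/upsampling bookkeeping*: poolings use floor semantics and each
  upsampling targets the recorded skip shape exactly, so odd intermediate
  sizes (60 → 30 → 15) round-trip without padding.
- *Activations*: rectifiers after every conv block; sigmoid at the output
  because targets are normalised to `[0, 1]`.
- *Initialisation*: seeded He fan-in normal weights, zero biases.

The `ct_only` variant keeps a single branch and feeds its features directly
to the encoder (the ablation arm). The `unet_baseline` is a standard 3D
U-net — four resolution steps of two 3×3×3 convolutions + ReLU with 2×2×2
max pooling, mirrored decoder with skip concatenation — taking both volumes
as a 2-channel input.

The network stack is implemented on a compact numpy reverse-mode
autodifferentiation engine written for this package (3D convolution as k³
shifted GEMMs, exact adjoints verified against identities in the tests).
Everything is float32 and seeded, so training histories are bit-reproducible
on a given machine.

## Training

Adam (β = 0.9/0.999), initial learning rate 1e-4, batch size 1, mean
absolute error. The loss is computed over lung voxels by default
(prediction and target zeroed outside the mask) because background voxels
are uninformative; a switch restores unmasked MAE. The learning rate is
flat until a decay-start epoch (default: half the total) and then decays
linearly to zero at the final epoch. Augmentation draws one joint geometric
transform per sample: per-axis flips (p = 0.5), in-plane rotation about the
superior-inferior axis within ±15°, border cropping within 10% of the
volume size followed by trilinear resize back (so the batch shape is
constant), and a smooth random elastic deformation bounded by 25% of the
grid in amplitude scale. The same transform is applied to both inputs, the
target and the mask (nearest-neighbour, so masks stay binary). Applying the
elastic warp identically to the Jacobian channel breaks strict physical
consistency between the two inputs; this mirrors joint input augmentation
as practised and is accepted.

Cross-validation splitting assigns shuffled cases round-robin to k folds
(sizes differ by at most one) and keeps an external test list that never
enters any fold.

## The synthetic phantom

The phantom exists so that every component is testable against known ground
truth without patient data. One case comprises K = 10 breathing phases of a
digital thorax, the true displacement field, the true ventilation map, a
lung mask, and an emulated reference ventilation scan.

**Anatomy.** An analytic template: soft-tissue body ellipsoid (0 HU), two
ellipsoidal lungs of aerated parenchyma (-850 HU), air background
(-1000 HU), and a handful of Gaussian vessel-like cords per lung peaking at
-450 HU. Tissue interfaces ramp over ~1 voxel, emulating scanner
partial-volume softening; visible-vessel volume fraction is kept near the
2–3% a 3 mm-voxel clinical CT resolves. The template is a continuous
function of position, which is what allows warped phases to be *evaluated*
rather than interpolated (interpolating a discrete sharp-edged image across
the 850 HU lung boundary would inject spurious mass).

**Motion.** Each lung expands radially about its centre,
`u(x) = A · m(x) · env(x) · (x - c)`, with peak fractional expansion
A = 0.15 (peak volume changes ≈ 0.5, deep free breathing), a ventilation
pattern `m` (uniform; a gravity gradient spanning 0.4→1.0 across the lung's
anteroposterior extent, giving the physiological ~2.5× ventral–dorsal
ventilation ratio; or a bilobed pattern), and a smooth cosine envelope that
is 1 inside the lung and decays to zero over a margin outside (so the field
has compact support and the deformation stays invertible). Phase k scales
the field by the raised-cosine respiratory trace
`a_k = (1 - cos(2πk/K))/2`; phase 0 is peak exhale, phase K/2 peak inhale.

**Ground truth.** True ventilation is *defined* as `det(I + grad u) - 1` of
the peak field inside the lung — the local volume change — so the Jacobian
surrogate is an unbiased estimator in the noiseless limit and
parameter-recovery tests are meaningful.

**Phases and mass conservation.** Phase-k HU obeys
`1000 + HU_k = (1000 + HU_ex) / J_k` at the material point: tissue mass is
conserved while density dilutes with inflation, which makes the density
surrogate recoverable too. Each phase is generated by inverting
`phi_k(x) = x + a_k u(x)` with a fixed-point iteration (8 iterations,
residual ~1e-4 voxels) and evaluating the analytic template at the material
point. Per-phase lung masses are computed with fractional (partial-volume)
lung weights; crisp thresholded masks alias the moving boundary coherently
and would overstate the discretisation error roughly threefold. The
residual mass wobble at the default 64³ grid is ≈0.6% across phases.

**Blocked lobe.** A tumor-obstructed airway is emulated by tapering the
displacement smoothly to zero inside a sphere while leaving density
untouched: anatomy looks normal, motion and true ventilation vanish. This
is the scenario in which anatomy-only models fail and the motion input
earns its keep. The taper shell is a fixed fraction of the sphere radius,
so the residual-ventilation invariants are stated at the default grid
resolution (coarser grids leak proportionally more).

**Reference scan emulation.** The true map is blurred with a Gaussian
(default 4.5 mm, SPECT/PET-like resolution), corrupted with additive
Gaussian noise, optionally given a central-airway hotspot brighter than the
95th percentile of the clean map, and clamped non-negative. The noise model
is a stand-in — real tracer statistics are not characterised here — and its
parameters are configuration, not claims.

**What the phantom does not emulate:** airway trees, lobar fissures, CT
acquisition physics (beam hardening, 4DCT sorting artifacts), registration
error in the displacement field (the true field is supplied), or realistic
reference-scan noise statistics. Passing recovery tests therefore shows the
estimators and the training loop are implemented correctly, not that
clinical-level accuracy would be achieved on patients.

## Evaluation metrics

Spearman correlation is computed by rank-transforming both maps (average
ranks for ties) over the evaluation set — in-mask voxels with non-zero
reference — and applying the product-moment formula to the ranks; a flag
computes the raw-value Pearson form for comparison. A threshold of 0.66 on
the normalised maps separates high- from low-functional lung (ties go to
low), and Dice coefficients are reported for both regions (two empty
regions count as Dice 1, exactly one empty as 0). Cohort runs tabulate
per-case rows with a mean ± sd footer.

## Problem sizes used in the automated studies

The shipped studies are scaled-down stand-ins for the full-size protocol
(60³ inputs, 800 epochs), chosen as the package's own test scale:

- *Smoke training*: 12 training + 4 held-out phantoms at 48³, network
  inputs 32³, channel widths scaled to one-eighth (8/16/32 branch), 30
  epochs. The trained dual model reaches held-out Spearman R ≈ 0.96
  against true ventilation.
- *Ablation*: 8 training phantoms (half blocked) + 2 blocked held-out at
  40³, inputs 24³, width 6, 12 epochs, repeated over seeds. The
  anatomy-only variant overestimates blocked-lobe ventilation by roughly
  threefold relative to the dual model.

## Known limitations

- The numpy engine targets CPU determinism and small studies, not speed at
  clinical volume sizes; full-scale training (60³, 800 epochs) is possible
  but slow.
- Batch normalisation at batch size 1 is instance normalisation over
  spatial axes; running statistics accumulate across samples as usual.
- The HU surrogate formula is one of several published variants; the
  specific air-volume change form implemented here is documented as an
  assumption.
- Orientation matrices beyond identity are not handled; inputs are assumed
  axis-aligned and pre-registered rigidly.
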