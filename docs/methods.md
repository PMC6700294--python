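# Methods

This note documents the models and procedures `tumorcascade` implements,
the choices made where the design was genuinely open, and what the
synthetic phantoms do and do not demonstrate.

## The segmentation problem and the cascade

The input is one BraTS-style case: four co-registered, skull-stripped,
1 mm isotropic MR volumes (FLAIR, T1, T1ce, T2) and, for training, a label
volume over the codes {0 background, 1 non-enhancing/necrotic core,
2 edema, 4 enhancing core}. The three clinically reported structures are
nested: whole tumor (codes {1,2,4}) ⊇ tumor core ({1,4}) ⊇ enhancing core
({4}).

Rather than predicting four classes at once, the pipeline decomposes the
task into three binary problems solved coarse-to-fine. WNet segments the
whole tumor on the full volume; the volume is cropped to that mask's
bounding box plus a context margin (default 5 voxels in-plane, 3
through-plane — the margin is not forced by the model, only by the wish to
give downstream networks context beyond the tight box); TNet segments the
tumor core inside the crop; a second crop and ENet yield the enhancing
core. Each downstream mask is intersected with its predecessor ("crisp
masking"), so the anatomical nesting holds *by construction*, and an empty
upstream mask short-circuits the remaining stages. `masks_to_labels`
applies the same intersection when recombining arbitrary binary masks, so
the 4-code ↔ 3-mask conversion is lossless in both directions.

Empty-vs-empty structures score Dice 1.0 and empty-vs-nonempty 0.0 (the
standard convention for absent structures); Hausdorff distances are
undefined for empty masks and raised as a distinct error.

## Anisotropic 2.5D networks

Each stage network replaces 3×3×3 convolutions by twenty in-plane 3×3×1
convolutions (ten residual blocks of two, each block with an in-plane
dilation factor) plus four 1×1×3 inter-slice convolutions, giving a large
in-plane and a small through-plane receptive field — a deliberate
trade-off between 3D context and memory. WNet/TNet downsample in-plane
twice, ENet once. Three intermediate 3×3×1 prediction heads at different
depths are upsampled in-plane to input resolution, concatenated, and fused
by a final 3×3×1 prediction layer. Deep supervision enters through the
concatenation only — the intermediate heads receive no auxiliary loss
terms, so the multi-scale predictions are trained implicitly through the
fusion layer. Every backbone convolution is followed by batch
normalization and PReLU; prediction layers are plain convolutions, since
activating a score map before softmax would be nonstandard. The first
residual block changes the channel count (4 → C0) and therefore has no
identity skip; adding a projection would change the fixed layer counts.
Defaults: C0 = 32 backbone channels, Cl = 2 output classes.

**Receptive-field arithmetic.** The target extents are 217×217×9 for
WNet/TNet and 113×113×9 for ENet. Two calculators are provided and must
agree exactly:

* an **analytic** calculator that propagates the demanded input interval
  of one central output voxel backward through the graph (union where
  paths merge). This is deliberately *not* the textbook recurrence
  `rf += (kernel−1)·dilation·jump`: with strided and upsampling layers the
  true dependency set depends on the output voxel's alignment, and the
  naive recurrence can be off by a voxel or two. The canonical centre is an
  output coordinate divisible by the total in-plane stride;
* a **numerical probe** that linearizes a realized network (weight
  magnitudes normalized per output channel, identity batch norm, PReLU
  slope 1 — an exactly linear map with nonnegative coefficients), injects
  a unit gradient at the canonical central voxel, and measures the support
  of the input gradient. Strict positivity is the support criterion; no
  tolerance is involved. A support touching the input boundary raises a
  probe-underflow error.

Layer conventions, mirrored exactly by both calculators: zero "same"
padding; stride-2 downsampling convolutions centred on even input
coordinates (kernels 5×5×1 then 3×3×1 for the two downsamplings; ENet
keeps only the first); in-plane ×2 upsampling by symmetric linear
interpolation `out[2i]=in[i]`, `out[2i+1]=(in[i]+in[i+1])/2`.

**Dilation schedules.** The published extents fix the layer counts but
not the per-block dilations, which are not recoverable from the source
figure. `search_dilation_schedules` enumerates every schedule consistent
with a target in-plane extent (the extent is affine in the block dilations,
so the search solves an integer equation and verifies each candidate with
the exact calculator). The shipped defaults are one solution each:
(1,1,2,1,2,2,2,2,1,1) for WNet/TNet and (1,2,1,1,2,2,2,1,1,1) for ENet.
They reproduce the published receptive fields; they are not asserted to be
the original authors' values.

**Backend.** Blueprints are realized through a backend contract (stacked
4-channel patch in, Cl-channel score map of the same spatial extent out).
The package ships a NumPy reverse-mode engine with exactly the required
layer inventory (dilated/strided convolutions, the upsampler, batch norm,
PReLU, concat, residual add); gradients were verified against central
finite differences at float64 (relative error ~1e-9). Inputs are padded on
the high side to a multiple of the total in-plane stride and cropped back,
so any input size is accepted. A "tiny" variant (C0 = 4, four blocks, one
downsampling) exists for desk-scale training and testing; it follows the
same construction but is exempt from the receptive-field requirement.

## Training

Each stage × view pair is trained separately with Adam on a soft Dice
loss, `1 − (2Σpg+ε)/(Σp²+Σg²+ε)` with ε = 1e-5 (a switch selects the
linear-denominator variant). Published-scale defaults: batch 5, weight
decay 1e-7, learning rate 1e-3, 30 000 iterations, patches 144×144×19 /
96×96×19 / 64×64×19 for the three stages. That scale is GPU-tier; the
desk-scale configuration (`TrainConfig.tiny_config`) trains the tiny
variant with patches 32×32×8 / 24×24×8 / 16×16×8, batch 4 and a few
hundred iterations, which converges in minutes on one CPU core on the
phantoms. Patches are foreground-centred with probability 0.5 (else
uniform); core/enhancing stages sample inside the ground-truth upstream
bounding box plus margin, matching inference-time cropping.
Training-time augmentation calls the identical transform/noise functions
used at test time — one implementation, asserted by a test.

Anisotropic networks are trained per view (axial/sagittal/coronal, i.e.
the through-plane axis aligned with each anatomical axis by cyclic axis
permutation); at inference the per-view softmax outputs are averaged with
equal weights. Test-time tiling uses overlapping sliding windows at the
training patch size with per-voxel averaging of covering patches; the
tiling scheme and stride are implementation choices, not part of the
model.

## Augmentation and test-time uncertainty

A spatial transform β is composed of per-axis flips, per-axis rotations
(Euler order x→y→z) and an isotropic scale, all about the volume centre,
realized as a single affine resampling; the inverse is the exact inverse
affine. Priors: rotation angles U(0, 2π) per axis, flips Bernoulli(0.5),
scale U(0.8, 1.2), additive Gaussian intensity noise with standard
deviation 0.05 on mean/std-normalized intensities ("N(0, 0.05)" is read as
a standard deviation; both the value and the reading are configurable).
Rotations are applied as written — fully 3D — with an in-plane-only
switch for strongly anisotropic data. Noise is drawn independently per
modality and needs no inversion (it perturbs the input only).

Test-time augmentation draws N = 20 transforms (desk-scale runs use
N = 5), segments each transformed copy, inverse-transforms the labelings
(nearest neighbour) back onto the original grid, and combines them by
per-voxel majority vote. Binary ties go to foreground (the rule
"vote ≥ N/2", favouring sensitivity); among tumor codes, ties go to the
deeper structure — the natural generalization of the same rule.

From the aligned prediction set:

* **voxel-wise entropy** H = −Σ p̂ ln p̂ over the empirical label
  frequencies at each voxel (natural log; 0·ln 0 := 0). Entropy is
  computed per hierarchical binary structure, matching the cascade's
  binary outputs; a combined-alphabet mode exists for multi-class use.
* **volume variation coefficient** VVC = σ_V/μ_V over the N member
  volumes of a structure, with the population (divide-by-N) standard
  deviation, matching the variation-coefficient convention (sample-std
  switch available). VVC is scale-invariant, so voxel counts and mm³ give
  identical values; a structure absent from every member raises a distinct
  "undefined structure" error rather than returning a number.

Intensity normalization computes mean/std over the nonzero (brain) region
only — background zeros would otherwise dominate the statistics of a
skull-stripped volume — and uses the population std; a switch selects
whole-volume statistics.

## Uncertainty-aware CRF

Post-processing operates per binary structure on the cascade's
probability output. The *gate* resets both class probabilities to 0.5
wherever the TTA entropy strictly exceeds θ = 0.2 nats (a voxel exactly at
the threshold is kept; the boundary convention is explicit and tested),
and is idempotent. The *CRF* is a pairwise Potts model over the truncated
Chebyshev window (radius 2 by default):

    E(y) = Σ_i −ln p_i(y_i) + Σ_{i<j} [y_i≠y_j] (w_s k_s(i,j) + w_a k_a(i,j))

with Gaussian spatial kernel k_s (bandwidth σ_γ, voxels) and appearance
kernel k_a (spatial bandwidth σ_α and intensity bandwidth σ_β on the
structure's most contrastive modality — FLAIR for whole tumor, T1ce for
core/enhancing, configurable). Probabilities are floored at 1e-6 before
the logarithm. Each Gaussian kernel is normalized over the window, so w_s
and w_a are the *total* coupling a voxel feels from all neighbours —
directly comparable to the unary scale regardless of bandwidth or window
radius (unnormalized kernels at radius 2 would multiply the nominal weight
by the ~124 window offsets and make even confident unaries irrelevant).

Inference is parallel mean field run from three initializations (unary
beliefs, foreground-biased, background-biased), each followed by a
monotone local-descent polish (iterated conditional modes over
congruence-class partitions, which vectorizes and can only lower the
energy); the lowest-energy labeling wins. Plain single-start mean field
occasionally sticks in poor fixed points on strongly coupled instances;
the restarts and polish cost little and, on exhaustively enumerable
instances (≤ 12 voxels), land within a few percent of the global minimum.
With both pairwise weights zero the refinement reduces exactly to the
unary argmax. The uncertainty-aware variant is gate-then-CRF; the naive
baseline is the CRF alone; θ = ∞ or an all-zero entropy map makes the two
coincide. After per-structure refinement the hierarchy is restored by
crisp re-nesting.

## Synthetic phantoms

Each phantom is a "brain" ellipsoid of roughly constant per-modality
intensity on a zero background containing three nested tumor ellipsoids
mapped to codes 2/1/4. Contrast follows the radiological pattern the
networks exploit: FLAIR/T2 elevated over the whole tumor, T1ce elevated
over the enhancing core, mild T1 hypointensity. Gaussian noise (default
std 5 on a tissue intensity of ~100, i.e. ~5% — a typical post-acquisition
noise level) is added inside the brain only, preserving exact background
zeros. Cohorts randomize centre, radii and contrast within stated ranges
and make a configurable minority of cases LGG-like (empty enhancing
region) to exercise the empty-target path. Ellipsoids were chosen because
their analytic volumes give oracle checks; an optional smoothed random
displacement field roughens boundaries for harder tests (off by default).

What passing on phantoms shows: the plumbing, geometry, optimization,
uncertainty estimation and post-processing behave as specified end to end.
What it does not show: performance on real tumors — phantoms have no
texture, no bias fields, no partial-volume effects, convex shapes and far
higher contrast-to-noise than clinical MRI, so Dice values here say
nothing about challenge-scale accuracy.

## Problem sizes used by the test suite

The suite and the reproduction script run entirely on generated data:
receptive-field probes on 224×224×13 (WNet/TNet) and 128×128×13 (ENet)
grids with 2-channel-wide networks (channel width does not enter the
receptive field); end-to-end training of the tiny cascade on twenty
64×64×32 phantoms for 150 iterations with five held-out cases and
N = 5 TTA; CRF optimality on 3×2×2 instances against exhaustive
enumeration of all 2¹² labelings. These sizes are the package's desk-scale
study conditions, chosen so a laptop CPU reproduces everything in a few
minutes.

## Known limitations

* The NumPy backend is single-threaded linear algebra; published-scale
  training (C0 = 32, 30k iterations) is provided for completeness but is
  not practical without a GPU-backed backend implementing the same
  contract.
* The dilation schedules are constraint-derived, not recovered from the
  original figure; any schedule found by the search is equally consistent
  with the published receptive fields.
* Mean-field + ICM is approximate MAP inference; optimality within a few
  percent is only verified on enumerable instances.
* The TTA rotation prior U(0, 2π) per axis is implemented as written;
  for strongly anisotropic acquisitions the in-plane-only switch may be
  more appropriate.
* Epistemic uncertainty (dropout/ensembles) is out of scope; the entropy
  and VVC quantify input-induced (aleatoric) variability only.
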