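# Methods

This document describes the model behind each pipeline stage, the default
parameters (all of which live in `ecleanse.config.CleanseConfig` and
`ecleanse.preprocess.ThresholdTable`), and the package's known limitations.

## Attenuation model

All reasoning is in Hounsfield units on these observed per-material ranges:

| material                      | range (HU)      | default pure mean used by the phantom |
|-------------------------------|-----------------|----------------------------------------|
| lumen air                     | −1000 … −800    | −980 |
| soft tissue (ST)              | −100 … 100      | 20 |
| fecal-tagged material (FTM)   | 200 … 1400      | 700 |
| air–tagging artifact layer    | −800 … 600      | — |

Working cut-offs: air mask `I < −600`, tagging mask `I > 200`. The display
window used for normalisation is `(−1000, 1400)`.

The phantom's air mean of −980 HU is a deliberate a-priori choice, not a
tuned value: the removal rule (below) can only push tagged voxels down to
about −645 HU at best, so the margin between native lumen air and cleansed
air is part of the modeled physics, and −980 sits where well-distended
colonic air actually reads.

## Stage 1 — torso preprocessing

Region growing is 6-connected throughout (diagonal adjacency would leak
through one-voxel walls). Removed voxels are flattened to the soft-tissue
floor (−100 HU).

* **Outside air**: seeds are boundary voxels below −100 HU; growth covers
  all connected sub-floor voxels. If the boundary holds no seed the volume
  is a cropped abdominal block — a warning is recorded and the stage is a
  no-op.
* **Lungs**: inside air is counted in the first and last 10 slices; the
  airier end segment hosts the lungs, and every inside-air region touching
  it is removed. Skipped (with a recorded warning) when no outside air was
  found, because in a cropped block the only end-segment air is colonic.
* **Bones**: seeds are > 200 HU voxels in the lung slices (ribs/spine reach
  the thoracic slices; colonic tagging does not). Skipped when no lungs were
  found, for the same reason.

These stages run on an internal working copy; the returned volume is
modified only inside the colonic lumen and its wall band.

## Stage 2 — colonic lumen

`lumen = dilate(air ∪ tagging, ball(r=3))`. The 3-voxel ball covers the
partial-volume shell around both the air and the tagging compartments and
bridges the intermediate-attenuation interface layer between them.

## Stage 3 — ambiguous-layer classification (AT vs. ATT)

Ambiguous layers are lumen voxels in −800…600 HU adjacent (26-connectivity)
to both air and tagging, excluding the air mask itself. Because CT scans are
acquired supine or prone, gravity makes artifact layers horizontal: on each
axial slice, each 8-connected layer component sends *leaping probes*
(distance 5 voxels) left/right (horizontal) and straight down (vertical,
only — an artifact layer floats *on top of* a pool) and counts hits per
adjacent tagged pool. A component is a **thin membrane (ATT)** iff some pool
is hit strictly more often horizontally than vertically — the layer stands
edge-on against the pool. Ties and vertical majorities mean **artifact
(AT)**: the conservative default is removal of flat layers, and a genuine
membrane seen edge-on produces a clear horizontal majority. ATT voxels are
excluded from every replacement rule.

Soft-tissue/tagging transition (STT) voxels are the tagging vicinity band
(`dilate(ftm, ball(2)) \ erode(ftm, ball(1))`) minus AT layers.

## Stage 4 — transition curve and material fractions

A two-material edge blurred by the scanner point-spread function follows an
erf intensity profile, so in the (intensity, gradient-magnitude) plane edge
voxels lie on the arch

```
arch(x) = (1/√(2π)) · exp(−erfinv(2x−1)²),  x ∈ [0,1]
```

scaled to the pair's intensity span: the curve is
`{(L + x(H−L), (H−L)·arch(x))}`. A measured sample
`(clip(I, L, H), θ·σ_ω·|∇I|)` is projected orthogonally onto this curve
(dense sampling at 4096 points plus vectorised golden-section refinement);
the curve parameter `x` at the nearest point is the fraction of the brighter
material.

* Gradients are plain central differences (`np.gradient`): the scanner PSF
  already provides the smoothing scale, and additional blurring would bias
  the gradient magnitudes the projection depends on.
* `θ` rescales the gradient axis so real samples sit on the model curve. It
  is estimated per pair by **apex matching**: `θ = (H−L)·arch(½) / q95`,
  where `q95` is the 95th percentile of `σ_ω·|∇I|` over that pair's
  transition voxels (at least 50 samples required; result clamped to
  [0.1, 10]). `theta_mode: fixed` in the config bypasses estimation.
* Bases `L`, `H` are interior means (1-voxel-eroded masks) of the pure
  material regions. Pairs: TA = air→tagging, TT = soft tissue→tagging, and
  SA = air→soft tissue, which **reuses** the air base as its low and the ST
  base as its high base.

Three-material fractions combine the pairwise fractions by averaging:

```
t_air = (t_L_SA + t_L_TA) / 3
t_ST  = (t_H_SA + t_L_TT) / 3
t_TR  = 1 − t_air − t_ST
```

The tagging fraction is defined as the complement, so the three fractions
sum to one identically (to machine precision), and each pairwise fraction
lies in [0,1] by construction of the projection.

## Stage 5 — gradient-directional second derivative (GDSD)

On the window-normalised volume (`(−1000,1400) → (0,1)`), with Gaussian
derivatives at σ = 1 voxel (mirror boundaries):

```
f_ww = (f_x² f_xx + f_y² f_yy + f_z² f_zz
        + 2 f_x f_y f_xy + 2 f_y f_z f_yz + 2 f_x f_z f_xz) / |∇f|²
```

defined as 0 where `|∇f| ≤ 10⁻⁴`, clipped to [−1, 1]. Across an edge the
GDSD is positive on the dark side and negative on the bright side with a
zero crossing at the edge: positive GDSD at elevated attenuation near
tagging is the signature of pseudo-enhanced soft tissue.

**Edge-response gain.** The raw GDSD of a tissue–tagging step edge peaks at
`amplitude / (σ²√(2πe))` with `amplitude = (H_TT − L_TT)/window` ≈ 0.28, so
its useful range is a small fraction of [−1, 1]. The blend weight used by
the replacement rule is therefore `f_eff = clip(f_ww · g, −1, 1)` with

```
g = σ²√(2πe) · window / (H_TT − L_TT)   (≈ 14.6 at the defaults)
```

which maps the canonical tissue–tagging edge response onto the full (−1, 1)
range. The sign and the gating set are unchanged by this normalisation.

## Stage 6 — replacement rules

Within the lumen, with ATT voxels always excluded:

* **Pseudo-enhancement correction** on STT voxels with `f_eff > 0` and
  `I > 100` HU (the gate keeps genuinely soft-tissue-valued voxels intact):

  ```
  I ← t_L_TT·L_TT + t_H_TT·( f_eff·L_TA + (1−f_eff)·H_TA )
  ```

  At `f_eff → 1` (pure pseudo-enhancement) the tagged fraction is sent to
  air; at small `f_eff` it stays near the tagging base.

* **Removal** on `(tagging ∪ AT ∪ T-junction) \ pseudo-enhancement set`:

  ```
  I ← (t_air + t_TR)·L_TA + t_ST·L_TT
  ```

  T-junction voxels are lumen voxels in −800…600 HU simultaneously adjacent
  (26-connectivity) to air, tagging and the soft-tissue range — the ring
  where a pool surface meets the wall.

* **Wall smoothing**: the freshly exposed wall band — `dilate(ftm, ball(1))
  \ ftm`, minus ATT — is replaced by the σ = 0.5 Gaussian-filtered volume.
  The band contains only voxels on the *tissue side* of the former tagging
  boundary: the pool side was just synthesised and must keep its exact
  cleansed values, and membranes are never touched.

Both replacement rules read fractions and bases computed on the *original*
volume and write into a copy, so the result is order-independent and
deterministic; everything outside `lumen ∪ wall band` is returned
bit-identical.

## Parameters (defaults)

| name | default | meaning |
|------|---------|---------|
| `dilation_radius` | 3 voxels | lumen dilation ball |
| `connectivity` | 6 | region-growing connectivity |
| `leap_distance` | 5 voxels | layer-classification probe length |
| `sigma_gdsd` | 1.0 voxel | Gaussian scale of the GDSD |
| `gdsd_eps` | 1e−4 | gradient floor below which the GDSD is 0 |
| `hu_window` | (−1000, 1400) | normalisation window |
| `sigma_wall` | 0.5 voxel | wall-smoothing Gaussian |
| `peh_hu_gate` | 100 HU | minimum attenuation for the pseudo-enhancement rule |
| `sigma_omega` | 1.0 | gradient-axis scale of the transition model |
| `theta_mode` / `theta_fixed` | apex_match / 1.0 | gradient rescaling estimation |
| `projection_samples` | 4096 | dense-sampling resolution of the projection |

## Problem sizes and runtime

On one CPU: the 128³ composite phantom generates in ≈ 20 s and cleanses in
≈ 13 s; the 40×64×64 unit scenes generate in under a second each. Memory
stays well under 2 GiB for 128³ volumes.

## Limitations

Two acceptance checks are red by design; both are properties of the method,
not implementation bugs.

* **Submerged fold surfaces (≈ 90% preserved vs. a 95% target).** The
  removal rule's output lies in roughly [−645, −312] HU given the default
  bases, i.e. always below the −300 HU "tissue survived" line. A fold-crest
  voxel is protected only if the pseudo-enhancement rule claims it
  (`f_eff > 0`), but pseudo-enhancement shifts the apparent soft-tissue/
  tagging edge outward, so the outermost crest voxels sit on the *bright*
  side of the blurred edge, get `f_eff < 0`, and fall through to removal.
  Relaxing the `f_eff > 0` gate would fix the number at the cost of
  corrupting the rule's meaning, so the gate stays.

* **Idempotence (≈ 1.3% of lumen voxels change on a second pass vs. a 0.1%
  target).** The pseudo-enhancement rule tends to the identity as
  `f_eff → 0⁺`, so a thin shell of corrected voxels keeps attenuations above
  200 HU. A second pass classifies that shell as tagging and rewrites it
  (plus its 1-voxel wall band). Forcing those voxels below 200 HU on the
  first pass would require either dropping the gate or clamping outputs,
  both of which change the rule itself.

Other limitations: the layer classifier assumes axial acquisition with
gravity along the in-slice vertical axis (`down_axis`); bases are estimated
globally per volume, so strongly inhomogeneous tagging will bias the
fractions; and the torso stages assume the standard supine/prone CTC
coverage (lungs at one end of the stack).
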