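# Methods

This note documents the models, conventions and numerical choices behind
`softceph`, and what the synthetic-data tests do and do not demonstrate.

## Landmark schema and coordinate conventions

The 34-point schema lists landmarks in clinical order (tragus → gonion →
chin → nose → eyes → mouth → pupils → incisors → profile points → scale
bar). Indices are 0-based in code; file headers and documentation use
the 1-based clinical numbering. Image coordinates are pixels with origin
at the top-left corner, x rightward and y downward; on a frontal
photograph the patient faces the camera, so the patient's right side is
on the image's left. Ten index pairs swap under a horizontal flip; the
mirror permutation is an involution, and midline points are fixed.

Pose availability encodes the acquisition protocol: the incisor edges
(UI/LI) require an open or smiling mouth, the lower incisor is hidden by
a postural smile, and the cheilions are not visible on a pure lateral
view. Lateral photographs keep bilateral labels by duplicating them onto
the visible side; a consequence is that the outer-canthal distance is
zero on lateral views, so interocular-normalized error metrics are
defined only for frontal poses (the metrics raise on a zero
denominator).

## Preprocessing

A face box — tight bounds of the annotated landmarks, or any external
detector's output — is expanded by 0.3·h above (forehead) and 0.1·h
below (chin), then padded symmetrically along the short axis to a 1:1
square; when the expanded height does not exceed the width the padding
is vertical, keeping the face centered. The square is cropped with zero
fill where it leaves the source image and resized bilinearly to the
network input (256 px by default). The crop transform is a pure affine
map kept in float, so original ↔ network coordinate round trips are
exact to ~1e-6 px regardless of the integer pixel grid used for
sampling.

## Heatmap codec

Landmarks are encoded as unit-peak Gaussians,
`f(x,y) = exp(−((x−x₀)²+(y−y₀)²)/2σ²)`, one channel per landmark, with
distances measured in heatmap cells. The single coordinate convention
is: cell (u,v) corresponds to input pixel (u·stride, v·stride);
encoding quantizes by rounding, decoding returns argmax × stride with
ties broken to the smallest row-major index. The round-trip error is
therefore at most stride/2 per axis for positions up to
`input_size − stride/2`; the final half-stride sliver at the far image
border clamps to the last cell. σ defaults to 2 heatmap pixels, the
customary width for 64–128 px maps; it is configurable. Unit-peak
(rather than unit-mass) normalization is used so confidences are
directly comparable across σ. Decoding is pure argmax by default for
determinism; an optional quarter-pixel shift toward the larger neighbor
exists but is off.

## Network

The model is a four-stage encoder–decoder heatmap regressor. A stride-4
stem (two stride-2 convolution blocks) brings the input to the
full-resolution stream at input/4 — 64 px heatmaps for a 256 px input.
Stage 1 is a U-Net-style encoder: three further stride-2 convolutions
(no max pooling) produce branches at 1/4 … 1/32 resolution, each
retained as a skip connection into the decoder. Stages 2–4 are
multi-scale exchange modules in the reversed high-resolution pattern:
every output branch sums resampled versions of every input branch
(chained stride-2 convolutions downward, 1×1 projection + nearest
upsampling upward) followed by a convolution block — but instead of
adding low-resolution branches, each stage *drops* its
lowest-resolution branch after fusing it, so Stage 2 runs on all four
scales (twice), Stage 3 on three (four times), Stage 4 on two. The head
projects the lowest-resolution output of each of Stages 2, 3 and 4 to
the base width, upsamples them to the full-resolution stream, sums them
with the Stage-4 output, and projects to one channel per landmark; this
is what routes the semantically richest low-resolution features into
the final map. When the heatmap is configured at input/2 (the
high-resolution option used with the 34-point schema) the head inserts
one 2× upsampling block.

Channel widths double at each downsample from a configurable
`base_width` (32 by default, 8 in scaled-down tests); block type is two
3×3 convolution + batch-norm + ReLU layers. These details are not fully
constrained by the architecture description and are exposed in
`ModelConfig`. Weights are He-initialized from a seeded generator, so
builds are bit-reproducible.

The network runs on `softceph.nn`, a compact NumPy reverse-mode
autodiff engine (im2col/GEMM convolutions, batch normalization with
running statistics, nearest upsampling, Adam). Gradients are verified
against central finite differences in the test suite. Everything is
float32; batched and single-image inference can differ by float32
accumulation order (~1e-4), which the tests tolerate explicitly.

## Training

The loss is the mean squared difference over all heatmap cells and
channels — the standard pixelwise L2 for heatmap regression (the
alternative reading, averaging per keypoint, differs only by a constant
factor). Defaults follow the clinical protocol: Adam, initial learning
rate 1e-3, batch 16, 300 epochs, with the rate cut tenfold whenever the
best loss has not improved for 20 consecutive epochs (training loss by
default; a validation-split option exists). Augmentation applies the
four protocol operations — rotation (±30° uniform), horizontal
mirroring (probability 0.5, with the schema's mirror permutation
applied to landmark order), graying (probability 0.25) and HSV jitter —
expanding the dataset fourfold, either materialized offline (default,
deterministic) or sampled on the fly.

## Measurements and diagnosis

The scale bar spans 10 mm, giving mm/px as `10 / ‖Scale0 − Scale1‖`.
"Horizontal" distances to the E-line (Prn→Pog) and the facial midline
are implemented as perpendicular distances — both lines are
near-vertical, making the two readings equivalent — and reported
unsigned, with a signed option. The facial midline is fit by regressing
x on y through N, Prn, Sn, Ss, Ls, Sl (well-posed for vertical
configurations; a horizontal fallback regresses y on x). The occlusal
slope k is computed in a y-up frame along the right→left cheilion line,
so k > 0 means the patient-left mouth corner sits higher. The
cheilion–chin distances D6/D7 use Gn as the chin point per the marker
numbering (a `mad_reference` switch selects Gna); D6 is the
patient-left distance. Angles are interior angles at the named vertex,
in [0°, 180°].

Each measurement is gated to the poses that define it: mouth opening D1
to the large and D2 to the slight opening, E-line distances and the
five angles to the lateral view, frontal asymmetry measures (D6–D10, k)
to frontal poses. A missing landmark voids the individual measurement
with a warning rather than the whole report.

Diagnosis thresholds: facial angle ≤ 157° → Class II, ≥ 165° → Class
III, strictly between → neither. |k| ≤ 0.01 → level (population k
values scatter around zero with SD ≈ 0.03, so exact zero is
unrealistic for measured floats); larger |k| tilts up or down with the
sign. MAD: |D6 − D7| ≤ 3 mm → none, otherwise the chin deviates toward
the side with the *shorter* distance (a longer patient-left D6 means
right skew). The left/right decision rule and both tolerances are
package choices — the clinical criterion only names the D6/D7
comparison — and are fully configurable; every Diagnosis records the
thresholds used. When a subject's supplied poses do not measure a task
at all, that task defaults to its normal label (screening semantics:
no evidence of deformity), and the `measured` flags in the thresholds
dict say which tasks had data.

## Synthetic faces

The generator emulates the acquisition protocol — uniform white or blue
background, one face, printed scale bar — with stylized geometry:
filled ellipses and polygons for the face, eyes, nose, lips and teeth,
drawn *from* the landmark template so image structure coincides with
ground truth. The template is constructed analytically: the profile
chin is placed by inverse trigonometry for an exact requested facial
angle (the chin deviates posterior of the straight N–Sn continuation,
so smaller angles give the retrusive Class II look); commissures are
sheared for an exact occlusal slope; the chin block translates
laterally by the requested offset while midline points stay on the
midline; incisor edges are separated by the requested mouth opening;
the scale bar spans exactly 10 mm at the requested scale. Lateral views
duplicate bilateral labels onto the visible side. Annotation noise is
modeled as isotropic Gaussian jitter on a copy of the landmarks
(`noisy_landmarks`); per-point normalized errors then follow a Rayleigh
distribution with mean σ√(π/2)/d_IOD, which the tests verify.

What passing tests show — and what they do not: parameter recovery
demonstrates that the measurement pipeline is exact on noise-free
geometry; the learning check demonstrates that the architecture, codec,
loss and optimizer can fit image→landmark structure from rendered
pixels. Neither says anything about photographic texture, occlusion,
illumination, pose variation beyond the template, or anatomical
diversity — claims about real photographs require real annotated data.

## Scaled-down study sizes

CPU-scale checks use reduced problem sizes, chosen once as the
package's own test conditions: the learning check trains a tiny network
(128 px input, 32 px heatmaps, 8 high-contrast landmarks, base width 8)
for 40 epochs on 300 synthetic frontal faces with 48 held-out, batch 4
and learning rate 3e-3. At 300-sample scale a batch of 16 gives only 19
optimizer steps per epoch — too few to converge in 40 epochs — so the
check uses smaller batches for more steps; the production defaults
remain the protocol values (batch 16, lr 1e-3). Measurement recovery
sweeps 200 generated faces; the ICC noise simulation uses 200 targets.

## Known limitations

- The detector requires an externally supplied face box on unannotated
  images (any callable returning a box; none is bundled).
- Argmax decoding quantizes to the stride grid; sub-pixel refinement is
  available but off by default.
- Lateral-view error metrics are undefined (zero interocular distance
  by the duplication rule).
- The NumPy engine is single-threaded BLAS-bound; it is meant for
  desk-scale experiments, not production training throughput.
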