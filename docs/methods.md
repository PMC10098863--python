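# Methods

This note documents the models, numerical choices, and limitations of
the henspec pipeline: hyperspectral comb cubes → end-member spectra →
Morlet scalograms → a small CNN separating normal from
low-egg-production hens.

## Cube model and I/O

A cube is a `(Y, X, L)` array of reflectance (or raw counts) with a
strictly increasing wavelength axis of length `L`. Serialization
follows the de-facto ENVI convention: a text header (`samples`,
`lines`, `bands`, `interleave`, `data type`, `byte order`, optional
`wavelength` block) plus a raw binary file in one of three interleave
orders — BIL `[line][band][sample]`, BIP `[line][sample][band]`, BSQ
`[band][line][sample]`. Byte order defaults to little-endian, the
dominant instrument convention. Supported scalar encodings include
unsigned 8/16-bit, signed 16/32-bit, and 32/64-bit float. Indices are
0-based; `y` is the line, `x` the sample.

## Preprocessing

Three steps, in the order a practitioner applies them:

- **Crop** to a half-open ROI `[y0,y1) × [x0,x1)`.
- **Spectral smoothing**: Savitzky–Golay along the band axis, default
  window 7 bands and polynomial order 2 — mild enough to preserve the
  ~100-band-wide physiological features of comb reflectance while
  suppressing band-to-band sensor noise. Edge windows are fitted with
  the same-order polynomial and evaluated in place, so the filter
  reproduces constants and straight lines everywhere including the
  edges (this identity is what the tests pin down; reflecting the
  signal at the edges instead would bend a linear spectrum there).
- **Reflectance correction** `R = (raw − dark)/(white − dark)`
  with full-cube or single-spectrum references, clipped to
  `[0, 1.5]`. The ceiling tolerates specular pixels without hiding a
  broken reference (a band where white = dark raises an error naming
  the band). The output is invariant under a common affine rescaling
  of raw/white/dark, which is the point of the correction: it removes
  illumination and shadow structure.

## Vertex Component Analysis

Linear mixing model per pixel: `r = γ M α + n`, with `M` the `L × p`
end-member matrix, `α ≥ 0`, `Σα = 1`, illumination scale `γ`, additive
noise `n`. The sum-to-one constraint is assumed by the simplex
geometry VCA relies on, and the simulator generates data accordingly.

The SNR is estimated from the power split between the p-dimensional
principal subspace of the mean-removed data and its residual, with the
`(p/L)·P_total` correction discounting noise leakage into the signal
subspace. A residual at numerical roundoff (≤ 1e−12 of total power)
returns a +300 dB sentinel; a non-positive corrected signal power
returns −300 dB. Above the threshold `15 + 10·log₁₀(p)` dB the
high-SNR branch projects the raw data onto its p principal directions
and applies the projective projection `y = x/(xᵀu)` with `u` the mean
of the projected data, removing per-pixel illumination scale. Below
it, the mean-removed data are projected onto `p−1` directions and
augmented with a constant coordinate equal to the largest projected
norm.

Vertices are then found iteratively: draw a seeded standard-normal
direction, orthogonalize it against the span of the vertices already
found (via the pseudoinverse), and take the pixel maximizing the
absolute projection. Ties resolve to the lowest pixel index;
already-selected pixels are excluded so the p returned indices are
always distinct, even for degenerate (rank-deficient) data, which
additionally raises a warning. `p = 1` degenerates to the longest
pixel vector. For comb cubes the default is `p = 2` (comb tissue +
background); the comb column is identified as the end member with the
highest mean reflectance over 600–1000 nm, where perfused tissue is
bright.

Recovery quality is measured by the spectral angle
`arccos(⟨a,b⟩/(‖a‖‖b‖))`, which is invariant to `γ`.

## Fast continuous wavelet transform

Mother wavelet: the analytic Morlet `ψ(t) = e^{iω₀t} e^{−t²/2}` with
Fourier transform `ψ̂(ω) = √(2π) e^{−(ω−ω₀)²/2}`. The peak amplitude
is exposed as a parameter (`amplitude`) because some conventions print
`2π`; changing it rescales every coefficient by one global constant
and nothing else. `ω₀ ≥ 5` is enforced so the admissibility (zero-mean)
correction, of order `e^{−ω₀²/2}`, is negligible. The RMS frequency
width of `|ψ̂|²` about `ω₀` is `1/√2` regardless of `ω₀`; the daughter
at scale `α`, `ψ̂(αω)`, is centered at `ω₀/α` with width `(1/√2)/α`.

Transform of a length-`L` signal: zero-pad to `N = 2·nextpow2(L)`
(suppressing circular wrap-around), FFT once, and per scale multiply
by the daughter window on the one-sided frequency grid
`ξ_k = 2πk/N`, `k = 0…N/2` — entries below `1e−8` of the window peak
are skipped, which is what makes the transform fast, since each
daughter occupies a narrow band. The first `L` samples of each inverse
FFT form one coefficient row; rows stack in scale order. Scales are
log₂-uniform over `[2^a, 2^b]` inclusive; defaults `a = 5`, `b = 6`,
`n = 200`, `ω₀ = 8`, chosen as the most informative setting for comb
spectra, give the 200 × 300 feature map. The feature map is the
element-wise magnitude `|W|` with no rescaling (magnitude, rather than
real part or complex pair, keeps the map nonnegative and phase-free
for the classifier).

`naive_cwt` is a deliberate O(n·L²) re-implementation of the same
contract — explicit DFT sums, no FFT, no window thresholding — kept as
an independent oracle; the fast path must agree with it to ~1e−6
relative, and does.

Numerical caveats: scales with `ω₀/α > π` center the daughter above
Nyquist; such rows contain only the window's tail and are not
time-local (the defaults are far from this regime — `ω₀/32 = 0.25`).
Columns within roughly `±5α` of either signal edge feel the
zero-padding; at the default scales that is most of a 300-band
spectrum, so feature maps should be compared like-for-like, which the
classifier does.

## Dataset assembly and normalization

Each labeled spectrum becomes one scalogram; labels travel with the
maps. Normalization is min–max to `[0, 1]` with two methods:

- `per_map`: each map scaled by its own extrema (constant maps become
  zero). Bounded inputs, but any between-bird amplitude difference is
  discarded.
- `global` (pipeline default): all maps scaled by the dataset-wide
  extrema. This preserves relative scalogram magnitude between birds,
  which matters here: the wavelet has zero mean, so the reflectance
  *offset* between classes is already gone from the maps, and the
  remaining class signal is carried largely by the *gain* (slope) of
  the curves — which per-map scaling would cancel too. Empirically,
  per-map scaling caps a linear probe near 0.93 validation accuracy on
  the default synthetic flock, while global scaling makes the classes
  cleanly separable, with training curves that drop toward zero loss
  within a few epochs.

The split is 4:1 by largest-remainder rounding (`round(N·4/5)` train),
stratified by default: per-class quotas are floored and the shortfall
distributed by largest remainder, so each class lands within one
sample of its exact proportion; a seeded generator shuffles within
class. The two subsets are disjoint and exhaustive, and identical
seeds give identical splits.

## The classifier

Layer stack (valid padding throughout, shapes for a 200 × 300 input):

| layer | configuration | output |
|---|---|---|
| conv1 | 8 filters, kernel (3,1), stride (3,1), ReLU | 66 × 300 × 8 |
| pool1 | max, (2,2), stride (2,2) | 33 × 150 × 8 |
| conv2 | 32 filters, kernel (1,1), stride (1,1), ReLU | 33 × 150 × 32 |
| pool2 | max, (3,3), stride (2,2) | 16 × 74 × 32 |
| head | flatten → dense(2) → softmax | 37 888 → 2 |

Each output dimension is `floor((d − k)/s) + 1`. conv1 mixes triples
of adjacent scales (non-overlapping, stride = kernel); conv2 is a
per-position channel mixer; the overlapping 3×3/stride-2 pool2
summarizes. Loss is softmax cross-entropy; the optimizer is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with defaults lr 1e−3, batch 16, 30
epochs — small-CNN standards; higher rates (3e−3, 1e−2) destabilize
this stack. He-normal initialization, seeded.

The network is implemented directly on NumPy arrays (im2col-style
convolution via strided window views; max-pool gradients routed per
tap to handle overlapping windows; single-precision compute). At this
scale a framework adds nothing, and the from-scratch path keeps the
entire training history bitwise reproducible from one integer seed on
a given platform — parameter init, batch order, and every update are
deterministically ordered array ops. Undefined metrics (zero
denominators, e.g. a never-predicted class) are reported as 0.

Evaluation reports per-class precision, recall,
`F1 = 2pr/(p + r)`, support, overall accuracy, and macro (unweighted)
and weighted (support-weighted) averages; weighted recall equals
accuracy for exhaustive, mutually exclusive classes.

## Synthetic data

The generator emulates the two documented properties of comb spectra
and nothing more:

- **Class templates**: logistic rises from a blue/green floor to a
  near-IR plateau. Normal: `0.08 + 0.45·σ((λ−580)/40)`. Abnormal:
  `0.12 + 0.45·g·σ((λ−560)/35)` with slope gain `g ∈ [1, 1.9]`
  (default 1.5, a free separability parameter). For every admissible
  `g` the abnormal template is strictly brighter over 400–600 nm and
  strictly steeper on average over 450–600 nm.
- **Per-bird variation**: a mild amplitude factor (`1 + 0.03·N(0,1)`),
  a smooth cubic-spline perturbation (8 knots, sd 0.01) standing in
  for physiological variation, and white noise (sd 0.005, a realistic
  level for calibrated reflectance), clipped to `[0, 1.2]`. Class
  counts follow largest-remainder rounding of the 7:3 flock ratio over
  300 birds by default; explicit counts (e.g. 203/197 for a
  400-spectrum study) can be fixed directly.
- **Mixed cubes**: `r = γ M α + n` with flat-Dirichlet abundances,
  `γ ~ U[0.8, 1.2]`, at least one planted pure pixel (one-hot `α`,
  `γ = 1`) per end member, optional white noise at a stated SNR, and
  ground truth returned.

What this does **not** emulate: real tissue optics (hemoglobin and
water absorption features), spatial texture, sensor striping,
illumination gradients, or inter-bird covariance structure. Passing
the end-to-end test therefore demonstrates that the pipeline's
machinery is correct and that it can exploit the documented class
contrast — not that field accuracy on farm data will match; the
synthetic problem at the default separation is easier than real combs,
whose within-class variation is richer.

## Problem sizes and determinism

The shipped tests and the acceptance script use: a 400-spectrum flock
(203/197) for the end-to-end run; 20 signals of length ≤ 128 for the
transform-oracle comparison; 32 × 32 × 300 cubes (one noiseless, 20 at
40 dB) for end-member recovery; 1 000 random label vectors for the
metric bounds. One global seed fans out to stage seeds by fixed
offsets (synthesis, split, model init, training), so any stage can be
reproduced in isolation and a full rerun with the same seed is
bit-identical on one platform.
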