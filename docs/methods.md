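# Methods

## The p-flow extractor

For a grayscale stack `I(x, y, t)` (intensities in [0, 1], x
rightward, y downward, origin at the top-left pixel center), each
frame transition `t → t+1` gets a gradient field: spatial derivatives
by central differences inside frame `t` (one-sided at the borders),
temporal derivative by the forward difference `I(t+1) − I(t)`. A field
therefore belongs to the earlier frame of its transition. Pixels whose
spatial gradient magnitude falls below `τ_g` carry no usable
constraint and are masked.

A gradient vector `g = (gx, gy, gt)` implies the brightness-constancy
normal flow `v = −gt·(gx, gy)/(gx²+gy²)`, the unique motion component
a single gradient determines; this is the displacement formula used
throughout. Candidates are seeded on a `seed_stride` grid at valid
pixels of every admissible transition. A candidate at position `p`
with vector `g` is advanced to `p' = p + v(g)`; the next transition's
field is sampled at `p'` (bilinear; nearest-pixel mode exists for
oracle cross-checks) and the step is accepted when the angle between
the full 3-vectors is ≤ `θ_tol` and the relative norm difference is
≤ `ρ_tol`. Tracks matched over ≥ `m_min` consecutive transitions are
kept; an implied position outside the frame simply ends the track.
The extraction is fully deterministic; only track subsampling is
randomized (seeded).

Matching on the full 3-vector versus only the spatial pair, and the
number of transitions required, are genuinely open design choices;
both are parameters (`spatial_only_match`, `m_min`), with the full
3-vector and `m_min = 2` as defaults.

Default parameters, all on [0, 1] intensities and pixel units:

| parameter | default | role |
|---|---|---|
| `τ_g` | 0.02 /px | minimum spatial-gradient magnitude |
| `θ_tol` | 10° | angular match tolerance |
| `ρ_tol` | 0.3 | relative magnitude tolerance |
| `m_min` | 2 | matched transitions required |
| `v_max` | 3 px/frame | speed cap (desk-scale motion) |
| `seed_stride` | 2 px | candidate grid spacing |
| `min_speed` | 0.05 px/frame | zero-motion suppression |

`θ_tol`/`ρ_tol` were chosen so that temporally independent noise
yields well under 5 % false acceptances in the Monte Carlo test.
Near-stationary tracks are suppressed by default because a point-light
display visualizes motion; set `min_speed = 0` to keep them.

A consequence worth stating: accepted displacements are *normal* flow,
so on a 1-D drifting grating every track moves strictly along the
gradient axis — the aperture problem is exhibited, not solved. On
isotropically textured scenes the matching stage instead acts as a
filter: candidates whose gradient is misaligned with the true motion
imply a wrong position, find a decorrelated vector there, and are
rejected, so the accepted subset concentrates at the true velocity.

## Lucas–Kanade baseline

`lk_step` solves the windowed normal equations
`(Σ∇I∇Iᵀ)v = −Σ∇I·I_t` with iterative re-warping (bilinear sampling),
declaring a window degenerate when the structure tensor's smaller
eigenvalue is below `λ_min = 1e−4`; a warped window leaving the frame
is out-of-bounds. Features come from the minimum-eigenvalue
(Shi–Tomasi) criterion with non-maximum suppression at the window
radius; tracks are re-seeded every 10 frames to keep dot counts
steady. Defaults: half-window 7 (15×15), `max_iter` 20, `conv_tol`
0.01 px. Pyramids are omitted — every scene here moves ≤ 3 px/frame;
pyramidal and affine variants are deliberate non-goals, as is tuning
either algorithm against the other. `match_dot_counts` subsamples
whole tracks of the larger set (seeded, uniform) until per-frame mean
active-dot counts differ by ≤ 1, since dot count approximates motion
energy.

## Synthetic scenes

All generators store the true per-transition velocity with the
convention that frame `t+1` equals frame `t` warped forward by
`velocity[t]`.

- **Texture**: Gaussian-smoothed white noise (σ = correlation_length/2,
  periodic), normalized to [0, 1]. The default correlation length of
  1 px is deliberate: gradient-vector matching is informative exactly
  when gradients decorrelate within about a pixel; coarse texture
  leaves the normal flow aperture-ambiguous nearly everywhere.
- **Translation**: integer shifts by exact roll, subpixel by Fourier
  shift; wrap-around, so the warp identity is exact.
- **Rotation**: each frame resampled from the original texture at the
  cumulative angle (no error accumulation); tangential truth
  `|v| = ω·r`; zero padding outside, evaluate in the interior.
- **Grating**: drifting sinusoid; the stored truth is the drift along
  the gradient axis, the orthogonal component being unobservable by
  construction.
- **Fluid proxy**: a stream function ψ per transition from AR(1)
  temporally correlated noise (ρ = 0.95) smoothed with a spatial
  Gaussian of scale `smoothness`; velocity = (∂ψ/∂y, −∂ψ/∂x). Because
  one-dimensional difference operators along different axes commute,
  the discrete central-difference divergence is zero to machine
  precision. The field is rescaled to RMS speed `speed_scale` and the
  texture advected semi-Lagrangially with periodic boundaries.

The fluid proxy stands in for physics-simulated liquid movies, which
are external media. Higher `smoothness` gives spatially smoother
deformation at equal RMS speed — a *rank-order* proxy for higher
viscosity; no quantitative mapping to Pa·s exists or is claimed. What
it does not emulate: free surfaces, specular highlights, gravity-driven
anisotropy, compressible splashes. Tests passing on it show the
extractors handle smooth nonrigid deformation fields, not that they
handle photorealistic liquids.

## Flow evaluation

Endpoint error is the Euclidean distance between a track's
per-transition displacement and the true velocity bilinearly sampled
at the transition's start position; angular error is the space-time
angle between homogeneous `(vx, vy, 1)` vectors; coverage is the mean
fraction of frame area within `r_cov = 10 px` of an active dot. These
are standard flow-benchmark metrics — the choice is recorded in the
comparison report's metadata. Empty track sets report errors as
absent, never as zero.

## Rating experiment

The expected rating is linear in log viscosity through the anchors
(0.0035938 Pa·s → 10, 7.7426 Pa·s → 80) and extrapolated beyond them
rather than re-anchored, since the measurement range exceeds the
anchor range; the mapping is exposed in output metadata. The 10
measurement viscosities are log-spaced over 0.0020771–40.103 Pa·s,
which places the expected ratings at 5, 15, …, 95 — evenly spaced
ratings, the natural reading of "evenly spaced in rank". Scale
expansion moves a bound outward by 10 whenever a rating sits exactly
on it, without limit; participants who ever used an expanded scale can
be excluded from analysis (`exclude_expanded`), and the filter is
exposed both before and after check-variable analysis because the
order is ambiguous in principle.

The moving-window diagnostic reorders each block after the first
*within block* to the first block's stimulus order (a global sort
would break block boundaries), then takes RMS rating error over every
window of 10 — 41 windows for 50 trials. Analysis retains blocks 3–5;
per-stimulus summaries use the three retained repetitions (sample SD,
n−1).

The split-plot ANOVA (one between-subject factor, one within) is
computed from explicit sums of squares: the between effect is tested
against subjects-within-groups (`df = N−a`), the within and
interaction effects against the within-subject residual
(`df = (N−a)(s−1)`); effect size is η² = SS_effect/SS_total. No
sphericity correction is applied by default. Tukey(-Kramer)
comparisons use the studentized-range distribution; for the between
factor they run on subject means against the pooled between-subject
variance. Degenerate inputs: a table with zero effect variance reports
F = 0, p = 1; missing cells and singular designs raise.

The synthetic observer rates `expected + bias + N(0, σ_algorithm)`,
clipped to the current scale with expansion applied on extremes, and
draws RT log-normally with a per-algorithm location. Defaults
σ = {original: 6, pflow: 8, lk: 11} rating units and a longer lk RT
location encode the structure the pipeline is designed to detect:
equal accuracy, algorithm-dependent precision and RT. Discontinuation
rules (3 aborts, 40-min limit) are represented as censoring flags
only. What the observer does not emulate: learning across blocks,
anchoring drift, heavy-tailed lapses — so recovery tests demonstrate
the statistical pipeline's sensitivity under its own model, not human
behavior.

## Problem sizes and numerics

Benchmarks use 64×64 stacks of 8–20 frames, cohorts of 60 simulated
observers per algorithm with 200 replicates for power estimates, and
1,000 null replicates for the type-I calibration — sizes at which
every pipeline stage runs in seconds while leaving Monte Carlo
standard errors well inside the asserted margins. Null-calibration
rejection rates aggregate the three F tests per replicate (all true
nulls), tripling the effective count. Media round trips are 16-bit
PNG sequences (quantization ≤ 1/65535); box-filter preprocessing uses
reflective padding (preserves constants, no dark rims); decolorization
uses Rec.601 luma weights. Neither the blur's boundary rule nor the
luminance weights are dictated by the stimulus-generation recipe this
mirrors; both are this package's own choices, stated here.

## Known limitations

- Video-container reading depends on available imageio plugins; the
  lossless, tested path is numbered image-sequence directories.
- The p-flow track set over-represents gradient orientations aligned
  with motion (by construction); it is a biased sample of the flow
  field, which is the point, but means coverage statistics must be
  read accordingly.
- The split-plot sums of squares assume (near-)balanced groups;
  heavily unbalanced between-group designs would need Type-III
  machinery not implemented here.
- `subsample_tracks` is greedy after a seeded shuffle; it guarantees
  the per-frame cap but not the maximum-cardinality selection.
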