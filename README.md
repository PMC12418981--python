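# pflow

Tools for studying the perception of nonrigid structure from motion:
extraction of a *trackable* subset of optical flow by matching
spatiotemporal image-gradient vectors ("p-flow"), a from-scratch
Lucas–Kanade (LK) baseline, point-light-display rendering, synthetic
ground-truth scenes (rigid motions, drifting gratings, and a
divergence-free advected-noise fluid proxy), and a simulation +
analysis pipeline for viscosity-rating experiments.

## The problem and the algorithm

A point-light display of a fluid is hard to construct: fluids have no
landmarks to attach lights to. Gradient-based flow estimators (LK)
give dense velocity but no *features* to follow; feature-based
trackers need landmarks a fluid does not have.

The p-flow resolves this by treating the spatiotemporal gradient
vector itself as the feature. At each pixel the gradient
`g = (I_x, I_y, I_t)` implies, under brightness constancy
`I_x v_x + I_y v_y + I_t = 0`, the normal-flow displacement

```
v(g) = -I_t (I_x, I_y) / (I_x² + I_y²)
```

— the unique motion component one gradient constrains. If `v(g)` is
genuine motion rather than noise, the *same* vector should reappear at
the implied position `p + v(g)` in the next frame's gradient field.
The extractor keeps exactly the candidates for which this
self-consistency holds over ≥ `m_min` consecutive transitions (angular
tolerance `θ_tol`, relative-magnitude tolerance `ρ_tol`). Accepted
trajectories are rendered as moving dots; LK tracks, with dot counts
matched to equalize motion energy, are the comparison display.

The rating-experiment pipeline implements the companion psychophysics:
an expected viscosity rating linear in log viscosity between anchors
(rating 10 at 0.0035938 Pa·s, 80 at 7.7426 Pa·s), a flexible 101-point
scale that expands by 10 whenever a rating hits a bound, per-stimulus
mean/SD of the rating error and mean RT over the last 3 of 5 blocks,
and a split-plot ANOVA (algorithm between subjects, stimulus within)
with Tukey post hocs at a Bonferroni-corrected α = 0.05/6. A synthetic
observer with algorithm-dependent rating noise replaces human data.

## Worked example

```python
import numpy as np
from pflow import (make_texture, translate_scene, extract_pflow,
                   track_lk, endpoint_error)

tex = make_texture(64, 64, correlation_length=1.0, rng_seed=0)
scene = translate_scene(tex, (1.0, 0.0), T=10)   # truth: 1 px/frame rightward

tracks = extract_pflow(scene.stack)
v = np.array([t.mean_velocity for t in tracks])
print(len(tracks), np.round(v.mean(axis=0), 3))
# 120 [ 1.03  -0.005]

print(round(endpoint_error(track_lk(scene.stack), scene).mean_epe, 5))
# 9e-05
```

120 gradient-vector tracks are accepted; their mean velocity
(1.03, −0.005) px/frame recovers the true (1, 0) translation — the
matching rule discards candidates whose normal flow disagrees with the
true motion, so the surviving subset is accurate. The LK baseline's
mean endpoint error on the same scene is ~9·10⁻⁵ px.

The same machinery runs from a shell: `pflow synth`, `pflow extract`,
`pflow lk`, `pflow render`, `pflow eval`, `pflow simulate`,
`pflow analyze` (see `pflow --help`).

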