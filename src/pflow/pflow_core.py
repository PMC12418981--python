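"""p-flow: trackable optical flow by matching spatiotemporal gradients.

The central idea: a pixel's spatiotemporal gradient vector
``g = (gx, gy, gt)`` implies, under brightness constancy, a normal-flow
displacement ``v = -gt * (gx, gy) / (gx^2 + gy^2)`` — the unique motion
component a single gradient measurement constrains.  If that
displacement comes from genuine optical flow rather than noise, the
*same* gradient vector should reappear at the implied position in the
next frame's gradient field.  The p-flow keeps exactly the candidates
for which this self-consistency check succeeds over several consecutive
transitions, producing a sparse set of trackable dot trajectories
("pseudo-flow", a subset of the true flow).

Because the displacement is normal flow, accepted tracks concentrate
where the gradient direction is aligned with the true motion: on a
drifting 1-D grating every track moves along the gradient axis only
(the aperture problem), while on isotropically textured scenes the
matching stage filters out candidates whose normal flow disagrees with
the true motion.

Coordinate convention: x rightward, y downward, origin at the center of
the top-left pixel, positions in continuous pixel units.  A gradient
field "belongs to" the earlier frame of its transition (temporal
derivative by forward difference).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .media_io import FrameStack

__all__ = [
    "GradientField",
    "NormalFlowField",
    "DotTrack",
    "PFlowParams",
    "spatiotemporal_gradient",
    "normal_flow",
    "match_vector",
    "extract_pflow",
    "subsample_tracks",
    "save_tracks_csv",
    "load_tracks_csv",
    "save_tracks_json",
]


@dataclasses.dataclass
class PFlowParams:
    """Parameters of the p-flow extractor.

    Attributes
    ----------
    tau_g : float
        Gradient-magnitude threshold (intensity/px): pixels whose
        spatial gradient magnitude falls below it carry no usable
        motion signal and are masked out.
    theta_tol : float
        Angular tolerance in degrees for the vector match (between the
        full 3-vectors g and g' by default).
    rho_tol : float
        Relative-magnitude tolerance: |  ||g'|| - ||g||  | / ||g||.
    m_min : int
        Minimum number of consecutively matched transitions for a
        track to be accepted (track length is m_min + 1 positions).
    v_max : float
        Maximum admissible speed in px/frame; faster implied motion is
        treated as noise.
    seed_stride : int
        Spacing of the candidate seed grid in pixels.
    min_speed : float
        Tracks whose mean speed is below this are suppressed (a
        point-light display visualizes motion; stationary dots carry
        none).  Set to 0 to keep them.
    spatial_only_match : bool
        Match only the spatial pair (gx, gy) instead of the full
        3-vector.
    nearest_sampling : bool
        Sample the gradient field at the nearest pixel instead of
        bilinearly (for oracle cross-checks).
    rng_seed : int
        Seed for any randomized stage (subsampling).
    """

    tau_g: float = 0.02
    theta_tol: float = 10.0
    rho_tol: float = 0.3
    m_min: int = 2
    v_max: float = 3.0
    seed_stride: int = 2
    min_speed: float = 0.05
    spatial_only_match: bool = False
    nearest_sampling: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_g <= 0 or self.theta_tol <= 0 or self.rho_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.m_min < 1:
            raise ValueError("m_min must be >= 1")
        if self.v_max <= 0 or self.seed_stride < 1:
            raise ValueError("v_max must be > 0 and seed_stride >= 1")


@dataclasses.dataclass
class GradientField:
    """Per-pixel spatiotemporal gradient for one frame transition."""

    gx: np.ndarray
    gy: np.ndarray
    gt: np.ndarray
    frame_index: int
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.gx.shape, self.gy.shape, self.gt.shape,
                  self.valid_mask.shape}
        if len(shapes) != 1:
            raise ValueError("gradient component shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.gx.shape


@dataclasses.dataclass
class NormalFlowField:
    """Implied normal-flow displacement per pixel (px/frame)."""

    vx: np.ndarray
    vy: np.ndarray
    defined_mask: np.ndarray


@dataclasses.dataclass
class DotTrack:
    """One accepted trajectory of a moving dot.

    ``positions[k]`` is the (x, y) position at frame ``start_frame + k``.
    """

    positions: np.ndarray  # (L, 2) float
    start_frame: int
    algorithm: str = "pflow"
    score: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (L, 2) array")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def displacements(self) -> np.ndarray:
        """Per-transition (dx, dy), shape (L-1, 2)."""
        return np.diff(self.positions, axis=0)

    @property
    def mean_velocity(self) -> np.ndarray:
        return self.displacements.mean(axis=0)

    def frames(self) -> range:
        return range(self.start_frame, self.start_frame + len(self.positions))


def spatiotemporal_gradient(
    stack: FrameStack, t: int, tau_g: float = 0.02
) -> GradientField:
    """Gradient field of the transition ``t -> t+1``.

    Spatial derivatives by central differences within frame ``t``
    (one-sided at the borders); temporal derivative by the forward
    difference ``frame(t+1) - frame(t)``.  The valid mask marks pixels
    whose spatial gradient magnitude reaches ``tau_g``.
    """
    T = stack.n_frames
    if not 0 <= t < T - 1:
        raise IndexError(f"transition index {t} out of range [0, {T - 2}]")
    frame = stack.frames[t]
    gy, gx = np.gradient(frame)
    gt = stack.frames[t + 1] - frame
    valid = (gx**2 + gy**2) >= tau_g**2
    return GradientField(gx=gx, gy=gy, gt=gt, frame_index=t, valid_mask=valid)


def normal_flow(field: GradientField, v_max: float = 3.0) -> NormalFlowField:
    """Brightness-constancy normal flow ``v = -gt * (gx, gy) / |grad I|^2``.

    Defined only where the spatial gradient passes the field's validity
    threshold and the implied speed does not exceed ``v_max``;
    aperture-degenerate pixels are masked, never raised.
    """
    g2 = field.gx**2 + field.gy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = np.where(g2 > 0, -field.gt * field.gx / g2, 0.0)
        vy = np.where(g2 > 0, -field.gt * field.gy / g2, 0.0)
    speed2 = vx**2 + vy**2
    defined = field.valid_mask & (g2 > 0) & (speed2 <= v_max**2)
    vx = np.where(defined, vx, np.nan)
    vy = np.where(defined, vy, np.nan)
    return NormalFlowField(vx=vx, vy=vy, defined_mask=defined)


def _sample_field(
    field: GradientField, x: np.ndarray, y: np.ndarray, nearest: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample (gx, gy, gt, inside) at continuous positions."""
    from scipy import ndimage

    h, w = field.shape
    inside = (x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1)
    xs = np.clip(x, 0, w - 1)
    ys = np.clip(y, 0, h - 1)
    order = 0 if nearest else 1
    coords = [ys, xs]
    gx = ndimage.map_coordinates(field.gx, coords, order=order, mode="nearest")
    gy = ndimage.map_coordinates(field.gy, coords, order=order, mode="nearest")
    gt = ndimage.map_coordinates(field.gt, coords, order=order, mode="nearest")
    return gx, gy, gt, inside


def _match_arrays(
    g: np.ndarray, gp: np.ndarray, params: PFlowParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized match test between gradient 3-vectors g and g'.

    Returns (matched, score) with score in [0, 1]: the product of the
    angular similarity (1 at zero angle, 0 at theta_tol) and the
    magnitude similarity (1 at equal norms, 0 at rho_tol relative
    difference).
    """
    if params.spatial_only_match:
        g = g[..., :2]
        gp = gp[..., :2]
    ng = np.linalg.norm(g, axis=-1)
    ngp = np.linalg.norm(gp, axis=-1)
    denom = ng * ngp
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(denom > 0, np.sum(g * gp, axis=-1) / denom, 0.0)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        relmag = np.where(ng > 0, np.abs(ngp - ng) / ng, np.inf)
    matched = (ang <= params.theta_tol) & (relmag <= params.rho_tol)
    score = np.clip(1 - ang / params.theta_tol, 0, 1) * np.clip(
        1 - relmag / params.rho_tol, 0, 1)
    return matched, np.where(matched, score, 0.0)


def match_vector(
    g: Sequence[float],
    position: Sequence[float],
    next_field: GradientField,
    params: PFlowParams | None = None,
) -> tuple[bool, tuple[float, float] | None, float]:
    """Test one gradient vector for self-consistent reappearance.

    The vector's implied normal-flow displacement is added to
    ``position``; the next transition's gradient field is sampled there
    (bilinear by default) and compared with ``g``: matched iff the
    angle between the 3-vectors is within ``theta_tol`` degrees and the
    relative magnitude difference within ``rho_tol``.

    Returns ``(matched, matched_position, score)``; an implied position
    outside the frame is simply unmatched.
    """
    params = params or PFlowParams()
    g = np.asarray(g, dtype=np.float64)
    gx, gy, gt = g
    g2 = gx**2 + gy**2
    if g2 < params.tau_g**2:
        raise ValueError("gradient below tau_g is not a valid match candidate")
    vx, vy = -gt * gx / g2, -gt * gy / g2
    if np.hypot(vx, vy) > params.v_max:
        return False, None, 0.0
    px, py = position[0] + vx, position[1] + vy
    sgx, sgy, sgt, inside = _sample_field(
        next_field, np.array([px]), np.array([py]), params.nearest_sampling)
    if not inside[0]:
        return False, None, 0.0
    gp = np.array([sgx[0], sgy[0], sgt[0]])
    matched, score = _match_arrays(g, gp, params)
    if not matched:
        return False, None, 0.0
    return True, (px, py), float(score)


def extract_pflow(stack: FrameStack, params: PFlowParams | None = None
                  ) -> list[DotTrack]:
    """Extract p-flow tracks from a grayscale frame stack.

    Candidates are seeded on a ``seed_stride`` grid at valid-mask
    pixels of every transition and extended frame to frame by the
    gradient-vector match; a candidate advances by its own normal-flow
    displacement each step.  Tracks matched over at least ``m_min``
    consecutive transitions are kept, near-stationary ones suppressed
    (see ``min_speed``), and the result is sorted by
    ``(start_frame, score descending)``.  Fully deterministic.
    """
    params = params or PFlowParams()
    stack.validate_for_motion()
    T, H, W = stack.shape
    if T < params.m_min + 1:
        raise ValueError(f"need at least m_min + 1 = {params.m_min + 1} frames")

    fields = [spatiotemporal_gradient(stack, t, params.tau_g)
              for t in range(T - 1)]

    # seed grid (same for every transition)
    gy_idx, gx_idx = np.mgrid[0:H:params.seed_stride, 0:W:params.seed_stride]
    seed_x = gx_idx.ravel().astype(np.float64)
    seed_y = gy_idx.ravel().astype(np.float64)

    tracks: list[DotTrack] = []
    for t0 in range(T - 1 - params.m_min + 0):
        field0 = fields[t0]
        ok = field0.valid_mask[seed_y.astype(int), seed_x.astype(int)]
        x = seed_x[ok].copy()
        y = seed_y[ok].copy()
        n = x.size
        if n == 0:
            continue
        g = np.stack([field0.gx[y.astype(int), x.astype(int)],
                      field0.gy[y.astype(int), x.astype(int)],
                      field0.gt[y.astype(int), x.astype(int)]], axis=-1)
        positions = [np.stack([x, y], axis=-1)]
        scores = np.zeros(n)
        steps = np.zeros(n, dtype=int)
        alive = np.ones(n, dtype=bool)
        for t in range(t0, T - 1):
            if not alive.any():
                break
            g2 = g[:, 0]**2 + g[:, 1]**2
            with np.errstate(divide="ignore", invalid="ignore"):
                vx = np.where(g2 > 0, -g[:, 2] * g[:, 0] / g2, 0.0)
                vy = np.where(g2 > 0, -g[:, 2] * g[:, 1] / g2, 0.0)
            speed_ok = (vx**2 + vy**2 <= params.v_max**2) & (g2 >= params.tau_g**2)
            px = x + vx
            py = y + vy
            if t + 1 <= T - 2:
                nxt = fields[t + 1]
            else:
                # final transition: the track ends at the implied
                # position of the last matched step; nothing to match
                # against beyond it
                alive &= False
                break
            sgx, sgy, sgt, inside = _sample_field(nxt, px, py,
                                                  params.nearest_sampling)
            gp = np.stack([sgx, sgy, sgt], axis=-1)
            matched, step_score = _match_arrays(g, gp, params)
            alive = alive & speed_ok & inside & matched
            x = np.where(alive, px, x)
            y = np.where(alive, py, y)
            g = np.where(alive[:, None], gp, g)
            scores = np.where(alive, scores + step_score, scores)
            steps = np.where(alive, steps + 1, steps)
            positions.append(np.stack([x, y], axis=-1))
        pos = np.stack(positions, axis=0)  # (n_steps+1, n, 2)
        keep = steps >= params.m_min
        for i in np.flatnonzero(keep):
            L = steps[i] + 1
            p = pos[:L, i, :]
            mean_speed = np.linalg.norm(np.diff(p, axis=0), axis=1).mean()
            if mean_speed < params.min_speed:
                continue
            tracks.append(DotTrack(
                positions=p, start_frame=t0, algorithm="pflow",
                score=float(scores[i] / steps[i]),
            ))
    tracks.sort(key=lambda tr: (tr.start_frame, -tr.score))
    return tracks


def per_frame_counts(tracks: Sequence[DotTrack], T: int) -> np.ndarray:
    """Number of active dots in each of T frames."""
    counts = np.zeros(T, dtype=int)
    for tr in tracks:
        lo = tr.start_frame
        hi = min(lo + len(tr), T)
        counts[lo:hi] += 1
    return counts


def subsample_tracks(
    tracks: Sequence[DotTrack], n_target: int, rng_seed: int = 0
) -> list[DotTrack]:
    """Uniformly subsample tracks so no frame holds more than ``n_target`` dots.

    Tracks are visited in a seeded random order and greedily accepted
    while they do not push any frame's active-dot count above the
    target; displacement statistics are preserved in expectation.
    Deterministic under the seed.
    """
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    if n_target == 0:
        return []
    if not tracks:
        return []
    T = max(tr.start_frame + len(tr) for tr in tracks)
    if per_frame_counts(tracks, T).max() <= n_target:
        return list(tracks)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(tracks))
    counts = np.zeros(T, dtype=int)
    chosen: list[DotTrack] = []
    for i in order:
        tr = tracks[i]
        lo, hi = tr.start_frame, tr.start_frame + len(tr)
        if counts[lo:hi].max() < n_target:
            counts[lo:hi] += 1
            chosen.append(tr)
    chosen.sort(key=lambda tr: (tr.start_frame, -tr.score))
    return chosen


# ---------------------------------------------------------------------------
# track serialization

def tracks_to_frame(tracks: Sequence[DotTrack]) -> pd.DataFrame:
    rows = []
    for tid, tr in enumerate(tracks):
        for k, (x, y) in enumerate(tr.positions):
            rows.append((tid, tr.start_frame + k, x, y, tr.score, tr.algorithm))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y",
                                       "score", "algorithm"])


def save_tracks_csv(tracks: Sequence[DotTrack], path: str | Path) -> Path:
    path = Path(path)
    tracks_to_frame(tracks).to_csv(path, index=False)
    return path


def load_tracks_csv(path: str | Path) -> list[DotTrack]:
    df = pd.read_csv(path)
    tracks = []
    for _, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(DotTrack(
            positions=grp[["x", "y"]].to_numpy(),
            start_frame=int(grp["frame"].iloc[0]),
            algorithm=str(grp["algorithm"].iloc[0]),
            score=float(grp["score"].iloc[0]),
        ))
    return tracks


def save_tracks_json(tracks: Sequence[DotTrack], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"start_frame": tr.start_frame, "algorithm": tr.algorithm,
         "score": tr.score, "positions": tr.positions.tolist()}
        for tr in tracks
    ]
    path.write_text(json.dumps(payload))
    return path
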