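"""Lucas-Kanade optical-flow tracker (from-scratch baseline).

LK estimates motion by assuming a whole spatial window moves together:
it solves the windowed least-squares problem on the brightness
constancy constraint, ``(sum grad I grad I^T) v = -sum grad I * It``,
iteratively re-warping until convergence.  Windows whose structure
tensor is rank-deficient (1-D gratings, flat regions) are degenerate —
the aperture problem manifests as an unsolvable system rather than as
a normal-flow answer, which is the qualitative contrast with p-flow.

Feature points are chosen by the minimum-eigenvalue criterion on the
structure tensor (Shi-Tomasi style) with non-maximum suppression.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .media_io import FrameStack
from .pflow_core import DotTrack, per_frame_counts, subsample_tracks

__all__ = [
    "LKParams",
    "good_features",
    "lk_step",
    "track_lk",
    "match_dot_counts",
]


@dataclasses.dataclass
class LKParams:
    """Lucas-Kanade tracking parameters.

    ``window`` is the half-size of the integration window (a value of 7
    gives a 15x15 window).  ``lam_min`` is the minimum smaller
    eigenvalue of the windowed structure tensor (on [0, 1] intensities)
    below which the system is considered degenerate.  Pyramids are
    omitted: all synthetic motions here are <= 3 px/frame.
    """

    window: int = 7
    lam_min: float = 1e-4
    max_iter: int = 20
    conv_tol: float = 0.01
    v_max: float = 3.0
    min_speed: float = 0.05
    reseed_every: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.lam_min <= 0 or self.conv_tol <= 0:
            raise ValueError("lam_min and conv_tol must be > 0")


def _gradients(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy, gx = np.gradient(frame)
    return gx, gy


def _min_eigenvalue_map(frame: np.ndarray, window: int) -> np.ndarray:
    """Smaller eigenvalue of the windowed structure tensor at each pixel."""
    gx, gy = _gradients(frame)
    size = 2 * window + 1
    sxx = ndimage.uniform_filter(gx * gx, size=size, mode="constant") * size**2
    syy = ndimage.uniform_filter(gy * gy, size=size, mode="constant") * size**2
    sxy = ndimage.uniform_filter(gx * gy, size=size, mode="constant") * size**2
    tr = sxx + syy
    det_term = np.sqrt(((sxx - syy) / 2) ** 2 + sxy**2)
    return tr / 2 - det_term


def good_features(
    frame: np.ndarray, params: LKParams | None = None, n_max: int = 200
) -> list[tuple[float, float]]:
    """Select trackable points by the minimum-eigenvalue criterion.

    Pixels are ranked by the smaller eigenvalue of the local structure
    tensor; candidates within the window radius of a stronger one are
    suppressed; at most ``n_max`` points are returned, strongest first.
    A constant frame (or a pure 1-D grating) yields an empty list.
    """
    params = params or LKParams()
    lam = _min_eigenvalue_map(frame, params.window)
    h, w = frame.shape
    # keep full windows inside the frame
    margin = params.window
    mask = np.zeros_like(lam, dtype=bool)
    if h > 2 * margin and w > 2 * margin:
        mask[margin:h - margin, margin:w - margin] = True
    lam = np.where(mask, lam, -np.inf)
    # non-maximum suppression at window radius
    localmax = lam == ndimage.maximum_filter(lam, size=2 * params.window + 1,
                                             mode="constant", cval=-np.inf)
    cand = np.flatnonzero((lam >= params.lam_min) & localmax)
    if cand.size == 0:
        return []
    order = np.argsort(lam.ravel()[cand])[::-1]
    cand = cand[order[:n_max]]
    ys, xs = np.unravel_index(cand, lam.shape)
    return [(float(x), float(y)) for x, y in zip(xs, ys)]


def _sample(frame: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(frame, [ys, xs], order=1, mode="nearest")


def lk_step(
    prev: np.ndarray,
    nxt: np.ndarray,
    p: Sequence[float],
    params: LKParams | None = None,
) -> tuple[tuple[float, float], str]:
    """One-point LK displacement from ``prev`` to ``nxt``.

    Returns ``((dx, dy), status)`` with status in
    ``converged | max_iter | degenerate | out_of_bounds``.
    """
    params = params or LKParams()
    h, w = prev.shape
    x0, y0 = float(p[0]), float(p[1])
    win = params.window
    if not (win <= x0 <= w - 1 - win and win <= y0 <= h - 1 - win):
        return (0.0, 0.0), "out_of_bounds"

    # window sample coordinates around the (possibly subpixel) point
    dy, dx = np.mgrid[-win:win + 1, -win:win + 1].astype(np.float64)
    wy = y0 + dy.ravel()
    wx = x0 + dx.ravel()

    gx_f, gy_f = _gradients(prev)
    gx = _sample(gx_f, wy, wx)
    gy = _sample(gy_f, wy, wx)
    i0 = _sample(prev, wy, wx)

    gxx = np.dot(gx, gx)
    gyy = np.dot(gy, gy)
    gxy = np.dot(gx, gy)
    tr = gxx + gyy
    lam_small = tr / 2 - np.sqrt(((gxx - gyy) / 2) ** 2 + gxy**2)
    if lam_small < params.lam_min:
        return (0.0, 0.0), "degenerate"
    det = gxx * gyy - gxy**2

    vx = vy = 0.0
    status = "max_iter"
    for _ in range(params.max_iter):
        # the warped window must stay fully inside the frame
        if not (win <= x0 + vx <= w - 1 - win
                and win <= y0 + vy <= h - 1 - win):
            return (vx, vy), "out_of_bounds"
        it = _sample(nxt, wy + vy, wx + vx) - i0
        bx = -np.dot(gx, it)
        by = -np.dot(gy, it)
        dvx = (gyy * bx - gxy * by) / det
        dvy = (gxx * by - gxy * bx) / det
        vx += dvx
        vy += dvy
        if np.hypot(dvx, dvy) < params.conv_tol:
            status = "converged"
            break
    if np.hypot(vx, vy) > params.v_max:
        return (vx, vy), "degenerate"
    return (vx, vy), status


def track_lk(
    stack: FrameStack, params: LKParams | None = None, n_max: int = 200
) -> list[DotTrack]:
    """Track good features across the stack with per-transition LK steps.

    Features are seeded on frame 0 and re-seeded every
    ``reseed_every`` frames (at positions not already occupied) to
    keep dot counts steady; a track is truncated when its step turns
    degenerate or leaves the frame.  Near-stationary tracks are
    suppressed like in the p-flow extractor.
    """
    params = params or LKParams()
    stack.validate_for_motion()
    T = stack.n_frames
    finished: list[DotTrack] = []
    active: list[dict] = []

    def _seed(frame_idx: int) -> None:
        pts = good_features(stack.frames[frame_idx], params, n_max)
        occupied = [(tr["pos"][-1]) for tr in active]
        for x, y in pts:
            if any(np.hypot(x - ox, y - oy) <= params.window
                   for ox, oy in occupied):
                continue
            active.append({"start": frame_idx, "pos": [(x, y)]})

    _seed(0)
    for t in range(T - 1):
        if params.reseed_every and t > 0 and t % params.reseed_every == 0:
            _seed(t)
        prev, nxt = stack.frames[t], stack.frames[t + 1]
        still = []
        for tr in active:
            x, y = tr["pos"][-1]
            (dx, dy), status = lk_step(prev, nxt, (x, y), params)
            if status in ("converged", "max_iter"):
                tr["pos"].append((x + dx, y + dy))
                still.append(tr)
            else:
                finished.append(tr)
        active = still
    finished.extend(active)

    tracks = []
    for tr in finished:
        pos = np.asarray(tr["pos"], dtype=np.float64)
        if len(pos) < 2:
            continue
        mean_speed = np.linalg.norm(np.diff(pos, axis=0), axis=1).mean()
        if mean_speed < params.min_speed:
            continue
        tracks.append(DotTrack(positions=pos, start_frame=tr["start"],
                               algorithm="lk", score=1.0))
    tracks.sort(key=lambda tr: (tr.start_frame, -tr.score))
    return tracks


def match_dot_counts(
    a: Sequence[DotTrack],
    b: Sequence[DotTrack],
    rng_seed: int = 0,
) -> tuple[list[DotTrack], list[DotTrack]]:
    """Equalize motion energy between two track sets by dot count.

    The set with the larger per-frame mean active-dot count is randomly
    subsampled (whole tracks, seeded) until the means differ by at most
    one dot; the number of moving dots approximates motion energy, so
    this makes the two point-light displays energetically comparable.
    """
    a, b = list(a), list(b)
    if not a or not b:
        return a, b
    T = max(tr.start_frame + len(tr) for tr in [*a, *b])

    def mean_count(tracks: Sequence[DotTrack]) -> float:
        return per_frame_counts(tracks, T).mean()

    ma, mb = mean_count(a), mean_count(b)
    if abs(ma - mb) <= 1.0:
        return a, b
    big, small, m_small = (a, b, mb) if ma > mb else (b, a, ma)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(big))
    chosen: list[DotTrack] = []
    total = 0.0
    target = m_small * T
    for i in order:
        L = len(big[i])
        if total + L > target:
            continue
        chosen.append(big[i])
        total += L
    chosen.sort(key=lambda tr: (tr.start_frame, -tr.score))
    if ma > mb:
        return chosen, small
    return small, chosen


# re-export used by the comparison pipeline
__all__.append("subsample_tracks")
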