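"""Ground-truth synthetic scenes for flow benchmarking.

Each generator returns a :class:`GroundTruthScene`: a frame stack plus
the true per-pixel velocity for every frame transition.  The velocity
convention is the displacement of image content, so frame ``t+1`` is
frame ``t`` warped forward by ``velocity[t]`` (equivalently, frame
``t+1`` sampled at ``x - v`` reproduces frame ``t``'s content).

The fluid scene is a statistical stand-in for physically simulated
liquid movies: a divergence-free velocity field derived from a smoothed
stream function advects a noise texture.  Its spatial smoothness
parameter plays the role of viscosity — smoother fields deform the
texture more coherently, the cue structure viscosity ratings rely on.
It is a rank-order proxy only; no mapping to physical Pa·s is defined.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .media_io import FrameStack

__all__ = [
    "GroundTruthScene",
    "make_texture",
    "translate_scene",
    "rotate_scene",
    "grating_scene",
    "fluid_scene",
    "warp_frame",
]


@dataclasses.dataclass
class GroundTruthScene:
    """A frame stack with known per-pixel velocity.

    Attributes
    ----------
    stack : FrameStack
        The rendered frames.
    velocity : ndarray, shape (T-1, H, W, 2)
        True (vx, vy) in px/frame for each transition t -> t+1.
    kind : str
        One of ``translate | rotate | grating | fluid``.
    params : dict
        Generator parameters, including any rng seed.
    """

    stack: FrameStack
    velocity: np.ndarray
    kind: str
    params: dict

    def __post_init__(self) -> None:
        t, h, w = self.stack.shape
        if self.velocity.shape != (t - 1, h, w, 2):
            raise ValueError(
                f"velocity shape {self.velocity.shape} does not match "
                f"stack ({t - 1}, {h}, {w}, 2)"
            )


def make_texture(
    height: int, width: int, correlation_length: float = 1.0, rng_seed: int = 0
) -> np.ndarray:
    """Gaussian-correlated noise texture, normalized to [0, 1].

    ``correlation_length`` sets the spatial scale of the texture: white
    noise is smoothed with a Gaussian of sigma = correlation_length / 2
    (so the autocorrelation at lag = correlation_length stays high).
    ``correlation_length = 0`` yields unfiltered white noise.  The
    default of 1 px gives fine-grained texture whose gradients
    decorrelate within about a pixel — the regime in which
    gradient-vector matching is informative (coarser texture leaves
    the normal flow aperture-ambiguous almost everywhere).
    """
    if correlation_length < 0:
        raise ValueError("correlation_length must be >= 0")
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal((height, width))
    if correlation_length > 0:
        noise = ndimage.gaussian_filter(noise, sigma=correlation_length / 2.0,
                                        mode="wrap")
    lo, hi = noise.min(), noise.max()
    if hi - lo < 1e-12:
        return np.full_like(noise, 0.5)
    return (noise - lo) / (hi - lo)


def _fourier_shift(frame: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Subpixel wrap-around shift of a 2-D frame by (dx, dy)."""
    dx, dy = shift
    f = np.fft.fft2(frame)
    shifted = ndimage.fourier_shift(f, (dy, dx))
    return np.real(np.fft.ifft2(shifted))


def warp_frame(frame: np.ndarray, velocity: np.ndarray,
               mode: str = "wrap") -> np.ndarray:
    """Warp a frame forward by a velocity field (semi-Lagrangian).

    Returns the frame whose value at x equals ``frame`` sampled at
    ``x - velocity(x)`` (bilinear), i.e. content moved by +v.
    """
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    src_x = xx - velocity[..., 0]
    src_y = yy - velocity[..., 1]
    if mode == "wrap":  # true periodic boundaries
        mode = "grid-wrap"
    return ndimage.map_coordinates(frame, [src_y, src_x], order=1, mode=mode)


def translate_scene(
    texture: np.ndarray, v: tuple[float, float], T: int, frame_rate: float = 30.0
) -> GroundTruthScene:
    """Rigid translation at constant (vx, vy) px/frame with wrap-around.

    Speeds are limited to 3 px/frame (the desk-scale motion regime all
    extractors here are parameterized for).
    """
    vx, vy = float(v[0]), float(v[1])
    if np.hypot(vx, vy) > 3.0:
        raise ValueError("translation speed must be <= 3 px/frame")
    h, w = texture.shape
    frames = np.empty((T, h, w))
    integer = float(vx).is_integer() and float(vy).is_integer()
    for t in range(T):
        if integer:
            frames[t] = np.roll(texture, (int(round(vy * t)), int(round(vx * t))),
                                axis=(0, 1))
        else:
            frames[t] = _fourier_shift(texture, (vx * t, vy * t))
    frames = np.clip(frames, 0.0, 1.0)
    velocity = np.broadcast_to(
        np.array([vx, vy]), (T - 1, h, w, 2)
    ).copy()
    stack = FrameStack(frames, frame_rate=frame_rate, provenance="synthetic:translate")
    return GroundTruthScene(stack, velocity, "translate", {"v": (vx, vy), "T": T})


def rotate_scene(
    texture: np.ndarray, omega: float, T: int, frame_rate: float = 30.0
) -> GroundTruthScene:
    """Rigid rotation about the frame center at ``omega`` rad/frame.

    The velocity at radius r is tangential with magnitude omega * r.
    Frames outside the source extent are zero-padded; evaluation should
    stay in the interior.
    """
    h, w = texture.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rim = np.hypot(max(cx, w - 1 - cx), max(cy, h - 1 - cy))
    if abs(omega) * rim > 3.0 + 1e-9:
        raise ValueError("rim speed must be <= 3 px/frame")
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    frames = np.empty((T, h, w))
    for t in range(T):
        # rotate the original texture by the cumulative angle (no error
        # accumulation across frames)
        a = omega * t
        ca, sa = np.cos(a), np.sin(a)
        # inverse map: source coords of each output pixel
        sx = ca * (xx - cx) + sa * (yy - cy) + cx
        sy = -sa * (xx - cx) + ca * (yy - cy) + cy
        frames[t] = ndimage.map_coordinates(texture, [sy, sx], order=1,
                                            mode="constant", cval=0.0)
    # forward motion of content at (x, y): d/dt of the rotation map
    vx = -omega * (yy - cy)
    vy = omega * (xx - cx)
    velocity = np.broadcast_to(
        np.stack([vx, vy], axis=-1), (T - 1, h, w, 2)
    ).copy()
    stack = FrameStack(np.clip(frames, 0, 1), frame_rate=frame_rate,
                       provenance="synthetic:rotate")
    return GroundTruthScene(stack, velocity, "rotate", {"omega": omega, "T": T})


def grating_scene(
    height: int,
    width: int,
    f: float,
    orientation: float,
    speed: float,
    T: int,
    frame_rate: float = 30.0,
) -> GroundTruthScene:
    """A drifting sinusoidal grating — the aperture-problem probe.

    ``f`` is spatial frequency in cycles/px, ``orientation`` the
    gradient axis in degrees (0 = gradient along x, i.e. vertical
    bars), ``speed`` the drift in px/frame along the gradient axis.
    Motion orthogonal to the gradient axis is unobservable by
    construction; the stored truth is the drift along the gradient.
    """
    if not 0 < f < 0.5:
        raise ValueError("f must be in (0, 0.5) cycles/px")
    th = np.deg2rad(orientation)
    ux, uy = np.cos(th), np.sin(th)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    u = xx * ux + yy * uy
    frames = np.empty((T, height, width))
    for t in range(T):
        frames[t] = 0.5 + 0.5 * np.sin(2 * np.pi * f * (u - speed * t))
    velocity = np.broadcast_to(
        np.array([speed * ux, speed * uy]), (T - 1, height, width, 2)
    ).copy()
    stack = FrameStack(frames, frame_rate=frame_rate, provenance="synthetic:grating")
    return GroundTruthScene(
        stack, velocity, "grating",
        {"f": f, "orientation": orientation, "speed": speed, "T": T},
    )


def fluid_scene(
    height: int,
    width: int,
    T: int,
    smoothness: float = 10.0,
    speed_scale: float = 1.0,
    temporal_corr: float = 0.95,
    rng_seed: int = 0,
    frame_rate: float = 30.0,
) -> GroundTruthScene:
    """Nonrigid advected-noise scene with a viscosity-like smoothness knob.

    A scalar stream function psi per transition is built from temporally
    AR(1)-correlated white noise smoothed with a spatial Gaussian of
    scale ``smoothness``; the velocity is its curl,
    ``v = (d psi/dy, -d psi/dx)``, so the discrete divergence (central
    differences) vanishes identically.  The field is rescaled so the RMS
    speed equals ``speed_scale`` and a noise texture is advected by
    semi-Lagrangian backtracing with wrap-around.

    Higher ``smoothness`` gives spatially smoother, more slowly varying
    deformation at the same RMS speed — a rank-order proxy for higher
    simulated viscosity.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    rng = np.random.default_rng(rng_seed)
    texture = make_texture(height, width, correlation_length=2.0,
                           rng_seed=int(rng.integers(2**31)))
    rho = float(temporal_corr)
    state = rng.standard_normal((height, width))
    frames = np.empty((T, height, width))
    frames[0] = texture
    velocity = np.empty((T - 1, height, width, 2))
    for t in range(T - 1):
        psi = ndimage.gaussian_filter(state, sigma=smoothness, mode="wrap")
        # curl of the stream function: central differences commute, so
        # div v = d2psi/dxdy - d2psi/dydx = 0 exactly on the grid
        dpsi_dy, dpsi_dx = np.gradient(psi)
        vx, vy = dpsi_dy, -dpsi_dx
        rms = np.sqrt(np.mean(vx**2 + vy**2))
        if rms > 1e-15:
            vx *= speed_scale / rms
            vy *= speed_scale / rms
        velocity[t, ..., 0] = vx
        velocity[t, ..., 1] = vy
        frames[t + 1] = warp_frame(frames[t], velocity[t], mode="wrap")
        state = rho * state + np.sqrt(1 - rho**2) * rng.standard_normal(
            (height, width))
    stack = FrameStack(np.clip(frames, 0, 1), frame_rate=frame_rate,
                       provenance="synthetic:fluid")
    return GroundTruthScene(
        stack, velocity, "fluid",
        {"smoothness": smoothness, "speed_scale": speed_scale,
         "temporal_corr": rho, "rng_seed": rng_seed},
    )
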