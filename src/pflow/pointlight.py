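"""Point-light display rendering.

Renders dot tracks as movies containing nothing but moving dots — the
stimulus format in which extracted motion is presented to observers.
Dots are anti-aliased discs (area-coverage weighting at the rim), so
subpixel positions survive a render/detect round trip to well under a
pixel.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .media_io import FrameStack
from .pflow_core import DotTrack

__all__ = ["RenderSpec", "render_dots", "detect_dot_centroids"]


@dataclasses.dataclass
class RenderSpec:
    """Geometry and contrast of a point-light display."""

    height: int = 128
    width: int = 128
    dot_radius: float = 2.0
    dot_value: float = 1.0
    background_value: float = 0.0
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.dot_radius < 1:
            raise ValueError("dot_radius must be >= 1")
        if self.dot_value == self.background_value:
            raise ValueError("dot_value must differ from background_value")


def _stamp(frame: np.ndarray, x: float, y: float, spec: RenderSpec) -> None:
    """Draw one anti-aliased disc in place (coverage alpha at the rim)."""
    h, w = frame.shape
    r = spec.dot_radius
    x0, x1 = int(np.floor(x - r - 1)), int(np.ceil(x + r + 1))
    y0, y1 = int(np.floor(y - r - 1)), int(np.ceil(y + r + 1))
    x0, x1 = max(x0, 0), min(x1, w - 1)
    y0, y1 = max(y0, 0), min(y1, h - 1)
    if x0 > x1 or y0 > y1:
        return  # entirely outside: silently clipped
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    dist = np.hypot(xx - x, yy - y)
    alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)
    patch = frame[y0:y1 + 1, x0:x1 + 1]
    target = patch * (1 - alpha) + spec.dot_value * alpha
    # dots may overlap; keep the stronger coverage
    if spec.dot_value >= spec.background_value:
        np.maximum(patch, target, out=patch)
    else:
        np.minimum(patch, target, out=patch)


def render_dots(
    tracks: Sequence[DotTrack], spec: RenderSpec, T: int
) -> FrameStack:
    """Render tracks as a point-light movie of ``T`` frames."""
    if T < 1:
        raise ValueError("T must be >= 1")
    frames = np.full((T, spec.height, spec.width), spec.background_value,
                     dtype=np.float64)
    for tr in tracks:
        for k, (x, y) in enumerate(tr.positions):
            t = tr.start_frame + k
            if 0 <= t < T:
                _stamp(frames[t], float(x), float(y), spec)
    return FrameStack(np.clip(frames, 0.0, 1.0), frame_rate=spec.frame_rate,
                      provenance="pointlight")


def detect_dot_centroids(
    stack: FrameStack, spec: RenderSpec
) -> list[tuple[int, float, float]]:
    """Recover dot positions from a rendered display (test oracle).

    Pixels beyond half contrast are grouped into connected components
    and reduced to intensity-weighted centroids; returns
    ``(frame, x, y)`` triples.
    """
    thresh = (spec.dot_value + spec.background_value) / 2.0
    bright = spec.dot_value > spec.background_value
    out: list[tuple[int, float, float]] = []
    for t, frame in enumerate(stack.frames):
        mask = frame > thresh if bright else frame < thresh
        labels, n = ndimage.label(mask)
        if n == 0:
            continue
        weight = np.abs(frame - spec.background_value)
        for cy, cx in ndimage.center_of_mass(weight, labels, range(1, n + 1)):
            out.append((t, float(cx), float(cy)))
    return out
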