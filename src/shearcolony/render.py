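"""Render colony histories into grayscale time-lapse stacks.

Cells are drawn as anti-aliased capsules (rectangles with semicircular
caps) spanning their two poles, darker than the background by default —
emulating background-subtracted phase contrast.  A Gaussian blur stands in
for the optical transfer function and additive Gaussian noise for the
camera; with probability ``flicker_prob`` a cell is omitted from a frame
while persisting in the ground truth, reproducing the detection flicker
that trajectory linking must bridge.  Halos, mosaics and focus drift are
deliberately not modeled: the rendered stacks exist to exercise the
segmentation/tracking pipeline against exact ground truth, not to imitate
optics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from shearcolony.colony import ColonyHistory

__all__ = ["OpticsConfig", "FrameStack", "render_frames", "OutOfFieldError"]


@dataclass(frozen=True)
class OpticsConfig:
    """Rendering parameters.

    ``pixel_size`` in um/px (0.1 um/px corresponds to a pixel area of
    0.01 um^2); intensities in 16-bit camera counts; ``blur_sigma`` in
    pixels.  ``cell_contrast`` may be negative to render bright cells.
    ``frame_interval`` is carried as metadata (minutes in growth mode).
    """

    pixel_size: float = 0.1
    image_shape: tuple[int, int] | None = None   # (rows, cols); None = fit
    margin: float = 10.0                         # um of field beyond the domain
    background_level: float = 30000.0
    cell_contrast: float = 12000.0
    noise_sd: float = 300.0
    blur_sigma: float = 1.0
    flicker_prob: float = 0.0
    frame_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.flicker_prob < 1.0:
            raise ValueError("flicker_prob must be in [0, 1)")
        if self.image_shape is not None and min(self.image_shape) <= 0:
            raise ValueError("image_shape must be positive")


@dataclass
class FrameStack:
    """Rendered image stack plus the optics metadata used to produce it."""

    frames: np.ndarray           # (n_frames, rows, cols), uint16
    optics: OpticsConfig
    times: np.ndarray            # minutes

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def render_blank_frames(optics: OpticsConfig, shape: tuple[int, int],
                        n_frames: int = 10, seed: int | None = None,
                        ) -> np.ndarray:
    """Cell-free frames with the same background, blur and noise statistics.

    Used to build a background model when the movie itself contains cells
    from the first frame onward (a real acquisition starts nearly empty;
    the simulator does not).
    """
    rng = np.random.default_rng(optics.seed + 1 if seed is None else seed)
    frames = np.empty((n_frames, *shape), dtype=np.uint16)
    for i in range(n_frames):
        img = np.full(shape, optics.background_level, dtype=float)
        if optics.noise_sd > 0:
            img = img + rng.normal(0.0, optics.noise_sd, shape)
        frames[i] = np.clip(img, 0, 65535).astype(np.uint16)
    return frames


class OutOfFieldError(ValueError):
    def __init__(self, agent_ids):
        self.agent_ids = sorted(set(int(a) for a in agent_ids))
        super().__init__(
            f"cells outside the field of view: agents {self.agent_ids}")


def _draw_capsule(img: np.ndarray, pa, pb, half_width_px: float) -> None:
    """Add an anti-aliased capsule (coverage in [0, 1]) to ``img`` in place.

    ``pa``/``pb`` are the cell poles (the extreme points of the outline);
    the capsule's core segment is contracted by half a width at each end so
    the drawn shape spans exactly pole to pole.  Coverage ramps linearly
    from 1 to 0 over one pixel at the boundary, approximating area
    sampling.
    """
    axis = pb - pa
    norm = float(np.hypot(*axis))
    if norm > 2 * half_width_px:
        u = axis / norm
        pa = pa + half_width_px * u
        pb = pb - half_width_px * u
    else:
        mid = 0.5 * (pa + pb)
        pa = pb = mid
    rows, cols = img.shape
    pad = int(np.ceil(half_width_px)) + 2
    r0 = max(int(min(pa[0], pb[0])) - pad, 0)
    r1 = min(int(max(pa[0], pb[0])) + pad + 1, rows)
    c0 = max(int(min(pa[1], pb[1])) - pad, 0)
    c1 = min(int(max(pa[1], pb[1])) + pad + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    p = np.stack([rr, cc], axis=-1).astype(float)
    d = pb - pa
    denom = float(d @ d)
    if denom < 1e-12:
        dist = np.linalg.norm(p - pa, axis=-1)
    else:
        t = np.clip(((p - pa) @ d) / denom, 0.0, 1.0)
        closest = pa + t[..., None] * d
        dist = np.linalg.norm(p - closest, axis=-1)
    coverage = np.clip(half_width_px + 0.5 - dist, 0.0, 1.0)
    region = img[r0:r1, c0:c1]
    np.maximum(region, coverage, out=region)


def render_frames(history: ColonyHistory, optics: OpticsConfig,
                  ) -> tuple[FrameStack, pd.DataFrame]:
    """Render a history and return the stack plus an exact ground-truth table.

    The ground truth carries one row per (frame, attached agent) with
    centroid, poles, length (um) and an ``omitted`` flag for cells dropped
    from that frame by flicker.  Raises :class:`OutOfFieldError` listing
    the offending agents if any cell pole falls outside the field of view.
    """
    px = optics.pixel_size
    m = optics.margin
    states = history.states
    if optics.image_shape is None:
        wx, wy = history.config.domain_size
        shape = (int(np.ceil((wy + 2 * m) / px)) + 1,
                 int(np.ceil((wx + 2 * m) / px)) + 1)
    else:
        shape = tuple(optics.image_shape)
    rows, cols = shape

    # x (um) maps to columns, y to rows; the image origin sits ``margin``
    # um outside the simulation domain so growing colonies stay in field.
    # Image coordinates are therefore world coordinates + margin.
    def to_px(x, y):
        return np.stack([(np.asarray(y) + m) / px,
                         (np.asarray(x) + m) / px], axis=-1)

    if len(states):
        pts = np.concatenate([
            to_px(states["pole_ax"], states["pole_ay"]),
            to_px(states["pole_bx"], states["pole_by"])])
        bad = (pts[:, 0] < 0) | (pts[:, 0] > rows - 1) \
            | (pts[:, 1] < 0) | (pts[:, 1] > cols - 1)
        if bad.any():
            ids = np.concatenate([states["agent_id"].to_numpy()] * 2)[bad]
            raise OutOfFieldError(ids)

    rng = np.random.default_rng(optics.seed)
    half_w = 0.5 * history.config.cell_width / px
    frames = np.empty((len(history.times), rows, cols), dtype=np.uint16)
    gt_rows = []
    by_frame = dict(iter(states.groupby("frame"))) if len(states) else {}

    for fi, t in enumerate(history.times):
        coverage = np.zeros((rows, cols))
        g = by_frame.get(fi)
        if g is not None:
            omitted = rng.random(len(g)) < optics.flicker_prob
            for k, (_, row) in enumerate(g.iterrows()):
                gt_rows.append((fi, t, int(row.agent_id), row.x, row.y,
                                row.pole_ax, row.pole_ay, row.pole_bx,
                                row.pole_by, row.length, bool(omitted[k])))
                if omitted[k]:
                    continue
                pa = np.array([(row.pole_ay + m) / px, (row.pole_ax + m) / px])
                pb = np.array([(row.pole_by + m) / px, (row.pole_bx + m) / px])
                _draw_capsule(coverage, pa, pb, half_w)
        img = optics.background_level - optics.cell_contrast * coverage
        if optics.blur_sigma > 0:
            img = gaussian_filter(img, optics.blur_sigma)
        if optics.noise_sd > 0:
            img = img + rng.normal(0.0, optics.noise_sd, img.shape)
        frames[fi] = np.clip(img, 0, 65535).astype(np.uint16)

    ground_truth = pd.DataFrame(
        gt_rows, columns=["frame", "time", "agent_id", "x", "y", "pole_ax",
                          "pole_ay", "pole_bx", "pole_by", "length",
                          "omitted"])
    stack = FrameStack(frames=frames, optics=optics,
                       times=np.asarray(history.times, dtype=float))
    return stack, ground_truth
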