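"""Silhouette and pixel-matched ellipse stimuli.

The silhouette connects the three digitized joints of each leg into a
thick stroke and adds two body ellipses (cephalothorax and opisthosoma)
anchored edge-on at the picture center and tilted toward the eyes and
spinneret dots.  The ellipse stimulus is a single axis-aligned ellipse,
centered on the shared stimulus center, whose rasterized black-pixel count
matches the silhouette's frame by frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .displays import DotDisplay
from .tracks import JointTrackSet, LEG_POINT_ROLES, center_path_of

logger = logging.getLogger(__name__)

SHAPE_KINDS = ("silhouette", "ellipse")


@dataclass(frozen=True)
class BodySpec:
    """Shape parameters for the two body segments and leg strokes (pixels)."""

    ceph_length_px: float = 60.0
    ceph_width_px: float = 40.0
    opi_length_px: float = 80.0
    opi_width_px: float = 38.0
    stroke_width_px: float = 3.0


@dataclass
class Ellipse:
    """Axis semi-lengths ``a`` (along ``angle``) and ``b``, center in local px."""

    center: np.ndarray
    a: float
    b: float
    angle: float = 0.0


@dataclass
class FrameShapes:
    """Vector geometry of one display frame: stroked polylines + ellipses."""

    segments: list[tuple[np.ndarray, np.ndarray, float]] = field(default_factory=list)
    ellipses: list[Ellipse] = field(default_factory=list)


@dataclass
class ShapeDisplay:
    """Per-frame vector shapes of a silhouette or ellipse stimulus."""

    kind: str
    frames: list[FrameShapes]
    center_path: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"kind must be one of {SHAPE_KINDS}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def mirrored(self) -> "ShapeDisplay":
        frames = []
        for fr in self.frames:
            segs = [
                (p0 * np.array([-1.0, 1.0]), p1 * np.array([-1.0, 1.0]), w)
                for p0, p1, w in fr.segments
            ]
            ells = [
                Ellipse(center=e.center * np.array([-1.0, 1.0]), a=e.a, b=e.b, angle=np.pi - e.angle)
                for e in fr.ellipses
            ]
            frames.append(FrameShapes(segments=segs, ellipses=ells))
        cp = self.center_path.copy()
        cp[:, 0] *= -1
        return ShapeDisplay(kind=self.kind, frames=frames, center_path=cp)


def make_silhouette(tracks: JointTrackSet, body: BodySpec | None = None) -> ShapeDisplay:
    """Connect same-leg joints into thick strokes and add tilted body shapes.

    Legs with fewer than two visible joints in a frame degrade to the
    available segment (or nothing), with a log entry.  Each body ellipse has
    one end anchored at the per-frame stimulus center and extends toward the
    eyes (cephalothorax) or spinneret (opisthosoma) dot.
    """
    body = body or BodySpec()
    center = center_path_of(tracks)
    legs = sorted({lid for lid in tracks.leg_ids if lid is not None})
    role_rank = {role: i for i, role in enumerate(LEG_POINT_ROLES)}

    def leg_point_indices(lid: int) -> list[int]:
        idx = [i for i, l in enumerate(tracks.leg_ids) if l == lid]
        # proximal-to-distal order when labels carry a known role suffix
        def rank(i: int) -> int:
            for role, r in role_rank.items():
                if role in tracks.labels[i]:
                    return r
            return len(role_rank)
        return sorted(idx, key=rank)

    try:
        i_eyes = tracks.labels.index("eyes")
        i_spin = tracks.labels.index("spinneret")
    except ValueError as exc:
        raise ValueError("silhouette needs 'eyes' and 'spinneret' body points") from exc

    filled = tracks.filled_positions()
    frames: list[FrameShapes] = []
    for f in range(tracks.n_frames):
        fs = FrameShapes()
        for lid in legs:
            idx = leg_point_indices(lid)
            pts = [tracks.positions[f, i] for i in idx if tracks.visible[f, i]]
            if len(pts) < 2:
                logger.debug("leg %s frame %d: <2 visible joints, degraded", lid, f)
            for p0, p1 in zip(pts[:-1], pts[1:]):
                fs.segments.append((np.asarray(p0, float), np.asarray(p1, float), body.stroke_width_px))
        c = center[f]
        for target, length, width in (
            (filled[f, i_eyes], body.ceph_length_px, body.ceph_width_px),
            (filled[f, i_spin], body.opi_length_px, body.opi_width_px),
        ):
            d = np.asarray(target, float) - c
            angle = float(np.arctan2(d[1], d[0])) if np.linalg.norm(d) > 0 else 0.0
            u = np.array([np.cos(angle), np.sin(angle)])
            fs.ellipses.append(Ellipse(center=c + u * length / 2, a=length / 2, b=width / 2, angle=angle))
        frames.append(fs)
    return ShapeDisplay(kind="silhouette", frames=frames, center_path=center)


# ---------------------------------------------------------------------------
# rasterization (pixel centers at integer coordinates, half rounded away
# from zero when a window is derived from float bounds)


def _raster_window(fr: FrameShapes, pad: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p0, p1, w in fr.segments:
        for p in (p0, p1):
            xs.extend([p[0] - w, p[0] + w])
            ys.extend([p[1] - w, p[1] + w])
    for e in fr.ellipses:
        r = max(e.a, e.b)
        xs.extend([e.center[0] - r, e.center[0] + r])
        ys.extend([e.center[1] - r, e.center[1] + r])
    if not xs:
        return np.arange(0), np.arange(0)
    lo = np.floor(min(xs) - pad)
    hi = np.ceil(max(xs) + pad)
    lo_y = np.floor(min(ys) - pad)
    hi_y = np.ceil(max(ys) + pad)
    return np.arange(lo, hi + 1), np.arange(lo_y, hi_y + 1)


def rasterize_frame(fr: FrameShapes) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Boolean black-pixel mask of one frame on an integer pixel grid.

    A pixel is black when its center lies inside any round-capped stroke
    (distance to the segment <= width/2) or inside any ellipse.
    Returns the mask (shape ``(len(ys), len(xs))``) and the grid axes.
    """
    xs, ys = _raster_window(fr)
    if xs.size == 0:
        return np.zeros((0, 0), dtype=bool), (xs, ys)
    gx, gy = np.meshgrid(xs, ys)
    mask = np.zeros(gx.shape, dtype=bool)
    for p0, p1, w in fr.segments:
        d = _dist_to_segment(gx, gy, p0, p1)
        mask |= d <= w / 2
    for e in fr.ellipses:
        dx, dy = gx - e.center[0], gy - e.center[1]
        ca, sa = np.cos(e.angle), np.sin(e.angle)
        u = dx * ca + dy * sa
        v = -dx * sa + dy * ca
        if e.a > 0 and e.b > 0:
            mask |= (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
    return mask, (xs, ys)


def _dist_to_segment(gx: np.ndarray, gy: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0.0:
        return np.hypot(gx - p0[0], gy - p0[1])
    t = np.clip(((gx - p0[0]) * v[0] + (gy - p0[1]) * v[1]) / vv, 0.0, 1.0)
    return np.hypot(gx - (p0[0] + t * v[0]), gy - (p0[1] + t * v[1]))


def pixel_count(fr: FrameShapes) -> int:
    """Number of black pixels in the rasterized frame."""
    mask, _ = rasterize_frame(fr)
    return int(mask.sum())


def make_ellipse(
    silhouette: ShapeDisplay,
    aspect: float = 170.0 / 60.0,
    tolerance: float = 0.01,
    max_iter: int = 40,
) -> ShapeDisplay:
    """Single ellipse per frame matching the silhouette's black-pixel count.

    The ellipse is axis-aligned, centered on the shared center trajectory,
    with fixed ``aspect`` (= a/b); the semi-axes are solved per frame from
    the target area and refined by bisection on a size factor until the
    rasterized count is within ``tolerance`` (relative) of the silhouette's.
    """
    if silhouette.kind != "silhouette":
        raise ValueError("make_ellipse expects a silhouette display")
    frames: list[FrameShapes] = []
    for f, fr in enumerate(silhouette.frames):
        target = pixel_count(fr)
        c = silhouette.center_path[f]
        if target == 0:
            frames.append(FrameShapes(ellipses=[Ellipse(center=c.copy(), a=0.0, b=0.0)]))
            continue
        b0 = float(np.sqrt(target / (np.pi * aspect)))

        def count_at(s: float) -> int:
            return pixel_count(
                FrameShapes(ellipses=[Ellipse(center=c.copy(), a=aspect * b0 * s, b=b0 * s)])
            )

        lo, hi = 0.5, 2.0
        while count_at(lo) > target:
            lo *= 0.5
        while count_at(hi) < target:
            hi *= 1.5
        best_s, best_err = 1.0, abs(count_at(1.0) - target)
        for _ in range(max_iter):
            mid = (lo + hi) / 2
            n = count_at(mid)
            err = abs(n - target)
            if err < best_err:
                best_s, best_err = mid, err
            if err == 0 or hi - lo < 1e-9:
                break
            if n < target:
                lo = mid
            else:
                hi = mid
        if best_err > tolerance * target:
            logger.warning(
                "frame pixel match off by %.2f%% (target %d)", 100 * best_err / target, target
            )
        frames.append(
            FrameShapes(ellipses=[Ellipse(center=c.copy(), a=aspect * b0 * best_s, b=b0 * best_s)])
        )
    return ShapeDisplay(kind="ellipse", frames=frames, center_path=silhouette.center_path.copy())


def silhouette_from_display(display: DotDisplay, tracks: JointTrackSet, body: BodySpec | None = None) -> ShapeDisplay:
    """Convenience: silhouette built from the tracks behind a biological display."""
    if display.kind != "biological":
        raise ValueError("silhouette is defined for the biological display")
    return make_silhouette(tracks, body)
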