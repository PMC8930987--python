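"""Seeded synthetic image patterns for training and probing the imager.

Four families stand in for the public handwriting/object datasets used to
calibrate waveform-to-image decoders, keeping the repository download-free:

* glyphs      - stroke-skeleton "handwritten" characters in up to 36 classes,
                binarised, with per-sample affine jitter;
* strokes     - complex random Bezier-line patterns, optionally expanded by
                shift/rotate/scale augmentation;
* bars        - USAF-1951-style three-bar resolution targets;
* grayscale   - smooth random blobs spanning [0, 1].

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ImagePattern",
    "make_glyphs",
    "make_random_strokes",
    "make_resolution_target",
    "make_grayscale",
]


@dataclass
class ImagePattern:
    """A 2D nonnegative intensity pattern with physical pixel pitch."""

    intensities: np.ndarray  # 2D float array in [0, 1]
    pixel_pitch_um: float = 7.56
    label: int | None = None
    kind: str = "glyph"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError("intensities must be 2D")
        if arr.min() < 0 or arr.max() > 1 + 1e-12:
            raise ValueError("intensities must lie in [0, 1]")
        self.intensities = arr


# --------------------------------------------------------------------------
# glyph templates: polylines in the unit square, one set per class.
# Classes 0-9 are digit-like skeletons; classes 10+ are deterministic
# pseudo-random polylines derived from the class index only, so templates
# are stable across runs and seeds.

_DIGIT_STROKES: dict[int, list[list[tuple[float, float]]]] = {
    0: [[(0.35, 0.2), (0.65, 0.2), (0.75, 0.4), (0.75, 0.6), (0.65, 0.8),
         (0.35, 0.8), (0.25, 0.6), (0.25, 0.4), (0.35, 0.2)]],
    1: [[(0.35, 0.3), (0.5, 0.2), (0.5, 0.8)], [(0.35, 0.8), (0.65, 0.8)]],
    2: [[(0.3, 0.3), (0.45, 0.2), (0.65, 0.25), (0.65, 0.4), (0.3, 0.8), (0.7, 0.8)]],
    3: [[(0.3, 0.25), (0.6, 0.2), (0.7, 0.35), (0.5, 0.5), (0.7, 0.65), (0.6, 0.8), (0.3, 0.75)]],
    4: [[(0.6, 0.8), (0.6, 0.2), (0.25, 0.6), (0.75, 0.6)]],
    5: [[(0.7, 0.2), (0.3, 0.2), (0.3, 0.5), (0.6, 0.45), (0.7, 0.6), (0.6, 0.8), (0.3, 0.8)]],
    6: [[(0.65, 0.2), (0.4, 0.35), (0.3, 0.6), (0.4, 0.8), (0.65, 0.75), (0.65, 0.55), (0.35, 0.55)]],
    7: [[(0.3, 0.2), (0.7, 0.2), (0.45, 0.8)]],
    8: [[(0.5, 0.5), (0.35, 0.4), (0.35, 0.25), (0.5, 0.2), (0.65, 0.25), (0.65, 0.4),
         (0.5, 0.5), (0.35, 0.6), (0.35, 0.75), (0.5, 0.8), (0.65, 0.75), (0.65, 0.6), (0.5, 0.5)]],
    9: [[(0.65, 0.45), (0.35, 0.45), (0.3, 0.3), (0.45, 0.2), (0.65, 0.25), (0.65, 0.45),
         (0.55, 0.8)]],
}


def _class_strokes(class_id: int) -> list[list[tuple[float, float]]]:
    if class_id in _DIGIT_STROKES:
        return _DIGIT_STROKES[class_id]
    # fixed pseudo-random polylines for letter-like classes 10..35
    rng = np.random.default_rng(10_000 + class_id)
    strokes = []
    for _ in range(rng.integers(2, 4)):
        pts = rng.uniform(0.2, 0.8, size=(rng.integers(3, 6), 2))
        strokes.append([tuple(p) for p in pts])
    return strokes


def _rasterize_polylines(
    strokes: list[list[tuple[float, float]]], shape: tuple[int, int], width_px: float = 1.5
) -> np.ndarray:
    """Paint unit-square polylines onto a pixel grid with ~1-2 px line width."""
    rows, cols = shape
    img = np.zeros(shape)
    for pts in strokes:
        pts = np.asarray(pts, dtype=float)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            n = max(int(4 * max(rows, cols) * np.hypot(x1 - x0, y1 - y0)), 2)
            xs = np.linspace(x0, x1, n) * (cols - 1)
            ys = np.linspace(y0, y1, n) * (rows - 1)
            img[np.round(ys).astype(int), np.round(xs).astype(int)] = 1.0
    if width_px > 1:
        img = ndimage.grey_dilation(img, size=(2, 2))
    return img


def _affine_jitter(
    img: np.ndarray,
    rng: np.random.Generator,
    max_scale: float = 0.10,
    max_rot_deg: float = 10.0,
    max_shift_px: float = 2.0,
) -> np.ndarray:
    """Random scale/rotation/shift about the image centre (bilinear)."""
    scale = 1.0 + rng.uniform(-max_scale, max_scale)
    theta = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg))
    shift = rng.uniform(-max_shift_px, max_shift_px, size=2)
    c, s = np.cos(theta), np.sin(theta)
    mat = np.array([[c, -s], [s, c]]) / scale
    centre = (np.asarray(img.shape) - 1) / 2.0
    offset = centre - mat @ (centre + shift)
    return ndimage.affine_transform(img, mat, offset=offset, order=1, mode="constant")


def make_glyphs(
    n: int,
    shape: tuple[int, int] = (28, 28),
    n_classes: int = 10,
    seed: int = 0,
    pixel_pitch_um: float = 7.56,
) -> list[ImagePattern]:
    """Labelled binary glyph images with per-sample affine jitter.

    Each class has a fixed stroke-skeleton template (rendered at 1-2 px
    width); samples apply +/-10% scale, +/-10 deg rotation and +/-2 px shift,
    then binarise at 0.5.
    """
    if n_classes > 36:
        raise ValueError("at most 36 glyph classes are defined")
    if shape[0] < 16 or shape[1] < 16:
        raise ValueError(f"glyph shape must be at least 16x16, got {shape}")
    rng = np.random.default_rng(seed)
    templates = [_rasterize_polylines(_class_strokes(c), shape) for c in range(n_classes)]
    labels = rng.integers(0, n_classes, size=n)
    out = []
    for lab in labels:
        img = _affine_jitter(templates[lab], rng)
        img = (img >= 0.5).astype(float)
        out.append(
            ImagePattern(img, pixel_pitch_um=pixel_pitch_um, label=int(lab), kind="glyph")
        )
    return out


def _bezier(p0, p1, p2, n=64):
    t = np.linspace(0, 1, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def make_random_strokes(
    n: int,
    shape: tuple[int, int] = (40, 40),
    strokes_per_image: tuple[int, int] = (3, 6),
    augment: bool = False,
    n_variants: int = 3,
    seed: int = 0,
    pixel_pitch_um: float = 7.56,
) -> list[ImagePattern]:
    """Complex random-line patterns (quadratic Bezier strokes), binarised.

    With ``augment=True`` each base pattern is additionally emitted under
    ``n_variants`` random shift/rotation/scale transforms, mimicking
    augmentation-expanded training corpora; output size is n*(1+n_variants).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    out = []
    for i in range(n):
        img = np.zeros(shape)
        k = rng.integers(strokes_per_image[0], strokes_per_image[1] + 1)
        for _ in range(k):
            pts = rng.uniform(0.1, 0.9, size=(3, 2))
            curve = _bezier(pts[0], pts[1], pts[2])
            xs = np.clip(np.round(curve[:, 0] * (cols - 1)).astype(int), 0, cols - 1)
            ys = np.clip(np.round(curve[:, 1] * (rows - 1)).astype(int), 0, rows - 1)
            img[ys, xs] = 1.0
        img = ndimage.grey_dilation(img, size=(2, 2))
        base = (img >= 0.5).astype(float)
        out.append(ImagePattern(base, pixel_pitch_um=pixel_pitch_um, kind="strokes",
                                meta={"base_id": i, "variant": 0}))
        if augment:
            for v in range(n_variants):
                aug = _affine_jitter(base, rng, max_scale=0.2, max_rot_deg=25.0,
                                     max_shift_px=0.1 * min(shape))
                aug = (aug >= 0.5).astype(float)
                out.append(ImagePattern(aug, pixel_pitch_um=pixel_pitch_um, kind="strokes",
                                        meta={"base_id": i, "variant": v + 1}))
    return out


def make_resolution_target(
    shape: tuple[int, int] = (40, 40),
    pitches_px: tuple[int, ...] = (6, 4, 2),
    pixel_pitch_um: float = 7.56,
) -> ImagePattern:
    """Three-bar resolution target with groups of descending pitch.

    Each group contains three vertical bars (top half) and three horizontal
    bars (bottom half); bar width is pitch/2 (a 2 px pitch at 7.56 um per
    pixel corresponds to a physical pitch of 15.12 um). Groups are laid out
    left to right in descending pitch. ``meta['groups']`` records, per
    pitch, the bounding boxes of both bar sets for contrast profiling.
    """
    if min(pitches_px) < 2:
        raise ValueError("minimum pitch is 2 px")
    rows, cols = shape
    img = np.zeros(shape)
    groups = []
    x = 1
    for pitch in sorted(pitches_px, reverse=True):
        bar = pitch // 2
        group_w = 3 * bar + 2 * (pitch - bar)
        height = min(3 * pitch, rows // 2 - 2)
        y0 = 1
        y1 = rows // 2 + 1
        if x + group_w >= cols or y1 + 2 * pitch + bar >= rows:
            raise ValueError(
                f"resolution-target layout overflows {shape} at pitch {pitch}px"
            )
        # vertical bars, top half
        for b in range(3):
            x0 = x + b * pitch
            img[y0 : y0 + height, x0 : x0 + bar] = 1.0
        vbox = (y0, x, y0 + height, x + group_w)
        # horizontal bars, bottom half
        for b in range(3):
            yb = y1 + b * pitch
            img[yb : yb + bar, x : x + height] = 1.0
        hbox = (y1, x, y1 + 3 * pitch - (pitch - bar), x + height)
        groups.append(
            {
                "pitch_px": pitch,
                "pitch_um": pitch * pixel_pitch_um,
                "vertical_box": vbox,
                "horizontal_box": hbox,
            }
        )
        x += group_w + 2
    return ImagePattern(
        img, pixel_pitch_um=pixel_pitch_um, kind="bars", meta={"groups": groups}
    )


def make_grayscale(
    n: int,
    shape: tuple[int, int] = (28, 28),
    seed: int = 0,
    pixel_pitch_um: float = 7.56,
) -> list[ImagePattern]:
    """Smooth grayscale blobs: sums of 2-5 Gaussians, min-max normalised."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    out = []
    for _ in range(n):
        img = np.zeros(shape)
        for _ in range(rng.integers(2, 6)):
            cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
            sy, sx = rng.uniform(2, rows / 3), rng.uniform(2, cols / 3)
            amp = rng.uniform(0.3, 1.0)
            img += amp * np.exp(-((yy - cy) ** 2 / (2 * sy**2) + (xx - cx) ** 2 / (2 * sx**2)))
        img -= img.min()
        img /= img.max()
        out.append(ImagePattern(img, pixel_pitch_um=pixel_pitch_um, kind="grayscale"))
    return out
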