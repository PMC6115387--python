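"""Synthetic piecewise-constant phantoms and Dice evaluation.

The generators emulate the geometry this segmentation method targets:
homogeneous regions (intervals, disks, rectangles, C-shapes, ellipsoids,
boxes, shells) of distinct mean intensity on a constant background, with
additive i.i.d. Gaussian noise.  Every phantom carries a ground-truth label
map (background = 1, then one label per listed shape, later shapes
overwriting earlier ones) and is reproducible from its generator seed.

Evaluation follows max-Dice matching: for each ground-truth label the
predicted label with the highest Dice overlap ``2|A∩B| / (|A|+|B|)`` is
reported, and the mean over the evaluated truth labels summarises the
segmentation.  Matching is per truth label (many-to-one allowed) and
invariant to how the prediction numbers its labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Disk",
    "Rectangle",
    "CShape",
    "Ellipsoid",
    "Box",
    "Phantom",
    "DiceReport",
    "make_step_signal",
    "make_phantom_2d",
    "make_phantom_3d",
    "two_disk_phantom",
    "two_ellipsoid_phantom",
    "dice_evaluate",
]


@dataclass(frozen=True)
class Disk:
    center: tuple[float, float]
    radius: float
    intensity: float


@dataclass(frozen=True)
class Rectangle:
    corner: tuple[int, int]  # top-left (row, col)
    size: tuple[int, int]
    intensity: float


@dataclass(frozen=True)
class CShape:
    """Annulus with an angular gap — a deliberately nonconvex region."""

    center: tuple[float, float]
    outer_radius: float
    inner_radius: float
    intensity: float
    gap_halfwidth_deg: float = 35.0  # gap is centered on the +col direction


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float


@dataclass(frozen=True)
class Box:
    corner: tuple[int, int, int]
    size: tuple[int, int, int]
    intensity: float


@dataclass
class Phantom:
    image: np.ndarray
    truth: np.ndarray  # contiguous labels 1..l, background = 1
    description: str


def make_step_signal(
    interval_lengths: Sequence[int],
    interval_values: Sequence[float],
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant 1D signal with one truth group per interval."""
    lengths = [int(x) for x in interval_lengths]
    values = [float(v) for v in interval_values]
    if not lengths or len(lengths) != len(values):
        raise ValueError("need equally many (>=1) interval lengths and values")
    if any(x <= 0 for x in lengths):
        raise ValueError("interval lengths must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    signal = np.repeat(values, lengths).astype(float)
    truth = np.repeat(np.arange(1, len(lengths) + 1), lengths)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("a generator is required when noise_sd > 0")
        signal = signal + rng.normal(0.0, noise_sd, signal.size)
    return signal, truth


def _paint_2d(image, truth, shape, label: int) -> None:
    rows, cols = np.indices(image.shape)
    if isinstance(shape, Disk):
        cr, cc = shape.center
        r = shape.radius
        if cr - r < -0.5 or cc - r < -0.5 or cr + r > image.shape[0] - 0.5 or cc + r > image.shape[1] - 0.5:
            raise ValueError(f"{shape} does not fit inside {image.shape}")
        mask = (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2
    elif isinstance(shape, Rectangle):
        r0, c0 = shape.corner
        h, w = shape.size
        if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
            raise ValueError(f"{shape} does not fit inside {image.shape}")
        mask = (rows >= r0) & (rows < r0 + h) & (cols >= c0) & (cols < c0 + w)
    elif isinstance(shape, CShape):
        cr, cc = shape.center
        ro = shape.outer_radius
        if cr - ro < -0.5 or cc - ro < -0.5 or cr + ro > image.shape[0] - 0.5 or cc + ro > image.shape[1] - 0.5:
            raise ValueError(f"{shape} does not fit inside {image.shape}")
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        ring = (d2 <= ro**2) & (d2 >= shape.inner_radius**2)
        ang = np.degrees(np.arctan2(rows - cr, cols - cc))
        mask = ring & (np.abs(ang) > shape.gap_halfwidth_deg)
    else:
        raise TypeError(f"unsupported 2D primitive {type(shape).__name__}")
    image[mask] = shape.intensity
    truth[mask] = label


def make_phantom_2d(
    shape: tuple[int, int],
    shapes: Iterable = (),
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    background: float = 0.0,
) -> Phantom:
    """2D phantom of disks/rectangles/C-shapes on a constant background."""
    shape = (int(shape[0]), int(shape[1]))
    image = np.full(shape, float(background))
    truth = np.ones(shape, dtype=np.int64)
    shapes = list(shapes)
    for i, s in enumerate(shapes):
        _paint_2d(image, truth, s, label=i + 2)
    # overwritten shapes may leave gaps in the label range
    truth = _compact_labels(truth)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("a generator is required when noise_sd > 0")
        image = image + rng.normal(0.0, noise_sd, image.shape)
    desc = f"phantom2d(shape={shape}, shapes={len(shapes)}, noise_sd={noise_sd})"
    return Phantom(image=image, truth=truth, description=desc)


def _paint_3d(image, truth, shape, label: int) -> None:
    xs = np.indices(image.shape)
    if isinstance(shape, Ellipsoid):
        for c, r, n in zip(shape.center, shape.radii, image.shape):
            if c - r < -0.5 or c + r > n - 0.5:
                raise ValueError(f"{shape} does not fit inside {image.shape}")
        mask = sum(
            ((x - c) / r) ** 2 for x, c, r in zip(xs, shape.center, shape.radii)
        ) <= 1.0
    elif isinstance(shape, Box):
        for c0, s, n in zip(shape.corner, shape.size, image.shape):
            if c0 < 0 or c0 + s > n:
                raise ValueError(f"{shape} does not fit inside {image.shape}")
        mask = np.ones(image.shape, dtype=bool)
        for x, c0, s in zip(xs, shape.corner, shape.size):
            mask &= (x >= c0) & (x < c0 + s)
    else:
        raise TypeError(f"unsupported 3D primitive {type(shape).__name__}")
    image[mask] = shape.intensity
    truth[mask] = label


def make_phantom_3d(
    shape: tuple[int, int, int],
    shapes: Iterable = (),
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    background: float = 0.0,
) -> Phantom:
    """3D phantom of ellipsoids/boxes on a constant background."""
    shape = tuple(int(s) for s in shape)
    image = np.full(shape, float(background))
    truth = np.ones(shape, dtype=np.int64)
    shapes = list(shapes)
    for i, s in enumerate(shapes):
        _paint_3d(image, truth, s, label=i + 2)
    truth = _compact_labels(truth)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("a generator is required when noise_sd > 0")
        image = image + rng.normal(0.0, noise_sd, image.shape)
    desc = f"phantom3d(shape={shape}, shapes={len(shapes)}, noise_sd={noise_sd})"
    return Phantom(image=image, truth=truth, description=desc)


def _compact_labels(truth: np.ndarray) -> np.ndarray:
    uniq = np.unique(truth)
    return np.searchsorted(uniq, truth) + 1


def two_disk_phantom(
    seed: int, shape: tuple[int, int] = (128, 128), noise_sd: float = 0.05
) -> Phantom:
    """Benchmark phantom: two bright disks (contrast 1) on a dark background."""
    rng = np.random.default_rng(seed)
    s = min(shape)
    return make_phantom_2d(
        shape,
        [
            Disk((s * 0.30, s * 0.30), s * 0.17, 1.0),
            Disk((s * 0.68, s * 0.66), s * 0.20, 1.0),
        ],
        noise_sd=noise_sd,
        rng=rng,
    )


def two_ellipsoid_phantom(
    seed: int, shape: tuple[int, int, int] = (48, 48, 48), noise_sd: float = 0.05
) -> Phantom:
    """Benchmark phantom: two bright ellipsoids (contrast 1) in a dark volume."""
    rng = np.random.default_rng(seed)
    s = min(shape)
    return make_phantom_3d(
        shape,
        [
            Ellipsoid((s * 0.32, s * 0.34, s * 0.30), (s * 0.18, s * 0.15, s * 0.20), 1.0),
            Ellipsoid((s * 0.68, s * 0.66, s * 0.70), (s * 0.20, s * 0.22, s * 0.17), 1.0),
        ],
        noise_sd=noise_sd,
        rng=rng,
    )


@dataclass
class DiceReport:
    """Max-Dice matching of predicted labels to ground-truth labels."""

    per_truth_label: dict = field(default_factory=dict)
    # truth label -> (matched predicted label, Dice in [0, 1])
    mean_dice: float = 0.0


def dice_evaluate(
    predicted: np.ndarray,
    truth: np.ndarray,
    exclude_truth_labels: Optional[set] = None,
) -> DiceReport:
    """Match every truth label to its max-Dice predicted label.

    ``exclude_truth_labels`` drops labels (typically the background) from
    both the matching report and the mean.  Ties between predicted labels
    break toward the smaller label value.
    """
    pred = np.asarray(predicted).ravel()
    tru = np.asarray(truth).ravel()
    if pred.size != tru.size or np.asarray(predicted).shape != np.asarray(truth).shape:
        raise ValueError("predicted and truth label images must share a shape")
    t_vals, t_inv = np.unique(tru, return_inverse=True)
    p_vals, p_inv = np.unique(pred, return_inverse=True)
    nt, npred = t_vals.size, p_vals.size
    joint = np.bincount(t_inv * npred + p_inv, minlength=nt * npred).reshape(nt, npred)
    t_sizes = joint.sum(axis=1)
    p_sizes = joint.sum(axis=0)
    dice = 2.0 * joint / (t_sizes[:, None] + p_sizes[None, :])
    excluded = set() if exclude_truth_labels is None else set(exclude_truth_labels)
    report = DiceReport()
    scores = []
    for ti, t in enumerate(t_vals):
        if int(t) in excluded:
            continue
        pi = int(np.argmax(dice[ti]))  # first max -> smallest predicted label
        report.per_truth_label[int(t)] = (int(p_vals[pi]), float(dice[ti, pi]))
        scores.append(dice[ti, pi])
    report.mean_dice = float(np.mean(scores)) if scores else 0.0
    return report
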