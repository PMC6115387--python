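"""Two-phase iterative label propagation over local-CM candidate sets.

Each pixel starts with its own unique label.  At every iteration each pixel
re-draws its label from the labels of its CM candidates — in phase 1 by
copying a uniformly random candidate's label, in phase 2 by taking the most
frequent candidate label.  Because candidates sit at (approximate) region
centers of mass, labels drain toward those centers and flood back out, so
pixels of one region end up sharing the label of the region's CM.  Phase 1's
randomness breaks the symmetry of the initial all-unique labeling; phase 2
is deterministic and reaches a fixed point, at which the loop stops.

Updates are synchronous: a step only ever reads the previous iteration's
label array.  All randomness flows from a single seeded generator consumed
in a fixed order (candidate thinning, then initialization, then the phase-1
draws), so a run is bit-for-bit reproducible from its configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np

from .cm1d import CMParams
from .io import normalize_array
from .orientations import CandidateSets, build_candidate_sets, compute_cm_field, generate_orientations

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "init_labels",
    "phase1_step",
    "phase2_step",
    "relabel_contiguous",
    "run_segmentation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Full parameterisation of a segmentation run."""

    cm_params: CMParams
    angular_resolution: float = 10.0  # degrees
    phase1_iterations: int = 200
    max_iterations: int = 1000
    seed: int = 0
    normalization: str = "minmax"  # "minmax" | "stddev" | "none"
    dimension: Optional[int] = None  # infer from the image when None

    def __post_init__(self) -> None:
        if self.phase1_iterations < 0:
            raise ValueError("phase1_iterations must be >= 0")
        if self.max_iterations < self.phase1_iterations:
            raise ValueError("max_iterations must be >= phase1_iterations")
        if self.normalization not in ("minmax", "stddev", "none"):
            raise ValueError(f"unknown normalization mode {self.normalization!r}")


@dataclass
class SegmentationResult:
    labels: np.ndarray  # final label image, values 1..l
    iterations: int  # iterations actually run
    converged: bool  # phase 2 reached a fixed point before the cap
    history: list = dataclass_field(default_factory=list)
    # history rows: (iteration, phase, distinct labels, changed pixels)


def init_labels(
    image_shape,
    rng: np.random.Generator,
    seeds: Optional[np.ndarray] = None,
    freeze_seeds: bool = False,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Initial label image: every pixel gets its own unique label.

    Without ``seeds`` the labels are a random permutation of ``1..N``.  With
    ``seeds`` (an array matching the shape; 0 marks unseeded pixels), seeded
    pixels take the given positive labels and the rest receive fresh unique
    labels above the seed range.  ``freeze_seeds`` additionally returns a
    mask of pixels the phase updates must never overwrite.
    """
    shape = tuple(int(s) for s in image_shape)
    N = int(np.prod(shape))
    if seeds is None:
        labels = rng.permutation(N).astype(np.int64) + 1
        return labels.reshape(shape), None
    seeds = np.asarray(seeds)
    if seeds.shape != shape:
        raise ValueError("seed label image shape does not match the image")
    if np.any(seeds < 0):
        raise ValueError("seed labels must be positive (0 = unseeded)")
    labels = np.asarray(seeds, dtype=np.int64).ravel().copy()
    free = labels == 0
    n_free = int(free.sum())
    base = int(labels.max())
    labels[free] = base + 1 + rng.permutation(n_free)
    frozen = None
    if freeze_seeds:
        frozen = (~free).reshape(shape)
    return labels.reshape(shape), frozen


def phase1_step(
    previous: np.ndarray,
    candidates: CandidateSets,
    rng: np.random.Generator,
    frozen: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Copy, for each pixel, the label of one uniformly drawn candidate."""
    prev = np.asarray(previous)
    flat = prev.ravel()
    counts = candidates.counts
    if np.any(counts == 0):
        raise ValueError("candidate sets must be nonempty")
    pick = candidates.indptr[:-1] + rng.integers(0, counts)
    new = flat[candidates.data[pick]]
    if frozen is not None:
        mask = np.asarray(frozen).ravel()
        new[mask] = flat[mask]
    return new.reshape(prev.shape)


def phase2_step(
    previous: np.ndarray,
    candidates: CandidateSets,
    frozen: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Assign each pixel the most frequent label among its candidates.

    Ties break toward the pixel's current label when it is among the tied
    modes, otherwise toward the label held by the lowest-indexed candidate
    pixel among the tied labels.  Both rules depend only on label
    *positions*, never on label values, so the step is deterministic and
    equivariant under relabeling; preferring the current label additionally
    damps the period-2 oscillations that synchronous mode updates can
    otherwise sustain.  Implemented as a segmented mode: candidate labels
    are sorted within each pixel's slice and run-lengths compared.
    """
    prev = np.asarray(previous)
    flat = prev.ravel()
    counts = candidates.counts
    if np.any(counts == 0):
        raise ValueError("candidate sets must be nonempty")
    N = flat.size
    lab = flat[candidates.data]
    row = np.repeat(np.arange(N, dtype=np.int64), counts)
    base = int(lab.max()) + 1
    key = row * base + lab
    order = np.argsort(key, kind="stable")
    key = key[order]
    pix = candidates.data[order]  # candidate pixel index per pool entry
    M = key.size
    run_start = np.flatnonzero(np.r_[True, key[1:] != key[:-1]])
    run_key = key[run_start]
    run_lab = run_key % base
    run_row = run_key // base
    run_cnt = np.diff(np.r_[run_start, M])
    nruns = run_start.size
    # smallest candidate pixel index carrying each (row, label) run
    run_min_pix = np.minimum.reduceat(pix, run_start)
    row_start = np.flatnonzero(np.r_[True, run_row[1:] != run_row[:-1]])
    # every pixel has >= 1 candidate, so rows appear in order 0..N-1
    max_cnt = np.maximum.reduceat(run_cnt, row_start)
    runs_per_row = np.diff(np.r_[row_start, nruns])
    is_best = run_cnt == np.repeat(max_cnt, runs_per_row)
    # among tied runs of a row, the one whose label sits on the smallest
    # candidate pixel (distinct labels occupy distinct pixels, so unique)
    rank = np.where(is_best, run_min_pix, M + N)
    sel_rank = np.minimum.reduceat(rank, row_start)
    is_sel = is_best & (rank == np.repeat(sel_rank, runs_per_row))
    sel_idx = np.where(is_sel, np.arange(nruns), nruns)
    new = run_lab[np.minimum.reduceat(sel_idx, row_start)]
    # keep the current label where it ties for the mode
    own = flat.copy()
    own[own >= base] = -1  # labels absent from every pool cannot tie
    is_own_best = is_best & (run_lab == np.repeat(own, runs_per_row))
    keep = np.zeros(N, dtype=bool)
    keep[run_row[is_own_best]] = True
    new = np.where(keep, flat, new)
    if frozen is not None:
        mask = np.asarray(frozen).ravel()
        new[mask] = flat[mask]
    return new.reshape(prev.shape)


def _mode_of(pool_pixels: np.ndarray, labels: np.ndarray, current: int) -> int:
    """Single-pixel mode with the same tie rules as :func:`phase2_step`."""
    pool_labels = labels[pool_pixels]
    vals, cnts = np.unique(pool_labels, return_counts=True)
    best = cnts.max()
    tied = vals[cnts == best]
    if current in tied:
        return int(current)
    carrier = pool_pixels[np.isin(pool_labels, tied)].min()
    return int(labels[carrier])


def _resolve_cycle(
    labels: np.ndarray, candidates: CandidateSets, cycling: np.ndarray, max_sweeps: int = 100
) -> np.ndarray:
    """Break a period-2 orbit by updating the cycling pixels sequentially.

    Synchronous mode updates can sustain two-cycles in which a handful of
    mutually referencing pixels swap labels forever.  Re-applying the same
    mode rule to just those pixels one at a time (each update immediately
    visible to the next) lets the group settle; the outer synchronous loop
    then re-verifies the stopping condition, so a run only ever reports
    convergence at a true fixed point of the synchronous update.
    """
    out = labels.copy()
    for _ in range(max_sweeps):
        changed = False
        for n in cycling:
            new = _mode_of(candidates.candidates(n), out, out[n])
            if new != out[n]:
                out[n] = new
                changed = True
        if not changed:
            break
    return out


def relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map label values to 1..l ordered by first occurrence in C order."""
    arr = np.asarray(labels)
    flat = arr.ravel()
    uniq, first = np.unique(flat, return_index=True)
    order = np.argsort(np.argsort(first)) + 1  # rank of first occurrence
    return order[np.searchsorted(uniq, flat)].reshape(arr.shape).astype(np.int64)


def run_segmentation(
    image,
    config: SegmentationConfig,
    seed_labels: Optional[np.ndarray] = None,
    freeze_seeds: bool = False,
) -> SegmentationResult:
    """Segment a 2D/3D image end to end.

    Pipeline: intensity normalization, per-orientation CM field, candidate
    thinning, unique-label initialization, ``t`` phase-1 iterations, then
    phase-2 iterations until the label image stops changing or the iteration
    cap is reached, and finally relabeling to contiguous ``1..l``.
    """
    img = np.asarray(image, dtype=float)
    dim = config.dimension
    if dim is None:
        # a trailing axis of <= 4 entries on a 3-axis array is read as channels
        if img.ndim == 2:
            dim = 2
        elif img.ndim == 3 and img.shape[-1] <= 4:
            dim = 2
        elif img.ndim == 3:
            dim = 3
        else:
            raise ValueError(f"cannot infer dimensionality of shape {img.shape}")
    spatial = img.shape[:dim]

    rng = np.random.default_rng(config.seed)
    img = normalize_array(img, config.normalization)
    orient = generate_orientations(dim, config.angular_resolution)
    logger.info(
        "CM field: K=%d orientations at %.3g deg, alpha=%.4g, p=%.3g",
        len(orient), config.angular_resolution, config.cm_params.alpha, config.cm_params.p,
    )
    field = compute_cm_field(img, orient, config.cm_params)
    cands = build_candidate_sets(field, dim, rng)
    labels, frozen = init_labels(spatial, rng, seeds=seed_labels, freeze_seeds=freeze_seeds)
    flat = labels.ravel()

    history = []
    converged = False
    iterations = 0
    prev2 = None
    for it in range(1, config.max_iterations + 1):
        phase = 1 if it <= config.phase1_iterations else 2
        if phase == 1:
            new = phase1_step(flat, cands, rng, frozen).ravel()
        else:
            new = phase2_step(flat, cands, frozen).ravel()
            if prev2 is not None and np.array_equal(new, prev2) and not np.array_equal(new, flat):
                cycling = np.flatnonzero(new != flat)
                if frozen is not None:
                    cycling = cycling[~np.asarray(frozen).ravel()[cycling]]
                logger.info("iter %d: period-2 orbit over %d pixels, resolving sequentially",
                            it, cycling.size)
                new = _resolve_cycle(new, cands, cycling)
            prev2 = flat
        changed = int((new != flat).sum())
        distinct = int(np.unique(new).size)
        history.append((it, phase, distinct, changed))
        logger.info(
            "iter %d phase %d: %d labels, %d pixels changed", it, phase, distinct, changed
        )
        flat = new
        iterations = it
        if phase == 2 and changed == 0:
            converged = True
            break
    final = relabel_contiguous(flat.reshape(spatial))
    return SegmentationResult(
        labels=final, iterations=iterations, converged=converged, history=history
    )
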