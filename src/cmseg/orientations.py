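"""Orientation sets, digital-line decompositions and per-orientation CM fields.

To extend the 1D local-CM operator to 2D/3D images, the pixel grid is
decomposed, for each of K orientations covering the unit semicircle
(2D) or hemisphere (3D), into disjoint *digital lines* — ordered runs of
grid-adjacent pixels following the orientation.  Each line is treated as a
1D signal (unit sample spacing), its local CM computed in O(length), and the
real-valued CM snapped to the nearest sample of the line.  The result is a
:class:`CMField`: for every pixel ``n`` and orientation ``k``, the grid index
``C_{n,k}`` of its snapped CM and the Euclidean distance ``d_{n,k}`` to it.

The union of CM pixels over orientations is angularly uniform but spatially
clustered near the pixel; :func:`build_candidate_sets` thins it to a
spatially uniform candidate pool by keeping candidate ``k`` with probability
``min(1, (d_min/d_k)^q)`` — ``q = 1`` in 2D, ``q = 2`` in 3D — where
``d_min`` is the pixel's smallest nonzero CM distance.  Zero-distance
candidates (the pixel itself) are always kept, so no set is ever empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cm1d import CMParams

__all__ = [
    "OrientationSet",
    "LineDecomposition",
    "CMField",
    "CandidateSets",
    "generate_orientations",
    "decompose_lines",
    "compute_cm_field",
    "build_candidate_sets",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class OrientationSet:
    """K unit direction vectors sampled on the semicircle or hemisphere."""

    directions: np.ndarray  # (K, dimension), unit rows
    angular_resolution: float  # degrees
    dimension: int

    def __len__(self) -> int:
        return self.directions.shape[0]


def _orientation_angles(directions: np.ndarray) -> np.ndarray:
    """Pairwise angular distances (radians) with antipodal identification."""
    dots = np.abs(directions @ directions.T)
    np.clip(dots, -1.0, 1.0, out=dots)
    return np.arccos(dots)


def _fibonacci_hemisphere(count: int, margin: float) -> np.ndarray:
    """Quasi-uniform spiral points on the upper hemisphere.

    ``margin`` lifts the lowest ring off the equator (in units of z) so that
    no two orientations become near-antipodal across the identification.
    """
    i = np.arange(count)
    z = margin + (1.0 - margin) * (i + 0.5) / count
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _mean_nn_angle(directions: np.ndarray) -> float:
    ang = _orientation_angles(directions)
    np.fill_diagonal(ang, np.inf)
    return float(ang.min(axis=1).mean())


def _hemisphere_count(resolution_deg: float) -> tuple[int, float]:
    """Point count whose mean nearest-neighbour angle matches the resolution.

    There is no closed form relating a spiral sampling's count to its mean
    nearest-neighbour angle, so we start from the hexagonal-packing estimate
    and apply two fixed-point corrections (mean NN angle scales ~ K^-1/2).
    """
    theta = math.radians(resolution_deg)
    margin = math.sin(theta / 4.0)  # equatorial clearance against antipodes
    K = max(3, round(7.3 / theta**2))
    for _ in range(3):
        measured = _mean_nn_angle(_fibonacci_hemisphere(K, margin))
        K = max(3, round(K * (measured / theta) ** 2))
    return K, margin


def generate_orientations(dimension: int, angular_resolution: float) -> OrientationSet:
    """Uniformly distributed undirected orientations at a given resolution.

    2D: ``K = round(180 / r)`` directions at angles ``(k-1) * r`` degrees on
    the semicircle.  3D: a deterministic spiral sampling of the hemisphere
    whose point count is calibrated so the mean nearest-neighbour angle is
    approximately ``r`` degrees.
    """
    if not (0 < angular_resolution <= 90):
        raise ValueError(
            f"angular resolution must lie in (0, 90] degrees, got {angular_resolution}"
        )
    if dimension == 2:
        K = round(180.0 / angular_resolution)
        theta = np.deg2rad(np.arange(K) * angular_resolution)
        directions = np.column_stack([np.cos(theta), np.sin(theta)])
    elif dimension == 3:
        K, margin = _hemisphere_count(angular_resolution)
        directions = _fibonacci_hemisphere(K, margin)
    else:
        raise ValueError(f"dimension must be 2 or 3, got {dimension}")
    return OrientationSet(
        directions=directions,
        angular_resolution=float(angular_resolution),
        dimension=dimension,
    )


# ---------------------------------------------------------------------------
# Digital-line decomposition


@dataclass
class _LineGrid:
    """Padded representation of one orientation's line decomposition.

    Row ``r`` of the padded arrays holds one digital line; column ``t`` is
    the coordinate along the driving axis.  ``flat`` is the C-order flat
    pixel index, or -1 where the line leaves the image.  Valid cells form a
    contiguous run per row.
    """

    axis: int  # driving axis
    shape: tuple[int, ...]
    flat: np.ndarray  # (R, T) int64, -1 outside
    valid: np.ndarray  # (R, T) bool
    shifts: list[np.ndarray]  # per non-driving axis, offset at each t
    other_axes: list[int]


def _line_grid(shape, direction) -> _LineGrid:
    shape = tuple(int(s) for s in shape)
    d = np.asarray(direction, dtype=float)
    if np.allclose(d, 0.0):
        raise ValueError("direction must be a nonzero vector")
    ndim = len(shape)
    if d.size != ndim:
        raise ValueError(f"direction has {d.size} components for a {ndim}D grid")
    axis = int(np.argmax(np.abs(d)))
    if d[axis] < 0:  # orientations are undirected; fix the driving sense
        d = -d
    slope = d / d[axis]
    T = shape[axis]
    t = np.arange(T)
    other = [j for j in range(ndim) if j != axis]
    # nearest-integer cross-axis offset at each driving step (half rounds up)
    shifts = [np.floor(t * slope[j] + 0.5).astype(np.int64) for j in other]

    offsets = []
    for j, sh in zip(other, shifts):
        offsets.append(np.arange(-int(sh.max()), shape[j] - int(sh.min())))
    if other:
        mesh = np.meshgrid(*offsets, indexing="ij")
        R = mesh[0].size
        coords = [None] * ndim
        valid = np.ones((R, T), dtype=bool)
        for j, o, sh in zip(other, mesh, shifts):
            cj = o.reshape(R, 1) + sh.reshape(1, T)
            coords[j] = cj
            valid &= (cj >= 0) & (cj < shape[j])
        coords[axis] = np.broadcast_to(t.reshape(1, T), (R, T))
        safe = [np.clip(c, 0, s - 1) for c, s in zip(coords, shape)]
        flat = np.ravel_multi_index(safe, shape).astype(np.int64)
    else:  # 1D grid: a single line
        valid = np.ones((1, T), dtype=bool)
        flat = t.reshape(1, T).astype(np.int64)
    flat[~valid] = -1
    keep = valid.any(axis=1)
    return _LineGrid(
        axis=axis,
        shape=shape,
        flat=flat[keep],
        valid=valid[keep],
        shifts=shifts,
        other_axes=other,
    )


@dataclass
class LineDecomposition:
    """Partition of a pixel grid into digital lines along one orientation."""

    lines: list[np.ndarray]  # flat pixel indices, ordered along the line
    line_id: np.ndarray  # per pixel (flat, C-order)
    position: np.ndarray  # per pixel, 0-based position within its line


def decompose_lines(image_shape, direction) -> LineDecomposition:
    """Decompose a grid into disjoint digital lines following ``direction``.

    Every pixel belongs to exactly one line; consecutive pixels of a line
    are Chebyshev-adjacent on the grid.  The construction shears the grid
    along the driving axis (the direction's largest component) with
    nearest-integer cross-axis offsets, so the union of lines is exactly the
    grid for any unit direction.
    """
    grid = _line_grid(image_shape, direction)
    n_pixels = int(np.prod(grid.shape))
    line_id = np.empty(n_pixels, dtype=np.int64)
    position = np.empty(n_pixels, dtype=np.int64)
    lines = []
    for r in range(grid.flat.shape[0]):
        pix = grid.flat[r][grid.valid[r]]
        lines.append(pix)
        line_id[pix] = r
        position[pix] = np.arange(pix.size)
    return LineDecomposition(lines=lines, line_id=line_id, position=position)


# ---------------------------------------------------------------------------
# CM field


@dataclass
class CMField:
    """Snapped local-CM pixel and distance for every pixel and orientation."""

    cm_index: np.ndarray  # (K, N) int64 flat pixel index of the snapped CM
    distance: np.ndarray  # (K, N) float64 Euclidean pixel-unit distance
    shape: tuple[int, ...]
    orientations: OrientationSet = field(repr=False)

    def to_table(self) -> np.ndarray:
        """(N*K, 4) table: pixel index, orientation index, CM index, distance."""
        K, N = self.cm_index.shape
        pix = np.tile(np.arange(N), K)
        orient = np.repeat(np.arange(K), N)
        return np.column_stack(
            [pix, orient, self.cm_index.ravel(), self.distance.ravel()]
        ).astype(float)


def _line_cm_positions(D: np.ndarray, valid: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Vectorised-across-lines O(T) local-CM recursion on padded line arrays.

    ``D`` is the per-cell edge integral (constant outside each line), ``pos``
    the 0-based within-line position.  Returns the real-valued CM in 1-based
    line coordinates (garbage at invalid cells).
    """
    R, T = D.shape
    if T == 1:
        return np.ones((R, 1))
    E = np.exp(D[:, :-1] - D[:, 1:])
    P = np.zeros((R, T))
    Q = np.zeros((R, T))
    m1 = np.where(valid, pos + 1.0, 0.0)  # 1-based index within the line
    P[:, 0] = m1[:, 0]
    Q[:, 0] = valid[:, 0]
    for t in range(1, T):
        cont = valid[:, t - 1] & valid[:, t]
        P[:, t] = np.where(cont, P[:, t - 1] * E[:, t - 1], 0.0) + m1[:, t]
        Q[:, t] = np.where(cont, Q[:, t - 1] * E[:, t - 1], 0.0) + valid[:, t]
    S = np.zeros((R, T))
    U = np.zeros((R, T))
    for t in range(T - 2, -1, -1):
        cont = valid[:, t] & valid[:, t + 1]
        S[:, t] = np.where(cont, E[:, t] * (S[:, t + 1] + m1[:, t + 1]), 0.0)
        U[:, t] = np.where(cont, E[:, t] * (U[:, t + 1] + 1.0), 0.0)
    denom = np.maximum(Q + U, np.finfo(float).tiny)
    return (P + S) / denom


def compute_cm_field(image, orientations: OrientationSet, params: CMParams) -> CMField:
    """Snapped local CM of every pixel along every orientation.

    For each orientation the image is decomposed into digital lines, each
    line's aggregate edge integral is accumulated along the line (multichannel
    images sum their per-channel step masses), the 1D local CM is evaluated
    with the O(length) recursion, snapped to the nearest line sample (ties at
    .5 toward the lower index), and converted back to a grid index and a true
    Euclidean distance.  Total cost is O(K * N).
    """
    img = np.asarray(image, dtype=float)
    dim = orientations.dimension
    if img.ndim == dim:
        channels = img[..., np.newaxis]
    elif img.ndim == dim + 1:
        channels = img
    else:
        raise ValueError(
            f"image with {img.ndim} axes does not match {dim}D orientations"
        )
    if not np.all(np.isfinite(channels)):
        raise ValueError("image contains non-finite values")
    spatial = channels.shape[:dim]
    N = int(np.prod(spatial))
    nch = channels.shape[-1]
    flatvals = channels.reshape(N, nch)
    K = len(orientations)
    cm_index = np.empty((K, N), dtype=np.int64)
    distance = np.empty((K, N), dtype=np.float64)

    for k, dvec in enumerate(orientations.directions):
        grid = _line_grid(spatial, dvec)
        flat, valid = grid.flat, grid.valid
        R, T = flat.shape
        safe = np.where(valid, flat, 0)
        vals = flatvals[safe]  # (R, T, nch)
        if T > 1:
            trans = valid[:, :-1] & valid[:, 1:]
            steps = (np.abs(np.diff(vals, axis=1)) ** params.p).sum(axis=2)
            steps *= trans
            cum = params.alpha * np.cumsum(steps, axis=1)
            D = np.zeros((R, T))
            if params.shifted:
                D[:, 1:] = cum
            else:
                # as-printed convention: D at t includes the step t -> t+1;
                # steps beyond the line end are zero, so the f_{N+1} := f_N
                # boundary is automatic.
                D[:, :-1] = cum
                D[:, -1] = D[:, -2]
        else:
            D = np.zeros((R, T))
        pos = np.cumsum(valid, axis=1) - 1  # 0-based within-line position
        C = _line_cm_positions(D, valid, pos)
        length = valid.sum(axis=1, keepdims=True)
        C = np.clip(C, 1.0, length)
        # nearest line sample; ties at .5 toward the lower index
        local = np.ceil(C - 0.5).astype(np.int64) - 1
        t_start = np.argmax(valid, axis=1)
        cm_t = np.clip(t_start[:, None] + local, 0, T - 1)
        cm_flat = np.take_along_axis(flat, cm_t, axis=1)

        t_here = np.broadcast_to(np.arange(T)[None, :], (R, T))
        d2 = (t_here - cm_t).astype(float) ** 2
        for sh in grid.shifts:
            d2 += (sh[t_here] - sh[cm_t]).astype(float) ** 2

        rr, tt = np.nonzero(valid)
        pix = flat[rr, tt]
        cm_index[k, pix] = cm_flat[rr, tt]
        distance[k, pix] = np.sqrt(d2[rr, tt])

    return CMField(
        cm_index=cm_index, distance=distance, shape=spatial, orientations=orientations
    )


# ---------------------------------------------------------------------------
# Candidate sets


@dataclass
class CandidateSets:
    """Per-pixel thinned CM candidate pools, stored in CSR-like form.

    ``data[indptr[n]:indptr[n+1]]`` are the flat pixel indices of the
    retained candidates of pixel ``n`` (one entry per retained orientation;
    a pixel index may repeat if several orientations snap to it).
    """

    indptr: np.ndarray  # (N+1,) int64
    data: np.ndarray  # (M,) int64 flat pixel indices
    shape: tuple[int, ...]

    @property
    def counts(self) -> np.ndarray:
        return np.diff(self.indptr)

    def candidates(self, n: int) -> np.ndarray:
        return self.data[self.indptr[n] : self.indptr[n + 1]]


def build_candidate_sets(
    field: CMField, dimension: int, rng: np.random.Generator
) -> CandidateSets:
    """Thin the CM field to spatially uniform per-pixel candidate sets.

    Candidate ``k`` of pixel ``n`` survives an independent Bernoulli draw
    with probability ``min(1, (d_min,n / d_{n,k})^q)`` where ``q = 1`` in 2D
    and ``q = 2`` in 3D and ``d_min,n`` is the smallest nonzero distance
    among the pixel's candidates.  Zero-distance candidates and the nearest
    nonzero candidate survive with probability 1, so every set is nonempty.
    The draw happens once; the sets stay frozen for the whole segmentation.
    """
    if field.cm_index.size == 0:
        raise ValueError("empty CM field")
    if dimension not in (2, 3):
        raise ValueError(f"dimension must be 2 or 3, got {dimension}")
    q = 1 if dimension == 2 else 2
    d = field.distance
    nz = np.where(d > 0, d, np.inf)
    dmin = nz.min(axis=0)  # inf when every candidate coincides with the pixel
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(d > 0, np.minimum(1.0, (dmin[None, :] / d) ** q), 1.0)
    prob = np.nan_to_num(prob, nan=1.0)
    keep = rng.random(d.shape) < prob
    keep_t = keep.T  # (N, K): row-major order groups candidates per pixel
    counts = keep_t.sum(axis=1).astype(np.int64)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    data = field.cm_index.T[keep_t]
    return CandidateSets(indptr=indptr, data=data, shape=field.shape)
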