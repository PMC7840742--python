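"""Statistical geometry of the bilayer: Delaunay tessellation and the
tetrahedrality distortion statistic.

Space is partitioned into Delaunay tetrahedra whose vertices are selected
heavy atoms (lipid phosphates, sterol and water oxygens).  Each tetrahedron
gets a tetrahedrality

    T = Σ_{i<j} (l_i − l_j)² / (15 · l̄²)

summed over the 15 unordered pairs of its 6 edge lengths.  T = 0 exactly
for a regular tetrahedron and grows with distortion; it is invariant under
rotation, translation and uniform scaling.  The default denominator reads
l̄² as (mean edge length)² — the standard statistical-geometry convention —
with ``mean_square=True`` switching to the mean of squared edge lengths
(both give 0 for regular tetrahedra).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .core_io import AtomSelection, Trajectory

log = logging.getLogger(__name__)

_EDGE_PAIRS = list(combinations(range(4), 2))  # the 6 edges of a tetrahedron


def tetrahedrality(vertices: np.ndarray, mean_square: bool = False) -> float:
    """Tetrahedrality T of a single tetrahedron given its 4×3 vertices."""
    v = np.asarray(vertices, dtype=float)
    if v.shape != (4, 3):
        raise ValueError("expected 4 vertices in 3-D")
    edges = np.array([np.linalg.norm(v[a] - v[b]) for a, b in _EDGE_PAIRS])
    return _tetrahedrality_from_edges(edges[None, :], mean_square)[0]


def _tetrahedrality_from_edges(edges: np.ndarray,
                               mean_square: bool = False) -> np.ndarray:
    """Vectorized T for an (n, 6) array of edge lengths.

    Uses Σ_{i<j}(l_i − l_j)² = 6 Σ l² − (Σ l)² over the 6 edges.
    """
    if np.any(edges <= 0):
        raise ValueError("degenerate tetrahedron: non-positive edge length")
    s1 = edges.sum(axis=1)
    s2 = (edges**2).sum(axis=1)
    num = 6.0 * s2 - s1**2
    lbar_sq = s2 / 6.0 if mean_square else (s1 / 6.0) ** 2
    return num / (15.0 * lbar_sq)


@dataclass
class TetraSet:
    """Delaunay tetrahedra over one frame's selected vertices."""

    simplices: np.ndarray        # (n_tetra, 4) indices into the primary points
    edge_lengths: np.ndarray     # (n_tetra, 6) Å
    t_values: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.simplices)

    def compute_t(self, mean_square: bool = False) -> np.ndarray:
        self.t_values = _tetrahedrality_from_edges(self.edge_lengths, mean_square)
        return self.t_values


def tessellate(points: np.ndarray, box: np.ndarray | None = None,
               margin: float = 15.0) -> TetraSet:
    """Delaunay-tessellate points, laterally periodic in x and y.

    Ghost images of points within ``margin`` Å of the lateral box faces are
    added before triangulating (z is non-periodic: the membrane is bounded
    by bulk water above and below).  Tetrahedra with no primary vertex are
    dropped, and tetrahedra that appear through several image combinations
    are de-duplicated by their primary-index set.  Degenerate (zero-volume)
    simplices are filtered with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    n = len(pts)
    if n < 5:
        raise ValueError(f"need at least 5 points to tessellate, got {n}")

    coords = [pts]
    origin = [np.arange(n)]
    if box is not None:
        lx, ly = float(box[0]), float(box[1])
        shifts = [(sx, sy) for sx in (-1, 0, 1) for sy in (-1, 0, 1)
                  if (sx, sy) != (0, 0)]
        for sx, sy in shifts:
            shifted = pts + np.array([sx * lx, sy * ly, 0.0])
            near = ((shifted[:, 0] > -margin) & (shifted[:, 0] < lx + margin)
                    & (shifted[:, 1] > -margin) & (shifted[:, 1] < ly + margin))
            if np.any(near):
                coords.append(shifted[near])
                origin.append(np.nonzero(near)[0])
    all_pts = np.concatenate(coords)
    all_origin = np.concatenate(origin)

    try:
        tri = Delaunay(all_pts)
    except QhullError as exc:
        raise ValueError(f"degenerate point set for Delaunay tessellation: "
                         f"{exc}") from exc

    simplices = tri.simplices
    has_primary = np.any(simplices < n, axis=1)
    simplices = simplices[has_primary]

    # filter near-degenerate slivers (coplanar vertices)
    a = all_pts[simplices[:, 1]] - all_pts[simplices[:, 0]]
    b = all_pts[simplices[:, 2]] - all_pts[simplices[:, 0]]
    c = all_pts[simplices[:, 3]] - all_pts[simplices[:, 0]]
    vol6 = np.abs(np.einsum("ij,ij->i", np.cross(a, b), c))
    scale = np.maximum(np.linalg.norm(a, axis=1), 1.0) ** 3
    good = vol6 > 1e-9 * scale
    if np.any(~good):
        log.warning("filtered %d degenerate simplices", int(np.sum(~good)))
    simplices = simplices[good]

    # map back to primary indices and de-duplicate image copies
    primary = all_origin[simplices]
    seen: set[tuple[int, ...]] = set()
    keep = []
    for row, prim in zip(simplices, primary):
        key = tuple(sorted(prim))
        if len(set(key)) < 4:
            continue  # a tetra joining a point to its own image: not physical
        if key in seen:
            continue
        seen.add(key)
        keep.append((row, prim))
    if not keep:
        raise ValueError("no valid tetrahedra after filtering")
    ghost_rows = np.array([r for r, _ in keep])
    prim_rows = np.array([p for _, p in keep])

    edges = np.empty((len(ghost_rows), 6))
    for e, (i, j) in enumerate(_EDGE_PAIRS):
        edges[:, e] = np.linalg.norm(
            all_pts[ghost_rows[:, i]] - all_pts[ghost_rows[:, j]], axis=1)
    return TetraSet(simplices=prim_rows, edge_lengths=edges)


@dataclass
class TetraHistogram:
    """Pooled tetrahedrality distribution across frames."""

    bin_edges: np.ndarray
    probability: np.ndarray      # density: Σ p·ΔT = 1
    mode: float
    mean: float
    tail_fraction: float
    tail_threshold: float
    n_tetrahedra: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def tetrahedrality_distribution(traj: Trajectory, vertex_sel: AtomSelection,
                                bins: int = 50, t_max: float = 2.0,
                                tail_threshold: float = 1.0,
                                mean_square: bool = False,
                                margin: float = 15.0) -> TetraHistogram:
    """Histogram of T pooled over all frames' tessellations.

    Mirrors the distribution analysis of bilayer regularity: a unimodal
    peak at low T indicates a regular arrangement; the tail above
    ``tail_threshold`` measures the fraction of strongly distorted
    tetrahedra.
    """
    if len(vertex_sel) < 5:
        raise ValueError("vertex selection must contain at least 5 atoms")
    box = traj.box
    pooled = []
    for f in range(traj.n_frames):
        pts = traj.coords[f, vertex_sel.indices, :]
        tset = tessellate(pts, box=box[f] if box is not None else None,
                          margin=margin)
        pooled.append(tset.compute_t(mean_square))
    t_all = np.concatenate(pooled)
    edges = np.linspace(0.0, t_max, bins + 1)
    prob, _ = np.histogram(np.clip(t_all, 0.0, t_max - 1e-12), bins=edges,
                           density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TetraHistogram(
        bin_edges=edges, probability=prob,
        mode=float(centers[np.argmax(prob)]),
        mean=float(t_all.mean()),
        tail_fraction=float(np.mean(t_all > tail_threshold)),
        tail_threshold=tail_threshold,
        n_tetrahedra=len(t_all),
    )
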