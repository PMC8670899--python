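"""Spatioangular graph construction for diffusion MRI patches.

Every diffusion measurement is a point (x_i, q̂_j, b_j) in the joint
spatioangular domain: voxel center x_i in mm, unit gradient direction q̂_j and
diffusion weighting b_j.  Two measurements are linked by an affinity

    w = exp(-||x_i - x_i'||^2 / (2 sigma_x^2))
      * exp(-(1 - <q̂_j, q̂_j'>^2) / (2 sigma_q^2))
      * exp(-(b̃_j - b̃_j')^2 / (2 sigma_b^2))

where b̃ = b / max(b) so the diffusion-weighting exponent argument lies in
[0, 1].  The angular term uses the squared inner product, which is antipodally
symmetric: q̂ and -q̂ sensitize the same diffusion direction.

To keep the graph sparse, edges are restricted to a Chebyshev spatial radius
(27-voxel cube by default) crossed with the k angularly nearest directions,
and the volume is processed patch by patch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import DWIVolume, GradientTable

__all__ = [
    "GraphConfig",
    "SpatioAngularGraph",
    "PatchGrid",
    "affinity_weight",
    "angular_neighbors",
    "build_patch_graph",
    "patch_graph_edges",
    "spatial_patch_edges",
    "spatial_patch_grid",
    "write_edge_list",
]


@dataclass(frozen=True)
class GraphConfig:
    """Affinity bandwidths and neighborhood system of the spatioangular graph.

    ``sigma_x`` is in mm; ``sigma_q`` and ``sigma_b`` are unitless (the b-value
    enters normalized by its maximum). ``spatial_radius`` is a Chebyshev radius
    in voxels; ``angular_k`` counts nearest directions including self. Edges
    with weight below ``weight_floor`` are dropped.
    """

    sigma_x: float = 8.0
    sigma_q: float = 1.1
    sigma_b: float = 1.0
    spatial_radius: int = 1
    angular_k: int = 5
    weight_floor: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_q, self.sigma_b) <= 0:
            raise ValueError("all bandwidths must be positive")
        if self.spatial_radius < 0:
            raise ValueError("spatial_radius must be >= 0")
        if self.angular_k < 1:
            raise ValueError("angular_k must be >= 1")
        if not 0 <= self.weight_floor < 1:
            raise ValueError("weight_floor must lie in [0, 1)")


@dataclass
class SpatioAngularGraph:
    """A sparse weighted graph over (voxel, volume) sampling points.

    ``nodes`` is an (N, 4) integer array of (ix, iy, iz, volume-index) rows;
    ``edges`` an (E, 2) array of node-index pairs with a < b in node order;
    ``weights`` the positive affinity per edge, stored once per unordered pair.
    """

    nodes: np.ndarray
    edges: np.ndarray
    weights: np.ndarray
    _op: Optional[object] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights length mismatch")
        if len(self.edges) and (
            self.edges.min() < 0 or self.edges.max() >= len(self.nodes)
        ):
            raise ValueError("edge refers to a node outside the graph")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class PatchGrid:
    """Overlapping patch tiling of a volume: corner ``origins`` spaced by ``step``."""

    dims: tuple
    patch_size: int
    step: int
    origins: np.ndarray

    def coverage_counts(self) -> np.ndarray:
        """Per-voxel number of covering patches (merge weight = 1 / count)."""
        counts = np.zeros(self.dims, dtype=np.int64)
        for o in self.origins:
            sl = tuple(
                slice(o[a], min(o[a] + self.patch_size, self.dims[a])) for a in range(3)
            )
            counts[sl] += 1
        return counts


def affinity_weight(
    xa: Sequence[float],
    qa: Sequence[float],
    ba: float,
    xb: Sequence[float],
    qb: Sequence[float],
    bb: float,
    cfg: GraphConfig,
    b_scale: Optional[float] = None,
) -> float:
    """Affinity between two spatioangular sampling points; symmetric, in (0, 1].

    ``b_scale`` is the normalization constant for the b-term (max b-value of
    the acquisition); it defaults to max(ba, bb).
    """
    xa = np.asarray(xa, dtype=np.float64)
    xb = np.asarray(xb, dtype=np.float64)
    qa = np.asarray(qa, dtype=np.float64)
    qb = np.asarray(qb, dtype=np.float64)
    for q, b in ((qa, ba), (qb, bb)):
        if b > 0 and abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValueError("gradient direction of a b>0 point must be unit norm")
    if b_scale is None:
        b_scale = max(ba, bb)
    bs = b_scale if b_scale > 0 else 1.0
    d2 = float(np.sum((xa - xb) ** 2))
    ang = 1.0 - float(np.dot(qa, qb)) ** 2
    db = (ba - bb) / bs
    return float(
        np.exp(-d2 / (2.0 * cfg.sigma_x**2))
        * np.exp(-ang / (2.0 * cfg.sigma_q**2))
        * np.exp(-(db**2) / (2.0 * cfg.sigma_b**2))
    )


def _angular_adjacency(bvecs: np.ndarray, k: int) -> np.ndarray:
    """Symmetrized k-nearest-direction adjacency (boolean, diagonal True).

    Nearness is by squared inner product (antipodally symmetric); self is
    always included; ties among the remaining candidates break toward the
    lower volume index for determinism.
    """
    V = len(bvecs)
    if k > V:
        raise ValueError(f"angular_k={k} exceeds the {V} available directions")
    if k < 1:
        raise ValueError("angular_k must be >= 1")
    gram2 = (bvecs @ bvecs.T) ** 2
    adj = np.zeros((V, V), dtype=bool)
    for j in range(V):
        order = np.argsort(-gram2[j], kind="stable")
        others = order[order != j][: k - 1]
        adj[j, j] = True
        adj[j, others] = True
    return adj | adj.T


def angular_neighbors(gradients: GradientTable, k: int) -> list:
    """Per-DW-direction neighbor lists (ascending, self included, symmetrized).

    Only b>0 entries participate; returned indices are positions within the
    diffusion-weighted subset in order of appearance.
    """
    bvecs = gradients.bvecs[gradients.dw_mask]
    adj = _angular_adjacency(bvecs, k)
    return [np.flatnonzero(adj[j]) for j in range(len(bvecs))]


def _spatial_offsets(radius: int) -> list:
    """Lexicographically positive offsets with Chebyshev norm <= radius."""
    offs = []
    rng = range(-radius, radius + 1)
    for off in itertools.product(rng, rng, rng):
        if off > (0, 0, 0):
            offs.append(off)
    return offs


def _offset_pairs(shape, off):
    """Linear voxel indices (a, b) with b = a + off, both inside ``shape``."""
    lin = np.arange(int(np.prod(shape)), dtype=np.int64).reshape(shape)
    sl_a, sl_b = [], []
    for d, o in zip(shape, off):
        if o >= 0:
            sl_a.append(slice(0, d - o))
            sl_b.append(slice(o, d))
        else:
            sl_a.append(slice(-o, d))
            sl_b.append(slice(0, d + o))
    return lin[tuple(sl_a)].ravel(), lin[tuple(sl_b)].ravel()


def patch_graph_edges(
    shape: Sequence[int],
    voxel_size: Sequence[float],
    bvals: np.ndarray,
    bvecs: np.ndarray,
    cfg: GraphConfig,
) -> tuple:
    """Edge list and weights of the spatioangular graph on a patch of ``shape``.

    Nodes are numbered voxel-major (C order over the patch) with the volume
    index fastest: node = voxel_lin * V + j.  Because Eq-style affinities
    depend only on coordinate differences, the result is identical for every
    patch of the same shape, which lets callers cache it.
    """
    shape = tuple(int(s) for s in shape)
    voxel_size = np.asarray(voxel_size, dtype=np.float64)
    bvals = np.asarray(bvals, dtype=np.float64)
    bvecs = np.asarray(bvecs, dtype=np.float64)
    V = len(bvals)
    nvox = int(np.prod(shape))

    adj = _angular_adjacency(bvecs, cfg.angular_k)
    gram2 = (bvecs @ bvecs.T) ** 2
    bmax = bvals.max()
    btilde = bvals / bmax if bmax > 0 else bvals
    wq = np.exp(-(1.0 - gram2) / (2.0 * cfg.sigma_q**2)) * np.exp(
        -((btilde[:, None] - btilde[None, :]) ** 2) / (2.0 * cfg.sigma_b**2)
    )

    # Direction pairs: ordered (incl. diagonal) for cross-voxel edges,
    # strictly upper-triangular for same-voxel edges.
    j1c, j2c = np.nonzero(adj)
    wqc = wq[j1c, j2c]
    j1s, j2s = np.nonzero(np.triu(adj, 1))
    wqs = wq[j1s, j2s]

    ea, eb, ew = [], [], []

    # Same-voxel angular edges (spatial factor = 1).
    if len(j1s):
        vox = np.arange(nvox, dtype=np.int64)
        ea.append((vox[:, None] * V + j1s[None, :]).ravel())
        eb.append((vox[:, None] * V + j2s[None, :]).ravel())
        ew.append(np.tile(wqs, nvox))

    # Cross-voxel edges, one lexicographically positive offset at a time.
    for off in _spatial_offsets(cfg.spatial_radius):
        va, vb = _offset_pairs(shape, off)
        if len(va) == 0 or len(j1c) == 0:
            continue
        d2 = float(np.sum((np.asarray(off) * voxel_size) ** 2))
        wsp = np.exp(-d2 / (2.0 * cfg.sigma_x**2))
        ea.append((va[:, None] * V + j1c[None, :]).ravel())
        eb.append((vb[:, None] * V + j2c[None, :]).ravel())
        ew.append(wsp * np.tile(wqc, len(va)))

    if not ea:
        return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.float64)
    a = np.concatenate(ea)
    b = np.concatenate(eb)
    w = np.concatenate(ew)
    keep = w > cfg.weight_floor if cfg.weight_floor > 0 else w > 0
    return np.stack([a[keep], b[keep]], axis=1), w[keep]


def spatial_patch_edges(
    shape: Sequence[int], voxel_size: Sequence[float], cfg: GraphConfig
) -> tuple:
    """Spatial-only edge list on a patch (angular and b factors = 1).

    Used for b=0 volumes, whose gradient direction is undefined. Nodes are
    voxel linear indices in C order.
    """
    shape = tuple(int(s) for s in shape)
    voxel_size = np.asarray(voxel_size, dtype=np.float64)
    ea, eb, ew = [], [], []
    for off in _spatial_offsets(cfg.spatial_radius):
        va, vb = _offset_pairs(shape, off)
        if len(va) == 0:
            continue
        d2 = float(np.sum((np.asarray(off) * voxel_size) ** 2))
        wsp = np.exp(-d2 / (2.0 * cfg.sigma_x**2))
        ea.append(va)
        eb.append(vb)
        ew.append(np.full(len(va), wsp))
    if not ea:
        return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.float64)
    a = np.concatenate(ea)
    b = np.concatenate(eb)
    w = np.concatenate(ew)
    keep = w > cfg.weight_floor if cfg.weight_floor > 0 else w > 0
    return np.stack([a[keep], b[keep]], axis=1), w[keep]


def build_patch_graph(
    origin: Sequence[int],
    patch_size: int,
    vol: DWIVolume,
    cfg: GraphConfig,
) -> SpatioAngularGraph:
    """Spatioangular graph over all (voxel, DW volume) pairs of one patch.

    The patch is clipped at the volume boundary. b=0 volumes are excluded
    (their direction is undefined; the pipeline denoises them on a
    spatial-only graph).
    """
    dims = vol.data.shape[:3]
    origin = tuple(int(o) for o in origin)
    shape = tuple(min(patch_size, dims[a] - origin[a]) for a in range(3))
    if any(s < 1 for s in shape):
        raise ValueError(f"patch at origin {origin} is empty for dims {dims}")
    dw_idx = np.flatnonzero(vol.gradients.dw_mask)
    if len(dw_idx) == 0:
        raise ValueError("volume has no diffusion-weighted (b>0) directions")
    bvals = vol.gradients.bvals[dw_idx]
    bvecs = vol.gradients.bvecs[dw_idx]
    k = min(cfg.angular_k, len(dw_idx))
    cfg_eff = cfg if k == cfg.angular_k else GraphConfig(
        cfg.sigma_x, cfg.sigma_q, cfg.sigma_b, cfg.spatial_radius, k, cfg.weight_floor
    )
    edges, weights = patch_graph_edges(shape, vol.voxel_size, bvals, bvecs, cfg_eff)

    vox = np.stack(
        np.meshgrid(*[np.arange(o, o + s) for o, s in zip(origin, shape)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    nodes = np.column_stack(
        [np.repeat(vox, len(dw_idx), axis=0), np.tile(dw_idx, len(vox))]
    )
    return SpatioAngularGraph(nodes, edges, weights)


def spatial_patch_grid(dims: Sequence[int], patch_size: int, step: int) -> PatchGrid:
    """Overlapping patch origins covering a volume, spaced by ``step`` per axis.

    The final origin on each axis is forced so the last patch touches the
    boundary; every voxel is covered by at least one patch.
    """
    dims = tuple(int(d) for d in dims)
    if step < 1:
        raise ValueError("step must be >= 1")
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if step > patch_size:
        raise ValueError("step must not exceed patch_size (coverage would have gaps)")
    per_axis = []
    for d in dims:
        if patch_size >= d:
            per_axis.append([0])
            continue
        origins = list(range(0, d - patch_size + 1, step))
        if origins[-1] != d - patch_size:
            origins.append(d - patch_size)
        per_axis.append(origins)
    origins = np.array(list(itertools.product(*per_axis)), dtype=np.int64)
    return PatchGrid(dims=dims, patch_size=patch_size, step=step, origins=origins)


def write_edge_list(g: SpatioAngularGraph, path) -> None:
    """Dump the graph as ``node_a node_b weight`` text lines (debug aid)."""
    with open(path, "w") as fh:
        for (a, b), w in zip(g.edges, g.weights):
            fh.write(f"{a} {b} {w:.17g}\n")
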