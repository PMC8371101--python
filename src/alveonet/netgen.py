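"""Random fiber-network generation on the unit square.

A network is seeded from ``n`` straight chords ("fibers") drawn through
uniformly random anchor points at uniformly random angles, each extended to
the boundary of the unit square.  Each fiber is collagen with probability
``alpha``, elastin otherwise.  Where two fibers cross inside the square they
are permanently bonded with probability ``rho`` (inter-fiber cross-linking);
a bonded crossing becomes a shared network node, an unbonded crossing leaves
the fibers mechanically independent.  Fibers are attached to the square
boundary where they meet it, and the perimeter between consecutive
attachment points and the four corners is covered by elastin-typed "edge"
segments.

The resulting :class:`FiberNetwork` stores nodes and segments as flat numpy
arrays (struct-of-arrays) for speed; :class:`Node` / :class:`Segment` views
are materialised on demand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

FORMAT_VERSION = 1

# segment type codes
COLLAGEN = 0
ELASTIN = 1
EDGE = 2
SEG_TYPE_NAMES = {COLLAGEN: "collagen", ELASTIN: "elastin", EDGE: "edge"}
SEG_TYPE_CODES = {v: k for k, v in SEG_TYPE_NAMES.items()}

# node kind codes
INTERIOR = 0
BOUNDARY = 1
CORNER = 2
NODE_KIND_NAMES = {
    INTERIOR: "interior-crosslink",
    BOUNDARY: "boundary-attachment",
    CORNER: "corner",
}
NODE_KIND_CODES = {v: k for k, v in NODE_KIND_NAMES.items()}

# boundary side bitmask
SIDE_LEFT = 1
SIDE_RIGHT = 2
SIDE_BOTTOM = 4
SIDE_TOP = 8

#: parent index used for perimeter (edge) segments
PERIMETER = -1

#: geometric tolerance: points closer than this are merged / snapped
GEOM_TOL = 1e-9
#: |sin(angle difference)| below which two fibers count as parallel
PARALLEL_TOL = 1e-12


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of one random network realisation.

    Parameters
    ----------
    n : int
        Number of seeded fibers (baseline 48 for mechanics, 480 for the
        bond-percolation experiment).
    alpha : float
        Probability that a fiber is collagen (the collagen area fraction of
        alveolar wall tissue is not well constrained; 0.5 is a documented
        placeholder default, not a measured value).
    rho : float
        Inter-fiber cross-linking probability in [0, 1].
    seed : int
        Seed of the single RNG stream that drives the realisation.
    """

    n: int = 48
    alpha: float = 0.5
    rho: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class FiberLine:
    """One straight fiber chord across the unit square."""

    anchor: tuple[float, float]
    angle: float
    endpoints: np.ndarray  # (2, 2): two boundary points
    fiber_type: str  # "collagen" | "elastin"

    @property
    def direction(self) -> np.ndarray:
        d = self.endpoints[1] - self.endpoints[0]
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class Node:
    id: int
    position: tuple[float, float]
    kind: str  # "interior-crosslink" | "boundary-attachment" | "corner"


@dataclass(frozen=True)
class Segment:
    id: int
    node_a: int
    node_b: int
    seg_type: str  # "collagen" | "elastin" | "edge"
    r0: float
    k: float
    parent_fiber: int  # fiber index, or PERIMETER (-1)


def _chord_endpoints(anchor: np.ndarray, angle: float, tol: float = GEOM_TOL) -> np.ndarray:
    """Extend the line through ``anchor`` at ``angle`` to the square boundary.

    Returns the two boundary points ordered by the line parameter, so the
    anchor always lies between them.
    """
    d = np.array([np.cos(angle), np.sin(angle)])
    ts = []
    # line: p = anchor + t * d; intersect with x=0, x=1, y=0, y=1
    for axis, value in ((0, 0.0), (0, 1.0), (1, 0.0), (1, 1.0)):
        if abs(d[axis]) < 1e-15:
            continue
        t = (value - anchor[axis]) / d[axis]
        p = anchor + t * d
        other = 1 - axis
        if -tol <= p[other] <= 1.0 + tol:
            ts.append(t)
    if len(ts) < 2:
        raise ValueError("fiber line does not span the unit square")
    t_lo, t_hi = min(ts), max(ts)
    pts = np.array([anchor + t_lo * d, anchor + t_hi * d])
    return np.clip(pts, 0.0, 1.0)


def generate_fibers(config: NetworkConfig, rng: np.random.Generator) -> list[FiberLine]:
    """Seed ``config.n`` random fibers on the unit square.

    RNG draw order (fixed for reproducibility): anchors, angles, types.
    """
    n = config.n
    anchors = rng.uniform(0.0, 1.0, size=(n, 2))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    is_collagen = rng.uniform(0.0, 1.0, size=n) < config.alpha
    fibers = []
    for i in range(n):
        eps = _chord_endpoints(anchors[i], angles[i])
        fibers.append(
            FiberLine(
                anchor=(float(anchors[i, 0]), float(anchors[i, 1])),
                angle=float(angles[i]),
                endpoints=eps,
                fiber_type="collagen" if is_collagen[i] else "elastin",
            )
        )
    return fibers


def intersect_fibers(
    fibers: list[FiberLine], tol: float = GEOM_TOL
) -> list[tuple[int, int, tuple[float, float]]]:
    """All pairwise interior crossing points of the fiber chords.

    Each unordered pair appears at most once (i < j).  Near-parallel pairs
    (|sin of angle difference| < 1e-12) are treated as non-intersecting, as
    are crossings on or outside the square boundary.
    """
    ii, jj, pts = _intersect_arrays(fibers, tol)
    return [
        (int(i), int(j), (float(p[0]), float(p[1])))
        for i, j, p in zip(ii, jj, pts)
    ]


def _intersect_arrays(fibers: list[FiberLine], tol: float = GEOM_TOL):
    """Vectorised all-pairs chord intersection; returns (i, j, points)."""
    m = len(fibers)
    if m < 2:
        return np.empty(0, int), np.empty(0, int), np.empty((0, 2))
    P = np.array([f.endpoints[0] for f in fibers])  # (m, 2)
    Q = np.array([f.endpoints[1] for f in fibers])
    D = Q - P
    L = np.linalg.norm(D, axis=1)
    U = D / L[:, None]  # unit directions

    i, j = np.triu_indices(m, k=1)
    # cross product of unit directions = sin(angle difference)
    cross = U[i, 0] * U[j, 1] - U[i, 1] * U[j, 0]
    ok = np.abs(cross) >= PARALLEL_TOL
    i, j, cross = i[ok], j[ok], cross[ok]

    # solve P_i + s D_i = P_j + u D_j
    dP = P[j] - P[i]
    denom = D[i, 0] * D[j, 1] - D[i, 1] * D[j, 0]
    s = (dP[:, 0] * D[j, 1] - dP[:, 1] * D[j, 0]) / denom
    u = (dP[:, 0] * D[i, 1] - dP[:, 1] * D[i, 0]) / denom
    # strictly interior crossings only: endpoints live on the boundary, so
    # require the crossing to sit strictly inside both chords
    inside = (s > tol) & (s < 1.0 - tol) & (u > tol) & (u < 1.0 - tol)
    i, j, s = i[inside], j[inside], s[inside]
    pts = P[i] + s[:, None] * D[i]
    # exclude points that sit on the square boundary itself
    interior = np.all((pts > tol) & (pts < 1.0 - tol), axis=1)
    return i[interior], j[interior], pts[interior]


@dataclass
class FiberNetwork:
    """Geometric/topological state of one network realisation.

    Nodes and segments are stored as parallel flat arrays.  ``seg_r0`` /
    ``seg_k`` start as the as-built geometric lengths with unit spring
    constants and are overwritten by the constitutive initialisation.
    """

    config: NetworkConfig
    fibers: list[FiberLine]
    node_xy: np.ndarray  # (N, 2) float
    node_kind: np.ndarray  # (N,) int8
    node_side: np.ndarray  # (N,) uint8 bitmask of boundary sides
    seg_nodes: np.ndarray  # (S, 2) int
    seg_type: np.ndarray  # (S,) int8
    seg_r0: np.ndarray  # (S,) float
    seg_k: np.ndarray  # (S,) float
    seg_parent: np.ndarray  # (S,) int, PERIMETER for edge segments
    seg_w: np.ndarray  # (S,) float, waviness of collagen segments (nan else)
    n_crossings: int  # candidate cross-link sites (bonded or not)
    stage: str = "as-built"  # as-built | pre-equilibration | final

    # ------------------------------------------------------------------ views
    @property
    def n_nodes(self) -> int:
        return len(self.node_xy)

    @property
    def n_segments(self) -> int:
        return len(self.seg_nodes)

    @property
    def nodes(self) -> list[Node]:
        return [
            Node(i, (float(x), float(y)), NODE_KIND_NAMES[int(k)])
            for i, ((x, y), k) in enumerate(zip(self.node_xy, self.node_kind))
        ]

    @property
    def segments(self) -> list[Segment]:
        return [
            Segment(
                s,
                int(self.seg_nodes[s, 0]),
                int(self.seg_nodes[s, 1]),
                SEG_TYPE_NAMES[int(self.seg_type[s])],
                float(self.seg_r0[s]),
                float(self.seg_k[s]),
                int(self.seg_parent[s]),
            )
            for s in range(self.n_segments)
        ]

    def adjacency(self) -> dict[int, list[int]]:
        """node id -> list of incident segment ids."""
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for s, (a, b) in enumerate(self.seg_nodes):
            adj[int(a)].append(s)
            adj[int(b)].append(s)
        return adj

    def segment_lengths(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.node_xy if positions is None else positions
        d = pos[self.seg_nodes[:, 1]] - pos[self.seg_nodes[:, 0]]
        return np.linalg.norm(d, axis=1)

    def degrees(self) -> np.ndarray:
        """Number of incident segments per node."""
        return np.bincount(self.seg_nodes.ravel(), minlength=self.n_nodes)

    @property
    def interior_mask(self) -> np.ndarray:
        return self.node_kind == INTERIOR

    def type_mask(self, code: int) -> np.ndarray:
        return self.seg_type == code

    @property
    def collagen_mask(self) -> np.ndarray:
        return self.seg_type == COLLAGEN

    @property
    def fiber_mask(self) -> np.ndarray:
        """Fiber-derived segments (collagen + elastin, excluding perimeter)."""
        return self.seg_type != EDGE

    def side_nodes(self, side: int) -> np.ndarray:
        """Node ids lying on the given boundary side (corners included)."""
        return np.flatnonzero(self.node_side & side)

    def copy(self) -> "FiberNetwork":
        return replace(
            self,
            node_xy=self.node_xy.copy(),
            node_kind=self.node_kind.copy(),
            node_side=self.node_side.copy(),
            seg_nodes=self.seg_nodes.copy(),
            seg_type=self.seg_type.copy(),
            seg_r0=self.seg_r0.copy(),
            seg_k=self.seg_k.copy(),
            seg_parent=self.seg_parent.copy(),
            seg_w=self.seg_w.copy(),
        )

    # ---------------------------------------------------------- serialization
    def to_json(self, positions: np.ndarray | None = None) -> str:
        obj = {
            "format_version": FORMAT_VERSION,
            "config": {
                "n": self.config.n,
                "alpha": self.config.alpha,
                "rho": self.config.rho,
                "seed": self.config.seed,
            },
            "stage": self.stage,
            "n_crossings": self.n_crossings,
            "nodes": [
                {
                    "id": i,
                    "x": float(self.node_xy[i, 0]),
                    "y": float(self.node_xy[i, 1]),
                    "kind": NODE_KIND_NAMES[int(self.node_kind[i])],
                    "side": int(self.node_side[i]),
                }
                for i in range(self.n_nodes)
            ],
            "segments": [
                {
                    "id": s,
                    "a": int(self.seg_nodes[s, 0]),
                    "b": int(self.seg_nodes[s, 1]),
                    "type": SEG_TYPE_NAMES[int(self.seg_type[s])],
                    "r0": float(self.seg_r0[s]),
                    "k": float(self.seg_k[s]),
                    "parent": (
                        "perimeter"
                        if self.seg_parent[s] == PERIMETER
                        else int(self.seg_parent[s])
                    ),
                    "w": (None if np.isnan(self.seg_w[s]) else float(self.seg_w[s])),
                }
                for s in range(self.n_segments)
            ],
        }
        if positions is not None:
            obj["positions"] = [[float(x), float(y)] for x, y in positions]
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FiberNetwork":
        obj = json.loads(text)
        if obj.get("format_version") != FORMAT_VERSION:
            raise ValueError("unsupported network format version")
        cfg = NetworkConfig(**obj["config"])
        nodes = sorted(obj["nodes"], key=lambda d: d["id"])
        segs = sorted(obj["segments"], key=lambda d: d["id"])
        node_xy = np.array([[d["x"], d["y"]] for d in nodes], float).reshape(-1, 2)
        node_kind = np.array([NODE_KIND_CODES[d["kind"]] for d in nodes], np.int8)
        node_side = np.array([d.get("side", 0) for d in nodes], np.uint8)
        seg_nodes = np.array([[d["a"], d["b"]] for d in segs], int).reshape(-1, 2)
        seg_type = np.array([SEG_TYPE_CODES[d["type"]] for d in segs], np.int8)
        seg_r0 = np.array([d["r0"] for d in segs], float)
        seg_k = np.array([d["k"] for d in segs], float)
        seg_parent = np.array(
            [PERIMETER if d["parent"] == "perimeter" else d["parent"] for d in segs],
            int,
        )
        seg_w = np.array(
            [np.nan if d.get("w") is None else d["w"] for d in segs], float
        )
        return cls(
            config=cfg,
            fibers=[],
            node_xy=node_xy,
            node_kind=node_kind,
            node_side=node_side,
            seg_nodes=seg_nodes,
            seg_type=seg_type,
            seg_r0=seg_r0,
            seg_k=seg_k,
            seg_parent=seg_parent,
            seg_w=seg_w,
            n_crossings=int(obj.get("n_crossings", 0)),
            stage=obj.get("stage", "as-built"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "FiberNetwork":
        with open(path) as fh:
            return cls.from_json(fh.read())


_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def _side_mask(p: np.ndarray, tol: float = GEOM_TOL) -> int:
    mask = 0
    if p[0] <= tol:
        mask |= SIDE_LEFT
    if p[0] >= 1.0 - tol:
        mask |= SIDE_RIGHT
    if p[1] <= tol:
        mask |= SIDE_BOTTOM
    if p[1] >= 1.0 - tol:
        mask |= SIDE_TOP
    return mask


def build_network(
    fibers: list[FiberLine],
    intersections: list[tuple[int, int, tuple[float, float]]],
    rho: float,
    rng: np.random.Generator,
    config: NetworkConfig | None = None,
    tol: float = GEOM_TOL,
) -> FiberNetwork:
    """Assemble the segment graph from fibers and their crossing points.

    Each crossing is bonded into a shared node with one Bernoulli(rho) draw
    (in crossing order); unbonded crossings leave no node and the two fibers
    pass through each other without interacting.  Every fiber is split into
    segments at its bonded nodes and its two boundary attachment points; the
    perimeter is covered by elastin-typed edge segments between consecutive
    boundary nodes.  Crossing points or attachment points closer than ``tol``
    are merged into one node; attachment points within ``tol`` of a corner
    reuse the corner node.
    """
    if intersections:
        ii = np.array([t[0] for t in intersections], int)
        jj = np.array([t[1] for t in intersections], int)
        pts = np.array([t[2] for t in intersections], float)
    else:
        ii = jj = np.empty(0, int)
        pts = np.empty((0, 2))
    return _build_core(fibers, ii, jj, pts, rho, rng, config, tol)


def _build_core(
    fibers: list[FiberLine],
    ii: np.ndarray,
    jj: np.ndarray,
    pts: np.ndarray,
    rho: float,
    rng: np.random.Generator,
    config: NetworkConfig | None = None,
    tol: float = GEOM_TOL,
) -> FiberNetwork:
    if config is None:
        config = NetworkConfig(n=len(fibers), alpha=0.5, rho=rho, seed=0)
    m = len(fibers)
    n_cross = len(ii)
    bonded = rng.uniform(0.0, 1.0, size=n_cross) < rho
    bi, bj, bpts = ii[bonded], jj[bonded], pts[bonded]
    nb = len(bi)

    # candidate node points: 4 corners, 2m fiber endpoints, bonded crossings
    ends = (
        np.array([f.endpoints for f in fibers]).reshape(-1, 2)
        if m
        else np.empty((0, 2))
    )
    all_pts = np.vstack([_CORNERS, ends, bpts])

    # merge points within tol (union-find over close pairs; rare at tol=1e-9)
    canon = np.arange(len(all_pts))
    if len(all_pts) > 1:
        tree = cKDTree(all_pts)
        close = tree.query_pairs(max(tol, 1e-12))
        if close:
            for a, b in close:
                ra, rb = a, b
                while canon[ra] != ra:
                    ra = canon[ra]
                while canon[rb] != rb:
                    rb = canon[rb]
                if ra != rb:
                    canon[max(ra, rb)] = min(ra, rb)
            for idx in range(len(canon)):
                r = idx
                while canon[r] != r:
                    r = canon[r]
                canon[idx] = r

    roots, node_of_pt = np.unique(canon, return_inverse=True)
    node_xy = all_pts[roots].copy()
    n_nodes = len(node_xy)

    # snap boundary coordinates exactly onto the boundary
    node_xy[np.abs(node_xy) <= tol] = 0.0
    node_xy[np.abs(node_xy - 1.0) <= tol] = 1.0

    on_l = node_xy[:, 0] <= tol
    on_r = node_xy[:, 0] >= 1.0 - tol
    on_b = node_xy[:, 1] <= tol
    on_t = node_xy[:, 1] >= 1.0 - tol
    node_side = (
        on_l * SIDE_LEFT + on_r * SIDE_RIGHT + on_b * SIDE_BOTTOM + on_t * SIDE_TOP
    ).astype(np.uint8)
    n_sides = on_l.astype(int) + on_r + on_b + on_t
    node_kind = np.full(n_nodes, INTERIOR, np.int8)
    node_kind[n_sides == 1] = BOUNDARY
    node_kind[n_sides >= 2] = CORNER

    end_nodes = node_of_pt[4 : 4 + 2 * m].reshape(m, 2)
    cross_nodes = node_of_pt[4 + 2 * m :]

    # ---- split each fiber at its bonded crossing nodes (vectorised):
    # every (fiber, chord parameter t, node) hit, sorted per fiber by t
    P = ends.reshape(m, 2, 2)[:, 0, :]
    D = ends.reshape(m, 2, 2)[:, 1, :] - P
    L2 = np.einsum("ij,ij->i", D, D)
    if nb:
        t_i = np.einsum("ij,ij->i", bpts - P[bi], D[bi]) / L2[bi]
        t_j = np.einsum("ij,ij->i", bpts - P[bj], D[bj]) / L2[bj]
    else:
        t_i = t_j = np.empty(0)
    fib_idx = np.concatenate([bi, bj, np.arange(m), np.arange(m)])
    t_all = np.concatenate([t_i, t_j, np.zeros(m), np.ones(m)])
    nid_all = np.concatenate([cross_nodes, cross_nodes, end_nodes[:, 0], end_nodes[:, 1]])
    order = np.lexsort((t_all, fib_idx))
    f_o, n_o = fib_idx[order], nid_all[order]
    same_fiber = f_o[:-1] == f_o[1:]
    a = n_o[:-1][same_fiber]
    b = n_o[1:][same_fiber]
    par = f_o[:-1][same_fiber]
    keep = a != b  # merged points would give zero-length segments
    a, b, par = a[keep], b[keep], par[keep]
    fiber_type_code = np.array(
        [COLLAGEN if f.fiber_type == "collagen" else ELASTIN for f in fibers], np.int8
    )
    seg_t_fiber = fiber_type_code[par] if m else np.empty(0, np.int8)

    # ---- perimeter edge segments between consecutive boundary nodes,
    # walking bottom L->R, right B->T, top R->L, left T->B
    bid = np.flatnonzero(node_side != 0)
    x, y = node_xy[bid, 0], node_xy[bid, 1]
    coord = np.where(
        (y <= tol) & (x < 1.0 - tol),
        x,
        np.where(
            (x >= 1.0 - tol) & (y < 1.0 - tol),
            1.0 + y,
            np.where((y >= 1.0 - tol) & (x > tol), 3.0 - x, 4.0 - y),
        ),
    )
    walk = bid[np.argsort(coord, kind="stable")]
    pa, pb = walk, np.roll(walk, -1)
    pkeep = pa != pb
    pa, pb = pa[pkeep], pb[pkeep]

    seg_nodes = np.column_stack(
        [np.concatenate([a, pa]), np.concatenate([b, pb])]
    ).astype(int)
    seg_type = np.concatenate([seg_t_fiber, np.full(len(pa), EDGE, np.int8)])
    seg_parent = np.concatenate([par, np.full(len(pa), PERIMETER)]).astype(int)

    net = FiberNetwork(
        config=config,
        fibers=fibers,
        node_xy=node_xy,
        node_kind=node_kind,
        node_side=node_side,
        seg_nodes=seg_nodes,
        seg_type=seg_type,
        seg_r0=np.zeros(len(seg_type)),
        seg_k=np.ones(len(seg_type)),
        seg_parent=seg_parent,
        seg_w=np.full(len(seg_type), np.nan),
        n_crossings=n_cross,
    )
    net.seg_r0 = net.segment_lengths()
    return net


def generate_network(config: NetworkConfig, rng: np.random.Generator | None = None) -> FiberNetwork:
    """Full pipeline: seed fibers, intersect, cross-link, assemble."""
    if rng is None:
        rng = config.rng()
    fibers = generate_fibers(config, rng)
    ii, jj, pts = _intersect_arrays(fibers)
    return _build_core(fibers, ii, jj, pts, config.rho, rng, config=config)


def average_degree(network: FiberNetwork, population: str = "crossings") -> float:
    """Mean connectivity degree of the network.

    population
        ``"crossings"`` (default): total degree of interior cross-link nodes
        divided by the number of candidate cross-link sites (fiber–fiber
        crossings), bonded or not — an unbonded crossing contributes degree 0.
        With cross-linking probability rho this averages 4·rho (3.4 at the
        baseline rho = 0.85).
        ``"interior-nodes"``: mean degree over existing interior nodes only
        (exactly 4 in an un-merged network, for any rho).
        ``"all-nodes"``: mean degree over every node including boundary
        attachments and corners.
    """
    deg = network.degrees()
    interior = network.interior_mask
    if population == "crossings":
        if network.n_crossings == 0:
            raise ValueError("degenerate network: no fiber crossings")
        return float(deg[interior].sum() / network.n_crossings)
    if population == "interior-nodes":
        if not interior.any():
            raise ValueError("degenerate network: no interior nodes")
        return float(deg[interior].mean())
    if population == "all-nodes":
        if network.n_nodes == 0:
            raise ValueError("degenerate network: no nodes")
        return float(deg.mean())
    raise ValueError(f"unknown population {population!r}")
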