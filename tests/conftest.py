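import numpy as np
import pytest

from alveonet.netgen import (
    BOUNDARY,
    COLLAGEN,
    CORNER,
    EDGE,
    ELASTIN,
    INTERIOR,
    PERIMETER,
    SIDE_BOTTOM,
    SIDE_LEFT,
    SIDE_RIGHT,
    SIDE_TOP,
    FiberLine,
    FiberNetwork,
    NetworkConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_line(p, q, fiber_type="collagen"):
    """FiberLine between two boundary points (anchor at the midpoint)."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    d = q - p
    return FiberLine(
        anchor=tuple((p + q) / 2.0),
        angle=float(np.arctan2(d[1], d[0]) % (2.0 * np.pi)),
        endpoints=np.array([p, q]),
        fiber_type=fiber_type,
    )


def side_mask_of(p, tol=1e-9):
    m = 0
    if p[0] <= tol:
        m |= SIDE_LEFT
    if p[0] >= 1 - tol:
        m |= SIDE_RIGHT
    if p[1] <= tol:
        m |= SIDE_BOTTOM
    if p[1] >= 1 - tol:
        m |= SIDE_TOP
    return m


def make_toy_network(node_xy, segments, n_crossings=1, stage="final"):
    """Hand-built FiberNetwork from (N,2) positions and segment tuples.

    segments: list of (a, b, type_code, r0, k) with type codes from netgen.
    Node kinds/sides are inferred from the positions.
    """
    node_xy = np.asarray(node_xy, float)
    side = np.array([side_mask_of(p) for p in node_xy], np.uint8)
    kind = np.full(len(node_xy), INTERIOR, np.int8)
    nbits = np.array([bin(int(s)).count("1") for s in side])
    kind[nbits == 1] = BOUNDARY
    kind[nbits >= 2] = CORNER
    seg = np.array([(a, b) for a, b, *_ in segments], int).reshape(-1, 2)
    st = np.array([t for _, _, t, *_ in segments], np.int8)
    r0 = np.array([r for *_, r, _ in segments], float)
    k = np.array([kk for *_, kk in segments], float)
    parent = np.where(st == EDGE, PERIMETER, 0)
    return FiberNetwork(
        config=NetworkConfig(n=1, alpha=1.0, rho=1.0, seed=0),
        fibers=[],
        node_xy=node_xy,
        node_kind=kind,
        node_side=side,
        seg_nodes=seg,
        seg_type=st,
        seg_r0=r0,
        seg_k=k,
        seg_parent=parent,
        seg_w=np.full(len(st), np.nan),
        n_crossings=n_crossings,
        stage=stage,
    )
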