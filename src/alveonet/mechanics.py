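"""Spring-network elasticity: energy, forces, equilibration, uniaxial stretch.

Every segment is a Hookean spring with energy U = 1/2 k (d - r0)^2, where d
is the current end-to-end distance.  Collagen is one-sided: a collagen
segment with d <= r0 is slack ("unrecruited") and stores no energy; once
d > r0 it is recruited and behaves as an ordinary spring.  Elastin and edge
springs support both tension and compression.

Uniaxial stretch moves the right boundary of the unit square outward in 5%
strain increments up to 100% strain.  Left- and right-edge nodes are
constrained to remain co-linear (fixed abscissa, free ordinate); all other
nodes, including top/bottom attachments, are fully free, so the sample may
neck inward.  At each increment the network is relaxed to an energy minimum
(quasi-Newton, warm-started from the previous step) until the net force on
every free node is below 1e-2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _lbfgs
from .netgen import (
    COLLAGEN,
    SIDE_BOTTOM,
    SIDE_LEFT,
    SIDE_RIGHT,
    SIDE_TOP,
    FiberNetwork,
    Segment,
)

#: residual net-force threshold per node
FORCE_TOL = 1e-2
#: energy/gradient evaluation cap per equilibration step
MAX_EVALS = 50_000
#: minimum spring length used to define a force direction
_D_FLOOR = 1e-300


@dataclass(frozen=True)
class Constraints:
    """Fixed-abscissa constraints of the uniaxial stretch geometry."""

    left_x: float
    right_x: float
    left_nodes: np.ndarray
    right_nodes: np.ndarray
    fixed_mask: np.ndarray  # (N, 2) bool, True where a coordinate is fixed
    fixed_values: np.ndarray  # (N, 2), values at fixed coordinates

    @classmethod
    def from_network(
        cls, network: FiberNetwork, strain: float = 0.0, width: float = 1.0
    ) -> "Constraints":
        left_x = 0.0
        right_x = width * (1.0 + strain)
        left = network.side_nodes(SIDE_LEFT)
        right = network.side_nodes(SIDE_RIGHT)
        fixed_mask = np.zeros((network.n_nodes, 2), bool)
        fixed_values = np.zeros((network.n_nodes, 2))
        fixed_mask[left, 0] = True
        fixed_values[left, 0] = left_x
        fixed_mask[right, 0] = True
        fixed_values[right, 0] = right_x
        if left_x >= right_x:
            raise ValueError("left_x must be smaller than right_x")
        return cls(left_x, right_x, left, right, fixed_mask, fixed_values)

    @classmethod
    def frame(cls, network: FiberNetwork) -> "Constraints":
        """Hold all four edges of the unit square co-linear.

        Left/right nodes keep x fixed, top/bottom nodes keep y fixed
        (corners both); every boundary node may still slide along its own
        edge.  Used for the initial (pre-stretch) equilibration so the
        reference configuration stays spread over the unit square.
        """
        left = network.side_nodes(SIDE_LEFT)
        right = network.side_nodes(SIDE_RIGHT)
        bottom = network.side_nodes(SIDE_BOTTOM)
        top = network.side_nodes(SIDE_TOP)
        fixed_mask = np.zeros((network.n_nodes, 2), bool)
        fixed_values = np.zeros((network.n_nodes, 2))
        fixed_mask[left, 0] = True
        fixed_values[left, 0] = 0.0
        fixed_mask[right, 0] = True
        fixed_values[right, 0] = 1.0
        fixed_mask[bottom, 1] = True
        fixed_values[bottom, 1] = 0.0
        fixed_mask[top, 1] = True
        fixed_values[top, 1] = 1.0
        return cls(0.0, 1.0, left, right, fixed_mask, fixed_values)

    def apply(self, positions: np.ndarray) -> np.ndarray:
        pos = positions.copy()
        pos[self.fixed_mask] = self.fixed_values[self.fixed_mask]
        return pos


@dataclass
class EquilibriumState:
    positions: np.ndarray  # (N, 2)
    total_energy: float
    max_residual: float  # largest net-force magnitude over free coordinates
    converged: bool
    n_evaluations: int = 0


@dataclass
class StretchResult:
    """Per-strain-step readouts of one uniaxial stretch protocol."""

    strain: np.ndarray
    force: np.ndarray  # total horizontal force on the right boundary
    stress: np.ndarray  # force / reference cross-section
    recruitment: np.ndarray  # recruited fraction of collagen segments
    percolated: np.ndarray  # bool: spanning recruited-collagen path exists
    converged: np.ndarray  # bool per step
    energy: np.ndarray
    max_residual: np.ndarray
    positions: list[np.ndarray] = field(default_factory=list, repr=False)
    network: FiberNetwork | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": self.strain,
                "force": self.force,
                "stress": self.stress,
                "recruitment_fraction": self.recruitment,
                "percolated": self.percolated.astype(int),
                "converged": self.converged.astype(int),
                "energy": self.energy,
            }
        )


def segment_energy(d: float, seg: Segment) -> float:
    """Spring energy of one segment at end-to-end distance ``d``.

    Collagen with d <= r0 is unrecruited and stores no energy.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    if seg.seg_type == "collagen" and d <= seg.r0:
        return 0.0
    return 0.5 * seg.k * (d - seg.r0) ** 2


def _spring_terms(network: FiberNetwork, positions: np.ndarray):
    """Per-segment extension, distance and activity mask."""
    a = network.seg_nodes[:, 0]
    b = network.seg_nodes[:, 1]
    dvec = positions[b] - positions[a]
    d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
    ext = d - network.seg_r0
    active = (network.seg_type != COLLAGEN) | (ext > 0)
    return a, b, dvec, d, ext, active


def total_energy(network: FiberNetwork, positions: np.ndarray) -> float:
    """Sum of spring energies over all segments (non-negative)."""
    _, _, _, _, ext, active = _spring_terms(network, positions)
    return float(0.5 * np.sum(network.seg_k * ext**2 * active))


def nodal_forces(network: FiberNetwork, positions: np.ndarray) -> np.ndarray:
    """Net spring force on every node: minus the energy gradient, (N, 2)."""
    a, b, dvec, d, ext, active = _spring_terms(network, positions)
    tension = np.where(active, network.seg_k * ext, 0.0)
    coef = tension / np.maximum(d, _D_FLOOR)
    fa = coef[:, None] * dvec  # pull on node a toward node b when taut
    n = network.n_nodes
    forces = np.empty((n, 2))
    for axis in range(2):
        forces[:, axis] = np.bincount(a, fa[:, axis], minlength=n) - np.bincount(
            b, fa[:, axis], minlength=n
        )
    return forces


def residual_force(
    network: FiberNetwork, positions: np.ndarray, constraints: Constraints
) -> float:
    """Largest net-force magnitude over free nodal coordinates."""
    f = nodal_forces(network, positions)
    f[constraints.fixed_mask] = 0.0
    return float(np.sqrt((f**2).sum(axis=1)).max()) if len(f) else 0.0


def _equilibrate_scipy(network, constraints, base, free_idx, anchor, force_tol,
                       max_evals, tether):
    """Reference minimisation route through scipy.optimize (L-BFGS-B)."""
    a = network.seg_nodes[:, 0]
    b = network.seg_nodes[:, 1]
    k = network.seg_k
    r0 = network.seg_r0
    not_collagen = network.seg_type != COLLAGEN
    n = network.n_nodes
    n_eval = 0

    def fun(x):
        nonlocal n_eval
        n_eval += 1
        pos = base.copy()
        pos.ravel()[free_idx] = x
        dvec = pos[b] - pos[a]
        d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        ext = d - r0
        active = not_collagen | (ext > 0)
        kx = np.where(active, k * ext, 0.0)
        energy = 0.5 * float(np.dot(kx, np.where(active, ext, 0.0)))
        coef = kx / np.maximum(d, _D_FLOOR)
        g = coef[:, None] * dvec
        grad = np.empty((n, 2))
        for axis in range(2):
            grad[:, axis] = np.bincount(b, g[:, axis], minlength=n) - np.bincount(
                a, g[:, axis], minlength=n
            )
        gfree = grad.ravel()[free_idx]
        if tether > 0.0:
            dx = x - anchor
            energy += 0.5 * tether * float(np.dot(dx, dx))
            gfree = gfree + tether * dx
        return energy, gfree

    # pgtol bounds single coordinates: per-node norm <= sqrt(2) * max coord
    pgtol = force_tol / 2.0
    x = base.ravel()[free_idx]
    for _ in range(4):  # restarts sharpen stalls near the tolerance
        out = minimize(
            fun, x, jac=True, method="L-BFGS-B",
            options={"maxfun": max(1, max_evals - n_eval),
                     "maxiter": max(1, max_evals - n_eval),
                     "ftol": 1e-16, "gtol": pgtol, "maxcor": 20},
        )
        x = out.x
        pos = base.copy()
        pos.ravel()[free_idx] = x
        res = residual_force(network, pos, constraints)
        if res <= force_tol or n_eval >= max_evals:
            break
        pgtol /= 10.0
    return pos, res, n_eval


def _equilibrate_own(network, constraints, base, free_idx, force_tol, max_evals,
                     tether):
    """Own L-BFGS route (numba-compiled when available)."""
    a = np.ascontiguousarray(network.seg_nodes[:, 0], np.int64)
    b = np.ascontiguousarray(network.seg_nodes[:, 1], np.int64)
    is_col = network.seg_type == COLLAGEN
    fixed_flat = constraints.fixed_mask.ravel()
    base_flat = base.ravel().copy()
    x = base_flat[free_idx]
    # diagonal inverse-Hessian seed: 1 / total spring stiffness at each node
    stiff = np.zeros(network.n_nodes)
    np.add.at(stiff, network.seg_nodes[:, 0], network.seg_k)
    np.add.at(stiff, network.seg_nodes[:, 1], network.seg_k)
    h0 = np.repeat(1.0 / np.maximum(stiff, 1e-12), 2)[free_idx].copy()
    n_eval = 0
    res = np.inf
    for _ in range(4):  # fresh-memory restarts after line-search stalls
        x, _, res, ne = _lbfgs.lbfgs_minimize(
            x, base_flat, free_idx, fixed_flat, a, b, network.seg_k,
            network.seg_r0, is_col, force_tol, max(1, max_evals - n_eval),
            20, tether, h0,
        )
        n_eval += ne
        if res <= force_tol or n_eval >= max_evals:
            break
    pos = base_flat.copy()
    pos[free_idx] = x
    return pos.reshape(-1, 2), float(res), n_eval


def equilibrate(
    network: FiberNetwork,
    constraints: Constraints,
    start_positions: np.ndarray,
    force_tol: float = FORCE_TOL,
    max_evals: int = MAX_EVALS,
    tether: float = 0.0,
    method: str = "lbfgs",
) -> EquilibriumState:
    """Minimise total energy over free coordinates at fixed boundary abscissae.

    Quasi-Newton (L-BFGS) minimisation with analytic gradient; the residual
    per-node net force is verified against ``force_tol`` (1e-2 by default).
    Non-convergence within the evaluation cap returns a state with
    ``converged=False`` and a warning, never an exception.

    ``method="lbfgs"`` (default) uses the package's compiled L-BFGS;
    ``method="scipy"`` routes through scipy.optimize.minimize (slower,
    kept as an independent cross-check).

    ``tether`` optionally adds a tiny quadratic well (weight ~1e-8)
    anchoring every free coordinate to its warm-start value.  This
    conditions the otherwise indeterminate positions of "floppy" nodes
    attached only to slack collagen; it is off by default and excluded
    from the residual-force criterion.
    """
    base = constraints.apply(start_positions)
    free_idx = np.flatnonzero(~constraints.fixed_mask.ravel())
    if len(free_idx) == 0:
        return EquilibriumState(base, total_energy(network, base), 0.0, True, 0)

    if method == "lbfgs":
        pos, res_force, n_eval = _equilibrate_own(
            network, constraints, base, free_idx, force_tol, max_evals, tether
        )
    elif method == "scipy":
        anchor = base.ravel()[free_idx].copy()
        pos, res_force, n_eval = _equilibrate_scipy(
            network, constraints, base, free_idx, anchor, force_tol, max_evals,
            tether,
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    converged = res_force <= force_tol
    if not converged:
        warnings.warn(
            f"equilibrate: residual force {res_force:.3g} above tolerance "
            f"{force_tol:g} after {n_eval} evaluations",
            RuntimeWarning,
            stacklevel=2,
        )
    return EquilibriumState(pos, total_energy(network, pos), res_force, converged, n_eval)


def boundary_force(
    network: FiberNetwork, positions: np.ndarray, constraints: Constraints
) -> float:
    """Total horizontal stretching force applied at the right boundary.

    Equals minus the sum of the horizontal spring-force components on the
    right-edge nodes (the constraint reaction holding the boundary out).
    """
    f = nodal_forces(network, positions)
    return float(-f[constraints.right_nodes, 0].sum())


def stress_from_force(force: float, strain: float, area_mode: str = "reference",
                      current_height: float | None = None) -> float:
    """Nominal stress: boundary force over the reference cross-section.

    The reference cross-section is the undeformed right-edge length (1) times
    unit thickness at every step, so stress equals force in these units.
    ``area_mode="current"`` divides by the current (necked) right-edge
    height instead.
    """
    if area_mode == "reference":
        return float(force)
    if area_mode == "current":
        if current_height is None or current_height <= 0:
            raise ValueError("current area mode needs a positive edge height")
        return float(force / current_height)
    raise ValueError(f"unknown area_mode {area_mode!r}")


def recruitment_fraction(network: FiberNetwork, positions: np.ndarray) -> float:
    """Fraction of collagen segments that are taut (d > r0)."""
    col = network.collagen_mask
    n_col = int(col.sum())
    if n_col == 0:
        raise ValueError("network has no collagen segments")
    d = network.segment_lengths(positions)
    return float(np.count_nonzero(d[col] > network.seg_r0[col]) / n_col)


def strain_grid(strain_step: float = 0.05, strain_max: float = 1.0) -> np.ndarray:
    n_steps = int(round(strain_max / strain_step))
    return np.round(np.linspace(0.0, strain_max, n_steps + 1), 12)


def run_stretch_protocol(
    network: FiberNetwork,
    start_positions: np.ndarray | None = None,
    strain_step: float = 0.05,
    strain_max: float = 1.0,
    force_tol: float = FORCE_TOL,
    max_evals: int = MAX_EVALS,
    tether: float = 0.0,
    area_mode: str = "reference",
    keep_positions: bool = True,
    method: str = "lbfgs",
) -> StretchResult:
    """Quasi-static uniaxial stretch in ``strain_step`` increments.

    Each step fixes the right-edge abscissa at 1 + strain, warm-starts from
    the previous equilibrium with all x-coordinates scaled affinely to the
    new width (which shifts the right-edge nodes onto the new abscissa),
    relaxes, and records force, stress, collagen recruitment and the
    mechanical-percolation flag.  Non-convergence at a step is recorded and
    the protocol continues.
    """
    from .percolation import mechanical_percolation

    if network.stage != "final":
        raise ValueError("network must be constitutively finalised before stretching")
    grid = strain_grid(strain_step, strain_max)
    pos = (network.node_xy if start_positions is None else start_positions).copy()
    prev_width = 1.0

    n_steps = len(grid)
    force = np.zeros(n_steps)
    stress = np.zeros(n_steps)
    recruit = np.zeros(n_steps)
    percolated = np.zeros(n_steps, bool)
    converged = np.zeros(n_steps, bool)
    energy = np.zeros(n_steps)
    residual = np.zeros(n_steps)
    snapshots: list[np.ndarray] = []

    for step, eps in enumerate(grid):
        cons = Constraints.from_network(network, strain=float(eps))
        width = 1.0 + float(eps)
        pos[:, 0] *= width / prev_width  # affine warm start
        prev_width = width
        state = equilibrate(network, cons, pos, force_tol, max_evals, tether,
                            method=method)
        pos = state.positions
        f = boundary_force(network, pos, cons)
        height = float(np.ptp(pos[cons.right_nodes, 1])) if len(cons.right_nodes) else 1.0
        force[step] = f
        stress[step] = stress_from_force(f, float(eps), area_mode, current_height=height)
        if network.collagen_mask.any():
            recruit[step] = recruitment_fraction(network, pos)
            percolated[step] = mechanical_percolation(network, pos).percolates
        else:  # pure elastin/edge network: nothing to recruit
            recruit[step] = 0.0
            percolated[step] = False
        converged[step] = state.converged
        energy[step] = state.total_energy
        residual[step] = state.max_residual
        if keep_positions:
            snapshots.append(pos.copy())

    return StretchResult(
        strain=grid,
        force=force,
        stress=stress,
        recruitment=recruit,
        percolated=percolated,
        converged=converged,
        energy=energy,
        max_residual=residual,
        positions=snapshots,
        network=network,
    )


def incremental_modulus(result_or_strain, stress: np.ndarray | None = None) -> np.ndarray:
    """Finite-difference slope d(stress)/d(strain) on the strain grid."""
    if stress is None:
        strain, stress = result_or_strain.strain, result_or_strain.stress
    else:
        strain = result_or_strain
    if len(strain) < 2:
        raise ValueError("need at least two strain steps")
    return np.gradient(np.asarray(stress, float), np.asarray(strain, float))
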