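"""Compiled energy/gradient kernels and an L-BFGS loop (numba).

The spring-network energy landscape is smooth (C1: the collagen slack
clause zeroes force continuously at d = r0) but stiff — spring constants
span ~5 orders of magnitude once collagen is amplified — so minimisation
needs many cheap iterations.  These kernels keep each energy/gradient
evaluation and the L-BFGS two-loop recursion free of interpreter overhead.

All functions are importable without numba installed (pure-Python
fallback); with numba they are jit-compiled on first use.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def energy_grad(x, base, free_idx, a, b, k, r0, is_col, grad_full):
    """Total spring energy and its gradient over the free coordinates.

    ``base`` is the flattened (2N,) position array with fixed coordinates
    already applied; ``x`` holds the free coordinates (scattered into base
    via ``free_idx``).  ``grad_full`` (2N,) is overwritten with the full
    gradient so the caller can read nodal residual forces.
    """
    pos = base.copy()
    for i in range(free_idx.size):
        pos[free_idx[i]] = x[i]
    grad_full[:] = 0.0
    energy = 0.0
    for s in range(a.size):
        ia, ib = 2 * a[s], 2 * b[s]
        dx = pos[ib] - pos[ia]
        dy = pos[ib + 1] - pos[ia + 1]
        d = math.sqrt(dx * dx + dy * dy)
        ext = d - r0[s]
        if is_col[s] and ext <= 0.0:
            continue  # slack (unrecruited) collagen
        energy += 0.5 * k[s] * ext * ext
        if d > 0.0:
            c = k[s] * ext / d
            gx = c * dx
            gy = c * dy
            grad_full[ib] += gx
            grad_full[ib + 1] += gy
            grad_full[ia] -= gx
            grad_full[ia + 1] -= gy
    g = np.empty(free_idx.size)
    for i in range(free_idx.size):
        g[i] = grad_full[free_idx[i]]
    return energy, g


@njit(cache=True)
def max_node_residual(grad_full, fixed_flat):
    """Largest net spring-force magnitude over free nodal coordinates."""
    best = 0.0
    for i in range(grad_full.size // 2):
        fx = 0.0 if fixed_flat[2 * i] else grad_full[2 * i]
        fy = 0.0 if fixed_flat[2 * i + 1] else grad_full[2 * i + 1]
        r = math.sqrt(fx * fx + fy * fy)
        if r > best:
            best = r
    return best


@njit(cache=True)
def lbfgs_minimize(
    x0,
    base,
    free_idx,
    fixed_flat,
    a,
    b,
    k,
    r0,
    is_col,
    force_tol,
    max_evals,
    mem,
    tether,
    h0,
):
    """L-BFGS with Armijo backtracking, stopping on the nodal-force residual.

    Convergence criterion: the largest per-node net *spring* force over free
    coordinates drops to ``force_tol``.  ``h0`` is a per-coordinate diagonal
    seed for the inverse Hessian (1 / total incident spring stiffness); the
    huge stiffness contrast between amplified collagen and unit-stiffness
    elastin makes this preconditioning essential for fast convergence.
    ``tether > 0`` adds a quadratic well of that weight anchoring each free
    coordinate at its start value (conditioning aid for floppy nodes); the
    tether enters the objective and its gradient but not the residual
    criterion.

    Returns (x, energy, residual, n_evals).
    """
    n = x0.size
    x = x0.copy()
    anchor = x0.copy()
    grad_full = np.zeros(base.size)
    S = np.zeros((mem, n))
    Y = np.zeros((mem, n))
    rho = np.zeros(mem)
    alpha = np.zeros(mem)

    f, g = energy_grad(x, base, free_idx, a, b, k, r0, is_col, grad_full)
    n_eval = 1
    n_pairs = 0
    head = 0
    res = max_node_residual(grad_full, fixed_flat)

    while n_eval < max_evals and res > force_tol:
        # two-loop recursion for the quasi-Newton direction
        q = -g.copy()
        if n_pairs > 0:
            for jj in range(n_pairs):
                idx = (head - 1 - jj) % mem
                alpha[idx] = rho[idx] * np.dot(S[idx], q)
                q -= alpha[idx] * Y[idx]
            last = (head - 1) % mem
            yhy = 0.0
            for i in range(n):
                yhy += Y[last, i] * h0[i] * Y[last, i]
            gam = np.dot(S[last], Y[last]) / yhy if yhy > 0.0 else 1.0
            for i in range(n):
                q[i] *= gam * h0[i]
            for jj in range(n_pairs - 1, -1, -1):
                idx = (head - 1 - jj) % mem
                beta = rho[idx] * np.dot(Y[idx], q)
                q += (alpha[idx] - beta) * S[idx]
        else:
            for i in range(n):
                q[i] *= h0[i]
        d = q
        dg = np.dot(d, g)
        if dg >= 0.0:  # safeguard: fall back to preconditioned steepest descent
            d = -g * h0
            dg = np.dot(d, g)
            n_pairs = 0
            head = 0
        if dg >= 0.0:
            break

        # Armijo backtracking line search
        t = 1.0
        ok = False
        fn = f
        gn = g
        for _ in range(40):
            xn = x + t * d
            fn, gn = energy_grad(xn, base, free_idx, a, b, k, r0, is_col, grad_full)
            if tether > 0.0:
                dxa = xn - anchor
                fn += 0.5 * tether * np.dot(dxa, dxa)
                gn = gn + tether * dxa
            n_eval += 1
            if fn <= f + 1e-4 * t * dg or n_eval >= max_evals:
                ok = fn <= f + 1e-4 * t * dg
                break
            t *= 0.5
        if not ok:
            # line search stalled: refresh gradient state at x and stop
            f, g = energy_grad(x, base, free_idx, a, b, k, r0, is_col, grad_full)
            n_eval += 1
            res = max_node_residual(grad_full, fixed_flat)
            return x, f, res, n_eval

        s = xn - x
        yv = gn - g
        sy = np.dot(s, yv)
        if sy > 1e-12 * math.sqrt(np.dot(s, s)) * math.sqrt(np.dot(yv, yv)):
            S[head] = s
            Y[head] = yv
            rho[head] = 1.0 / sy
            head = (head + 1) % mem
            if n_pairs < mem:
                n_pairs += 1
        x = xn
        f = fn
        g = gn
        res = max_node_residual(grad_full, fixed_flat)

    return x, f, res, n_eval
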