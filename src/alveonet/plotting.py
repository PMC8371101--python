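"""Network and result rendering (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mechanics import nodal_forces
from .netgen import COLLAGEN, EDGE, ELASTIN, FiberNetwork


def plot_network(
    network: FiberNetwork,
    positions: np.ndarray | None = None,
    ax=None,
    node_scale: float = 20.0,
):
    """Draw the network: elastin blue, collagen red (bright when recruited),
    perimeter gray; node glyph size grows with the log of the net force."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pos = network.node_xy if positions is None else positions
    d = network.segment_lengths(pos)
    colors = {ELASTIN: "#3b6fb6", EDGE: "#9aa0a6"}
    for s in range(network.n_segments):
        a, b = network.seg_nodes[s]
        t = int(network.seg_type[s])
        if t == COLLAGEN:
            recruited = d[s] > network.seg_r0[s]
            color = "#e3342f" if recruited else "#7a1f1c"
            lw = 1.4 if recruited else 1.0
        else:
            color = colors[t]
            lw = 0.9
        ax.plot(
            [pos[a, 0], pos[b, 0]], [pos[a, 1], pos[b, 1]],
            color=color, lw=lw, solid_capstyle="round", zorder=1,
        )
    interior = network.interior_mask
    if interior.any():
        f = np.linalg.norm(nodal_forces(network, pos), axis=1)[interior]
        size = node_scale * np.log10(1.0 + f / 1e-3) / 3.0 + 2.0
        ax.scatter(pos[interior, 0], pos[interior, 1], s=size,
                   c="black", zorder=2, linewidths=0)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_stress_strain(ensembles: dict, ax=None, level: float = 0.99):
    """Mean stress-strain curves with shaded confidence bands per condition."""
    if ax is None:
        _, ax = plt.subplots()
    for name, ens in ensembles.items():
        mean, lo, hi = ens.stress_ci(level)
        (line,) = ax.plot(ens.strain, mean, label=name)
        ax.fill_between(ens.strain, lo, hi, alpha=0.25, color=line.get_color())
    ax.set_xlabel("strain")
    ax.set_ylabel("normalized stress")
    ax.legend()
    return ax


def plot_percolation_curve(curve, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.p_grid, curve.mean_giant_fraction)
    ax.axvline(curve.threshold, ls="--", color="gray",
               label=f"threshold {curve.threshold:.3f}")
    ax.set_xlabel("occupation probability")
    ax.set_ylabel("giant component fraction")
    ax.legend()
    return ax
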