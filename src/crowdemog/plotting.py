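"""Plot helpers: ternary weight distributions, joint-SFS heatmaps, and
profile-likelihood curves.  All functions return the matplotlib Axes and
accept an existing one, so they compose into multi-panel figures."""

from __future__ import annotations

import math

import numpy as np


def _require_axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def _ternary_xy(w):
    """Project simplex weights (w1, w2, w3) to 2-D (equilateral triangle
    with corners w1 bottom-left, w2 bottom-right, w3 top)."""
    w = np.asarray(w, dtype=float)
    x = w[..., 1] + 0.5 * w[..., 2]
    y = w[..., 2] * math.sqrt(3) / 2
    return x, y


def plot_ternary_weights(weights, ax=None, labels=("topo1", "topo2", "topo3"),
                         **scatter_kw):
    """Scatter of three-topology weight vectors on the simplex."""
    ax = _require_axes(ax)
    x, y = _ternary_xy(np.asarray(weights, dtype=float))
    tri_x = [0, 1, 0.5, 0]
    tri_y = [0, 0, math.sqrt(3) / 2, 0]
    ax.plot(tri_x, tri_y, color="k", lw=0.8)
    scatter_kw.setdefault("s", 6)
    scatter_kw.setdefault("alpha", 0.5)
    ax.scatter(x, y, **scatter_kw)
    ax.text(-0.02, -0.02, labels[0], ha="right", va="top")
    ax.text(1.02, -0.02, labels[1], ha="left", va="top")
    ax.text(0.5, math.sqrt(3) / 2 + 0.02, labels[2], ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_ternary_grid(grid, ax=None, cmap="viridis"):
    """Filled triangular cells of a TernaryBinGrid (counts as colour)."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    ax = _require_axes(ax)
    k = grid.k
    polys, vals = [], []
    for (i, j, o), c in grid.counts.items():
        if o == 0:
            corners = [(i, j, k - 1 - i - j), (i + 1, j, k - 1 - i - j),
                       (i, j + 1, k - 1 - i - j)]
        else:
            corners = [(i + 1, j, k - 2 - i - j), (i, j + 1, k - 2 - i - j),
                       (i + 1, j + 1, k - 2 - i - j)]
        pts = [_ternary_xy(np.array(p, dtype=float) / k) for p in corners]
        polys.append(pts)
        vals.append(c)
    pc = PolyCollection(polys, array=np.array(vals), cmap=cmap,
                        edgecolors="none")
    ax.add_collection(pc)
    plt.colorbar(pc, ax=ax, label="blocks")
    ax.plot([0, 1, 0.5, 0], [0, 0, math.sqrt(3) / 2, 0], color="k", lw=0.8)
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, math.sqrt(3) / 2 + 0.05)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_jsfs(jsfs, ax=None, log: bool = True):
    """Heatmap of a folded joint SFS (masked corners blank)."""
    ax = _require_axes(ax)
    mat = np.where(jsfs.mask, jsfs.matrix, np.nan)
    with np.errstate(divide="ignore"):
        img = np.log10(mat + 1) if log else mat
    im = ax.imshow(img.T, origin="lower", aspect="auto", cmap="magma")
    import matplotlib.pyplot as plt

    plt.colorbar(im, ax=ax, label="log10(sites+1)" if log else "sites")
    ax.set_xlabel(f"minor allele count {jsfs.pop_a}")
    ax.set_ylabel(f"minor allele count {jsfs.pop_b}")
    return ax


def plot_profile(grid, loglik, truth=None, ax=None, xlabel="parameter"):
    """Profile of the composite log10-likelihood over a parameter grid."""
    ax = _require_axes(ax)
    ll = np.asarray(loglik, dtype=float)
    ax.plot(grid, ll - np.nanmax(ll), marker="o", ms=3)
    if truth is not None:
        ax.axvline(truth, color="grey", ls="--", lw=0.8, label="truth")
        ax.legend()
    ax.set_xlabel(xlabel)
    ax.set_ylabel("Δ log10 composite likelihood")
    return ax
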