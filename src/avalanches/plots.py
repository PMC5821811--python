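"""Optional rendering of exponent color-maps (requires matplotlib)."""

from __future__ import annotations

from .powerlaw import ExponentMap


def plot_exponent_map(emap: ExponentMap, which: str = "exponent", ax=None):
    """Color-map of the exponent (or p-value) over all cutoff intervals.

    The x-axis is the lower cutoff, the y-axis the upper cutoff; the
    selected plateau interval is marked.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    grid = emap.exponent_grid if which == "exponent" else emap.p_grid
    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(
        emap.x_low_grid, emap.x_high_grid, grid.T, shading="nearest",
        cmap="viridis" if which == "exponent" else "magma",
    )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$X_{low}$")
    ax.set_ylabel(r"$X_{high}$")
    sel = emap.selected.model
    ax.plot([sel.x_low], [sel.x_high], marker="*", color="red", markersize=12)
    label = "exponent" if which == "exponent" else "KS p-value"
    ax.figure.colorbar(mesh, ax=ax, label=label)
    return ax
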