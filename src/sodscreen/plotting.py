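"""Selectivity-map plotting."""

from __future__ import annotations

from .thermo import Conditions, DEFAULT_CONDITIONS, criterion_thresholds, x1_grid


def plot_x1_contour(
    ho_range: tuple[float, float] = (-5.0, 0.0),
    h_range: tuple[float, float] = (-6.0, 0.0),
    n: int = 200,
    cond: Conditions = DEFAULT_CONDITIONS,
    ax=None,
    show_thresholds: bool = True,
):
    """Contour map of the dismutation fraction x1 over adsorption energies.

    Returns the matplotlib axes.  The x1 = 0.5 selectivity boundary and the
    rectangle thresholds are overlaid by default.
    """
    import matplotlib.pyplot as plt

    grid = x1_grid(ho_range, h_range, n, n, cond)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(grid.e_ads_ho, grid.e_ads_h, grid.x1, levels=21, cmap="viridis")
    ax.contour(grid.e_ads_ho, grid.e_ads_h, grid.x1, levels=[0.5], colors="white")
    if show_thresholds:
        ho_thr, h_thr = criterion_thresholds(cond)
        ax.axvline(ho_thr, color="white", ls="--", lw=0.8)
        ax.axhline(h_thr, color="white", ls="--", lw=0.8)
    ax.set_xlabel(r"$E_\mathrm{ads,HO}$ (eV)")
    ax.set_ylabel(r"$E_\mathrm{ads,H}$ (eV)")
    ax.figure.colorbar(cs, ax=ax, label=r"$x_1$")
    return ax
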