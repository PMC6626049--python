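"""Plotting helpers: lesion-aligned group mean curves.

One figure style: per-group mean normalized intersection count against
position, smoothed curves solid, the lesion plane marked by a vertical bar
at 0.
"""

from __future__ import annotations

import numpy as np

from .profiles import smooth_profile


def plot_group_curves(profiles_by_group, smooth_um=50, out_path=None, ax=None):
    """Plot per-group mean normalized profiles (smoothed) with the lesion at 0.

    ``profiles_by_group`` maps group name → list of NormalizedProfile sharing
    one grid. Returns the matplotlib axes; saves to ``out_path`` when given.
    """
    import matplotlib

    if out_path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for group, profiles in profiles_by_group.items():
        grid = profiles[0].positions_um
        values = np.vstack([p.values for p in profiles])
        mean = np.nanmean(values, axis=0)
        ax.plot(grid, mean, alpha=0.25, lw=0.8)
        ax.plot(grid, smooth_profile(mean, smooth_um), lw=1.8, label=group)
    ax.axvline(0.0, color="red", lw=2, alpha=0.8)
    ax.set_xlabel("position relative to lesion (µm)")
    ax.set_ylabel("normalized intersections")
    ax.legend()
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
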