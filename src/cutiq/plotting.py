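"""Publication-style plots: mean +/- SEM density curves with a semi-log
p-value trace underneath the significance threshold line."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .cohort_stats import DensityComparison
from .profile_densitometry import MeanProfile


def plot_density_comparison(
    mean_a: MeanProfile,
    mean_b: MeanProfile,
    comparison: DensityComparison,
    label_a: str = "cohort A",
    label_b: str = "cohort B",
    path=None,
):
    """Overlay two mean OD curves (shaded SEM) and the per-position KS
    p-values on a twin semi-log axis; returns the figure."""
    positions = np.arange(101)
    fig, ax = plt.subplots(figsize=(7, 4))
    for mp, label, color in ((mean_a, label_a, "tab:green"), (mean_b, label_b, "tab:red")):
        ax.plot(positions, mp.mean, color=color, label=f"{label} (n={mp.n})")
        ax.fill_between(
            positions, mp.mean - mp.sem, mp.mean + mp.sem, color=color, alpha=0.25, lw=0
        )
    ax.set_xlabel("normalized cuticle position (0 = wall interface, 100 = outer edge)")
    ax.set_ylabel("optical density")
    ax.legend(loc="upper left", frameon=False)

    ax2 = ax.twinx()
    ax2.semilogy(positions, comparison.p_values, color="tab:blue", lw=1, label="KS p")
    ax2.axhline(comparison.alpha, color="navy", ls=":", lw=1)
    ax2.set_ylabel("KS p-value")
    ax2.set_ylim(top=1.5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
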