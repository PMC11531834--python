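"""Optional figure output: trace/fit overlays and forest-style contrast plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .distributions import BinnedDistribution  # noqa: E402
from .mixture import FitResult, model_density  # noqa: E402

__all__ = ["plot_fit", "plot_comparisons"]


def plot_fit(dist: BinnedDistribution, fit: FitResult, path) -> None:
    """Observed percent-density trace with the fitted mixture overlaid."""
    from .mixture import _as_density

    dens = _as_density(dist)
    d = np.geomspace(dens.bin_edges[0], dens.bin_edges[-1], 400)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(dens.centers, dens.values, ".", ms=3, label="observed")
    ax.plot(d, model_density(fit.model, d), "-", label="fitted mixture")
    ax.set_xlabel("diameter (µm)")
    ax.set_ylabel("volume % density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_comparisons(table: pd.DataFrame, path) -> None:
    """Difference-of-means dots with CI whiskers, one panel per phenotype."""
    phenos = list(table["phenotype"].unique())
    fig, axes = plt.subplots(1, max(len(phenos), 1),
                             figsize=(4 * max(len(phenos), 1), 3 + 0.3 * len(table)),
                             squeeze=False)
    for ax, pheno in zip(axes[0], phenos):
        sub = table[table["phenotype"] == pheno].reset_index(drop=True)
        labels = [f"{r.group_a} − {r.group_b}"
                  + (f" [{r.stratum}]" if r.stratum != "" else "")
                  for r in sub.itertuples()]
        y = np.arange(len(sub))[::-1]
        diff = sub["diff_means"].to_numpy()
        ax.errorbar(diff, y,
                    xerr=[diff - sub["ci_low"].to_numpy(),
                          sub["ci_high"].to_numpy() - diff],
                    fmt="o", capsize=3)
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(y)
        ax.set_yticklabels(labels, fontsize=8)
        ax.set_title(pheno, fontsize=9)
        ax.set_xlabel("difference of means")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
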