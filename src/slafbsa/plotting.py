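"""Minimal figure exports: Spearman heat map and predicted-vs-actual MW."""

from __future__ import annotations

import pandas as pd


def plot_spearman_heatmap(corr: pd.DataFrame, order: list[str], path: str) -> None:
    """Write the clustered Spearman correlation heat map to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = corr.loc[order, order]
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(order), 1 + 0.5 * len(order)))
    im = ax.imshow(data.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90)
    ax.set_yticks(range(len(order)), order)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_predicted_vs_actual(model, path: str) -> None:
    """Scatter of a SNP network's fitted vs actual marketing weight."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(model.actual, model.fitted, s=8, alpha=0.6)
    lims = [min(model.actual.min(), model.fitted.min()),
            max(model.actual.max(), model.fitted.max())]
    ax.plot(lims, lims, lw=0.8, color="grey")
    ax.set_xlabel("actual MW (kg)")
    ax.set_ylabel("predicted MW (kg)")
    ax.set_title(f"SNP network: {', '.join(model.members)} (R2={model.r2:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
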