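"""Standard figures for mechanotyping results.

Thin matplotlib wrappers around the DIC-box table: population boxplots of the
modulus components, the loss-versus-storage density scatter with the
G'' = G' reference line, and the modulus-versus-edge-distance profile.  Each
function writes a file when given a path and always returns the figure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import edge_profile, loss_vs_storage

_COMPONENTS = [("g_abs", "|G|"), ("g_storage", "G'"), ("g_loss", "G''")]


def _get_axes(n: int = 1):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    return fig, axes[0]


def modulus_boxplots(table: pd.DataFrame, path=None):
    """Boxplots of |G|, G' and G'' per channel label (outliers hidden, as the
    1.5 IQR rule applies to rendering only)."""
    df = table[table["label"] != "unassigned"]
    labels = sorted(df["label"].unique())
    fig, axes = _get_axes(len(_COMPONENTS))
    for ax, (col, name) in zip(axes, _COMPONENTS):
        data = [df.loc[df["label"] == lab, col].dropna() / 1e3 for lab in labels]
        ax.boxplot(data, tick_labels=labels, showfliers=False, showmeans=True)
        ax.set_ylabel(f"{name} (kPa)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig

def loss_storage_scatter(table: pd.DataFrame, path=None):
    """G'' against G' per DIC box, coloured by local kernel density, with the
    G'' = G' line."""
    df = loss_vs_storage(table)
    fig, (ax,) = _get_axes(1)
    ax.scatter(df["g_storage"] / 1e3, df["g_loss"] / 1e3, c=df["density"], s=4, cmap="viridis")
    lim = max(df["g_storage"].max(), df["g_loss"].max()) / 1e3 if len(df) else 1.0
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="G'' = G'")
    ax.set_xlabel("G' (kPa)")
    ax.set_ylabel("G'' (kPa)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def edge_profile_plot(table: pd.DataFrame, bin_width_um: float = 2.0, path=None):
    """Mean |G| versus distance to the cell edge per label, with SEM bars."""
    prof = edge_profile(table, bin_width_um)
    fig, (ax,) = _get_axes(1)
    for label, rows in prof.groupby("label"):
        rows = rows.sort_values("bin_center_um")
        ax.errorbar(
            rows["bin_center_um"], rows["mean"] / 1e3, yerr=rows["sem"] / 1e3,
            marker="o", capsize=2, label=str(label),
        )
    ax.set_xlabel("distance to cell edge (um)")
    ax.set_ylabel("|G| (kPa)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
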