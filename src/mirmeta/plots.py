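"""Minimal volcano and Kaplan-Meier plots for run reports."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def volcano(meta_table, path, alpha: float = 0.05) -> None:
    """Volcano plot of combined effect vs -log10 p, coloured by direction."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = meta_table["es_meta"]
    y = -np.log10(np.maximum(meta_table["p"], 1e-300))
    sig = meta_table["adj_p"] < alpha
    up = sig & (meta_table["es_meta"] > 0)
    down = sig & (meta_table["es_meta"] <= 0)
    ax.scatter(x[~sig], y[~sig], s=8, c="grey", alpha=0.5, label="ns")
    ax.scatter(x[up], y[up], s=10, c="green", label="up")
    ax.scatter(x[down], y[down], s=10, c="gold", label="down")
    ax.set_xlabel("combined log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(result, path) -> None:
    """Step plot of the two Kaplan-Meier curves with HR annotation."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in result.km_curves.items():
        t = np.concatenate([[0.0], curve["time"].to_numpy()])
        s = np.concatenate([[1.0], curve["survival"].to_numpy()])
        ax.step(t, s, where="post", label=group)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if np.isfinite(result.hr):
        ax.set_title(
            f"HR={result.hr:.2f} ({result.ci_low:.2f}-{result.ci_high:.2f}), "
            f"log-rank p={result.p:.2g}",
            fontsize=9,
        )
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
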