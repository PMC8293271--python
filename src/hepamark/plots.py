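"""Diagnostic plots: permutation scatter, predicted vs observed, network."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from hepamark.chemometrics import PermutationResult, PLSModel

__all__ = ["permutation_plot", "predicted_vs_observed_plot", "network_plot"]


def permutation_plot(result: PermutationResult, path: str | Path, title: str = "") -> None:
    """R2Y and Q2 of permuted models vs their correlation with the
    original response; the original model sits at correlation 1.0."""
    fig, ax = plt.subplots(figsize=(5, 4))
    rec = result.records
    ax.scatter(rec["corr"], rec["r2y"], s=12, alpha=0.6, label="R$^2$Y (permuted)")
    ax.scatter(rec["corr"], rec["q2"], s=12, alpha=0.6, label="Q$^2$ (permuted)")
    ax.scatter([1.0], [result.original_r2y], marker="s", color="C0", label="R$^2$Y")
    ax.scatter([1.0], [result.original_q2], marker="s", color="C1", label="Q$^2$")
    for intercept, orig, color in (
        (result.intercept_r2y, result.original_r2y, "C0"),
        (result.intercept_q2, result.original_q2, "C1"),
    ):
        ax.plot([0, 1], [intercept, orig], color=color, lw=0.8, ls="--")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("correlation of permuted with original response")
    ax.set_ylabel("R$^2$Y / Q$^2$")
    ax.set_title(title or f"{result.n_perm} permutations")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def predicted_vs_observed_plot(model: PLSModel, X, y, path: str | Path, trait: str = "Y") -> None:
    yhat = model.predict(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(y, yhat, s=16)
    lims = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
    ax.plot(lims, lims, color="grey", lw=0.8)
    ax.set_xlabel(f"observed {trait}")
    ax.set_ylabel(f"predicted {trait}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def network_plot(g: nx.Graph, path: str | Path) -> None:
    """Spring layout; edge color by correlation sign."""
    fig, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(g, seed=0)
    colors = ["C3" if d["sign"] < 0 else "C2" for _, _, d in g.edges(data=True)]
    widths = [2.5 * abs(d["weight"]) for _, _, d in g.edges(data=True)]
    nx.draw_networkx(g, pos, ax=ax, node_size=350, font_size=7,
                     edge_color=colors, width=widths, node_color="#dddddd")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
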