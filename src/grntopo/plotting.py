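"""Figure rendering: persistence diagrams, barcodes, Betti curves, weight
histograms. All figures are written to files with deterministic names."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import CohortTopologyReport
from .topology import PersistencePair

__all__ = [
    "plot_persistence_diagram",
    "plot_barcode",
    "plot_betti_curves",
    "plot_weight_histogram",
    "render_outputs",
]

_DIM_STYLE = {0: ("k", "o"), 1: ("tab:orange", "^"), 2: ("tab:blue", "s")}


def _finite_max(pairs: list[PersistencePair]) -> float:
    vals = [p.birth for p in pairs] + [p.death for p in pairs if not p.essential]
    return max(vals) if vals else 1.0


def plot_persistence_diagram(pairs: list[PersistencePair], path: str | Path,
                             title: str = "") -> None:
    """Birth-death scatter per dimension; essential classes sit on a dashed
    horizontal line above the finite range."""
    fig, ax = plt.subplots(figsize=(5, 5))
    top = _finite_max(pairs) * 1.15 + 1e-9
    for dim, (color, marker) in _DIM_STYLE.items():
        sub = [p for p in pairs if p.dimension == dim]
        if not sub:
            continue
        births = [p.birth for p in sub]
        deaths = [p.death if not p.essential else top for p in sub]
        ax.scatter(births, deaths, c=color, marker=marker, s=25,
                   label=f"dim {dim}", alpha=0.8)
    ax.axhline(top, color="red", ls="--", lw=1, label="essential")
    lim = top * 1.05
    ax.plot([0, lim], [0, lim], color="gray", lw=0.8)
    ax.set_xlabel("birth weight")
    ax.set_ylabel("death weight")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_barcode(pairs: list[PersistencePair], path: str | Path, title: str = "") -> None:
    """Horizontal bar per class, arrow markers for essential classes."""
    fig, ax = plt.subplots(figsize=(6, 4))
    end = _finite_max(pairs) * 1.1 + 1e-9
    y = 0
    for dim, (color, _) in _DIM_STYLE.items():
        sub = sorted(
            (p for p in pairs if p.dimension == dim), key=lambda p: (p.birth, p.death)
        )
        for p in sub:
            stop = end if p.essential else p.death
            ax.hlines(y, p.birth, stop, color=color, lw=2)
            if p.essential:
                ax.annotate("", xy=(end * 1.03, y), xytext=(stop, y),
                            arrowprops=dict(arrowstyle="->", color=color, lw=1.5))
            y += 1
    ax.set_xlabel("weight")
    ax.set_ylabel("class")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_betti_curves(report: CohortTopologyReport, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    grid = report.curves.thresholds
    for dim, beta in sorted(report.curves.beta.items()):
        color, _ = _DIM_STYLE.get(dim, ("gray", "o"))
        ax.step(grid, beta, where="post", color=color, label=rf"$\beta_{dim}$")
    ax.set_xlabel("weight threshold")
    ax.set_ylabel("Betti number")
    ax.set_title(f"Betti curves — {report.label}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_weight_histogram(report: CohortTopologyReport, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    h = report.histogram
    widths = np.diff(h["edges"])
    ax.bar(h["edges"][:-1], h["counts"], width=widths, align="edge",
           color="tab:blue", alpha=0.7)
    ax.set_xlabel("edge weight")
    ax.set_ylabel("count")
    ax.set_title(f"weights — {report.label} (sd={h['std']:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_outputs(
    reports: list[CohortTopologyReport], out_dir: str | Path
) -> dict[str, Path]:
    """Render the standard figure set for each report; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for rep in reports:
        base = rep.label.replace(" ", "_")
        p = out / f"{base}_persistence_diagram.png"
        plot_persistence_diagram(rep.pairs, p, title=rep.label)
        paths[f"{base}_persistence_diagram"] = p
        p = out / f"{base}_barcode.png"
        plot_barcode(rep.pairs, p, title=rep.label)
        paths[f"{base}_barcode"] = p
        p = out / f"{base}_betti_curves.png"
        plot_betti_curves(rep, p)
        paths[f"{base}_betti_curves"] = p
        if rep.network.edge_weights().size:
            p = out / f"{base}_weight_histogram.png"
            plot_weight_histogram(rep, p)
            paths[f"{base}_weight_histogram"] = p
    return paths
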