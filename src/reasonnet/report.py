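"""Figures and machine-readable run reports.

The network figure follows the source study's visual conventions: node area
proportional to the reason's sole-mention weight, edge width proportional to
the accumulated co-mention weight, labels annotated with normalized
eigencentrality.  Layout is force-directed with a fixed seed so renders are
deterministic; SVG output additionally pins matplotlib's hash salt and
strips the date metadata so two runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .centrality import CentralityResult, rank_reasons
from .network import CoMentionMatrix, to_graph
from .response_io import AGE_GROUPS, ResponseSet, reason_frequencies
from .stratify import StratifiedResult, stratified_table

__all__ = ["PlotSpec", "render_network", "render_age_bars", "run_report"]

_SVG_SALT = "reasonnet"


@dataclass(frozen=True)
class PlotSpec:
    """Rendering parameters for network and bar figures."""

    node_size_scale: float = 40.0
    edge_width_scale: float = 1.0
    layout_seed: int = 0
    label_top_k: int = 10
    output_format: str = "svg"

    def __post_init__(self) -> None:
        if self.node_size_scale <= 0 or self.edge_width_scale <= 0:
            raise ValueError("plot scales must be positive")
        if self.output_format not in ("png", "svg"):
            raise ValueError("output_format must be 'png' or 'svg'")


def _deterministic_savefig(fig, path, fmt: str) -> None:
    with plt.rc_context({"svg.hashsalt": _SVG_SALT}):
        fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
    plt.close(fig)


def render_network(M: CoMentionMatrix, C: CentralityResult, spec: PlotSpec, path) -> Path:
    """Render the co-mention network figure.

    Node area scales with sole-mention weight, edge width with co-mention
    weight; the ``label_top_k`` highest-centrality nodes carry a label with
    their normalized eigencentrality.  Deterministic given
    ``spec.layout_seed``.
    """
    if tuple(M.reasons) != tuple(C.reasons):
        raise ValueError("matrix and centrality result have mismatched reason orders")
    path = Path(path)
    G = to_graph(M)
    pos = nx.spring_layout(G, seed=spec.layout_seed, weight="weight")

    fig, ax = plt.subplots(figsize=(8, 8))
    sizes = [spec.node_size_scale * (1.0 + G.nodes[n]["self_weight"]) for n in G.nodes()]
    widths = [spec.edge_width_scale * d["weight"] for _, _, d in G.edges(data=True)]
    nx.draw_networkx_edges(G, pos, ax=ax, width=widths, edge_color="#888888", alpha=0.7)
    nx.draw_networkx_nodes(G, pos, ax=ax, node_size=sizes, node_color="#4477aa", alpha=0.9)

    ranking = rank_reasons(C)
    top = set(ranking.head(spec.label_top_k)["reason"])
    cent = dict(zip(C.reasons, C.X))
    labels = {n: f"{n}\n{cent[n]:.2f}" for n in G.nodes() if n in top}
    nx.draw_networkx_labels(G, pos, labels=labels, ax=ax, font_size=8)
    ax.set_axis_off()
    _deterministic_savefig(fig, path, spec.output_format)
    return path


def render_age_bars(sr: StratifiedResult, spec: PlotSpec, path) -> Path:
    """Grouped bar chart: one group per reason, one bar per age bin,
    y = normalized eigencentrality."""
    path = Path(path)
    table = stratified_table(sr)
    reasons = list(sr.pooled.centrality.reasons)
    ages = [a for a in AGE_GROUPS if a in set(table["age_group"])]
    n_ages = len(ages)
    width = 0.8 / max(n_ages, 1)
    x = np.arange(len(reasons))

    fig, ax = plt.subplots(figsize=(max(8, len(reasons) * 1.1), 5))
    cmap = plt.get_cmap("viridis")
    for i, age in enumerate(ages):
        sub = table[table["age_group"] == age].set_index("reason")["centrality"]
        heights = [float(sub.get(r, 0.0)) for r in reasons]
        ax.bar(x + (i - (n_ages - 1) / 2) * width, heights, width=width,
               label=age, color=cmap(i / max(n_ages - 1, 1)))
    ax.set_xticks(x)
    ax.set_xticklabels(reasons, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("normalized eigencentrality")
    ax.legend(title="age group", fontsize=8)
    fig.tight_layout()
    _deterministic_savefig(fig, path, spec.output_format)
    return path


def run_report(
    rs: ResponseSet,
    matrix: CoMentionMatrix,
    centrality: CentralityResult,
    stratified: StratifiedResult | None = None,
    config_echo: dict | None = None,
    path=None,
) -> dict:
    """Aggregate one pipeline run into a machine-readable summary.

    Includes mention frequencies, the centrality ranking, convergence
    diagnostics, the conservation check, an echo of the run configuration
    (seeds included) and the package version.  Re-running the pipeline from
    the echoed configuration reproduces identical outputs.
    """
    freq = reason_frequencies(rs)
    ranking = rank_reasons(centrality)
    n_edges = int((np.triu(matrix.A, k=1) > 0).sum())
    report = {
        "package": "reasonnet",
        "version": __version__,
        "group": rs.group,
        "n_respondents": len(rs),
        "n_reasons": len(matrix.reasons),
        "n_edges": n_edges,
        "conservation": {
            "total_mass": matrix.total_mass,
            "expected": matrix.n_respondents,
            "abs_error": abs(matrix.total_mass - matrix.n_respondents),
        },
        "frequencies": freq.to_dict(orient="records"),
        "centrality": ranking.drop(columns="degenerate").to_dict(orient="records"),
        "diagnostics": {
            "eigenvalue": centrality.lam,
            "n_iterations": centrality.n_iterations,
            "converged": centrality.converged,
            "norm": centrality.norm,
            "gap_degenerate": centrality.gap_degenerate,
            "degenerate_centrality": bool(ranking["degenerate"].iloc[0]),
        },
        "config": config_echo or {},
    }
    if stratified is not None:
        report["strata"] = {
            age: {
                "n_respondents": s.n_respondents,
                "centrality": {
                    r: float(v) for r, v in zip(s.centrality.reasons, s.centrality.X)
                },
            }
            for age, s in stratified.strata.items()
        }
        report["n_unknown_age"] = stratified.n_unknown_age
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return report
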