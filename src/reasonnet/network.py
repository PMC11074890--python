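"""Participant-normalized co-mention adjacency matrices.

Each respondent contributes total weight exactly 1 to the network,
regardless of how many reasons they mention:

* one reason → weight 1 on that reason alone (a "sole mention");
* two reasons → the single pair gets weight 1;
* k ≥ 3 reasons → each of the C(k, 2) unordered pairs gets weight 1/C(k, 2).

Pair weights accumulate symmetrically off-diagonal (A[i, j] = A[j, i] = the
total pair weight, stored once per unordered pair for conservation
accounting).  Sole-mention weights go on the diagonal by default
(``diagonal_mode="self_weight"``) so that frequently-sole-mentioned reasons
carry spectral weight; a ``"zero"`` mode keeps the diagonal empty and
records sole mentions in a side vector only, for sensitivity analysis.

Accumulation is done in exact rational arithmetic (``fractions.Fraction``)
and converted to float on finalization, so the conservation identity
(upper-triangle + diagonal mass == number of respondents) holds to
floating-point rounding only.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .codebook import Codebook
from .response_io import ResponseSet

__all__ = [
    "CoMentionMatrix",
    "participant_weights",
    "build_matrix",
    "export_network",
    "import_edge_list",
    "import_graphml",
    "to_graph",
]

DIAGONAL_MODES = ("self_weight", "zero")


@dataclass(frozen=True)
class CoMentionMatrix:
    """Symmetric nonnegative reason-by-reason co-mention matrix.

    Attributes
    ----------
    reasons
        Reason codes in canonical (codebook) order; row/column labels of A.
    A
        The symmetric adjacency matrix.  Off-diagonal entries are accumulated
        pair weights; the diagonal holds sole-mention weights in
        ``self_weight`` mode and zeros in ``zero`` mode.
    self_weights
        Accumulated sole-mention weight per reason (always populated,
        identical to the diagonal in ``self_weight`` mode).
    n_respondents
        Number of respondents the matrix accumulates.
    """

    reasons: tuple
    A: np.ndarray
    self_weights: np.ndarray
    n_respondents: int
    diagonal_mode: str = "self_weight"

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "self_weights", np.asarray(self.self_weights, dtype=float))
        k = len(self.reasons)
        if A.shape != (k, k):
            raise ValueError(f"matrix shape {A.shape} does not match {k} reasons")
        if not np.allclose(A, A.T):
            raise ValueError("co-mention matrix must be symmetric")
        if (A < 0).any() or (self.self_weights < 0).any():
            raise ValueError("co-mention weights must be nonnegative")
        if self.diagonal_mode not in DIAGONAL_MODES:
            raise ValueError(f"diagonal_mode must be one of {DIAGONAL_MODES}")

    @property
    def total_mass(self) -> float:
        """Upper-triangle plus diagonal mass; equals n_respondents in self_weight mode."""
        return float(np.triu(self.A).sum() + (0.0 if self.diagonal_mode == "self_weight" else self.self_weights.sum()))

    def index(self, code: str) -> int:
        return self.reasons.index(code)


def participant_weights(reasons) -> dict:
    """Exact per-respondent weights over unordered reason pairs (or self).

    Returns a dict mapping sorted ``(a, b)`` tuples (``a == b`` for a sole
    mention) to :class:`~fractions.Fraction` weights that sum to exactly 1.
    """
    codes = sorted(set(reasons))
    if not codes:
        raise ValueError("a respondent must mention at least one reason")
    if len(codes) == 1:
        return {(codes[0], codes[0]): Fraction(1)}
    n_pairs = comb(len(codes), 2)
    w = Fraction(1, n_pairs)
    return {pair: w for pair in combinations(codes, 2)}


def build_matrix(rs: ResponseSet, diagonal_mode: str = "self_weight") -> CoMentionMatrix:
    """Accumulate participant weights over a ResponseSet into a matrix.

    Every respondent contributes exactly 1 of total weight; the conservation
    identity ``triu(A).sum() + diag mass == len(rs)`` holds up to float
    conversion (accumulation itself is exact).
    """
    if len(rs) == 0:
        raise ValueError("cannot build a co-mention matrix from an empty ResponseSet")
    if diagonal_mode not in DIAGONAL_MODES:
        raise ValueError(f"diagonal_mode must be one of {DIAGONAL_MODES}")
    codes = list(rs.codebook.codes)
    extra = sorted({c for r in rs.respondents for c in r.reasons} - set(codes))
    codes = codes + extra  # permissive "other" bucket, if present
    idx = {c: i for i, c in enumerate(codes)}
    k = len(codes)
    acc = {}
    for r in rs.respondents:
        for (a, b), w in participant_weights(r.reasons).items():
            key = (idx[a], idx[b]) if idx[a] <= idx[b] else (idx[b], idx[a])
            acc[key] = acc.get(key, Fraction(0)) + w
    A = np.zeros((k, k))
    self_w = np.zeros(k)
    for (i, j), w in acc.items():
        if i == j:
            self_w[i] = float(w)
        else:
            A[i, j] = A[j, i] = float(w)
    if diagonal_mode == "self_weight":
        A[np.diag_indices(k)] = self_w
    return CoMentionMatrix(
        reasons=tuple(codes),
        A=A,
        self_weights=self_w,
        n_respondents=len(rs),
        diagonal_mode=diagonal_mode,
    )


def to_graph(M: CoMentionMatrix, codebook: Codebook | None = None) -> nx.Graph:
    """NetworkX view: weighted edges off-diagonal, self-weights as node attributes."""
    G = nx.Graph()
    labels = codebook.labels if codebook is not None else {}
    for i, code in enumerate(M.reasons):
        G.add_node(code, self_weight=float(M.self_weights[i]), label=labels.get(code, code))
    k = len(M.reasons)
    for i in range(k):
        for j in range(i + 1, k):
            if M.A[i, j] > 0:
                G.add_edge(M.reasons[i], M.reasons[j], weight=float(M.A[i, j]))
    return G


def export_network(M: CoMentionMatrix, fmt: str, path) -> None:
    """Write the network as ``edge_list_csv`` or ``graphml``.

    The edge list holds one record per strictly-upper-triangle nonzero
    entry; sole-mention weights are exported as node attributes (a sibling
    ``*.nodes.csv`` file for the CSV format, node attributes for GraphML),
    never as self-edges.
    """
    path = Path(path)
    if fmt == "edge_list_csv":
        k = len(M.reasons)
        rows = [
            {"source": M.reasons[i], "target": M.reasons[j], "weight": M.A[i, j]}
            for i in range(k)
            for j in range(i + 1, k)
            if M.A[i, j] > 0
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)
        nodes = pd.DataFrame(
            {"code": list(M.reasons), "self_weight": M.self_weights}
        )
        nodes.to_csv(path.with_suffix(".nodes.csv"), index=False)
    elif fmt == "graphml":
        G = to_graph(M)
        G.graph["n_respondents"] = M.n_respondents
        G.graph["diagonal_mode"] = M.diagonal_mode
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unsupported export format {fmt!r}")


def _from_graph(G: nx.Graph, reasons, n_respondents: int, diagonal_mode: str) -> CoMentionMatrix:
    reasons = tuple(reasons)
    idx = {c: i for i, c in enumerate(reasons)}
    k = len(reasons)
    A = np.zeros((k, k))
    self_w = np.zeros(k)
    for code, data in G.nodes(data=True):
        self_w[idx[code]] = float(data.get("self_weight", 0.0))
    for u, v, data in G.edges(data=True):
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = float(data["weight"])
    if diagonal_mode == "self_weight":
        A[np.diag_indices(k)] = self_w
    return CoMentionMatrix(
        reasons=reasons,
        A=A,
        self_weights=self_w,
        n_respondents=n_respondents,
        diagonal_mode=diagonal_mode,
    )


def import_edge_list(path, reasons, n_respondents: int, diagonal_mode: str = "self_weight") -> CoMentionMatrix:
    """Rebuild a CoMentionMatrix from an exported edge list + node CSV pair."""
    path = Path(path)
    edges = pd.read_csv(path)
    nodes = pd.read_csv(path.with_suffix(".nodes.csv"))
    G = nx.Graph()
    for _, row in nodes.iterrows():
        G.add_node(row["code"], self_weight=float(row["self_weight"]))
    for _, row in edges.iterrows():
        G.add_edge(row["source"], row["target"], weight=float(row["weight"]))
    return _from_graph(G, reasons, n_respondents, diagonal_mode)


def import_graphml(path) -> CoMentionMatrix:
    """Round-trip an exported GraphML document back into a CoMentionMatrix."""
    G = nx.read_graphml(path)
    return _from_graph(
        G,
        reasons=tuple(G.nodes()),
        n_respondents=int(G.graph.get("n_respondents", 0)),
        diagonal_mode=G.graph.get("diagonal_mode", "self_weight"),
    )
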