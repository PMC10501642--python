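"""Weighted directed graphs (with self-loops) for evolutionary dynamics.

A spatial structure is an ``N x N`` matrix of non-negative link weights,
``weights[i, j]`` being the weight of the link directed from node ``i`` to
node ``j``.  Diagonal entries are self-loops: they let an offspring replace
its own parent.  All dynamics only ever use the row-normalized matrix (the
probability that node ``i``'s offspring lands on node ``j``), so weights may
be entered on any convenient scale.

The node *temperature* is the column sum of the row-normalized matrix; it
measures how often a node is replaced, and therefore where new mutants tend
to arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "WeightedGraph",
    "GRAPH_FAMILIES",
    "build_family",
    "graph_from_spec",
    "temperatures",
    "read_edgelist",
    "write_edgelist",
]

#: Parametric families understood by :func:`build_family`.
GRAPH_FAMILIES = (
    "complete",
    "cycle",
    "star",
    "selflooped_weighted_star",
    "selflooped_complete",
    "selflooped_cycle",
    "selflooped_star",
    "selflooped_directed_line",
    "directed_line",
    "molded_directed_line",
    "burst",
    "modified_burst",
)

_ATOL = 1e-12


@dataclass(frozen=True)
class WeightedGraph:
    """An ``N``-node weighted directed adjacency with optional self-loops.

    Parameters
    ----------
    weights
        Raw non-negative link weights, shape ``(N, N)``.
    family_tag
        Optional label recording the constructor and its parameters.
    allow_sinks
        Permit rows with zero total outgoing weight.  A sink node can be
        replaced but never places offspring anywhere; only the directed
        families without self-loops (``burst``, ``directed_line`` and their
        repaired variants) produce sinks.  Everywhere else a zero row is an
        error, because such a node could never reproduce.
    """

    weights: np.ndarray
    family_tag: str | None = None
    allow_sinks: bool = False
    _normalized: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be a square matrix, got shape {w.shape}")
        if w.shape[0] < 2:
            raise ValueError("a graph needs at least 2 nodes")
        if np.any(w < 0):
            raise ValueError("link weights must be non-negative")
        row_sums = w.sum(axis=1)
        if not self.allow_sinks and np.any(row_sums <= 0):
            bad = int(np.flatnonzero(row_sums <= 0)[0])
            raise ValueError(
                f"node {bad} has zero total outgoing weight; every node must be "
                "able to reproduce somewhere (possibly onto itself)"
            )
        object.__setattr__(self, "weights", w)
        norm = np.zeros_like(w)
        positive = row_sums > 0
        norm[positive] = w[positive] / row_sums[positive, None]
        object.__setattr__(self, "_normalized", norm)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def sink_nodes(self) -> np.ndarray:
        """Indices of nodes with zero outgoing weight (usually empty)."""
        return np.flatnonzero(self.weights.sum(axis=1) == 0)

    def normalized(self) -> np.ndarray:
        """Row-stochastic replacement matrix (sink rows stay all-zero)."""
        return self._normalized.copy()

    def temperatures(self) -> np.ndarray:
        """Per-node temperature ``T_j = sum_i w_ij`` of the normalized matrix."""
        return self._normalized.sum(axis=0)


def temperatures(g: WeightedGraph) -> np.ndarray:
    """Column sums of the row-normalized weight matrix.

    For a graph without sink nodes the temperatures sum to ``N`` exactly:
    each of the ``N`` rows contributes total mass one.
    """
    return g.temperatures()


def _star_matrix(n: int, lam: float, delta: float) -> np.ndarray:
    """Self-looped weighted star: center node 0, ``n`` leaves.

    Row 0 is ``(1 - delta, delta/n, ..., delta/n)``; every leaf row has
    ``lam`` toward the center and ``1 - lam`` on its own diagonal.
    """
    w = np.zeros((n + 1, n + 1))
    w[0, 0] = 1.0 - delta
    w[0, 1:] = delta / n
    w[1:, 0] = lam
    idx = np.arange(1, n + 1)
    w[idx, idx] = 1.0 - lam
    return w


def build_family(family: str, n_nodes: int, params: Mapping | None = None) -> WeightedGraph:
    """Construct one of the built-in parametric graph families.

    Parameters
    ----------
    family
        One of :data:`GRAPH_FAMILIES`.  Star-family graphs place the center
        at node 0 and have ``n = N - 1`` leaves; line graphs have their root
        at node 0 and terminal node ``N - 1``.
    n_nodes
        Population size ``N >= 2``.
    params
        ``lam`` and ``delta`` for ``selflooped_weighted_star`` (defaults
        ``1/(N-1)`` and ``1/(N-1)^2``); ignored elsewhere.

    Notes
    -----
    ``selflooped_directed_line`` follows the equal-outgoing-weight rule:
    node ``i`` sends weight 1/2 to itself and 1/2 to node ``i + 1``; the
    terminal node keeps all weight on its self-loop.  ``burst`` is one
    center with equal-weight links to its leaves and no other links, so its
    leaves are sink nodes; ``modified_burst`` additionally directs one leaf
    (node 1) back to the center so every node has an incoming link.
    """
    params = dict(params or {})
    N = int(n_nodes)
    if N < 2:
        raise ValueError("n_nodes must be at least 2")
    if family not in GRAPH_FAMILIES:
        raise ValueError(f"unknown graph family {family!r}; choose from {GRAPH_FAMILIES}")

    allow_sinks = False
    if family == "complete":
        w = np.ones((N, N)) - np.eye(N)
    elif family == "selflooped_complete":
        w = np.ones((N, N))
    elif family in ("cycle", "selflooped_cycle"):
        w = np.zeros((N, N))
        idx = np.arange(N)
        w[idx, (idx + 1) % N] += 1.0
        w[idx, (idx - 1) % N] += 1.0
        if family == "selflooped_cycle":
            w[idx, idx] = 1.0
    elif family in ("star", "selflooped_weighted_star", "selflooped_star"):
        n = N - 1
        if family == "star":
            lam, delta = 1.0, 1.0
        elif family == "selflooped_star":
            # equal outgoing weight on every link including the self-loop
            lam, delta = 0.5, n / (n + 1.0)
        else:
            lam = float(params.pop("lam", params.pop("lambda", 1.0 / n)))
            delta = float(params.pop("delta", 1.0 / n**2))
        if not (0.0 < lam <= 1.0 and 0.0 < delta <= 1.0):
            raise ValueError("star parameters must satisfy 0 < lam <= 1 and 0 < delta <= 1")
        w = _star_matrix(n, lam, delta)
    elif family == "selflooped_directed_line":
        w = np.zeros((N, N))
        idx = np.arange(N - 1)
        w[idx, idx] = 1.0
        w[idx, idx + 1] = 1.0
        w[N - 1, N - 1] = 1.0
    elif family in ("directed_line", "molded_directed_line"):
        w = np.zeros((N, N))
        idx = np.arange(N - 1)
        w[idx, idx + 1] = 1.0
        if family == "molded_directed_line":
            w[1, 0] = 1.0
        allow_sinks = True  # terminal node has no forward neighbour
    elif family in ("burst", "modified_burst"):
        w = np.zeros((N, N))
        w[0, 1:] = 1.0
        if family == "modified_burst":
            w[1, 0] = 1.0
        allow_sinks = True  # leaves have no outgoing links
    else:  # pragma: no cover - guarded by the membership check above
        raise ValueError(family)

    tag = family if not params else f"{family}({params})"
    if family == "selflooped_weighted_star":
        tag = f"selflooped_weighted_star(lam={lam:g}, delta={delta:g})"
    return WeightedGraph(w, family_tag=tag, allow_sinks=allow_sinks)


def graph_from_spec(spec: Mapping | WeightedGraph) -> WeightedGraph:
    """Accept ``{"family": ..., "n_nodes": ..., "params": {...}}`` descriptors."""
    if isinstance(spec, WeightedGraph):
        return spec
    spec = dict(spec)
    return build_family(spec["family"], spec["n_nodes"], spec.get("params"))


def write_edgelist(g: WeightedGraph, path: str | Path) -> None:
    """Write a graph as a TSV edge list with a ``src dst weight`` header.

    Zero-weight links are omitted; the node count is recorded in a leading
    comment so isolated trailing nodes survive the round trip.
    """
    path = Path(path)
    lines = [f"# n_nodes={g.n_nodes}", "src\tdst\tweight"]
    for i, j in zip(*np.nonzero(g.weights)):
        lines.append(f"{i}\t{j}\t{float(g.weights[i, j])!r}")
    path.write_text("\n".join(lines) + "\n")


def read_edgelist(path: str | Path, allow_sinks: bool = False) -> WeightedGraph:
    """Read a TSV edge list written by :func:`write_edgelist`.

    The file must carry the ``src dst weight`` header; 0-based integer node
    ids; self-loops are ordinary ``src == dst`` rows.  Raises on negative
    weights, on node ids at or beyond the declared node count, and (unless
    ``allow_sinks``) on nodes with zero total outgoing weight.
    """
    path = Path(path)
    n_declared: int | None = None
    rows: list[tuple[int, int, float]] = []
    header_seen = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "n_nodes=" in line:
                n_declared = int(line.split("n_nodes=")[1])
            continue
        if not header_seen:
            if [c.strip() for c in line.split("\t")] != ["src", "dst", "weight"]:
                raise ValueError(f"expected 'src\\tdst\\tweight' header, got {line!r}")
            header_seen = True
            continue
        src_s, dst_s, w_s = line.split("\t")
        src, dst, wgt = int(src_s), int(dst_s), float(w_s)
        if wgt < 0:
            raise ValueError(f"negative weight {wgt} on link {src}->{dst}")
        rows.append((src, dst, wgt))
    if not rows:
        raise ValueError(f"{path} contains no edges")
    n = n_declared if n_declared is not None else max(max(s, d) for s, d, _ in rows) + 1
    w = np.zeros((n, n))
    for src, dst, wgt in rows:
        if src >= n or dst >= n:
            raise ValueError(f"node id {max(src, dst)} >= declared node count {n}")
        w[src, dst] = wgt
    return WeightedGraph(w, family_tag=f"edgelist:{path.name}", allow_sinks=allow_sinks)
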