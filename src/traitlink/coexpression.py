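"""Co-expression networks and Markov (MCL) clustering.

From a gene-by-sample expression matrix, every gene pair receives a Pearson
product-moment correlation

    r = sum_i (x_i - xbar)(y_i - ybar)
        / ( sqrt(sum_i (x_i - xbar)^2) * sqrt(sum_i (y_i - ybar)^2) )

stabilised by the Fisher transformation Z = (1/2) ln((1+r)/(1-r)). Pairs
passing the edge rule (minimum |r|, or top-k neighbours) form an undirected
weighted graph. For clustering, the graph becomes a column-stochastic
transition matrix M (|r| edge weights plus unit self-loops, columns
normalised to 1) and the MCL algorithm alternates

* expansion: M <- M @ M (random-walk flow spreading), and
* inflation: (Gamma_r M)_pq = (M_pq)^r / sum_i (M_iq)^r — entry-wise power
  then per-column renormalisation —

until the matrix stops changing. Modules are read off from the attractors
of the limit matrix. Inflation r = 1 leaves any stochastic matrix unchanged,
so module definition requires r > 1; the default here is 2.0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationSet, enrich

__all__ = [
    "CoexpressionError",
    "EmptyNetworkError",
    "ConstantVectorError",
    "load_expression",
    "pearson_correlation",
    "fisher_z",
    "CoexpressionNetwork",
    "build_network",
    "mcl_inflate",
    "mcl_cluster",
    "module_overlap",
]

logger = logging.getLogger(__name__)

_STOCHASTIC_ATOL = 1e-9


class CoexpressionError(Exception):
    pass


class EmptyNetworkError(CoexpressionError):
    """No edge survives the threshold rule."""


class ConstantVectorError(CoexpressionError):
    """Correlation is undefined for a zero-variance expression vector."""


def load_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids, header samples).

    Genes with any missing value are dropped with a log report; duplicate
    gene or sample ids are rejected. At least 3 samples are required for
    correlation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_expression(df)


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.duplicated().any():
        raise CoexpressionError("duplicate gene ids in expression matrix")
    if df.columns.duplicated().any():
        raise CoexpressionError("duplicate sample ids in expression matrix")
    if df.shape[1] < 3:
        raise CoexpressionError(
            f"need >= 3 samples for correlation, got {df.shape[1]}"
        )
    incomplete = df.index[df.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "dropping %d genes with missing expression values: %s%s",
            len(incomplete), list(incomplete[:5]), "..." if len(incomplete) > 5 else "",
        )
        df = df.drop(index=incomplete)
    return df


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0.0 or sy == 0.0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float(xd @ yd) / (sx * sy)


def fisher_z(r: float) -> float:
    """Fisher transformation Z = (1/2) ln((1+r)/(1-r)); odd in r.

    |r| >= 1 (possible from floating-point round-off at perfect
    correlation) is clipped to 1 - 1e-12 with a warning.
    """
    if abs(r) >= 1.0:
        logger.warning("fisher_z: |r| >= 1 (%.17g); clipping", r)
        r = math.copysign(1.0 - 1e-12, r)
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


@dataclass
class CoexpressionNetwork:
    """A thresholded co-expression graph plus its MCL bookkeeping.

    ``graph`` holds genes as nodes and surviving pairs as edges with ``r``
    and ``Z`` attributes. ``transition_matrix`` is column-stochastic over
    ``genes`` (|r| weights + unit self-loops, columns sum to 1). ``modules``
    maps gene -> module id once :func:`mcl_cluster` has run.
    """

    graph: nx.Graph
    genes: tuple[str, ...]
    transition_matrix: np.ndarray
    modules: dict[str, int] | None = None
    converged: bool | None = None

    def module_members(self) -> dict[int, frozenset[str]]:
        if self.modules is None:
            raise CoexpressionError("modules not assigned; run mcl_cluster first")
        out: dict[int, set[str]] = {}
        for g, m in self.modules.items():
            out.setdefault(m, set()).add(g)
        return {m: frozenset(gs) for m, gs in out.items()}

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": d["r"], "Z": d["Z"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "Z"])

    def modules_frame(self) -> pd.DataFrame:
        if self.modules is None:
            raise CoexpressionError("modules not assigned; run mcl_cluster first")
        return pd.DataFrame(
            sorted(self.modules.items()), columns=["gene_id", "module_id"]
        )


def _column_normalize(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    if np.any(sums <= 0):
        raise CoexpressionError("cannot normalize a column with non-positive sum")
    return m / sums


def build_network(
    expr: pd.DataFrame,
    min_abs_r: float | None = 0.7,
    top_k: int | None = None,
) -> CoexpressionNetwork:
    """Threshold the all-pairs correlation matrix into a weighted graph.

    The edge rule is either a minimum |r| (default 0.7) or, if ``top_k`` is
    given instead, each gene's k strongest-|r| partners (an edge survives if
    either endpoint ranks it). Every surviving edge stores both r and its
    Fisher Z. Isolated genes stay in the network as singleton nodes.

    Raises
    ------
    EmptyNetworkError
        If no edge survives.
    """
    expr = validate_expression(expr)
    if (min_abs_r is None) == (top_k is None):
        raise ValueError("specify exactly one of min_abs_r or top_k")
    genes = tuple(expr.index)
    values = expr.to_numpy(dtype=float)
    if np.any(values.std(axis=1) == 0):
        bad = [g for g, s in zip(genes, values.std(axis=1)) if s == 0][:5]
        raise ConstantVectorError(f"constant expression vectors: {bad}")
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 0.0)

    n = len(genes)
    if top_k is not None:
        keep = np.zeros_like(corr, dtype=bool)
        order = np.argsort(-np.abs(corr), axis=1, kind="stable")
        for i in range(n):
            keep[i, order[i, : top_k]] = True
        mask = keep | keep.T
    else:
        mask = np.abs(corr) >= min_abs_r

    g = nx.Graph()
    g.add_nodes_from(genes)
    ii, jj = np.nonzero(np.triu(mask, k=1))
    if ii.size == 0:
        raise EmptyNetworkError("no gene pair passes the edge rule")
    for i, j in zip(ii, jj):
        r = float(corr[i, j])
        g.add_edge(genes[i], genes[j], r=r, Z=fisher_z(r))

    # transition matrix: |r| weights, unit self-loops, columns sum to 1
    w = np.abs(corr) * mask
    np.fill_diagonal(w, 1.0)
    m = _column_normalize(w)
    return CoexpressionNetwork(graph=g, genes=genes, transition_matrix=m)


def mcl_inflate(matrix: np.ndarray, r: float) -> np.ndarray:
    """Inflation operator: entry-wise power r, then column renormalisation.

    r = 1 is the identity on stochastic matrices; r > 1 sharpens each
    column toward its largest entries.
    """
    if r <= 0:
        raise ValueError(f"inflation power must be positive, got {r}")
    m = np.asarray(matrix, dtype=float)
    sums = m.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=_STOCHASTIC_ATOL):
        raise ValueError("matrix columns must sum to 1")
    return _column_normalize(np.power(m, r))


def _modules_from_limit(limit: np.ndarray, genes: Sequence[str],
                        attractor_eps: float = 1e-6) -> dict[str, int]:
    """Read module assignment off an MCL limit matrix.

    Rows with appreciable diagonal mass are attractors; each column joins
    the attractors it flows into, and attractor sets sharing a column are
    merged (union-find over columns). Module ids are renumbered by the
    smallest member gene for determinism.
    """
    n = len(genes)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for q in range(n):
        flows = np.nonzero(limit[:, q] > attractor_eps)[0]
        anchor = flows[0] if flows.size else q
        union(anchor, q)
        for p in flows[1:]:
            union(anchor, int(p))

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda idx: genes[min(idx)])
    return {genes[i]: mid for mid, idx in enumerate(ordered, start=1) for i in idx}


def mcl_cluster(
    net: CoexpressionNetwork,
    inflation: float = 2.0,
    max_iter: int = 100,
    prune_eps: float = 1e-5,
    conv_tol: float = 1e-6,
) -> dict[str, int]:
    """Partition the network into modules by Markov clustering.

    Alternates expansion (matrix self-multiplication) and inflation on the
    network's transition matrix, pruning entries below ``prune_eps`` and
    renormalising, until the largest entry change falls below ``conv_tol``
    or ``max_iter`` is hit (in which case the best partition so far is
    returned and ``net.converged`` is set False). Deterministic for fixed
    inputs; modules can never span disconnected graph components.
    """
    if inflation <= 1.0:
        raise ValueError(f"inflation must exceed 1 to define modules, got {inflation}")
    m = net.transition_matrix.copy()
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = mcl_inflate(_column_normalize(m), inflation)
        m[m < prune_eps] = 0.0
        m = _column_normalize(m)
        if np.max(np.abs(m - prev)) < conv_tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)
    modules = _modules_from_limit(m, net.genes)
    net.modules = modules
    net.converged = converged
    return modules


def module_overlap(
    gene_set: Iterable[str],
    net: CoexpressionNetwork,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Map a gene set onto MCL modules with per-module enrichment p-values.

    Counts query genes per module and tests each module for
    over-representation (hypergeometric, modules as terms over the network's
    gene universe). Query genes absent from the network are tallied in an
    ``unassigned`` row with no test.
    """
    members = net.module_members()
    query = set(gene_set)
    in_net = query & set(net.genes)
    unassigned = sorted(query - in_net)

    rows = []
    if in_net:
        ann = AnnotationSet(
            {f"module_{m}": gs for m, gs in members.items()},
            background=net.genes,
            source="module",
        )
        results = {r.term_id: r for r in enrich(sorted(in_net), ann, alpha=alpha)}
        for m in sorted(members):
            res = results[f"module_{m}"]
            rows.append(
                {"module_id": m, "module_size": len(members[m]),
                 "query_count": res.k, "p_value": res.p_value,
                 "enriched": res.enriched}
            )
    else:
        for m in sorted(members):
            rows.append({"module_id": m, "module_size": len(members[m]),
                         "query_count": 0, "p_value": 1.0, "enriched": False})
    rows.append({"module_id": "unassigned", "module_size": np.nan,
                 "query_count": len(unassigned), "p_value": np.nan,
                 "enriched": False})
    return pd.DataFrame(rows)
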