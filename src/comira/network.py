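"""Gene-gene coexpression networks: adjacency, thresholding, components, hubs.

The adjacency between genes i and j is a power of their Pearson correlation,
``|r|^beta`` (unsigned, the default) or ``((1+r)/2)^beta`` (signed).  Edges
keep only the strongest correlations (|r| >= 0.7 by default, sign-agnostic:
strong negative coexpression also indicates interaction), the resulting
graph is split into connected components ("networks", largest first), and
hub genes are nodes with more than ``min_degree`` neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .correlation import _standardize_rows

DEFAULT_EDGE_THRESHOLD = 0.7
DEFAULT_HUB_DEGREE = 20


@dataclass
class AdjacencySpec:
    """Parameters of the correlation-power adjacency.

    beta
        Exponent applied to the (absolute or shifted) correlation; must be
        positive. With a hard threshold on |r| the exponent does not change
        the edge set, so beta=1 is the default; larger beta gives
        soft-threshold-style weights.
    edge_threshold
        Inclusive edge cutoff on the thresholding scale, in (0, 1].
    signed
        If True use ((1+r)/2)^beta so negative correlations get low weight;
        default False (|r|^beta), treating strong negative coexpression as
        interaction too.
    """

    beta: float = 1.0
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    signed: bool = False

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0 < self.edge_threshold <= 1):
            raise ValueError("edge_threshold must be in (0, 1]")


@dataclass
class CoexpressionGraph:
    """Thresholded coexpression graph with components and degrees.

    ``graph`` is an undirected networkx graph whose edges carry ``r`` (the
    correlation) and ``weight`` (the adjacency value on the thresholding
    scale). Isolated genes are not nodes. ``components`` lists connected
    components by decreasing size, ties broken by smallest lexicographic
    member.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def degree(self) -> dict[str, int]:
        return {n: d for n, d in self.graph.degree()}

    @property
    def components(self) -> list[set[str]]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        comps.sort(key=lambda c: (-len(c), min(c)))
        return comps


def gene_gene_correlation(m: ExpressionMatrix) -> tuple[list[str], np.ndarray]:
    """Symmetric gene-gene Pearson matrix of a log2 expression matrix.

    Zero-variance genes get NaN correlations (warned), diagonal is 1 for
    well-defined genes.
    """
    if m.scale != "log2":
        raise ValueError("coexpression operates on log2-scale matrices")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    z, bad = _standardize_rows(m.values)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance gene(s): correlations undefined")
    r = np.clip(z @ z.T, -1.0, 1.0)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    return list(m.gene_ids), r


def gene_gene_adjacency(m: ExpressionMatrix, spec: AdjacencySpec) -> pd.DataFrame:
    """Correlation-power adjacency M(i,j), diagonal zeroed, symmetric.

    Undefined correlations (zero-variance genes) contribute weight 0; the
    gene stays in the matrix, it just cannot gain edges.
    """
    genes, r = gene_gene_correlation(m)
    if spec.signed:
        a = ((1.0 + r) / 2.0) ** spec.beta
    else:
        a = np.abs(r) ** spec.beta
    a = np.nan_to_num(a, nan=0.0)
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def threshold_edges(
    matrix: pd.DataFrame,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    on: Literal["correlation", "adjacency"] = "correlation",
    r_matrix: pd.DataFrame | None = None,
) -> CoexpressionGraph:
    """Build the graph of entries meeting the inclusive threshold.

    ``on="correlation"`` treats ``matrix`` as a signed correlation matrix and
    tests ``|r| >= threshold`` (positive or negative both count);
    ``on="adjacency"`` tests the value itself. Isolated genes do not become
    nodes. ``r_matrix`` optionally supplies the correlations stored on edges
    when thresholding an adjacency.
    """
    vals = matrix.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    genes = list(matrix.index)
    score = np.abs(vals) if on == "correlation" else vals
    with np.errstate(invalid="ignore"):
        mask = score >= threshold
    np.fill_diagonal(mask, False)
    rsrc = r_matrix.to_numpy(dtype=float) if r_matrix is not None else vals
    g = nx.Graph()
    ii, jj = np.nonzero(np.triu(mask, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(
            genes[i], genes[j], r=float(rsrc[i, j]), weight=float(np.abs(vals[i, j]))
        )
    return CoexpressionGraph(g)


def connected_components(g: CoexpressionGraph) -> list[set[str]]:
    """Connected components by decreasing size (deterministic tie-break)."""
    return g.components


def hub_genes(
    g: CoexpressionGraph, min_degree_exclusive: int = DEFAULT_HUB_DEGREE
) -> list[tuple[str, int]]:
    """Genes with strictly more than ``min_degree_exclusive`` neighbors.

    Sorted by decreasing degree, then lexicographically; degree 21 is a hub
    at the default, degree 20 is not.
    """
    hubs = [(n, d) for n, d in g.graph.degree() if d > min_degree_exclusive]
    hubs.sort(key=lambda t: (-t[1], t[0]))
    return hubs


def export_edge_list(
    g: CoexpressionGraph, path: str | Path, format: Literal["sif", "tsv"] = "tsv"
) -> None:
    """Write the edge list Cytoscape-style.

    SIF: one ``geneA<TAB>co<TAB>geneB`` line per edge; TSV: columns source,
    target, r, weight. Each unordered edge appears once, endpoints in
    lexicographic order, edges sorted.
    """
    rows = []
    for u, v, data in g.graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append((a, b, data.get("r", float("nan")), data.get("weight", float("nan"))))
    rows.sort()
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for a, b, _, _ in rows:
                fh.write(f"{a}\tco\t{b}\n")
    elif format == "tsv":
        pd.DataFrame(rows, columns=["source", "target", "r", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_edge_list_tsv(path: str | Path) -> CoexpressionGraph:
    """Re-parse a TSV edge list written by :func:`export_edge_list`."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.source, row.target, r=float(row.r), weight=float(row.weight))
    return CoexpressionGraph(g)


def build_network(
    m: ExpressionMatrix,
    spec: AdjacencySpec | None = None,
    genes: list[str] | None = None,
) -> CoexpressionGraph:
    """Adjacency + threshold in one step, optionally on a gene subset."""
    spec = spec or AdjacencySpec()
    if genes is not None:
        m = ExpressionMatrix(m.data.loc[genes], scale=m.scale)
    gene_ids, r = gene_gene_correlation(m)
    rdf = pd.DataFrame(r, index=gene_ids, columns=gene_ids)
    return threshold_edges(rdf, threshold=spec.edge_threshold, on="correlation")
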