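"""Gene co-expression network: Pearson edges with FDR-controlled retention.

Pairwise Pearson correlations are computed across all samples of all
three conditions pooled, each correlation gets a Student asymptotic
two-sided p-value (t = r*sqrt((n-2)/(1-r^2)) on n-2 df), p-values are
adjusted jointly by Benjamini-Hochberg over every tested pair, and pairs
with q below the edge threshold (default 0.05) become edges.  Negative
correlations are eligible; edge records keep r's sign.  Zero-variance
genes are excluded from pairing (their correlation is undefined).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_EDGE_FDR = 0.05


def pairwise_correlation(
    expr: pd.DataFrame, genes: list[str] | None = None
) -> pd.DataFrame:
    """All unordered-pair Pearson correlations over pooled samples.

    Returns a DataFrame with columns ``gene_a``, ``gene_b``, ``r`` (pairs in
    lexicographic order, a < b).  Pairs involving zero-variance genes are
    skipped with a log message.  Requires >= 3 samples.
    """
    if genes is not None:
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise KeyError(f"genes absent from expression table: {missing[:5]}")
        expr = expr.loc[list(genes)]
    n = expr.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {n}")

    expr = expr.sort_index()
    variances = expr.var(axis=1, ddof=0)
    degenerate = variances[variances == 0].index
    if len(degenerate):
        logger.warning(
            "skipping %d zero-variance gene(s) in correlation: %s",
            len(degenerate), list(degenerate[:5]),
        )
        expr = expr.drop(index=degenerate)
    ids = expr.index.to_numpy()
    if len(ids) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r"])

    r = np.corrcoef(expr.to_numpy())
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame(
        {"gene_a": ids[iu], "gene_b": ids[ju], "r": np.clip(r[iu, ju], -1.0, 1.0)}
    )


def correlation_pvalue(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided Student asymptotic p-value for a Pearson correlation.

    |r| = 1 is clipped to p = 0 (the t statistic diverges).
    """
    if n < 3:
        raise ValueError("need n >= 3 samples")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("|r| must be <= 1")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r_arr * np.sqrt((n - 2) / (1.0 - r_arr**2))
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return p if np.ndim(r) else float(p)


def build_gcn(
    pairs: pd.DataFrame,
    n_samples: int,
    nodes: list[str] | None = None,
    fdr_max: float = DEFAULT_EDGE_FDR,
) -> nx.Graph:
    """Assemble the co-expression network from correlated pairs.

    ``pairs`` needs columns gene_a, gene_b, r; p-values are computed here
    and BH-adjusted jointly over all tested pairs.  Edges are kept where
    q < fdr_max (strict); genes with no surviving edge remain as isolated
    nodes (``nodes`` extends the node set beyond the paired genes, e.g.
    with zero-variance genes dropped at the correlation stage).
    """
    G = nx.Graph(n_samples_used=n_samples, edge_fdr_max=fdr_max)
    node_set = set(pairs["gene_a"]) | set(pairs["gene_b"])
    if nodes is not None:
        node_set |= set(nodes)
    G.add_nodes_from(sorted(node_set))
    if not len(pairs):
        return G
    p = np.asarray(correlation_pvalue(pairs["r"].to_numpy(), n_samples))
    q = multipletests(p, method="fdr_bh")[1]
    keep = q < fdr_max
    G.add_edges_from(
        (a, b, {"r": float(r), "pvalue": float(pv), "qvalue": float(qv)})
        for a, b, r, pv, qv in zip(
            pairs["gene_a"].to_numpy()[keep],
            pairs["gene_b"].to_numpy()[keep],
            pairs["r"].to_numpy()[keep],
            p[keep],
            q[keep],
        )
    )
    return G


def coexpression_network(
    expr: pd.DataFrame,
    genes: list[str] | None = None,
    fdr_max: float = DEFAULT_EDGE_FDR,
) -> nx.Graph:
    """Convenience: correlations + p-values + FDR edge filter in one call."""
    pairs = pairwise_correlation(expr, genes)
    node_list = list(genes) if genes is not None else list(expr.index)
    return build_gcn(pairs, n_samples=expr.shape[1], nodes=node_list, fdr_max=fdr_max)


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    rows = [
        {"gene_a": min(a, b), "gene_b": max(a, b), "r": d["r"],
         "p": d["pvalue"], "q": d["qvalue"]}
        for a, b, d in G.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "q"])
    df.sort_values(["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, path)
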