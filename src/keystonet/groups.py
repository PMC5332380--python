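"""Pathway enrichment, background-network merge, and functional groups.

Enriched pathways (hypergeometric over-representation, p < 0.05) are
merged into one undirected simple "background" graph; the drug-responsive
genes induce a sub-network of it; and that sub-network is divided into
functional groups by Newman's leading-eigenvector modularity method:
recursive spectral bisection on the (generalized) modularity matrix
B_ij = A_ij - k_i k_j / (2m), splitting by the sign of the leading
eigenvector, with a Kernighan-Lin style single-vertex fine-tuning sweep
after each split, stopping when the leading eigenvalue is ~0 or the split
no longer increases modularity.  Connected components are processed
independently; isolated nodes become singleton groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree
from scipy import stats
from scipy.linalg import eigh

logger = logging.getLogger(__name__)

DEFAULT_ORA_P_MAX = 0.05
EIGEN_TOL = 1e-8


# --------------------------------------------------------------------------
# pathway collection I/O

@dataclass
class PathwayCollection:
    """Gene sets (from GMT) and gene-gene graphs (from KGML or edge lists)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    graphs: dict[str, nx.Graph] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for pid, G in self.graphs.items():
            members = self.sets.get(pid, set())
            stray = set(G.nodes) - members
            if stray:
                raise ValueError(
                    f"pathway {pid}: graph nodes outside the gene set: {sorted(stray)[:5]}"
                )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: tab-separated lines of set name, description, member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, desc, genes): {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def read_pathway_edges(path: str | Path) -> dict[str, nx.Graph]:
    """Edge-list TSV with columns pathway_id, gene_a, gene_b."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    graphs: dict[str, nx.Graph] = {}
    for pid, sub in df.groupby("pathway_id"):
        G = nx.Graph()
        G.add_edges_from(zip(sub["gene_a"], sub["gene_b"]))
        G.remove_edges_from(nx.selfloop_edges(G))
        graphs[pid] = G
    return graphs


def read_kgml(path: str | Path) -> nx.Graph:
    """Parse a KEGG KGML pathway file into a gene-gene graph.

    Entry elements of type "gene" become nodes (one node per KEGG gene id
    listed in the entry's name attribute); relation elements become edges
    between the genes of the two entries.  Compounds, maps and other
    non-gene entries are dropped, as are self-loops.
    """
    tree = etree.parse(str(path))
    entry_genes: dict[str, list[str]] = {}
    for entry in tree.findall("entry"):
        if entry.get("type") != "gene":
            continue
        entry_genes[entry.get("id")] = entry.get("name", "").split()
    G = nx.Graph()
    for genes in entry_genes.values():
        G.add_nodes_from(genes)
    for rel in tree.findall("relation"):
        g1 = entry_genes.get(rel.get("entry1"), [])
        g2 = entry_genes.get(rel.get("entry2"), [])
        for a in g1:
            for b in g2:
                if a != b:
                    G.add_edge(a, b)
    return G


def collection_from_files(
    gmt_path: str | Path,
    edges_path: str | Path | None = None,
    kgml_paths: dict[str, str | Path] | None = None,
    universe: set[str] | None = None,
) -> PathwayCollection:
    sets = read_gmt(gmt_path)
    graphs: dict[str, nx.Graph] = {}
    if edges_path is not None:
        graphs.update(read_pathway_edges(edges_path))
    if kgml_paths:
        for pid, p in kgml_paths.items():
            graphs[pid] = read_kgml(p)
    for pid, G in graphs.items():
        if pid in sets:  # keep the gene-set contract: edges within the set only
            G.remove_nodes_from(set(G.nodes) - sets[pid])
    coll = PathwayCollection(
        sets=sets,
        graphs=graphs,
        universe=universe if universe is not None else set().union(*sets.values()),
    )
    coll.validate()
    return coll


# --------------------------------------------------------------------------
# over-representation analysis

def ora(
    query: set[str],
    collection: PathwayCollection,
    p_max: float = DEFAULT_ORA_P_MAX,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``query`` in each pathway.

    p = P(X >= overlap) for X ~ Hypergeom(|universe|, |pathway|, |query|),
    with query and pathway sets restricted to the universe.  Returns the
    pathways with p < p_max (strict), sorted by p ascending.
    """
    universe = collection.universe
    if not universe:
        raise ValueError("pathway collection has an empty universe")
    q = query & universe
    M, N = len(universe), len(q)
    rows = []
    for pid in sorted(collection.sets):
        pset = collection.sets[pid] & universe
        k = len(q & pset)
        p = stats.hypergeom.sf(k - 1, M, len(pset), N)
        rows.append({"pathway_id": pid, "overlap": k, "size": len(pset), "pvalue": p})
    df = pd.DataFrame(rows)
    return df[df["pvalue"] < p_max].sort_values("pvalue", kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# background network and sub-network

class EmptySubnetworkError(ValueError):
    pass


def merge_pathways(
    enriched_ids: list[str], collection: PathwayCollection
) -> nx.Graph:
    """Union the enriched pathways' graphs into one undirected simple graph.

    Node attribute ``pathways`` keeps per-node provenance.  Pathways with
    no graph are skipped with a warning (clique fallback deliberately off:
    a gene set carries no topology).
    """
    B = nx.Graph()
    for pid in enriched_ids:
        G = collection.graphs.get(pid)
        if G is None:
            logger.warning("enriched pathway %s has no graph; skipped in merge", pid)
            continue
        for node in G.nodes:
            if node in B:
                B.nodes[node]["pathways"].append(pid)
            else:
                B.add_node(node, pathways=[pid])
        B.add_edges_from((a, b) for a, b in G.edges if a != b)
    return B


def extract_subnetwork(background: nx.Graph, responsive: set[str]) -> nx.Graph:
    """Induced subgraph of the background on the responsive genes."""
    nodes = set(background.nodes) & set(responsive)
    if not nodes:
        raise EmptySubnetworkError(
            "no responsive gene appears in the background network"
        )
    return background.subgraph(nodes).copy()


# --------------------------------------------------------------------------
# leading-eigenvector community detection

@dataclass
class FunctionalGroup:
    group_id: int
    genes: list
    pathways: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.genes)


def modularity(G: nx.Graph, communities: list[set]) -> float:
    """Newman modularity Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) d(c_i, c_j)."""
    m2 = 2.0 * G.number_of_edges()
    if m2 == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        sub = G.subgraph(comm)
        l_c = sub.number_of_edges()
        d_c = sum(d for _, d in G.degree(comm))
        q += l_c / (G.number_of_edges()) - (d_c / m2) ** 2
    return q


def _fine_tune(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style sweep: flip each vertex once, greedily, keep the
    best intermediate state; repeat while the objective improves.

    The objective is s^T Bg s (proportional to the modularity change of the
    bisection); Bg is the generalized modularity matrix of the subgraph.
    """
    n = len(s)
    best_obj = float(s @ Bg @ s)
    improved = True
    while improved:
        improved = False
        s_work = s.copy()
        obj = best_obj
        free = np.ones(n, dtype=bool)
        states = []
        for _ in range(n):
            # flipping vertex v changes the objective by -4 s_v (Bg s)_v + 4 Bg_vv
            bs = Bg @ s_work
            gains = -4.0 * s_work * bs + 4.0 * np.diag(Bg)
            gains[~free] = -np.inf
            v = int(np.argmax(gains))
            s_work[v] = -s_work[v]
            free[v] = False
            obj += gains[v]
            states.append((obj, s_work.copy()))
        top_obj, top_s = max(states, key=lambda t: t[0])
        if top_obj > best_obj + 1e-12:
            best_obj, s = top_obj, top_s
            improved = True
    return s


def _split_sign(Bg: np.ndarray) -> np.ndarray | None:
    """Leading-eigenvector bisection of the (sub)graph with matrix Bg.

    Returns the +/-1 membership vector, or None when no modularity-
    increasing split exists (leading eigenvalue <= tolerance, or the
    fine-tuned split has non-positive objective, or it is one-sided).
    """
    vals, vecs = eigh(Bg)
    lead = vals[-1]
    if lead <= EIGEN_TOL:
        return None
    v = vecs[:, -1]
    s = np.where(v >= 0, 1.0, -1.0)  # exact zeros join the positive side
    s = _fine_tune(Bg, s)
    if float(s @ Bg @ s) <= 1e-12 or np.all(s == s[0]):
        return None
    return s


def detect_groups(subnetwork: nx.Graph) -> list[FunctionalGroup]:
    """Divide the sub-network into functional groups (leading eigenvector).

    Deterministic: nodes are processed in sorted order, the eigenpair comes
    from a dense symmetric eigendecomposition, and exact-zero eigenvector
    entries are assigned to the positive side.  Returns groups numbered
    1..n, sorted by size descending then lexicographic member order; the
    groups partition all sub-network nodes.
    """
    if subnetwork.number_of_nodes() == 0:
        raise EmptySubnetworkError("cannot detect groups on an empty sub-network")
    nodes = sorted(subnetwork.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    A = nx.to_numpy_array(subnetwork, nodelist=nodes, weight=None)
    k = A.sum(axis=1)
    m2 = k.sum()

    communities: list[list] = []

    def recurse(members: np.ndarray) -> None:
        if len(members) == 1 or m2 == 0:
            communities.append(list(members))
            return
        sub = A[np.ix_(members, members)]
        B = sub - np.outer(k[members], k[members]) / m2
        Bg = B - np.diag(B.sum(axis=1))  # generalized modularity matrix
        s = _split_sign(Bg)
        if s is None:
            communities.append(list(members))
            return
        recurse(members[s > 0])
        recurse(members[s < 0])

    for comp in nx.connected_components(subnetwork):
        recurse(np.array(sorted(index[g] for g in comp)))

    communities.sort(key=lambda c: (-len(c), sorted(nodes[i] for i in c)))
    groups = []
    for gid, comm in enumerate(communities, start=1):
        genes = sorted(nodes[i] for i in comm)
        pw = sorted(
            {p for g in genes for p in subnetwork.nodes[g].get("pathways", [])}
        )
        groups.append(FunctionalGroup(group_id=gid, genes=genes, pathways=pw))
    return groups


def write_groups_tsv(groups: list[FunctionalGroup], path: str | Path) -> None:
    rows = [
        {"group_id": g.group_id, "gene": gene, "n_group": g.size,
         "pathways": ";".join(g.pathways)}
        for g in groups
        for gene in g.genes
    ]
    pd.DataFrame(rows, columns=["group_id", "gene", "n_group", "pathways"]).to_csv(
        path, sep="\t", index=False
    )
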