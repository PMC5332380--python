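"""Hub-gene selection: PageRank centrality and targeted network attack.

PageRank on the undirected co-expression network (damping 0.85, uniform
teleport, isolated nodes treated as dangling) ranks genes by centrality.
Removing nodes in ranking order ("targeted attack") and tracking the
largest-connected-component fraction among the remaining nodes shows how
quickly connectivity collapses; the keystone (hub) set is the shortest
ranking prefix whose removal drives that fraction below a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DAMPING = 0.85
DEFAULT_COLLAPSE_THETA = 0.10


def pagerank(
    network: nx.Graph,
    damping: float = DEFAULT_DAMPING,
    tolerance: float = 1e-12,
) -> pd.Series:
    """PageRank scores on the undirected network, sorted for ranking.

    Returns a Series gene -> score, ordered by descending score with ties
    broken by gene identifier ascending; scores sum to 1.
    """
    if not 0 < damping < 1:
        raise ValueError("damping must lie in (0, 1)")
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    scores = nx.pagerank(network, alpha=damping, tol=tolerance, max_iter=1000)
    s = pd.Series(scores, name="pagerank")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


@dataclass
class AttackCurve:
    """LCC fraction after removing the first k nodes, k = 0..N."""

    k: np.ndarray
    lcc_fraction: np.ndarray
    mode: str
    random_repeats: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "lcc_fraction": self.lcc_fraction, "mode": self.mode}
        )


def _lcc_fraction(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n == 0:
        return 0.0
    return max(len(c) for c in nx.connected_components(G)) / n


def _targeted_curve(network: nx.Graph, order: list) -> np.ndarray:
    """LCC fraction after removing order[:k], for k = 0..N.

    Computed backwards with a union-find: nodes are re-inserted in reverse
    removal order, merging components as their edges reappear, which costs
    near O(V + E) instead of N component scans.
    """
    n = len(order)
    idx = {g: i for i, g in enumerate(order)}
    parent = list(range(n))
    size = [1] * n

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    fractions = np.zeros(n + 1)
    present: set[int] = set()
    largest = 0
    for k in range(n - 1, -1, -1):
        i = idx[order[k]]
        present.add(i)
        largest = max(largest, 1)
        for nb in network.adj[order[k]]:
            j = idx[nb]
            if j in present:
                ra, rb = find(i), find(j)
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
                largest = max(largest, size[find(i)])
        fractions[k] = largest / (n - k)
    return fractions


def attack_curve(
    network: nx.Graph,
    order: list,
    mode: str = "targeted",
    random_repeats: int = 20,
    seed: int | None = None,
) -> AttackCurve:
    """Network degradation under node removal.

    ``targeted`` removes the first k nodes of ``order`` for each k;
    ``random`` removes k uniformly sampled nodes, averaged over
    ``random_repeats`` seeded replicates.  The LCC fraction is measured
    against the count of *remaining* nodes, and is 0 by convention once
    every node is removed.
    """
    nodes = list(network.nodes)
    if mode == "targeted":
        missing = set(nodes) - set(order)
        if missing:
            raise ValueError(f"order does not cover {len(missing)} network node(s)")
        fr = _targeted_curve(network, [g for g in order if g in set(nodes)])
        return AttackCurve(np.arange(len(fr)), fr, "targeted")
    if mode == "random":
        rng = np.random.default_rng(seed)
        acc = np.zeros(len(nodes) + 1)
        for _ in range(random_repeats):
            perm = [nodes[i] for i in rng.permutation(len(nodes))]
            acc += _targeted_curve(network, perm)
        return AttackCurve(
            np.arange(len(nodes) + 1), acc / random_repeats, "random",
            random_repeats=random_repeats, seed=seed,
        )
    raise ValueError(f"unknown attack mode {mode!r}")


@dataclass
class KeystoneSet:
    """Top-k ranking prefix selected as hub genes, with the rule that chose k."""

    genes: list
    k: int
    rule: str
    params: dict = field(default_factory=dict)


def _elbow_k(curve: AttackCurve) -> int:
    """Maximum-curvature point: largest discrete second difference."""
    f = curve.lcc_fraction
    if len(f) < 3:
        return int(len(f) - 1)
    second = f[2:] - 2 * f[1:-1] + f[:-2]
    return int(np.argmax(second) + 1)


def select_keystones(
    ranking: pd.Series,
    curve: AttackCurve,
    rule: str = "collapse_threshold",
    theta: float = DEFAULT_COLLAPSE_THETA,
) -> KeystoneSet:
    """Choose the keystone set from the targeted-attack curve.

    ``collapse_threshold`` (default): smallest k with lcc_fraction(k) < theta.
    If the curve never crosses theta, falls back to the ``elbow`` rule with
    a logged warning.  ``elbow``: maximum-curvature point of the curve.
    """
    genes = list(ranking.index)
    if len(curve.lcc_fraction) != len(genes) + 1:
        raise ValueError("curve length does not match ranking length")
    if rule == "collapse_threshold":
        below = np.nonzero(curve.lcc_fraction < theta)[0]
        if len(below):
            k = int(below[0])
            return KeystoneSet(genes[:k], k, "collapse_threshold", {"theta": theta})
        logger.warning(
            "attack curve never falls below theta=%.3g; falling back to elbow rule",
            theta,
        )
        rule = "elbow"
    if rule == "elbow":
        k = _elbow_k(curve)
        return KeystoneSet(genes[:k], k, "elbow", {})
    raise ValueError(f"unknown selection rule {rule!r}")


def write_ranking_tsv(ranking: pd.Series, path: str | Path) -> None:
    df = ranking.rename("score").rename_axis("gene").reset_index()
    df["rank"] = np.arange(1, len(df) + 1)
    df.to_csv(path, sep="\t", index=False)


def write_attack_curve_tsv(curve: AttackCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)
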