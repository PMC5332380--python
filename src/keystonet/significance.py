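"""Keystone-gene-based group significance analysis.

The method asks whether a functional group C concentrates at the top of a
priority list L of keystone genes.  L holds the keystone genes present in
the pathway sub-network, ordered by their min-max scaled PageRank scores
s_j in [0, 1].  Walking down L, a running sum gains s_i at each gene of C
(hit) and loses a constant penalty N_diff / (N_genelist * N_group) at each
gene outside C (miss), where N_diff = |C \\ L|, N_genelist = |L| and
N_group = |C|; the enrichment score ES is the maximum of the running sum.
Groups with many high-priority keystone members therefore get large ES,
while groups mostly outside L pay a large per-miss penalty and can go
negative.

Significance: ES is compared against a Monte Carlo null built by sampling
B (default 10,000) random same-size groups uniformly without replacement
from the background-network genes and re-scoring each; the nominal p is
the fraction of null scores >= the observed ES (ties counted).  Nominal
p-values across groups are adjusted by the Simes-Hochberg step-up
procedure, and groups with adjusted p < 0.005 are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_B = 10_000
DEFAULT_ADJUSTED_MAX = 0.005


# --------------------------------------------------------------------------
# priority list

def scale_scores(ranking: pd.Series) -> pd.Series:
    """Min-max scale centrality scores into [0, 1].

    s = (score - min) / (max - min); a degenerate all-equal ranking maps
    to all zeros with a logged warning.
    """
    if len(ranking) == 0:
        raise ValueError("ranking is empty")
    lo, hi = float(ranking.min()), float(ranking.max())
    if hi == lo:
        logger.warning("all centrality scores equal; scaled scores set to 0")
        return pd.Series(0.0, index=ranking.index, name="scaled_score")
    return ((ranking - lo) / (hi - lo)).rename("scaled_score")


@dataclass
class PriorityList:
    """Keystone genes in the sub-network, by scaled score descending.

    Ties are broken by gene identifier ascending, so the list is a pure
    function of its inputs.
    """

    genes: list
    scores: np.ndarray  # aligned with genes, non-increasing
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in priority list")
        self._pos = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def position(self, gene) -> int | None:
        return self._pos.get(gene)


def build_priority_list(
    keystones: list,
    subnetwork_nodes: set,
    scaled: pd.Series,
    provenance: dict | None = None,
) -> PriorityList:
    """L = keystone genes that are sub-network nodes, by score descending."""
    members = [g for g in keystones if g in subnetwork_nodes]
    if not members:
        raise ValueError("no keystone gene appears in the sub-network")
    missing = [g for g in members if g not in scaled.index]
    if missing:
        raise KeyError(f"scaled scores missing for: {missing[:5]}")
    members.sort(key=lambda g: (-scaled[g], g))
    return PriorityList(
        genes=members,
        scores=scaled.loc[members].to_numpy(),
        provenance=provenance or {},
    )


# --------------------------------------------------------------------------
# enrichment score

def enrichment_score(L: PriorityList, group: set) -> tuple[float, int, np.ndarray]:
    """Running-sum enrichment of ``group`` along the priority list.

    Returns (ES, N_diff, running sums).  With N_diff = 0 every step is a
    hit or a zero-penalty miss, so ES reduces to the sum of the scaled
    scores of the group's members in L.
    """
    if len(L) == 0:
        raise ValueError("priority list is empty")
    if not group:
        raise ValueError("group is empty")
    hit = np.fromiter((g in group for g in L.genes), dtype=bool, count=len(L))
    n_diff = len(group) - int(hit.sum())
    penalty = n_diff / (len(L) * len(group))
    steps = np.where(hit, L.scores, -penalty)
    running = np.cumsum(steps)
    return float(running.max()), int(n_diff), running


def _null_matrix_scores(
    L: PriorityList, draws: np.ndarray, background_genes: list
) -> np.ndarray:
    """Vectorized ES for B sampled groups (rows of ``draws`` index
    ``background_genes``)."""
    B, group_size = draws.shape
    n_list = len(L)
    pos_of = np.full(len(background_genes), -1, dtype=np.int64)
    for i, g in enumerate(background_genes):
        p = L.position(g)
        if p is not None:
            pos_of[i] = p
    positions = pos_of[draws]  # (B, group_size); -1 = not in L

    hit = np.zeros((B, n_list), dtype=bool)
    rows, cols = np.nonzero(positions >= 0)
    hit[rows, positions[rows, cols]] = True
    n_diff = group_size - hit.sum(axis=1)
    penalty = n_diff / (n_list * group_size)
    steps = np.where(hit, L.scores[None, :], -penalty[:, None])
    return np.cumsum(steps, axis=1).max(axis=1)


@dataclass
class NullDistribution:
    es_null: np.ndarray
    group_size: int
    seed: int | None

    @property
    def B(self) -> int:
        return len(self.es_null)


def null_distribution(
    L: PriorityList,
    group_size: int,
    background_genes: list,
    B: int = DEFAULT_B,
    seed: int | None = None,
) -> NullDistribution:
    """Monte Carlo null: B random size-N_C groups from the background.

    Groups are sampled uniformly without replacement within a draw (a
    group is a set), independently across draws, and scored against the
    same list L.  Sampling from *all* background genes — not just L —
    makes the null sensitive to how much of the background lies outside
    the keystone list, via the N_diff penalty.
    """
    background_genes = list(background_genes)
    if group_size > len(background_genes):
        raise ValueError(
            f"group_size {group_size} exceeds background size {len(background_genes)}"
        )
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.empty((B, group_size), dtype=np.int64)
    n_bg = len(background_genes)
    for b in range(B):
        draws[b] = rng.choice(n_bg, size=group_size, replace=False)
    es = _null_matrix_scores(L, draws, background_genes)
    return NullDistribution(es_null=es, group_size=group_size, seed=seed)


def nominal_p(es_obs: float, null: NullDistribution) -> float:
    """P = #(ES_null >= ES_obs) / B, ties counted in the numerator.

    A zero count is stored as 0.0; the display layer renders it "<1/B".
    """
    if null.B == 0:
        raise ValueError("null distribution is empty")
    return float(np.count_nonzero(null.es_null >= es_obs) / null.B)


def render_p(p: float, B: int = DEFAULT_B) -> str:
    """Text rendering: a stored 0 becomes the resolution bound '<1/B'."""
    return f"<{1.0 / B:g}" if p == 0 else f"{p:.4g}"


# --------------------------------------------------------------------------
# multiple testing and the fitted-test surface

def hochberg_adjust(pvalues) -> np.ndarray:
    """Simes-Hochberg step-up adjusted p-values, in the input order.

    adjusted p_(i) = min_{j >= i} (m - j + 1) * p_(j), clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a nonempty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


@dataclass
class EnrichmentRecord:
    group_id: int | str
    es: float
    n_group: int
    n_diff: int
    nominal_p: float
    adjusted_p: float = np.nan
    significant: bool = False


class EnrichmentResults:
    """Per-group test results with a printable summary table."""

    def __init__(
        self,
        records: list[EnrichmentRecord],
        B: int,
        adjusted_max: float,
        nulls: dict | None = None,
    ):
        self.records = records
        self.B = B
        self.adjusted_max = adjusted_max
        self.nulls = nulls or {}

    def to_frame(self, rendered: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "group_id": r.group_id,
                    "ES": r.es,
                    "n_group": r.n_group,
                    "n_diff": r.n_diff,
                    "nominal_p": r.nominal_p,
                    "adjusted_p": r.adjusted_p,
                    "significant": r.significant,
                }
                for r in self.records
            ]
        )
        if rendered:
            df["nominal_p"] = [render_p(p, self.B) for p in df["nominal_p"]]
            df["adjusted_p"] = [render_p(p, self.B) for p in df["adjusted_p"]]
        return df

    def summary(self) -> str:
        df = self.to_frame(rendered=True).sort_values(
            "ES", ascending=False, kind="stable"
        )
        lines = [
            "Keystone-gene group significance",
            f"  Monte Carlo draws per group: {self.B}",
            f"  significance call: adjusted p < {self.adjusted_max}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class KeystoneGroupTest:
    """Significance test of functional groups against a keystone priority list.

    Parameters
    ----------
    priority_list : PriorityList
        Keystone genes in the sub-network with scaled scores, descending.
    background_genes : list
        Node set of the merged background network (null sampling frame).
    groups : dict
        group_id -> member gene set (the functional groups under test).
    """

    def __init__(self, priority_list: PriorityList, background_genes, groups: dict):
        self.L = priority_list
        self.background_genes = sorted(background_genes)
        self.groups = dict(groups)
        if not self.groups:
            raise ValueError("no groups to test")

    def fit(
        self,
        B: int = DEFAULT_B,
        seed: int | None = None,
        adjusted_max: float = DEFAULT_ADJUSTED_MAX,
        keep_nulls: bool = False,
    ) -> EnrichmentResults:
        """Score every group, estimate Monte Carlo p, adjust, and flag.

        Null distributions are shared across groups of equal size (a draw
        depends on the group only through its size); seeds for each size
        are derived from ``seed`` deterministically.
        """
        size_of = {gid: len(members) for gid, members in self.groups.items()}
        nulls: dict[int, NullDistribution] = {}
        root = np.random.default_rng(seed)
        for size in sorted(set(size_of.values())):
            sub_seed = int(root.integers(0, 2**31 - 1))
            nulls[size] = null_distribution(
                self.L, size, self.background_genes, B=B, seed=sub_seed
            )
        records = []
        for gid in self.groups:
            es, n_diff, _ = enrichment_score(self.L, set(self.groups[gid]))
            p = nominal_p(es, nulls[size_of[gid]])
            records.append(
                EnrichmentRecord(
                    group_id=gid, es=es, n_group=size_of[gid],
                    n_diff=n_diff, nominal_p=p,
                )
            )
        adj = hochberg_adjust([r.nominal_p for r in records])
        for r, a in zip(records, adj):
            r.adjusted_p = float(a)
            r.significant = bool(a < adjusted_max)
        return EnrichmentResults(
            records, B=B, adjusted_max=adjusted_max,
            nulls=nulls if keep_nulls else None,
        )


def filter_significant(
    results: pd.DataFrame, adjusted_max: float = DEFAULT_ADJUSTED_MAX
) -> pd.DataFrame:
    """Flag rows with adjusted_p < adjusted_max (strict)."""
    out = results.copy()
    out["significant"] = out["adjusted_p"] < adjusted_max
    return out
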