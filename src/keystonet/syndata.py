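"""Seeded synthetic three-condition RNA count profiles with planted structure.

The generator emulates the statistical shape of a tag-based cardiac
transcriptome experiment: negative-binomial counts for three conditions
(sham/control, disease model, treated) with a handful of replicates each,
a planted set of disease-perturbed genes of which a fraction is restored
to baseline by the treatment, latent-factor co-expression blocks, and a
pathway collection containing one planted gene group concentrated at the
top of a supplied gene ranking.  Every draw is controlled by a single
integer seed, and ground-truth labels for every planted feature are
returned alongside the counts so downstream stages can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("control", "disease", "treated")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate the profiled rat study design: ~10,515 genes over
    3 conditions x 3 replicates, ~800 disease-perturbed genes with a
    |log2 fold change| of 2, of which 62.5% (500) are restored under
    treatment, and library sizes jittered +/-20% around 3M tags.
    """

    n_genes: int = 10515
    replicates_per_condition: int = 3
    baseline_mean_log: float = 5.0       # natural-log mean expression; with the
                                         # log-normal spread this gives ~300 counts
                                         # per gene, i.e. ~3M tags over ~10k genes
    baseline_sigma_log: float = 1.2      # spread of per-gene baselines
    dispersion: float = 0.05             # NB dispersion (gamma-Poisson)
    n_perturbed: int = 800
    effect_log2fc: float = 2.0
    restored_fraction: float = 0.625
    block_sizes: tuple[int, ...] = (60, 60, 60, 60, 60)
    block_correlation: float = 0.8
    block_factor_sd: float = 0.8         # amplitude of the shared module factor;
                                         # large vs count noise so the realized
                                         # count correlation stays near
                                         # block_correlation after attenuation
    sample_noise_sd: float = 0.25        # per-gene, per-sample log-noise
    nominal_depth: float = 3.0e6
    n_pathways: int = 15
    pathway_size_range: tuple[int, int] = (10, 40)
    planted_group_size: int = 10
    planted_group_pool: int = 15         # planted genes drawn from this many top-ranked
    pathway_hint_fraction: float = 0.5   # share of pathway members taken from the hint list
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "replicates_per_condition": self.replicates_per_condition,
        }
        for name, v in counts.items():
            if not np.isfinite(v) or v < 1:
                raise ConfigurationError(f"{name} must be a count >= 1, got {v!r}")
        for name in ("dispersion", "sample_noise_sd", "nominal_depth"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"{name} must be finite and > 0, got {v!r}")
        if not np.isfinite(self.effect_log2fc):
            raise ConfigurationError("effect_log2fc must be finite")
        if not 0.0 <= self.restored_fraction <= 1.0:
            raise ConfigurationError("restored_fraction must lie in [0, 1]")
        if not 0.0 <= self.block_correlation <= 1.0:
            raise ConfigurationError("block_correlation must lie in [0, 1]")
        if self.n_perturbed < 0 or self.n_perturbed > self.n_genes:
            raise ConfigurationError("n_perturbed must lie in [0, n_genes]")
        if any(b < 1 for b in self.block_sizes):
            raise ConfigurationError("block sizes must be counts >= 1")
        if sum(self.block_sizes) > self.n_genes:
            raise ConfigurationError("sum(block_sizes) exceeds n_genes")
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("pathway_size_range must satisfy 1 <= lo <= hi")
        if self.planted_group_size < 0:
            raise ConfigurationError("planted_group_size must be >= 0")
        if not 0.0 <= self.pathway_hint_fraction <= 1.0:
            raise ConfigurationError("pathway_hint_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted-feature labels emitted next to the synthetic counts."""

    perturbed_genes: dict[str, int] = field(default_factory=dict)   # gene -> +1/-1
    restored_genes: set[str] = field(default_factory=set)
    block_membership: dict[str, int] = field(default_factory=dict)  # gene -> block id
    planted_group: set[str] = field(default_factory=set)
    pathway_sets: dict[str, set[str]] = field(default_factory=dict)
    pathway_graphs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "perturbed_genes": self.perturbed_genes,
            "restored_genes": sorted(self.restored_genes),
            "block_membership": self.block_membership,
            "planted_group": sorted(self.planted_group),
            "pathway_sets": {k: sorted(v) for k, v in self.pathway_sets.items()},
            "pathway_graphs": {
                k: [list(e) for e in v] for k, v in self.pathway_graphs.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def simulate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Draw a gene x sample count matrix plus condition map and ground truth.

    Counts are gamma-Poisson (negative binomial) around per-gene log-normal
    baselines.  Perturbed genes have their disease-condition mean multiplied
    by 2**(direction * effect_log2fc); restored genes revert to baseline in
    the treated condition while unrestored ones keep the disease mean.
    Co-expression blocks share a per-sample latent factor on the log-mean
    scale with weight sqrt(block_correlation).  Identical configs and seeds
    give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rep = config.replicates_per_condition
    genes = _gene_ids(config.n_genes)
    samples = [f"{cond}_{r+1}" for cond in CONDITIONS for r in range(n_rep)]
    condition_of = pd.Series(
        [cond for cond in CONDITIONS for _ in range(n_rep)], index=samples, name="condition"
    )
    n_samples = len(samples)

    base_log = rng.normal(config.baseline_mean_log, config.baseline_sigma_log, config.n_genes)

    truth = GroundTruth()
    perturbed_idx = rng.choice(config.n_genes, size=config.n_perturbed, replace=False)
    directions = rng.choice([-1, 1], size=config.n_perturbed)
    n_restored = int(round(config.restored_fraction * config.n_perturbed))
    restored_idx = perturbed_idx[:n_restored]  # perturbed_idx already in random order
    for i, d in zip(perturbed_idx, directions):
        truth.perturbed_genes[genes[i]] = int(d)
    truth.restored_genes = {genes[i] for i in restored_idx}

    # Condition-level mean shifts (natural log of 2**log2fc).
    shift = np.zeros((config.n_genes, len(CONDITIONS)))
    ln2 = np.log(2.0)
    dir_of = dict(zip(perturbed_idx, directions))
    restored = set(restored_idx.tolist())
    for i in perturbed_idx:
        shift[i, 1] = dir_of[i] * config.effect_log2fc * ln2
        if i not in restored:
            shift[i, 2] = shift[i, 1]

    # Latent-factor co-expression blocks on the log scale.
    rho = config.block_correlation
    tau = config.sample_noise_sd
    sigma_f = config.block_factor_sd
    log_noise = rng.normal(0.0, tau, size=(config.n_genes, n_samples))
    pos = 0
    for b, size in enumerate(config.block_sizes):
        factor = rng.normal(0.0, sigma_f, size=n_samples)
        idx = np.arange(pos, pos + size)
        log_noise[idx, :] = (
            np.sqrt(rho) * factor[None, :]
            + np.sqrt(1.0 - rho) * rng.normal(0.0, sigma_f, size=(size, n_samples))
        )
        for i in idx:
            truth.block_membership[genes[i]] = b
        pos += size

    depth = rng.uniform(0.8, 1.2, size=n_samples)  # relative library sizes
    cond_idx = np.repeat(np.arange(len(CONDITIONS)), n_rep)
    log_mu = base_log[:, None] + shift[:, cond_idx] + log_noise + np.log(depth)[None, :]
    mu = np.exp(log_mu)
    # Gamma-Poisson mixture: Var = mu + dispersion * mu^2.
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu / shape)
    values = rng.poisson(lam).astype(np.int64)

    counts = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return counts, condition_of, truth


def simulate_pathways(
    config: SimulationConfig,
    ranking_hint: list[str],
    truth: GroundTruth | None = None,
    universe: list[str] | None = None,
) -> GroundTruth:
    """Build a pathway collection with one planted high-priority group.

    ``ranking_hint`` orders genes by expected downstream centrality; the
    planted group is drawn from its top ``planted_group_pool`` entries so
    the group's members concentrate at the top of the priority list.  Every
    pathway graph is connected (random spanning tree plus extra chords);
    the planted group's members are wired densely inside their pathway so
    community detection can recover them.  Seeded by ``config.seed + 1``
    so pathway structure is independent of the count draw.
    """
    config.validate()
    if not ranking_hint:
        raise ConfigurationError("ranking_hint must be nonempty")
    if config.planted_group_size > len(ranking_hint):
        raise ConfigurationError(
            "planted_group_size exceeds the ranking hint length "
            f"({config.planted_group_size} > {len(ranking_hint)})"
        )
    rng = np.random.default_rng(config.seed + 1)
    truth = truth if truth is not None else GroundTruth()
    pool = universe if universe is not None else list(ranking_hint)
    pool = list(dict.fromkeys(pool))  # dedupe, keep order

    if config.planted_group_size > 0:
        top = ranking_hint[: max(config.planted_group_pool, config.planted_group_size)]
        picked = rng.choice(len(top), size=config.planted_group_size, replace=False)
        truth.planted_group = {top[i] for i in sorted(picked)}
    else:
        truth.planted_group = set()

    lo, hi = config.pathway_size_range
    for p in range(config.n_pathways):
        pid = f"pw{p:03d}"
        size = int(rng.integers(lo, hi + 1))
        if p == 0 and truth.planted_group:
            members = sorted(truth.planted_group)
            extra_n = max(size - len(members), 0)
            others = [g for g in pool if g not in truth.planted_group]
            if extra_n and others:
                extra = rng.choice(len(others), size=min(extra_n, len(others)), replace=False)
                members = members + [others[i] for i in sorted(extra)]
        else:
            # Bias pathway membership toward the hint list so enriched
            # pathways overlap the responsive genes, as KEGG hits would.
            size = min(size, len(pool))
            n_hint = min(int(round(size * config.pathway_hint_fraction)), len(ranking_hint))
            hi_idx = rng.choice(len(ranking_hint), size=n_hint, replace=False)
            members = [ranking_hint[i] for i in sorted(hi_idx)]
            others = [g for g in pool if g not in set(members)]
            n_other = min(size - len(members), len(others))
            if n_other > 0:
                ot_idx = rng.choice(len(others), size=n_other, replace=False)
                members = members + [others[i] for i in sorted(ot_idx)]
        truth.pathway_sets[pid] = set(members)
        truth.pathway_graphs[pid] = _connected_edges(
            members, rng, dense_core=sorted(truth.planted_group) if p == 0 else None
        )
    return truth


def _connected_edges(
    members: list[str], rng: np.random.Generator, dense_core: list[str] | None = None
) -> list[tuple[str, str]]:
    """Random spanning tree over ``members`` plus chords; optional dense core."""
    n = len(members)
    if n == 1:
        return []
    order = list(rng.permutation(n))
    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edges.add((min(a, b), max(a, b)))

    for k in range(1, n):
        parent = order[int(rng.integers(0, k))]
        add(members[order[k]], members[parent])
    for _ in range(n // 2):  # chords
        i, j = rng.integers(0, n, size=2)
        add(members[int(i)], members[int(j)])
    if dense_core and len(dense_core) > 2:
        core = list(dense_core)
        for i in range(len(core)):
            add(core[i], core[(i + 1) % len(core)])
            add(core[i], core[(i + 2) % len(core)])
    return sorted(edges)


# --------------------------------------------------------------------------
# plain-text writers

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_condition_map_tsv(condition_of: pd.Series, path: str | Path) -> None:
    condition_of.rename_axis("sample").to_csv(path, sep="\t", header=True)


def write_gmt(pathway_sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathway_sets):
            genes = "\t".join(sorted(pathway_sets[pid]))
            fh.write(f"{pid}\tsynthetic pathway\t{genes}\n")


def write_pathway_edges_tsv(
    pathway_graphs: dict[str, list[tuple[str, str]]], path: str | Path
) -> None:
    rows = [
        {"pathway_id": pid, "gene_a": a, "gene_b": b}
        for pid in sorted(pathway_graphs)
        for a, b in pathway_graphs[pid]
    ]
    pd.DataFrame(rows, columns=["pathway_id", "gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["block_sizes"] = list(config.block_sizes)
    d["pathway_size_range"] = list(config.pathway_size_range)
    return d
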