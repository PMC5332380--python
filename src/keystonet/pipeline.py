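"""End-to-end orchestration: counts -> reverse-regulated genes -> GCN ->
keystones -> functional groups -> group significance, with a manifest.

Every stage logs its input/output cardinalities (genes tested, DEGs,
edges, groups) and all artifacts are plain-text tables, so a run is fully
reproducible from its manifest: rerunning with the same configuration and
seed gives byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import diffexpr, gcn, groups as groups_mod, keystone, significance, syndata

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """File paths and stage parameters for one pipeline run.

    When ``counts_path`` is unset the run starts from the synthetic
    generator (``simulate`` holds its parameters), and the pathway
    collection is simulated too, ranked by the run's own centrality
    ordering.
    """

    counts_path: str | None = None
    condition_map_path: str | None = None
    disease_table_path: str | None = None      # optional precomputed DE tables
    treatment_table_path: str | None = None
    gmt_path: str | None = None
    pathway_edges_path: str | None = None
    control: str = "control"
    disease: str = "disease"
    treated: str = "treated"
    deg_fdr_max: float = diffexpr.DEFAULT_FDR_MAX
    deg_abs_log2fc_min: float = diffexpr.DEFAULT_ABS_LOG2FC_MIN
    edge_fdr_max: float = gcn.DEFAULT_EDGE_FDR
    damping: float = keystone.DEFAULT_DAMPING
    attack_theta: float = keystone.DEFAULT_COLLAPSE_THETA
    attack_rule: str = "collapse_threshold"
    ora_p_max: float = groups_mod.DEFAULT_ORA_P_MAX
    permutations: int = significance.DEFAULT_B
    alpha_adjusted: float = significance.DEFAULT_ADJUSTED_MAX
    seed: int = 0
    simulate: syndata.SimulationConfig = field(default_factory=syndata.SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = syndata.SimulationConfig(**{
            **raw.pop("simulate", {}),
        })
        known = {f.name for f in dataclasses.fields(cls)} - {"simulate"}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", "unknown-key", f"unknown keys: {sorted(unknown)}")
        cfg = cls(simulate=sim, **raw)
        for p in (cfg.counts_path, cfg.condition_map_path, cfg.gmt_path,
                  cfg.pathway_edges_path, cfg.disease_table_path,
                  cfg.treatment_table_path):
            if p is not None and not Path(p).exists():
                raise PipelineError("config", "missing-file", f"file not found: {p}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = syndata.config_to_dict(self.simulate)
        return d


@dataclass
class PipelineResults:
    """Everything a run produced, for inspection or report writing."""

    config: PipelineConfig
    counts: pd.DataFrame
    condition_of: pd.Series
    truth: syndata.GroundTruth | None
    disease_table: pd.DataFrame
    treatment_table: pd.DataFrame
    disease_degs: pd.Series
    treatment_degs: pd.Series
    regulated: pd.Series
    network: nx.Graph
    ranking: pd.Series
    curve: keystone.AttackCurve
    keystones: keystone.KeystoneSet
    enriched: pd.DataFrame
    background: nx.Graph
    subnetwork: nx.Graph
    functional_groups: list
    priority_list: significance.PriorityList
    enrichment: significance.EnrichmentResults

    def cardinalities(self) -> dict:
        return {
            "genes": int(self.counts.shape[0]),
            "samples": int(self.counts.shape[1]),
            "disease_degs": int(len(self.disease_degs)),
            "treatment_degs": int(len(self.treatment_degs)),
            "reverse_regulated": int(len(self.regulated)),
            "gcn_nodes": int(self.network.number_of_nodes()),
            "gcn_edges": int(self.network.number_of_edges()),
            "keystones": int(self.keystones.k),
            "enriched_pathways": int(len(self.enriched)),
            "background_nodes": int(self.background.number_of_nodes()),
            "background_edges": int(self.background.number_of_edges()),
            "subnetwork_nodes": int(self.subnetwork.number_of_nodes()),
            "functional_groups": int(len(self.functional_groups)),
            "priority_list": int(len(self.priority_list)),
            "significant_groups": int(
                sum(r.significant for r in self.enrichment.records)
            ),
        }


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """(comparison - reference) / reference * 100; sign gives direction."""
    if reference_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return (comparison_mean - reference_mean) / reference_mean * 100.0


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResults:
    """Execute every stage in order; optionally write all artifacts."""
    # --- inputs ----------------------------------------------------------
    truth: syndata.GroundTruth | None = None
    if config.counts_path is not None:
        try:
            counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
            condition_of = pd.read_csv(
                config.condition_map_path, sep="\t", index_col=0
            ).iloc[:, 0]
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("input", "read-failed", str(exc)) from exc
    else:
        counts, condition_of, truth = syndata.simulate_counts(config.simulate)
    try:
        diffexpr.validate_count_matrix(counts, condition_of)
    except ValueError as exc:
        raise PipelineError("input", "invalid-counts", str(exc)) from exc
    logger.info("input: %d genes x %d samples", *counts.shape)

    # --- differential expression ----------------------------------------
    try:
        if config.disease_table_path:
            disease_table = diffexpr.read_differential_table(
                config.disease_table_path, f"{config.disease}-vs-{config.control}"
            )
        else:
            disease_table = diffexpr.test_differential(
                counts, condition_of, (config.control, config.disease)
            )
        if config.treatment_table_path:
            treatment_table = diffexpr.read_differential_table(
                config.treatment_table_path, f"{config.treated}-vs-{config.disease}"
            )
        else:
            treatment_table = diffexpr.test_differential(
                counts, condition_of, (config.disease, config.treated)
            )
    except (ValueError, diffexpr.ContrastError) as exc:
        raise PipelineError("diffexpr", "test-failed", str(exc)) from exc
    disease_degs = diffexpr.call_degs(
        disease_table, config.deg_fdr_max, config.deg_abs_log2fc_min
    )
    treatment_degs = diffexpr.call_degs(
        treatment_table, config.deg_fdr_max, config.deg_abs_log2fc_min
    )
    regulated = diffexpr.reverse_regulated(disease_degs, treatment_degs)
    logger.info(
        "diffexpr: %d disease DEGs, %d treatment DEGs, %d reverse-regulated",
        len(disease_degs), len(treatment_degs), len(regulated),
    )
    if len(regulated) < 2:
        raise PipelineError(
            "diffexpr", "too-few-regulated",
            f"only {len(regulated)} reverse-regulated gene(s); cannot build a network",
        )

    # --- co-expression network ------------------------------------------
    tpm = diffexpr.normalize_tpm(counts)
    network = gcn.coexpression_network(
        tpm, genes=sorted(regulated.index), fdr_max=config.edge_fdr_max
    )
    logger.info("gcn: %d nodes, %d edges", network.number_of_nodes(),
                network.number_of_edges())

    # --- keystones -------------------------------------------------------
    ranking = keystone.pagerank(network, damping=config.damping)
    curve = keystone.attack_curve(network, list(ranking.index), mode="targeted")
    keys = keystone.select_keystones(
        ranking, curve, rule=config.attack_rule, theta=config.attack_theta
    )
    logger.info("keystone: %d hub genes (rule=%s)", keys.k, keys.rule)

    # --- pathway collection ---------------------------------------------
    if config.gmt_path is not None:
        collection = groups_mod.collection_from_files(
            config.gmt_path, config.pathway_edges_path,
            universe=set(counts.index),
        )
    else:
        truth = syndata.simulate_pathways(
            config.simulate,
            ranking_hint=list(ranking.index),
            truth=truth,
            universe=list(counts.index),
        )
        collection = groups_mod.PathwayCollection(
            sets=truth.pathway_sets,
            graphs={
                pid: nx.Graph(edges) if edges else nx.Graph()
                for pid, edges in truth.pathway_graphs.items()
            },
            universe=set(counts.index),
        )
        for pid in collection.graphs:  # singletons carry nodes, not edges
            collection.graphs[pid].add_nodes_from(truth.pathway_sets[pid])

    # --- enrichment, background, groups ---------------------------------
    responsive = set(treatment_degs.index)
    enriched = groups_mod.ora(responsive, collection, p_max=config.ora_p_max)
    if not len(enriched):
        raise PipelineError("groups", "no-enrichment",
                            "no pathway enriched below the ORA threshold")
    background = groups_mod.merge_pathways(list(enriched["pathway_id"]), collection)
    try:
        subnetwork = groups_mod.extract_subnetwork(background, responsive)
    except groups_mod.EmptySubnetworkError as exc:
        raise PipelineError("groups", "empty-subnetwork", str(exc)) from exc
    functional_groups = groups_mod.detect_groups(subnetwork)
    logger.info(
        "groups: %d enriched pathways, background %d/%d, sub-network %d nodes, %d groups",
        len(enriched), background.number_of_nodes(), background.number_of_edges(),
        subnetwork.number_of_nodes(), len(functional_groups),
    )

    # --- significance ----------------------------------------------------
    scaled = significance.scale_scores(ranking)
    try:
        priority = significance.build_priority_list(
            keys.genes, set(subnetwork.nodes), scaled,
            provenance={"keystone_rule": keys.rule, "k": keys.k},
        )
    except ValueError as exc:
        raise PipelineError("significance", "empty-priority-list", str(exc)) from exc
    test = significance.KeystoneGroupTest(
        priority, list(background.nodes),
        {g.group_id: set(g.genes) for g in functional_groups},
    )
    enrichment = test.fit(
        B=config.permutations, seed=config.seed, adjusted_max=config.alpha_adjusted
    )
    logger.info("significance: %d/%d groups significant",
                sum(r.significant for r in enrichment.records),
                len(enrichment.records))

    results = PipelineResults(
        config=config, counts=counts, condition_of=condition_of, truth=truth,
        disease_table=disease_table, treatment_table=treatment_table,
        disease_degs=disease_degs, treatment_degs=treatment_degs,
        regulated=regulated, network=network, ranking=ranking, curve=curve,
        keystones=keys, enriched=enriched, background=background,
        subnetwork=subnetwork, functional_groups=functional_groups,
        priority_list=priority, enrichment=enrichment,
    )
    if outdir is not None:
        write_artifacts(results, outdir)
    return results


def write_artifacts(results: PipelineResults, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    syndata.write_counts_tsv(results.counts, out / "counts.tsv")
    syndata.write_condition_map_tsv(results.condition_of, out / "conditions.tsv")
    diffexpr.write_differential_table(results.disease_table, out / "de_disease_vs_control.tsv")
    diffexpr.write_differential_table(results.treatment_table, out / "de_treated_vs_disease.tsv")
    results.regulated.rename_axis("gene").to_csv(out / "reverse_regulated.tsv", sep="\t")
    gcn.write_edge_list(results.network, out / "gcn_edges.tsv")
    gcn.write_graphml(results.network, out / "gcn.graphml")
    keystone.write_ranking_tsv(results.ranking, out / "pagerank.tsv")
    keystone.write_attack_curve_tsv(results.curve, out / "attack_curve.tsv")
    pd.Series(results.keystones.genes, name="gene").to_csv(
        out / "keystones.tsv", sep="\t", index=False
    )
    results.enriched.to_csv(out / "enriched_pathways.tsv", sep="\t", index=False)
    nx.write_graphml(_strip_attrs(results.background), out / "background.graphml")
    nx.write_graphml(_strip_attrs(results.subnetwork), out / "subnetwork.graphml")
    groups_mod.write_groups_tsv(results.functional_groups, out / "functional_groups.tsv")
    results.enrichment.to_frame(rendered=True).to_csv(
        out / "group_significance.tsv", sep="\t", index=False
    )
    if results.truth is not None:
        syndata.write_ground_truth(results.truth, out / "ground_truth.json")
    manifest = {
        "config": results.config.to_dict(),
        "cardinalities": results.cardinalities(),
        "keystone_rule": {"rule": results.keystones.rule, **results.keystones.params},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def _strip_attrs(G: nx.Graph) -> nx.Graph:
    """GraphML cannot serialize list attributes; join pathway provenance."""
    H = G.copy()
    for _, data in H.nodes(data=True):
        if isinstance(data.get("pathways"), list):
            data["pathways"] = ";".join(data["pathways"])
    return H


def checksum_tables(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every TSV artifact, for determinism checks."""
    out = Path(outdir)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.tsv"))
    }
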