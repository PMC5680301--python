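"""End-to-end orchestration: two expression datasets in, result tables out.

The same stages run independently on each dataset — variant-gene
selection, gene-module consensus clustering, network pruning, cell-line
consensus clustering, cluster characterization and drug association —
followed by the cross-dataset stages (clustering concordance and the
robust intersection of significant drug associations).  Every run is a
pure function of (inputs, config); a provenance block records the
configuration, seed and input checksums next to the results.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .concordance import (
    build_similarity_matrix,
    concordance_accuracy,
    match_clusters,
    order_for_heatmap,
)
from .consensus import (
    clustering_from_result,
    consensus_cluster,
    modules_from_gene_clusters,
    select_k,
)
from .characterization import (
    differential_expression,
    mutation_enrichment,
    preranked_gsea,
)
from .datatypes import (
    AnalysisConfig,
    CellLineClustering,
    DrugResponseTable,
    ExpressionMatrix,
    GeneModule,
    InteractionGraph,
    MutationMatrix,
    ValidationError,
)
from .drug_association import (
    cluster_drug_association,
    compare_partitions,
    robust_associations,
    transform_sensitivity,
)
from .gene_selection import compute_iqr_profile, find_inflexion_point
from .network_filter import filter_by_network

__all__ = ["PipelineError", "DatasetResult", "StudyResult", "run_study",
           "run_pipeline", "write_study_result"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done", name)
            return out
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


@dataclass
class DatasetResult:
    tag: str
    iqr_table: pd.DataFrame
    selected_genes: tuple[str, ...]
    gene_k: int
    modules: list[GeneModule]
    filter_reports: list
    kept_genes: tuple[str, ...]
    sample_k: int
    clustering: CellLineClustering
    de_tables: dict                      # cluster -> DataFrame
    gsea_table: pd.DataFrame
    mutation_table: pd.DataFrame | None
    pseudo_f_table: pd.DataFrame | None
    association_table: pd.DataFrame | None
    weak_structure: bool = False


@dataclass
class StudyResult:
    a: DatasetResult
    b: DatasetResult
    similarity: pd.DataFrame
    accuracy_jaccard: float
    accuracy_rand: float
    cluster_match: dict
    robust_table: pd.DataFrame | None
    config: AnalysisConfig


@_stage("gene_selection")
def _select_genes(expr: ExpressionMatrix):
    profile = compute_iqr_profile(expr)
    knee = find_inflexion_point(profile)
    table = pd.DataFrame({
        "gene_id": profile.gene_ids,
        "iqr": profile.iqr_values,
        "selected": [g in knee.selected_gene_ids for g in profile.gene_ids],
    })
    return table, tuple(sorted(knee.selected_gene_ids))


@_stage("gene_modules")
def _gene_modules(expr: ExpressionMatrix, genes, config: AnalysisConfig, tag: str):
    sub = expr.subset_genes(list(genes))
    k_range = [k for k in config.gene_k_range if k <= len(genes)]
    if not k_range:
        raise ValidationError("no feasible k for gene clustering")
    result = consensus_cluster(
        sub, axis="genes", k_range=k_range,
        n_iterations=config.n_iterations,
        subsample_fraction=config.subsample_fraction,
        seed=config.seed,
    )
    k = select_k(result, tol=config.delta_area_tol, override=config.gene_k)
    return modules_from_gene_clusters(result, k, dataset_tag=tag), k


@_stage("network_filter")
def _filter_modules(modules, graph, expr, config: AnalysisConfig):
    reports = [
        filter_by_network(
            m, graph, expr,
            score_min=config.edge_score_min,
            corr_min=config.correlation_min,
        )
        for m in modules
    ]
    kept = sorted(set().union(*(r.kept_gene_ids for r in reports)))
    if not kept:
        raise ValidationError("network filter removed every gene")
    filtered_modules = [
        GeneModule(module_id=r.module_id, gene_ids=r.kept_gene_ids,
                   dataset_tag=m.dataset_tag)
        for m, r in zip(modules, reports) if r.kept_gene_ids
    ]
    return reports, tuple(kept), filtered_modules


@_stage("cell_line_clustering")
def _cluster_cell_lines(expr: ExpressionMatrix, genes, config: AnalysisConfig):
    sub = expr.subset_genes(list(genes))
    k_range = [k for k in config.sample_k_range if k <= expr.n_samples]
    if not k_range:
        raise ValidationError("no feasible k for cell-line clustering")
    result = consensus_cluster(
        sub, axis="samples", k_range=k_range,
        n_iterations=config.n_iterations,
        subsample_fraction=config.subsample_fraction,
        seed=config.seed + 1,
    )
    k = select_k(result, tol=config.delta_area_tol, override=config.sample_k)
    return clustering_from_result(result, k), k, result.weak_structure


@_stage("characterization")
def _characterize(expr, genes, clustering, modules, config, gsea_permutations):
    sub = expr.subset_genes(list(genes))
    de_tables = {}
    gsea_rows = []
    for ci, cluster in enumerate(sorted(clustering.cluster_labels())):
        n_in = len(clustering.members(cluster))
        n_out = len(clustering.sample_ids) - n_in
        if n_in < 2 or n_out < 2:
            logger.info("skipping characterization of cluster %s (size %d)",
                        cluster, n_in)
            continue
        ranked = differential_expression(sub, clustering, cluster)
        de_tables[cluster] = pd.DataFrame(
            [dataclasses.asdict(r) for r in ranked]
        )
        for mi, module in enumerate(modules):
            members = module.gene_ids & set(sub.gene_ids)
            if not members or len(members) >= sub.n_genes:
                continue
            mod = GeneModule(module_id=module.module_id, gene_ids=frozenset(members),
                             dataset_tag=module.dataset_tag)
            res = preranked_gsea(
                ranked, mod, n_permutations=gsea_permutations,
                seed=config.seed + 100 + 7 * ci + mi,
            )
            gsea_rows.append(dataclasses.asdict(res))
    return de_tables, pd.DataFrame(gsea_rows)


@_stage("mutation_enrichment")
def _mutations(mut: MutationMatrix | None, clustering: CellLineClustering):
    if mut is None:
        return None
    results = mutation_enrichment(mut, clustering)
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


@_stage("drug_association")
def _drugs(drugs: DrugResponseTable | None, clustering, tissues, config):
    if drugs is None:
        return None, None
    vectors = transform_sensitivity(drugs)
    pf = None
    if tissues is not None:
        pf = compare_partitions(vectors, clustering, tissues)
        pf = pf.assign(
            paired_t=pf.attrs["paired_t"], paired_p=pf.attrs["paired_p"]
        )
    assoc = cluster_drug_association(
        vectors, clustering, fdr_alpha=config.fdr_alpha
    )
    assoc_df = pd.DataFrame([dataclasses.asdict(r) for r in assoc])
    if not assoc_df.empty:
        assoc_df["significant"] = assoc_df["adjusted_p"] < config.fdr_alpha
    return pf, assoc_df


def _run_dataset(
    tag: str,
    expr: ExpressionMatrix,
    graph: InteractionGraph,
    config: AnalysisConfig,
    drugs: DrugResponseTable | None,
    mutations: MutationMatrix | None,
    tissues: dict | None,
    gsea_permutations: int,
) -> DatasetResult:
    iqr_table, selected = _select_genes(expr)
    modules, gene_k = _gene_modules(expr, selected, config, tag)
    reports, kept, filtered_modules = _filter_modules(modules, graph, expr, config)
    clustering, sample_k, weak = _cluster_cell_lines(expr, kept, config)
    de_tables, gsea_table = _characterize(
        expr, kept, clustering, filtered_modules, config, gsea_permutations
    )
    mut_table = _mutations(mutations, clustering)
    pf_table, assoc_table = _drugs(drugs, clustering, tissues, config)
    return DatasetResult(
        tag=tag,
        iqr_table=iqr_table,
        selected_genes=selected,
        gene_k=gene_k,
        modules=modules,
        filter_reports=reports,
        kept_genes=kept,
        sample_k=sample_k,
        clustering=clustering,
        de_tables=de_tables,
        gsea_table=gsea_table,
        mutation_table=mut_table,
        pseudo_f_table=pf_table,
        association_table=assoc_table,
        weak_structure=weak,
    )


def run_study(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    graph: InteractionGraph,
    config: AnalysisConfig,
    drugs_a: DrugResponseTable | None = None,
    drugs_b: DrugResponseTable | None = None,
    mutations: MutationMatrix | None = None,
    tissues: dict | None = None,
    gsea_permutations: int = 1000,
) -> StudyResult:
    """Run the full pipeline on two harmonized expression datasets."""
    expr_a, expr_b = pio.harmonize_datasets(expr_a, expr_b)
    res_a = _run_dataset("A", expr_a, graph, config, drugs_a, mutations,
                         tissues, gsea_permutations)
    res_b = _run_dataset("B", expr_b, graph, config, drugs_b, mutations,
                         tissues, gsea_permutations)

    sim = build_similarity_matrix(res_a.clustering, res_b.clustering)
    acc_j = concordance_accuracy(sim, "jaccard")
    acc_r = concordance_accuracy(sim, "rand")
    match = match_clusters(res_a.clustering, res_b.clustering)
    robust = None
    if res_a.association_table is not None and res_b.association_table is not None:
        from .drug_association import AssociationResult

        def _records(df):
            cols = ["drug_id", "cluster", "t_statistic", "p_value",
                    "adjusted_p", "phenotype", "n_in", "n_out"]
            return [AssociationResult(**row[cols].to_dict())
                    for _, row in df.iterrows()] if not df.empty else []

        robust = robust_associations(
            _records(res_a.association_table),
            _records(res_b.association_table),
            match, fdr_alpha=config.fdr_alpha,
        )
    return StudyResult(
        a=res_a, b=res_b,
        similarity=order_for_heatmap(sim),
        accuracy_jaccard=acc_j,
        accuracy_rand=acc_r,
        cluster_match={"mapping": dict(match.mapping),
                       "unmatched_a": list(match.unmatched_a),
                       "unmatched_b": list(match.unmatched_b)},
        robust_table=robust,
        config=config,
    )


def write_study_result(result: StudyResult, out_dir: str | Path,
                       provenance: dict | None = None) -> None:
    """Write every result table of a study run as TSV under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for res in (result.a, result.b):
        tag = res.tag.lower()
        res.iqr_table.to_csv(out / f"{tag}_gene_iqr.tsv", sep="\t", index=False)
        pd.DataFrame({
            "gene_id": [g for m in res.modules for g in sorted(m.gene_ids)],
            "module_id": [m.module_id for m in res.modules
                          for _ in sorted(m.gene_ids)],
        }).to_csv(out / f"{tag}_gene_modules.tsv", sep="\t", index=False)
        rows = []
        for rep in res.filter_reports:
            for g in sorted(rep.kept_gene_ids):
                rows.append({"module_id": rep.module_id, "gene_id": g,
                             "status": "kept", "reason": ""})
            for g, reason in sorted(rep.dropped.items()):
                rows.append({"module_id": rep.module_id, "gene_id": g,
                             "status": "dropped", "reason": reason})
        pd.DataFrame(rows).to_csv(out / f"{tag}_network_filter.tsv",
                                  sep="\t", index=False)
        pio.save_clustering(res.clustering, out / f"{tag}_clustering.tsv")
        if not res.gsea_table.empty:
            res.gsea_table.to_csv(out / f"{tag}_gsea.tsv", sep="\t", index=False)
        for cluster, df in res.de_tables.items():
            df.to_csv(out / f"{tag}_de_{cluster}.tsv", sep="\t", index=False)
        if res.mutation_table is not None:
            res.mutation_table.to_csv(out / f"{tag}_mutation_enrichment.tsv",
                                      sep="\t", index=False)
        if res.pseudo_f_table is not None:
            res.pseudo_f_table.to_csv(out / f"{tag}_pseudo_f.tsv",
                                      sep="\t", index=False)
        if res.association_table is not None:
            res.association_table.to_csv(out / f"{tag}_associations.tsv",
                                         sep="\t", index=False)
    result.similarity.to_csv(out / "similarity_matrix.tsv", sep="\t",
                             index_label="sample_id")
    pd.DataFrame([{
        "accuracy_jaccard": result.accuracy_jaccard,
        "accuracy_rand": result.accuracy_rand,
        "k_a": result.a.sample_k,
        "k_b": result.b.sample_k,
    }]).to_csv(out / "concordance.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"cluster_a": a, "cluster_b": b}
        for a, b in result.cluster_match["mapping"].items()
    ]).to_csv(out / "cluster_match.tsv", sep="\t", index=False)
    if result.robust_table is not None:
        result.robust_table.to_csv(out / "robust_associations.tsv",
                                   sep="\t", index=False)
    prov_lines = [f"{k}: {v}" for k, v in sorted(dataclasses.asdict(
        result.config).items())]
    if provenance:
        prov_lines += [f"{k}: {v}" for k, v in sorted(provenance.items())]
    (out / "provenance.txt").write_text("\n".join(prov_lines) + "\n",
                                        encoding="utf-8")


def run_pipeline(
    config: AnalysisConfig,
    inputs: dict,
    out_dir: str | Path,
    gsea_permutations: int = 1000,
) -> StudyResult:
    """File-based entry point: load inputs, run the study, write results.

    ``inputs`` maps names to paths: ``expression_a``, ``expression_b`` and
    ``graph`` are required; ``drugs_a``, ``drugs_b``, ``mutations`` and
    ``tissues`` are optional.  Drug tables are read as micromolar IC50s
    unless ``drug_metric`` / ``drug_orientation`` entries say otherwise.
    """
    expr_a = pio.load_expression_matrix(inputs["expression_a"])
    expr_b = pio.load_expression_matrix(inputs["expression_b"])
    graph = pio.load_interaction_graph(inputs["graph"])
    metric = inputs.get("drug_metric", "ic50_uM")
    orientation = inputs.get("drug_orientation", "high_is_resistant")
    drugs_a = drugs_b = None
    if "drugs_a" in inputs:
        drugs_a = pio.load_drug_response(inputs["drugs_a"], metric, orientation)
    if "drugs_b" in inputs:
        drugs_b = pio.load_drug_response(inputs["drugs_b"], metric, orientation)
    mutations = (pio.load_mutation_matrix(inputs["mutations"])
                 if "mutations" in inputs else None)
    tissues = None
    if "tissues" in inputs:
        df = pd.read_csv(inputs["tissues"], sep="\t", dtype=str)
        tissues = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))

    provenance = {"seed": config.seed}
    for key in ("expression_a", "expression_b", "graph", "drugs_a",
                "drugs_b", "mutations", "tissues"):
        if key in inputs:
            provenance[f"sha256_{key}"] = pio.file_checksum(inputs[key])

    result = run_study(
        expr_a, expr_b, graph, config,
        drugs_a=drugs_a, drugs_b=drugs_b,
        mutations=mutations, tissues=tissues,
        gsea_permutations=gsea_permutations,
    )
    write_study_result(result, out_dir, provenance)
    return result
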