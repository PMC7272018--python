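"""End-to-end orchestration: preprocess → DEGs → clustering → enrichment →
PPI → pathway scores → SVM classification, from a single config.

Inputs come either from files (expression TSV, optional probe map, metadata
CSV, GMT collections, PPI edge lists) or from the synthetic-cohort generator;
exactly one of the two modes must be configured.  Every stage writes its
artifact to the output directory, so any later stage can be re-run in
isolation, and a machine-readable JSON summary collects the headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import classify, cluster_eval, diffexpr, enrichment, pathscore, ppi, preprocess
from .synthetic_data import SimulationConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; thresholds default to the study's values."""

    # real-input mode
    expression: str | None = None
    probe_map: str | None = None
    metadata: str | None = None
    gmt_files: list[str] = field(default_factory=list)
    edge_files: list[str] = field(default_factory=list)
    # synthetic mode
    synthetic: SimulationConfig | None = None
    # thresholds / parameters
    adj_p_max: float = 0.01
    abs_lfc_min: float = 0.6
    enrich_p_max: float = 0.05
    epsilon: float = 1e-8
    min_weight: float = 0.0
    rfe_step: int = 1
    folds: int = 5
    svm_c: float = 1.0
    # bookkeeping
    seed: int = 0
    outdir: str = "pathrisk_out"

    def __post_init__(self):
        real = any([self.expression, self.metadata, self.gmt_files, self.edge_files])
        if self.synthetic is not None and real:
            raise ValueError("configure either real input paths or synthetic mode, not both")
        if self.synthetic is None and not real:
            raise ValueError("no inputs configured: set input paths or synthetic mode")
        if self.synthetic is None:
            for name in ("expression", "metadata"):
                if getattr(self, name) is None:
                    raise ValueError(f"real-input mode requires {name!r}")
            if not self.gmt_files or not self.edge_files:
                raise ValueError("real-input mode requires gmt_files and edge_files")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SimulationConfig(**raw["synthetic"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2^31."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return (and write) the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)  # cohort, rfe, cv_path, cv_full
    summary: dict = {"seed": config.seed}

    stage = "inputs"
    try:
        if config.synthetic is not None:
            sim = dataclasses.replace(config.synthetic, seed=seeds[0])
            cohort = generate_cohort(sim)
            write_cohort(cohort, outdir / "inputs")
            probe_matrix, probe_map = cohort.expression, None
            annotations = cohort.annotations
            gene_set_collections = {"synthetic": cohort.gene_sets}
            graph = nx.Graph()
            graph.add_edges_from(cohort.ppi_edges)
            graph.graph["n_self_loops"] = 0
        else:
            probe_matrix = pd.read_csv(config.expression, sep="\t", index_col=0)
            probe_map = (
                preprocess.read_probe_map(config.probe_map) if config.probe_map else None
            )
            annotations = pd.read_csv(config.metadata, index_col=0)
            gene_set_collections = {
                Path(p).stem: enrichment.read_gmt(p) for p in config.gmt_files
            }
            graph = ppi.load_union(config.edge_files)
        if "group" not in annotations.columns:
            raise ValueError("metadata must contain a 'group' column (case/control)")
        labels = annotations["group"]

        stage = "preprocess"
        if probe_map is not None:
            probe_matrix = preprocess.collapse_probes(probe_matrix, probe_map).matrix
        z = preprocess.zscore_rows(probe_matrix)
        expr = z.matrix
        expr.to_csv(outdir / "expression_zscore.tsv", sep="\t", index_label="gene")
        summary["n_genes"] = int(expr.shape[0])
        summary["n_samples"] = int(expr.shape[1])
        summary["n_zero_sd_dropped"] = z.n_zero_sd

        stage = "diffexpr"
        table = diffexpr.moderated_t(expr, labels)
        selection = diffexpr.select_degs(table, config.adj_p_max, config.abs_lfc_min)
        diffexpr.write_deg_table(selection, outdir / "deg_table.tsv")
        summary["n_degs"] = len(selection.up) + len(selection.down)
        summary["n_up"] = len(selection.up)
        summary["n_down"] = len(selection.down)

        stage = "cluster_eval"
        degs = selection.up + selection.down
        if len(degs) >= 2:
            dist = cluster_eval.pearson_distance(expr.loc[degs])
            result = cluster_eval.average_linkage(dist, k=2)
            confusion = cluster_eval.evaluate_clusters(result.labels, labels)
            dist.loc[result.leaf_order, result.leaf_order].to_csv(
                outdir / "distance_matrix.tsv", sep="\t"
            )
            confusion.matrix.to_csv(outdir / "confusion_matrix.tsv", sep="\t")
            summary["confusion_matrix"] = confusion.matrix.to_dict()
            summary["per_cluster_accuracy"] = confusion.per_cluster_accuracy
        else:
            logger.warning("fewer than 2 DEGs; clustering skipped")
            summary["per_cluster_accuracy"] = None

        stage = "enrichment"
        background = list(expr.index)
        up_results, down_results = [], []
        for name, sets in gene_set_collections.items():
            if selection.up:
                up_results += enrichment.hypergeom_enrich(
                    selection.up, background, sets, config.enrich_p_max, "up"
                )
            if selection.down:
                down_results += enrichment.hypergeom_enrich(
                    selection.down, background, sets, config.enrich_p_max, "down"
                )
        enrichment.write_term_results(up_results + down_results, outdir / "enrichment.tsv")
        all_sets: dict[str, list[str]] = {}
        for sets in gene_set_collections.values():
            all_sets.update(sets)
        terms = enrichment.build_feature_terms(
            up_results, down_results, selection.up, selection.down, all_sets
        )
        summary["n_feature_terms"] = len(terms)
        if not terms:
            raise ValueError("no significant terms; feature space is empty")

        stage = "ppi"
        sub, tags = ppi.deg_subnetwork(graph, selection.up, selection.down)
        ppi.write_node_table(sub, tags, graph, outdir / "subnetwork_nodes.tsv")
        summary["subnetwork_nodes"] = int(sub.number_of_nodes())
        summary["subnetwork_edges"] = int(sub.number_of_edges())

        stage = "pathscore"
        member_genes = {g for t in terms.values() for g in t.up_members + t.down_members}
        weights = ppi.degree_weights(graph, member_genes)
        control_ids = labels.index[labels == "control"]
        psm = pathscore.score_matrix(
            expr, terms, control_ids, weights, config.epsilon, config.min_weight
        )
        psm.scores.to_csv(outdir / "path_scores.tsv", sep="\t", index_label="term")

        stage = "classify"
        feats = classify.pathway_features(psm.scores)
        if feats.values.shape[0] >= 2:
            curve = classify.rfe_select(
                feats, labels, step=config.rfe_step, folds=config.folds,
                seed=seeds[1], C=config.svm_c,
            )
            opt = curve.optimum_features
            with open(outdir / "rfe_curve.tsv", "w") as fh:
                fh.write("n_features\tcv_accuracy\tfeatures\n")
                for s, a, r in zip(curve.sizes, curve.accuracies, curve.retained):
                    fh.write(f"{s}\t{a:.4f}\t{','.join(r)}\n")
        else:
            opt = list(feats.values.index)
        summary["optimum_n_features"] = len(opt)
        summary["optimum_features"] = opt

        path_feats = classify.FeatureTable(
            feats.values.loc[opt], feats.provenance.loc[opt]
        )
        report_path = classify.svm_cv(
            path_feats, labels, folds=config.folds, seed=seeds[2], C=config.svm_c
        )
        clinical = classify.encode_clinical(annotations)
        fused = path_feats.append(clinical)
        report_full = classify.svm_cv(
            fused, labels, folds=config.folds, seed=seeds[3], C=config.svm_c
        )
        summary["n_features_with_clinical"] = int(fused.values.shape[0])
        summary["mean_auc_pathway"] = round(report_path.mean_auc, 6)
        summary["mean_accuracy_pathway"] = round(report_path.mean_accuracy, 6)
        summary["mean_auc_with_clinical"] = round(report_full.mean_auc, 6)
        summary["mean_accuracy_with_clinical"] = round(report_full.mean_accuracy, 6)
        _write_cv_report(report_path, outdir / "cv_report_pathway.json")
        _write_cv_report(report_full, outdir / "cv_report_with_clinical.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete; summary at %s", outdir / "summary.json")
    return summary


def _write_cv_report(report: classify.CVReport, path: Path) -> None:
    payload = {
        "fold_aucs": report.fold_aucs,
        "fold_accuracies": report.fold_accuracies,
        "mean_auc": report.mean_auc,
        "mean_accuracy": report.mean_accuracy,
        "fold_rocs": [
            {"fpr": fpr.tolist(), "tpr": tpr.tolist()} for fpr, tpr in report.fold_rocs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
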