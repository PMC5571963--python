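"""End-to-end orchestration of the fraction-landscape analysis.

``run_pipeline`` chains: feature-class filtering -> replicate pooling ->
RPKM -> per-fraction enrichment -> overlap gene set -> ranked landscape,
quota curves, tail tests with BH correction, Mann-Whitney / KS tests and
class summaries -> optional motif scanning and expression-ratio
clustering. Every run writes a manifest recording inputs, parameters and
seeds, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as fio
from . import landscape as ls
from . import quantify as qt
from .cluster import kmeans_cluster, log2_ratio_matrix, merge_singletons
from .core import CountMatrix
from .motifs import compile_builtin_rules, count_table, scan_genes

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Paths, labels and thresholds for one pipeline run."""

    counts_path: str
    samples_path: str
    catalog_path: str
    out_dir: str
    fractions: list[str] = field(default_factory=list)  # empty = all but reference
    reference: str = "extract"
    fasta_path: str | None = None
    min_rpkm: float = 1.0
    tail_fraction: float = 0.30
    window_width: float = 10.0
    window_step: float = 1.0
    min_spearman: float = 0.9
    rpkm_total_all_features: bool = False
    cluster_conditions: list[str] = field(default_factory=list)
    cluster_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tail_fraction < 1:
            raise ValueError("tail_fraction must be in (0, 1)")
        if self.min_rpkm < 0:
            raise ValueError("min_rpkm must be >= 0")


def read_inputs(config: RunConfig):
    catalog = fio.read_catalog(config.catalog_path)
    counts = fio.read_counts(config.counts_path, config.samples_path)
    counts.check_catalog(catalog)
    sequences = None
    if config.fasta_path:
        sequences = fio.read_fasta(config.fasta_path, catalog)
    return counts, catalog, sequences


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "parameters": asdict(config),
                      "stages": [], "outputs": []}
    stage = "read_inputs"
    try:
        counts, catalog, sequences = read_inputs(config)
        manifest["stages"].append(stage)

        stage = "filter_feature_classes"
        mrna = qt.filter_feature_classes(counts, catalog)
        manifest["stages"].append(stage)

        stage = "pool_and_rpkm"
        pooled = qt.pool_replicates(mrna, config.min_spearman)
        totals = None
        if config.rpkm_total_all_features:
            totals = qt.pool_replicates(counts, validate=False).counts.sum(axis=0)
        rpkm = qt.compute_rpkm(pooled, catalog, totals=totals)
        manifest["stages"].append(stage)

        stage = "enrichment"
        fractions = config.fractions or [
            f for f in pooled.samples["fraction"] if f != config.reference]
        tables = {}
        for f in fractions:
            t = qt.enrichment_ratio(rpkm, f, config.reference, config.min_rpkm)
            tables[f] = t
            fio.write_enrichment(t, out / f"enrichment_{f}.tsv", catalog)
            fio.write_drop_report(t, out / f"dropped_{f}.tsv")
            manifest["outputs"] += [f"enrichment_{f}.tsv", f"dropped_{f}.tsv"]
        manifest["stages"].append(stage)

        stage = "overlap"
        shared = qt.overlap_gene_set(list(tables.values()), catalog)
        manifest["overlap_genes"] = len(shared)
        manifest["stages"].append(stage)

        stage = "landscape_stats"
        classes = catalog["loc_class"]
        tests: list[dict] = []
        tails = []
        for f, t in tables.items():
            ranked = ls.percentile_rank(t.ratios.loc[shared], classes)
            fio._to_tsv(ranked.rename_axis("gene_id"), out / f"landscape_{f}.tsv")
            quota = ls.quota_curve(ranked, classes, config.window_width,
                                   config.window_step)
            fio._to_tsv(quota, out / f"quota_{f}.tsv", index=False)
            manifest["outputs"] += [f"landscape_{f}.tsv", f"quota_{f}.tsv"]
            for side in ("top", "bottom"):
                for cls in ("MPR", "CPR"):
                    if (ranked["loc_class"] == cls).any():
                        tails.append((f, ls.tail_overrepresentation(
                            ranked, cls, config.tail_fraction, side)))
            mpr = ranked.loc[ranked["loc_class"] == "MPR", "ratio"]
            cpr = ranked.loc[ranked["loc_class"] == "CPR", "ratio"]
            if len(mpr) and len(cpr):
                for res in (ls.mann_whitney_test(mpr, cpr), ls.ks_test(mpr, cpr)):
                    tests.append({"fraction": f, **asdict(res)})
            summary = ls.class_summary(ranked)
            fio._to_tsv(summary, out / f"class_summary_{f}.tsv")
            manifest["outputs"].append(f"class_summary_{f}.tsv")
        adjusted = ls.adjust_tail_tests([t for _, t in tails])
        tail_payload = [
            {"fraction": f, **asdict(r)} for (f, _), r in zip(tails, adjusted)]
        fio.write_json({"tail_tests": tail_payload, "rank_tests": tests},
                       out / "tests.json")
        manifest["outputs"].append("tests.json")
        manifest["stages"].append(stage)

        if sequences:
            stage = "motifs"
            rules = compile_builtin_rules()
            groups = {
                "MPR": [g for g in shared if classes.get(g) == "MPR"],
                "CPR": [g for g in shared if classes.get(g) == "CPR"],
            }
            groups = {k: [g for g in v if g in sequences]
                      for k, v in groups.items()}
            census = count_table(sequences, groups, rules)
            fio._to_tsv(census, out / "motif_counts.tsv", index=False)
            sites = [s for rule in rules
                     for s in scan_genes(sequences, rule)]
            fio.write_bed(sites, out / "motif_sites.bed")
            manifest["outputs"] += ["motif_counts.tsv", "motif_sites.bed"]
            manifest["stages"].append(stage)
        else:
            logger.info("no sequences supplied: motif stage skipped")

        if config.cluster_conditions:
            stage = "clustering"
            ratios = log2_ratio_matrix(rpkm, config.cluster_conditions,
                                       config.reference, config.min_rpkm)
            result = merge_singletons(
                kmeans_cluster(ratios, k=config.cluster_k, seed=config.seed),
                ratios)
            fio._to_tsv(result.labels.rename_axis("gene_id").to_frame(),
                        out / "cluster_labels.tsv")
            fio.write_json({"k": result.k, "davies_bouldin": result.davies_bouldin,
                            "merge_log": result.merge_log},
                           out / "cluster_summary.json")
            manifest["outputs"] += ["cluster_labels.tsv", "cluster_summary.json"]
            manifest["stages"].append(stage)
        else:
            logger.info("no cluster conditions supplied: clustering skipped")
    except Exception as exc:
        fio.write_json(manifest, out / "manifest.partial.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    fio.write_json(manifest, out / "manifest.json")
    return manifest
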