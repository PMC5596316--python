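"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — simulate, build-catalog, assign-names,
quantify, poles, cluster-temporal, cluster-spatial — writing each stage's
outputs under one directory plus a manifest JSON recording the package
version, seed and thresholds.  Any stage failure aborts with the stage name
and cause.  Thresholds default to the procedure's standard values and are
validated before anything runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import (
    family_enrichment,
    flat_clusters,
    normalize_by_max,
    spatial_zscore_cluster,
    ward_linkage,
)
from .expression import detection_summary, distribution_compare, WHOLE_EMBRYO
from .families import DbdFamilyList, default_families
from .io import (
    ground_truth_to_json,
    write_alignment_hits,
    write_catalog,
    write_domain_hits,
    write_expression_set,
    write_json,
    write_names,
    write_pole_calls,
    write_transcript_fasta,
)
from .orf import build_catalog
from .orthology import (
    best_hits_table,
    detect_expansions,
    propose_names,
    reciprocal_best,
)
from .regional import call_poles, pairwise_de
from .simulate import SimConfig, gen_counts, gen_homology_hits, gen_transcriptome

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "build-catalog", "assign-names", "quantify",
    "poles", "cluster-temporal", "cluster-spatial",
)


@dataclass
class RunConfig:
    """Pipeline thresholds and run parameters (defaults = standard values)."""

    out_dir: str = "tfcatalog_run"
    seed: int = 42
    domain_e_value: float = 0.01
    homology_e_value: float = 1e-8
    ppde_cutoff: float = 0.95
    fold_min: float = 2.0
    tpm_floor: float = 1.0
    cluster_gap: float = 5.0
    fdr_cutoff: float = 0.1
    sim: SimConfig = field(default_factory=SimConfig)
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("domain_e_value", "homology_e_value", "ppde_cutoff",
                     "fold_min", "tpm_floor", "cluster_gap", "fdr_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ppde_cutoff", "fdr_cutoff"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must be <= 1")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig, families: DbdFamilyList | None = None) -> dict:
    """Run all stages on a fresh synthetic dataset; returns the manifest."""
    cfg.validate()
    families = families or default_families()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "domain_e_value": cfg.domain_e_value,
            "homology_e_value": cfg.homology_e_value,
            "ppde_cutoff": cfg.ppde_cutoff,
            "fold_min": cfg.fold_min,
            "tpm_floor": cfg.tpm_floor,
            "cluster_gap": cfg.cluster_gap,
            "fdr_cutoff": cfg.fdr_cutoff,
        },
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
            manifest["stages"].append(name)
            return result
        return deco

    @stage("simulate")
    def _simulate():
        transcripts, hits, truth = gen_transcriptome(sim)
        fwd, rev = gen_homology_hits(truth, sim)
        regional, temporal = gen_counts(truth, sim)
        write_transcript_fasta(transcripts, out / "transcripts.fasta")
        write_domain_hits(hits, out / "domain_hits.tsv")
        write_alignment_hits(fwd, out / "hits_fwd.tsv")
        write_alignment_hits(rev, out / "hits_rev.tsv")
        write_expression_set(regional, out / "counts_regional.tsv",
                             out / "eff_lengths.tsv", out / "samples_regional.tsv")
        write_expression_set(temporal, out / "counts_temporal.tsv",
                             out / "eff_lengths_temporal.tsv",
                             out / "samples_temporal.tsv")
        ground_truth_to_json(truth, out / "ground_truth.json")
        return transcripts, hits, truth, fwd, rev, regional, temporal

    transcripts, hits, truth, fwd, rev, regional, temporal = _simulate

    @stage("build-catalog")
    def _catalog():
        homology = {}
        for _, r in fwd.iterrows():
            homology.setdefault(r["qseqid"], []).append({
                "qstart": int(r["qstart"]) - 1, "bit_score": float(r["bitscore"]),
                "e_value": float(r["evalue"]), "subject_id": r["sseqid"],
            })
        catalog, dubious, summary = build_catalog(
            transcripts, hits, homology, families, e_value_max=cfg.domain_e_value)
        write_catalog(catalog, dubious, out / "catalog.tsv")
        write_json(summary, out / "catalog_summary.json")
        return catalog, dubious, summary

    catalog, dubious, _summary = _catalog
    tx_to_gene = {t.transcript_id: t.gene_id for t in transcripts}

    @stage("assign-names")
    def _names():
        fwd_best = best_hits_table(_df_to_hits(fwd, "human", cfg.homology_e_value))
        rev_best = best_hits_table(_df_to_hits(rev, "frog", cfg.homology_e_value))
        forward_map = {tx_to_gene.get(q, q): h.subject_id for q, h in fwd_best.items()}
        reverse_map = {s: tx_to_gene.get(h.subject_id, h.subject_id)
                       for s, h in rev_best.items()}
        rbh = reciprocal_best(forward_map, reverse_map)
        expansions = detect_expansions(forward_map)
        gene_best = {tx_to_gene.get(q, q): h for q, h in fwd_best.items()}
        assignments = propose_names(gene_best, rbh, expansions, truth.symbol_map)
        write_names(assignments, out / "names.tsv")
        return assignments

    _assignments = _names
    catalog_genes = [r.gene_id for r in catalog]

    @stage("quantify")
    def _quantify():
        we = regional.samples_for_region(WHOLE_EMBRYO)
        summary = detection_summary(regional.tpm, catalog_genes, samples=we)
        dist = distribution_compare(regional.tpm[we].mean(axis=1), catalog_genes)
        write_json({"detection": summary, "ks_distance": dist["ks_distance"]},
                   out / "detection_summary.json")
        return summary

    _det = _quantify

    @stage("poles")
    def _poles():
        de_table, de_union = pairwise_de(regional, ppde_cutoff=cfg.ppde_cutoff)
        de_table.to_csv(out / "pairwise_de.tsv", sep="\t", index=False)
        calls, summary = call_poles(regional, fold_min=cfg.fold_min,
                                    tpm_floor=cfg.tpm_floor,
                                    ppde_cutoff=cfg.ppde_cutoff)
        write_pole_calls(calls, summary, out / "pole_calls.tsv",
                         out / "pole_summary.json")
        return de_union, calls, summary

    de_union, _calls, _pole_summary = _poles

    @stage("cluster-temporal")
    def _temporal():
        profiles = normalize_by_max(temporal.tpm.loc[
            [g for g in catalog_genes if g in temporal.genes]])
        tree = ward_linkage(profiles)
        clusters = flat_clusters(tree, threshold=cfg.cluster_gap)
        fam_map = {r.gene_id: sorted(r.dbd_families) for r in catalog}
        enrich = family_enrichment(clusters, fam_map, fdr_cutoff=cfg.fdr_cutoff)
        pd.Series(clusters, name="cluster").rename_axis("gene_id").to_csv(
            out / "temporal_clusters.tsv", sep="\t")
        enrich.to_csv(out / "family_enrichment.tsv", sep="\t", index=False)
        return clusters, enrich

    _clusters, _enrich = _temporal

    @stage("cluster-spatial")
    def _spatial():
        genes = sorted(de_union & set(catalog_genes)) or catalog_genes
        result = spatial_zscore_cluster(regional.region_mean_tpm(), genes)
        result["matrix"].rename_axis("gene_id").to_csv(
            out / "spatial_zscore_matrix.tsv", sep="\t")
        return result

    _spatial_result = _spatial

    write_json(manifest, out / "manifest.json")
    return manifest


def _df_to_hits(df: pd.DataFrame, species: str, e_value_max: float):
    from .orthology import AlignmentHit

    hits = []
    for _, r in df.iterrows():
        if float(r["evalue"]) > e_value_max:
            continue
        hits.append(AlignmentHit(
            query_id=str(r["qseqid"]), subject_id=str(r["sseqid"]),
            subject_species=species, bit_score=float(r["bitscore"]),
            e_value=float(r["evalue"]), qstart=int(r["qstart"]) - 1,
            qend=int(r["qend"]),
        ))
    return hits
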