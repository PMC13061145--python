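"""End-to-end pipeline: cohort -> QC -> bootstrap DE -> overlap -> enrichment
-> network -> validation, from a single seeded configuration.

The pipeline runs either on user-supplied files (counts, metadata, gene sets,
edges, reference, Ct table) or in synthetic mode, where every input is
generated with planted ground truth.  All randomness derives from one master
seed, and a manifest (config echo, seed, per-stage row counts) makes a run
reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .bootstrap import bootstrap_de, select_naags, tally_bootstrap
from .cohort import assign_groups, cohort_table
from .de import filter_protein_coding, pca_outliers
from .enrichment import derive_cnaags, go_enrichment, unique_naags
from .network import (canonicalize_edges, confirm_edges, induced_edges,
                      load_string_edges, network_summary)
from .synthetic import (SimulationConfig, simulate_annotation, simulate_counts,
                        simulate_network, simulate_qpcr, simulate_reference)
from .validation import qpcr_validation, reference_profile

logger = logging.getLogger(__name__)

_SEED_MOD = 2 ** 31


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds in one place.

    Exactly one of ``synthetic`` (a SimulationConfig) or ``counts_path`` +
    ``metadata_path`` must be set.  Threshold defaults are the analysis
    defaults: B=100 bootstrap iterations, nominal p < .05, linear FC > 1.5,
    >= 50% direction-consistent iterations, |r| > 0.3 coexpression
    confirmation, FDR < 0.1 enrichment, combined score >= 400, hub quantile
    0.9.
    """

    seed: int = 0
    out_dir: str = "adipoplacenta_out"
    synthetic: SimulationConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    edges_path: str | None = None
    reference_path: str | None = None
    ct_path: str | None = None
    coding_list_path: str | None = None
    qpcr_targets: list[str] = field(default_factory=list)
    qpcr_reference_gene: str = "RPL17"
    B: int = 100
    p_thr: float = 0.05
    fc_thr: float = 1.5
    consistency: float = 0.5
    r_thr: float = 0.3
    fdr_thr: float = 0.1
    score_min: float = 400.0
    hub_q: float = 0.9
    pca_k: float = 5.0
    n_permutations: int = 999


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Range-check thresholds and enforce input-mode exclusivity."""
    synthetic_mode = config.synthetic is not None
    file_mode = config.counts_path is not None or config.metadata_path is not None
    if synthetic_mode and file_mode:
        raise ConfigError("set either synthetic mode or input paths, not both")
    if not synthetic_mode:
        if not (config.counts_path and config.metadata_path):
            raise ConfigError("file mode needs counts_path and metadata_path")
        for name in ("counts_path", "metadata_path", "gmt_path", "edges_path",
                     "reference_path", "ct_path", "coding_list_path"):
            p = getattr(config, name)
            if p is not None and not os.path.exists(p):
                raise ConfigError(f"{name}: no such file {p!r}")
    for name, lo, hi in (("p_thr", 0, 1), ("consistency", 0, 1),
                         ("fdr_thr", 0, 1), ("hub_q", 0, 1), ("r_thr", 0, 1)):
        v = getattr(config, name)
        if not (lo < v <= hi):
            raise ConfigError(f"{name}={v} outside ({lo}, {hi}]")
    if config.fc_thr < 1:
        raise ConfigError("fc_thr is a linear fold change and must be >= 1")
    if config.B < 1:
        raise ConfigError("B must be >= 1")
    if config.seed is None:
        raise ConfigError("seed is mandatory")
    if config.synthetic is not None:
        config.synthetic.validate()
    return config


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    syn = d.pop("synthetic", None)
    cfg = PipelineConfig(**d)
    if syn is not None:
        if isinstance(syn, dict):
            for key in ("n_per_group", "n_mid_per_stratum", "depth_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            syn = SimulationConfig(**syn)
        cfg.synthetic = syn
    return cfg


def _derived_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % _SEED_MOD


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the output bundle.

    Returns a dict of in-memory stage results, including the manifest.  Any
    stage failure raises StageError naming the stage; outputs written before
    the failure are kept.
    """
    validate_config(config)
    out = io.ensure_dir(config.out_dir)
    manifest: dict = {"seed": config.seed, "stages": {},
                      "config": _jsonable_config(config)}
    results: dict = {"manifest": manifest}
    stage = "inputs"
    try:
        inputs = _load_inputs(config)
        results.update(inputs)
        manifest["stages"]["inputs"] = {
            "n_genes": int(len(inputs["counts"])),
            "n_samples": int(inputs["counts"].shape[1]),
            "synthetic": config.synthetic is not None,
        }

        stage = "cohort"
        metadata = assign_groups(inputs["metadata"])
        metadata["maternal_group"] = metadata["bmi_category"]
        io.write_metadata_csv(metadata, os.path.join(out, "group_assignment.csv"))
        cont_vars = [c for c in ("birth_weight_kg", "length_cm",
                                 "flank_skinfold_mm", "pct_body_fat")
                     if c in metadata.columns]
        summary = cohort_table(
            metadata[metadata["adiposity_class"].isin(["LA", "HA"])],
            continuous=cont_vars, categorical=["sex"])
        summary.to_csv(os.path.join(out, "cohort_summary.tsv"), sep="\t",
                       index=False)
        results["metadata"] = metadata
        results["cohort_summary"] = summary
        manifest["stages"]["cohort"] = {
            "n_assigned": int((metadata["study_group"] != "NONE").sum())}

        stage = "qc_filter"
        counts = inputs["counts"]
        if inputs.get("coding_list") is not None:
            counts = filter_protein_coding(counts, inputs["coding_list"])
        study_md = metadata[metadata["adiposity_class"].isin(["LA", "HA"])
                            & metadata["maternal_group"].isin(["LE", "OB"])]
        study_counts = counts[[s for s in study_md["sample_id"]
                               if s in counts.columns]]
        outliers = pca_outliers(study_counts, k=config.pca_k)
        if outliers:
            logger.info("removing %d PCA outlier samples: %s",
                        len(outliers), outliers)
            study_counts = study_counts.drop(columns=outliers)
            study_md = study_md[~study_md["sample_id"].isin(outliers)]
        results["counts_qc"] = study_counts
        results["metadata_qc"] = study_md
        manifest["stages"]["qc_filter"] = {
            "n_genes": int(len(study_counts)),
            "n_samples": int(study_counts.shape[1]),
            "n_outliers_removed": len(outliers),
        }

        naags = {}
        for i, stratum in enumerate(("LE", "OB")):
            stage = f"bootstrap_de_{stratum}"
            boot = bootstrap_de(study_counts, study_md, stratum, B=config.B,
                                seed=_derived_seed(config.seed, i + 1))
            tallies = tally_bootstrap(boot, p_thr=config.p_thr,
                                      fc_thr=config.fc_thr)
            sel = select_naags(tallies, consistency=config.consistency,
                               stratum=stratum)
            sel.to_csv(os.path.join(out, f"naags_{stratum}.tsv"), sep="\t")
            naags[stratum] = sel
            manifest["stages"][stage] = {"B": config.B,
                                         "n_naags": int(len(sel))}
        results["naags"] = naags

        stage = "overlap"
        cnaags = derive_cnaags(naags["LE"], naags["OB"])
        le_only, ob_only = unique_naags(naags["LE"], naags["OB"])
        cnaags.to_csv(os.path.join(out, "cnaags.tsv"), sep="\t")
        results["cnaags"] = cnaags
        results["le_only"], results["ob_only"] = le_only, ob_only
        manifest["stages"]["overlap"] = {
            "n_cnaags": int(len(cnaags)),
            "n_concordant": int((cnaags["concordance"] == "concordant").sum()),
            "n_le_only": len(le_only), "n_ob_only": len(ob_only),
        }

        stage = "enrichment"
        if inputs.get("gene_sets"):
            universe = list(study_counts.index)
            enrich = {}
            for name, genes in (("cnaag", set(cnaags.index)),
                                ("le_only", le_only), ("ob_only", ob_only)):
                genes = set(genes) & set(universe)
                if genes:
                    res = go_enrichment(genes, universe, inputs["gene_sets"],
                                        fdr_thr=config.fdr_thr)
                    res.to_csv(os.path.join(out, f"enrichment_{name}.tsv"),
                               sep="\t", index=False)
                    enrich[name] = res
            results["enrichment"] = enrich
            manifest["stages"]["enrichment"] = {
                k: int(v["significant"].sum()) for k, v in enrich.items()}

        stage = "network"
        if inputs.get("edges") is not None:
            edges = inputs["edges"]
            edges = canonicalize_edges(
                edges[edges["combined_score"] >= config.score_min])
            universe = list(study_counts.index)
            nets = {}
            for name, genes, group in (
                    ("LE", set(naags["LE"].index), "LE"),
                    ("OB", set(naags["OB"].index), "OB"),
                    ("cnaag", set(cnaags.index), "pooled")):
                genes = set(genes) & set(universe)
                if len(genes) < 2:
                    continue
                ind = induced_edges(edges, genes)
                groups = [group] if group != "pooled" else ["LE", "OB",
                                                            "pooled"]
                annotated = None
                for grp in groups:
                    ann = confirm_edges(ind, study_counts, study_md,
                                        group=grp, r_thr=config.r_thr) \
                        if len(ind) else ind.assign(
                            pearson_r=[], pearson_p=[], confirmed=[])
                    ann.to_csv(os.path.join(
                        out, f"network_{name}_{grp}.tsv"), sep="\t",
                        index=False)
                    if annotated is None:
                        annotated = ann
                summ = network_summary(
                    annotated if len(ind) else ind.assign(confirmed=[]),
                    genes, universe, edges, hub_q=config.hub_q,
                    M=config.n_permutations,
                    seed=_derived_seed(config.seed, 17))
                nets[name] = summ
                manifest["stages"][f"network_{name}"] = {
                    "n_edges": summ["n_edges"],
                    "n_confirmed": summ["n_confirmed"],
                    "enrichment_p": summ["enrichment_p"],
                    "n_hubs": len(summ["hubs"]),
                }
            results["networks"] = nets

        stage = "reference_profile"
        if inputs.get("reference") is not None and len(cnaags):
            genes = [g for g in cnaags.index
                     if g in inputs["reference"].columns]
            if genes:
                prof = reference_profile(list(cnaags.index),
                                         inputs["reference"])
                prof["zscores"].to_csv(
                    os.path.join(out, "reference_zscores.tsv"), sep="\t")
                results["reference_profile"] = prof
                manifest["stages"]["reference_profile"] = {
                    "n_profiled": int(prof["profile"].shape[1]),
                    "n_not_expressed": len(prof["not_expressed"]),
                }

        stage = "qpcr_validation"
        if inputs.get("ct") is not None:
            targets = config.qpcr_targets or [
                g for g in inputs["ct"]["gene"].unique()
                if g != config.qpcr_reference_gene]
            stats_out = {}
            for g in targets:
                v = qpcr_validation(inputs["ct"], study_counts, study_md, g,
                                    config.qpcr_reference_gene)
                stats_out[g] = {k: val for k, val in v.items()
                                if not isinstance(val, pd.DataFrame)}
            with open(os.path.join(out, "qpcr_validation.json"), "w") as fh:
                json.dump(stats_out, fh, indent=2)
            results["qpcr"] = stats_out
            manifest["stages"]["qpcr_validation"] = {
                "n_targets": len(stats_out)}
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise StageError(stage, exc) from exc

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results


def _jsonable_config(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _load_inputs(config: PipelineConfig) -> dict:
    if config.synthetic is not None:
        sim = config.synthetic
        counts, metadata, truth = simulate_counts(sim)
        gene_sets = simulate_annotation(sim, truth)
        edges = simulate_network(sim, truth)
        reference = simulate_reference(sim, truth)
        qpcr_targets = (config.qpcr_targets
                        or truth.genes_of("shared_concordant")[:2]
                        or list(counts.index[:2]))
        ct = simulate_qpcr(sim, counts, target_genes=qpcr_targets,
                           reference_gene=config.qpcr_reference_gene)
        return {"counts": counts, "metadata": metadata, "truth": truth,
                "gene_sets": gene_sets, "edges": edges,
                "reference": reference, "ct": ct, "coding_list": None}
    counts = (io.read_counts_mtx(config.counts_path)
              if config.counts_path.endswith(".mtx")
              else io.read_counts_tsv(config.counts_path))
    metadata = io.read_metadata_csv(config.metadata_path)
    coding = None
    if config.coding_list_path:
        with open(config.coding_list_path) as fh:
            coding = {line.strip() for line in fh if line.strip()}
    gene_sets = io.read_gmt(config.gmt_path) if config.gmt_path else None
    edges = (load_string_edges(config.edges_path, score_min=0)
             if config.edges_path else None)
    reference = (io.read_reference_tsv(config.reference_path)
                 if config.reference_path else None)
    ct = io.read_ct_csv(config.ct_path) if config.ct_path else None
    return {"counts": counts, "metadata": metadata, "gene_sets": gene_sets,
            "edges": edges, "reference": reference, "ct": ct,
            "coding_list": coding}
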