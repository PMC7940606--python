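"""End-to-end pipeline orchestration over synthetic or user-supplied inputs.

Stages run in dependency order: simulate -> bulk scoring -> single-cell
annotation -> TCR -> abundance -> TMB -> report. The report echoes every
threshold in force so a run is auditable from its outputs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .abundance import compare_compartments, relative_abundance
from .bulk import (
    compare_strata,
    log2_transform,
    normalize_counts,
    qc_housekeeping,
    signature_enrichment,
    stratify_patients,
)
from .sc import (
    CSF_RULES,
    TUMOR_RULES,
    AnnotationEvidence,
    QCRules,
    annotate_clusters,
    choose_csf_min_genes,
    cluster_cells,
    compute_qc_metrics,
    doublet_coexpression_fraction,
    gsea_preranked,
    marker_fractions,
    normalize_log1p,
    qc_filter,
    rank_markers,
    recluster_t_cells,
    select_variable_genes,
)
from .simulate import (
    SimulationConfig,
    default_signatures,
    simulate_bulk_cohort,
    simulate_sc_cohort,
    simulate_tcr_repertoire,
    simulate_variant_calls,
)
from .tcr import (
    call_clonotypes,
    classify_expansion,
    clonotype_identity_set,
    compartment_overlap,
    expansion_enrichment,
    parse_contigs,
)
from .tmb import LIBRARY_MB, compute_tmb, consensus_variants

logger = logging.getLogger("brmtme")

#: every analysis threshold the pipeline applies, echoed in the report
THRESHOLDS = {
    "housekeeping_min_geomean": 50,
    "bulk_strata_k": 3,
    "tumor_min_genes": 100,
    "csf_min_genes_grid": [70, 100],
    "max_genes": 2500,
    "tumor_max_pct_mito": 10,
    "csf_max_pct_mito": 20,
    "cluster_resolution": 0.4,
    "pc_sd_min": 2.0,
    "gsea_fdr_max": 0.25,
    "p_significant": 0.05,
    "cycle_fold_change_min": 0.1,
    "expansion_min_cells": 2,
    "tmb_library_mb": LIBRARY_MB,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the missing dependency."""


@dataclass
class PipelineResult:
    strata: pd.Series | None = None
    scores: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None
    clusters: pd.Series | None = None
    expansion_counts: dict = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None
    overlap_regions: dict | None = None
    volcano: pd.DataFrame | None = None
    tmb: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path,
    profile: str = "test",
    n_true_variants: int = 94,
) -> PipelineResult:
    """Run the full synthetic-cohort pipeline and write a report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    res = PipelineResult()
    if profile == "test":
        config = config.with_(
            n_cells_per_sample={"tumor": 900, "csf": 300}, n_genes_sc=3000
        )

    # ---- bulk scoring
    mat, truth = simulate_bulk_cohort(config)
    kept, qc_report = qc_housekeeping(mat)
    scored = signature_enrichment(
        log2_transform(normalize_counts(kept)), default_signatures()
    )
    strata = stratify_patients(scored)
    res.scores, res.strata = scored.score, strata.label
    io.write_csv(scored.score, out / "bulk_scores.csv", seed=seed)
    io.write_csv(strata.label.to_frame(), out / "bulk_strata.csv", seed=seed)
    ttest = compare_strata(scored.score["IFNg signature"], strata)
    io.write_csv(ttest, out / "bulk_strata_ttests.csv", seed=seed, index=False)

    # ---- single-cell
    adata, sc_truth = simulate_sc_cohort(config)
    compute_qc_metrics(adata)
    tumor_mask = (adata.obs["compartment"] == "tumor").to_numpy()
    tum, tum_counts = qc_filter(adata[tumor_mask].copy(), TUMOR_RULES)
    csf_all = adata[~tumor_mask].copy()
    csf_min = choose_csf_min_genes(csf_all)
    csf_rules = QCRules(
        min_genes=csf_min, max_genes=CSF_RULES.max_genes,
        max_pct_mito=CSF_RULES.max_pct_mito,
    )
    csf, csf_counts = qc_filter(csf_all, csf_rules)
    import anndata as ad

    filt = ad.concat([tum, csf], join="outer", merge="same")
    normalize_log1p(filt)
    vg = select_variable_genes(filt, 2000)
    clusters = cluster_cells(filt, vg, seed=seed)
    clusters = recluster_t_cells(filt, clusters, seed=seed)
    res.clusters = clusters

    curated = io.read_markers_yaml()
    de = rank_markers(filt, clusters)
    mf = marker_fractions(filt, clusters, curated)
    n_perm = 100 if profile == "test" else 1000
    gs_rows = []
    for c in sorted(clusters.unique()):
        ranking = de[de["cluster"] == c].set_index("gene")["log_fc"]
        g = gsea_preranked(ranking, curated, n_perm=n_perm, seed=seed)
        g.insert(0, "cluster", c)
        gs_rows.append(g)
    gsea = pd.concat(gs_rows, ignore_index=True)
    evidence = AnnotationEvidence(marker_fractions=mf, de_table=de, gsea_table=gsea)
    dfrac = doublet_coexpression_fraction(filt, clusters)
    annotation = annotate_clusters(evidence, curated, doublet_fractions=dfrac)
    res.annotation = annotation
    io.write_csv(annotation, out / "sc_annotation.csv", seed=seed, index=False)
    io.write_csv(clusters.to_frame(), out / "sc_clusters.csv", seed=seed)
    (out / "sc_qc.json").write_text(
        json.dumps({"tumor": tum_counts, "csf": csf_counts, "csf_min_genes": csf_min}, indent=2)
    )

    # ---- TCR
    contigs = simulate_tcr_repertoire(sc_truth, config)
    chains = parse_contigs(contigs)
    clono = call_clonotypes(chains)
    counts, cell_classes = classify_expansion(clono)
    res.expansion_counts = counts
    label_of = annotation.set_index("cluster")["label"]
    cell_clusters = clusters.map(label_of)
    try:
        res.enrichment = expansion_enrichment(cell_classes, cell_clusters)
    except ValueError as e:
        raise PipelineError(f"tcr stage: {e}") from e
    sets = {}
    for (comp, tp), sub in chains.groupby(
        [chains["sample"].str.startswith("CSF").map({True: "csf", False: "tumor"}),
         "timepoint"]
    ):
        key = "tumor" if comp == "tumor" else f"csf_{tp}"
        sets[key] = clonotype_identity_set(call_clonotypes(sub))
    overlap = compartment_overlap(sets)
    res.overlap_regions = {
        "|".join(sorted(k)): v for k, v in overlap.region_counts.items()
    }
    io.write_csv(res.enrichment, out / "tcr_enrichment.csv", seed=seed, index=False)
    (out / "tcr_overlap.json").write_text(json.dumps(res.overlap_regions, indent=2))

    # ---- abundance
    ann_cells = pd.DataFrame(
        {"sample": filt.obs["sample"], "cell_type": cell_clusters}
    )
    ab = relative_abundance(ann_cells)
    comp_of = filt.obs.groupby("sample", observed=True)["compartment"].first()
    try:
        res.volcano = compare_compartments(ab, comp_of)
    except ValueError:
        res.volcano = None  # single-sample compartments in the test profile
    io.write_csv(ab.proportion, out / "abundance.csv", seed=seed)

    # ---- TMB
    a, b, vt = simulate_variant_calls(config, n_true=n_true_variants)
    cons = consensus_variants(a, b)
    tmb = compute_tmb(cons)
    res.tmb = {"n_consensus": tmb.n_consensus, "n_nonsyn": tmb.n_nonsyn, "tmb": tmb.tmb}
    (out / "tmb.json").write_text(json.dumps(res.tmb, indent=2))

    # ---- report
    res.report = {
        "version": __version__,
        "seed": seed,
        "profile": profile,
        "thresholds": THRESHOLDS,
        "bulk_qc": {k: v for k, v in qc_report.items() if k != "housekeeping_geomean"},
        "n_cells_kept": int(filt.n_obs),
        "n_clusters": int(clusters.nunique()),
        "expansion_counts": counts,
        "tmb": res.tmb,
    }
    (out / "report.json").write_text(json.dumps(res.report, indent=2))
    return res
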