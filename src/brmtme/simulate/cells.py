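"""Synthetic multi-cell-type single-cell count matrices with planted QC failures.

Each cell type overexpresses its marker program by a fixed log2-fold factor on
top of a shared baseline; counts are negative binomial with a shared
dispersion. Planted artifacts: low-complexity cells (< 100 genes), degraded
high-mitochondrial cells, T x myeloid doublets detecting > 2500 genes, and —
in CSF only — hemoglobin-positive erythrocyte-like barcodes concentrated at
very low gene counts.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .._utils import substream
from .bulk import _nb
from .config import GroundTruth, SimulationConfig

MITO_GENES = [f"MT-{g}" for g in
              ("ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3", "ND4", "CYB")]
HB_GENES = ["HBB", "HBA1", "HBA2"]
CYCLE_GENES = [
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG", "GINS2", "MCM6",
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "MKI67", "CENPF", "AURKB",
]

#: marker program per cell type (log2 fold overexpression applied to each)
MARKER_PROGRAMS: dict[str, list[str]] = {
    "cytotoxic T": ["CD3D", "CD3E", "CD8A", "GZMB", "GZMA", "PRF1", "NKG7", "CCL5"],
    "naive T": ["CD3D", "CD3E", "CD4", "CCR7", "LEF1", "SELL", "TCF7", "IL7R"],
    "Treg": ["CD3D", "CD3E", "CD4", "FOXP3", "IL2RA", "CTLA4", "IKZF2", "TNFRSF4"],
    "NK": ["NKG7", "GNLY", "KLRD1", "NCAM1", "KLRF1", "FCGR3A", "PRF1", "GZMB"],
    "TAM/microglia": ["CD68", "LYZ", "AIF1", "CD14", "C1QA", "C1QB", "P2RY12", "TMEM119"],
    "B cells": ["MS4A1", "CD79A", "CD79B", "CD19", "IGHM", "BANK1", "CD74", "HLA-DRA"],
    "DC": ["FCER1A", "CD1C", "CLEC9A", "LILRA4", "CD74", "HLA-DRA", "ITGAX", "BATF3"],
    "neutrophils": ["FCGR3B", "CSF3R", "S100A8", "S100A9", "CXCR2", "FPR1", "ELANE", "MPO"],
}
#: lineage markers are close to on/off: low baseline weight in non-expressing
#: types, overexpressed by 2**MARKER_LOG2FC in the type's own program
MARKER_OFF_WEIGHT = 0.2
MARKER_LOG2FC = 6.0

#: planted artifact fractions (of the configured cell count)
FRAC_LOW_GENES = 0.04
FRAC_HIGH_MITO = 0.04
FRAC_DOUBLET = 0.03
FRAC_ERYTHROCYTE = 0.10  # CSF only


def sc_gene_panel(config: SimulationConfig) -> list[str]:
    """Fixed gene panel: markers, mitochondrial and hemoglobin genes, filler."""
    markers = sorted({g for prog in MARKER_PROGRAMS.values() for g in prog})
    named = markers + CYCLE_GENES + MITO_GENES + HB_GENES
    n_filler = config.n_genes_sc - len(named)
    if n_filler < 0:
        raise ValueError("n_genes_sc smaller than the named marker panel")
    return named + [f"FILLER_{i:04d}" for i in range(n_filler)]


def simulate_sc_dataset(
    config: SimulationConfig,
    compartment: str,
    timepoint: str = "t0",
    sample: str | None = None,
) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate one sample's cells x genes counts plus planted cell types."""
    if compartment not in config.celltype_proportions:
        raise ValueError(f"unknown compartment {compartment!r}")
    sample = sample or (f"CSF_{timepoint}" if compartment == "csf" else "TUM")
    rng = substream(config.seed, f"sc:{compartment}:{timepoint}:{sample}")

    genes = sc_gene_panel(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    props = config.celltype_proportions[compartment]
    n_cells = int(config.n_cells_per_sample[compartment])

    # baseline relative expression, shared across types within a sample
    base = rng.gamma(shape=2.0, scale=1.0, size=n_genes)
    base[[gene_idx[g] for g in MITO_GENES]] = 0.0
    base[[gene_idx[g] for g in HB_GENES]] = 0.0
    all_markers = {g for prog in MARKER_PROGRAMS.values() for g in prog}
    base[[gene_idx[g] for g in all_markers]] = MARKER_OFF_WEIGHT

    type_means = {}
    for ct, prog in MARKER_PROGRAMS.items():
        m = base.copy()
        for g in prog:
            m[gene_idx[g]] = MARKER_OFF_WEIGHT * 2.0**MARKER_LOG2FC
        type_means[ct] = m

    cell_types = list(props)
    counts_per_type = rng.multinomial(n_cells, [props[t] for t in cell_types])

    rows, meta = [], []
    idx = 0
    for ct, n_ct in zip(cell_types, counts_per_type):
        for _ in range(n_ct):
            qc_class = "ok"
            mito_frac = rng.uniform(*config.mito_fraction_range)
            lib = rng.lognormal(mean=0.0, sigma=0.2)
            mean = type_means[ct].copy()
            u = rng.uniform()
            if u < FRAC_LOW_GENES:
                qc_class = "low_genes"
                lib *= 0.02
            elif u < FRAC_LOW_GENES + FRAC_HIGH_MITO:
                qc_class = "high_mito"
                mito_frac = rng.uniform(0.25, 0.45)
            elif u < FRAC_LOW_GENES + FRAC_HIGH_MITO + FRAC_DOUBLET:
                qc_class = "doublet"
                partner = "TAM/microglia" if ct != "TAM/microglia" else "cytotoxic T"
                mean = mean + type_means[partner]
                # two transcriptomes in one droplet: library deep enough that
                # detected genes clear the doublet threshold on this panel
                lib = 2.25 * n_genes / 1000.0
            elif compartment == "csf" and u < (
                FRAC_LOW_GENES + FRAC_HIGH_MITO + FRAC_DOUBLET + FRAC_ERYTHROCYTE
            ):
                qc_class = "erythrocyte"
                mean = base * 0.0
                lib = 1.0
            mean = mean / mean.sum() if mean.sum() > 0 else mean
            mean = mean * 2000.0 * lib * (1.0 - mito_frac)
            mean[[gene_idx[g] for g in MITO_GENES]] = (
                2000.0 * lib * mito_frac / len(MITO_GENES)
            )
            if qc_class == "erythrocyte":
                # near-pure hemoglobin content, ~30-90 genes detected
                mean[:] = 0.0
                n_bg = int(rng.integers(30, 90))
                bg = rng.choice(n_genes, size=n_bg, replace=False)
                mean[bg] = 1.2
                for g in HB_GENES:
                    mean[gene_idx[g]] = 40.0
            counts = _nb(rng, mean, config.nb_dispersion)
            if qc_class == "erythrocyte":
                # hemoglobin positivity is the planted identity; force >= 1
                for g in HB_GENES:
                    counts[gene_idx[g]] = max(counts[gene_idx[g]], 1)
            rows.append(sp.csr_matrix(counts))
            bc = f"{sample}:BC{idx:06d}"
            true_ct = qc_class if qc_class in ("doublet", "erythrocyte") else ct
            meta.append(
                {
                    "barcode": bc,
                    "sample": sample,
                    "compartment": compartment,
                    "timepoint": timepoint,
                    "cell_type": true_ct,
                    "qc_class": qc_class,
                }
            )
            idx += 1

    X = sp.vstack(rows).tocsr()
    obs = pd.DataFrame(meta).set_index("barcode")
    adata = ad.AnnData(
        X=X, obs=obs[["sample", "compartment", "timepoint"]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = GroundTruth(
        cell_type=obs["cell_type"].to_dict(),
        cell_meta=obs,
    )
    return adata, truth
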