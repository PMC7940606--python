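"""Single-cell quality control: per-cell metrics, filtering rules, CSF threshold choice.

Removal conditions are strict inequalities (fewer than ``min_genes`` genes,
more than ``max_genes`` genes, more than ``max_pct_mito`` percent
mitochondrial), so boundary cells are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np

logger = logging.getLogger("brmtme")

MITO_PREFIX = "MT-"


@dataclass(frozen=True)
class QCRules:
    min_genes: int = 100
    max_genes: int = 2500
    max_pct_mito: float = 10.0

    def __post_init__(self):
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")


#: rules used for tumor and CSF compartments; the CSF min_genes default is
#: refined per cohort by choose_csf_min_genes
TUMOR_RULES = QCRules(min_genes=100, max_genes=2500, max_pct_mito=10.0)
CSF_RULES = QCRules(min_genes=100, max_genes=2500, max_pct_mito=20.0)


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = MITO_PREFIX) -> ad.AnnData:
    """Attach genes_detected and pct_mito to ``adata.obs`` (in place)."""
    X = adata.X
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    adata.obs["genes_detected"] = genes_detected.astype(int)
    adata.obs["pct_mito"] = pct
    return adata


def qc_filter(adata: ad.AnnData, rules: QCRules) -> tuple[ad.AnnData, dict]:
    """Keep cells passing all three rules; report per-filter removal counts.

    Per-filter counts refer to cells failing that rule (a cell can fail
    several); ``removed`` is the size of their union.
    """
    if "genes_detected" not in adata.obs or "pct_mito" not in adata.obs:
        compute_qc_metrics(adata)
    gd = adata.obs["genes_detected"].to_numpy()
    pm = adata.obs["pct_mito"].to_numpy()
    low = gd < rules.min_genes
    high = gd > rules.max_genes
    mito = pm > rules.max_pct_mito
    keep = ~(low | high | mito)
    counts = {
        "input": int(adata.n_obs),
        "low_genes": int(low.sum()),
        "high_mito": int(mito.sum()),
        "high_genes": int(high.sum()),
        "removed": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    if counts["kept"] == 0:
        raise ValueError(f"QC removed every cell: {counts}")
    logger.info("QC filter: %s", counts)
    return adata[keep].copy(), counts


def choose_csf_min_genes(
    adata: ad.AnnData,
    hb_genes: list[str] | None = None,
    grid: range = range(70, 101),
) -> int:
    """Pick the CSF gene-count threshold that best separates erythrocytes.

    A barcode is erythrocyte-like iff its summed hemoglobin counts are
    positive. For each candidate threshold t the objective is (fraction of
    erythrocyte-like cells with genes_detected < t, i.e. removed) minus
    (fraction of other cells removed); the smallest maximizing t is returned.
    """
    hb_genes = hb_genes or ["HBB", "HBA1", "HBA2"]
    present = [g for g in hb_genes if g in adata.var_names]
    if not present:
        raise ValueError(f"no hemoglobin genes {hb_genes} in panel")
    if "genes_detected" not in adata.obs:
        compute_qc_metrics(adata)
    hb = np.asarray(adata[:, present].X.sum(axis=1)).ravel()
    ery = hb > 0
    gd = adata.obs["genes_detected"].to_numpy()
    best_t, best_obj = None, -np.inf
    for t in grid:
        removed = gd < t
        frac_ery = removed[ery].mean() if ery.any() else 0.0
        frac_other = removed[~ery].mean() if (~ery).any() else 0.0
        obj = frac_ery - frac_other
        if obj > best_obj + 1e-12:
            best_t, best_obj = t, obj
    return int(best_t)
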