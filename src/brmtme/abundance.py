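"""Cell-type relative abundance and tumor-vs-CSF compartment comparison."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss

logger = logging.getLogger("brmtme")

#: default coarse aggregation: fine subclusters into display-level cell types
DEFAULT_AGGREGATION = {
    "B cells 1": "B cells",
    "B cells 2": "B cells",
    "T cell": "CLym",
    "NK": "CLym",
    "cytotoxic T": "CLym",
    "naive T": "T cell",
}

PSEUDO_PROPORTION = 1e-6


def aggregate_cell_types(labels: pd.Series, mapping: dict[str, str]) -> pd.Series:
    """Replace fine labels by coarse ones; unmapped labels pass through."""
    return labels.map(lambda x: mapping.get(x, x)).rename(labels.name)


@dataclass
class AbundanceTable:
    counts: pd.DataFrame  # sample x cell type integer counts
    proportion: pd.DataFrame  # sample x cell type, rows sum to 1
    pan: pd.Series  # pooled proportions over all samples


def relative_abundance(labels_by_sample: pd.DataFrame) -> AbundanceTable:
    """Per-sample cell-type proportions plus the pooled (PAN) column.

    ``labels_by_sample`` has columns ``sample`` and ``cell_type`` (one row per
    cell). The PAN column is recomputed from pooled counts, not averaged over
    samples. Rows are ordered by descending cross-sample variance.
    """
    if labels_by_sample.empty:
        raise ValueError("no cells provided")
    annotated = labels_by_sample.dropna(subset=["cell_type"])
    lost = set(labels_by_sample["sample"]) - set(annotated["sample"])
    if lost:
        raise ValueError(f"samples without annotated cells: {sorted(lost)}")
    counts = (
        annotated.groupby(["sample", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    prop = counts.div(counts.sum(axis=1), axis=0)
    pan = counts.sum(axis=0) / counts.to_numpy().sum()
    order = prop.var(axis=0).sort_values(ascending=False).index
    return AbundanceTable(
        counts=counts[order], proportion=prop[order], pan=pan[order].rename("PAN")
    )


def compare_compartments(
    ab: AbundanceTable,
    compartment: pd.Series,
    alpha: float = 0.05,
    pseudo: float = PSEUDO_PROPORTION,
) -> pd.DataFrame:
    """Volcano table of tumor vs CSF relative abundance per cell type.

    log2 fold change of arithmetic mean proportions (tumor over CSF, with a
    pseudo-proportion for zeros) and a two-sided Mann-Whitney p; classes at
    p < 0.05 are tumor-enriched or csf-enriched by the sign of the fold
    change.
    """
    prop = ab.proportion
    comp = compartment.loc[prop.index]
    tumor = prop[comp == "tumor"]
    csf = prop[comp == "csf"]
    if len(tumor) < 2 or len(csf) < 2:
        raise ValueError("need at least 2 samples per compartment")
    rows = []
    for ct in prop.columns:
        mt, mc = tumor[ct].mean(), csf[ct].mean()
        flagged = bool(mt == 0 or mc == 0)
        if flagged:
            warnings.warn(f"cell type {ct!r} absent from a compartment; pseudo-proportion used")
        lfc = float(np.log2((mt + pseudo) / (mc + pseudo)))
        if tumor[ct].nunique() == 1 and csf[ct].nunique() == 1 and mt == mc:
            p = 1.0
        else:
            _, p = ss.mannwhitneyu(tumor[ct], csf[ct], alternative="two-sided")
        if p < alpha:
            cls = "tumor-enriched" if lfc > 0 else "csf-enriched"
        else:
            cls = "ns"
        rows.append(
            {"cell_type": ct, "mean_tumor": float(mt), "mean_csf": float(mc),
             "log2_fc": lfc, "p": float(p), "class": cls, "pseudo_used": flagged}
        )
    return pd.DataFrame(rows)


def cd8_cd4_ratio(
    counts: pd.DataFrame,
    cd8_type: str = "CD8 T",
    cd4_type: str = "CD4 T",
    pairs: pd.DataFrame | None = None,
) -> tuple[pd.Series, dict]:
    """Per-sample CD8/CD4 count ratio plus a paired tumor-vs-CSF Wilcoxon test.

    ``counts`` is sample x cell type; samples with zero CD4 cells have an
    undefined ratio and are excluded (logged). ``pairs`` has columns
    ``patient``, ``tumor_sample``, ``csf_sample``; pairs with an undefined
    ratio on either side are dropped from the test.
    """
    cd8 = counts[cd8_type] if cd8_type in counts else pd.Series(0, index=counts.index)
    cd4 = counts[cd4_type] if cd4_type in counts else pd.Series(0, index=counts.index)
    valid = cd4 > 0
    if (~valid).any():
        logger.info("CD8/CD4 ratio undefined (CD4 = 0) for %s", counts.index[~valid].tolist())
    ratio = (cd8[valid] / cd4[valid]).rename("cd8_cd4_ratio")
    test: dict = {}
    if pairs is not None:
        t = pairs[
            pairs["tumor_sample"].isin(ratio.index) & pairs["csf_sample"].isin(ratio.index)
        ]
        x = ratio[t["tumor_sample"]].to_numpy()
        y = ratio[t["csf_sample"]].to_numpy()
        if len(x) >= 2 and np.any(x != y):
            stat, p = ss.wilcoxon(x, y, alternative="two-sided")
            test = {"n_pairs": len(x), "statistic": float(stat), "p": float(p)}
        elif len(x) >= 2:
            test = {"n_pairs": len(x), "statistic": 0.0, "p": 1.0}
    return ratio, test
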