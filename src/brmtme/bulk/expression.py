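"""Targeted-expression matrix container, housekeeping QC and control normalization.

The processing chain mirrors standard targeted immune-panel practice:
housekeeping-based sample QC, background thresholding by negative controls,
positive-control then housekeeping geometric-mean scaling, and a log2
transform before cohort-level z-scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .._utils import geomean

logger = logging.getLogger("brmtme")

GENE_CLASSES = ("endogenous", "housekeeping", "positive_control", "negative_control")
_STATES = ("raw", "thresholded", "normalized", "log2", "zscored")


@dataclass
class BulkExpressionMatrix:
    """Samples x genes counts with per-gene class labels and processing state.

    ``state`` only moves forward through raw -> thresholded -> normalized ->
    log2 -> zscored; attempting to skip backward raises.
    """

    values: pd.DataFrame  # samples x genes, non-negative
    gene_class: pd.Series  # gene -> class
    state: str = "raw"

    def __post_init__(self):
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = set(self.values.columns) - set(self.gene_class.index)
        if missing:
            raise ValueError(f"genes without class label: {sorted(missing)[:5]}...")
        bad = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {bad}")

    def genes_of(self, cls: str) -> list[str]:
        keep = self.gene_class[self.gene_class == cls].index
        return [g for g in self.values.columns if g in set(keep)]

    def _advance(self, new_state: str, values: pd.DataFrame) -> "BulkExpressionMatrix":
        if _STATES.index(new_state) <= _STATES.index(self.state):
            raise ValueError(f"cannot move from state {self.state!r} to {new_state!r}")
        return replace(self, values=values, state=new_state)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


def qc_housekeeping(
    raw: BulkExpressionMatrix, min_geomean: float = 50.0
) -> tuple[BulkExpressionMatrix, dict]:
    """Drop low-quality samples and resolve technical duplicates.

    A sample is kept iff the geometric mean of its housekeeping counts is
    >= ``min_geomean`` (strictly lower is discarded). Duplicates share a base
    id and carry a ``_2`` suffix; the member with the higher housekeeping
    geometric mean is kept and renamed to the base id.
    """
    hk = raw.genes_of("housekeeping")
    if not hk:
        raise ValueError("no housekeeping genes in matrix")
    gm = raw.values[hk].apply(geomean, axis=1)
    kept = gm[gm >= min_geomean].index.tolist()
    dropped = sorted(set(raw.samples) - set(kept))

    resolution: dict[str, str] = {}
    final: list[str] = []
    rename: dict[str, str] = {}
    kept_set = set(kept)
    for s in kept:
        if s.endswith("_2"):
            continue  # handled from the base member
        dup = f"{s}_2"
        if dup in kept_set:
            winner = s if gm[s] >= gm[dup] else dup
            resolution[s] = winner
            rename[winner] = s
            final.append(winner)
        else:
            final.append(s)
    # duplicates whose base member failed QC
    for s in kept:
        if s.endswith("_2") and s[:-2] not in kept_set:
            base = s[:-2]
            resolution[base] = s
            rename[s] = base
            final.append(s)

    values = raw.values.loc[final].rename(index=rename)
    report = {
        "kept": list(values.index),
        "dropped_low_quality": dropped,
        "duplicate_resolution": resolution,
        "housekeeping_geomean": gm.to_dict(),
    }
    if dropped:
        logger.info("housekeeping QC removed %d sample(s): %s", len(dropped), dropped)
    return replace(raw, values=values), report


class NanostringNormalizer:
    """Background thresholding and two-stage control normalization.

    Per sample, every count below the maximum negative-control count is raised
    to that maximum; samples are then rescaled so their positive-control
    geometric means (and next their housekeeping geometric means) match the
    cohort arithmetic mean of those geometric means. sklearn-style: ``fit``
    learns the cohort reference means, ``transform`` applies them.

    Attributes
    ----------
    pos_reference_ : float
        Cohort mean of per-sample positive-control geometric means.
    hk_reference_ : float
        Cohort mean of per-sample housekeeping geometric means computed after
        positive-control scaling.
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "NanostringNormalizer":
        return self

    def fit(self, mat: BulkExpressionMatrix) -> "NanostringNormalizer":
        thresholded = _threshold(mat)
        pos_gm = _class_geomeans(thresholded, "positive_control")
        self.pos_reference_ = float(pos_gm.mean())
        scaled = thresholded.values.mul(self.pos_reference_ / pos_gm, axis=0)
        hk_gm = _geomeans_of(scaled, mat.genes_of("housekeeping"))
        self.hk_reference_ = float(hk_gm.mean())
        return self

    def transform(self, mat: BulkExpressionMatrix) -> BulkExpressionMatrix:
        if not hasattr(self, "pos_reference_"):
            raise ValueError("NanostringNormalizer is not fitted")
        thresholded = _threshold(mat)
        pos_gm = _class_geomeans(thresholded, "positive_control")
        values = thresholded.values.mul(self.pos_reference_ / pos_gm, axis=0)
        hk_gm = _geomeans_of(values, mat.genes_of("housekeeping"))
        if (hk_gm == 0).any():
            raise ValueError("zero housekeeping geometric mean after scaling")
        values = values.mul(self.hk_reference_ / hk_gm, axis=0)
        return thresholded._advance("normalized", values)

    def fit_transform(self, mat: BulkExpressionMatrix) -> BulkExpressionMatrix:
        return self.fit(mat).transform(mat)


def _threshold(mat: BulkExpressionMatrix) -> BulkExpressionMatrix:
    neg = mat.genes_of("negative_control")
    pos = mat.genes_of("positive_control")
    hk = mat.genes_of("housekeeping")
    if not (neg and pos and hk):
        raise ValueError("all three control classes must be present")
    if mat.state != "raw":
        return mat
    floor = mat.values[neg].max(axis=1)
    values = mat.values.clip(lower=floor, axis=0)
    return mat._advance("thresholded", values)


def _class_geomeans(mat: BulkExpressionMatrix, cls: str) -> pd.Series:
    gm = _geomeans_of(mat.values, mat.genes_of(cls))
    if (gm == 0).any():
        bad = gm[gm == 0].index.tolist()
        raise ValueError(f"zero {cls} geometric mean in samples {bad}")
    return gm


def _geomeans_of(values: pd.DataFrame, genes: list[str]) -> pd.Series:
    return values[genes].apply(geomean, axis=1)


def normalize_counts(raw: BulkExpressionMatrix) -> BulkExpressionMatrix:
    """One-shot cohort normalization (fit and transform on the same cohort)."""
    return NanostringNormalizer().fit_transform(raw)


def log2_transform(mat: BulkExpressionMatrix) -> BulkExpressionMatrix:
    """log2 of normalized values; falls back to log2(x + 1) if values < 1 remain."""
    v = mat.values
    if (v.to_numpy() < 1).any():
        logger.info("values < 1 present after normalization; using log2(x + 1)")
        out = np.log2(v + 1.0)
    else:
        out = np.log2(v)
    return mat._advance("log2", out)
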