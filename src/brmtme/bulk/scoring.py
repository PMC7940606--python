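"""Immune-signature enrichment scoring and infiltration stratification.

The enrichment score of signature :math:`S` in patient :math:`i` is the
min–max-rescaled mean gene z-score

.. math::

    z_i(S) = \\frac{1}{|S|} \\sum_{g \\in S}
             \\frac{x_{ig} - \\mu_g}{\\sigma_g},
    \\qquad
    \\mathrm{ES}_i(S) = \\frac{z_i - \\min_j z_j}{\\max_j z_j - \\min_j z_j}

with :math:`\\mu_g, \\sigma_g` the mean and sample standard deviation of the
log2 expression of gene :math:`g` across patients. Patients are stratified by
Ward-linkage hierarchical clustering of the per-cell-type score matrix.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss

from .expression import BulkExpressionMatrix

logger = logging.getLogger("brmtme")

STRATA_NAMES = ("low", "intermediate", "high")


@dataclass
class EnrichmentScores:
    """Per-patient, per-signature scores in [0, 1] plus the raw mean z-scores."""

    score: pd.DataFrame  # patients x signatures, in [0, 1]
    patient_z: pd.DataFrame  # patients x signatures, unscaled

    def __post_init__(self):
        vals = self.score.to_numpy()
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("enrichment scores outside [0, 1]")


class SignatureScorer:
    """Cohort-level signature enrichment scoring (transformer-style).

    Parameters
    ----------
    signatures : mapping of signature name -> gene list
        Genes absent from the matrix or with zero variance across patients are
        dropped with a warning and the signature size reduced accordingly.
    """

    def __init__(self, signatures: dict[str, list[str]]):
        for name, genes in signatures.items():
            if len(genes) == 0:
                raise ValueError(f"signature {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature {name!r} has duplicate genes")
        self.signatures = dict(signatures)

    def get_params(self, deep: bool = True) -> dict:
        return {"signatures": self.signatures}

    def set_params(self, **params) -> "SignatureScorer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, mat, y=None) -> "SignatureScorer":
        return self

    def transform(self, mat: BulkExpressionMatrix | pd.DataFrame) -> EnrichmentScores:
        values = mat.values if isinstance(mat, BulkExpressionMatrix) else mat
        if len(values) < 2:
            raise ValueError("enrichment scoring needs at least 2 patients")
        cols = {}
        zcols = {}
        for name, genes in self.signatures.items():
            z = _patient_z(values, name, genes)
            zcols[name] = z
            cols[name] = _minmax(z, name)
        scores = pd.DataFrame(cols, index=values.index)
        return EnrichmentScores(score=scores, patient_z=pd.DataFrame(zcols, index=values.index))

    def fit_transform(self, mat, y=None) -> EnrichmentScores:
        return self.transform(mat)


def _patient_z(values: pd.DataFrame, name: str, genes: list[str]) -> pd.Series:
    present = [g for g in genes if g in values.columns]
    dropped = [g for g in genes if g not in values.columns]
    sd = values[present].std(ddof=1) if present else pd.Series(dtype=float)
    flat = [g for g in present if sd[g] == 0]
    if flat:
        dropped += flat
        present = [g for g in present if sd[g] > 0]
    if dropped:
        warnings.warn(
            f"signature {name!r}: dropped {len(dropped)} absent/zero-variance "
            f"gene(s): {dropped[:5]}",
            stacklevel=3,
        )
    if not present:
        raise ValueError(f"signature {name!r}: all genes absent or zero-variance")
    sub = values[present]
    z = (sub - sub.mean()) / sub.std(ddof=1)
    return z.mean(axis=1)


def _minmax(z: pd.Series, name: str) -> pd.Series:
    lo, hi = z.min(), z.max()
    if hi - lo == 0:
        warnings.warn(f"signature {name!r}: constant across patients; scores set to 0.5")
        return pd.Series(0.5, index=z.index)
    return (z - lo) / (hi - lo)


def signature_enrichment(
    mat: BulkExpressionMatrix | pd.DataFrame, signatures: dict[str, list[str]]
) -> EnrichmentScores:
    """Score every signature on a log2 expression matrix."""
    return SignatureScorer(signatures).transform(mat)


@dataclass
class StrataAssignment:
    label: pd.Series  # patient -> stratum name
    linkage_record: np.ndarray  # scipy linkage matrix


class InfiltrationStratifier:
    """Ward-linkage stratification of patients into k infiltration groups.

    Clusters the patients x signatures score matrix (Euclidean distance, Ward
    linkage), cuts at ``n_clusters`` groups and names them by ascending mean
    enrichment across the clustering signatures (low / intermediate / high
    when k = 3; rank labels otherwise).

    Attributes
    ----------
    labels_ : pd.Series patient -> group name
    linkage_ : scipy linkage matrix
    """

    def __init__(self, n_clusters: int = 3, exclude: tuple[str, ...] = ("IFNg signature",)):
        self.n_clusters = n_clusters
        self.exclude = exclude

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "exclude": self.exclude}

    def set_params(self, **params) -> "InfiltrationStratifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, scores: EnrichmentScores | pd.DataFrame, y=None) -> "InfiltrationStratifier":
        df = scores.score if isinstance(scores, EnrichmentScores) else scores
        feats = df.drop(columns=[c for c in self.exclude if c in df.columns])
        k = self.n_clusters
        if k > len(df):
            raise ValueError(f"n_clusters={k} exceeds {len(df)} patients")
        self.linkage_ = sch.linkage(feats.to_numpy(), method="ward")
        raw = sch.fcluster(self.linkage_, t=k, criterion="maxclust")
        means = (
            pd.Series(feats.mean(axis=1).to_numpy(), index=raw).groupby(level=0).mean()
        )
        order = means.sort_values().index.tolist()
        if k == 3:
            names = dict(zip(order, STRATA_NAMES))
        else:
            names = {c: f"group{r + 1}" for r, c in enumerate(order)}
        self.labels_ = pd.Series([names[c] for c in raw], index=df.index, name="stratum")
        return self

    def fit_predict(self, scores, y=None) -> pd.Series:
        return self.fit(scores).labels_


def stratify_patients(scores: EnrichmentScores, k: int = 3) -> StrataAssignment:
    """Ward stratification over the cell-type signatures (IFNg excluded)."""
    est = InfiltrationStratifier(n_clusters=k).fit(scores)
    return StrataAssignment(label=est.labels_, linkage_record=est.linkage_)


def compare_strata(
    scores: pd.Series,
    strata: StrataAssignment | pd.Series,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sided t-tests of one score column between strata.

    Defaults to the classic pooled-variance Student t; ``welch=True`` switches
    to unequal-variance. Pairs where either group has fewer than 2 patients
    are skipped with a warning.
    """
    labels = strata.label if isinstance(strata, StrataAssignment) else strata
    rows = []
    groups = {g: scores[labels[labels == g].index] for g in labels.unique()}
    for a, b in itertools.combinations(sorted(groups), 2):
        xa, xb = groups[a], groups[b]
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"strata pair ({a}, {b}) skipped: group with < 2 patients")
            continue
        t, p = ss.ttest_ind(xa, xb, equal_var=not welch)
        rows.append(
            {
                "group1": a,
                "group2": b,
                "n1": len(xa),
                "n2": len(xb),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
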