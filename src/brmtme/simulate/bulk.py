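"""Synthetic targeted-expression cohort with planted infiltration groups.

Emulates a three-group immune-infiltration cohort measured on a targeted
immune panel: negative-binomial counts for endogenous genes, housekeeping
genes independent of group, positive-control ladder and near-background
negative controls, plus (for cohorts of >= 10 patients) one deliberately
low-quality sample and one technical duplicate pair so the housekeeping QC
stage has something to do.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._utils import substream
from ..bulk.expression import BulkExpressionMatrix
from .config import ConfigurationError, GroundTruth, SimulationConfig

#: the seven cell-type signatures displayed in the infiltration heatmap plus
#: the IFN-gamma inflammation signature (scored but excluded from clustering)
SIGNATURE_CELL_TYPES = ("CLym", "TAM", "Treg", "DC", "B cells", "NK", "Neutrophils")
IFNG_SIGNATURE = "IFNg signature"
GENES_PER_SIGNATURE = 10

_GROUP_LEVEL = {"low": 0.0, "intermediate": 0.5, "high": 1.0}


def default_signatures() -> dict[str, list[str]]:
    """Signature name -> gene list for the simulated panel."""
    sigs = {
        ct: [f"{_slug(ct)}_SIG_{i:02d}" for i in range(GENES_PER_SIGNATURE)]
        for ct in SIGNATURE_CELL_TYPES
    }
    sigs[IFNG_SIGNATURE] = [f"IFNG_SIG_{i:02d}" for i in range(GENES_PER_SIGNATURE)]
    return sigs


def _slug(name: str) -> str:
    return name.upper().replace(" ", "").replace("/", "")


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial by (mean, dispersion): var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(np.int64)


def simulate_bulk_cohort(
    config: SimulationConfig,
) -> tuple[BulkExpressionMatrix, GroundTruth]:
    """Simulate the raw samples x genes count table plus planted groups."""
    if config.n_patients < 6:
        raise ConfigurationError("n_patients must be >= 6")
    sigs = default_signatures()
    sig_genes = [g for genes in sigs.values() for g in genes]
    if config.n_genes < len(sig_genes):
        raise ConfigurationError(
            f"n_genes must cover the {len(sig_genes)} signature genes"
        )
    rng = substream(config.seed, "bulk_cohort")

    n_filler = config.n_genes - len(sig_genes)
    endo = sig_genes + [f"GENE_{i:04d}" for i in range(n_filler)]
    hk = [f"HK_{i:02d}" for i in range(config.n_housekeeping)]
    pos = [f"POS_{c}" for c in "ABCDEF"]
    neg = [f"NEG_{c}" for c in "ABCDEFGH"]
    gene_class = pd.Series(
        {**{g: "endogenous" for g in endo},
         **{g: "housekeeping" for g in hk},
         **{g: "positive_control" for g in pos},
         **{g: "negative_control" for g in neg}}
    )

    patients = [f"P{i + 1}" for i in range(config.n_patients)]
    groups = _assign_groups(rng, config)
    truth = GroundTruth(patient_group=dict(zip(patients, groups)))

    # per-gene baseline means, shared across patients
    endo_base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=len(endo))
    hk_base = rng.lognormal(mean=np.log(500.0), sigma=0.5, size=len(hk))
    pos_base = np.array([32.0, 128.0, 512.0, 2048.0, 8192.0, 32768.0])
    neg_base = np.full(len(neg), 8.0)

    sig_idx = {g: i for i, g in enumerate(endo)}
    rows = []
    for pat, grp in zip(patients, groups):
        rows.append(
            _simulate_sample(rng, config, grp, endo_base, hk_base, pos_base, neg_base, sigs, sig_idx)
        )
    values = pd.DataFrame(rows, index=patients, columns=endo + hk + pos + neg)

    if config.n_patients >= 10:
        # technical duplicate of the first patient (same group, fresh noise)
        dup = _simulate_sample(
            rng, config, groups[0], endo_base, hk_base, pos_base, neg_base, sigs, sig_idx
        )
        values.loc[f"{patients[0]}_2"] = dup
        # one low-quality extra sample: housekeeping geometric mean < 50
        lq_grp = groups[-1]
        lq = _simulate_sample(
            rng, config, lq_grp, endo_base * 0.05, hk_base, pos_base, neg_base, sigs, sig_idx
        )
        n_endo = len(endo)
        lq[n_endo : n_endo + len(hk)] = rng.poisson(5.0, size=len(hk))
        lq_name = f"P{config.n_patients + 1}LQ"
        values.loc[lq_name] = lq
        truth.patient_group[lq_name] = lq_grp

    mat = BulkExpressionMatrix(values=values.astype(float), gene_class=gene_class)
    return mat, truth


def _assign_groups(rng: np.random.Generator, config: SimulationConfig) -> list[str]:
    n = config.n_patients
    counts = [int(round(p * n)) for p in config.group_proportions]
    while sum(counts) < n:
        counts[int(np.argmax(config.group_proportions))] += 1
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    labels = sum(([g] * c for g, c in zip(("low", "intermediate", "high"), counts)), [])
    rng.shuffle(labels)
    return labels


def _simulate_sample(
    rng, config, group, endo_base, hk_base, pos_base, neg_base, sigs, sig_idx
) -> np.ndarray:
    level = _GROUP_LEVEL[group]
    mean_endo = endo_base.copy()
    for name, genes in sigs.items():
        shift = 2.0 ** (config.signature_effect * level)
        for g in genes:
            mean_endo[sig_idx[g]] *= shift
    endo_counts = _nb(rng, mean_endo, config.nb_dispersion)
    hk_counts = _nb(rng, hk_base, config.nb_dispersion)
    pos_counts = _nb(rng, pos_base, 0.01)
    neg_counts = rng.poisson(neg_base)
    return np.concatenate([endo_counts, hk_counts, pos_counts, neg_counts]).astype(float)
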