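"""Two-caller consensus variant intersection and tumor mutational burden.

TMB is the number of nonsynonymous consensus mutations divided by the
captured library size in megabases (47 Mb by default). Only variants reported
by both callers enter the numerator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("brmtme")

LIBRARY_MB = 47.0

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

#: consequence vocabulary normalization (annotation tools differ)
CONSEQUENCE_SYNONYMS = {
    "nonsynonymous": "nonsynonymous",
    "non-synonymous": "nonsynonymous",
    "missense": "nonsynonymous",
    "missense_variant": "nonsynonymous",
    "stop_gained": "nonsynonymous",
    "stop_lost": "nonsynonymous",
    "start_lost": "nonsynonymous",
    "frameshift": "nonsynonymous",
    "frameshift_variant": "nonsynonymous",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
    "silent": "synonymous",
}


@dataclass
class TmbResult:
    n_consensus: int
    n_nonsyn: int
    tmb: float
    library_mb: float = LIBRARY_MB


def _normalize(variants: pd.DataFrame) -> pd.DataFrame:
    """Split multi-allelic records and deduplicate keys (with a warning)."""
    missing = [c for c in VARIANT_KEY if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing column(s): {missing}")
    v = variants.copy()
    if v["alt"].astype(str).str.contains(",").any():
        v = v.assign(alt=v["alt"].astype(str).str.split(",")).explode("alt")
    v["pos"] = v["pos"].astype(int)
    if (v["pos"] < 1).any():
        raise ValueError("variant positions must be 1-based (>= 1)")
    if (v["ref"] == v["alt"]).any():
        raise ValueError("ref allele equals alt allele in some records")
    n0 = len(v)
    v = v.drop_duplicates(subset=VARIANT_KEY, keep="first")
    if len(v) < n0:
        warnings.warn(f"deduplicated {n0 - len(v)} repeated variant key(s)")
    return v.reset_index(drop=True)


def consensus_variants(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intersection keyed on (chrom, pos, ref, alt); consequence taken from a.

    Disagreeing consequence labels are logged and resolved in favor of the
    first caller.
    """
    va, vb = _normalize(a), _normalize(b)
    merged = va.merge(
        vb[VARIANT_KEY + (["consequence"] if "consequence" in vb else [])],
        on=VARIANT_KEY, how="inner", suffixes=("", "_b"),
    )
    if "consequence" in merged and "consequence_b" in merged:
        disagree = merged["consequence"] != merged["consequence_b"]
        if disagree.any():
            logger.info(
                "consequence disagreement on %d variant(s); caller A label kept",
                int(disagree.sum()),
            )
        merged = merged.drop(columns="consequence_b")
    return merged


def compute_tmb(
    consensus: pd.DataFrame,
    library_mb: float = LIBRARY_MB,
    synonyms: dict[str, str] = CONSEQUENCE_SYNONYMS,
) -> TmbResult:
    """TMB = nonsynonymous consensus mutations / library megabases."""
    if "consequence" not in consensus.columns:
        raise ValueError("consensus variants lack a consequence column")
    cons = consensus["consequence"].astype(str).str.lower()
    missing = consensus[cons.isin(("", "nan", "none"))]
    if not missing.empty:
        raise ValueError(
            f"records without consequence annotation: {missing[VARIANT_KEY].to_dict('records')[:5]}"
        )
    normalized = cons.map(lambda c: synonyms.get(c, "other"))
    n_nonsyn = int((normalized == "nonsynonymous").sum())
    return TmbResult(
        n_consensus=len(consensus),
        n_nonsyn=n_nonsyn,
        tmb=n_nonsyn / library_mb,
        library_mb=library_mb,
    )
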