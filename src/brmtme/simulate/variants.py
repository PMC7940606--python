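"""Synthetic two-caller somatic variant sets with controllable concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._utils import substream
from .config import GroundTruth, SimulationConfig

BASES = "ACGT"
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "consequence", "caller"]
#: private false positives per caller, as a fraction of n_true
FP_FRACTION = 0.15


def _make_variants(rng, n: int, used: set, consequences, caller: str) -> pd.DataFrame:
    rows = []
    while len(rows) < n:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1, 50_000_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = BASES[int(rng.integers(4))]
        alt = rng.choice([b for b in BASES if b != ref])
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": str(alt),
                     "consequence": next(consequences), "caller": caller})
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def simulate_variant_calls(
    config: SimulationConfig, n_true: int, patient: str = "P1"
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two caller outputs with round(n_true * caller_overlap) shared variants.

    The consensus of the two returned sets equals the planted shared set
    exactly; each caller additionally reports private true variants and
    private false positives.
    """
    if n_true < 0:
        raise ValueError("n_true must be non-negative")
    rng = substream(config.seed, f"variants:{patient}")
    n_shared = int(round(n_true * config.caller_overlap))

    def consequence_stream():
        while True:
            yield "nonsynonymous" if rng.uniform() < config.nonsyn_fraction else "synonymous"

    cons = consequence_stream()
    used: set = set()
    shared = _make_variants(rng, n_shared, used, cons, "shared")
    n_priv = n_true - n_shared
    priv_a = _make_variants(rng, n_priv // 2 + n_priv % 2, used, cons, "A")
    priv_b = _make_variants(rng, n_priv // 2, used, cons, "B")
    n_fp = int(round(FP_FRACTION * n_true))
    fp_a = _make_variants(rng, n_fp, used, cons, "A")
    fp_b = _make_variants(rng, n_fp, used, cons, "B")

    a = pd.concat([shared.assign(caller="A"), priv_a, fp_a], ignore_index=True)
    b = pd.concat([shared.assign(caller="B"), priv_b, fp_b], ignore_index=True)

    n_nonsyn = int((shared["consequence"] == "nonsynonymous").sum())
    truth = GroundTruth(
        tmb_true={patient: n_nonsyn / 47.0},
        shared_variants=shared.drop(columns="caller"),
    )
    return a, b, truth
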