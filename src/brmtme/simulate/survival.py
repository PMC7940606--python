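"""Synthetic overall-survival records with a planted hazard ratio between strata."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._utils import substream
from .config import GroundTruth, SimulationConfig

#: baseline hazard (1/months), exponential event times; median OS ~ 38 months
BASELINE_HAZARD = np.log(2) / 38.0
#: independent exponential censoring rate plus administrative cutoff
CENSOR_HAZARD = 1.0 / 80.0
ADMIN_CENSOR = 120.0


def simulate_survival_records(
    config: SimulationConfig, strata: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Exponential survival with hazard scaled by the configured ratio.

    Strata are ordered alphabetically by label and assigned hazards on a
    geometric ladder from baseline to baseline * survival_hazard_ratio.
    Returns a table with columns patient, time (months), event, stratum.
    """
    if isinstance(strata, pd.Series):
        strata = strata.to_dict()
    if not strata:
        raise ValueError("strata mapping is empty")
    labels = sorted(set(strata.values()))
    if len(labels) < 2:
        raise ValueError("need at least two strata")
    rng = substream(config.seed, "survival")
    hr = config.survival_hazard_ratio
    hazard_of = {
        lab: BASELINE_HAZARD * hr ** (i / (len(labels) - 1))
        for i, lab in enumerate(labels)
    }
    rows = []
    for patient, lab in strata.items():
        t_event = rng.exponential(1.0 / hazard_of[lab])
        t_cens = min(rng.exponential(1.0 / CENSOR_HAZARD), ADMIN_CENSOR)
        rows.append({
            "patient": patient,
            "time": float(min(t_event, t_cens)),
            "event": int(t_event <= t_cens),
            "stratum": lab,
        })
    return pd.DataFrame(rows)
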