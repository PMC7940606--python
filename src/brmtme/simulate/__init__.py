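"""Synthetic-data generators with planted ground truth for every pipeline stage."""

import anndata as ad
import pandas as pd

from .bulk import IFNG_SIGNATURE, SIGNATURE_CELL_TYPES, default_signatures, simulate_bulk_cohort
from .cells import HB_GENES, MARKER_PROGRAMS, MITO_GENES, sc_gene_panel, simulate_sc_dataset
from .config import ConfigurationError, GroundTruth, SimulationConfig
from .survival import simulate_survival_records
from .tcr import simulate_tcr_repertoire
from .variants import simulate_variant_calls


def simulate_sc_cohort(
    config: SimulationConfig, csf_timepoints: tuple[str, ...] = ("t0", "t1", "t2")
) -> tuple["ad.AnnData", GroundTruth]:
    """One tumor sample plus longitudinal CSF samples, concatenated."""
    adatas, truth = [], GroundTruth()
    a, t = simulate_sc_dataset(config, "tumor", "t0", sample="TUM")
    adatas.append(a)
    truth.update(t)
    for tp in csf_timepoints:
        a, t = simulate_sc_dataset(config, "csf", tp)
        adatas.append(a)
        truth.update(t)
    combined = ad.concat(adatas, join="outer", merge="same")
    return combined, truth


__all__ = [
    "ConfigurationError",
    "GroundTruth",
    "SimulationConfig",
    "IFNG_SIGNATURE",
    "SIGNATURE_CELL_TYPES",
    "MARKER_PROGRAMS",
    "MITO_GENES",
    "HB_GENES",
    "default_signatures",
    "sc_gene_panel",
    "simulate_bulk_cohort",
    "simulate_sc_dataset",
    "simulate_sc_cohort",
    "simulate_survival_records",
    "simulate_tcr_repertoire",
    "simulate_variant_calls",
]
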