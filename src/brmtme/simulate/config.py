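"""Simulation configuration and planted ground truth containers.

The defaults describe the study conditions the generator emulates: a 48-patient
targeted-expression cohort stratifiable into three infiltration groups, tumor
and CSF single-cell samples of a few thousand immune cells each, paired TCR
repertoires dominated by singletons with expansion concentrated in cytotoxic
cells, and two somatic variant callers with high but incomplete concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


#: default cell-type composition per compartment. Tumor infiltrate is
#: macrophage-dominated; CSF is lymphocyte-dominated.
DEFAULT_CELLTYPE_PROPORTIONS: dict[str, dict[str, float]] = {
    "tumor": {
        "TAM/microglia": 0.40,
        "cytotoxic T": 0.18,
        "naive T": 0.12,
        "Treg": 0.08,
        "NK": 0.07,
        "B cells": 0.08,
        "DC": 0.04,
        "neutrophils": 0.03,
    },
    "csf": {
        "TAM/microglia": 0.17,
        "cytotoxic T": 0.30,
        "naive T": 0.25,
        "Treg": 0.10,
        "NK": 0.08,
        "B cells": 0.06,
        "DC": 0.04,
    },
}

#: cell types that carry a TCR
T_CELL_TYPES = ("cytotoxic T", "naive T", "Treg")
#: cell types whose clones receive the expansion bias
CYTOTOXIC_TYPES = ("cytotoxic T",)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # bulk targeted-expression cohort
    n_patients: int = 48
    n_genes: int = 730  # endogenous genes on the panel
    n_housekeeping: int = 40
    group_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    signature_effect: float = 2.0  # mean log2 shift, high vs low group
    # single-cell
    n_cells_per_sample: Mapping[str, int] = field(
        default_factory=lambda: {"tumor": 1700, "csf": 500}
    )
    n_genes_sc: int = 4000
    celltype_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_CELLTYPE_PROPORTIONS
    )
    nb_dispersion: float = 0.1
    mito_fraction_range: tuple[float, float] = (0.01, 0.09)
    # TCR repertoire
    clone_size_law: tuple = ("geometric", 0.85)
    sharing_fraction: float = 0.3
    expansion_bias: float = 5.0
    persistence_prob: float = 0.6
    # WES
    caller_overlap: float = 0.8
    nonsyn_fraction: float = 0.75
    # survival
    survival_hazard_ratio: float = 2.0

    def __post_init__(self):
        def _check_simplex(name, vals):
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1, got {sum(vals)!r}")
            if any(v < 0 for v in vals):
                raise ConfigurationError(f"{name} must be non-negative")

        _check_simplex("group_proportions", self.group_proportions)
        for comp, props in self.celltype_proportions.items():
            _check_simplex(f"celltype_proportions[{comp}]", list(props.values()))
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not 0 <= self.sharing_fraction <= 1:
            raise ConfigurationError("sharing_fraction must lie in [0, 1]")
        if not 0 <= self.persistence_prob <= 1:
            raise ConfigurationError("persistence_prob must lie in [0, 1]")
        if not 0 <= self.caller_overlap <= 1:
            raise ConfigurationError("caller_overlap must lie in [0, 1]")
        if not 0 <= self.nonsyn_fraction <= 1:
            raise ConfigurationError("nonsyn_fraction must lie in [0, 1]")
        if self.expansion_bias < 1:
            raise ConfigurationError("expansion_bias must be >= 1")
        law = self.clone_size_law
        if law[0] not in ("geometric", "zipf"):
            raise ConfigurationError(f"unknown clone_size_law {law[0]!r}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted truth for every simulated entity.

    ``cell_meta`` is a per-barcode table (sample, compartment, timepoint,
    cell_type, qc_class) so downstream stages can be scored against the
    simulation; ``clone_assignments`` maps TCR-bearing barcodes to clone ids.
    """

    patient_group: dict[str, str] = field(default_factory=dict)
    cell_type: dict[str, str] = field(default_factory=dict)
    clone_assignments: dict[str, str] = field(default_factory=dict)
    tmb_true: dict[str, float] = field(default_factory=dict)
    survival_hazard_ratio: float | None = None
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    clones: pd.DataFrame = field(default_factory=pd.DataFrame)
    shared_variants: pd.DataFrame = field(default_factory=pd.DataFrame)

    def update(self, other: "GroundTruth") -> "GroundTruth":
        """Merge another truth object in place (disjoint barcodes assumed)."""
        self.patient_group.update(other.patient_group)
        self.cell_type.update(other.cell_type)
        self.clone_assignments.update(other.clone_assignments)
        self.tmb_true.update(other.tmb_true)
        if other.survival_hazard_ratio is not None:
            self.survival_hazard_ratio = other.survival_hazard_ratio
        if not other.cell_meta.empty:
            self.cell_meta = pd.concat([self.cell_meta, other.cell_meta])
        if not other.clones.empty:
            self.clones = pd.concat([self.clones, other.clones], ignore_index=True)
        if not other.shared_variants.empty:
            self.shared_variants = other.shared_variants
        return self
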