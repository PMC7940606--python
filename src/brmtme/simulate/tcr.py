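"""Synthetic paired tumor/CSF TCR repertoires with planted clonal structure.

Clone sizes follow a configurable law (geometric or zipf); expanded-clone
membership is biased toward cytotoxic phenotypes by an odds multiplier; a
controllable fraction of expanded tumor clones is shared with the CSF; and
CSF clones persist across consecutive timepoints with a fixed probability.
CDR3 strings are random amino-acid sequences — identity, not biology, is what
downstream clonotype calling tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._utils import substream
from .config import CYTOTOXIC_TYPES, T_CELL_TYPES, GroundTruth, SimulationConfig

AA = "ACDEFGHIKLMNPQRSTVWY"

#: fraction of cells with only one recovered chain
SINGLE_CHAIN_FRACTION = 0.15
#: fraction of decoy contigs flagged non-productive or not full-length
ARTIFACT_FRACTION = 0.08

CONTIG_COLUMNS = [
    "barcode", "is_cell", "high_confidence", "chain", "cdr3",
    "productive", "full_length", "sample", "timepoint",
]


def _random_cdr3(rng: np.random.Generator) -> str:
    n = int(rng.integers(6, 19))  # total length 8..20 with the C...F affixes
    mid = "".join(AA[i] for i in rng.integers(0, len(AA), size=n))
    return f"C{mid}F"


def _draw_clone_sizes(rng, law, n_cells: int) -> list[int]:
    kind, param = law
    sizes = []
    total = 0
    while total < n_cells:
        if kind == "geometric":
            s = int(rng.geometric(param))
        else:  # zipf
            s = int(rng.zipf(param))
        s = min(s, n_cells - total)
        sizes.append(s)
        total += s
    return sizes


def simulate_tcr_repertoire(
    sc_truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Generate a filtered-contig-style chain table for the simulated T cells."""
    meta = sc_truth.cell_meta
    if meta.empty:
        raise ValueError("sc_truth carries no cells")
    t_mask = meta["cell_type"].isin(T_CELL_TYPES)
    t_meta = meta[t_mask]
    if t_meta.empty:
        raise ValueError("no T cells in sc_truth")
    compartments = set(t_meta["compartment"])
    csf_tps = sorted(t_meta.loc[t_meta["compartment"] == "csf", "timepoint"].unique())
    if "tumor" not in compartments or not csf_tps:
        raise ValueError("sc_truth must cover tumor and at least one CSF timepoint")

    rng = substream(config.seed, "tcr")
    clone_registry: dict[str, dict] = {}  # clone id -> {cdr3a, cdr3b}
    assignments: dict[str, str] = {}  # barcode -> clone id
    clone_rows = []

    def new_clone(prefix: str, k: int) -> str:
        cid = f"{prefix}{k:05d}"
        clone_registry[cid] = {"cdr3a": _random_cdr3(rng), "cdr3b": _random_cdr3(rng)}
        return cid

    def partition(barcodes: list[str], types: pd.Series, prefix: str) -> dict[str, list[str]]:
        """Assign barcodes to clones; expanded clones favor cytotoxic cells."""
        sizes = sorted(_draw_clone_sizes(rng, config.clone_size_law, len(barcodes)),
                       reverse=True)
        wmap = {
            b: config.expansion_bias if types.loc[b] in CYTOTOXIC_TYPES else 1.0
            for b in barcodes
        }
        pool = list(barcodes)
        out: dict[str, list[str]] = {}
        for k, s in enumerate(sizes):
            if s >= 2:
                w = np.array([wmap[b] for b in pool])
                idx = rng.choice(len(pool), size=s, replace=False, p=w / w.sum())
                members = [pool[i] for i in idx]
                for i in sorted(idx, reverse=True):
                    pool.pop(i)
            else:
                members = [pool.pop(int(rng.integers(len(pool))))]
            out[new_clone(prefix, k)] = members
        return out

    types = t_meta["cell_type"]

    # ---- tumor repertoire
    tum_bcs = t_meta.index[t_meta["compartment"] == "tumor"].tolist()
    tumor_clones = partition(tum_bcs, types, "TC")

    # ---- CSF t0: a sharing_fraction of expanded tumor clones re-appears
    expanded_tumor = [c for c, m in tumor_clones.items() if len(m) >= 2]
    n_shared = int(round(config.sharing_fraction * len(expanded_tumor)))
    shared = list(rng.choice(expanded_tumor, size=n_shared, replace=False)) if n_shared else []

    csf_clones_by_tp: dict[str, dict[str, list[str]]] = {}
    prev_tp_clones: list[str] = []
    for tp_i, tp in enumerate(csf_tps):
        bcs = t_meta.index[
            (t_meta["compartment"] == "csf") & (t_meta["timepoint"] == tp)
        ].tolist()
        if not bcs:
            continue
        planted: dict[str, list[str]] = {}
        carry = shared if tp_i == 0 else [
            c for c in prev_tp_clones if rng.uniform() < config.persistence_prob
        ]
        pool = list(bcs)
        # one cell per carried clone first (so persistence is representable),
        # then a few extras while cells remain
        for cid in carry:
            if not pool:
                break
            planted[cid] = [pool.pop(int(rng.integers(len(pool))))]
        for cid in carry:
            if cid not in planted or len(pool) <= len(carry):
                continue
            extra = int(rng.integers(0, 3))
            for _ in range(min(extra, len(pool) - len(carry))):
                planted[cid].append(pool.pop(int(rng.integers(len(pool)))))
        fresh = partition(pool, types, f"C{tp}_") if pool else {}
        all_tp = {**planted, **fresh}
        csf_clones_by_tp[tp] = all_tp
        prev_tp_clones = list(all_tp)

    # ---- emit contig records
    records = []
    all_assign = dict(tumor_clones)
    for tp, clones in csf_clones_by_tp.items():
        for cid, members in clones.items():
            all_assign.setdefault(cid, [])
            all_assign[cid] = all_assign[cid] + members

    for cid, members in all_assign.items():
        info = clone_registry[cid]
        for bc in members:
            assignments[bc] = cid
            row = meta.loc[bc]
            chains = ["TRA", "TRB"]
            if rng.uniform() < SINGLE_CHAIN_FRACTION:
                chains = [chains[int(rng.integers(2))]]
            for ch in chains:
                records.append({
                    "barcode": bc, "is_cell": True, "high_confidence": True,
                    "chain": ch,
                    "cdr3": info["cdr3a"] if ch == "TRA" else info["cdr3b"],
                    "productive": True, "full_length": True,
                    "sample": row["sample"], "timepoint": row["timepoint"],
                })
        clone_rows.append({
            "clone_id": cid, "cdr3a": info["cdr3a"], "cdr3b": info["cdr3b"],
            "size": len(members),
        })

    # decoy artifacts: non-productive / truncated / background contigs
    n_artifacts = int(round(ARTIFACT_FRACTION * len(records)))
    t_bcs = t_meta.index.tolist()
    for _ in range(n_artifacts):
        bc = t_bcs[int(rng.integers(len(t_bcs)))]
        row = meta.loc[bc]
        kind = int(rng.integers(3))
        records.append({
            "barcode": bc, "is_cell": kind != 2, "high_confidence": False,
            "chain": "TRA" if rng.uniform() < 0.5 else "TRB",
            "cdr3": _random_cdr3(rng),
            "productive": kind != 0, "full_length": kind != 1,
            "sample": row["sample"], "timepoint": row["timepoint"],
        })

    contigs = pd.DataFrame(records, columns=CONTIG_COLUMNS)
    sc_truth.clone_assignments.update(assignments)
    sc_truth.clones = pd.DataFrame(clone_rows)
    return contigs
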