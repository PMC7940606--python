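"""TCR clonotype calling, expansion classification, enrichment and sharing.

A clonotype is a distinct (chain, CDR3 amino-acid) sequence — alpha and beta
chains are counted separately, so a cell with both chains contributes to two
clonotypes. A clonotype is *expanded* when supported by at least two cells;
cells carrying any expanded sequence are classed expanded. Per-cluster
enrichment of expanded vs singleton cells uses the two-sided Fisher exact
test with the sample (cross-product) odds ratio.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss

logger = logging.getLogger("brmtme")

REQUIRED_CONTIG_COLUMNS = [
    "barcode", "is_cell", "chain", "cdr3", "productive", "full_length",
]


@dataclass
class Clonotype:
    id: str
    chain: str
    cdr3_aa: str
    cells: frozenset
    expansion_threshold: int = 2

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def expansion(self) -> str:
        return "expanded" if self.size >= self.expansion_threshold else "singleton"


def parse_contigs(table: pd.DataFrame) -> pd.DataFrame:
    """Keep chains from true cells that are productive and full-length.

    Returns the retained records; removal counts per filter are logged.
    """
    missing = [c for c in REQUIRED_CONTIG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"contig table missing required column(s): {missing}")
    if table.empty:
        warnings.warn("contig table is empty")
        return table.copy()
    t = table.copy()
    for col in ("is_cell", "productive", "full_length"):
        if t[col].dtype == object:
            t[col] = t[col].astype(str).str.lower().isin(("true", "t", "1", "yes"))
    removal = {
        "not_cell": int((~t["is_cell"]).sum()),
        "not_productive": int((t["is_cell"] & ~t["productive"]).sum()),
        "not_full_length": int((t["is_cell"] & t["productive"] & ~t["full_length"]).sum()),
    }
    keep = t["is_cell"] & t["productive"] & t["full_length"]
    logger.info("contig filtering removed %s", removal)
    out = t[keep].copy()
    out.attrs["removal"] = removal
    return out


def call_clonotypes(
    chains: pd.DataFrame,
    scope: set[str] | None = None,
    expansion_threshold: int = 2,
) -> list[Clonotype]:
    """Group retained chains by (chain, CDR3-aa); cells are distinct barcodes.

    ``scope`` optionally restricts to a sample set (requires a ``sample``
    column). Duplicate contigs of the same barcode/chain/CDR3 count once.
    """
    if chains.empty:
        raise ValueError("no chains to call clonotypes from")
    t = chains
    if scope is not None:
        t = t[t["sample"].isin(scope)]
        if t.empty:
            raise ValueError(f"no chains in scope {scope}")
    out = []
    grouped = t.groupby(["chain", "cdr3"], sort=True)["barcode"].agg(set)
    for k, ((ch, cdr3), cells) in enumerate(grouped.items()):
        out.append(
            Clonotype(
                id=f"ct{k:05d}", chain=ch, cdr3_aa=cdr3, cells=frozenset(cells),
                expansion_threshold=expansion_threshold,
            )
        )
    return out


def classify_expansion(clonotypes: list[Clonotype]) -> tuple[dict, pd.Series]:
    """Sequence-level singleton/expanded counts plus per-cell expansion class.

    A cell is expanded iff it carries at least one expanded sequence.
    """
    n_exp = sum(1 for c in clonotypes if c.expansion == "expanded")
    counts = {
        "n_singleton": len(clonotypes) - n_exp,
        "n_expanded": n_exp,
        "total": len(clonotypes),
    }
    cell_class: dict[str, str] = {}
    for c in clonotypes:
        for bc in c.cells:
            if c.expansion == "expanded":
                cell_class[bc] = "expanded"
            else:
                cell_class.setdefault(bc, "singleton")
    return counts, pd.Series(cell_class, name="expansion")


def expansion_enrichment(
    cell_classes: pd.Series, clusters: pd.Series
) -> pd.DataFrame:
    """Per-cluster Fisher exact enrichment of expanded vs singleton cells.

    The 2x2 table is [[expanded-in, singleton-in], [expanded-out,
    singleton-out]] over TCR-bearing cells only; the odds ratio is the sample
    cross-product (inf/0 at zero cells), p the two-sided conditional exact test.
    """
    common = cell_classes.index.intersection(clusters.index)
    cc = cell_classes.loc[common]
    cl = clusters.loc[common]
    with_tcr = cl[cc.index]
    if with_tcr.nunique() < 2:
        raise ValueError("need TCR-bearing cells in at least 2 clusters")
    exp = cc == "expanded"
    rows = []
    for c in sorted(cl.unique()):
        mask = cl == c
        if mask.sum() == 0:
            continue
        a = int((exp & mask).sum())  # expanded in cluster
        b = int((~exp & mask).sum())  # singleton in cluster
        cc_ = int((exp & ~mask).sum())
        d = int((~exp & ~mask).sum())
        if a + b == 0:
            continue  # no TCR cells in this cluster
        _, p = ss.fisher_exact([[a, b], [cc_, d]], alternative="two-sided")
        if b * cc_ == 0:
            odds = np.inf if a * d > 0 else (0.0 if a == 0 else np.inf)
        else:
            odds = (a * d) / (b * cc_)
        rows.append(
            {"cluster": c, "expanded_in": a, "singleton_in": b,
             "expanded_out": cc_, "singleton_out": d,
             "odds_ratio": float(odds), "p": float(p)}
        )
    return pd.DataFrame(rows)


@dataclass
class OverlapResult:
    """Venn regions over (chain, CDR3) identity across sample types."""

    region_counts: dict[frozenset, int]
    region_members: dict[frozenset, set]
    sets: dict[str, set] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def intersection_all(self) -> int:
        full = frozenset(self.sets)
        return self.region_counts.get(full, 0)

    def pairwise_intersection(self, a: str, b: str) -> int:
        return len(self.sets[a] & self.sets[b])


def compartment_overlap(clonotype_sets: dict[str, set]) -> OverlapResult:
    """Exact Venn-region cardinalities of clonotype identity sets.

    Keys are sample types (e.g. tumor, csf_t0); values are sets of
    (chain, cdr3_aa) tuples. Every element is assigned to exactly one region
    (the subset of sample types containing it), so region counts sum to the
    union size.
    """
    if len(clonotype_sets) < 2:
        raise ValueError("need at least 2 sample types")
    names = list(clonotype_sets)
    universe = set().union(*clonotype_sets.values())
    counts: dict[frozenset, int] = {}
    members: dict[frozenset, set] = {}
    for el in universe:
        region = frozenset(n for n in names if el in clonotype_sets[n])
        counts[region] = counts.get(region, 0) + 1
        members.setdefault(region, set()).add(el)
    return OverlapResult(
        region_counts=counts, region_members=members,
        sets={k: set(v) for k, v in clonotype_sets.items()},
    )


def clonotype_identity_set(clonotypes: list[Clonotype]) -> set:
    return {(c.chain, c.cdr3_aa) for c in clonotypes}


def clonal_trajectories(
    chains_by_timepoint: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Clone frequencies over timepoints plus persistence flags (fish-plot table).

    Frequency of a clone at a timepoint is its supporting cells over all
    TCR-bearing cells there (0 when absent). A clone is persistent when it is
    present at every sampled timepoint from its first appearance onward. The
    table is flat (parent = none): clonal ancestry is not inferred.
    """
    tps = sorted(chains_by_timepoint)
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints")
    freq: dict[tuple, dict[str, float]] = {}
    for tp in tps:
        t = chains_by_timepoint[tp]
        if t.empty:
            raise ValueError(f"timepoint {tp!r} has no TCR-bearing cells")
        n_cells = t["barcode"].nunique()
        sizes = t.groupby(["chain", "cdr3"])["barcode"].nunique()
        for key, s in sizes.items():
            freq.setdefault(key, {})[tp] = s / n_cells
    rows = []
    for (ch, cdr3), by_tp in sorted(freq.items()):
        present = [tp in by_tp for tp in tps]
        first = present.index(True)
        persistent = all(present[first:])
        rows.append(
            {"clone": f"{ch}:{cdr3}", "chain": ch, "cdr3": cdr3, "parent": "none",
             **{f"freq_{tp}": by_tp.get(tp, 0.0) for tp in tps},
             "persistent": persistent}
        )
    return pd.DataFrame(rows)
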