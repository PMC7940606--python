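import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from brmtme.bulk import BulkExpressionMatrix
from brmtme.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """A cohort small enough for fast unit tests."""
    return SimulationConfig(
        seed=0,
        n_patients=12,
        n_genes=120,
        n_cells_per_sample={"tumor": 400, "csf": 200},
        n_genes_sc=3000,
    )


@pytest.fixture
def tiny_bulk():
    """4 samples x (2 endogenous + 2 HK + 2 pos + 2 neg) with easy numbers."""
    genes = ["G1", "G2", "HK1", "HK2", "POS1", "POS2", "NEG1", "NEG2"]
    values = pd.DataFrame(
        [
            [20.0, 40.0, 100.0, 100.0, 100.0, 100.0, 5.0, 10.0],
            [30.0, 60.0, 120.0, 120.0, 100.0, 100.0, 4.0, 8.0],
            [25.0, 50.0, 110.0, 110.0, 100.0, 100.0, 6.0, 9.0],
            [35.0, 70.0, 130.0, 130.0, 100.0, 100.0, 5.0, 7.0],
        ],
        index=["S1", "S2", "S3", "S4"],
        columns=genes,
    )
    gene_class = pd.Series(
        {
            "G1": "endogenous", "G2": "endogenous",
            "HK1": "housekeeping", "HK2": "housekeeping",
            "POS1": "positive_control", "POS2": "positive_control",
            "NEG1": "negative_control", "NEG2": "negative_control",
        }
    )
    return BulkExpressionMatrix(values=values, gene_class=gene_class)


def make_adata(counts: np.ndarray, genes=None, barcodes=None) -> ad.AnnData:
    n, g = counts.shape
    genes = genes or [f"g{i}" for i in range(g)]
    barcodes = barcodes or [f"c{i}" for i in range(n)]
    return ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


@pytest.fixture
def contig_table():
    """Five contigs, two failing the productive/full-length filters."""
    return pd.DataFrame(
        {
            "barcode": ["c1", "c1", "c2", "c3", "c4"],
            "is_cell": [True, True, True, True, True],
            "high_confidence": [True] * 5,
            "chain": ["TRA", "TRB", "TRB", "TRB", "TRA"],
            "cdr3": ["CAAAF", "CASSLGQFF", "CASSLGQFF", "CQQQF", "CWWWF"],
            "productive": [True, True, True, False, True],
            "full_length": [True, True, True, True, False],
            "sample": ["TUM"] * 5,
            "timepoint": ["t0"] * 5,
        }
    )
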