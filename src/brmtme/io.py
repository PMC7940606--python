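"""Readers and writers for the pipeline's text formats.

Matrix-Market bundles follow the 10x convention: ``matrix.mtx`` is genes x
cells (1-based indices in the file), ``barcodes.tsv`` one barcode per line,
``features.tsv`` with 2 or 3 tab-separated columns. All CSV outputs carry a
metadata header line (# version, seed, config hash) so results are traceable
to the run that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import __version__

logger = logging.getLogger("brmtme")


def read_mtx_bundle(directory: str | Path) -> ad.AnnData:
    """Load matrix.mtx + barcodes.tsv + features.tsv as cells x genes AnnData."""
    d = Path(directory)
    for fn in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (d / fn).exists():
            raise FileNotFoundError(f"{fn} missing from {d}")
    m = scipy.io.mmread(d / "matrix.mtx").tocsr()  # genes x cells
    barcodes = pd.read_csv(d / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
    feats = pd.read_csv(d / "features.tsv", header=None, sep="\t")
    if feats.shape[1] not in (2, 3):
        raise ValueError(f"features.tsv must have 2 or 3 columns, got {feats.shape[1]}")
    gene_names = feats[1].astype(str) if feats.shape[1] >= 2 else feats[0].astype(str)
    if m.shape[0] != len(gene_names):
        raise ValueError(
            f"matrix has {m.shape[0]} rows but features.tsv lists {len(gene_names)} genes"
        )
    if m.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {m.shape[1]} columns but barcodes.tsv lists {len(barcodes)} barcodes"
        )
    names = _disambiguate(gene_names.tolist())
    adata = ad.AnnData(
        X=m.T.tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(names, name="gene")),
    )
    return adata


def _disambiguate(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def write_mtx_bundle(adata: ad.AnnData, directory: str | Path) -> None:
    """Write a cells x genes AnnData as a genes x cells 10x-style bundle."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(d / "matrix.mtx"), X.T.tocoo(), field="integer")
    (d / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    (d / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in adata.var_names)
    )


def metadata_header(seed: int | None, config: dict | None = None) -> str:
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# brmtme v{__version__} seed={seed} config_hash={cfg_hash}"


def write_csv(
    df: pd.DataFrame, path: str | Path, seed: int | None = None,
    config: dict | None = None, index: bool = True,
) -> None:
    """CSV with a one-line provenance header; floats at 12 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(metadata_header(seed, config) + "\n")
        df.to_csv(fh, index=index, float_format="%.12g")


def read_csv(path: str | Path, **kw) -> pd.DataFrame:
    """Read a CSV, skipping any leading provenance comment lines."""
    return pd.read_csv(path, comment="#", **kw)


def read_bulk_csv(counts_path: str | Path, classes_path: str | Path):
    """Bulk samples x genes CSV plus a gene,class sidecar -> BulkExpressionMatrix."""
    from .bulk import BulkExpressionMatrix

    values = read_csv(counts_path, index_col=0)
    classes = read_csv(classes_path)
    gene_class = pd.Series(classes["class"].values, index=classes["gene"].values)
    return BulkExpressionMatrix(values=values.astype(float), gene_class=gene_class)


def write_bulk_csv(mat, counts_path: str | Path, classes_path: str | Path,
                   seed: int | None = None) -> None:
    write_csv(mat.values, counts_path, seed=seed)
    sidecar = pd.DataFrame({"gene": mat.gene_class.index, "class": mat.gene_class.values})
    write_csv(sidecar, classes_path, seed=seed, index=False)


def read_signatures(path: str | Path) -> dict[str, list[str]]:
    """Signatures as 2-column CSV (signature,gene) or a YAML mapping."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return {str(k): list(v) for k, v in data.items()}
    df = read_csv(path)
    return {
        str(name): grp["gene"].astype(str).tolist()
        for name, grp in df.groupby("signature", sort=False)
    }


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_markers_yaml(path: str | Path | None = None) -> dict[str, list[str]]:
    """Curated cell type -> marker gene mapping; falls back to the shipped default."""
    if path is None:
        from importlib.resources import files

        path = files("brmtme").joinpath("data/markers.yaml")
        text = path.read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    return {str(k): list(v) for k, v in data.items()}


def default_cell_cycle_sets() -> dict[str, list[str]]:
    """Shipped default G1/S and G2/M gene lists (keys ``g1s`` and ``g2m``)."""
    from importlib.resources import files

    data = yaml.safe_load(files("brmtme").joinpath("data/cell_cycle.yaml").read_text())
    return {str(k): list(v) for k, v in data.items()}


def read_variants(path: str | Path) -> pd.DataFrame:
    """Variant table from the CSV dialect or a minimal VCF (1-based positions)."""
    path = Path(path)
    text_head = path.open().readline()
    if path.suffix.lower() == ".vcf" or text_head.startswith("##fileformat=VCF"):
        return _read_minimal_vcf(path)
    return read_csv(path)


def _read_minimal_vcf(path: Path) -> pd.DataFrame:
    rows = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 5:
            raise ValueError(f"malformed VCF line: {line[:60]!r}")
        info = f[7] if len(f) > 7 else ""
        consequence = ""
        for kv in info.split(";"):
            if kv.startswith(("CSQ=", "Consequence=", "CONSEQUENCE=")):
                consequence = kv.split("=", 1)[1]
        rows.append(
            {"chrom": f[0], "pos": int(f[1]), "ref": f[3], "alt": f[4],
             "consequence": consequence}
        )
    return pd.DataFrame(rows)
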