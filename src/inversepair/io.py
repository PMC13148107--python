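"""On-disk formats for count matrices and gene/cell metadata.

Counts are exchanged as MatrixMarket (genes x cells, the 10x/CellRanger
orientation) plus ``genes.tsv`` (gene_id and boolean flags) and ``cells.tsv``
(cell_id and subtype label). A dense CSV with cells as rows and genes as
header columns is accepted as an alternative input.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .errors import ValidationError
from ._util import atomic_open

FLAG_COLUMNS = ("is_csm", "is_mito", "is_ercc", "is_marker")


def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    spio.mmwrite(outdir / "matrix.mtx", mat.T.astype(np.int64))
    genes = adata.var.copy()
    genes.insert(0, "gene_id", adata.var_names)
    with atomic_open(outdir / "genes.tsv") as fh:
        genes.to_csv(fh, sep="\t", index=False)
    cells = pd.DataFrame({"cell_id": adata.obs_names})
    if "subtype" in adata.obs:
        cells["subtype"] = adata.obs["subtype"].to_numpy()
    with atomic_open(outdir / "cells.tsv") as fh:
        cells.to_csv(fh, sep="\t", index=False)


def read_counts(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    mat = sp.csr_matrix(spio.mmread(indir / "matrix.mtx")).T
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    if mat.shape != (len(cells), len(genes)):
        raise ValidationError(
            f"matrix shape {mat.shape} inconsistent with {len(cells)} cells x {len(genes)} genes"
        )
    var = genes.set_index("gene_id")
    for col in FLAG_COLUMNS:
        if col in var:
            var[col] = var[col].astype(bool)
        else:
            var[col] = False
    obs = cells.set_index("cell_id")
    if "subtype" in obs:
        obs["subtype"] = pd.Categorical(obs["subtype"])
    adata = ad.AnnData(X=mat.astype(np.int64), obs=obs, var=var)
    return adata


def read_counts_csv(path: str | Path) -> ad.AnnData:
    """Dense CSV: first column = cell id, header row = gene ids."""
    df = pd.read_csv(path, index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError("counts must be non-negative")
    var = pd.DataFrame(index=df.columns.astype(str))
    from .synthetic import ERCC_PREFIX, MITO_PREFIX

    var["is_csm"] = False
    var["is_mito"] = [g.startswith(MITO_PREFIX) for g in var.index]
    var["is_ercc"] = [g.startswith(ERCC_PREFIX) for g in var.index]
    var["is_marker"] = False
    return ad.AnnData(
        X=sp.csr_matrix(df.to_numpy(dtype=np.int64)),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=var,
    )
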