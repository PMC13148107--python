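"""Cell-level quality control and CPM/log normalization.

The filter cascade mirrors the study design for 384-well SMART-seq2 plates:

1. drop cells whose ERCC spike-in count fraction is an outlier
   (above median + k * MAD across cells);
2. drop low-quality cells — library size strictly below 100,000 counts or
   mitochondrial count fraction strictly above 5%;
3. keep only cells expressing user-supplied neuronal marker genes.

Normalization converts retained counts to log2(CPM + 1). ERCC spike-ins are
excluded from the library size (they are not cellular transcripts) and dropped
from the normalized output; mitochondrial genes stay in both. Raw counts of
the surviving genes are kept in ``layers['counts']`` so downstream code can
compute detection ("expression fraction") from raw counts > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np

from .errors import ConfigurationError, QCError
from ._util import log


@dataclass
class QCReport:
    step: str
    n_before: int
    n_after: int
    removed_cells: list[str]
    params: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_before - self.n_after

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "n_removed": self.n_removed,
            "removed_cells": list(self.removed_cells),
            "params": dict(self.params),
        }


def _counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def _apply_keep(adata: ad.AnnData, keep: np.ndarray, step: str, params: dict) -> tuple[ad.AnnData, QCReport]:
    removed = [str(c) for c in adata.obs_names[~keep]]
    out = adata[keep].copy()
    report = QCReport(
        step=step,
        n_before=adata.n_obs,
        n_after=out.n_obs,
        removed_cells=removed,
        params=params,
    )
    log.info("qc %s: %d -> %d cells (%d removed)", step, report.n_before, report.n_after, report.n_removed)
    return out, report


def filter_ercc_outliers(adata: ad.AnnData, mad_k: float = 3.0) -> tuple[ad.AnnData, QCReport]:
    """Remove cells whose ERCC count fraction exceeds median + mad_k * MAD."""
    if "is_ercc" not in adata.var:
        raise ConfigurationError("var['is_ercc'] flags are required")
    ercc = adata.var["is_ercc"].to_numpy()
    if not ercc.any():
        keep = np.ones(adata.n_obs, dtype=bool)
        out, report = _apply_keep(adata, keep, "ercc_outliers", {"mad_k": mad_k, "threshold": None})
        return out, report
    X = _counts(adata)
    total = X.sum(axis=1)
    frac = np.divide(X[:, ercc].sum(axis=1), total, out=np.zeros(len(total)), where=total > 0)
    med = float(np.median(frac))
    mad = float(np.median(np.abs(frac - med)))
    threshold = med + mad_k * mad
    keep = frac <= threshold
    if not keep.any():
        raise QCError("ERCC outlier filter removed every cell")
    return _apply_keep(
        adata, keep, "ercc_outliers", {"mad_k": mad_k, "median": med, "mad": mad, "threshold": threshold}
    )


def filter_low_quality(
    adata: ad.AnnData, min_counts: int = 100_000, max_mito_frac: float = 0.05
) -> tuple[ad.AnnData, QCReport]:
    """Remove cells with library size < min_counts OR mito fraction > max_mito_frac.

    Both inequalities are strict, so a cell at exactly 100,000 counts and
    exactly 5% mitochondrial content is retained.
    """
    if "is_mito" not in adata.var:
        raise ConfigurationError("var['is_mito'] flags are required")
    X = _counts(adata)
    lib = X.sum(axis=1)
    mito = adata.var["is_mito"].to_numpy()
    mito_frac = np.divide(X[:, mito].sum(axis=1), lib, out=np.zeros(len(lib)), where=lib > 0)
    keep = (lib >= min_counts) & (mito_frac <= max_mito_frac)
    if not keep.any():
        raise QCError(
            f"low-quality filter removed all {adata.n_obs} cells "
            f"(library < {min_counts}: {(lib < min_counts).sum()}, "
            f"mito > {max_mito_frac:.0%}: {(mito_frac > max_mito_frac).sum()})"
        )
    return _apply_keep(
        adata, keep, "low_quality", {"min_counts": min_counts, "max_mito_frac": max_mito_frac}
    )


def filter_marker_positive(
    adata: ad.AnnData, marker_ids: Sequence[str], min_count: int = 1
) -> tuple[ad.AnnData, QCReport]:
    """Keep cells with at least ``min_count`` summed counts over marker genes.

    An empty marker list is the identity (the marker panel is a user input;
    none configured means no purity filter).
    """
    marker_ids = list(marker_ids)
    if not marker_ids:
        keep = np.ones(adata.n_obs, dtype=bool)
        return _apply_keep(adata, keep, "marker_positive", {"marker_ids": [], "min_count": min_count})
    unknown = [g for g in marker_ids if g not in adata.var_names]
    if unknown:
        raise ConfigurationError(f"unknown marker gene id(s): {unknown}")
    X = _counts(adata)
    idx = [adata.var_names.get_loc(g) for g in marker_ids]
    keep = X[:, idx].sum(axis=1) >= min_count
    if not keep.any():
        raise QCError("marker filter removed every cell")
    return _apply_keep(
        adata, keep, "marker_positive", {"marker_ids": marker_ids, "min_count": min_count}
    )


def run_qc(
    adata: ad.AnnData,
    marker_ids: Sequence[str] = (),
    *,
    mad_k: float = 3.0,
    min_counts: int = 100_000,
    max_mito_frac: float = 0.05,
    min_marker_count: int = 1,
) -> tuple[ad.AnnData, list[QCReport]]:
    """Apply the full cascade in its fixed order: ERCC -> low-quality -> marker."""
    out, r1 = filter_ercc_outliers(adata, mad_k=mad_k)
    out, r2 = filter_low_quality(out, min_counts=min_counts, max_mito_frac=max_mito_frac)
    out, r3 = filter_marker_positive(out, marker_ids, min_count=min_marker_count)
    return out, [r1, r2, r3]


def normalize_cpm_log(
    adata: ad.AnnData,
    *,
    exclude_ercc_from_library: bool = True,
    drop_ercc: bool = True,
    exclude_mito_from_library: bool = False,
) -> ad.AnnData:
    """log2(1e6 * count / library + 1) per cell.

    Returns a new AnnData whose ``X`` holds the normalized values and whose
    ``layers['counts']`` holds the raw counts of the retained genes.
    """
    X = _counts(adata).astype(float)
    lib_mask = np.ones(adata.n_vars, dtype=bool)
    if exclude_ercc_from_library and "is_ercc" in adata.var:
        lib_mask &= ~adata.var["is_ercc"].to_numpy()
    if exclude_mito_from_library and "is_mito" in adata.var:
        lib_mask &= ~adata.var["is_mito"].to_numpy()
    lib = X[:, lib_mask].sum(axis=1)
    if np.any(lib <= 0):
        bad = list(adata.obs_names[lib <= 0][:5])
        raise QCError(
            f"{int((lib <= 0).sum())} cell(s) have zero library counts (e.g. {bad}); "
            "run the QC filters before normalizing"
        )
    keep_genes = np.ones(adata.n_vars, dtype=bool)
    if drop_ercc and "is_ercc" in adata.var:
        keep_genes = ~adata.var["is_ercc"].to_numpy()
    values = np.log2(1e6 * X[:, keep_genes] / lib[:, None] + 1.0)
    out = ad.AnnData(
        X=values,
        obs=adata.obs.copy(),
        var=adata.var.loc[keep_genes].copy(),
    )
    out.layers["counts"] = X[:, keep_genes].astype(np.int64)
    out.uns["normalization"] = {
        "unit": "log2(CPM+1)",
        "exclude_ercc_from_library": exclude_ercc_from_library,
        "exclude_mito_from_library": exclude_mito_from_library,
        "drop_ercc": drop_ercc,
    }
    return out
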