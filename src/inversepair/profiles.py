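"""Subtype-level expression profiles and cosine label transfer.

Single cells are aggregated per subtype into two aligned matrices:

* ``mean`` — arithmetic mean of log2(CPM+1) values ("expression intensity");
* ``fraction`` — proportion of the subtype's cells with raw count > 0
  ("expression fraction", the breadth of detection).

Unlabeled clusters can be matched to annotated reference types by maximum
cosine similarity of their mean profiles over a shared gene set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from ._util import atomic_open, log


@dataclass
class SubtypeProfiles:
    """Aligned subtype x gene intensity and detection-fraction matrices."""

    mean: pd.DataFrame      # log2(CPM+1)
    fraction: pd.DataFrame  # in [0, 1]
    n_cells: pd.Series

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.fraction.index) or not self.mean.columns.equals(
            self.fraction.columns
        ):
            raise ValidationError("mean and fraction matrices must share axes")
        if ((self.fraction.to_numpy() < 0) | (self.fraction.to_numpy() > 1)).any():
            raise ValidationError("fraction entries must lie in [0, 1]")
        if not self.n_cells.index.equals(self.mean.index):
            raise ValidationError("n_cells must be indexed by subtype")
        if (self.n_cells < 1).any():
            raise ValidationError("every subtype needs at least one cell")

    @property
    def subtypes(self) -> list[str]:
        return list(self.mean.index)

    @property
    def genes(self) -> list[str]:
        return list(self.mean.columns)

    def subset_genes(self, genes: Sequence[str]) -> "SubtypeProfiles":
        missing = [g for g in genes if g not in self.mean.columns]
        if missing:
            raise ConfigurationError(f"unknown gene id(s): {missing}")
        return SubtypeProfiles(
            mean=self.mean.loc[:, list(genes)].copy(),
            fraction=self.fraction.loc[:, list(genes)].copy(),
            n_cells=self.n_cells.copy(),
        )

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with atomic_open(outdir / "mean.tsv") as fh:
            self.mean.to_csv(fh, sep="\t")
        with atomic_open(outdir / "fraction.tsv") as fh:
            self.fraction.to_csv(fh, sep="\t")
        with atomic_open(outdir / "profiles.json") as fh:
            json.dump(
                {"unit": "log2(CPM+1)", "n_cells": self.n_cells.to_dict()},
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, indir: str | Path) -> "SubtypeProfiles":
        indir = Path(indir)
        mean = pd.read_csv(indir / "mean.tsv", sep="\t", index_col=0)
        fraction = pd.read_csv(indir / "fraction.tsv", sep="\t", index_col=0)
        meta = json.loads((indir / "profiles.json").read_text())
        n_cells = pd.Series(meta["n_cells"]).reindex(mean.index)
        return cls(mean=mean, fraction=fraction, n_cells=n_cells.astype(int))


def aggregate_profiles(nm: ad.AnnData, labels: Sequence[str] | None = None) -> SubtypeProfiles:
    """Aggregate a normalized matrix into per-subtype mean and fraction profiles.

    ``nm.X`` must hold log2(CPM+1) values; detection is taken from raw counts
    in ``nm.layers['counts']`` (falling back to X > 0 with a warning).
    """
    if labels is None:
        if "subtype" not in nm.obs:
            raise ConfigurationError("no labels given and obs['subtype'] absent")
        labels = nm.obs["subtype"]
    labels = pd.Series(np.asarray(labels, dtype=object), index=nm.obs_names)
    if labels.isna().any():
        raise ValidationError("every cell needs a non-null subtype label")
    values = np.asarray(nm.X.todense()) if hasattr(nm.X, "todense") else np.asarray(nm.X)
    if "counts" in nm.layers:
        counts = nm.layers["counts"]
        counts = np.asarray(counts.todense()) if hasattr(counts, "todense") else np.asarray(counts)
        detected = counts > 0
    else:
        warnings.warn("no layers['counts']; using normalized values > 0 for detection")
        detected = values > 0
    groups = sorted(set(labels))
    mean_rows, frac_rows, ncell = [], [], []
    for g in groups:
        mask = (labels == g).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"subtype {g!r} has no cells")
        mean_rows.append(values[mask].mean(axis=0))
        frac_rows.append(detected[mask].mean(axis=0))
        ncell.append(int(mask.sum()))
    return SubtypeProfiles(
        mean=pd.DataFrame(mean_rows, index=groups, columns=nm.var_names),
        fraction=pd.DataFrame(frac_rows, index=groups, columns=nm.var_names),
        n_cells=pd.Series(ncell, index=pd.Index(groups)),
    )


def cosine_match(
    query: SubtypeProfiles,
    reference: SubtypeProfiles,
    shared_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign each query cluster the reference type with maximal cosine similarity.

    Similarity is computed on the mean (intensity) profiles over
    ``shared_genes`` (default: the intersection of gene sets). Ties break
    lexicographically by reference label. All-zero query vectors are flagged
    unassignable (``reference`` = NA).

    Returns a DataFrame indexed by query cluster with columns
    ``reference`` and ``similarity``.
    """
    if shared_genes is None:
        shared_genes = [g for g in query.genes if g in set(reference.genes)]
    shared_genes = list(shared_genes)
    if not shared_genes:
        raise ConfigurationError("no shared genes between query and reference")
    q = query.subset_genes(shared_genes).mean.to_numpy(dtype=float)
    ref_labels = sorted(reference.subtypes)  # lexicographic order makes argmax tie-break stable
    r = reference.subset_genes(shared_genes).mean.loc[ref_labels].to_numpy(dtype=float)
    qn = np.linalg.norm(q, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn == 0):
        raise ValidationError("reference contains an all-zero profile")
    sims = q @ r.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = sims / (qn[:, None] * rn[None, :])
    rows = []
    for i, label in enumerate(query.subtypes):
        if qn[i] == 0:
            log.warning("cluster %s has an all-zero profile; unassignable", label)
            rows.append((label, pd.NA, np.nan))
            continue
        j = int(np.argmax(sims[i]))
        rows.append((label, ref_labels[j], float(sims[i, j])))
    return pd.DataFrame(rows, columns=["cluster", "reference", "similarity"]).set_index("cluster")
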