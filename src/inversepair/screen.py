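"""Anti-correlation screen for inverse-expression binding-partner candidates.

Given subtype-level profiles, the screen

1. gates the candidate cell-surface molecules (CSMs): a CSM is kept if some
   subtype shows mean expression > 3 log2(CPM+1) AND detection fraction > 50%
   (both thresholds in the same subtype under the default joint reading);
2. correlates each surviving CSM with the target gene twice — Pearson r over
   the intensity matrix columns (r_cpm) and over the fraction matrix columns
   (r_frac);
3. integrates the two as score = (r_cpm + r_frac) / 2 and sorts ascending, so
   the strongest inverse-expression candidates (score near -1) rank first;
4. optionally merges structure-prediction confidence (per-model ipTM scores,
   averaged) for the shortlisted candidates.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError, ZeroVarianceError
from .profiles import SubtypeProfiles
from ._util import log


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation sum((x-x̄)(y-ȳ)) / sqrt(sum(x-x̄)² sum(y-ȳ)²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson needs two equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("pearson needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def filter_csms(
    p: SubtypeProfiles,
    csm_ids: Sequence[str],
    min_mean: float = 3.0,
    min_frac: float = 0.5,
    joint: bool = True,
) -> list[str]:
    """Expression gate: keep CSMs clearing both thresholds in at least one subtype.

    ``joint=True`` (default) requires mean > min_mean and fraction > min_frac
    in the *same* subtype; ``joint=False`` lets different subtypes satisfy the
    two thresholds. Both comparisons are strict.
    """
    csm_ids = list(csm_ids)
    if not csm_ids:
        raise ConfigurationError("empty CSM list")
    missing = [g for g in csm_ids if g not in p.mean.columns]
    if missing:
        raise ConfigurationError(f"CSM id(s) not in gene universe: {missing}")
    mean = p.mean.loc[:, csm_ids].to_numpy()
    frac = p.fraction.loc[:, csm_ids].to_numpy()
    if joint:
        ok = ((mean > min_mean) & (frac > min_frac)).any(axis=0)
    else:
        ok = (mean > min_mean).any(axis=0) & (frac > min_frac).any(axis=0)
    kept = [g for g, k in zip(csm_ids, ok) if k]
    log.info("CSM gate: %d/%d pass (min_mean=%g, min_frac=%g, joint=%s)",
             len(kept), len(csm_ids), min_mean, min_frac, joint)
    return kept


def anticorr_scores(
    p: SubtypeProfiles, target: str, candidates: Sequence[str]
) -> pd.DataFrame:
    """Per-candidate r_cpm, r_frac and integrated score against ``target``.

    Candidates with zero variance in either matrix get NaN entries (Pearson r
    is undefined for them) and are reported but excluded from ranking.
    """
    if target not in p.mean.columns:
        raise ConfigurationError(f"target gene {target!r} not in gene universe")
    candidates = list(candidates)
    if target in candidates:
        raise ConfigurationError("target must be excluded from the candidate list")
    missing = [g for g in candidates if g not in p.mean.columns]
    if missing:
        raise ConfigurationError(f"candidate id(s) not in gene universe: {missing}")
    tm = p.mean[target].to_numpy(dtype=float)
    tf = p.fraction[target].to_numpy(dtype=float)
    for name, vec in (("mean", tm), ("fraction", tf)):
        if np.ptp(vec) == 0:
            raise ZeroVarianceError(f"target {target!r} has zero variance in the {name} matrix")
    rows = []
    for g in candidates:
        try:
            r_cpm = pearson(tm, p.mean[g].to_numpy(dtype=float))
            r_frac = pearson(tf, p.fraction[g].to_numpy(dtype=float))
            score = (r_cpm + r_frac) / 2.0
        except ZeroVarianceError:
            log.warning("candidate %s has zero variance; score undefined", g)
            r_cpm = r_frac = score = np.nan
        rows.append((g, r_cpm, r_frac, score))
    return pd.DataFrame(rows, columns=["gene_id", "r_cpm", "r_frac", "score"])


def rank_candidates(results: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Ascending stable sort by score (ties by gene_id); return the top_k with ranks."""
    defined = results.dropna(subset=["score"])
    if defined.empty:
        raise ValidationError("no candidate has a defined score")
    n_undef = len(results) - len(defined)
    if n_undef:
        log.info("excluding %d candidate(s) with undefined scores from ranking", n_undef)
    ordered = defined.sort_values(["score", "gene_id"], kind="stable").reset_index(drop=True)
    out = ordered.head(min(top_k, len(ordered))).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def ingest_iptm(table: pd.DataFrame | Iterable[tuple[str, Sequence[float]]]) -> pd.DataFrame:
    """Average per-model ipTM scores and sort candidates by confidence.

    Accepts either an iterable of (gene_id, [model scores]) or a DataFrame
    with a ``gene_id`` column and one ``model_*`` column per predicted model
    (missing models allowed). Returns gene_id, model_iptms, mean_iptm sorted
    descending by mean_iptm.
    """
    if isinstance(table, pd.DataFrame):
        if "gene_id" not in table.columns:
            raise ValidationError("ipTM table needs a gene_id column")
        model_cols = [c for c in table.columns if c.startswith("model")]
        if not model_cols:
            raise ValidationError("ipTM table needs model_* columns")
        records = [
            (row["gene_id"], [v for v in row[model_cols].tolist() if pd.notna(v)])
            for _, row in table.iterrows()
        ]
    else:
        records = [(g, list(scores)) for g, scores in table]
    rows = []
    for gene, scores in records:
        if len(scores) == 0:
            raise ValidationError(f"{gene}: at least one model ipTM required")
        scores = [float(s) for s in scores]
        if any(not 0.0 <= s <= 1.0 for s in scores):
            raise ValidationError(f"{gene}: ipTM scores must lie in [0, 1]")
        rows.append((gene, scores, float(np.mean(scores))))
    out = pd.DataFrame(rows, columns=["gene_id", "model_iptms", "mean_iptm"])
    return out.sort_values(
        ["mean_iptm", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def run_screen(
    p: SubtypeProfiles,
    target: str,
    csm_ids: Sequence[str],
    *,
    top_k: int = 10,
    min_mean: float = 3.0,
    min_frac: float = 0.5,
    joint_filter: bool = True,
    iptm: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Full screen: gate CSMs, score, rank, and merge structure confidence.

    Returns a dict with ``results`` (all gated candidates with scores and a
    passed_filter flag), ``top`` (the ranked shortlist) and, when an ipTM
    table is supplied, ``merged`` (shortlist joined with mean_iptm).
    """
    passed = filter_csms(p, csm_ids, min_mean=min_mean, min_frac=min_frac, joint=joint_filter)
    candidates = [g for g in passed if g != target]
    if not candidates:
        raise ValidationError("no filter-passing CSM candidates besides the target")
    results = anticorr_scores(p, target, candidates)
    results["passed_filter"] = True
    skipped = [g for g in csm_ids if g not in passed and g != target]
    if skipped:
        results = pd.concat(
            [
                results,
                pd.DataFrame(
                    {
                        "gene_id": skipped,
                        "r_cpm": np.nan,
                        "r_frac": np.nan,
                        "score": np.nan,
                        "passed_filter": False,
                    }
                ),
            ],
            ignore_index=True,
        )
    top = rank_candidates(results[results["passed_filter"]], top_k=top_k)
    out = {"results": results, "top": top}
    if iptm is not None:
        ranked_iptm = ingest_iptm(iptm)
        out["merged"] = top.merge(
            ranked_iptm[["gene_id", "mean_iptm"]], on="gene_id", how="left"
        )
    return out
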