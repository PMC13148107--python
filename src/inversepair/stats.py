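"""Statistical procedures for penetrance and binding comparisons.

Covers the study's inferential toolkit: two-sided Fisher exact tests on 2x2
contingency tables (probability method), Benjamini-Hochberg FDR over a family
of p-values, the Sidak adjustment, a balanced repeated-measures two-factor
ANOVA with Sidak-adjusted pairwise contrasts, Pearson correlation of
mis-innervation frequency vectors, and penetrance summarization with a strict
>20% "primary destination" rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError, ZeroVarianceError


@dataclass(frozen=True)
class PenetranceRecord:
    """Clone-scoring tallies for one genotype.

    ``n_total`` antennal lobes examined, ``n_mistargeted`` scored as
    mistargeted, plus per-glomerulus mis-innervation counts.
    """

    genotype: str
    n_total: int
    n_mistargeted: int
    per_glomerulus: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")
        if not 0 <= self.n_mistargeted <= self.n_total:
            raise ValidationError("n_mistargeted must lie in [0, n_total]")
        for g, c in self.per_glomerulus.items():
            if not 0 <= c <= self.n_total:
                raise ValidationError(f"glomerulus {g}: count {c} exceeds n_total")

    @property
    def penetrance(self) -> float:
        return self.n_mistargeted / self.n_total


def significance_stars(p: float) -> str:
    """Display convention: *p<0.05, **p<0.01, ***p<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table by the probability method.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (with a small
    relative tolerance for floating-point ties). Degenerate margins give p=1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValidationError("table entries must be non-negative integers")
    if t.sum() == 0:
        raise ValidationError("at least one margin must be positive")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must lie in [0, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def _f_p(ss_effect: float, df_effect: int, ss_error: float, df_error: int) -> tuple[float, float]:
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    if ms_error <= 1e-300:
        if ms_effect <= 1e-300:
            return 0.0, 1.0
        return np.inf, 0.0
    f = ms_effect / ms_error
    return float(f), float(sps.f.sf(f, df_effect, df_error))


def rm_two_way_anova(
    data: pd.DataFrame,
    *,
    subject: str = "subject",
    factor_a: str = "group",
    factor_b: str = "construct",
    response: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated-measures two-way ANOVA on a balanced complete design.

    Both factors vary within subject (one observation per subject x A x B
    cell). Each effect is tested against its interaction with subjects:
    F_A = MS_A / MS_{AxS}, F_B = MS_B / MS_{BxS}, F_{AB} = MS_{AB} / MS_{ABxS}.
    Pairwise A contrasts (paired t over subjects) are run within each B level
    and Sidak-adjusted across the family.

    Returns (effects table, contrasts table).
    """
    cols = [subject, factor_a, factor_b, response]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValidationError(f"missing column(s): {missing_cols}")
    d = data[cols].copy()
    subjects = sorted(d[subject].unique())
    a_levels = sorted(d[factor_a].unique())
    b_levels = sorted(d[factor_b].unique())
    expected = {(s, a, b) for s in subjects for a in a_levels for b in b_levels}
    observed = {tuple(r) for r in d[[subject, factor_a, factor_b]].itertuples(index=False)}
    if expected != observed or len(d) != len(expected):
        missing = sorted(expected - observed)
        raise ValidationError(f"design must be balanced and complete; missing cells: {missing}")

    y = d.set_index([subject, factor_a, factor_b])[response].astype(float)
    cube = np.array(
        [[[y[(s, a, b)] for b in b_levels] for a in a_levels] for s in subjects]
    )  # (S, A, B)
    S, A, B = cube.shape
    gm = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_a = S * B * ((m_a - gm) ** 2).sum()
    ss_b = S * A * ((m_b - gm) ** 2).sum()
    ss_ab = S * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_as = B * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_bs = A * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    resid = (
        cube
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - gm
    )
    ss_abs = (resid**2).sum()

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in [
        (factor_a, ss_a, A - 1, ss_as, (A - 1) * (S - 1)),
        (factor_b, ss_b, B - 1, ss_bs, (B - 1) * (S - 1)),
        (f"{factor_a}:{factor_b}", ss_ab, (A - 1) * (B - 1), ss_abs, (A - 1) * (B - 1) * (S - 1)),
    ]:
        f, p = _f_p(ss_eff, df_eff, ss_err, df_err)
        rows.append(
            {"effect": name, "ss": float(ss_eff), "df": df_eff, "F": f, "p": p}
        )
    effects = pd.DataFrame(rows)

    contrasts = []
    n_family = len(b_levels) * (A * (A - 1) // 2)
    for b in b_levels:
        for i in range(A):
            for j in range(i + 1, A):
                xi = cube[:, i, b_levels.index(b)]
                xj = cube[:, j, b_levels.index(b)]
                diff = xi - xj
                if np.allclose(diff, diff[0]):
                    # paired t undefined when all differences are equal
                    p_raw = 1.0 if np.allclose(diff, 0) else 0.0
                    tstat = 0.0 if np.allclose(diff, 0) else np.inf
                else:
                    tstat, p_raw = sps.ttest_rel(xi, xj)
                contrasts.append(
                    {
                        "comparison": f"{a_levels[i]} vs {a_levels[j]} | {factor_b}={b}",
                        "statistic": float(tstat),
                        "p": float(p_raw),
                        "p_adj": sidak_adjust(float(p_raw), n_family),
                        "method": "paired t, Sidak",
                    }
                )
    contrasts = pd.DataFrame(contrasts)
    if not contrasts.empty:
        contrasts["stars"] = contrasts["p_adj"].map(significance_stars)
    return effects, contrasts


def penetrance_summary(
    records: Sequence[PenetranceRecord], primary_threshold: float = 0.20
) -> dict[str, pd.DataFrame]:
    """Penetrance table, per-glomerulus frequencies, and pairwise Fisher tests.

    Glomeruli with mis-innervation frequency strictly above
    ``primary_threshold`` are flagged as primary destinations. All pairwise
    genotype comparisons (mistargeted vs correctly targeted) use the
    two-sided Fisher exact test with BH adjustment over the family of
    pairwise tests submitted here.
    """
    if not records:
        raise ValidationError("no penetrance records given")
    summary = pd.DataFrame(
        {
            "genotype": [r.genotype for r in records],
            "n_total": [r.n_total for r in records],
            "n_mistargeted": [r.n_mistargeted for r in records],
            "penetrance": [r.penetrance for r in records],
        }
    )
    glom_rows = []
    for r in records:
        for g, c in sorted(r.per_glomerulus.items()):
            freq = c / r.n_total
            glom_rows.append(
                {
                    "genotype": r.genotype,
                    "glomerulus": g,
                    "count": c,
                    "frequency": freq,
                    "primary": freq > primary_threshold,
                }
            )
    glomeruli = pd.DataFrame(glom_rows)

    tests = pd.DataFrame(
        columns=["comparison", "statistic", "p", "p_adj", "method", "stars"]
    )
    if len(records) >= 2:
        rows = []
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                a, b = records[i], records[j]
                table = [
                    [a.n_mistargeted, a.n_total - a.n_mistargeted],
                    [b.n_mistargeted, b.n_total - b.n_mistargeted],
                ]
                p = fisher_exact_2x2(table)
                odds = sps.fisher_exact(np.asarray(table))[0]
                rows.append(
                    {
                        "comparison": f"{a.genotype} vs {b.genotype}",
                        "statistic": float(odds),
                        "p": p,
                    }
                )
        tests = pd.DataFrame(rows)
        tests["p_adj"] = bh_fdr(tests["p"].to_numpy())
        tests["method"] = "Fisher exact (two-sided), BH"
        tests["stars"] = tests["p_adj"].map(significance_stars)
    return {"summary": summary, "glomeruli": glomeruli, "tests": tests}


def frequency_correlation(
    freq_a: pd.Series | Sequence[float], freq_b: pd.Series | Sequence[float]
) -> float:
    """Pearson r between two per-glomerulus mis-innervation frequency vectors."""
    if isinstance(freq_a, pd.Series) and isinstance(freq_b, pd.Series):
        shared = freq_a.index.intersection(freq_b.index)
        if len(shared) != len(freq_a) or len(shared) != len(freq_b):
            raise ValidationError("frequency vectors must cover the same glomeruli")
        a = freq_a.loc[shared].to_numpy(dtype=float)
        b = freq_b.loc[shared].to_numpy(dtype=float)
    else:
        a = np.asarray(freq_a, dtype=float)
        b = np.asarray(freq_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValidationError("need aligned vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("frequency vector has zero variance")
    return float(sps.pearsonr(a, b)[0])


# ------------------------------------------------------------------
# clone-table CSV round-trip (schema: genotype,n_total,n_mistargeted,
# glomerulus,glomerulus_count — one row per genotype x glomerulus)
# ------------------------------------------------------------------

def write_clone_table(records: Sequence[PenetranceRecord], path) -> None:
    from ._util import atomic_open

    rows = []
    for r in records:
        if r.per_glomerulus:
            for g, c in sorted(r.per_glomerulus.items()):
                rows.append((r.genotype, r.n_total, r.n_mistargeted, g, c))
        else:
            rows.append((r.genotype, r.n_total, r.n_mistargeted, "", 0))
    df = pd.DataFrame(
        rows, columns=["genotype", "n_total", "n_mistargeted", "glomerulus", "glomerulus_count"]
    )
    with atomic_open(path) as fh:
        df.to_csv(fh, index=False)


def read_clone_table(path) -> list[PenetranceRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for genotype, grp in df.groupby("genotype", sort=True):
        n_total = int(grp["n_total"].iloc[0])
        n_mis = int(grp["n_mistargeted"].iloc[0])
        per_glom = {
            str(row.glomerulus): int(row.glomerulus_count)
            for row in grp.itertuples()
            if str(row.glomerulus)
        }
        records.append(
            PenetranceRecord(
                genotype=str(genotype), n_total=n_total, n_mistargeted=n_mis,
                per_glomerulus=per_glom,
            )
        )
    return records
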