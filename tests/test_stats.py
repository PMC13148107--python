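"""Fisher/BH/Sidak/ANOVA against enumeration and independent implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from inversepair.errors import ValidationError, ZeroVarianceError
from inversepair.stats import (
    PenetranceRecord,
    bh_fdr,
    fisher_exact_2x2,
    frequency_correlation,
    penetrance_summary,
    read_clone_table,
    rm_two_way_anova,
    sidak_adjust,
    significance_stars,
    write_clone_table,
)


def fisher_enumeration_oracle(table, rel_tol=1e-7):
    """Two-sided Fisher p by exhaustive enumeration over the free cell."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: sps.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + rel_tol))


class TestFisher:
    def test_balanced_table_gives_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_example(self):
        # margins 3/3: probabilities {1,9,9,1}/20, extremes sum to 0.1
        assert fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_degenerate_margin_gives_p_one(self):
        assert fisher_exact_2x2([[0, 0], [4, 7]]) == pytest.approx(1.0)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_matches_enumeration_on_all_small_tables(self):
        # every 2x2 table whose row and column margins are all <= 12
        checked = 0
        for a, b, c, d in itertools.product(range(13), repeat=4):
            if a + b > 12 or c + d > 12 or a + c > 12 or b + d > 12:
                continue
            if a + b + c + d == 0:
                continue
            table = [[a, b], [c, d]]
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_enumeration_oracle(table), rel=1e-9, abs=1e-12
            ), table
            checked += 1
        assert checked > 5000

    def test_invariant_to_transpose_and_row_swap(self, rng):
        for _ in range(30):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            p = fisher_exact_2x2(t)
            assert fisher_exact_2x2(t.T) == pytest.approx(p)
            assert fisher_exact_2x2(t[::-1]) == pytest.approx(p)


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_stepup_arithmetic_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_stepup_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 15))
            adj = bh_fdr(p)
            order = np.argsort(p)
            m = len(p)
            # classic step-up: p_adj(i) = min_{j>=i} m*p(j)/j on the sorted list
            sorted_adj = np.minimum.accumulate(
                (m * p[order] / np.arange(1, m + 1))[::-1]
            )[::-1]
            sorted_adj = np.minimum(sorted_adj, 1.0)
            expected = np.empty(m)
            expected[order] = sorted_adj
            np.testing.assert_allclose(adj, expected, rtol=1e-12)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, 40)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_rejection_set_matches_classic_rule(self, rng):
        q = 0.1
        for _ in range(10):
            p = rng.uniform(0, 0.5, 12)
            adj = bh_fdr(p)
            srt = np.sort(p)
            below = np.nonzero(srt <= q * np.arange(1, 13) / 12)[0]
            k = below.max() + 1 if below.size else 0
            classic = set(np.argsort(p)[:k])
            assert set(np.nonzero(adj <= q)[0]) == classic


class TestSidak:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.2, 1, 0.2), (0.01, 3, 0.029701), (1.0, 5, 1.0), (0.0, 4, 0.0)],
    )
    def test_formula(self, p, m, expected):
        assert sidak_adjust(p, m) == pytest.approx(expected)


def _balanced_fixture(rng, effect=0.0):
    rows = []
    for s in range(3):
        subj_eff = rng.normal(0, 2)
        for a in ("control", "transfected"):
            for b in ("WT", "mut"):
                mu = 10 + subj_eff + (effect if (a == "transfected" and b == "WT") else 0)
                rows.append((f"s{s}", a, b, mu + rng.normal(0, 0.5)))
    return pd.DataFrame(rows, columns=["subject", "group", "construct", "value"])


class TestRmAnova:
    def test_all_equal_responses_give_f_zero_p_one(self):
        rows = [
            (f"s{s}", a, b, 5.0)
            for s in range(3)
            for a in ("x", "y")
            for b in ("u", "v")
        ]
        df = pd.DataFrame(rows, columns=["subject", "group", "construct", "value"])
        effects, _ = rm_two_way_anova(df)
        assert (effects["F"] == 0).all()
        assert (effects["p"] == 1).all()

    def test_pure_subject_effect_absorbed_by_blocking(self, rng):
        rows = [
            (f"s{s}", a, b, 10.0 * s)
            for s in range(4)
            for a in ("x", "y")
            for b in ("u", "v")
        ]
        df = pd.DataFrame(rows, columns=["subject", "group", "construct", "value"])
        effects, _ = rm_two_way_anova(df)
        assert (effects["F"] == 0).all()

    def test_missing_cell_rejected(self, rng):
        df = _balanced_fixture(rng).iloc[:-1]
        with pytest.raises(ValidationError, match="missing"):
            rm_two_way_anova(df)

    def test_matches_pingouin_on_random_fixture(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = _balanced_fixture(rng, effect=3.0)
        effects, _ = rm_two_way_anova(df)
        ref = pingouin.rm_anova(
            data=df, dv="value", within=["group", "construct"], subject="subject",
            detailed=True,
        )
        ref_map = {
            "group": "group", "construct": "construct",
            "group * construct": "group:construct",
        }
        mine = effects.set_index("effect")
        for _, row in ref.iterrows():
            name = ref_map[row["Source"]]
            assert mine.loc[name, "F"] == pytest.approx(row["F"], rel=1e-6)
            assert mine.loc[name, "p"] == pytest.approx(row["p_unc"], rel=1e-6)

    def test_contrasts_sidak_adjusted(self, rng):
        df = _balanced_fixture(rng, effect=5.0)
        _, contrasts = rm_two_way_anova(df)
        assert len(contrasts) == 2  # one A contrast per construct level
        for _, row in contrasts.iterrows():
            assert row["p_adj"] == pytest.approx(sidak_adjust(row["p"], 2))


class TestPenetrance:
    def test_basic_penetrance_ratio(self):
        rec = PenetranceRecord("g", n_total=10, n_mistargeted=7)
        assert rec.penetrance == pytest.approx(0.7)

    def test_primary_destination_threshold_is_strict(self):
        recs = [
            PenetranceRecord(
                "g", 10, 6, per_glomerulus={"at": 2, "above": 3, "below": 1}
            )
        ]
        out = penetrance_summary(recs)["glomeruli"].set_index("glomerulus")
        assert not out.loc["at", "primary"]          # exactly 20%
        assert out.loc["above", "primary"]
        assert not out.loc["below", "primary"]

    def test_pairwise_tests_cover_all_pairs_with_bh(self):
        recs = [
            PenetranceRecord("a", 30, 2),
            PenetranceRecord("b", 30, 25),
            PenetranceRecord("c", 30, 5),
        ]
        tests = penetrance_summary(recs)["tests"]
        assert len(tests) == 3
        np.testing.assert_allclose(tests["p_adj"], bh_fdr(tests["p"].to_numpy()))

    def test_clone_table_csv_roundtrip(self, tmp_path):
        recs = [
            PenetranceRecord("ctl", 40, 3, per_glomerulus={"DA4l": 1}),
            PenetranceRecord("mut", 35, 30, per_glomerulus={"DA4l": 22, "VA1v": 8}),
        ]
        path = tmp_path / "clones.csv"
        write_clone_table(recs, path)
        back = read_clone_table(path)
        assert back == sorted(recs, key=lambda r: r.genotype)

    def test_stars_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == "ns"


class TestFrequencyCorrelation:
    def test_identity_and_reflection(self, rng):
        f = pd.Series(rng.uniform(0, 1, 8), index=[f"G{i}" for i in range(8)])
        assert frequency_correlation(f, f) == pytest.approx(1.0)
        assert frequency_correlation(f, 1.0 - f) == pytest.approx(-1.0)

    def test_matches_formula_oracle(self, rng):
        for _ in range(10):
            a, b = rng.uniform(0, 1, size=(2, 6))
            num = ((a - a.mean()) * (b - b.mean())).sum()
            den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
            assert frequency_correlation(a, b) == pytest.approx(num / den)

    def test_zero_variance_signaled(self):
        with pytest.raises(ZeroVarianceError):
            frequency_correlation([0.2, 0.2, 0.2], [0.1, 0.5, 0.9])
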