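"""TPS quantification, discretization, kappa, ICC, Bland-Altman, majority vote."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.inter_rater import cohens_kappa

from pdl1bench import (
    CellClass,
    TPSUndefinedError,
    bland_altman,
    compute_tps,
    discretize_tps,
    icc_2_1,
    kappa_at_cutoff,
    linear_kappa,
    majority_vote_agreement,
)
from conftest import make_set
from oracle_utils import icc_2_1_manual, weighted_kappa_exact


def codes_from_table(table):
    """Expand a contingency table into two parallel rating vectors."""
    a, b = [], []
    for i, row in enumerate(table):
        for j, n in enumerate(row):
            a += [i] * n
            b += [j] * n
    return a, b


class TestComputeTPS:
    def test_definition_ignores_other_cells(self):
        pts = (
            [(float(i), 0.0) for i in range(30)],
            [CellClass.POS_TUMOR] * 30,
        )
        coords = pts[0] + [(float(i), 10.0) for i in range(70)] + [(float(i), 20.0) for i in range(500)]
        labels = pts[1] + [CellClass.NEG_TUMOR] * 70 + [CellClass.OTHER] * 500
        rec = compute_tps(make_set(coords, labels))
        assert rec.tps_pct == pytest.approx(30.0)
        assert (rec.n_pos_tumor, rec.n_neg_tumor) == (30, 70)

    def test_zero_positive_is_zero_not_error(self):
        coords = [(float(i), 0.0) for i in range(10)]
        rec = compute_tps(make_set(coords, [CellClass.NEG_TUMOR] * 10))
        assert rec.tps_pct == 0.0

    def test_no_tumor_cells_raises_undefined(self):
        coords = [(float(i), 0.0) for i in range(50)]
        with pytest.raises(TPSUndefinedError):
            compute_tps(make_set(coords, [CellClass.OTHER] * 50))

    def test_scale_invariance_of_counts(self):
        base = make_set([(float(i), 0.0) for i in range(8)],
                        [CellClass.POS_TUMOR] * 2 + [CellClass.NEG_TUMOR] * 6)
        tripled = make_set([(float(i), 0.0) for i in range(24)],
                           ([CellClass.POS_TUMOR] * 2 + [CellClass.NEG_TUMOR] * 6) * 3)
        assert compute_tps(base).tps_pct == pytest.approx(compute_tps(tripled).tps_pct)


class TestDiscretize:
    @pytest.mark.parametrize(
        "tps,code",
        [(0.0, 0), (0.5, 0), (0.999, 0), (1.0, 1), (25.0, 1), (49.999, 1), (50.0, 2), (100.0, 2)],
    )
    def test_clinical_cutoff_boundaries(self, tps, code):
        assert discretize_tps(tps) == code

    def test_mapping_total_and_monotone(self):
        grid = np.linspace(0, 100, 2001)
        codes = [discretize_tps(t) for t in grid]
        assert sorted(codes) == codes
        assert set(codes) == {0, 1, 2}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discretize_tps(101.0)


class TestLinearKappa:
    def test_identical_ratings_give_one(self):
        r = [0, 1, 2, 1, 0, 2]
        assert linear_kappa(r, r) == 1.0

    def test_hand_worked_table_exact_rational_oracle(self):
        table = [[5, 2, 0], [1, 7, 1], [0, 2, 6]]
        a, b = codes_from_table(table)
        want = float(weighted_kappa_exact(table, linear=True))
        assert linear_kappa(a, b) == pytest.approx(want, abs=1e-10)

    def test_agrees_with_statsmodels_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            table = rng.integers(1, 8, size=(3, 3))
            a, b = codes_from_table(table.tolist())
            want = cohens_kappa(table.astype(float), wt="linear").kappa
            assert linear_kappa(a, b) == pytest.approx(want, abs=1e-12)

    def test_chance_level_independent_ratings_near_zero(self):
        rng = np.random.default_rng(123)
        a = rng.integers(0, 3, 10000)
        b = rng.integers(0, 3, 10000)
        assert abs(linear_kappa(a, b)) < 0.03

    def test_binary_linear_equals_unweighted(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            table = rng.integers(1, 10, size=(2, 2))
            a, b = codes_from_table(table.tolist())
            want = cohens_kappa(table.astype(float)).kappa
            assert linear_kappa(a, b, n_categories=2) == pytest.approx(want, abs=1e-12)

    def test_degenerate_marginals_convention(self):
        assert linear_kappa([1, 1, 1], [1, 1, 1]) == 1.0
        assert math.isnan(linear_kappa([1, 1, 1], [1, 2, 1]))


class TestKappaAtCutoff:
    def test_printed_two_by_two_table(self):
        # {{20,5},{5,20}}: po = 0.8, pe = 0.5 -> kappa = 0.6.
        a, b = codes_from_table([[20, 5], [5, 20]])
        tps_a = [0.0 if x == 0 else 80.0 for x in a]
        tps_b = [0.0 if x == 0 else 80.0 for x in b]
        assert kappa_at_cutoff(tps_a, tps_b, 50.0) == pytest.approx(0.6, abs=1e-12)

    def test_all_same_side_is_undefined(self):
        assert math.isnan(kappa_at_cutoff([10, 20, 30], [12, 28, 33], 50.0))

    def test_perfect_agreement_both_categories_present(self):
        assert kappa_at_cutoff([0.5, 70.0], [0.0, 90.0], 50.0) == 1.0

    def test_cutoff_boundary_is_inclusive(self):
        # 1.0 counts as positive at the 1% cutoff on both sides.
        assert kappa_at_cutoff([1.0, 0.0], [1.0, 0.5], 1.0) == 1.0


class TestICC:
    def test_identical_raters_varying_cases_give_one(self):
        x = np.tile(np.array([[10.0], [30.0], [70.0], [90.0]]), (1, 3))
        res = icc_2_1(x)
        assert res.value == 1.0
        assert res.ci_low == 1.0 and res.ci_high == 1.0

    def test_hand_entered_matrix_matches_manual_anova(self):
        x = [
            [9.0, 2.0, 5.0],
            [6.0, 1.0, 3.0],
            [8.0, 4.0, 6.0],
            [7.0, 1.0, 2.0],
            [10.0, 5.0, 6.0],
            [6.0, 2.0, 4.0],
        ]
        want, msr, msc, mse = icc_2_1_manual(x)
        res = icc_2_1(np.array(x))
        assert res.value == pytest.approx(want, abs=1e-10)
        assert res.msr == pytest.approx(msr, abs=1e-10)
        assert res.msc == pytest.approx(msc, abs=1e-10)
        assert res.mse == pytest.approx(mse, abs=1e-10)

    def test_matches_pingouin_value_and_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1)) * 2.0
        res = icc_2_1(x)
        n, k = x.shape
        df = pd.DataFrame({
            "case": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "y": x.ravel(),
        })
        icc_tab = pg.intraclass_corr(df, targets="case", raters="rater", ratings="y")
        row = icc_tab[icc_tab["Type"] == "ICC(A,1)"].iloc[0]
        assert res.value == pytest.approx(float(row["ICC"]), abs=1e-9)
        lo, hi = row["CI95"]
        assert res.ci_low == pytest.approx(float(lo), abs=0.02)
        assert res.ci_high == pytest.approx(float(hi), abs=0.02)

    def test_variance_components_recovery(self):
        # raters = case + noise: ICC -> var_case / (var_case + var_noise).
        rng = np.random.default_rng(8)
        var_case, var_noise = 9.0, 4.0
        case = rng.normal(0, math.sqrt(var_case), size=(1000, 1))
        x = case + rng.normal(0, math.sqrt(var_noise), size=(1000, 4))
        res = icc_2_1(x)
        assert res.value == pytest.approx(var_case / (var_case + var_noise), abs=0.03)

    def test_invariant_under_shift_and_scale(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(20, 3)) + rng.normal(size=(20, 1))
        base = icc_2_1(x).value
        assert icc_2_1(x + 100.0).value == pytest.approx(base, abs=1e-9)
        assert icc_2_1(x * 7.0).value == pytest.approx(base, abs=1e-9)

    def test_zero_between_case_variance_undefined(self):
        x = np.ones((5, 3))
        assert math.isnan(icc_2_1(x).value)

    def test_rows_with_missing_values_dropped_and_counted(self):
        x = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0], [7.0, 8.0]])
        res = icc_2_1(x)
        assert res.n_dropped == 1 and res.n_cases == 3


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_diff == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)

    def test_constant_offset(self):
        a = [10.0, 40.0, 90.0]
        b = [x - 5 for x in a]
        res = bland_altman(a, b)
        assert res.mean_diff == pytest.approx(5.0)
        assert res.sd_diff == 0.0

    def test_three_point_hand_arithmetic(self):
        res = bland_altman([10.0, 20.0, 30.0], [12.0, 18.0, 33.0])
        assert res.mean_diff == pytest.approx(-1.0)
        assert res.sd_diff == pytest.approx(math.sqrt(7.0), abs=1e-12)
        assert res.loa_low == pytest.approx(-1.0 - 1.96 * math.sqrt(7.0), abs=1e-9)
        assert res.loa_low <= res.mean_diff <= res.loa_high


class TestMajorityVote:
    def _table(self, rows, columns):
        return pd.DataFrame(rows, columns=columns)

    def test_simple_majority(self):
        cols = ["P1", "P2", "P3", "P4", "P5", "AI"]
        t = self._table([[80, 80, 80, 10, 10, 80]], cols)
        # One case only is too few for kappa; check the vote logic via ties.
        t2 = self._table([[80, 80, 80, 10, 10, 80], [10, 10, 10, 80, 80, 10]], cols)
        res = majority_vote_agreement(t2, "AI", 50.0, readers=cols[:5])
        assert res.kappa == 1.0
        assert res.n_ties == 0

    def test_target_reader_excluded_from_own_majority(self):
        # P1's own vote would flip the majority; excluding it, the
        # remaining readers vote 'negative' and P1 disagrees.
        cols = ["P1", "P2", "P3", "P4"]
        rows = [[80, 80, 10, 10], [10, 10, 80, 80]]
        t = self._table(rows, cols)
        res = majority_vote_agreement(t, "P1", 50.0, readers=cols, tie_rule="drop")
        # without P1: votes are (80,10,10) -> neg and (10,80,80) -> pos;
        # P1 rated pos then neg -> complete disagreement.
        assert res.n_ties == 0
        assert res.kappa == pytest.approx(-1.0)

    def test_ties_counted_and_dropped(self):
        cols = ["P1", "P2", "P3", "P4", "AI"]
        rows = [
            [80, 80, 10, 10, 80],  # tie among the 4 readers
            [80, 80, 80, 10, 80],
            [10, 10, 10, 80, 10],
        ]
        t = self._table(rows, cols)
        res = majority_vote_agreement(t, "AI", 50.0, readers=cols[:4])
        assert res.n_ties == 1
        assert res.n_cases_used == 2
        assert res.kappa == 1.0

    def test_tie_rule_higher_keeps_all_cases(self):
        cols = ["P1", "P2", "P3", "P4", "AI"]
        rows = [[80, 80, 10, 10, 80], [10, 10, 10, 10, 10], [80, 80, 80, 80, 80]]
        t = self._table(rows, cols)
        res = majority_vote_agreement(t, "AI", 50.0, readers=cols[:4], tie_rule="higher")
        assert res.n_cases_used == 3
        assert res.kappa == 1.0

    def test_truthful_reader_attains_highest_majority_kappa(self):
        rng = np.random.default_rng(11)
        n = 300
        truth = rng.uniform(0, 100, n)
        cols = {}
        cols["P1"] = truth.copy()  # always right
        for i in range(2, 6):
            noise = rng.normal(0, 25, n)
            cols[f"P{i}"] = np.clip(truth + noise, 0, 100)
        t = pd.DataFrame(cols)
        readers = list(t.columns)
        kappas = {
            r: majority_vote_agreement(t, r, 50.0, readers=readers).kappa for r in readers
        }
        assert max(kappas, key=kappas.get) == "P1"
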