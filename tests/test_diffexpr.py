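import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.base import clone

from plasmapanel import diffexpr
from plasmapanel.diffexpr import (DEConfig, DifferentialExpressionSelector,
                                  anova_per_protein, consolidate_arms,
                                  default_candidates, pairwise_ttests,
                                  protein_stats, select_candidates,
                                  stage_fold_changes)
from plasmapanel.quantio import total_area_normalize
from plasmapanel.simulate import FixtureConfig, generate_fixture

from conftest import make_matrix, triplicate_conditions


# ---------------------------------------------------------------------------
# independent oracles (hand-coded, loop-based)

def oracle_anova(groups):
    """Brute-force one-way ANOVA from explicit sums of squares."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, float(sps.f.sf(F, df_b, df_w))


def oracle_ttest(a, b, welch=True):
    """Closed-form unpaired t statistic + reference distribution function."""
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    if welch:
        se2 = va / len(a) + vb / len(b)
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / len(a)) ** 2 / (len(a) - 1)
                         + (vb / len(b)) ** 2 / (len(b) - 1))
    else:
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
        t = (ma - mb) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        df = len(a) + len(b) - 2
    return t, float(2 * sps.t.sf(abs(t), df))


def random_log_matrix(seed, n_proteins=100):
    rng = np.random.default_rng(seed)
    vals = 2.0 ** rng.normal(10, 2, size=(n_proteins, 15))
    return make_matrix(vals, triplicate_conditions(), scale="linear_normalized")


class TestStatisticalOracles:
    def test_anova_matches_sum_of_squares_oracle(self):
        m = random_log_matrix(0)
        res = anova_per_protein(m).set_index("protein_id")
        logged = np.log2(m.values.to_numpy())
        for i, pid in enumerate(m.protein_ids):
            groups = [list(logged[i, 3 * j:3 * j + 3]) for j in range(5)]
            F, p = oracle_anova(groups)
            assert abs(res.loc[pid, "F"] - F) < 1e-10 * max(1, abs(F))
            assert abs(res.loc[pid, "p"] - p) < 1e-10

    @pytest.mark.parametrize("variant", ["welch", "student"])
    def test_ttests_match_closed_form_oracle(self, variant):
        m = random_log_matrix(1)
        res = pairwise_ttests(m, variant=variant)
        logged = np.log2(m.values.to_numpy())
        for i, pid in enumerate(m.protein_ids):
            healthy = list(logged[i, 0:3])
            for j, stage in enumerate(("I", "II", "III", "IV"), start=1):
                g = list(logged[i, 3 * j:3 * j + 3])
                t, p = oracle_ttest(g, healthy, welch=(variant == "welch"))
                assert abs(res.loc[pid, f"t_{stage}"] - t) < 1e-10 * max(1, abs(t))
                assert abs(res.loc[pid, f"p_{stage}"] - p) < 1e-10


class TestDegenerateCases:
    def test_identical_groups_give_f_zero_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0], (1, 5))
        m = make_matrix(vals, triplicate_conditions(), scale="linear_normalized")
        res = anova_per_protein(m)
        assert res.loc[0, "F"] == 0.0 and res.loc[0, "p"] == 1.0

    def test_zero_within_variation_gives_p_zero(self):
        vals = np.array([[1.0] * 3 + [2.0] * 3 + [4.0] * 3 + [8.0] * 3 + [16.0] * 3])
        m = make_matrix(vals, triplicate_conditions(), scale="linear_normalized")
        res = anova_per_protein(m)
        assert res.loc[0, "p"] == 0.0

    def test_ttest_constant_groups(self):
        vals = np.array([[2.0, 2.0, 2.0, 2.0, 2.0, 2.0] + [1.0] * 9])  # I == healthy
        m = make_matrix(vals, triplicate_conditions(), scale="linear_normalized")
        res = pairwise_ttests(m)
        assert res.iloc[0]["p_I"] == 1.0      # identical constant groups
        assert res.iloc[0]["p_II"] == 0.0     # distinct constant groups


class TestFoldChanges:
    def test_fc_definition_and_boundary(self):
        # healthy mean 2; stages at mean 3 (FC 1.5), 1 (FC 0.5), 4, 2
        vals = np.array([[2, 2, 2, 3, 3, 3, 1, 1, 1, 4, 4, 4, 2, 2, 2]], dtype=float)
        m = make_matrix(vals, triplicate_conditions(), scale="linear_normalized")
        fc = stage_fold_changes(m).iloc[0]
        assert np.isclose(fc["FC_I"], 1.5) and fc["trend_I"] == 1
        assert np.isclose(fc["FC_II"], 0.5) and fc["trend_II"] == -1
        assert fc["trend_IV"] == 0
        stats = protein_stats(m)
        # max symmetric FC is 2.0 (from FC_II = 0.5), so magnitude passes,
        # but FC 1.5 itself would not pass the strict > 1.5 rule
        assert np.isclose(stats.iloc[0]["max_abs_fc"], 2.0)
        assert max(fc["FC_I"], 1 / fc["FC_I"]) <= 1.5

    def test_zero_healthy_mean_flags_protein(self):
        rng = np.random.default_rng(0)
        vals = np.vstack([[0, 0, 0] + [1.0] * 12,
                          rng.uniform(1, 2, size=15)])
        m = make_matrix(vals, triplicate_conditions(), scale="linear_normalized")
        fc = stage_fold_changes(m)
        assert bool(fc.loc["P0", "undefined_fc"])
        # the zero-healthy protein cannot enter the candidate list: its healthy
        # log-values are all masked, so it is excluded from the ANOVA join
        stats = protein_stats(m)
        assert "P0" not in stats.index
        assert "P0" not in select_candidates(stats).index


class TestSelection:
    def _stats_row(self, anova_p, fcs):
        """protein_stats output for a synthetic triplicate profile."""
        healthy = np.array([100.0, 101.0, 99.0])
        cols = [healthy]
        for fc in fcs:
            cols.append(healthy * fc * np.array([1.0, 1.02, 0.98]))
        vals = np.concatenate(cols)[None, :]
        m = make_matrix(vals, triplicate_conditions(), scale="linear_normalized")
        return protein_stats(m).iloc[0]

    def test_consistent_upregulation_selected(self):
        row = self._stats_row(0.04, (1.6, 1.7, 1.8, 2.0))
        assert row["passes"] and row["direction"] == "up"

    def test_inconsistent_trend_rejected(self):
        row = self._stats_row(0.01, (1.8, 0.7, 1.9, 2.2))
        assert row["consistent_trend"] == False  # noqa: E712
        assert not row["passes"]

    def test_ordering_by_p_then_accession(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(10, 20, size=(30, 15))
        vals[:10] *= np.array([1] * 3 + [4] * 12)[None, :]  # strong DE for 10
        m = make_matrix(vals, triplicate_conditions(), scale="linear_normalized")
        sel = select_candidates(protein_stats(m))
        ps = sel["anova_p"].to_numpy()
        assert (np.diff(ps) >= 0).all()

    def test_fc_threshold_monotonicity(self, single_arm_fixture):
        m, _ = single_arm_fixture
        sets = []
        for fc in (1.2, 1.5, 2.0, 3.0):
            cfg = DEConfig(fc_threshold=fc)
            sets.append(set(select_candidates(protein_stats(m, cfg=cfg), cfg).index))
        for small, large in zip(sets[1:], sets[:-1]):
            assert small <= large

    def test_scale_invariance_of_selection(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(1, 100, size=(40, 15))
        conds = triplicate_conditions()
        m1 = total_area_normalize(make_matrix(vals, conds))
        m2 = total_area_normalize(make_matrix(vals * 1e4, conds))
        s1 = set(select_candidates(protein_stats(m1)).index)
        s2 = set(select_candidates(protein_stats(m2)).index)
        assert s1 == s2


class TestTypeIError:
    def test_null_fixture_anova_rate_near_alpha(self):
        cfg = FixtureConfig(seed=19, n_proteins=600, n_de=0, driver_panel_size=0,
                            arms=("none",), arm_retention=(1.0,),
                            noise_model="lognormal")
        m = generate_fixture(cfg)[0]["none"]
        stats = protein_stats(m)
        alpha = 0.05
        frac = (stats["anova_p"] < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / len(stats))
        assert abs(frac - alpha) < 3 * se
        # the full filter is strictly more stringent than the p criterion alone
        assert stats["passes"].sum() < (stats["anova_p"] < alpha).sum()


class TestConsolidation:
    def _sel(self, pids, direction="up"):
        return pd.DataFrame({"direction": direction, "anova_p": 0.01},
                            index=pd.Index(pids, name="protein_id"))

    def test_same_direction_merged(self):
        table = consolidate_arms({"MARS14": self._sel(["A"]),
                                  "API_MARS14": self._sel(["A"])})
        assert len(table) == 1 and table.iloc[0]["n_arms"] == 2
        assert not table.iloc[0]["conflict_flag"]

    def test_opposite_directions_conflict_flagged(self):
        table = consolidate_arms({"MARS14": self._sel(["A"], "up"),
                                  "none": self._sel(["A"], "down")})
        assert table.iloc[0]["conflict_flag"]
        assert default_candidates(table) == []

    def test_disjoint_lists_union(self):
        table = consolidate_arms({"a": self._sel([f"P{i}" for i in range(10)]),
                                  "b": self._sel([f"Q{i}" for i in range(7)])})
        assert len(table) == 17


class TestSelectorEstimator:
    def _xy(self, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(10, 20, size=(30, 15))
        vals[:5] *= np.array([1] * 3 + [3] * 12)[None, :]
        X = pd.DataFrame(vals.T, columns=[f"P{i}" for i in range(30)])
        y = triplicate_conditions()
        return X, y

    def test_fit_transform_selects_planted_features(self):
        X, y = self._xy()
        sel = DifferentialExpressionSelector().fit(X, y)
        assert set(sel.selected_proteins_) >= {f"P{i}" for i in range(5)}
        Xt = sel.transform(X)
        assert Xt.shape == (15, sel.support_.sum())
        assert list(Xt.columns) == [p for p, s in zip(X.columns, sel.support_) if s]

    def test_clone_and_get_params_roundtrip(self):
        sel = DifferentialExpressionSelector(alpha=0.01, fc_threshold=2.0)
        params = clone(sel).get_params()
        assert params["alpha"] == 0.01 and params["fc_threshold"] == 2.0

    def test_stats_consistent_with_functional_api(self):
        X, y = self._xy(3)
        sel = DifferentialExpressionSelector().fit(X, y)
        m = make_matrix(X.to_numpy().T, y, proteins=list(X.columns),
                        scale="linear_normalized")
        direct = protein_stats(m)
        pd.testing.assert_series_equal(sel.stats_["anova_p"], direct["anova_p"])
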