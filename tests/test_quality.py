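import numpy as np
import pandas as pd
import pytest

from qmarker import datasets, quality


class TestMinMaxNormalize:
    def test_published_anchor_values(self, contents):
        nm = quality.minmax_normalize(contents)
        assert round(nm.loc["S1", "swertiamarin"], 3) == 0.804
        assert nm.loc["S23", "swertiamarin"] == 1.0
        assert nm.loc["S42", "swertiamarin"] == 0.0

    def test_extremes_map_to_unit_interval(self, contents):
        nm = quality.minmax_normalize(contents)
        np.testing.assert_allclose(nm.min(), 0.0, atol=1e-15)
        np.testing.assert_allclose(nm.max(), 1.0, atol=1e-15)

    def test_affine_invariance(self, contents):
        nm1 = quality.minmax_normalize(contents)
        shifted = contents * 7.3 + 11.0
        nm2 = quality.minmax_normalize(shifted)
        np.testing.assert_allclose(nm1.to_numpy(), nm2.to_numpy(), atol=1e-12)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [5.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            quality.minmax_normalize(df)

    def test_cost_criterion_flipped(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        nm = quality.minmax_normalize(df, cost_columns=("a",))
        np.testing.assert_allclose(nm["a"], [1.0, 0.5, 0.0])


class TestProportionMatrix:
    def test_published_anchor_value(self, contents):
        p = quality.proportion_matrix(quality.minmax_normalize(contents))
        assert round(p.loc["S1", "swertiamarin"], 3) == 0.037

    def test_columns_sum_to_one(self, contents):
        p = quality.proportion_matrix(quality.minmax_normalize(contents))
        np.testing.assert_allclose(p.sum(), 1.0)

    def test_binary_column(self):
        p = quality.proportion_matrix(pd.DataFrame({"a": [0.0, 1.0]}))
        np.testing.assert_allclose(p["a"], [0.0, 1.0])

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            quality.proportion_matrix(pd.DataFrame({"a": [0.0, 0.0]}))


class TestEntropyWeights:
    def test_uniform_criterion_gets_zero_weight(self):
        p = pd.DataFrame({"u": [0.25] * 4, "v": [0.97, 0.01, 0.01, 0.01]})
        ew = quality.entropy_weights(p)
        assert ew.weights["u"] == pytest.approx(0.0, abs=1e-12)
        assert ew.weights["v"] == pytest.approx(1.0)

    def test_degenerate_column_has_zero_entropy(self):
        p = pd.DataFrame({"a": [1.0, 0.0], "b": [0.5, 0.5]})
        ew = quality.entropy_weights(p)
        assert ew.entropy["a"] == pytest.approx(0.0, abs=1e-12)

    def test_weights_sum_to_one_on_study_matrix(self, contents):
        p = quality.proportion_matrix(quality.minmax_normalize(contents))
        ew = quality.entropy_weights(p)
        assert ew.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (ew.weights >= 0).all()

    def test_row_permutation_and_duplication_invariance(self, contents):
        def weights_of(df):
            p = quality.proportion_matrix(quality.minmax_normalize(df))
            return quality.entropy_weights(p).weights

        base = weights_of(contents)
        permuted = weights_of(contents.sample(frac=1, random_state=0))
        doubled = weights_of(pd.concat([contents, contents]))
        np.testing.assert_allclose(base, permuted, atol=1e-12)
        np.testing.assert_allclose(base, doubled, atol=1e-12)

    def test_all_uniform_rejected(self):
        p = pd.DataFrame({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        with pytest.raises(ValueError):
            quality.entropy_weights(p)


class TestTopsis:
    def test_ideal_alternative_closeness_one(self):
        nm = pd.DataFrame(
            {"a": [1.0, 0.5, 0.0], "b": [1.0, 0.2, 0.0]}, index=["best", "mid", "worst"]
        )
        res = quality.topsis(nm, pd.Series({"a": 0.5, "b": 0.5}))
        assert res.closeness["best"] == pytest.approx(1.0)
        assert res.closeness["worst"] == pytest.approx(0.0)

    def test_single_criterion_hand_values(self):
        nm = pd.DataFrame({"a": [0.0, 0.5, 1.0]})
        res = quality.topsis(nm, pd.Series({"a": 1.0}))
        np.testing.assert_allclose(res.closeness, [0.0, 0.5, 1.0])

    def test_unnormalized_weights_rejected(self):
        nm = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(ValueError):
            quality.topsis(nm, pd.Series({"a": 0.5}))

    def test_monotone_in_non_extreme_criterion(self, contents):
        # raising a middling batch's content (extremes unchanged) never
        # lowers its closeness
        nm = quality.minmax_normalize(contents)
        w = quality.entropy_weights(quality.proportion_matrix(nm)).weights
        before = quality.topsis(nm, w).closeness["S25"]
        bumped = nm.copy()
        bumped.loc["S25", "gentiopicroside"] += 0.05
        after = quality.topsis(bumped, w).closeness["S25"]
        assert after >= before

    def test_five_by_two_spreadsheet_oracle(self):
        # independent hand computation, spreadsheet style
        x = pd.DataFrame(
            {"c1": [2.0, 4.0, 6.0, 8.0, 10.0], "c2": [1.0, 1.5, 9.0, 3.0, 2.0]},
            index=list("vwxyz"),
        )
        nm = (x - x.min()) / (x.max() - x.min())
        p = nm / nm.sum()
        n = 5
        e = []
        for col in p:
            s = 0.0
            for v in p[col]:
                if v > 0:
                    s += v * np.log(v)
            e.append(-s / np.log(n))
        d = [1 - v for v in e]
        w = np.array(d) / sum(d)
        v = nm * w
        dp = np.sqrt(((v - v.max()) ** 2).sum(axis=1))
        dm = np.sqrt(((v - v.min()) ** 2).sum(axis=1))
        oracle = dm / (dp + dm)
        res = quality.evaluate_topsis(x)
        np.testing.assert_allclose(res.closeness, oracle, atol=1e-6)

    def test_variant_proportion_differs_but_agrees_on_extremes(self, contents):
        a = quality.evaluate_topsis(contents, variant="normalized")
        b = quality.evaluate_topsis(contents, variant="proportion")
        assert a.closeness.idxmax() == b.closeness.idxmax()
        assert a.closeness.idxmin() == b.closeness.idxmin()
        assert not np.allclose(a.closeness, b.closeness)


class TestCompositeScore:
    def test_pc_score_mean_zero_and_constant_ratio(self, contents):
        comp = quality.composite_score(contents)
        assert comp.pc_score.mean() == pytest.approx(0.0, abs=1e-10)
        ratio = comp.score / comp.pc_score
        np.testing.assert_allclose(ratio, comp.variance_proportion, atol=1e-12)

    def test_affine_rescaling_invariance(self, contents):
        base = quality.composite_score(contents).score
        rescaled = contents.copy()
        rescaled["sweroside"] = rescaled["sweroside"] * 1000.0 + 5.0
        again = quality.composite_score(rescaled).score
        np.testing.assert_allclose(base, again, atol=1e-9)

    def test_published_scores_and_ranks(self, contents):
        comp = quality.composite_score(contents)
        published = datasets.load_published_scores()
        # 2-decimal printed values of Y and F
        np.testing.assert_allclose(
            comp.pc_score.round(2), published["pc_score"], atol=0.011
        )
        np.testing.assert_allclose(
            comp.score.round(2), published["composite_score"], atol=0.011
        )


class TestHCAGrade:
    def test_three_separated_blobs_recovered(self, rng):
        centers = {"lo": 5.0, "mid": 50.0, "hi": 200.0}
        frames = []
        truth = []
        for g, c in centers.items():
            frames.append(
                pd.DataFrame(
                    rng.normal(c, 1.0, (8, 3)),
                    columns=["a", "b", "c"],
                    index=[f"{g}{i}" for i in range(8)],
                )
            )
            truth += [g] * 8
        X = pd.concat(frames)
        res = quality.hca_grade(X, k=3)
        labels = res.labels
        for g in centers:
            sub = labels[[i for i in labels.index if i.startswith(g)]]
            assert sub.nunique() == 1
        assert labels[[i for i in labels.index if i.startswith("hi")]].iloc[0] == 1

    def test_duplicated_rows_identical_labels(self, contents):
        dup = pd.concat([contents, contents.loc[["S10"]].rename(index={"S10": "S10b"})])
        res = quality.hca_grade(dup, k=3)
        assert res.labels["S10"] == res.labels["S10b"]

    def test_k_not_smaller_than_n_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            quality.hca_grade(df, k=2)


class TestQualityReport:
    def test_identical_rankings_rho_one(self, contents):
        top = quality.evaluate_topsis(contents)
        comp = quality.composite_score(contents)
        grades = quality.hca_grade(contents, order_by=top.closeness)
        # feed TOPSIS ranks as composite ranks: rho must be exactly 1
        comp.rank = top.rank
        comp.score = top.closeness
        report = quality.quality_report(top, comp, grades)
        assert report.attrs["spearman_rho"] == pytest.approx(1.0)

    def test_reversed_rankings_rho_minus_one(self, contents):
        top = quality.evaluate_topsis(contents)
        comp = quality.composite_score(contents)
        grades = quality.hca_grade(contents, order_by=top.closeness)
        comp.rank = (len(contents) + 1) - top.rank
        report = quality.quality_report(top, comp, grades)
        assert report.attrs["spearman_rho"] == pytest.approx(-1.0)

    def test_study_table_rank_1_agrees_across_methods(self, contents):
        top = quality.evaluate_topsis(contents)
        comp = quality.composite_score(contents)
        grades = quality.hca_grade(contents, order_by=top.closeness)
        report = quality.quality_report(top, comp, grades)
        best_topsis = report["topsis_rank"].idxmin()
        best_composite = report["composite_rank"].idxmin()
        assert best_topsis == best_composite == "S10"

    def test_mismatched_ids_rejected(self, contents):
        top = quality.evaluate_topsis(contents)
        comp = quality.composite_score(contents.rename(index={"S1": "X1"}))
        grades = quality.hca_grade(contents, order_by=top.closeness)
        with pytest.raises(ValueError):
            quality.quality_report(top, comp, grades)
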