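"""Association models, signature score, batch correction and survival."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from eccdecon import (
    batch_correct,
    generate_survival,
    km_logrank,
    median_split,
    multivariate_assoc,
    signature_score,
    univariate_assoc,
)


def _attrs(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"p{i}" for i in range(n)])


class TestUnivariateAssoc:
    def test_identity_attribute(self):
        attrs = _attrs(x=[0.0, 0.25, 0.5, 0.75, 1.0])
        resp = attrs["x"].copy()
        out = univariate_assoc(attrs, resp)
        assert out.loc[0, "estimate"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] < 1e-10

    def test_three_point_toy(self):
        attrs = _attrs(x=[0.0, 1.0, 2.0])
        out = univariate_assoc(attrs, attrs["x"] * 1.0)
        assert out.loc[0, "estimate"] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_ols_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.1, 0.9, 0.5, 0.8, 0.6, 1.0])
        out = univariate_assoc(_attrs(x=x), pd.Series(y, index=_attrs(x=x).index))
        # hand-computed least squares: slope, then t-test on the slope
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt(resid @ resid / (len(x) - 2) / np.sum((x - x.mean()) ** 2))
        t = slope / se
        p = 2 * scipy.stats.t.sf(abs(t), len(x) - 2)
        assert out.loc[0, "estimate"] == pytest.approx(slope, abs=1e-10)
        assert out.loc[0, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_constant_shift_invariance(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = pd.Series([0.2, 0.8, 0.4, 1.0, 0.5],
                      index=[f"p{i}" for i in range(5)])
        a = univariate_assoc(_attrs(x=x), y)
        b = univariate_assoc(_attrs(x=x + 100.0), y)
        assert a.loc[0, "estimate"] == pytest.approx(b.loc[0, "estimate"])
        assert a.loc[0, "p_value"] == pytest.approx(b.loc[0, "p_value"])

    def test_zero_variance_skipped(self, caplog):
        attrs = _attrs(flat=[1.0, 1.0, 1.0], x=[0.0, 1.0, 2.0])
        with caplog.at_level("WARNING"):
            out = univariate_assoc(attrs, pd.Series([0.0, 0.5, 1.0],
                                                    index=attrs.index))
        assert list(out["term"]) == ["x"]


class TestMultivariateAssoc:
    def test_signal_on_one_of_two_orthogonalish_attrs(self):
        rng = np.random.default_rng(0)
        n = 50
        attrs = _attrs(a=rng.normal(size=n), b=rng.normal(size=n))
        resp = pd.Series(attrs["a"] + 0.05 * rng.normal(size=n),
                         index=attrs.index)
        out = multivariate_assoc(attrs, resp).set_index("term")
        assert out.loc["a", "p_value"] < 1e-10
        assert out.loc["b", "p_value"] > 0.01

    def test_duplicated_attribute_raises(self):
        attrs = _attrs(a=[1.0, 2.0, 3.0, 4.0])
        attrs["b"] = attrs["a"]
        with pytest.raises(ValueError, match="collinear"):
            multivariate_assoc(attrs, pd.Series([1.0, 2.0, 3.0, 4.0],
                                                index=attrs.index))

    def test_single_attribute_matches_univariate(self):
        rng = np.random.default_rng(1)
        attrs = _attrs(x=rng.random(20))
        resp = pd.Series(rng.random(20), index=attrs.index)
        multi = multivariate_assoc(attrs, resp)
        uni = univariate_assoc(attrs, resp)
        assert multi.loc[0, "estimate"] == pytest.approx(
            uni.loc[0, "estimate"], abs=1e-10)
        assert multi.loc[0, "p_value"] == pytest.approx(
            uni.loc[0, "p_value"], abs=1e-10)

    def test_exclusions_recorded(self):
        attrs = _attrs(a=[1.0, 2.0, 3.0, 5.0], b=[2.0, 1.0, 4.0, 3.0])
        out = multivariate_assoc(attrs, pd.Series([1.0, 2.0, 3.0, 4.0],
                                                  index=attrs.index),
                                 exclusions=["b"])
        assert out.attrs["excluded"] == ["b"]
        assert list(out["term"]) == ["a"]


class TestSignatureScore:
    def test_zero_weights(self):
        cpm = pd.DataFrame({"s1": [10.0, 20.0]}, index=["g1", "g2"])
        out = signature_score(cpm, {"g1": 0.0, "g2": 0.0})
        assert out["s1"] == 0.0

    def test_single_gene_library(self):
        cpm = pd.DataFrame({"s1": [1e6]}, index=["g1"])
        out = signature_score(cpm, {"g1": 1.0})
        assert out["s1"] == pytest.approx(np.log2(1e6 + 1))

    def test_depth_invariance_via_cpm(self):
        from eccdecon import cpm_normalize

        counts = pd.DataFrame({"s1": [5.0, 15.0], "s2": [50.0, 150.0]},
                              index=["g1", "g2"])
        score = signature_score(cpm_normalize(counts), {"g1": 1.0, "g2": -0.5})
        assert score["s1"] == pytest.approx(score["s2"])

    def test_missing_genes_warned_absent_error(self, caplog):
        cpm = pd.DataFrame({"s1": [10.0]}, index=["g1"])
        with caplog.at_level("WARNING"):
            signature_score(cpm, {"g1": 1.0, "ghost": 2.0})
        assert any("absent" in r.message for r in caplog.records)
        with pytest.raises(ValueError, match="no signature gene"):
            signature_score(cpm, {"ghost": 1.0})


class TestBatchCorrect:
    def _frame(self, arr, batches):
        return (pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])],
                             columns=[f"s{i}" for i in range(arr.shape[1])]),
                pd.Series(batches, index=[f"s{i}" for i in range(arr.shape[1])]))

    def test_additive_shift_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 4))
        arr = np.hstack([base, base + 3.0])
        X, batch = self._frame(arr, ["b1"] * 4 + ["b2"] * 4)
        out = batch_correct(X, batch)
        np.testing.assert_allclose(out.iloc[:, :4].to_numpy(),
                                   out.iloc[:, 4:].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(out.mean(axis=1), X.mean(axis=1),
                                   atol=1e-12)

    def test_identical_batches_unchanged(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(5, 3))
        X, batch = self._frame(np.hstack([base, base]), ["a"] * 3 + ["b"] * 3)
        out = batch_correct(X, batch)
        pd.testing.assert_frame_equal(out, X)

    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(6, 7))
        batches = ["a", "a", "a", "b", "b", "b", "b"]
        X, batch = self._frame(arr, batches)
        out = batch_correct(X, batch)
        grand = arr.mean(axis=1, keepdims=True)
        expected = arr.copy()
        for b in ("a", "b"):
            cols = np.array([x == b for x in batches])
            expected[:, cols] -= (arr[:, cols].mean(axis=1, keepdims=True)
                                  - grand)
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)

    def test_single_batch_warned_noop(self, caplog):
        X, batch = self._frame(np.ones((2, 3)), ["a"] * 3)
        with caplog.at_level("WARNING"):
            out = batch_correct(X, batch)
        pd.testing.assert_frame_equal(out, X)


class TestMedianSplit:
    def test_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        out = median_split(s)
        assert list(out) == ["low", "low", "high", "high"]

    def test_median_tie_goes_low(self):
        out = median_split(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert list(out) == ["low", "low", "high"]

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            median_split(pd.Series([2.0, 2.0]))


class TestKmLogrank:
    def _table(self, times, events, groups):
        return pd.DataFrame({"sample_id": range(len(times)), "time": times,
                             "event": events, "group": groups})

    def test_identical_groups_null(self):
        t = self._table([1.0, 2.0, 3.0] * 2, [1, 1, 0] * 2,
                        ["a"] * 3 + ["b"] * 3)
        res = km_logrank(t)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert res["p_value"] == pytest.approx(1.0)

    def test_matches_hand_computed_logrank(self):
        # group A events at 1, 2; group B events at 3, 4 — explicit O-E/V
        t = self._table([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                        ["A", "A", "B", "B"])
        res = km_logrank(t)
        O_A, E_A, V = 0.0, 0.0, 0.0
        at_risk = {"A": 2, "B": 2}
        for time, grp in [(1, "A"), (2, "A"), (3, "B"), (4, "B")]:
            n = at_risk["A"] + at_risk["B"]
            d = 1
            O_A += 1.0 if grp == "A" else 0.0
            E_A += d * at_risk["A"] / n
            if n > 1:
                V += (d * (at_risk["A"] / n) * (1 - at_risk["A"] / n)
                      * (n - d) / (n - 1))
            at_risk[grp] -= 1
        expected_chi2 = (O_A - E_A) ** 2 / V
        assert res["chi2"] == pytest.approx(expected_chi2, abs=1e-10)
        assert res["p_value"] == pytest.approx(
            scipy.stats.chi2.sf(expected_chi2, 1), abs=1e-10)

    def test_km_curve_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(1.0, size=40)
        t = self._table(np.concatenate([times, times * 0.5]),
                        [1] * 80, ["a"] * 40 + ["b"] * 40)
        res = km_logrank(t)
        curve = res["curves"][res["curves"]["group"] == "a"]
        surv = curve.set_index("time")["survival"]
        assert (surv.diff().dropna() <= 1e-12).all()
        assert surv.iloc[0] == pytest.approx(1.0)
        for time, s in surv.items():
            emp = (times > time).mean()
            assert s == pytest.approx(emp, abs=1e-10)

    def test_power_at_hazard_ratio_four(self):
        # 100 replicates, n=200/arm, no censoring: alpha=0.05 rejections
        rejections = 0
        groups = pd.Series(["a"] * 200 + ["b"] * 200,
                           index=[f"p{i}" for i in range(400)])
        for rep in range(100):
            surv = generate_survival(groups, {"a": 1.0, "b": 4.0}, seed=rep)
            if km_logrank(surv)["p_value"] < 0.05:
                rejections += 1
        assert rejections >= 95

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="missing column"):
            km_logrank(pd.DataFrame({"time": [1.0], "event": [1]}))
        with pytest.raises(ValueError, match="two groups"):
            km_logrank(self._table([1.0, 2.0], [1, 1], ["a", "a"]))
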