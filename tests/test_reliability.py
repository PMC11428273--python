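import numpy as np
import pytest

from boldcast import (FcMatrix, RoiTimeSeries, fc_matrix, grade_icc, icc21,
                      icc_edges, reliability_report, subject_pearson)


def _fc_from(values, labels=None):
    m = values.shape[0]
    return FcMatrix(values, labels or [f"R{i}" for i in range(m)])


class TestFcMatrix:
    def test_duplicated_rows_give_unit_correlation(self):
        row = np.sin(np.linspace(0, 10, 50))
        s = RoiTimeSeries("s", ["A", "B"], np.vstack([row, row]), 1.0)
        fc = fc_matrix(s)
        assert fc.values[0, 1] == pytest.approx(1.0)

    def test_negated_row(self):
        row = np.sin(np.linspace(0, 10, 50))
        s = RoiTimeSeries("s", ["A", "B"], np.vstack([row, -row]), 1.0)
        assert fc_matrix(s).values[0, 1] == pytest.approx(-1.0)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(0)
        s = RoiTimeSeries("s", [f"R{i}" for i in range(4)],
                          rng.standard_normal((4, 2000)), 1.0)
        fc = fc_matrix(s)
        off = fc.upper_edges()
        assert np.all(np.abs(off) < 0.08)

    def test_constant_row_rejected(self):
        s = RoiTimeSeries("s", ["A", "B"],
                          np.vstack([np.ones(10), np.arange(10.0)]), 1.0)
        with pytest.raises(ValueError, match="'A'"):
            fc_matrix(s)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((3, 100))
        s1 = RoiTimeSeries("s", ["A", "B", "C"], data, 1.0)
        s2 = RoiTimeSeries("s", ["A", "B", "C"],
                           data * np.array([[2.0], [0.5], [7.0]]) + 3.0, 1.0)
        np.testing.assert_allclose(fc_matrix(s1).values,
                                   fc_matrix(s2).values, atol=1e-12)


class TestIcc:
    def test_identical_sessions_give_one(self):
        rng = np.random.default_rng(2)
        mats = []
        for _ in range(6):
            x = rng.standard_normal((4, 80))
            mats.append(fc_matrix(RoiTimeSeries(
                "s", ["A", "B", "C", "D"], x, 1.0)))
        icc = icc_edges(mats, mats)
        assert np.all(np.isfinite(icc))
        np.testing.assert_allclose(icc, 1.0, atol=1e-9)

    def test_independent_sessions_near_zero(self):
        rng = np.random.default_rng(3)
        def sessions():
            out = []
            for _ in range(50):
                x = rng.standard_normal((4, 100))
                out.append(fc_matrix(RoiTimeSeries(
                    "s", ["A", "B", "C", "D"], x, 1.0)))
            return out
        icc = icc_edges(sessions(), sessions())
        assert abs(np.nanmean(icc)) <= 0.15

    def test_degenerate_edge_reported_missing(self):
        base = np.eye(3)
        mats_a, mats_b = [], []
        rng = np.random.default_rng(4)
        for _ in range(5):
            v = base.copy()
            v[0, 1] = v[1, 0] = 0.5           # constant edge everywhere
            v[0, 2] = v[2, 0] = rng.uniform(-0.5, 0.5)
            v[1, 2] = v[2, 1] = rng.uniform(-0.5, 0.5)
            mats_a.append(_fc_from(v))
            mats_b.append(_fc_from(v + 0.0))
        icc = icc_edges(mats_a, mats_b)
        assert np.isnan(icc[0])

    def test_session_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a = [_fc_from(np.corrcoef(rng.standard_normal((3, 50))))
             for _ in range(5)]
        b = [_fc_from(np.corrcoef(rng.standard_normal((3, 50))))
             for _ in range(5)]
        np.testing.assert_allclose(icc_edges(a, b), icc_edges(b, a),
                                   atol=1e-12)

    def test_matches_pingouin(self):
        """Cross-check the ANOVA implementation against pingouin's ICC2."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(6)
        ratings = rng.uniform(-1, 1, size=(10, 2))
        ours = icc21(ratings)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(10), 2),
            "raters": np.tile([0, 1], 10),
            "scores": ratings.ravel(),
        })
        res = pingouin.intraclass_corr(df, targets="targets",
                                       raters="raters", ratings="scores")
        mask = res["Type"].isin(["ICC2", "ICC(A,1)"])
        theirs = float(res.loc[mask, "ICC"].iloc[0])
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestGrading:
    @pytest.mark.parametrize("icc,grade", [
        (0.39, "poor"), (0.40, "fair"), (0.59, "fair"), (0.60, "good"),
        (0.70, "good"), (0.75, "good"), (0.80, "excellent"),
    ])
    def test_thresholds(self, icc, grade):
        assert grade_icc(icc) == grade

    def test_monotone_step_function(self):
        order = ["poor", "fair", "good", "excellent"]
        grades = [order.index(grade_icc(v))
                  for v in np.linspace(-0.5, 1.0, 200)]
        assert all(a <= b for a, b in zip(grades, grades[1:]))


class TestSubjectPearson:
    def test_perfect_and_negated(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((2, 60))
        s = RoiTimeSeries("s", ["A", "B"], data, 1.0)
        np.testing.assert_allclose(subject_pearson(s, s), 1.0)
        neg = RoiTimeSeries("s", ["A", "B"], -data, 1.0)
        np.testing.assert_allclose(subject_pearson(neg, s), -1.0)

    def test_attenuation_with_noise(self):
        # r ~ 1/sqrt(1 + sigma^2/var) ~ 0.995 for sigma = 0.1 sd
        rng = np.random.default_rng(8)
        truth = np.sin(np.linspace(0, 20, 2000))[None, :]
        noisy = truth + 0.1 * truth.std() * rng.standard_normal(truth.shape)
        r = subject_pearson(RoiTimeSeries("s", ["A"], noisy, 1.0),
                            RoiTimeSeries("s", ["A"], truth, 1.0))
        assert r[0] >= 0.99


class TestReport:
    def test_full_report(self):
        rng = np.random.default_rng(9)
        truth = [RoiTimeSeries(f"s{i}", ["A", "B", "C"],
                               rng.standard_normal((3, 120)), 1.0)
                 for i in range(4)]
        pred = [RoiTimeSeries(s.subject_id, s.region_labels,
                              s.data + 0.05 * rng.standard_normal(s.data.shape),
                              1.0) for s in truth]
        rep = reliability_report(pred, truth)
        assert rep.icc_per_edge.shape == (3,)
        assert rep.per_subject_pearson.shape == (4, 3)
        assert sum(rep.grade_histogram().values()) + rep.n_degenerate_edges == 3
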