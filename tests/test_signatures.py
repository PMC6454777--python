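"""Signature-score algebra, enzyme scores, correlation and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmirnet import signatures as sg
from methmirnet.errors import AlignmentError, AnalysisError, ParameterError, UndefinedResultError

from conftest import make_matrix


class TestGsScore:
    def test_empty_members_rejected(self):
        with pytest.raises(UndefinedResultError):
            sg.gs_score(make_matrix([[1.0, 2.0]]), [])

    def test_singleton_equals_feature_row(self):
        m = make_matrix([[1.0, -2.0, 0.5]])
        s = sg.gs_score(m, ["g1"])
        np.testing.assert_allclose(s.scores.to_numpy(), [1.0, -2.0, 0.5])

    def test_hand_summation(self):
        m = make_matrix([[1, -1, 0], [2, 0, -2]])
        s = sg.gs_score(m, ["g1", "g2"])
        np.testing.assert_allclose(s.scores.to_numpy(), [3, -1, -2])

    def test_additive_over_disjoint_sets(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.standard_normal((6, 4)))
        s_union = sg.gs_score(m, ["g1", "g2", "g3", "g4"])
        s_a = sg.gs_score(m, ["g1", "g2"])
        s_b = sg.gs_score(m, ["g3", "g4"])
        np.testing.assert_allclose(
            s_union.scores.to_numpy(), (s_a.scores + s_b.scores).to_numpy(), atol=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.permutations(["g1", "g2", "g3"]))
    def test_member_order_irrelevant(self, members):
        m = make_matrix(np.arange(12, dtype=float).reshape(3, 4))
        base = sg.gs_score(m, ["g1", "g2", "g3"]).scores
        np.testing.assert_array_equal(sg.gs_score(m, members).scores, base)

    def test_missing_members_dropped(self):
        m = make_matrix([[1.0, 2.0]])
        s = sg.gs_score(m, ["g1", "absent"])
        assert s.n_members_used == 1
        np.testing.assert_allclose(s.scores.to_numpy(), [1.0, 2.0])


class TestComposite:
    def test_equal_inputs_zero(self):
        m = make_matrix([[1.0, 2.0]])
        s = sg.gs_score(m, ["g1"])
        assert (sg.composite_score(s, s).scores == 0).all()

    def test_antisymmetry_exact(self):
        m = make_matrix([[1.0, 2.0], [0.5, -3.0]])
        a, b = sg.gs_score(m, ["g1"]), sg.gs_score(m, ["g2"])
        fwd = sg.composite_score(a, b).scores
        rev = sg.composite_score(b, a).scores
        assert (fwd == -rev).all()

    def test_hand_subtraction(self):
        m = make_matrix([[3.0, -1.0], [1.0, 1.0]])
        comp = sg.composite_score(sg.gs_score(m, ["g1"]), sg.gs_score(m, ["g2"]))
        np.testing.assert_allclose(comp.scores.to_numpy(), [2.0, -2.0])

    def test_patient_mismatch_rejected(self):
        a = sg.gs_score(make_matrix([[1.0, 2.0]], samples=["s1", "s2"]), ["g1"])
        b = sg.gs_score(make_matrix([[1.0, 2.0]], samples=["x1", "x2"]), ["g1"])
        with pytest.raises(AlignmentError):
            sg.composite_score(a, b)


class TestMethGs:
    def test_balanced_patient_zero(self):
        m = make_matrix([[1.0, 5.0], [1.0, 2.0]], layer="methylation")
        s = sg.meth_gs_score(m, ["g1"], ["g2"])
        assert s.scores.iloc[0] == pytest.approx(0.0)

    def test_hand_difference(self):
        m = make_matrix(
            [[1, 0], [2, 1], [0.5, 0.5], [0.5, 1.5]], layer="methylation",
            features=["h1", "h2", "l1", "l2"],
        )
        s = sg.meth_gs_score(m, ["h1", "h2"], ["l1", "l2"])
        np.testing.assert_allclose(s.scores.to_numpy(), [2.0, -1.0])

    def test_sign_semantics_high_means_ts_methylated(self):
        # patient 1 has heavily methylated hyper (TS) genes -> high meth-GS
        m = make_matrix([[5.0, 0.0], [0.0, 5.0]], layer="methylation",
                        features=["ts_gene", "og_gene"])
        s = sg.meth_gs_score(m, ["ts_gene"], ["og_gene"])
        assert s.scores.iloc[0] > 0 > s.scores.iloc[1]


class TestEnzymeScores:
    def test_sign_propagation(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((4, 20)) * 0.1
        vals[:2, :10] -= 2.0  # catabolic enzymes suppressed in tumors
        m = make_matrix(vals, conditions=["tumor"] * 10 + ["normal"] * 10)
        ann = pd.DataFrame({"gene_id": ["g1", "g2", "g3", "g4"],
                            "role": ["catabolic", "catabolic", "anabolic", "anabolic"]})
        scores = sg.catabolic_anabolic_scores(m, ann)
        assert scores.loc["catabolic", "tumor"] < scores.loc["catabolic", "normal"]

    def test_hand_arithmetic(self):
        m = make_matrix([[1.0, 3.0, 0.0, 2.0], [2.0, 2.0, 1.0, 1.0]],
                        conditions=["tumor", "tumor", "normal", "normal"])
        ann = pd.DataFrame({"gene_id": ["g1", "g2"], "role": ["anabolic", "catabolic"]})
        scores = sg.catabolic_anabolic_scores(m, ann)
        assert scores.loc["anabolic", "tumor"] == pytest.approx(2.0)
        assert scores.loc["anabolic", "normal"] == pytest.approx(1.0)
        assert scores.loc["catabolic", "tumor"] == pytest.approx(2.0)
        assert scores.loc["catabolic", "normal"] == pytest.approx(1.0)

    def test_unknown_role_rejected(self):
        m = make_matrix([[1.0, 2.0]])
        ann = pd.DataFrame({"gene_id": ["g1"], "role": ["mystery"]})
        with pytest.raises(AnalysisError, match="mystery"):
            sg.catabolic_anabolic_scores(m, ann)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = sg.correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = sg.correlate(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        r, _ = sg.correlate(x, y)
        expected = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(expected, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedResultError):
            sg.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareGroups:
    def _score(self, values, patients):
        return sg.SignatureScore(name="s", layer="mRNA",
                                 scores=pd.Series(values, index=patients),
                                 n_members=1, n_members_used=1)

    def test_identical_groups_p_one(self):
        s = self._score([1.0, 2.0, 1.0, 2.0], ["a", "b", "c", "d"])
        labels = pd.Series(["x", "x", "y", "y"], index=["a", "b", "c", "d"])
        t, p = sg.compare_groups(s, labels)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        pats = [f"p{i}" for i in range(100)]
        labels = pd.Series(["no"] * 50 + ["yes"] * 50, index=pats)
        _, p = sg.compare_groups(self._score(vals, pats), labels)
        assert p < 1e-6

    def test_single_patient_level_rejected(self):
        s = self._score([1.0, 2.0, 3.0], ["a", "b", "c"])
        labels = pd.Series(["x", "x", "y"], index=["a", "b", "c"])
        with pytest.raises(ParameterError):
            sg.compare_groups(s, labels)
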