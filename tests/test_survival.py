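"""KM, log-rank, Cox HR and candidate classification against oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from methmirnet import differential as dm
from methmirnet import survival as sv
from methmirnet.containers import ClinicalTable
from methmirnet.errors import AnalysisError, ParameterError
from methmirnet.synthetic import generate_survival_times

from conftest import make_matrix


def brute_force_logrank(time_a, event_a, time_b, event_b):
    """Exhaustive O/E/V risk-table tabulation of the two-group log-rank
    chi-square (independent of the package implementation)."""
    times = sorted(set([t for t, e in zip(time_a, event_a) if e]
                       + [t for t, e in zip(time_b, event_b) if e]))
    o_minus_e, var = 0.0, 0.0
    for t in times:
        n_a = sum(1 for x in time_a if x >= t)
        n_b = sum(1 for x in time_b if x >= t)
        d_a = sum(1 for x, e in zip(time_a, event_a) if x == t and e)
        d_b = sum(1 for x, e in zip(time_b, event_b) if x == t and e)
        n, d = n_a + n_b, d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        v = d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += d_a - e_a
        var += v
    return o_minus_e**2 / var


def brute_force_km(time, event):
    """Hand product-limit values at the distinct event times."""
    out = []
    s = 1.0
    for t in sorted({x for x, e in zip(time, event) if e}):
        n = sum(1 for x in time if x >= t)
        d = sum(1 for x, e in zip(time, event) if x == t and e)
        s *= 1 - d / n
        out.append((t, s))
    return out


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        curve = sv.km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.at(10) == 1.0

    def test_hand_product_limit(self):
        curve = sv.km_estimate([1, 2, 3], [1, 1, 0])
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2.5) == pytest.approx(1 / 3)
        assert curve.at(99) == pytest.approx(1 / 3)

    def test_double_event_drops_to_zero(self):
        curve = sv.km_estimate([1, 1], [1, 1])
        assert curve.at(1) == 0.0

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, 40)
        curve = sv.km_estimate(t, np.ones(40))
        for q in (0.5, 1.0, 3.0):
            assert curve.at(q) == pytest.approx(np.mean(t > q), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            sv.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        chi, p = sv.logrank_test([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_tabulation(self):
        ta, ea = [1, 2], [1, 1]
        tb, eb = [3, 4], [1, 1]
        chi, _ = sv.logrank_test(ta, ea, tb, eb)
        assert chi == pytest.approx(brute_force_logrank(ta, ea, tb, eb), abs=1e-6)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(1, 30), rng.exponential(2, 25)
        ea, eb = np.ones(30), np.ones(25)
        chi1, p1 = sv.logrank_test(ta, ea, tb, eb)
        chi2, p2 = sv.logrank_test(tb, eb, ta, ea)
        assert chi1 == pytest.approx(chi2, rel=1e-10)
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_no_events_anywhere(self):
        chi, p = sv.logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert chi == 0.0 and p == 1.0

    def test_power_against_planted_hazard_ratio(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(1.0, 200)
            tb = rng.exponential(1.0 / 3.0, 200)
            _, p = sv.logrank_test(ta, np.ones(200), tb, np.ones(200))
            hits += p < 0.05
        assert hits >= 95


class TestCoxHR:
    def test_identical_groups_hr_one(self):
        # both arms carry the same survival data -> exact null
        rng = np.random.default_rng(8)
        t = rng.exponential(1, 500)
        t_all = np.concatenate([t, t])
        g = np.concatenate([np.zeros(500), np.ones(500)])
        hr, _ = sv.cox_hr(t_all, np.ones(1000), g)
        assert abs(math.log(hr)) < 0.05

    def test_parameter_recovery_hr2(self):
        lp = np.concatenate([np.zeros(2000), np.full(2000, math.log(2))])
        t, e = generate_survival_times(lp, 0.1, 0.0, seed=5)
        g = np.concatenate([np.zeros(2000), np.ones(2000)])
        hr, p = sv.cox_hr(t, e, g)
        assert 1.8 <= hr <= 2.2
        assert p < 1e-6

    def test_label_swap_inverts(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 60)
        e = (rng.random(60) < 0.8).astype(float)
        g = (rng.random(60) < 0.5).astype(float)
        hr1, _ = sv.cox_hr(t, e, g)
        hr2, _ = sv.cox_hr(t, e, 1 - g)
        assert hr1 == pytest.approx(1 / hr2, rel=1e-6)

    def test_matches_lifelines_on_tie_free_data(self):
        # on continuous (tie-free) times Breslow and Efron coincide
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(11)
        g = (rng.random(80) < 0.5).astype(float)
        t, e = generate_survival_times(0.7 * g, 0.2, 0.2, seed=3)
        hr, p = sv.cox_hr(t, e, g)
        df = pd.DataFrame({"T": t, "E": e, "g": g})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert math.log(hr) == pytest.approx(cph.params_["g"], abs=1e-5)
        assert p == pytest.approx(cph.summary.loc["g", "p"], abs=1e-4)

    def test_monotone_likelihood_boundary(self):
        with pytest.warns(UserWarning, match="boundary"):
            hr, p = sv.cox_hr([1, 2, 3, 4], [1, 1, 0, 0], [1, 1, 0, 0])
        assert hr in (0.0, np.inf) and math.isnan(p)


class TestMedianSplit:
    def test_even_split(self):
        labels = sv.median_split([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        labels = sv.median_split([1, 2, 2, 3])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_constant_vector_single_group(self):
        labels = sv.median_split([5, 5, 5])
        assert set(labels) == {"low"}


def _clinical_for(patients, time, event):
    df = pd.DataFrame(
        {
            "os_time": time, "os_event": event,
            "rfs_time": np.nan, "rfs_event": np.nan,
            "vascular_invasion": "no", "stage": "I", "grade": "G1", "t_size": "T1",
        },
        index=pd.Index(patients, name="patient_id"),
    )
    return ClinicalTable(data=df)


class TestClassifyCandidates:
    def _setup(self, protective=True, seed=0, n=120):
        rng = np.random.default_rng(seed)
        risk = rng.standard_normal(n)
        expr = np.vstack([
            -risk + 0.3 * rng.standard_normal(n),  # protective, down in tumor
            rng.standard_normal(n),                 # null gene
        ])
        # tumor block plus a small normal block so the diff test sees a shift
        normals = rng.standard_normal((2, 40))
        normals[0] += 1.5  # gene g1 down in tumor relative to normal
        vals = np.hstack([expr, normals])
        patients = [f"P{i}" for i in range(n)]
        m = make_matrix(
            vals,
            conditions=["tumor"] * n + ["normal"] * 40,
            patients=patients + [None] * 40,
            samples=[f"t{i}" for i in range(n)] + [f"nn{i}" for i in range(40)],
        )
        lp = math.log(2) * risk if protective else np.zeros(n)
        t, e = generate_survival_times(lp, 0.1, 0.2, seed=seed + 1)
        return m, _clinical_for(patients, t, e)

    def test_planted_protective_gene_classified_ts(self):
        m, clin = self._setup(protective=True)
        diff = dm.differential_test(m)
        ts, og = sv.classify_candidates(diff, m, clin, alpha=0.05)
        assert "g1" in ts.feature_ids
        assert og.members.empty

    def test_down_gene_with_null_survival_excluded(self):
        m, clin = self._setup(protective=False)
        diff = dm.differential_test(m)
        ts, og = sv.classify_candidates(diff, m, clin, alpha=0.05)
        assert "g1" not in ts.feature_ids

    def test_patients_without_survival_excluded(self):
        m, clin = self._setup(protective=True)
        # strip survival from half the patients; the screen must still run
        data = clin.data.copy()
        data.iloc[:60, data.columns.get_loc("os_time")] = np.nan
        data.iloc[:60, data.columns.get_loc("os_event")] = np.nan
        clin2 = ClinicalTable(data=data)
        diff = dm.differential_test(m)
        ts, _ = sv.classify_candidates(diff, m, clin2, alpha=0.05)
        if "g1" in ts.feature_ids:
            assert ts.members.loc["g1", "n"] == 60

    def test_no_clinical_overlap_raises(self):
        m, clin = self._setup()
        other = _clinical_for(["X1", "X2"], [1.0, 2.0], [1.0, 0.0])
        diff = dm.differential_test(m)
        with pytest.raises(AnalysisError, match="overlap"):
            sv.classify_candidates(diff, m, other, alpha=0.05)
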