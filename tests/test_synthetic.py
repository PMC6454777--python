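"""Generator contracts: planted effects, couplings, survival model,
determinism, serialization round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmirnet.errors import ConfigurationError, ParameterError
from methmirnet.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_survival_times,
    read_cohort,
    write_cohort,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            ({"n_planted_ts": 300, "n_planted_og": 300, "n_genes": 500}, "n_genes"),
            ({"censor_rate": 1.0}, "censor_rate"),
            ({"n_tumor": -1}, "n_tumor"),
            ({"mirna_coupling": 1.5}, "mirna_coupling"),
            ({"baseline_hazard": 0.0}, "baseline_hazard"),
        ],
    )
    def test_violations_name_the_bound(self, kwargs, fragment):
        with pytest.raises(ConfigurationError, match=fragment):
            generate_cohort(CohortConfig(**kwargs))


class TestGenerateCohort:
    def test_planted_shift_recovered_from_emitted_matrix(self):
        cfg = CohortConfig(
            n_tumor=40, n_normal=40, n_genes=2000, n_planted_ts=100,
            n_planted_og=100, effect_size=1.5, seed=7,
        )
        c = generate_cohort(cfg)
        tum = c.mrna.values.loc[:, c.mrna.tumor_samples()]
        nor = c.mrna.values.loc[:, c.mrna.normal_samples()]
        diff = (tum.mean(axis=1) - nor.mean(axis=1))
        ts_diff = diff.loc[sorted(c.truth.ts_genes)].mean()
        og_diff = diff.loc[sorted(c.truth.og_genes)].mean()
        assert ts_diff == pytest.approx(-1.5, abs=0.2)
        assert og_diff == pytest.approx(+1.5, abs=0.2)

    def test_determinism_same_seed_byte_identical(self):
        cfg = CohortConfig(n_tumor=20, n_normal=10, n_genes=80, n_mirnas=20,
                           n_planted_ts=10, n_planted_og=10, targets_per_mirna=3,
                           n_decoy_edges=30, seed=9)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.mrna.values.to_csv() == b.mrna.values.to_csv()
        assert a.meth.values.to_csv() == b.meth.values.to_csv()
        assert a.clinical.data.to_csv() == b.clinical.data.to_csv()
        assert a.truth.planted_edges == b.truth.planted_edges

    def test_null_model_type_one_rate(self):
        cfg = CohortConfig(n_tumor=30, n_normal=30, n_genes=2000, n_mirnas=0,
                           n_planted_ts=0, n_planted_og=0, n_planted_ts_mirna=0,
                           n_planted_og_mirna=0, effect_size=0.0,
                           hazard_log_ratio=0.0, n_decoy_edges=0, seed=1)
        c = generate_cohort(cfg)
        tum = c.mrna.values.loc[:, c.mrna.tumor_samples()].to_numpy()
        nor = c.mrna.values.loc[:, c.mrna.normal_samples()].to_numpy()
        _, p = stats.ttest_ind(tum, nor, axis=1)
        rate = float(np.mean(p < 0.05))
        # 99% binomial interval around 0.05 at n=2000
        half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < half
        assert c.truth.is_empty()

    def test_mirna_target_coupling_magnitude(self):
        cfg = CohortConfig(n_tumor=150, n_normal=50, n_genes=400, n_mirnas=40,
                           n_planted_ts=60, n_planted_og=60, targets_per_mirna=10,
                           mirna_coupling=0.6, seed=4)
        c = generate_cohort(cfg)
        tum = c.mrna.tumor_samples()
        rs = []
        for m, g, _conf in c.truth.planted_edges:
            r = np.corrcoef(
                c.mirna.values.loc[m, tum], c.mrna.values.loc[g, tum]
            )[0, 1]
            rs.append(r)
        assert np.mean(rs) < 0
        assert np.mean(rs) == pytest.approx(-0.6, abs=0.15)

    def test_meth_expression_coupling_sign(self, small_cohort):
        c = small_cohort
        tum = c.mrna.tumor_samples()
        hyper_ts = sorted(c.truth.hyper_genes & c.truth.ts_genes)
        rs = [
            np.corrcoef(c.meth.values.loc[g, tum], c.mrna.values.loc[g, tum])[0, 1]
            for g in hyper_ts
        ]
        assert np.mean(rs) == pytest.approx(-c.config.meth_coupling, abs=0.15)

    def test_planted_edges_join_opposite_roles(self, small_cohort):
        t = small_cohort.truth
        for m, g, conf in t.planted_edges:
            assert 0.5 <= conf <= 1.0
            assert (m in t.ts_mirnas and g in t.og_genes) or (
                m in t.og_mirnas and g in t.ts_genes
            )

    def test_decoy_confidence_below_planted(self, small_cohort):
        c = small_cohort
        planted = {(m, g) for m, g, _ in c.truth.planted_edges}
        decoy_conf = [
            row["confidence"]
            for _, row in c.interactions.data.iterrows()
            if (row["mirna_id"], row["gene_id"]) not in planted
        ]
        assert decoy_conf and max(decoy_conf) < 0.5


class TestSurvivalTimes:
    def test_exponential_mean_matches_closed_form(self):
        t, e = generate_survival_times(np.zeros(10000), baseline_hazard=0.25,
                                       censor_rate=0.0, seed=3)
        assert e.all() and (t > 0).all()
        assert t.mean() == pytest.approx(4.0, abs=4 * 3 / np.sqrt(10000))

    def test_heavy_censoring_flags(self):
        t, e = generate_survival_times(np.zeros(100), 0.1, censor_rate=0.99, seed=0)
        assert set(np.unique(e)) <= {0, 1}
        assert (e == 0).sum() > 0 and (t > 0).all()

    def test_censor_fraction_calibrated(self):
        rng_lp = np.random.default_rng(1).normal(0, 1, 5000)
        _, e = generate_survival_times(rng_lp, 0.1, censor_rate=0.4, seed=2)
        assert (e == 0).mean() == pytest.approx(0.4, abs=0.03)

    def test_invalid_baseline_hazard(self):
        with pytest.raises(ParameterError, match="baseline_hazard"):
            generate_survival_times([0.0], 0.0, 0.0, 1)


class TestWriteCohort:
    def test_round_trip_and_manifest_counts(self, tmp_path, small_cohort):
        manifest = write_cohort(small_cohort, tmp_path)
        back = read_cohort(tmp_path)
        np.testing.assert_allclose(
            back.mrna.values.to_numpy(), small_cohort.mrna.values.to_numpy(),
            rtol=1e-9, atol=1e-12,
        )
        assert back.truth.ts_genes == small_cohort.truth.ts_genes
        assert len(back.interactions) == len(small_cohort.interactions)
        assert manifest["mrna"]["rows"] == small_cohort.config.n_genes
        # feature column + one column per sample
        n_samples = small_cohort.config.n_tumor + small_cohort.config.n_normal
        assert manifest["mrna"]["columns"] == n_samples + 1
        assert manifest["clinical"]["rows"] == small_cohort.config.n_tumor

    def test_empty_cohort_valid_files(self, tmp_path):
        cfg = CohortConfig(n_tumor=6, n_normal=6, n_genes=20, n_mirnas=5,
                           n_planted_ts=0, n_planted_og=0, n_planted_ts_mirna=0,
                           n_planted_og_mirna=0, n_decoy_edges=5,
                           n_background_meth=0, seed=0)
        write_cohort(generate_cohort(cfg), tmp_path)
        back = read_cohort(tmp_path)
        assert back.truth.is_empty()
        assert back.truth.planted_edges == []
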