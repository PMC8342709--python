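"""Epoching, fidelity time courses, generalization, voxel sorting, and the
neural-behavioral coupling analyses."""

import numpy as np
import pandas as pd
import pytest

from wmdecode.analyses import (EPOCHS, batch_fidelity,
                               behavioral_bias, coupling_analysis,
                               epoch_average, fidelity_timecourse,
                               loro_generalization, near_distractor_select,
                               rf_sorted_timecourse, toward_distractor,
                               train_encoding_model)
from wmdecode.bold import DEFAULT_TR_ONSETS, simulate_timeseries
from wmdecode.design import generate_design
from wmdecode.iem import invert
from wmdecode.population import generate_population


@pytest.fixture(scope="module")
def trained(training_session, basis):
    design, ts = training_session
    return train_encoding_model(design, ts, basis)


class TestEpochAverage:
    def test_train_epoch_spans_nine_trs(self, training_session):
        _, ts = training_session
        onsets = ts.tr_onsets
        mask = (onsets >= 5.25) & (onsets < 12.0)
        assert mask.sum() == 9

    def test_pre_epoch_spans_the_two_expected_onsets(self):
        mask = (DEFAULT_TR_ONSETS >= EPOCHS["PRE"].window[0]) & \
            (DEFAULT_TR_ONSETS < EPOCHS["PRE"].window[1])
        assert list(DEFAULT_TR_ONSETS[mask]) == [3.75, 4.5]

    def test_constant_series_average_to_the_constant(self, training_session):
        _, ts = training_session
        const = ts.__class__(data=np.full_like(ts.data, 2.5),
                             tr_onsets=ts.tr_onsets, run_ids=ts.run_ids,
                             participant_ids=ts.participant_ids)
        assert np.allclose(epoch_average(const, "DIST"), 2.5)

    def test_empty_window_raises(self, training_session):
        _, ts = training_session
        from wmdecode.analyses import EpochDefinition
        with pytest.raises(ValueError, match="no TR"):
            epoch_average(ts, EpochDefinition("X", (100.0, 101.0)))


class TestNearDistractorSelect:
    def _table(self, rels):
        return pd.DataFrame({
            "condition": ["distractor_present"] * len(rels),
            "relative_distractor_angle": rels})

    @pytest.mark.parametrize("rel,expected", [
        (11.9, True), (-12.0, True), (12.0, True), (13.0, False),
    ])
    def test_inclusive_threshold(self, rel, expected):
        assert near_distractor_select(self._table([rel])).iloc[0] == expected

    def test_absent_trials_never_selected(self):
        df = self._table([5.0])
        df["condition"] = "distractor_absent"
        df["relative_distractor_angle"] = np.nan
        assert not near_distractor_select(df).any()


class TestFidelityTimecourse:
    def test_sustained_target_code(self, training_session, task_design,
                                   population, trained):
        ts = simulate_timeseries(task_design, population, noise_sd=0.5,
                                 seed=31)
        tc = fidelity_timecourse(ts, task_design, trained, align_to="target")
        mean = tc.groupby("tr_onset")["fidelity"].mean()
        assert mean.loc[8.25:12.0].min() > 3 * mean.loc[:0.0].abs().max()

    def test_distractor_locked_transient(self, task_design, population,
                                         trained):
        ts = simulate_timeseries(task_design, population, noise_sd=0.2,
                                 distractor_gain=2.5, seed=32)
        tc = fidelity_timecourse(ts, task_design, trained,
                                 align_to="distractor")
        assert (tc["condition"] == "distractor_present").all()
        mean = tc.groupby("tr_onset")["fidelity"].mean()
        # bump after distractor onset (4.5 s) + hemodynamic lag, not before
        assert mean.loc[7.5:10.5].max() > 5 * abs(mean.loc[:4.5]).max()

    def test_counterbalancing_washes_out_distractor(self, population,
                                                    trained, basis):
        """Target-aligned averages show no net distractor signal: with the
        sustained target code removed, mean target-aligned fidelity of a
        distractor-only signal is ~0 while distractor-aligned is large."""
        design = generate_design(30, seed=33)
        pop = population
        ts = simulate_timeseries(design, pop, noise_sd=0.0,
                                 distractor_gain=2.5, seed=34, zscore=False)
        quiet = simulate_timeseries(design, pop, noise_sd=0.0,
                                    distractor_gain=0.0, seed=34,
                                    zscore=False)
        ts.data -= quiet.data          # isolate the distractor component
        present = (design["condition"] == "distractor_present").to_numpy()
        B = epoch_average(ts, "DIST")[present]
        C = invert(B, trained)
        f_target = batch_fidelity(
            C, basis, design["target_angle"].to_numpy()[present]).mean()
        f_dist = batch_fidelity(
            C, basis, design["distractor_angle"].to_numpy()[present]).mean()
        assert f_dist > 0
        assert abs(f_target) < 0.1 * f_dist


class TestGeneralization:
    def test_stable_code_has_all_positive_cells(self, task_design,
                                                population, basis):
        ts = simulate_timeseries(task_design, population, noise_sd=0.5,
                                 seed=41)
        mat, labels = loro_generalization(ts, task_design, basis,
                                         mode="epoch")
        assert labels == ["PRE", "DIST", "POST"]
        assert np.all(mat > 0)

    def test_morphed_code_kills_cross_epoch_cells(self, task_design, basis):
        """If tuning remaps after the distractor, PRE<->POST transfer dies
        while the diagonal stays positive."""
        pop_a = generate_population(120, seed=51)
        pop_b = generate_population(120, seed=52)   # remapped preferences
        ts_a = simulate_timeseries(task_design, pop_a, noise_sd=0.3, seed=53,
                                   zscore=False)
        ts_b = simulate_timeseries(task_design, pop_b, noise_sd=0.3, seed=53,
                                   zscore=False)
        late = ts_a.tr_onsets >= 9.0     # post-distractor timepoints
        spliced = ts_a
        spliced.data = np.where(late[None, :, None], ts_b.data, ts_a.data)
        mat, labels = loro_generalization(spliced, task_design, basis,
                                          mode="epoch")
        i, j = labels.index("PRE"), labels.index("POST")
        diag = min(mat[i, i], mat[j, j])
        assert diag > 0
        assert abs(mat[i, j]) < 0.2 * diag
        assert abs(mat[j, i]) < 0.2 * diag

    def test_single_run_rejected(self, population, basis):
        design = generate_design(1, seed=42)
        ts = simulate_timeseries(design, population, seed=43)
        with pytest.raises(ValueError, match="runs"):
            loro_generalization(ts, design, basis)


class TestBehavioralBias:
    def test_uniform_pull_toward_distractor(self):
        errors = np.array([2.0, 2.0, -2.0, 2.0])
        rels = np.array([30.0, 12.0, -20.0, 5.0])
        per_p, res = behavioral_bias(errors, rels, ["s1"] * 4, n_perm=100,
                                     seed=0)
        assert per_p.loc["s1"] == pytest.approx(2.0)

    def test_hand_computed_flipped_mean(self):
        errors = np.array([3.0, -1.0, 4.0, -2.0, 0.0])
        rels = np.array([10.0, -15.0, -30.0, 20.0, 8.0])
        # toward-distractor flips: +3, +1, -4, -2, 0 -> mean -0.4
        per_p, _ = behavioral_bias(errors, rels, ["s"] * 5, n_perm=50, seed=0)
        assert per_p.loc["s"] == pytest.approx(-0.4)

    def test_null_bias_not_significant(self, rng):
        errors = rng.normal(0, 5, 200)
        rels = rng.uniform(-30, 30, 200)
        pid = np.repeat([f"s{i}" for i in range(5)], 40)
        _, res = behavioral_bias(errors, rels, pid, n_perm=300, seed=1)
        assert res.p > 0.05


class TestCoupling:
    def _errors(self, rho, n_sub=6, n=24, seed=0, motor=3.0):
        rng = np.random.default_rng(seed)
        pid = np.repeat([f"s{i}" for i in range(n_sub)], n)
        neural = rng.normal(0, 12, n_sub * n)
        behav = rho * neural + rng.normal(0, motor, n_sub * n)
        return neural, behav, pid

    def test_perfect_coupling_hits_floor(self):
        neural, behav, pid = self._errors(rho=1.0, motor=0.0)
        res = coupling_analysis(neural, behav, pid, n_perm=200, seed=1)
        assert np.allclose(res.per_participant_r, 1.0 - 1e-10)
        assert res.p == pytest.approx(1 / 200)

    def test_quartile_variant_agrees_in_sign(self):
        neural, behav, pid = self._errors(rho=0.6, seed=2)
        res = coupling_analysis(neural, behav, pid, n_perm=200, seed=2)
        assert res.quartile_r > 0
        assert np.sign(res.quartile_r) == np.sign(res.fisher_z.mean())
        assert res.quartile_p < 0.05

    def test_undefined_neural_errors_dropped(self):
        neural, behav, pid = self._errors(rho=0.5, seed=3)
        neural[::10] = np.nan
        res = coupling_analysis(neural, behav, pid, n_perm=50, seed=3)
        assert res.n_dropped == len(neural[::10])

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            coupling_analysis([1.0, 2.0], [1.0, 2.0], ["a", "a"], n_perm=10)

    def test_false_positive_rate_calibrated(self):
        """rho=0: one-tailed rejections at alpha=.05 within binomial CI."""
        rng = np.random.default_rng(9)
        n_rep, rejections = 500, 0
        for rep in range(n_rep):
            pid = np.repeat([f"s{i}" for i in range(6)], 16)
            neural = rng.normal(0, 12, pid.size)
            behav = rng.normal(0, 5, pid.size)
            res = coupling_analysis(neural, behav, pid, n_perm=99, seed=rep)
            rejections += res.p <= 0.05
        rate = rejections / n_rep
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - half <= rate <= 0.05 + half


class TestRfSorting:
    def test_rf_in_exceeds_rf_out_and_baseline_zeroed(self, population):
        design = generate_design(2, seed=61)
        ts = simulate_timeseries(design, population, noise_sd=0.0, seed=62,
                                 zscore=False)
        tc = rf_sorted_timecourse(ts, population, design, align_to="target")
        piv = tc.pivot_table(index="tr_onset", columns="rf",
                             values="activation", aggfunc="mean")
        delay = piv.loc[6.0:12.0]
        assert (delay["RF_in"] > delay["RF_out"]).all()
        base = piv.loc[-2.25:-0.75]
        assert np.allclose(base.mean(), 0.0, atol=1e-12)

    def test_boundary_voxel_counts_as_rf_out(self):
        pop = generate_population(40, seed=63)
        pop.prf_angle[:] = 165.0     # exactly at the inclusive boundary
        pop.r2[:] = 0.5
        pop.prf_ecc[:] = 8.0
        design = generate_design(1, seed=64).head(2).copy()
        design["target_angle"] = 0.0
        design["condition"] = "distractor_absent"
        design["distractor_angle"] = np.nan
        ts = simulate_timeseries(design, pop, noise_sd=0.0, seed=65,
                                 zscore=False)
        with pytest.raises(ValueError, match="RF_in"):
            rf_sorted_timecourse(ts, pop, design, align_to="target")
        tc = rf_sorted_timecourse(ts, pop, design, align_to="target",
                                  in_thresh=165.0)
        assert set(tc["rf"]) == {"RF_in", "RF_out"}
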