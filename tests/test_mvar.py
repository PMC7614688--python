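"""MVAR fitting and the statistics derived from it."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynalign import mvar, synth
from dynalign.mvar import (
    MVARFit,
    behavioral_stats,
    celltype_loading,
    celltype_perturbation_response,
    conditional_mode_averages,
    discriminants,
    fit_mvar,
    fit_mvar_constrained,
    impulse_time_constant,
    information_summary,
    mode_density_change,
    mvar_modes,
    pool_modes,
    preferred_stim_changes,
    random_discriminant_inputs,
    shuffle_null,
    trial_average_svd,
)
from dynalign.synth import CONDITIONS, N_FRAMES

from conftest import make_scenario_recordings


def toy_fit(A, Ts=125.0, n_types=True):
    """Wrap an interaction matrix in a minimal MVARFit for the analytic
    operations (modes, impulse responses, pathways)."""
    n = A.shape[0]
    u = np.zeros((3, N_FRAMES - 1, n))
    u[0, 8:] = 1.0  # V input along all neurons
    time_axis = (np.arange(N_FRAMES) - 8) * Ts / 1000.0
    return MVARFit(
        A=np.asarray(A, dtype=float), u=u, xi=np.zeros(n),
        residuals=np.zeros((1, N_FRAMES - 1, n)), resid_cov=np.eye(n),
        Ts=Ts, condition=np.array(["V"]),
        cell_types=np.array((["PYR"] * (n - n // 2)) + ["PV"] * (n // 2)),
        time_axis=time_axis,
    )


class TestFit:
    def test_parameter_recovery(self, realignment_small):
        pairs, recs_pre, _ = realignment_small
        gt = pairs[0]["pre"]
        fit = fit_mvar(recs_pre[0])
        off = ~np.eye(gt.n_neurons, dtype=bool)
        r = np.corrcoef(gt.A[off], fit.A[off])[0, 1]
        assert r > 0.9
        np.testing.assert_allclose(fit.xi, gt.xi, atol=0.05)

    def test_residual_means_vanish_per_cell(self, realignment_small):
        _, recs_pre, _ = realignment_small
        rec = recs_pre[0]
        fit = fit_mvar(rec)
        cidx = np.array([CONDITIONS.index(c) for c in rec.condition])
        for c in range(3):
            means = fit.residuals[cidx == c].mean(axis=0)
            assert np.max(np.abs(means)) < 1e-8

    def test_residual_orthogonality(self, realignment_small):
        """OLS residuals are orthogonal to every design column."""
        _, recs_pre, _ = realignment_small
        rec = recs_pre[0]
        fit = fit_mvar(rec)
        prev = rec.activity[:, :-1].reshape(-1, rec.n_neurons)
        res = fit.residuals.reshape(-1, rec.n_neurons)
        scale = np.linalg.norm(prev) * np.linalg.norm(res)
        assert np.max(np.abs(prev.T @ res)) < 1e-6 * scale
        run = rec.run_speed[:, 1:].reshape(-1)
        assert np.max(np.abs(run @ res)) < 1e-6 * np.linalg.norm(run) * \
            np.linalg.norm(res)

    def test_zero_activity_recording(self, small_recording):
        rec = small_recording
        zero = synth.PopulationRecording(
            activity=np.zeros_like(rec.activity),
            condition=rec.condition, time_axis=rec.time_axis,
            run_speed=np.zeros_like(rec.run_speed), licks=rec.licks * 0,
            cell_types=rec.cell_types, Ts=rec.Ts,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_mvar(zero)
        assert np.allclose(fit.A, 0.0)
        assert np.allclose(fit.u, 0.0)
        assert np.allclose(fit.residuals, 0.0)

    def test_lick_regressor_inert_without_licks(self, small_recording):
        rec = small_recording
        no_licks = synth.PopulationRecording(
            activity=rec.activity, condition=rec.condition,
            time_axis=rec.time_axis, run_speed=rec.run_speed,
            licks=np.zeros_like(rec.licks), cell_types=rec.cell_types,
            Ts=rec.Ts,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            with_lick = fit_mvar(no_licks, include_lick=True)
        without = fit_mvar(no_licks)
        np.testing.assert_allclose(with_lick.A, without.A, atol=1e-6)

    def test_too_few_trials_rejected(self, small_recording):
        rec = small_recording
        keep = np.concatenate([
            rec.trials_of("V")[:1], rec.trials_of("A"), rec.trials_of("gray")
        ])
        bad = synth.PopulationRecording(
            activity=rec.activity[keep], condition=rec.condition[keep],
            time_axis=rec.time_axis, run_speed=rec.run_speed[keep],
            licks=rec.licks[keep], cell_types=rec.cell_types, Ts=rec.Ts,
        )
        with pytest.raises(ValueError, match="trials"):
            fit_mvar(bad)

    def test_standardize_rescales_units(self, small_recording):
        fit = fit_mvar(small_recording, standardize=True)
        assert fit.standardized
        # standardized residual covariance should be O(1) per neuron
        assert np.all(np.diag(fit.resid_cov) < 10.0)


class TestConstrainedFit:
    def test_identical_sessions_match_unconstrained(self, small_recording):
        rec = small_recording
        for shared in ("A", "u"):
            fits = fit_mvar_constrained(rec, rec, shared=shared)
            free = fit_mvar(rec)
            np.testing.assert_allclose(fits["pre"].A, free.A, atol=1e-8)
            np.testing.assert_allclose(fits["pre"].u, free.u, atol=1e-8)

    def test_both_tied_equals_pooled(self, realignment_small):
        _, recs_pre, recs_post = realignment_small
        rec_pre, rec_post = recs_pre[0], recs_post[0]
        fits = fit_mvar_constrained(rec_pre, rec_post, shared="both")
        pooled_rec = synth.PopulationRecording(
            activity=np.concatenate([rec_pre.activity, rec_post.activity]),
            condition=np.concatenate([rec_pre.condition,
                                      rec_post.condition]),
            time_axis=rec_pre.time_axis,
            run_speed=np.concatenate([rec_pre.run_speed,
                                      rec_post.run_speed]),
            licks=np.concatenate([rec_pre.licks, rec_post.licks]),
            cell_types=rec_pre.cell_types, Ts=rec_pre.Ts,
        )
        pooled = fit_mvar(pooled_rec)
        np.testing.assert_allclose(fits["pre"].A, pooled.A, atol=1e-8)

    def test_integration_change_survives_tied_inputs(self, realignment_small):
        """On realignment data the positive learning-related change in the
        discriminant impulse time constant persists when the stimulus
        inputs are tied across sessions — the change lives in the
        interaction weights, not the input."""
        _, recs_pre, recs_post = realignment_small
        rec_pre, rec_post = recs_pre[0], recs_post[0]

        def delta(fits):
            out = []
            for name, rec in (("pre", rec_pre), ("post", rec_post)):
                d = discriminants(rec, fits[name])
                out.append(impulse_time_constant(fits[name], d["w_input"],
                                                 d["w_output"]))
            return out[1] - out[0]

        d_free = delta({"pre": fit_mvar(rec_pre),
                        "post": fit_mvar(rec_post)})
        d_shared_u = delta(fit_mvar_constrained(rec_pre, rec_post, "u"))
        assert d_free > 0
        assert d_shared_u > 0


class TestDiscriminantsAndInformation:
    def test_no_signal_gives_zero_discriminant(self, small_recording):
        rec = small_recording
        sym = synth.PopulationRecording(
            activity=np.concatenate([rec.activity, rec.activity]),
            condition=np.concatenate([
                np.where(rec.condition == "V", "A",
                         np.where(rec.condition == "A", "V",
                                  rec.condition)),
                rec.condition,
            ]),
            time_axis=rec.time_axis,
            run_speed=np.concatenate([rec.run_speed, rec.run_speed]),
            licks=np.concatenate([rec.licks, rec.licks]),
            cell_types=rec.cell_types, Ts=rec.Ts,
        )
        fit = fit_mvar(sym)
        d = discriminants(sym, fit)
        assert np.max(np.abs(d["w_output"])) < 1e-8

    def test_direction_recovery(self):
        pairs, recs_pre, _ = make_scenario_recordings(
            "null", seed=21, n_neurons=25, n_trials=500
        )
        gt = pairs[0]["pre"]
        rec = recs_pre[0]
        fit = fit_mvar(rec)
        d = discriminants(rec, fit)
        truth = np.linalg.solve(gt.resid_cov, gt.meta["discriminant"])
        cos = abs(d["w_input"] @ truth) / np.linalg.norm(d["w_input"]) \
            / np.linalg.norm(truth)
        assert cos > 0.95

    def test_output_info_invariant_under_rebasis(self, small_recording):
        rec = small_recording
        rng = np.random.default_rng(0)
        T = rng.standard_normal((rec.n_neurons, rec.n_neurons)) \
            + 3 * np.eye(rec.n_neurons)
        rebased = synth.PopulationRecording(
            activity=rec.activity @ T.T, condition=rec.condition,
            time_axis=rec.time_axis, run_speed=rec.run_speed,
            licks=rec.licks, cell_types=rec.cell_types, Ts=rec.Ts,
        )
        i1 = information_summary(rec, fit_mvar(rec))
        i2 = information_summary(rebased, fit_mvar(rebased))
        assert i1.output_info == pytest.approx(i2.output_info, rel=1e-6)

    def test_realignment_raises_gain(self, realignment_small):
        _, recs_pre, recs_post = realignment_small
        g_pre = information_summary(recs_pre[0],
                                    fit_mvar(recs_pre[0])).gain_percent
        g_post = information_summary(recs_post[0],
                                     fit_mvar(recs_post[0])).gain_percent
        assert g_post > g_pre

    def test_downstream_snr_invariant_to_w_scale(self, realignment_small):
        _, recs_pre, _ = realignment_small
        rec = recs_pre[0]
        fit = fit_mvar(rec)
        d = discriminants(rec, fit)
        t1 = impulse_time_constant(fit, d["w_input"], d["w_output"])
        t2 = impulse_time_constant(fit, 5.0 * d["w_input"],
                                   0.2 * d["w_output"])
        assert t1 == pytest.approx(t2, rel=1e-9)


class TestImpulseTimeConstant:
    def test_geometric_closed_form(self):
        lam = 0.8
        fit = toy_fit(np.diag([lam - 1.0, -0.9]))
        p = np.array([1.0, 0.0])
        tau = impulse_time_constant(fit, p, p)
        assert tau == pytest.approx(0.5 * 125.0 * (1 + lam) / (1 - lam))
        assert tau == pytest.approx(562.5)

    def test_continuum_limit(self):
        tau_star = 1000.0
        lam = np.exp(-125.0 / tau_star)
        fit = toy_fit(np.array([[lam - 1.0]]))
        p = np.array([1.0])
        assert impulse_time_constant(fit, p, p) == pytest.approx(
            tau_star, rel=0.02
        )

    def test_orthogonal_readout_flagged(self):
        fit = toy_fit(np.diag([-0.5, -0.5]))
        with pytest.warns(RuntimeWarning, match="orthogonal"):
            tau = impulse_time_constant(fit, np.array([1.0, 0.0]),
                                        np.array([0.0, 1.0]))
        assert np.isnan(tau)

    def test_divergent_dynamics_rejected(self):
        fit = toy_fit(np.diag([0.05, -0.5]))  # lambda+1 > 1
        p = np.array([1.0, 0.0])
        with pytest.raises(ValueError, match="diverges"):
            impulse_time_constant(fit, p, p)

    def test_random_input_distribution_brackets_discriminant(
        self, realignment_small
    ):
        _, recs_pre, _ = realignment_small
        rec = recs_pre[0]
        fit = fit_mvar(rec)
        d = discriminants(rec, fit)
        tau_d = impulse_time_constant(fit, d["w_input"], d["w_output"])
        pairs = random_discriminant_inputs(fit, rec, 200, seed=0)
        taus = np.array([
            impulse_time_constant(fit, pr["p"], pr["w"]) for pr in pairs
        ])
        taus = taus[np.isfinite(taus)]
        assert taus.min() < tau_d < taus.max()

    def test_random_inputs_reproducible(self, realignment_small):
        _, recs_pre, _ = realignment_small
        rec = recs_pre[0]
        fit = fit_mvar(rec)
        a = random_discriminant_inputs(fit, rec, 3, seed=5)
        b = random_discriminant_inputs(fit, rec, 3, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x["p"], y["p"])


class TestModes:
    def test_discrete_to_continuous_tau(self):
        fit = toy_fit(np.diag([-0.5, -0.8]))
        ms = mvar_modes(fit)
        assert ms.time_constant[0] == pytest.approx(-125.0 / np.log(0.5))
        assert ms.time_constant[0] == pytest.approx(180.3, abs=0.1)

    def test_aligned_mode_has_unit_normalized_snr(self):
        # diagonal A with isotropic residuals: mode 0 is axis-aligned,
        # input difference along the same axis
        fit = toy_fit(np.diag([-0.3, -0.6]))
        fit.u[0, 8:] = np.array([1.0, 0.0])
        ms = mvar_modes(fit)
        assert ms.normalized_snr.max() == pytest.approx(1.0)

    def test_normalized_snr_bounded(self, realignment_small):
        _, recs_pre, recs_post = realignment_small
        for rec in (recs_pre[0], recs_post[0]):
            ms = mvar_modes(fit_mvar(rec))
            assert np.all(ms.normalized_snr <= 1.0 + 1e-8)
            assert np.all(ms.time_constant > 0)

    def test_ground_truth_tau_recovered_from_exact_parameters(self):
        spec = synth.ScenarioSpec("realignment", n_neurons=20, seed=30)
        pair = synth.make_ground_truth_pair(spec)
        fit = toy_fit(pair["pre"].A)
        ms = mvar_modes(fit)
        assert ms.time_constant.max() == pytest.approx(spec.slow_tau_ms,
                                                       rel=0.10)

    def test_oscillatory_modes_excluded(self):
        rot = 0.5 * np.array([[np.cos(1.0), -np.sin(1.0)],
                              [np.sin(1.0), np.cos(1.0)]])
        fit = toy_fit(rot - np.eye(2))
        assert mvar_modes(fit).n_modes == 0


class TestModeAggregation:
    def test_single_mode_curves(self):
        fit = toy_fit(np.array([[np.exp(-125.0 / 850.0) - 1.0]]))
        fit.u[0, 8:] = 1.0
        ms = mvar_modes(fit)
        curves = conditional_mode_averages(ms)
        tau = ms.time_constant[0]
        in_win = np.abs(curves["tau_centers"] - tau) <= 50.0
        assert np.all(curves["snr_given_tau"][in_win]
                      == pytest.approx(ms.normalized_snr[0]))
        assert np.all(np.isnan(curves["snr_given_tau"][~in_win]))

    def test_curves_invariant_to_mode_order(self, realignment_small):
        _, recs_pre, _ = realignment_small
        ms = mvar_modes(fit_mvar(recs_pre[0]))
        rng = np.random.default_rng(1)
        perm = rng.permutation(ms.n_modes)
        shuffled = dataclasses.replace(
            ms, eigenvalue=ms.eigenvalue[perm],
            time_constant=ms.time_constant[perm],
            input_snr=ms.input_snr[perm],
            normalized_snr=ms.normalized_snr[perm],
            patterns=ms.patterns[perm], real_valid=ms.real_valid[perm],
        )
        a = conditional_mode_averages(ms)
        b = conditional_mode_averages(shuffled)
        np.testing.assert_allclose(a["snr_given_tau"], b["snr_given_tau"])

    def test_density_change_zero_for_identical_sets(self, realignment_small):
        _, recs_pre, _ = realignment_small
        ms = mvar_modes(fit_mvar(recs_pre[0]))
        out = mode_density_change(ms, ms)
        np.testing.assert_allclose(out["delta"], 0.0)

    def test_density_total_mass(self):
        """The smoothed density integrates to 2 pi sigma_tau sigma_snr per
        mode (fine grid, mode well inside the grid)."""
        fit = toy_fit(np.array([[np.exp(-125.0 / 700.0) - 1.0]]))
        fit.u[0, 8:] = 0.2
        ms = mvar_modes(fit)
        ms.normalized_snr[:] = 0.15
        tau_grid = np.arange(0.0, 1500.0, 5.0)
        snr_grid = np.arange(0.0, 0.3, 0.00125)
        out = mode_density_change(ms, ms, tau_grid=tau_grid,
                                  snr_grid=snr_grid)
        mass = out["n_pre"].sum() * 5.0 * 0.00125
        assert mass == pytest.approx(2 * np.pi * 100.0 * 0.025, rel=0.01)

    def test_pool_modes_concatenates(self, realignment_small):
        _, recs_pre, recs_post = realignment_small
        a = mvar_modes(fit_mvar(recs_pre[0]))
        b = mvar_modes(fit_mvar(recs_post[0]))
        pooled = pool_modes([a, b])
        assert pooled.n_modes == a.n_modes + b.n_modes


class TestShuffleNull:
    def test_single_shuffle_degenerate_ci(self, realignment_small):
        _, recs_pre, recs_post = realignment_small
        res = shuffle_null(recs_pre[0], recs_post[0], "delta_info_gain",
                           n_shuffles=1, seed=0)
        assert res["ci_low"] == pytest.approx(res["ci_high"])

    def test_seeded_reproducibility(self, realignment_small):
        _, recs_pre, recs_post = realignment_small
        a = shuffle_null(recs_pre[0], recs_post[0], "delta_info_gain",
                         n_shuffles=3, seed=7)
        b = shuffle_null(recs_pre[0], recs_post[0], "delta_info_gain",
                         n_shuffles=3, seed=7)
        np.testing.assert_array_equal(a["null"], b["null"])

    def test_unknown_statistic_rejected(self, realignment_small):
        _, recs_pre, recs_post = realignment_small
        with pytest.raises(KeyError):
            shuffle_null(recs_pre[0], recs_post[0], "nope", 2, 0)

    def test_shuffle_preserves_trial_counts(self, realignment_small):
        _, recs_pre, recs_post = realignment_small
        rng = np.random.default_rng(0)
        a, b = mvar._shuffled_pair(recs_pre[0], recs_post[0], rng)
        for cond in CONDITIONS:
            assert a.trials_of(cond).shape == \
                recs_pre[0].trials_of(cond).shape
            assert b.trials_of(cond).shape == \
                recs_post[0].trials_of(cond).shape


class TestCellTypes:
    def test_uniform_magnitudes_give_unit_loading(self):
        w = np.array([1.0, -1.0, 1.0, -1.0])
        types = np.array(["PYR", "PYR", "PV", "PV"])
        out = celltype_loading(w, types)
        assert out["PYR"] == pytest.approx(1.0)
        assert out["PV"] == pytest.approx(1.0)

    def test_concentrated_loading(self):
        w = np.array([1.0, 1.0, 0.0, 0.0])
        types = np.array(["PYR", "PYR", "PV", "PV"])
        out = celltype_loading(w, types)
        assert out["PYR"] == pytest.approx(2.0)
        assert out["PV"] == pytest.approx(0.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_weighted_sum_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        w = rng.standard_normal(n)
        types = rng.choice(["PYR", "PV", "SOM"], size=n)
        if not np.any(w):
            return
        out = celltype_loading(w, types)
        total = sum(
            out[c] * np.sum(types == c) / n for c in np.unique(types)
        )
        assert total == pytest.approx(1.0)

    def test_perturbation_decomposition_identity(self, realignment_small):
        _, recs_pre, _ = realignment_small
        rec = recs_pre[0]
        fit = fit_mvar(rec)
        rng = np.random.default_rng(2)
        w = rng.standard_normal(rec.n_neurons)
        p = rng.standard_normal(rec.n_neurons)
        out = celltype_perturbation_response(fit, w, p, horizon=12)
        summed = sum(out["pathways"].values())
        np.testing.assert_allclose(summed, out["total"], atol=1e-10)

    def test_single_class_equals_total(self):
        fit = toy_fit(np.diag([-0.4, -0.7]))
        fit.cell_types = np.array(["PYR", "PYR"])
        w = np.array([1.0, 2.0])
        p = np.array([0.5, -1.0])
        out = celltype_perturbation_response(fit, w, p, horizon=5)
        np.testing.assert_allclose(out["pathways"][("PYR", "PYR")],
                                   out["total"])

    def test_time_zero_block_inner_products(self):
        fit = toy_fit(np.diag([-0.4, -0.7]))
        w = np.array([1.0, 2.0])
        p = np.array([0.5, -1.0])
        out = celltype_perturbation_response(fit, w, p, horizon=1)
        types = fit.cell_types
        for x in ("PYR", "PV"):
            for y in ("PYR", "PV"):
                wx = np.where(types == x, w, 0.0)
                py = np.where(types == y, p, 0.0)
                assert out["pathways"][(x, y)][0] == pytest.approx(wx @ py)


class TestBehavioralStats:
    def test_all_licks_on_v_trials(self, small_recording):
        rec = small_recording
        licks = np.zeros_like(rec.licks)
        licks[rec.condition == "V", 10] = 1
        with_licks = synth.PopulationRecording(
            activity=rec.activity, condition=rec.condition,
            time_axis=rec.time_axis, run_speed=rec.run_speed,
            licks=licks, cell_types=rec.cell_types, Ts=rec.Ts,
        )
        w = np.ones(rec.n_neurons)
        out = behavioral_stats(with_licks, w)
        occupied = ~np.isnan(out["hit_rate"])
        assert np.all(out["hit_rate"][occupied] == 1.0)
        assert np.all(out["fa_rate"][occupied] == 0.0)

    def test_white_noise_autocorrelation(self):
        rng = np.random.default_rng(3)
        n_trials, n = 600, 5
        activity = rng.standard_normal((n_trials, N_FRAMES, n))
        rec = synth.PopulationRecording(
            activity=activity,
            condition=np.array((["V", "A", "gray"] * n_trials)[:n_trials]),
            time_axis=(np.arange(N_FRAMES) - 8) * 0.125,
            run_speed=np.zeros((n_trials, N_FRAMES)),
            licks=np.zeros((n_trials, N_FRAMES), dtype=np.int8),
            cell_types=np.array(["PYR"] * n),
            Ts=125.0,
        )
        out = behavioral_stats(rec, np.ones(n))
        T = 8
        ac = out["autocorrelation"]["V"]
        assert ac[0] == pytest.approx(1.0)
        assert np.max(np.abs(ac[1:])) < 0.15
        assert out["autocorrelation_auc"]["V"] == pytest.approx(
            1.0 / (2 * T + 1), abs=0.05
        )

    def test_no_licks_flagged(self, small_recording):
        rec = small_recording
        silent = synth.PopulationRecording(
            activity=rec.activity, condition=rec.condition,
            time_axis=rec.time_axis, run_speed=rec.run_speed,
            licks=np.zeros_like(rec.licks), cell_types=rec.cell_types,
            Ts=rec.Ts,
        )
        out = behavioral_stats(silent, np.ones(rec.n_neurons))
        assert out["has_licks"] is False
        assert out["hit_rate"] is None

    def test_snr_timecourse_rises_after_onset(self, realignment_small):
        _, _, recs_post = realignment_small
        rec = recs_post[0]
        fit = fit_mvar(rec)
        w = discriminants(rec, fit)["w_output"]
        out = behavioral_stats(rec, w)
        snr = out["snr_timecourse"]
        pre = snr[rec.time_axis < 0].mean()
        post = snr[rec.time_axis >= 0.25].mean()
        assert post > 3 * pre


class TestTrialAverageSVD:
    def test_reconstruction(self, realignment_small):
        _, recs_pre, _ = realignment_small
        out = trial_average_svd(recs_pre)
        X = out["U"] @ np.diag(out["S"]) @ out["Vt"]
        np.testing.assert_allclose(X, out["X"], atol=1e-8)

    def test_alignments_bounded(self, realignment_small):
        _, recs_pre, _ = realignment_small
        out = trial_average_svd(recs_pre)
        assert np.all(np.abs(out["alignments"]) <= 1.0 + 1e-12)

    def test_rank_one_input(self, small_recording):
        rec = small_recording
        pattern = np.outer(np.linspace(0, 1, N_FRAMES),
                           np.arange(rec.n_neurons) + 1.0)
        rank1 = synth.PopulationRecording(
            activity=np.tile(pattern, (rec.n_trials, 1, 1)),
            condition=rec.condition, time_axis=rec.time_axis,
            run_speed=rec.run_speed, licks=rec.licks,
            cell_types=rec.cell_types, Ts=rec.Ts,
        )
        out = trial_average_svd([rank1])
        assert out["S"][0] > 0
        assert np.all(out["S"][1:] < 1e-10 * out["S"][0])


class TestPreferredStimulusChanges:
    def _pref_recording(self, resp, seed, n_trials=60):
        """Sessions with an explicit (neuron x condition) response table.

        ``resp`` maps condition -> per-neuron post-stimulus response
        amplitude; independent trial noise is added on top.
        """
        rng = np.random.default_rng(seed)
        n = resp["V"].shape[0]
        cond = np.repeat(CONDITIONS, n_trials)
        time_axis = (np.arange(N_FRAMES) - 8) * 0.125
        env = (time_axis >= 0).astype(float)
        act = 0.3 * rng.standard_normal((3 * n_trials, N_FRAMES, n))
        for i, c in enumerate(cond):
            act[i] += env[:, None] * resp[c][None, :]
        return synth.PopulationRecording(
            activity=act, condition=cond, time_axis=time_axis,
            run_speed=np.zeros((3 * n_trials, N_FRAMES)),
            licks=np.zeros((3 * n_trials, N_FRAMES), dtype=np.int8),
            cell_types=np.array(["PYR"] * n), Ts=125.0,
        )

    def _base_resp(self, n=20):
        pref_v = np.array([True] * (n // 2) + [False] * (n // 2))
        resp_v = np.where(pref_v, 1.0, 0.4)
        resp_a = np.where(pref_v, 0.4, 1.0)
        return {"V": resp_v, "A": resp_a, "gray": np.zeros(n)}

    def test_identical_sessions_zero_change(self):
        rec = self._pref_recording(self._base_resp(), seed=0)
        out = preferred_stim_changes(rec, rec)
        assert out["summary"] is not None
        assert out["summary"]["pref"]["mean"] == pytest.approx(0.0)
        assert out["summary"]["nonpref"]["mean"] == pytest.approx(0.0)
        assert out["table"].included.sum() > 0

    def test_nonpreferred_suppression_detected(self):
        """Post-learning suppression of the non-preferred input shows up
        as a negative mean non-preferred change, with a more heterogeneous
        (boosted and suppressed) preferred change."""
        base = self._base_resp()
        rng = np.random.default_rng(42)
        n = base["V"].shape[0]
        pref_v = base["V"] > base["A"]
        jitter = 0.25 * rng.standard_normal(n)  # heterogeneous pref change
        post = {
            "V": np.where(pref_v, base["V"] + jitter, base["V"] - 0.25),
            "A": np.where(pref_v, base["A"] - 0.25, base["A"] + jitter),
            "gray": base["gray"],
        }
        pre = self._pref_recording(base, seed=1)
        post_rec = self._pref_recording(post, seed=2)
        out = preferred_stim_changes(pre, post_rec)
        s = out["summary"]
        assert s["nonpref"]["mean"] < 0
        assert s["pref"]["var"] > s["nonpref"]["var"]

    def test_flipped_preference_excluded(self):
        pre = self._pref_recording(self._base_resp(), seed=3)
        flipped = synth.PopulationRecording(
            activity=-pre.activity, condition=pre.condition,
            time_axis=pre.time_axis, run_speed=pre.run_speed,
            licks=pre.licks, cell_types=pre.cell_types, Ts=pre.Ts,
        )
        out = preferred_stim_changes(pre, flipped)
        assert out["table"].included.sum() == 0
        assert out["summary"] is None
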