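import warnings
from dataclasses import replace

import numpy as np
import pytest

from olfnet.betas import condition_summary, single_trial_betas, trial_regressors
from olfnet.bold import canonical_hrf, simulate_network_series
from olfnet.cohort import simulate_cohort
from olfnet.hrf import (
    HRFEstimate,
    drift_matrix,
    estimate_fir_hrf,
    fir_design,
    group_hrf,
    phase_relation,
)
from olfnet.paradigm import ODOR_VISUAL, build_paradigm
from olfnet.templates import DMN, ON


def _event_response(design, n_lags=11):
    """A response with support inside the FIR window (kernel 14 s + 6 s box)."""
    kernel = canonical_hrf(design.tr, duration=14.0)
    box = np.ones(int(6 / design.tr))
    resp = np.convolve(box, kernel)
    assert resp.size <= n_lags
    out = np.zeros(n_lags)
    out[: resp.size] = resp
    return out


def _timecourse_from(design, resp, amps=None, condition=ODOR_VISUAL):
    y = np.zeros(design.n_volumes)
    onsets = design.onset_volumes(condition)
    amps = np.ones(onsets.size) if amps is None else amps
    for a, o in zip(amps, onsets):
        stop = min(o + resp.size, design.n_volumes)
        y[o:stop] += a * resp[: stop - o]
    return y


class TestFIRDeconvolution:
    def test_window_of_20s_gives_11_coefficients(self, design):
        F = fir_design(design, window=20.0)
        assert F.shape == (234, 11)

    def test_noiseless_recovery_matches_generator_exactly(self, design):
        resp = _event_response(design)
        y = _timecourse_from(design, resp)
        est = estimate_fir_hrf(y, design, window=20.0)
        np.testing.assert_allclose(est.values * est.scale, resp, atol=1e-6)
        assert est.peak_latency == np.argmax(resp) * design.tr

    def test_noisy_peak_latency_within_one_tr(self, design, spec, cn_cohort):
        from olfnet.bold import convolved_regressors

        gen_resp = convolved_regressors(design)[:, 0]
        onset0 = design.onset_volumes(ODOR_VISUAL)[0]
        gen_peak = (np.argmax(gen_resp[onset0:onset0 + 11])) * design.tr
        hits = 0
        for seed in range(20):
            out = simulate_network_series(
                cn_cohort.iloc[seed % len(cn_cohort)], design, spec,
                np.random.default_rng(seed),
            )
            est = estimate_fir_hrf(out["eta"][:, 0], design, network=ON)
            hits += abs(est.peak_latency - gen_peak) <= design.tr
        assert hits >= 19

    def test_rank_deficient_fir_design_rejected(self):
        # a lone event so close to the scan end that trailing lag columns
        # are empty leaves the FIR design singular
        from olfnet.paradigm import Event, ParadigmDesign

        d = ParadigmDesign(
            tr=2.0, n_volumes=54,
            events=(Event(100.0, 6.0, ODOR_VISUAL, 1),),
        )
        with pytest.raises(ValueError, match="rank-deficient|overlap"):
            estimate_fir_hrf(np.zeros(54), d, window=20.0)


class TestGroupHRF:
    def _estimate(self, values):
        values = np.asarray(values, float)
        peak = int(np.argmax(np.abs(values)))
        return HRFEstimate(ON, np.arange(values.size) * 2.0, values,
                           peak * 2.0, 1.0)

    def test_mean_of_identical_inputs_is_identity(self):
        e = self._estimate([0.1, 0.8, 1.0, 0.4, -0.1])
        g = group_hrf([e, e, e])
        np.testing.assert_allclose(g.values, e.values)

    def test_mirrored_inputs_flagged_degenerate(self):
        e = self._estimate([0.1, 0.8, 1.0, 0.4, -0.1])
        m = self._estimate(-np.asarray([0.1, 0.8, 1.0, 0.4, -0.1]))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            g = group_hrf([e, m])
        assert g.degenerate
        assert any("near zero" in str(w.message) for w in caught)

    def test_group_hrf_beats_median_individual_estimate(self, design, spec, cn_cohort):
        # pooling CN subjects should land closer to the generator response
        from olfnet.bold import convolved_regressors

        gen = convolved_regressors(design)[:, 0]
        onset0 = design.onset_volumes(ODOR_VISUAL)[0]
        gen_curve = gen[onset0:onset0 + 11]
        gen_curve = gen_curve / np.abs(gen_curve).max()
        wins = 0
        for seed in range(10):
            ests = [
                estimate_fir_hrf(
                    simulate_network_series(
                        row, design, spec, np.random.default_rng(seed * 50 + i)
                    )["eta"][:, 0],
                    design, network=ON,
                )
                for i, (_, row) in enumerate(cn_cohort.iterrows())
            ]
            g = group_hrf(ests)
            g_err = np.linalg.norm(g.values - gen_curve)
            ind_err = np.median(
                [np.linalg.norm(e.values - gen_curve) for e in ests]
            )
            wins += g_err < ind_err
        assert wins >= 8

    def test_mismatched_lag_grids_rejected(self):
        a = self._estimate([0.0, 1.0, 0.5])
        b = HRFEstimate(ON, np.arange(4) * 2.0, np.array([0, 1, 0.5, 0.1]),
                        2.0, 1.0)
        with pytest.raises(ValueError, match="lag grid"):
            group_hrf([a, b])


class TestPhaseRelation:
    def _pair(self, on_vals, dmn_vals):
        lags = np.arange(len(on_vals)) * 2.0
        return (
            HRFEstimate(ON, lags, np.asarray(on_vals, float), 0.0, 1.0),
            HRFEstimate(DMN, lags, np.asarray(dmn_vals, float), 0.0, 1.0),
        )

    def test_mirror_is_perfectly_antiphase(self):
        on, dmn = self._pair([0, 1, 0.5, -0.2], [0, -1, -0.5, 0.2])
        rel = phase_relation(on, dmn)
        assert rel.correlation == pytest.approx(-1.0)
        assert rel.antiphase

    def test_identical_curves_are_in_phase(self):
        on, dmn = self._pair([0, 1, 0.5, -0.2], [0, 1, 0.5, -0.2])
        rel = phase_relation(on, dmn)
        assert rel.correlation == pytest.approx(1.0)
        assert not rel.antiphase

    def test_constant_curve_flagged(self):
        on, dmn = self._pair([1, 1, 1, 1], [0, 1, 0, 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rel = phase_relation(on, dmn)
        assert rel.degenerate and not rel.antiphase


class TestSingleTrialBetas:
    def _hrf(self, design):
        resp = _event_response(design)
        peak = int(np.argmax(np.abs(resp)))
        return HRFEstimate(ON, np.arange(resp.size) * design.tr,
                           resp / np.abs(resp).max(), peak * design.tr,
                           float(np.abs(resp).max()))

    def test_noiseless_planted_amplitudes_recovered(self, design):
        hrf = self._hrf(design)
        rng = np.random.default_rng(20)
        amps = rng.uniform(0.5, 2.0, size=len(design.events))
        y = np.zeros(design.n_volumes)
        X = trial_regressors(design, hrf)
        y = X @ amps
        table = single_trial_betas(y, design, hrf)
        np.testing.assert_allclose(table.beta.to_numpy(), amps, atol=1e-6)

    def test_doubling_odor_amplitude_doubles_odor_betas(self, design):
        hrf = self._hrf(design)
        X = trial_regressors(design, hrf)
        amps = np.ones(len(design.events))
        odor_idx = [j for j, e in enumerate(design.events)
                    if e.condition == ODOR_VISUAL]
        amps2 = amps.copy()
        amps2[odor_idx] = 2.0
        b1 = single_trial_betas(X @ amps, design, hrf)
        b2 = single_trial_betas(X @ amps2, design, hrf)
        m1 = b1[b1.condition == ODOR_VISUAL].beta.mean()
        m2 = b2[b2.condition == ODOR_VISUAL].beta.mean()
        assert m2 == pytest.approx(2 * m1, rel=1e-8)

    @pytest.mark.parametrize("c", [0.5, 3.0, -2.0])
    def test_scaling_timecourse_scales_every_beta(self, design, c):
        hrf = self._hrf(design)
        rng = np.random.default_rng(21)
        y = rng.standard_normal(design.n_volumes)
        b = single_trial_betas(y, design, hrf).beta.to_numpy()
        bc = single_trial_betas(c * y, design, hrf).beta.to_numpy()
        np.testing.assert_allclose(bc, c * b, rtol=1e-8)

    def test_least_squares_matches_normal_equations_oracle(self, design):
        hrf = self._hrf(design)
        rng = np.random.default_rng(22)
        y = rng.standard_normal(design.n_volumes)
        X = np.column_stack(
            [trial_regressors(design, hrf), drift_matrix(design.n_volumes, 2)]
        )
        oracle = np.linalg.solve(X.T @ X, X.T @ y)[: len(design.events)]
        got = single_trial_betas(y, design, hrf).beta.to_numpy()
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_collinear_regressors_rejected(self, design):
        flat = HRFEstimate(ON, np.array([0.0]), np.array([0.0]), 0.0, 0.0)
        with pytest.raises(ValueError, match="collinear|rank"):
            single_trial_betas(np.zeros(design.n_volumes), design, flat)


class TestConditionSummary:
    def _table(self, odor, visual, subject="s1"):
        rows = [{"subject_id": subject, "trial": i, "condition": ODOR_VISUAL,
                 "intensity": 1, "beta": b} for i, b in enumerate(odor)]
        rows += [{"subject_id": subject, "trial": 100 + i,
                  "condition": "visual_only", "intensity": None, "beta": b}
                 for i, b in enumerate(visual)]
        import pandas as pd

        return pd.DataFrame(rows)

    def test_equal_condition_amplitudes_zero_difference(self):
        s = condition_summary(self._table([1.0, 1.0], [1.0, 1.0]))
        assert s.difference.iloc[0] == pytest.approx(0.0)

    def test_planted_odor_excess_positive_difference(self):
        s = condition_summary(self._table([2.0, 2.2], [1.0, 0.8]))
        assert s.difference.iloc[0] > 0

    def test_missing_condition_flagged_with_undefined_difference(self):
        t = self._table([1.0, 1.5], [])
        s = condition_summary(t)
        assert not s.complete.iloc[0]
        assert np.isnan(s.difference.iloc[0])

    def test_group_pattern_on_default_cohorts(self, design, spec):
        # CN odor response exceeds MCI's; AD odor-vs-visual difference ~ 0
        df = simulate_cohort(spec.with_sizes(5, 5, 5), seed=30)
        hrf = self._hrf(design)
        means = {}
        for g in ("CN", "MCI", "AD"):
            rows = df[df.group == g]
            odor, diff = [], []
            for i, (_, row) in enumerate(rows.iterrows()):
                out = simulate_network_series(
                    row, design, spec, np.random.default_rng(300 + i)
                )
                b = single_trial_betas(out["eta"][:, 0], design, hrf,
                                       subject_id=row.subject_id)
                s = condition_summary(b)
                odor.append(s[ODOR_VISUAL].iloc[0])
                diff.append(s.difference.iloc[0])
            means[g] = (np.mean(odor), np.mean(diff))
        assert means["CN"][0] > means["MCI"][0]
        assert means["CN"][1] > 0.1 and means["MCI"][1] > 0.1
        assert abs(means["AD"][1]) < 0.1

    def _hrf(self, design):
        resp = _event_response(design)
        peak = int(np.argmax(np.abs(resp)))
        return HRFEstimate(ON, np.arange(resp.size) * design.tr,
                           resp / np.abs(resp).max(), peak * design.tr,
                           float(np.abs(resp).max()))
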