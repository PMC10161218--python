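"""T-jump calibration, relaxation fitting, and the kinetic melting fit."""

import numpy as np
import pytest

from cagrna import thermo
from cagrna.thermo import MeltingParameters
from cagrna.tjump import (AmplitudeCurve, JumpProtocol, RelaxationFit,
                          RelaxationTrace, TemperatureCalibration,
                          build_amplitude_curve, calibrate_temperature,
                          fit_melting, fit_relaxation)
from cagrna.synthetic import NoiseSpec, gen_amplitude_curve, gen_tjump_experiment


class TestCalibration:
    def test_reference_point_identity(self):
        cal = TemperatureCalibration(f_ref=100.0, t_ref=296.0, sensitivity=0.02)
        assert cal.to_temperature(100.0) == pytest.approx(296.0, abs=1e-12)

    def test_two_pair_fit_recovers_sensitivity(self):
        # ln(100/60.65)/25 = 0.0200 K^-1
        cal = TemperatureCalibration.from_pairs([100.0, 60.65], [296.0, 321.0])
        assert cal.sensitivity == pytest.approx(0.02, abs=1e-4)

    def test_noiseless_roundtrip(self):
        temps = np.linspace(296.0, 330.0, 40)
        f = 100.0 * np.exp(-0.02 * (temps - 296.0))
        cal = TemperatureCalibration.from_pairs(f, temps)
        recovered = calibrate_temperature(f, cal)
        assert np.max(np.abs(recovered - temps)) < 1e-6

    def test_non_monotone_pairs_rejected(self):
        with pytest.raises(ValueError):
            TemperatureCalibration.from_pairs([100.0, 110.0, 90.0],
                                              [296.0, 300.0, 305.0])

    def test_extrapolation_warns(self):
        cal = TemperatureCalibration.from_pairs([100.0, 60.65], [296.0, 321.0])
        with pytest.warns(UserWarning, match="extrapolat"):
            cal.to_temperature(20.0)


def _make_trace(a=0.05, k=2.0, offset=1.0, noise=0.0, seed=0, dt=0.1, dwell=25.0):
    t = np.arange(0.0, dwell, dt)
    rng = np.random.default_rng(seed)
    ratio = offset + a * (1.0 - np.exp(-k * t))
    donor = 1000.0 * ratio * (1.0 + rng.normal(0, noise, t.shape))
    return RelaxationTrace(time=t, donor=donor, acceptor=np.full_like(t, 1000.0),
                           pre_jump_T=300.0, post_jump_T=310.0)


class TestRelaxation:
    def test_noiseless_exact_recovery(self):
        fit = fit_relaxation(_make_trace(a=0.05, k=2.0))
        assert fit.amplitude == pytest.approx(0.05, abs=1e-8)
        assert fit.k_obs == pytest.approx(2.0, abs=1e-8)
        assert not fit.flagged

    def test_flat_trace_flagged_with_zero_amplitude(self):
        fit = fit_relaxation(_make_trace(a=0.0))
        assert fit.flagged
        assert fit.amplitude == 0.0

    def test_negative_amplitude_sign_preserved(self):
        fit = fit_relaxation(_make_trace(a=-0.04, k=1.5))
        assert fit.amplitude == pytest.approx(-0.04, abs=1e-8)

    def test_too_few_post_jump_points_rejected(self):
        t = np.arange(5) * 1.0
        with pytest.raises(ValueError):
            fit_relaxation(RelaxationTrace(time=t, donor=np.full(5, 600.0),
                                           acceptor=np.full(5, 1000.0),
                                           pre_jump_T=300.0, post_jump_T=310.0))

    def test_onset_detection_from_temperature_series(self):
        tr = _make_trace()
        tr.temperature = np.where(tr.time < 2.0, 300.0, 310.0)
        assert tr.onset_index() == np.searchsorted(tr.time, 2.0)

    def test_amplitude_recovery_under_ladder_noise(self, dpbs_params, ladder):
        """Across seeded noisy ladders the mean fitted amplitude of the
        largest jump stays within 2% of the generating truth."""
        truth = None
        recovered = []
        for seed in range(100):
            exp = gen_tjump_experiment(dpbs_params, ladder, NoiseSpec(0.01, seed))
            k = int(np.argmax(np.abs(exp.true_curve.amplitudes)))
            truth = exp.true_curve.amplitudes[k]
            recovered.append(fit_relaxation(exp.traces[k]).amplitude)
        assert np.mean(recovered) == pytest.approx(truth, rel=0.02)


class TestAmplitudeCurve:
    def _fits(self, n, flag=()):
        return [RelaxationFit(amplitude=0.01 * k, k_obs=1.0, offset=0.6,
                              residual_rms=0.0, flagged=(k in flag),
                              message="fit did not converge" if k in flag else "")
                for k in range(n)]

    def test_count_conservation(self, ladder):
        curve = build_amplitude_curve(self._fits(19), ladder)
        assert len(curve) == 19

    def test_flagged_fits_excluded(self, ladder, caplog):
        import logging
        with caplog.at_level(logging.INFO, logger="cagrna.tjump"):
            curve = build_amplitude_curve(self._fits(19, flag={2, 5, 7}), ladder)
        assert len(curve) == 16
        assert sum("excluded" in r.message for r in caplog.records) == 3

    def test_all_flagged_is_error(self, ladder):
        with pytest.raises(ValueError, match="all relaxation fits flagged"):
            build_amplitude_curve(self._fits(19, flag=set(range(19))), ladder)

    def test_protocol_fits_in_eight_minutes(self, ladder):
        assert ladder.n_jumps == 19
        assert ladder.total_duration == pytest.approx(475.0)
        assert ladder.total_duration <= 480.0


class TestMeltingFit:
    def test_noiseless_roundtrip(self, dpbs_params, ladder):
        curve = gen_amplitude_curve(dpbs_params, ladder)
        res = fit_melting(curve)
        assert res.params.tm == pytest.approx(349.0, abs=1e-4)
        assert res.params.g1 == pytest.approx(dpbs_params.g1, abs=1e-4)
        assert res.dg37 == pytest.approx(20.7, abs=1e-3)

    def test_roundtrip_with_drift(self, dpbs_params, ladder):
        curve = gen_amplitude_curve(dpbs_params, ladder, c=0.8, drift=5e-4)
        res = fit_melting(curve)
        assert res.params.tm == pytest.approx(349.0, abs=1e-3)
        assert res.drift == pytest.approx(5e-4, rel=1e-3)

    def test_scale_invariance_of_melting_parameters(self, dpbs_params, ladder):
        """Multiplying all amplitudes by a positive constant only rescales c."""
        curve = gen_amplitude_curve(dpbs_params, ladder)
        scaled = AmplitudeCurve(curve.temperatures, 37.0 * curve.amplitudes,
                                curve.sigmas, curve.start_temperature)
        r1, r2 = fit_melting(curve), fit_melting(scaled)
        assert r2.params.tm == pytest.approx(r1.params.tm, abs=1e-6)
        assert r2.params.g1 == pytest.approx(r1.params.g1, abs=1e-6)
        assert r2.scale == pytest.approx(37.0 * r1.scale, rel=1e-6)

    def test_model_amplitudes_telescope(self, dpbs_params, ladder):
        """With zero drift the fitted per-jump amplitudes sum to
        c*(f_u(T_last) - f_u(T_first))."""
        curve = gen_amplitude_curve(dpbs_params, ladder)
        res = fit_melting(curve)
        p = res.params
        fu = lambda T: thermo.unfolded_fraction(thermo.free_energy_at(p, T), T)
        temps = curve.temperatures
        model_sum = res.scale * (fu(temps[-1]) - fu(curve.start_temperature)) \
            + res.drift * (temps[-1] - curve.start_temperature)
        assert np.sum(curve.amplitudes) == pytest.approx(model_sum, abs=1e-9)

    @pytest.mark.parametrize("tm", [322.3, 335.0, 347.3])
    def test_amplitude_curve_peaks_at_tm_bracket(self, ladder, tm):
        # mid-interval T_m: at interval boundaries the 1/T asymmetry of K(T)
        # can legitimately move the peak to the neighbouring jump
        curve = gen_amplitude_curve(MeltingParameters(tm=tm, g1=-0.5), ladder)
        k = int(np.argmax(np.abs(curve.amplitudes)))
        t_prev = ladder.start_temperature if k == 0 else curve.temperatures[k - 1]
        assert t_prev <= tm <= curve.temperatures[k]

    def test_no_signal_flagged(self, ladder):
        flat = MeltingParameters(tm=349.0, g1=-0.5)
        curve = gen_amplitude_curve(flat, ladder, c=0.0, drift=1e-4)
        res = fit_melting(curve)
        assert res.flagged

    def test_parameter_recovery_generic(self, ladder):
        """Noiseless recovery holds across the (T_m, g1) plane inside the ladder."""
        for tm in (320.0, 335.0, 352.0):
            for g1 in (-1.5, -0.6, -0.15):
                p = MeltingParameters(tm=tm, g1=g1)
                res = fit_melting(gen_amplitude_curve(p, ladder))
                assert res.params.tm == pytest.approx(tm, abs=1e-3), (tm, g1)
                assert res.params.g1 == pytest.approx(g1, abs=1e-3), (tm, g1)

    def test_too_few_points_rejected(self, dpbs_params):
        proto = JumpProtocol(target_temperatures=(310.0, 320.0, 330.0, 340.0),
                             start_temperature=305.0)
        with pytest.raises(ValueError, match=">= 6"):
            fit_melting(gen_amplitude_curve(dpbs_params, proto))

    def test_narrow_span_rejected(self, dpbs_params):
        proto = JumpProtocol(
            target_temperatures=tuple(np.linspace(330.0, 344.0, 8)),
            start_temperature=329.0)
        with pytest.raises(ValueError, match="20 K"):
            fit_melting(gen_amplitude_curve(dpbs_params, proto))
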