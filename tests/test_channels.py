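"""Channel bank: pooling, transduction, adaptation, read-out, decoding."""

from dataclasses import replace

import numpy as np
import pytest
from sklearn.base import clone

from chronopop.channels import (
    ChannelBank,
    DurationChannelModel,
    PopulationResponse,
    TransducerParams,
    adapt_gains,
    build_channel_bank,
    calibrate_baseline,
    channel_drive,
    readout_peak,
    transduce,
)
from chronopop.frontend import FilteredSignal, make_biphasic_filter


class TestBuildChannelBank:
    def test_log_spacing_has_constant_ratio(self):
        bank = build_channel_bank(61, 50, 4000)
        ratios = bank.widths_ms[1:] / bank.widths_ms[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        assert len(bank.widths_ms) == 61

    def test_octave_spacing_example(self):
        bank = build_channel_bank(9, 100, 25600)
        np.testing.assert_allclose(
            bank.widths_ms, 100 * 2.0 ** np.arange(9), rtol=1e-9
        )

    def test_gains_start_at_unity(self):
        assert np.all(build_channel_bank().gains == 1.0)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="n_channels"):
            build_channel_bank(n_channels=7)

    def test_widths_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ChannelBank(widths_ms=np.array([50, 40, 60, 70, 80, 90, 100, 110]))


class TestChannelDrive:
    def test_zero_signal_gives_zero_drives(self):
        bank = build_channel_bank()
        signal = FilteredSignal(np.zeros(1000), 1000.0)
        assert np.all(channel_drive(signal, bank) == 0.0)

    def test_rectangular_windows_integrate_boxcar_analytically(self):
        """Constant unit drive of 800 ms: L_i = min(width_i, 800)/1000 s."""
        bank = build_channel_bank(
            9, 100, 25600, window_shape="rectangular"
        )
        signal = FilteredSignal(np.ones(800), 1000.0)
        expected = np.minimum(bank.widths_ms, 800.0) / 1000.0
        np.testing.assert_allclose(channel_drive(signal, bank), expected, rtol=1e-9)

    def test_rectangular_drives_nondecreasing_for_any_nonnegative_signal(self, rng):
        bank = build_channel_bank(window_shape="rectangular")
        signal = FilteredSignal(rng.random(1500), 1000.0)
        L = channel_drive(signal, bank)
        assert np.all(np.diff(L) >= -1e-12)

    def test_negative_signal_rejected_at_construction(self):
        with pytest.raises(ValueError, match="non-negative"):
            FilteredSignal(np.array([-0.1, 0.2]), 1000.0)


class TestTransduce:
    def test_zero_drives_give_zero_responses(self):
        bank = build_channel_bank()
        pop = transduce(np.zeros(bank.n_channels), bank)
        assert np.all(pop.R == 0.0)

    def test_large_z_limit_is_pure_power_law(self):
        """With z >> every drive term, suppression is negligible: R ~ L^p."""
        tr = TransducerParams(p=2.4, q=2.0, z=1e12)
        bank = build_channel_bank(transducer=tr)
        L = np.linspace(0.1, 1.0, bank.n_channels)
        R = transduce(L, bank).R
        np.testing.assert_allclose(R / R[-1], (L / L[-1]) ** 2.4, rtol=1e-6)

    def test_nonpositive_z_rejected(self):
        with pytest.raises(ValueError, match="z"):
            TransducerParams(z=0.0)

    def test_exponent_ordering_enforced(self):
        with pytest.raises(ValueError, match="p > q"):
            TransducerParams(p=2.0, q=2.4)


class TestReadoutPeak:
    def test_logistic_profile_peaks_at_centre(self):
        """Derivative of a logistic in log-width peaks at its midpoint."""
        bank = build_channel_bank(61, 50, 4000)
        x = np.log(bank.widths_ms)
        R = 1.0 / (1.0 + np.exp(-(x - np.log(800.0)) / 0.3))
        pop = PopulationResponse(R=R, widths_ms=bank.widths_ms)
        peak = readout_peak(pop).peak_width_ms
        assert peak == pytest.approx(800.0, rel=0.02)

    def test_flat_population_is_error(self):
        bank = build_channel_bank()
        pop = PopulationResponse(np.ones(bank.n_channels), bank.widths_ms)
        with pytest.raises(ValueError, match="no peak"):
            readout_peak(pop)

    def test_concave_rise_then_flat_peaks_at_steepest_pair(self):
        widths = np.geomspace(100, 1000, 10)
        R = np.array([0.0, 0.1, 0.3, 0.7, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        pop = PopulationResponse(R=R, widths_ms=widths)
        out = readout_peak(pop)
        # steepest increment is 0.3 -> 0.7, between channels 2 and 3
        assert out.pair_widths_ms[np.argmax(out.derivative)] == pytest.approx(
            np.sqrt(widths[2] * widths[3])
        )

    def test_needs_three_channels(self):
        pop = PopulationResponse(np.array([0.0, 1.0]), np.array([100.0, 200.0]))
        with pytest.raises(ValueError, match="3 channels"):
            readout_peak(pop)


class TestAdaptGains:
    def _bank(self, **kw):
        return build_channel_bank(**kw)

    @pytest.mark.parametrize("rule", ["linear", "divisive", "saturating"])
    def test_alpha_zero_leaves_gains_at_unity(self, rule):
        bank = self._bank(adapt_strength=0.0, adapt_rule=rule)
        pop = PopulationResponse(
            np.linspace(0, 1, bank.n_channels), bank.widths_ms
        )
        assert np.allclose(adapt_gains(bank, pop).gains, 1.0)

    @pytest.mark.parametrize("rule,expected", [("linear", 0.2), ("saturating", 0.2)])
    def test_most_driven_channel_hits_floor(self, rule, expected):
        bank = self._bank(adapt_strength=0.8, adapt_rule=rule)
        pop = PopulationResponse(
            np.linspace(0, 1, bank.n_channels), bank.widths_ms
        )
        gains = adapt_gains(bank, pop).gains
        assert gains[-1] == pytest.approx(expected)
        assert gains.min() >= expected - 1e-12

    @pytest.mark.parametrize("rule", ["linear", "divisive", "saturating"])
    def test_gains_antitone_in_adaptor_response(self, rule, rng):
        bank = self._bank(adapt_strength=0.7, adapt_rule=rule)
        R = rng.random(bank.n_channels)
        gains = adapt_gains(
            bank, PopulationResponse(R, bank.widths_ms)
        ).gains
        order = np.argsort(R)
        assert np.all(np.diff(gains[order]) <= 1e-12)

    def test_zero_adaptor_response_is_noop(self):
        bank = self._bank()
        pop = PopulationResponse(np.zeros(bank.n_channels), bank.widths_ms)
        assert np.all(adapt_gains(bank, pop).gains == 1.0)

    def test_input_bank_is_unmodified(self):
        bank = self._bank(adapt_strength=0.8)
        pop = PopulationResponse(
            np.linspace(0, 1, bank.n_channels), bank.widths_ms
        )
        adapt_gains(bank, pop)
        assert np.all(bank.gains == 1.0)


class TestBaselineMappingAndDecoding:
    def test_decode_inverts_lookup_on_grid(self, fitted_model):
        mapping = fitted_model.mapping_
        for d in mapping.durations_ms[:: 10]:
            assert mapping.decode(mapping.lookup(d)) == pytest.approx(d, rel=1e-9)

    def test_mapping_strictly_increasing(self, fitted_model):
        assert np.all(np.diff(fitted_model.mapping_.widths_ms) > 0)
        assert np.all(np.diff(fitted_model.mapping_.durations_ms) > 0)

    def test_calibration_requires_unadapted_bank(self, fitted_model):
        bank = replace(
            fitted_model.bank_, gains=np.full(fitted_model.bank_.n_channels, 0.5)
        )
        with pytest.raises(ValueError, match="unadapted"):
            calibrate_baseline(bank, fitted_model.filter_, np.array([200.0, 400.0]))

    def test_out_of_range_decode_is_error(self, fitted_model):
        with pytest.raises(ValueError, match="outside"):
            fitted_model.mapping_.decode(1e6)
        with pytest.raises(ValueError, match="outside"):
            fitted_model.predict(10.0)  # far below calibrated range


class TestDurationChannelModel:
    def test_unadapted_prediction_is_identity(self, fitted_model):
        durations = np.array([300.0, 600.0, 1200.0, 2000.0])
        np.testing.assert_allclose(
            fitted_model.predict(durations), durations, rtol=5e-3
        )

    def test_no_adaptation_when_alpha_zero(self):
        model = DurationChannelModel(adapt_strength=0.0).fit()
        effects = model.adaptation_effect(
            np.array([400.0, 800.0, 1600.0]), "flicker:5/20"
        )
        assert np.max(np.abs(effects)) < 0.5

    def test_model_path_is_deterministic(self):
        a = DurationChannelModel().fit()
        b = DurationChannelModel().fit()
        np.testing.assert_array_equal(a.mapping_.widths_ms, b.mapping_.widths_ms)
        durs = np.array([350.0, 900.0, 1500.0])
        np.testing.assert_array_equal(
            a.predict(durs, adaptor="flicker:5/20"),
            b.predict(durs, adaptor="flicker:5/20"),
        )

    def test_gain_bounds_conserved_through_adapt_predict_cycle(self, fitted_model):
        from chronopop.channels import _adaptor_population

        for spec in ("fixed:800", "flicker:5/20"):
            pop = _adaptor_population(
                spec, fitted_model.bank_, fitted_model.filter_
            )
            gains = adapt_gains(fitted_model.bank_, pop).gains
            assert gains.min() >= 1.0 - fitted_model.adapt_strength - 1e-12
            assert gains.max() <= 1.0 + 1e-12

    def test_sklearn_surface(self, fitted_model):
        params = fitted_model.get_params()
        assert params["n_channels"] == 61
        fresh = clone(fitted_model)
        assert not hasattr(fresh, "mapping_")
        with pytest.raises(RuntimeError, match="not fitted"):
            fresh.predict(600.0)

    def test_unknown_adaptor_spec_is_error(self, fitted_model):
        with pytest.raises(ValueError, match="adaptor spec"):
            fitted_model.predict(600.0, adaptor="gaussian:3")

    def test_rectangular_window_variant_still_monotone(self):
        model = DurationChannelModel(
            window_shape="rectangular", calib_min_ms=200, calib_max_ms=2000
        ).fit()
        decoded = model.predict(np.array([400.0, 800.0, 1600.0]))
        assert np.all(np.diff(decoded) > 0)
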