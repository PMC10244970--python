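"""Duration-tuned channel bank: pooling, transduction, adaptation, read-out.

The model represents perceived duration with a labelled-line population code.
A bank of mechanisms pools the rectified front-end drive over causal temporal
windows of increasing width (the channel's duration label is the window's
full width at half height, FWHH).  Pooled drives pass through a non-linear
transducer with divisive suppression driven by the widest mechanism, giving a
sigmoidal, then saturating response profile across the population for a
fixed-duration target.  The read-out differentiates this profile (response
difference between neighbouring mechanisms) and takes the peak of the
derivative; the peak's width is decoded to a physical-duration equivalent by
inverting a calibration curve measured on the unadapted model.

Adaptation rescales each mechanism's gain in proportion to its (normalized)
response to the adapting stimulus.  A fixed-duration adaptor carves a notch
into the gain profile around its own duration, repelling the read-out for
targets on either side; a long flickering adaptor suppresses gains over a
broad range of widths, compressing the read-out for every target, most
strongly for short ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from chronopop.frontend import (
    FilteredSignal,
    TemporalFilter,
    apply_frontend,
    make_biphasic_filter,
    make_lowpass_filter,
)
from chronopop.stimuli import StimulusWaveform, make_adaptor_waveform, make_test_waveform

MIN_CHANNELS = 8


@dataclass(frozen=True)
class TransducerParams:
    """Parameters of the divisive-suppression transducer.

    ``R_i = (g_i L_i)**p / (z + w_self*(g_i L_i)**q + w_sup*(g_N L_N)**q)``

    where ``L`` are pooled linear drives, ``g`` the adaptable gains and ``N``
    the widest channel.  ``p > q >= 1`` makes the population profile
    accelerate and then saturate across widths.  ``w_self`` adds the standard
    own-drive saturation of divisive gain control; ``w_sup`` is the weight of
    the suppressive drive from the widest mechanism.
    """

    p: float = 2.4
    q: float = 2.0
    z: float = 1e-3
    w_sup: float = 1.0
    w_self: float = 1.0

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError(f"saturation constant z must be > 0, got {self.z}")
        if not self.p > self.q >= 1.0:
            raise ValueError(
                f"transducer needs p > q >= 1 for a sigmoidal profile, "
                f"got p={self.p}, q={self.q}"
            )


@dataclass(frozen=True)
class ChannelBank:
    """Bank of duration-tuned pooling mechanisms with adaptable gains."""

    widths_ms: np.ndarray
    window_shape: str = "raised_cosine"
    gains: np.ndarray | None = None
    transducer: TransducerParams = field(default_factory=TransducerParams)
    adapt_strength: float = 0.8
    adapt_rule: str = "saturating"
    adapt_sat: float = 0.004
    adapt_mix: float = 0.6

    def __post_init__(self) -> None:
        widths = np.asarray(self.widths_ms, dtype=float)
        object.__setattr__(self, "widths_ms", widths)
        if len(widths) < MIN_CHANNELS:
            raise ValueError(
                f"need >= {MIN_CHANNELS} channels for a usable derivative "
                f"read-out, got {len(widths)}"
            )
        if np.any(np.diff(widths) <= 0):
            raise ValueError("channel widths must be strictly increasing")
        gains = self.gains
        if gains is None:
            gains = np.ones(len(widths))
        gains = np.asarray(gains, dtype=float)
        object.__setattr__(self, "gains", gains)
        if len(gains) != len(widths):
            raise ValueError("one gain per channel required")
        if gains.min() < 0 or gains.max() > 1 + 1e-12:
            raise ValueError("gains must lie in [0, 1]")
        if self.window_shape not in ("rectangular", "raised_cosine"):
            raise ValueError(f"unknown window shape {self.window_shape!r}")
        if not 0.0 <= self.adapt_strength < 1.0:
            raise ValueError("adapt_strength must lie in [0, 1)")
        if self.adapt_rule not in ("linear", "divisive", "saturating"):
            raise ValueError(f"unknown adaptation rule {self.adapt_rule!r}")
        if self.adapt_sat <= 0:
            raise ValueError("adapt_sat (semi-saturation of the gain rule) must be > 0")
        if not 0.0 <= self.adapt_mix <= 1.0:
            raise ValueError("adapt_mix must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return len(self.widths_ms)

    def window(self, i: int, sample_rate: float, n_samples: int) -> np.ndarray:
        """Sampled pooling window of channel ``i`` (unit peak, onset-anchored)."""
        w_s = self.widths_ms[i] / 1000.0
        t = np.arange(n_samples) / sample_rate
        if self.window_shape == "rectangular":
            return (t < w_s).astype(float)
        # raised cosine (Hann) with support [0, 2W) and FWHH exactly W
        win = 0.5 * (1.0 - np.cos(np.pi * t / w_s))
        win[t >= 2.0 * w_s] = 0.0
        return win


@dataclass(frozen=True)
class PopulationResponse:
    """Per-channel transduced responses to one stimulus."""

    R: np.ndarray
    widths_ms: np.ndarray
    stimulus_label: str = ""

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "widths_ms", np.asarray(self.widths_ms, dtype=float))
        if len(R) != len(self.widths_ms):
            raise ValueError("one response per channel required")
        if R.size and R.min() < 0:
            raise ValueError("population responses must be non-negative")


@dataclass(frozen=True)
class DurationReadout:
    """Peak of the population derivative, with its decoded duration."""

    peak_width_ms: float
    decoded_ms: float | None
    derivative: np.ndarray
    pair_widths_ms: np.ndarray


def build_channel_bank(
    n_channels: int = 61,
    min_width_ms: float = 50.0,
    max_width_ms: float = 4000.0,
    spacing: str = "log",
    window_shape: str = "raised_cosine",
    transducer: TransducerParams | None = None,
    adapt_strength: float = 0.8,
    adapt_rule: str = "saturating",
    adapt_sat: float = 0.004,
    adapt_mix: float = 0.6,
) -> ChannelBank:
    """Construct an unadapted bank with log-spaced (default) widths."""
    if min_width_ms >= max_width_ms:
        raise ValueError("min_width_ms must be < max_width_ms")
    if n_channels < MIN_CHANNELS:
        raise ValueError(
            f"n_channels must be >= {MIN_CHANNELS} (derivative read-out too "
            f"coarse otherwise), got {n_channels}"
        )
    if spacing == "log":
        widths = np.geomspace(min_width_ms, max_width_ms, n_channels)
    elif spacing == "linear":
        widths = np.linspace(min_width_ms, max_width_ms, n_channels)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return ChannelBank(
        widths_ms=widths,
        window_shape=window_shape,
        transducer=transducer if transducer is not None else TransducerParams(),
        adapt_strength=adapt_strength,
        adapt_rule=adapt_rule,
        adapt_sat=adapt_sat,
        adapt_mix=adapt_mix,
    )


def channel_drive(signal: FilteredSignal, bank: ChannelBank) -> np.ndarray:
    """Linear pooled drive of every channel: window-weighted sum of the drive.

    Windows are anchored at stimulus onset (t = 0 of the signal) and have
    unit peak, so with rectangular windows the drive of a channel is simply
    the integral of the signal over the channel's width, and drives are
    non-decreasing across widths for any non-negative signal.  Returned in
    amplitude*seconds units (sample sums scaled by the sample interval).
    """
    x = np.asarray(signal.samples, dtype=float)
    n = len(x)
    rate = signal.sample_rate
    if n == 0:
        return np.zeros(bank.n_channels)
    if x.min() < -1e-12:
        raise ValueError("channel_drive expects a non-negative (rectified) signal")
    L = np.empty(bank.n_channels)
    if bank.window_shape == "rectangular":
        csum = np.concatenate([[0.0], np.cumsum(x)])
        for i, w in enumerate(bank.widths_ms):
            k = min(n, int(round(w / 1000.0 * rate)))
            L[i] = csum[k]
    else:
        t = np.arange(n) / rate
        for i, w in enumerate(bank.widths_ms):
            w_s = w / 1000.0
            k = min(n, int(np.ceil(2.0 * w_s * rate)))
            L[i] = np.dot(x[:k], 0.5 * (1.0 - np.cos(np.pi * t[:k] / w_s)))
    return L / rate


def transduce(L: np.ndarray, bank: ChannelBank) -> PopulationResponse:
    """Non-linear transduction with divisive suppression from the widest channel."""
    L = np.asarray(L, dtype=float)
    if L.size and L.min() < 0:
        raise ValueError("transduce expects non-negative drives")
    tr = bank.transducer
    gL = bank.gains * L
    suppressive = gL[-1]
    denom = tr.z + tr.w_self * gL**tr.q + tr.w_sup * suppressive**tr.q
    R = gL**tr.p / denom
    return PopulationResponse(R=R, widths_ms=bank.widths_ms)


def readout_peak(pop: PopulationResponse) -> DurationReadout:
    """Locate the peak of the population derivative.

    The derivative is the response difference between neighbouring channels,
    assigned to the geometric-mean width of each pair.  The raw argmax (ties
    broken toward the narrower width) is refined by 3-point parabolic
    interpolation in log-width; edge peaks are returned uninterpolated.
    """
    R = pop.R
    if len(R) < 3:
        raise ValueError("need at least 3 channels to differentiate")
    d = np.diff(R)
    if np.all(d == 0):
        raise ValueError("no peak: population response is flat")
    x = np.sqrt(pop.widths_ms[:-1] * pop.widths_ms[1:])  # geometric-mean widths
    k = int(np.argmax(d))
    log_x = np.log(x)
    if 0 < k < len(d) - 1:
        y0, y1, y2 = d[k - 1], d[k], d[k + 1]
        curv = y0 - 2.0 * y1 + y2
        if curv < 0:
            delta = 0.5 * (y0 - y2) / curv
            delta = float(np.clip(delta, -1.0, 1.0))
        else:
            delta = 0.0
        step_lo = log_x[k] - log_x[k - 1]
        step_hi = log_x[k + 1] - log_x[k]
        shift = delta * (step_hi if delta > 0 else step_lo)
        peak_width = float(np.exp(log_x[k] + shift))
    else:
        peak_width = float(x[k])
    peak_width = float(np.clip(peak_width, pop.widths_ms[0], pop.widths_ms[-1]))
    return DurationReadout(
        peak_width_ms=peak_width, decoded_ms=None, derivative=d, pair_widths_ms=x
    )


def adapt_gains(bank: ChannelBank, adaptor_pop: PopulationResponse) -> ChannelBank:
    """Return a new bank with gains reduced according to the adaptor response.

    All rules reduce gains monotonically in the normalized adaptor response
    ``Rhat_i = R_i / max_j R_j`` and leave the most-driven channel at gain
    ``1 - alpha`` (linear/saturating) or ``1 / (1 + alpha)`` (divisive):

    * ``"linear"``: ``g_i = 1 - alpha * Rhat_i`` -- strictly proportional.
    * ``"divisive"``: ``g_i = 1 / (1 + alpha * Rhat_i)``.
    * ``"saturating"`` (default): the gain loss is a blend of a proportional
      and a Naka-Rushton-saturating component,
      ``g_i = 1 - alpha * ((1-b) * Rhat_i + b * (1+s) * Rhat_i / (s + Rhat_i))``
      with semi-saturation ``s = adapt_sat`` and mix ``b = adapt_mix`` --
      proportional for weakly driven channels, saturating for strongly
      driven ones, the way adaptation depth saturates with drive
      physiologically; ``b = 0`` recovers the linear rule.

    An all-zero adaptor response leaves gains unchanged (documented no-op).
    """
    if len(adaptor_pop.R) != bank.n_channels:
        raise ValueError("adaptor response does not match the bank")
    Rmax = float(np.max(adaptor_pop.R))
    if Rmax == 0.0:
        return replace(bank, gains=bank.gains.copy())
    Rhat = adaptor_pop.R / Rmax
    alpha = bank.adapt_strength
    if bank.adapt_rule == "linear":
        gains = 1.0 - alpha * Rhat
    elif bank.adapt_rule == "divisive":
        gains = 1.0 / (1.0 + alpha * Rhat)
    else:  # saturating
        s, b = bank.adapt_sat, bank.adapt_mix
        sat = (1.0 + s) * Rhat / (s + Rhat)
        gains = 1.0 - alpha * ((1.0 - b) * Rhat + b * sat)
    return replace(bank, gains=gains)


@dataclass(frozen=True)
class BaselineMapping:
    """Monotone map between physical duration and unadapted peak width.

    Built by running the unadapted model over a duration grid and isotonically
    smoothing the resulting peak widths (removing the carrier-phase wiggles at
    brief durations), then strictified so the map is invertible.  Lookup and
    decoding interpolate linearly in log-log coordinates.
    """

    durations_ms: np.ndarray
    widths_ms: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.durations_ms, dtype=float)
        w = np.asarray(self.widths_ms, dtype=float)
        object.__setattr__(self, "durations_ms", d)
        object.__setattr__(self, "widths_ms", w)
        if len(d) != len(w) or len(d) < 2:
            raise ValueError("mapping needs >= 2 (duration, width) pairs")
        if np.any(np.diff(d) <= 0) or np.any(np.diff(w) <= 0):
            raise ValueError("mapping must be strictly increasing")

    def lookup(self, duration_ms: float) -> float:
        """Unadapted peak width (ms) for a physical duration on the grid range."""
        d = float(duration_ms)
        if not self.durations_ms[0] <= d <= self.durations_ms[-1]:
            raise ValueError(
                f"duration {d} ms outside calibrated range "
                f"[{self.durations_ms[0]}, {self.durations_ms[-1]}] ms"
            )
        return float(
            np.exp(
                np.interp(
                    np.log(d), np.log(self.durations_ms), np.log(self.widths_ms)
                )
            )
        )

    def decode(self, peak_width_ms: float) -> float:
        """Physical-duration equivalent (ms) of a peak width."""
        w = float(peak_width_ms)
        if not self.widths_ms[0] <= w <= self.widths_ms[-1]:
            raise ValueError(
                f"peak width {w:.2f} ms outside decodable range "
                f"[{self.widths_ms[0]:.2f}, {self.widths_ms[-1]:.2f}] ms"
            )
        return float(
            np.exp(
                np.interp(np.log(w), np.log(self.widths_ms), np.log(self.durations_ms))
            )
        )


def _population_response(
    waveform: StimulusWaveform,
    bank: ChannelBank,
    filt: TemporalFilter,
    rectifier: str = "abs",
) -> PopulationResponse:
    signal = apply_frontend(waveform, filt, rectifier=rectifier)
    L = channel_drive(signal, bank)
    pop = transduce(L, bank)
    return PopulationResponse(R=pop.R, widths_ms=pop.widths_ms, stimulus_label=waveform.label)


def calibrate_baseline(
    bank: ChannelBank,
    filt: TemporalFilter,
    duration_grid_ms: np.ndarray,
    test_tf_hz: float = 10.0,
    test_contrast: float = 0.8,
    rectifier: str = "abs",
    monotone_tol: float = 0.05,
) -> BaselineMapping:
    """Measure the unadapted duration -> peak-width curve and smooth it.

    Isotonic regression removes the non-monotonic carrier-phase wiggles; if
    the raw curve deviates from its isotonic fit by more than ``monotone_tol``
    (relative), the bank is considered misconfigured and an error is raised.
    Flat isotonic segments are strictified with a negligible geometric ramp so
    the mapping stays invertible.
    """
    if np.any(bank.gains != 1.0):
        raise ValueError("baseline calibration requires an unadapted bank")
    grid = np.asarray(duration_grid_ms, dtype=float)
    widths = np.empty(len(grid))
    for j, dur in enumerate(grid):
        wave = make_test_waveform(
            dur, tf_hz=test_tf_hz, contrast=test_contrast, sample_rate=filt.sample_rate
        )
        pop = _population_response(wave, bank, filt, rectifier)
        widths[j] = readout_peak(pop).peak_width_ms
    iso = IsotonicRegression(increasing=True)
    smooth = iso.fit_transform(np.log(grid), np.log(widths))
    rel_dev = np.max(np.abs(smooth - np.log(widths)))
    if rel_dev > monotone_tol:
        raise ValueError(
            f"baseline read-out deviates from monotone by {rel_dev:.3f} "
            f"(log units, tol {monotone_tol}); bank misconfigured"
        )
    # strictify flat runs with an epsilon ramp (invertibility only)
    eps = 1e-9
    smooth = smooth + eps * np.arange(len(smooth))
    return BaselineMapping(durations_ms=grid, widths_ms=np.exp(smooth))


def _adaptor_population(
    adaptor: str,
    bank: ChannelBank,
    filt: TemporalFilter,
    rectifier: str = "abs",
    adaptor_contrast: float = 0.5,
    test_tf_hz: float = 10.0,
    flicker_exposure_s: float = 4.0,
    segment_ms: float = 500.0,
) -> PopulationResponse:
    """Population response to an adaptor given as a spec string.

    ``"fixed:<ms>"`` -- a test-like modulation (test carrier frequency) of
    the given duration: the repeated-duration adaptor of duration-adaptation
    experiments.  Each presentation is a discrete event with an onset, so the
    response is computed exactly like a test's (onset-anchored windows),
    which gives the duration-tuned response profile that adaptation notches.

    ``"flicker:<f1>/<f2>"`` -- prolonged flicker alternating between two
    frequencies in 500 ms segments (50/50 occupancy).  Adaptation to a
    continuous stimulus reflects the steady-state response, long after any
    onset: each channel's pooled drive is the time-averaged rectified drive
    times the window's area (for unit-peak windows, area = FWHH), which is
    the sliding-window average and is free of onset/segment-phase artifacts.
    The time average is measured over a ``flicker_exposure_s``-second epoch.
    """
    kind, _, arg = adaptor.partition(":")
    if kind == "fixed":
        wave = make_test_waveform(
            float(arg), tf_hz=test_tf_hz, contrast=adaptor_contrast,
            sample_rate=filt.sample_rate,
        )
        return _population_response(wave, bank, filt, rectifier)
    if kind == "flicker":
        f1s, _, f2s = arg.partition("/")
        f1, f2 = float(f1s), float(f2s)
        wave = make_adaptor_waveform(
            total_s=flicker_exposure_s,
            segment_ms=segment_ms,
            tf_pair_hz=(f1, f2),
            contrast=adaptor_contrast,
            sample_rate=filt.sample_rate,
            order_seed=None,
        )
        signal = apply_frontend(wave, filt, rectifier=rectifier)
        mean_drive = float(np.mean(signal.samples[: len(wave.samples)]))
        # unit-peak rectangular and raised-cosine windows both have area FWHH
        L = mean_drive * bank.widths_ms / 1000.0
        pop = transduce(L, bank)
        return PopulationResponse(
            R=pop.R,
            widths_ms=bank.widths_ms,
            stimulus_label=f"flicker {f1:g}/{f2:g} Hz (steady state)",
        )
    raise ValueError(
        f"unknown adaptor spec {adaptor!r} (use 'fixed:<ms>' or 'flicker:<f1>/<f2>')"
    )


def predict_perceived_duration(
    duration_ms,
    adaptor: str | None,
    bank: ChannelBank,
    filt: TemporalFilter,
    mapping: BaselineMapping,
    rectifier: str = "abs",
    test_tf_hz: float = 10.0,
    test_contrast: float = 0.8,
    adaptor_contrast: float = 0.5,
    flicker_exposure_s: float = 4.0,
):
    """Decoded perceived duration (ms) of a test, optionally after adaptation.

    The adaptor (if any) is presented to the unadapted bank, gains are
    rescaled, the (possibly adapted) population response to the test is read
    out and the peak width is inverted through the unadapted baseline mapping.
    """
    if adaptor is not None:
        adaptor_pop = _adaptor_population(
            adaptor,
            bank,
            filt,
            rectifier=rectifier,
            adaptor_contrast=adaptor_contrast,
            test_tf_hz=test_tf_hz,
            flicker_exposure_s=flicker_exposure_s,
        )
        bank = adapt_gains(bank, adaptor_pop)
    durations = np.atleast_1d(np.asarray(duration_ms, dtype=float))
    decoded = np.empty(len(durations))
    for j, dur in enumerate(durations):
        wave = make_test_waveform(
            dur, tf_hz=test_tf_hz, contrast=test_contrast, sample_rate=filt.sample_rate
        )
        pop = _population_response(wave, bank, filt, rectifier)
        peak = readout_peak(pop).peak_width_ms
        decoded[j] = mapping.decode(peak)
    if np.isscalar(duration_ms):
        return float(decoded[0])
    return decoded


def predict_adaptation_effect(duration_ms, adaptor: str, **kwargs):
    """Predicted change in perceived duration, in % of the physical duration.

    ``100 * (decoded_adapted - duration) / duration``; negative values mean
    the test appears compressed.
    """
    decoded = predict_perceived_duration(duration_ms, adaptor, **kwargs)
    durations = np.asarray(duration_ms, dtype=float)
    return 100.0 * (decoded - durations) / durations


class DurationChannelModel(BaseEstimator):
    """Full forward model with an sklearn-style fit/predict surface.

    ``fit()`` builds the front-end filter and channel bank and calibrates the
    unadapted duration -> peak-width mapping; ``predict(durations, adaptor=...)``
    returns decoded perceived durations in ms and
    ``adaptation_effect(durations, adaptor)`` the percentage change.  The
    model path is fully deterministic: identical configuration gives
    bit-identical outputs.

    Parameters mirror the model components: channel grid (``n_channels``
    log-spaced widths between ``min_width_ms`` and ``max_width_ms``), pooling
    ``window_shape``, transducer exponents ``p``/``q`` with saturation ``z``
    and suppression weights, adaptation strength/rule, front-end
    ``filter_family`` ("biphasic" or "lowpass"), rectifier, and the stimulus
    constants (test carrier frequency and contrasts).
    """

    def __init__(
        self,
        n_channels: int = 61,
        min_width_ms: float = 50.0,
        max_width_ms: float = 4000.0,
        spacing: str = "log",
        window_shape: str = "raised_cosine",
        p: float = 2.4,
        q: float = 2.0,
        z: float = 1e-3,
        w_sup: float = 1.0,
        w_self: float = 1.0,
        adapt_strength: float = 0.8,
        adapt_rule: str = "saturating",
        adapt_sat: float = 0.004,
        adapt_mix: float = 0.6,
        filter_family: str = "biphasic",
        filter_params: dict | None = None,
        rectifier: str = "abs",
        sample_rate: float = 1000.0,
        test_tf_hz: float = 10.0,
        test_contrast: float = 0.8,
        adaptor_contrast: float = 0.5,
        flicker_exposure_s: float = 4.0,
        calib_min_ms: float = 100.0,
        calib_max_ms: float = 3000.0,
        calib_step_ms: float = 50.0,
    ):
        self.n_channels = n_channels
        self.min_width_ms = min_width_ms
        self.max_width_ms = max_width_ms
        self.spacing = spacing
        self.window_shape = window_shape
        self.p = p
        self.q = q
        self.z = z
        self.w_sup = w_sup
        self.w_self = w_self
        self.adapt_strength = adapt_strength
        self.adapt_rule = adapt_rule
        self.adapt_sat = adapt_sat
        self.adapt_mix = adapt_mix
        self.filter_family = filter_family
        self.filter_params = filter_params
        self.rectifier = rectifier
        self.sample_rate = sample_rate
        self.test_tf_hz = test_tf_hz
        self.test_contrast = test_contrast
        self.adaptor_contrast = adaptor_contrast
        self.flicker_exposure_s = flicker_exposure_s
        self.calib_min_ms = calib_min_ms
        self.calib_max_ms = calib_max_ms
        self.calib_step_ms = calib_step_ms

    def _make_filter(self) -> TemporalFilter:
        params = dict(self.filter_params or {})
        if self.filter_family == "biphasic":
            return make_biphasic_filter(sample_rate=self.sample_rate, **params)
        if self.filter_family == "lowpass":
            return make_lowpass_filter(sample_rate=self.sample_rate, **params)
        raise ValueError(f"unknown filter family {self.filter_family!r}")

    def fit(self, X=None, y=None) -> "DurationChannelModel":
        """Build filter and bank, calibrate the baseline mapping.

        ``X``/``y`` are ignored (sklearn API compatibility); the model is
        specified entirely by its constructor parameters.
        """
        self.filter_ = self._make_filter()
        self.bank_ = build_channel_bank(
            n_channels=self.n_channels,
            min_width_ms=self.min_width_ms,
            max_width_ms=self.max_width_ms,
            spacing=self.spacing,
            window_shape=self.window_shape,
            transducer=TransducerParams(
                p=self.p, q=self.q, z=self.z, w_sup=self.w_sup, w_self=self.w_self
            ),
            adapt_strength=self.adapt_strength,
            adapt_rule=self.adapt_rule,
            adapt_sat=self.adapt_sat,
            adapt_mix=self.adapt_mix,
        )
        grid = np.arange(
            self.calib_min_ms, self.calib_max_ms + self.calib_step_ms / 2, self.calib_step_ms
        )
        self.mapping_ = calibrate_baseline(
            self.bank_,
            self.filter_,
            grid,
            test_tf_hz=self.test_tf_hz,
            test_contrast=self.test_contrast,
            rectifier=self.rectifier,
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "mapping_"):
            raise RuntimeError("model is not fitted; call fit() first")

    def predict(self, durations_ms, adaptor: str | None = None):
        """Decoded perceived duration (ms) for each test duration."""
        self._check_fitted()
        return predict_perceived_duration(
            durations_ms,
            adaptor,
            self.bank_,
            self.filter_,
            self.mapping_,
            rectifier=self.rectifier,
            test_tf_hz=self.test_tf_hz,
            test_contrast=self.test_contrast,
            adaptor_contrast=self.adaptor_contrast,
            flicker_exposure_s=self.flicker_exposure_s,
        )

    def adaptation_effect(self, durations_ms, adaptor: str):
        """Predicted change in perceived duration (% of physical duration)."""
        self._check_fitted()
        return predict_adaptation_effect(
            durations_ms,
            adaptor,
            bank=self.bank_,
            filt=self.filter_,
            mapping=self.mapping_,
            rectifier=self.rectifier,
            test_tf_hz=self.test_tf_hz,
            test_contrast=self.test_contrast,
            adaptor_contrast=self.adaptor_contrast,
            flicker_exposure_s=self.flicker_exposure_s,
        )

    def population_response(self, waveform: StimulusWaveform, adapted_to: str | None = None):
        """Transduced population response to an arbitrary waveform."""
        self._check_fitted()
        bank = self.bank_
        if adapted_to is not None:
            adaptor_pop = _adaptor_population(
                adapted_to,
                bank,
                self.filter_,
                rectifier=self.rectifier,
                adaptor_contrast=self.adaptor_contrast,
                test_tf_hz=self.test_tf_hz,
                flicker_exposure_s=self.flicker_exposure_s,
            )
            bank = adapt_gains(bank, adaptor_pop)
        return _population_response(waveform, bank, self.filter_, self.rectifier)
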