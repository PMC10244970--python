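"""Temporal stimulus waveforms and the experiment's design constants.

A drifting Gabor seen through a local one-dimensional temporal filter is
indistinguishable from counterphase flicker at the corresponding temporal
frequency, so stimuli are represented as sampled 1-D contrast modulations:
a sinusoidal carrier inside a rectangular duration envelope.  No spatial
dimension is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SAMPLE_RATE = 1000.0
"""Model sample rate in Hz.

The model is continuous-time in spirit; 1 kHz cleanly represents carriers up
to a few tens of Hz and keeps one sample per millisecond so durations map to
sample counts exactly.
"""


@dataclass(frozen=True)
class StimulusWaveform:
    """A sampled 1-D contrast modulation.

    Parameters
    ----------
    samples:
        Contrast amplitudes (dimensionless, ``|samples| <= 1``).
    sample_rate:
        Sampling rate in Hz.
    duration_ms:
        Nominal stimulus duration in milliseconds;
        ``len(samples) == round(duration_ms / 1000 * sample_rate)``.
    label:
        Free-text description, carried through the model for diagnostics.
    """

    samples: np.ndarray
    sample_rate: float
    duration_ms: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.duration_ms < 0:
            raise ValueError(f"duration_ms must be >= 0, got {self.duration_ms}")
        expected = int(round(self.duration_ms / 1000.0 * self.sample_rate))
        if len(samples) != expected:
            raise ValueError(
                f"sample count {len(samples)} inconsistent with duration "
                f"{self.duration_ms} ms at {self.sample_rate} Hz (expected {expected})"
            )
        if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-12:
            raise ValueError("waveform amplitudes must satisfy |sample| <= 1")

    @property
    def time_s(self) -> np.ndarray:
        """Sample times in seconds, starting at stimulus onset."""
        return np.arange(len(self.samples)) / self.sample_rate

    def to_csv(self, path) -> None:
        """Write ``time_s,amplitude`` rows for external inspection/plotting."""
        arr = np.column_stack([self.time_s, self.samples])
        np.savetxt(path, arr, delimiter=",", header="time_s,amplitude", comments="")


# The seven comparison durations, as fractions of the standard.
COMPARISON_FRACTIONS = (1 / 3, 2 / 3, 5 / 6, 1.0, 7 / 6, 4 / 3, 5 / 3)


@dataclass(frozen=True)
class ExperimentDesign:
    """Constants of the 2AFC duration-adaptation experiment.

    Two standard durations (600 and 1200 ms, sub- and supra-second) are each
    judged against comparisons at seven fractions of the standard.  The
    adaptor drifts/flickers at two temporal frequencies (5 and 20 Hz) in
    500 ms segments occupying exactly half the adaptation time each, so that
    speed adaptation is balanced; tests modulate at 10 Hz.
    """

    standards_ms: tuple[float, ...] = (600.0, 1200.0)
    comparison_fractions: tuple[float, ...] = COMPARISON_FRACTIONS
    min_reps: int = 20
    adaptor_contrast: float = 0.5
    test_contrast: float = 0.8
    test_tf_hz: float = 10.0
    adaptor_tf_hz: tuple[float, float] = (5.0, 20.0)
    segment_ms: float = 500.0
    initial_adapt_s: float = 32.0
    topup_adapt_s: float = 8.0
    isi_ms: float = 500.0

    def __post_init__(self) -> None:
        fr = self.comparison_fractions
        if list(fr) != sorted(fr):
            raise ValueError("comparison fractions must be sorted ascending")
        if not any(abs(f - 1.0) < 1e-12 for f in fr):
            raise ValueError("comparison fractions must include 1 (the standard)")
        if len(self.adaptor_tf_hz) != 2:
            raise ValueError("adaptor_tf_hz must hold exactly two frequencies")

    @property
    def comparison_pcts(self) -> np.ndarray:
        """Comparison levels as signed % difference from the standard."""
        return (np.asarray(self.comparison_fractions) - 1.0) * 100.0


def speed_to_temporal_frequency(speed_deg_per_s: float, spatial_freq_cpd: float) -> float:
    """Temporal frequency (Hz) of a grating drifting at ``speed_deg_per_s``.

    A grating of spatial frequency ``f_s`` cycles/deg translating at ``v``
    deg/s modulates any fixed point at ``v * f_s`` Hz.
    """
    if speed_deg_per_s <= 0 or spatial_freq_cpd <= 0:
        raise ValueError(
            "speed and spatial frequency must be positive, got "
            f"({speed_deg_per_s}, {spatial_freq_cpd})"
        )
    return speed_deg_per_s * spatial_freq_cpd


def make_test_waveform(
    duration_ms: float,
    tf_hz: float = 10.0,
    contrast: float = 0.8,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    phase: float = 0.0,
) -> StimulusWaveform:
    """Sinusoidal test modulation inside a rectangular duration envelope.

    ``contrast * sin(2*pi*tf_hz*t + phase)`` for ``0 <= t < duration``, zero
    outside.  Onset phase is a controlled constant (default 0): the
    interaction between carrier phase and the envelope is what produces the
    small-duration wiggles in the model's read-out, so it must not vary
    covertly.
    """
    if duration_ms < 0:
        raise ValueError(f"duration_ms must be >= 0, got {duration_ms}")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError(f"contrast must lie in [0, 1], got {contrast}")
    if sample_rate < 4.0 * tf_hz:
        raise ValueError(
            f"sample_rate {sample_rate} Hz undersamples a {tf_hz} Hz carrier "
            f"(Nyquist requires > {2 * tf_hz} Hz; >= {4 * tf_hz} Hz enforced)"
        )
    n = int(round(duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    samples = contrast * np.sin(2.0 * np.pi * tf_hz * t + phase)
    return StimulusWaveform(
        samples=samples,
        sample_rate=sample_rate,
        duration_ms=duration_ms,
        label=f"test {duration_ms:g} ms @ {tf_hz:g} Hz",
    )


def make_adaptor_waveform(
    total_s: float,
    segment_ms: float = 500.0,
    tf_pair_hz: tuple[float, float] = (5.0, 20.0),
    contrast: float = 0.5,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    order_seed: int | None = 0,
) -> StimulusWaveform:
    """Flickering adaptor: 500 ms sinusoidal segments at two frequencies.

    The two frequencies each occupy exactly half of the total duration
    (segment counts are split 50/50); the segment order is shuffled by
    ``order_seed`` within that constraint, or alternates deterministically
    when ``order_seed`` is None.  Each segment restarts the carrier at zero
    phase, standing in for the direction reversals of the drifting adaptor
    (no directional signal is modelled).
    """
    total_ms = total_s * 1000.0
    n_seg_f = total_ms / segment_ms
    if abs(n_seg_f - round(n_seg_f)) > 1e-9:
        raise ValueError(
            f"total duration {total_s} s is not a whole number of "
            f"{segment_ms} ms segments"
        )
    n_seg = int(round(n_seg_f))
    if len(tf_pair_hz) != 2:
        raise ValueError("tf_pair_hz must hold exactly two frequencies")
    f1, f2 = tf_pair_hz
    distinct = abs(f1 - f2) > 1e-12
    if distinct and n_seg % 2 != 0:
        raise ValueError(
            f"{n_seg} segments cannot be split 50-50 between {f1} and {f2} Hz"
        )
    if distinct:
        freqs = np.array([f1] * (n_seg // 2) + [f2] * (n_seg - n_seg // 2))
        if order_seed is None:
            freqs = np.array([f1 if i % 2 == 0 else f2 for i in range(n_seg)])
        else:
            rng = np.random.default_rng(order_seed)
            rng.shuffle(freqs)
    else:
        freqs = np.full(n_seg, f1)

    n_per_seg = int(round(segment_ms / 1000.0 * sample_rate))
    t_seg = np.arange(n_per_seg) / sample_rate
    segments = [contrast * np.sin(2.0 * np.pi * f * t_seg) for f in freqs]
    samples = np.concatenate(segments) if segments else np.empty(0)
    return StimulusWaveform(
        samples=samples,
        sample_rate=sample_rate,
        duration_ms=total_ms,
        label=f"adaptor {total_s:g} s @ {f1:g}/{f2:g} Hz",
    )
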