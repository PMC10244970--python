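"""Temporal front-end: biphasic band-pass filtering and rectification.

The model's first stage convolves the stimulus modulation with a causal
temporal impulse-response function and rectifies the result, producing the
non-negative drive that the duration-tuned pooling mechanisms integrate.
The default kernel is the classic psychophysical biphasic form -- the
difference of two cascaded-exponential (gamma) stages -- which is band-pass
with near-zero DC gain, so sustained (constant) inputs produce essentially
no drive while modulation around 10 Hz drives the system strongly.  A
low-pass variant (a single gamma stage) is provided because the model's
qualitative behaviour should not hinge on the exact filter shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TemporalFilter:
    """A causal FIR temporal filter kernel.

    ``kernel[0]`` corresponds to lag 0; the kernel is zero for negative lags
    by construction.  ``params`` records the generating parameters
    (excitatory/inhibitory time constants in ms, stage counts, inhibitory
    weight) for provenance.
    """

    kernel: np.ndarray
    sample_rate: float
    params: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernel", np.asarray(self.kernel, dtype=float))

    @property
    def dc_gain(self) -> float:
        """Kernel integral (continuous-time approximation)."""
        return float(np.sum(self.kernel) / self.sample_rate)

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Magnitude response at the given frequencies (Hz)."""
        freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
        t = np.arange(len(self.kernel)) / self.sample_rate
        ph = np.exp(-2j * np.pi * np.outer(freqs_hz, t))
        return np.abs(ph @ self.kernel) / self.sample_rate

    def to_csv(self, path) -> None:
        """Write ``time_s,amplitude`` rows of the kernel."""
        t = np.arange(len(self.kernel)) / self.sample_rate
        arr = np.column_stack([t, self.kernel])
        np.savetxt(path, arr, delimiter=",", header="time_s,amplitude", comments="")


@dataclass(frozen=True)
class FilteredSignal:
    """Non-negative (rectified) drive produced by the front end."""

    samples: np.ndarray
    sample_rate: float
    source_label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size and samples.min() < 0:
            raise ValueError("FilteredSignal samples must be non-negative")


def _gamma_stage_kernel(t: np.ndarray, tau_s: float, n_stages: int) -> np.ndarray:
    """Impulse response of ``n_stages`` cascaded first-order low-pass stages.

    Proportional to ``t**(n-1) * exp(-t/tau)``; returned with unit area so
    lobes can be balanced exactly.
    """
    with np.errstate(over="ignore"):
        h = t ** (n_stages - 1) * np.exp(-t / tau_s)
    area = np.trapezoid(h, t)
    if area <= 0:
        raise ValueError("degenerate gamma stage (check time constants)")
    return h / area


def make_biphasic_filter(
    tau_exc_ms: float = 8.0,
    n_exc: int = 9,
    tau_inh_ms: float = 10.0,
    n_inh: int = 10,
    inh_weight: float = 0.9,
    sample_rate: float = 1000.0,
    dc_balance: bool = True,
) -> TemporalFilter:
    """Biphasic band-pass impulse response: excitatory minus delayed inhibitory lobe.

    Each lobe is a cascade of exponential stages (a gamma density); the
    inhibitory lobe has a longer time constant and one more stage, so it
    peaks later and subtracting it yields the characteristic fast positive
    phase followed by a slower negative undershoot.  With ``dc_balance`` the
    inhibitory lobe is rescaled so the kernel integrates to zero (strictly
    band-pass); the kernel is then normalized to unit peak.

    Doubling both time constants stretches the kernel in time by two -- the
    gamma-stage scale property -- which is how the filter (and hence the
    whole model) can be re-tuned to other frequency bands.
    """
    if tau_exc_ms <= 0 or tau_inh_ms <= 0:
        raise ValueError("time constants must be positive")
    if not 0.0 < inh_weight <= 1.0:
        raise ValueError(
            f"inhibitory weight must lie in (0, 1], got {inh_weight}; "
            "weight 0 would leave a monophasic (non-band-pass) kernel"
        )
    # Support long enough for the slower lobe to decay: mean + 10 sd of the
    # gamma density, which also preserves the time-stretch property exactly.
    support_s = max(
        n_exc * tau_exc_ms + 10.0 * np.sqrt(n_exc) * tau_exc_ms,
        n_inh * tau_inh_ms + 10.0 * np.sqrt(n_inh) * tau_inh_ms,
    ) / 1000.0
    n = int(np.ceil(support_s * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    exc = _gamma_stage_kernel(t, tau_exc_ms / 1000.0, n_exc)
    inh = inh_weight * _gamma_stage_kernel(t, tau_inh_ms / 1000.0, n_inh)
    if dc_balance:
        # unit-area lobes: scaling inh by area_exc/area_inh zeroes the integral
        inh = inh * (np.trapezoid(exc, t) / np.trapezoid(inh, t))
    kernel = exc - inh
    peak = np.max(np.abs(kernel))
    if peak <= 0:
        raise ValueError("degenerate kernel (all zero)")
    kernel = kernel / peak
    return TemporalFilter(
        kernel=kernel,
        sample_rate=sample_rate,
        params={
            "family": "biphasic",
            "tau_exc_ms": tau_exc_ms,
            "n_exc": n_exc,
            "tau_inh_ms": tau_inh_ms,
            "n_inh": n_inh,
            "inh_weight": inh_weight,
            "dc_balance": dc_balance,
        },
    )


def make_lowpass_filter(
    tau_ms: float = 15.0,
    n_stages: int = 1,
    sample_rate: float = 1000.0,
) -> TemporalFilter:
    """Monophasic low-pass kernel (cascade of exponential stages, unit peak).

    Used to check that the model's qualitative adaptation behaviour is robust
    to the front-end filter family and does not require band-pass tuning.
    """
    if tau_ms <= 0:
        raise ValueError("time constant must be positive")
    support_s = (n_stages * tau_ms + 10.0 * np.sqrt(n_stages) * tau_ms) / 1000.0
    n = int(np.ceil(support_s * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    kernel = _gamma_stage_kernel(t, tau_ms / 1000.0, n_stages)
    kernel = kernel / np.max(np.abs(kernel))
    return TemporalFilter(
        kernel=kernel,
        sample_rate=sample_rate,
        params={"family": "lowpass", "tau_ms": tau_ms, "n_stages": n_stages},
    )


def filter_response(waveform, filt: TemporalFilter) -> np.ndarray:
    """Signed (pre-rectification) linear convolution of waveform and kernel.

    Output length is ``len(input) + len(kernel) - 1`` so the filter's ringing
    after stimulus offset is retained; amplitudes are scaled by the sample
    interval to approximate the continuous-time convolution integral.
    """
    if abs(waveform.sample_rate - filt.sample_rate) > 1e-9:
        raise ValueError(
            f"sample-rate mismatch: waveform {waveform.sample_rate} Hz vs "
            f"filter {filt.sample_rate} Hz"
        )
    if len(waveform.samples) == 0:
        return np.empty(0)
    return np.convolve(waveform.samples, filt.kernel) / filt.sample_rate


def apply_frontend(
    waveform,
    filt: TemporalFilter,
    rectifier: str = "abs",
) -> FilteredSignal:
    """Filter a stimulus waveform and rectify the result.

    ``rectifier`` is ``"abs"`` (full-wave, keeps drive proportional to
    contrast) or ``"square"`` (energy-like, drive proportional to
    contrast squared).
    """
    signed = filter_response(waveform, filt)
    if rectifier == "abs":
        samples = np.abs(signed)
    elif rectifier == "square":
        samples = signed**2
    else:
        raise ValueError(f"unknown rectifier {rectifier!r} (use 'abs' or 'square')")
    return FilteredSignal(
        samples=samples,
        sample_rate=filt.sample_rate,
        source_label=getattr(waveform, "label", ""),
    )
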