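"""Skin-conductance trace containers, synthesis and preprocessing.

The phasic part of a skin-conductance signal is modeled as a train of
impulses convolved with a biexponential (Bateman) impulse response

    g(t) = (exp(-t/tau2) - exp(-t/tau1)) / (tau2 - tau1),   t >= 0,

normalized to unit time integral, riding on a slowly varying tonic level.
``synthesize_trace`` builds such a signal with known ground truth so the
decomposition can be validated; ``preprocess`` applies the standard
conditioning chain: resampling to 80 Hz, Gaussian smoothing with a 16-sample
window and a zero-phase low-pass Butterworth filter with 2 Hz cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

from .task import Condition

__all__ = [
    "IRFParams",
    "bateman",
    "bateman_peak",
    "SCTrace",
    "synthesize_trace",
    "preprocess",
]


@dataclass(frozen=True)
class IRFParams:
    """Biexponential impulse-response time constants (seconds)."""

    tau1: float = 0.75
    tau2: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tau1 < self.tau2:
            raise ValueError("require 0 < tau1 < tau2")


def bateman(t: np.ndarray, irf: IRFParams = IRFParams()) -> np.ndarray:
    """Unit-integral Bateman kernel evaluated at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t >= 0.0,
        (np.exp(-np.clip(t, 0, None) / irf.tau2) - np.exp(-np.clip(t, 0, None) / irf.tau1))
        / (irf.tau2 - irf.tau1),
        0.0,
    )
    return out


def bateman_peak(irf: IRFParams = IRFParams()) -> tuple[float, float]:
    """Closed-form (time, value) of the unit-integral kernel maximum."""
    t_max = irf.tau1 * irf.tau2 / (irf.tau2 - irf.tau1) * math.log(irf.tau2 / irf.tau1)
    return t_max, float(bateman(np.array([t_max]), irf)[0])


@dataclass
class SCTrace:
    """A continuous conductance recording with condition-onset events.

    ``samples`` are conductance in microsiemens; ``events`` pairs each
    condition-cue onset (seconds from trace start) with its condition.
    ``ground_truth`` carries the generating impulse amplitudes when the trace
    is synthetic.
    """

    sampling_rate: float
    samples: np.ndarray
    events: list[tuple[float, Condition]] = field(default_factory=list)
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        dur = self.duration_s
        for onset, _ in self.events:
            if not 0.0 <= onset <= dur:
                raise ValueError(f"event onset {onset} s outside trace [0, {dur:.3f}]")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


def synthesize_trace(
    event_onsets_s: Sequence[float],
    conditions: Sequence[Condition],
    amplitudes: Sequence[float],
    *,
    duration_s: Optional[float] = None,
    sampling_rate: float = 500.0,
    irf: IRFParams = IRFParams(),
    latency_s: float = 2.5,
    tonic_level_uS: float = 2.0,
    tonic_slope_uS_per_s: float = -0.0005,
    tonic_wander_uS: float = 0.05,
    tonic_wander_period_s: float = 120.0,
    noise_sd_uS: float = 0.0,
    seed: "int | np.random.Generator" = 0,
) -> SCTrace:
    """Ground-truth generator: tonic drift + impulse train * IRF + noise.

    Each event contributes one phasic impulse of mass ``amplitude`` (uS*s)
    placed ``latency_s`` after the condition onset; the response it evokes
    peaks at ``amplitude * max(g)`` uS.  The tonic component is a gentle
    linear drift plus a slow sinusoidal wander.  Gaussian measurement noise
    is added sample-wise.  The generating amplitudes, latency and tonic curve
    are stored in ``ground_truth`` for recovery tests.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    onsets = np.asarray(event_onsets_s, dtype=float)
    if len(onsets) != len(conditions) or len(onsets) != len(amplitudes):
        raise ValueError("onsets, conditions and amplitudes must align")
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be >= 0")
    if noise_sd_uS < 0:
        raise ValueError("noise SD must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if duration_s is None:
        tail = 8.0 * irf.tau2
        duration_s = (float(onsets.max()) if len(onsets) else 0.0) + latency_s + tail
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    dt = 1.0 / sampling_rate

    tonic = (
        tonic_level_uS
        + tonic_slope_uS_per_s * t
        + tonic_wander_uS * np.sin(2.0 * np.pi * t / tonic_wander_period_s)
    )

    spikes = np.zeros(n)
    for onset, amp in zip(onsets, amplitudes):
        idx = int(round((onset + latency_s) * sampling_rate))
        if 0 <= idx < n:
            spikes[idx] += amp
    kernel_t = np.arange(0.0, 10.0 * irf.tau2, dt)
    kernel = bateman(kernel_t, irf)  # amplitude density, 1/s scale
    phasic = signal.fftconvolve(spikes, kernel)[:n]

    samples = tonic + phasic
    if noise_sd_uS > 0:
        samples = samples + rng.normal(0.0, noise_sd_uS, size=n)
    samples = np.clip(samples, 0.0, None)

    return SCTrace(
        sampling_rate=sampling_rate,
        samples=samples,
        events=list(zip(onsets.tolist(), list(conditions))),
        ground_truth={
            "amplitudes": amplitudes.copy(),
            "onsets_s": onsets.copy(),
            "latency_s": latency_s,
            "irf": irf,
            "tonic": tonic,
            "phasic": phasic,
            "noise_sd_uS": noise_sd_uS,
        },
    )


def preprocess(
    trace: SCTrace,
    *,
    target_rate: float = 80.0,
    smooth_window_samples: int = 16,
    butter_order: int = 4,
    cutoff_hz: float = 2.0,
) -> SCTrace:
    """Condition a raw trace: resample to 80 Hz, Gauss-smooth, low-pass.

    Resampling uses polyphase filtering at the exact rational rate ratio.
    The Gaussian smoother uses a 16-sample window (sigma = (w-1)/5, matching
    the conventional gaussian-window shape parameter of 2.5); the Butterworth
    low-pass is applied forward-backward (zero phase).  Event times are in
    seconds and therefore unchanged.
    """
    if trace.sampling_rate < target_rate:
        raise ValueError("input sampling rate must be >= target rate")
    ratio = Fraction(target_rate / trace.sampling_rate).limit_denominator(10_000)
    if ratio == 1:
        x = trace.samples.copy()
    else:
        x = signal.resample_poly(
            trace.samples, ratio.numerator, ratio.denominator, padtype="line"
        )

    sigma = (smooth_window_samples - 1) / 5.0
    x = ndimage.gaussian_filter1d(x, sigma=sigma, mode="nearest")

    sos = signal.butter(butter_order, cutoff_hz, btype="low", fs=target_rate, output="sos")
    padlen = 3 * (2 * butter_order + 1)
    if len(x) <= padlen:
        raise ValueError("trace too short for zero-phase filtering")
    x = signal.sosfiltfilt(sos, x)

    return SCTrace(
        sampling_rate=target_rate,
        samples=np.clip(x, 0.0, None),
        events=list(trace.events),
        ground_truth=trace.ground_truth,
    )
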