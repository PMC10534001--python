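"""Gain normalisation, saturation QC and 30-s windowing.

The only signal conditioning applied is division by the per-channel
amplifier gain; no digital filtering is performed. Quality control flags
electronically clipped (saturated) traces, which in practice excludes the
whole participant. Each channel is then cut into consecutive,
non-overlapping 30-second windows; a trailing partial window is dropped
so every window has identical time support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import PPGRecording


@dataclass(frozen=True)
class SignalWindow:
    """One 30-s single-channel epoch with provenance."""

    participant_id: str
    class_label: str
    channel: str
    window_index: int
    samples: np.ndarray
    start_time: float
    fs: float


@dataclass(frozen=True)
class SaturationReport:
    passed: bool
    worst_fraction: float
    worst_span_start: float
    threshold: float


def gain_normalize(recording: PPGRecording) -> PPGRecording:
    """Divide each channel by its amplifier gain; output gains are 1."""
    for ch, g in recording.channel_gains.items():
        if g <= 0:
            raise ValueError(f"channel {ch!r} has non-positive gain {g}")
    channels = {
        ch: recording.channels[ch] / recording.channel_gains[ch]
        for ch in recording.channels
    }
    gains = {ch: 1.0 for ch in recording.channel_gains}
    return recording.copy_with_channels(channels, gains)


def detect_saturation(
    samples: np.ndarray,
    fs: float,
    clip_fraction_threshold: float = 0.02,
    span_seconds: float = 10.0,
    amp_tol: float = 1e-4,
) -> SaturationReport:
    """Flag electronically clipped traces.

    A sample counts as clipped when it lies within ``amp_tol`` times the
    signal range of the channel maximum or minimum. The trace fails when
    the clipped fraction within any ``span_seconds`` span exceeds
    ``clip_fraction_threshold``. A constant trace (zero range) fails
    outright. The report carries the worst span for diagnostics.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    lo, hi = float(x.min()), float(x.max())
    rng = hi - lo
    if rng == 0:
        return SaturationReport(False, 1.0, 0.0, clip_fraction_threshold)
    tol = amp_tol * rng
    near = (x >= hi - tol) | (x <= lo + tol)
    span = min(int(round(span_seconds * fs)), x.size)
    hop = max(1, int(round(fs)))  # 1-s hop
    csum = np.concatenate([[0], np.cumsum(near)])
    starts = np.arange(0, x.size - span + 1, hop)
    fracs = (csum[starts + span] - csum[starts]) / span
    worst = int(np.argmax(fracs))
    worst_frac = float(fracs[worst])
    return SaturationReport(
        passed=worst_frac <= clip_fraction_threshold,
        worst_fraction=worst_frac,
        worst_span_start=float(starts[worst] / fs),
        threshold=clip_fraction_threshold,
    )


def window_signal(recording: PPGRecording, window_seconds: float = 30.0) -> list[SignalWindow]:
    """Cut every channel into consecutive non-overlapping windows.

    Returns floor(duration / window_seconds) windows per channel, in
    protocol channel order then window order; the trailing partial
    window is discarded. Every window inherits the participant's label.
    """
    wlen = int(round(window_seconds * recording.fs))
    n = recording.n_samples
    if n < wlen:
        raise ValueError(
            f"recording ({n / recording.fs:.1f} s) shorter than one window ({window_seconds} s)"
        )
    n_windows = n // wlen
    windows: list[SignalWindow] = []
    for ch in recording.protocol.channels:
        x = recording.channels[ch]
        for i in range(n_windows):
            windows.append(
                SignalWindow(
                    participant_id=recording.participant_id,
                    class_label=recording.class_label,
                    channel=ch,
                    window_index=i,
                    samples=x[i * wlen : (i + 1) * wlen],
                    start_time=i * wlen / recording.fs,
                    fs=recording.fs,
                )
            )
    return windows
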