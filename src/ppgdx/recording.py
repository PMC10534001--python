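"""Core domain types: measurement protocol, participant phenotype, recording.

A recording is one participant's simultaneous multi-site PPG measurement
under the 3-phase protocol: supine baseline, unilateral arm-cuff occlusion
at 300 mmHg, and post-release reactive-hyperaemia ("flush") monitoring.
Signals are stored in arbitrary units as captured, i.e. *including* the
per-channel amplifier gain; gain normalisation is a preprocessing step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SSC = "SSc"
CONTROL = "Control"
CLASS_LABELS = (SSC, CONTROL)

#: Measurement sites in fixed order (feature ordering depends on this).
DEFAULT_CHANNELS = (
    "right_ear",
    "left_ear",
    "right_finger",
    "left_finger",
    "right_toe",
    "left_toe",
)

FINGER_CHANNELS = ("right_finger", "left_finger")


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and channel layout of the 3-phase measurement protocol.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz. Must exceed 40 Hz so the 20 Hz band edge of
        the PPG amplifiers sits below Nyquist. The clinical instrument
        samples at 2000 Hz; synthetic studies default to 200 Hz.
    duration, baseline_end, occlusion_end : float
        Protocol timing in seconds: baseline is [0, baseline_end),
        occlusion [baseline_end, occlusion_end), flush the remainder.
    channels : tuple of str
        Ordered measurement-site names.
    occluded_channels : tuple of str
        Channels distal to the arm cuff (default: left index finger).
    """

    fs: float = 2000.0
    duration: float = 1200.0
    baseline_end: float = 600.0
    occlusion_end: float = 900.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    occluded_channels: tuple[str, ...] = ("left_finger",)

    def __post_init__(self) -> None:
        if self.fs <= 40:
            raise ValueError(f"fs must exceed 40 Hz (Nyquist above the 20 Hz band edge); got {self.fs}")
        if not (0 < self.baseline_end < self.occlusion_end < self.duration):
            raise ValueError(
                "protocol timing must satisfy 0 < baseline_end < occlusion_end < duration; "
                f"got {self.baseline_end}, {self.occlusion_end}, {self.duration}"
            )
        if not set(self.occluded_channels) <= set(self.channels):
            unknown = set(self.occluded_channels) - set(self.channels)
            raise ValueError(f"occluded_channels not in channels: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class ParticipantProfile:
    """Phenotype parameters driving one participant's synthetic waveforms.

    ``pulse_amplitudes`` are per-channel baseline beat amplitudes (a.u.).
    ``flush_overshoot`` is the ratio of the first post-release beat
    amplitude to baseline on occluded channels: Controls typically show a
    hyperaemic overshoot (> 1), SSc an attenuated flush (<= 1) with a
    slower recovery time constant ``flush_tau`` (seconds).
    ``amplitude_heterogeneity`` is the coefficient of variation of
    amplitude across the finger channels; ``noise_sd`` the additive
    instrument-noise SD in a.u.
    """

    participant_id: str
    class_label: str
    heart_rate: float
    pulse_amplitudes: Mapping[str, float]
    flush_overshoot: float
    flush_tau: float
    amplitude_heterogeneity: float
    noise_sd: float
    channel_gains: Mapping[str, float]
    drift_amplitude: float = 0.02
    drift_period: float = 300.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}; got {self.class_label!r}")
        if not (0.7 < self.heart_rate < 2.0):
            raise ValueError(f"heart_rate must lie in (0.7, 2.0) Hz; got {self.heart_rate}")
        if self.flush_tau <= 0:
            raise ValueError("flush_tau must be positive")
        if any(a < 0 for a in self.pulse_amplitudes.values()):
            raise ValueError("pulse amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PPGRecording:
    """One participant's multi-channel gain-annotated PPG time series."""

    participant_id: str
    class_label: str
    channels: dict[str, np.ndarray]
    fs: float
    channel_gains: dict[str, float]
    protocol: ProtocolConfig

    def __post_init__(self) -> None:
        lengths = {len(x) for x in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"all channels must have equal length; got lengths {sorted(lengths)}")
        for name, x in self.channels.items():
            if not np.all(np.isfinite(x)):
                raise ValueError(f"channel {name!r} contains non-finite samples")
        if set(self.channels) != set(self.protocol.channels):
            raise ValueError("recording channels do not match protocol channels")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with_channels(self, channels: dict[str, np.ndarray], gains: dict[str, float]) -> "PPGRecording":
        return PPGRecording(
            participant_id=self.participant_id,
            class_label=self.class_label,
            channels=channels,
            fs=self.fs,
            channel_gains=gains,
            protocol=self.protocol,
        )


def save_recording(recording: PPGRecording, path: str | Path) -> None:
    """Write a recording as delimited text: a time column plus one column per channel."""
    path = Path(path)
    cols = {"time_s": np.arange(recording.n_samples) / recording.fs}
    for name in recording.protocol.channels:
        cols[name] = recording.channels[name]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def load_recording(
    path: str | Path,
    participant_id: str,
    class_label: str,
    channel_gains: Mapping[str, float],
    protocol: ProtocolConfig,
) -> PPGRecording:
    df = pd.read_csv(path)
    channels = {name: df[name].to_numpy(dtype=np.float64) for name in protocol.channels}
    return PPGRecording(
        participant_id=participant_id,
        class_label=class_label,
        channels=channels,
        fs=protocol.fs,
        channel_gains=dict(channel_gains),
        protocol=protocol,
    )
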