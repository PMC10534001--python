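"""Seeded synthetic cohorts of 3-phase multi-site PPG recordings.

The generator emulates the study conditions of a cuff-occlusion PPG
protocol: 20-minute 6-site recordings with a 10-min baseline, a 5-min
left-arm occlusion that abolishes the left-finger pulse, and a 5-min
reactive-hyperaemia flush. Class phenotypes follow the published PPG
literature on scleroderma: SSc participants have lower sphygmic-wave
amplitude (24 +/- 24 a.u. vs 56 +/- 19 a.u. for healthy controls),
an attenuated and slower flush, and heterogeneous finger amplitudes,
whereas Controls show a clear hyperaemic overshoot and homogeneous
amplitudes.

The waveform model is a stand-in, not a claim of morphological fidelity:
each beat is a two-Gaussian bump (systolic peak + dicrotic bump), the
train is band-passed to the 0.5-20 Hz amplifier band, and additive
instrument noise (low-passed at 20 Hz) is applied on top. Instrument
noise is amplitude-independent, so low-perfusion participants have a
correspondingly lower signal-to-noise ratio.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import (
    CONTROL,
    FINGER_CHANNELS,
    SSC,
    ParticipantProfile,
    PPGRecording,
    ProtocolConfig,
    save_recording,
)

#: Relative mean amplitude of each site vs the finger pads.
SITE_AMPLITUDE_SCALE = {
    "right_ear": 0.6,
    "left_ear": 0.6,
    "right_finger": 1.0,
    "left_finger": 1.0,
    "right_toe": 0.8,
    "left_toe": 0.8,
}

#: Time constant (s) of pulse decay after cuff inflation.
OCCLUSION_DECAY_TAU = 5.0


@dataclass(frozen=True)
class ClassPhenotype:
    """Sampling distributions for one class's phenotype parameters."""

    amplitude_mean: float
    amplitude_sd: float
    amplitude_floor: float
    overshoot_mean: float
    overshoot_sd: float
    overshoot_bounds: tuple[float, float]
    tau_mean: float
    tau_sd: float
    heterogeneity: float
    noise_sd: float = 1.0
    heart_rate_range: tuple[float, float] = (0.9, 1.5)


@dataclass(frozen=True)
class PhenotypeDistributions:
    """Per-class phenotype distributions for cohort sampling."""

    ssc: ClassPhenotype
    control: ClassPhenotype

    @classmethod
    def defaults(cls) -> "PhenotypeDistributions":
        """Literature-based defaults: SSc 24 +/- 24 a.u. (truncated at 0),
        Control 56 +/- 19 a.u.; Controls overshoot > 1, SSc <= 1 with a
        slower recovery; SSc fingers heterogeneous."""
        return cls(
            ssc=ClassPhenotype(
                amplitude_mean=24.0, amplitude_sd=24.0, amplitude_floor=0.5,
                overshoot_mean=0.85, overshoot_sd=0.12, overshoot_bounds=(0.2, 1.0),
                tau_mean=45.0, tau_sd=12.0, heterogeneity=0.35,
            ),
            control=ClassPhenotype(
                amplitude_mean=56.0, amplitude_sd=19.0, amplitude_floor=5.0,
                overshoot_mean=1.8, overshoot_sd=0.25, overshoot_bounds=(1.05, 3.0),
                tau_mean=15.0, tau_sd=4.0, heterogeneity=0.05,
            ),
        )

    @classmethod
    def strongly_separated(cls) -> "PhenotypeDistributions":
        """Widely separated phenotypes for pipeline acceptance runs."""
        return cls(
            ssc=ClassPhenotype(
                amplitude_mean=12.0, amplitude_sd=4.0, amplitude_floor=2.0,
                overshoot_mean=0.7, overshoot_sd=0.05, overshoot_bounds=(0.3, 0.9),
                tau_mean=60.0, tau_sd=10.0, heterogeneity=0.4,
            ),
            control=ClassPhenotype(
                amplitude_mean=60.0, amplitude_sd=8.0, amplitude_floor=20.0,
                overshoot_mean=2.0, overshoot_sd=0.1, overshoot_bounds=(1.5, 2.6),
                tau_mean=10.0, tau_sd=2.0, heterogeneity=0.02,
            ),
        )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float = np.inf) -> float:
    # rejection sampling; distributions here are far from pathological
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


def sample_profile(
    participant_id: str,
    class_label: str,
    phenotype: ClassPhenotype,
    protocol: ProtocolConfig,
    rng: np.random.Generator,
) -> ParticipantProfile:
    """Draw one participant's phenotype from the class distributions."""
    base_amp = _truncated_normal(rng, phenotype.amplitude_mean, phenotype.amplitude_sd,
                                 phenotype.amplitude_floor)
    het = phenotype.heterogeneity
    amplitudes: dict[str, float] = {}
    for ch in protocol.channels:
        scale = SITE_AMPLITUDE_SCALE.get(ch, 1.0)
        cv = het if ch in FINGER_CHANNELS else 0.03
        factor = max(0.05, 1.0 + cv * rng.standard_normal())
        amplitudes[ch] = base_amp * scale * factor
    gains = {ch: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))) for ch in protocol.channels}
    return ParticipantProfile(
        participant_id=participant_id,
        class_label=class_label,
        heart_rate=float(rng.uniform(*phenotype.heart_rate_range)),
        pulse_amplitudes=amplitudes,
        flush_overshoot=_truncated_normal(rng, phenotype.overshoot_mean, phenotype.overshoot_sd,
                                          *phenotype.overshoot_bounds),
        flush_tau=_truncated_normal(rng, phenotype.tau_mean, phenotype.tau_sd, 1.0),
        amplitude_heterogeneity=het,
        noise_sd=phenotype.noise_sd,
        channel_gains=gains,
    )


def phase_envelope(profile: ParticipantProfile, protocol: ProtocolConfig, channel: str) -> np.ndarray:
    """Per-sample beat-amplitude multiplier for one channel.

    Non-occluded channels stay near 1 (slow sinusoidal vasomotor drift,
    amplitude ``profile.drift_amplitude``). Occluded channels decay
    exponentially to ~0 after cuff inflation, jump to ``flush_overshoot``
    at cuff release and relax toward 1 with time constant ``flush_tau``.
    The drift term is suppressed outside the baseline phase on occluded
    channels so occlusion/flush dynamics are exactly the closed form.
    """
    if channel not in protocol.channels:
        raise ValueError(f"unknown channel {channel!r}; protocol has {protocol.channels}")
    t = protocol.time_axis()
    base = np.ones_like(t)
    drift_gate = np.ones_like(t)
    if channel in protocol.occluded_channels:
        occ = (t >= protocol.baseline_end) & (t < protocol.occlusion_end)
        base[occ] = np.exp(-(t[occ] - protocol.baseline_end) / OCCLUSION_DECAY_TAU)
        flush = t >= protocol.occlusion_end
        base[flush] = 1.0 + (profile.flush_overshoot - 1.0) * np.exp(
            -(t[flush] - protocol.occlusion_end) / profile.flush_tau
        )
        drift_gate = (t < protocol.baseline_end).astype(float)
    phase0 = 2 * np.pi * (zlib.crc32(f"{profile.participant_id}:{channel}".encode()) % 997) / 997.0
    drift = profile.drift_amplitude * np.sin(2 * np.pi * t / profile.drift_period + phase0)
    return base * (1.0 + drift * drift_gate)


def generate_pulse_train(
    profile: ParticipantProfile,
    envelope: np.ndarray,
    fs: float,
    duration: float,
    rng: np.random.Generator,
    amplitude: float | None = None,
) -> np.ndarray:
    """Quasi-periodic two-component pulse train with band-limited noise.

    Each beat is a systolic Gaussian peak plus a smaller, later dicrotic
    bump; beat amplitude is ``amplitude * envelope`` at the beat onset.
    The beat train is band-passed to 0.5-20 Hz (AC-coupled amplifier
    emulation) and zero-mean Gaussian noise, low-passed at 20 Hz with
    SD ``profile.noise_sd``, is added.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    n = int(round(fs * duration))
    envelope = np.asarray(envelope, dtype=np.float64)
    if len(envelope) != n:
        raise ValueError(f"envelope length {len(envelope)} != fs*duration {n}")
    if np.any(envelope < 0):
        raise ValueError("envelope must be non-negative")
    if amplitude is None:
        amplitude = float(np.mean(list(profile.pulse_amplitudes.values())))

    period = 1.0 / profile.heart_rate
    x = np.zeros(n)
    if amplitude > 0 and np.any(envelope > 0):
        t_beat = rng.uniform(0.0, 0.2 * period)  # random first-beat phase
        sys_width = 0.09 * period
        dic_width = 0.14 * period
        half_span = int(round(1.2 * period * fs))
        while t_beat < duration:
            onset = int(t_beat * fs)
            if onset >= n:
                break
            amp = amplitude * envelope[onset]
            if amp > 0:
                lo = max(0, onset - half_span // 4)
                hi = min(n, onset + half_span)
                tt = np.arange(lo, hi) / fs - t_beat
                x[lo:hi] += amp * np.exp(-0.5 * ((tt - 0.25 * period) / sys_width) ** 2)
                x[lo:hi] += 0.35 * amp * np.exp(-0.5 * ((tt - 0.55 * period) / dic_width) ** 2)
            t_beat += period * (1.0 + 0.03 * rng.standard_normal())
        sos = sps.butter(2, [0.5, 20.0], btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)

    if profile.noise_sd > 0:
        noise = rng.normal(0.0, profile.noise_sd, n)
        sos_lp = sps.butter(4, 20.0, btype="lowpass", fs=fs, output="sos")
        noise = sps.sosfiltfilt(sos_lp, noise)
        # refilter changes the SD; rescale so the delivered noise floor is noise_sd
        sd = noise.std()
        if sd > 0:
            noise *= profile.noise_sd / sd
        x = x + noise
    return x


def generate_recording(
    profile: ParticipantProfile,
    protocol: ProtocolConfig,
    rng: np.random.Generator,
) -> PPGRecording:
    """Synthesise all channels of one participant, gains applied."""
    channels: dict[str, np.ndarray] = {}
    for ch in protocol.channels:
        env = phase_envelope(profile, protocol, ch)
        x = generate_pulse_train(
            profile, env, protocol.fs, protocol.duration, rng,
            amplitude=profile.pulse_amplitudes[ch],
        )
        channels[ch] = (x * profile.channel_gains[ch]).astype(np.float64)
    return PPGRecording(
        participant_id=profile.participant_id,
        class_label=profile.class_label,
        channels=channels,
        fs=protocol.fs,
        channel_gains=dict(profile.channel_gains),
        protocol=protocol,
    )


def _manifest_row(profile: ParticipantProfile, protocol: ProtocolConfig, seed: int) -> dict:
    row = {
        "participant_id": profile.participant_id,
        "class_label": profile.class_label,
        "heart_rate_hz": profile.heart_rate,
        "flush_overshoot": profile.flush_overshoot,
        "flush_tau_s": profile.flush_tau,
        "amplitude_heterogeneity": profile.amplitude_heterogeneity,
        "noise_sd": profile.noise_sd,
        "seed": seed,
    }
    for ch in protocol.channels:
        row[f"amp_{ch}"] = profile.pulse_amplitudes[ch]
        row[f"gain_{ch}"] = profile.channel_gains[ch]
    return row


def generate_cohort(
    n_ssc: int,
    n_control: int,
    protocol: ProtocolConfig | None = None,
    phenotype: PhenotypeDistributions | None = None,
    seed: int = 0,
) -> tuple[list[PPGRecording], pd.DataFrame]:
    """Generate a seeded cohort; returns recordings and a parameter manifest.

    SSc participants are generated first (ids SSC001...), then Controls
    (CTL001...). The manifest records every sampled phenotype parameter,
    so a cohort is fully reproducible from the seed.
    """
    if n_ssc < 0 or n_control < 0:
        raise ValueError("cohort sizes must be non-negative")
    protocol = protocol or ProtocolConfig()
    phenotype = phenotype or PhenotypeDistributions.defaults()
    rng = np.random.default_rng(seed)
    recordings: list[PPGRecording] = []
    rows: list[dict] = []
    plan = [(SSC, phenotype.ssc, f"SSC{i + 1:03d}") for i in range(n_ssc)]
    plan += [(CONTROL, phenotype.control, f"CTL{i + 1:03d}") for i in range(n_control)]
    for label, pheno, pid in plan:
        profile = sample_profile(pid, label, pheno, protocol, rng)
        recordings.append(generate_recording(profile, protocol, rng))
        rows.append(_manifest_row(profile, protocol, seed))
    columns = list(_manifest_row(
        sample_profile("X", SSC, phenotype.ssc, protocol, np.random.default_rng(0)),
        protocol, seed)) if not rows else list(rows[0])
    manifest = pd.DataFrame(rows, columns=columns)
    return recordings, manifest


def write_cohort(recordings: Sequence[PPGRecording], manifest: pd.DataFrame, out_dir: str | Path) -> None:
    """One delimited-text file per participant plus ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        save_recording(rec, out_dir / f"{rec.participant_id}.csv")
    manifest.to_csv(out_dir / "manifest.csv", index=False)
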