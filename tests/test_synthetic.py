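"""Synthetic 3-phase PPG cohort generator."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from ppgdx.preprocess import detect_saturation
from ppgdx.recording import CONTROL, SSC, ProtocolConfig
from ppgdx.synthetic import (
    PhenotypeDistributions,
    generate_cohort,
    generate_pulse_train,
    phase_envelope,
    sample_profile,
)


def _profile(protocol, label=CONTROL, seed=0, **overrides):
    pheno = PhenotypeDistributions.defaults()
    prof = sample_profile(
        "P01", label, pheno.ssc if label == SSC else pheno.control,
        protocol, np.random.default_rng(seed),
    )
    for k, v in overrides.items():
        object.__setattr__(prof, k, v)
    return prof


class TestPulseTrain:
    def test_zero_envelope_yields_noise_only(self, short_protocol):
        prof = _profile(short_protocol)
        x = generate_pulse_train(prof, np.zeros(2000), 200.0, 10.0,
                                 np.random.default_rng(0), amplitude=50.0)
        assert abs(x.mean()) < 0.5
        assert x.std() <= 1.2 * prof.noise_sd

    def test_beat_count_matches_heart_rate(self, short_protocol):
        # oracle: count peaks above half the configured amplitude
        prof = _profile(short_protocol, heart_rate=1.2, noise_sd=0.5)
        x = generate_pulse_train(prof, np.ones(2000), 200.0, 10.0,
                                 np.random.default_rng(3), amplitude=50.0)
        peaks, _ = find_peaks(x, height=25.0, distance=int(0.4 * 200))
        assert len(peaks) in {11, 12, 13}

    def test_seeded_determinism(self, short_protocol):
        prof = _profile(short_protocol)
        env = np.ones(2000)
        a = generate_pulse_train(prof, env, 200.0, 10.0, np.random.default_rng(5))
        b = generate_pulse_train(prof, env, 200.0, 10.0, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_band_limited_to_pulse_band(self, short_protocol):
        prof = _profile(short_protocol, heart_rate=1.2)
        x = generate_pulse_train(prof, np.ones(200 * 60), 200.0, 60.0,
                                 np.random.default_rng(7), amplitude=50.0)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(len(x), 1 / 200.0)
        inband = spec[(freqs >= 0.4) & (freqs <= 21)].sum()
        assert inband / spec.sum() > 0.99

    def test_invalid_parameters_raise(self, short_protocol):
        prof = _profile(short_protocol)
        with pytest.raises(ValueError):
            generate_pulse_train(prof, np.ones(10), -1.0, 10.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_pulse_train(prof, np.ones(10), 200.0, 10.0, np.random.default_rng(0))


class TestPhaseEnvelope:
    def test_non_occluded_stays_near_one(self, short_protocol):
        prof = _profile(short_protocol)
        env = phase_envelope(prof, short_protocol, "right_ear")
        assert np.abs(env - 1.0).max() <= prof.drift_amplitude + 1e-9

    def test_occlusion_abolishes_pulse(self, short_protocol):
        prof = _profile(short_protocol)
        env = phase_envelope(prof, short_protocol, "left_finger")
        # 25 s into the occlusion the cuff has long stopped the flow
        i = int((short_protocol.baseline_end + 25) * short_protocol.fs)
        assert env[i] < 0.05

    def test_flush_jumps_to_overshoot(self, short_protocol):
        # closed-form oracle: env(occlusion_end + eps) = overshoot
        prof = _profile(short_protocol, flush_overshoot=1.8)
        env = phase_envelope(prof, short_protocol, "left_finger")
        i = int(short_protocol.occlusion_end * short_protocol.fs) + 1
        assert env[i] == pytest.approx(1.8, rel=0.01)

    def test_flush_relaxes_toward_baseline(self, short_protocol):
        prof = _profile(short_protocol, flush_overshoot=1.8, flush_tau=5.0)
        env = phase_envelope(prof, short_protocol, "left_finger")
        t_rel = 25.0  # 5 time constants after release
        i = int((short_protocol.occlusion_end + t_rel) * short_protocol.fs)
        assert env[i] == pytest.approx(1.0 + 0.8 * np.exp(-5), abs=1e-3)

    def test_unknown_channel_raises(self, short_protocol):
        with pytest.raises(ValueError, match="unknown channel"):
            phase_envelope(_profile(short_protocol), short_protocol, "nose")


class TestCohort:
    def test_single_control(self, short_protocol):
        recs, manifest = generate_cohort(0, 1, short_protocol, seed=0)
        assert len(recs) == 1 and len(manifest) == 1
        assert recs[0].class_label == CONTROL

    def test_study_size_cohort(self):
        # 20 SSc vs 51 Controls (healthy + primary Raynaud's merged)
        proto = ProtocolConfig(fs=80.0, duration=120.0, baseline_end=60.0, occlusion_end=90.0)
        recs, manifest = generate_cohort(20, 51, proto, seed=3)
        assert len(recs) == 71
        assert sum(r.class_label == SSC for r in recs) == 20
        assert (manifest["class_label"] == SSC).sum() == 20

    def test_same_seed_identical_output(self, short_protocol):
        a_recs, a_man = generate_cohort(1, 1, short_protocol, seed=9)
        b_recs, b_man = generate_cohort(1, 1, short_protocol, seed=9)
        assert a_man.equals(b_man)
        for ra, rb in zip(a_recs, b_recs):
            for ch in short_protocol.channels:
                np.testing.assert_array_equal(ra.channels[ch], rb.channels[ch])

    def test_flush_overshoot_class_separation(self, short_protocol):
        # Controls' overshoot distribution stochastically dominates SSc's
        pheno = PhenotypeDistributions.defaults()
        rng = np.random.default_rng(17)
        ssc = [sample_profile(f"S{i}", SSC, pheno.ssc, short_protocol, rng).flush_overshoot
               for i in range(100)]
        ctl = [sample_profile(f"C{i}", CONTROL, pheno.control, short_protocol, rng).flush_overshoot
               for i in range(100)]
        qs = np.linspace(0.05, 0.95, 19)
        assert np.all(np.quantile(ctl, qs) > np.quantile(ssc, qs))

    def test_occlusion_fidelity(self):
        # long occlusion: occluded-channel beat amplitude < 5% of baseline
        proto = ProtocolConfig(fs=200.0, duration=480.0, baseline_end=120.0, occlusion_end=420.0)
        pheno = PhenotypeDistributions.defaults()
        prof = sample_profile("P1", CONTROL, pheno.control, proto, np.random.default_rng(4))
        object.__setattr__(prof, "noise_sd", 0.0)  # measure the pulse alone
        from ppgdx.synthetic import generate_recording

        rec = generate_recording(prof, proto, np.random.default_rng(5))
        x = rec.channels["left_finger"]
        fs = proto.fs
        base = x[int(10 * fs): int(110 * fs)]
        occ = x[int(140 * fs): int(415 * fs)]  # skip the 20-s decay transient
        assert np.sqrt((occ ** 2).mean()) < 0.05 * np.sqrt((base ** 2).mean())

    def test_generated_signals_pass_saturation_qc(self, small_cohort):
        recs, _ = small_cohort
        for rec in recs[:3]:
            for ch in rec.protocol.channels:
                assert detect_saturation(rec.channels[ch], rec.fs).passed

    def test_negative_cohort_size_raises(self, short_protocol):
        with pytest.raises(ValueError):
            generate_cohort(-1, 5, short_protocol, seed=0)
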