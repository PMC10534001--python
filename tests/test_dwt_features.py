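"""10-level db4 DWT band features (144 per participant)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ppgdx.dwt_features import (
    SELECTED_BANDS,
    band_features,
    dwt_decompose,
    feature_table,
    participant_features,
    select_bands,
)
from ppgdx.evaluation import round_half_up
from ppgdx.preprocess import gain_normalize

#: Dyadic band edges at the clinical 2000 Hz sampling rate, to 2 d.p.
PRINTED_BANDS_2000 = {
    "d6": (15.63, 31.25),
    "d7": (7.81, 15.63),
    "d8": (3.91, 7.81),
    "d9": (1.95, 3.91),
    "d10": (0.98, 1.95),
}


class TestDecomposition:
    def test_band_edges_at_clinical_rate(self):
        x = np.random.default_rng(0).normal(size=4096)
        bc = dwt_decompose(x, fs=2000.0)
        for band, (lo, hi) in PRINTED_BANDS_2000.items():
            got_lo, got_hi = bc.band_edges[band]
            assert round_half_up(got_lo, 2) == lo
            assert round_half_up(got_hi, 2) == hi
        assert bc.band_edges["ap"] == (0.0, 2000.0 / 2**11)

    @pytest.mark.parametrize("n", [4096, 6000])
    def test_parseval_energy_conservation(self, n):
        x = np.random.default_rng(1).normal(size=n)
        bc = dwt_decompose(x, fs=200.0)
        total = sum(float((c**2).sum()) for c in bc.coefficients.values())
        kept = x[: n - n % 2**10]  # analysed prefix (multiple of 2^levels)
        assert total == pytest.approx(float((kept**2).sum()), rel=1e-10)

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            dwt_decompose(np.ones(512), fs=200.0)

    def test_select_bands_order_and_cardinality(self):
        bc = dwt_decompose(np.random.default_rng(2).normal(size=2048), fs=200.0)
        sel = select_bands(bc)
        assert tuple(sel) == SELECTED_BANDS
        assert "d1" not in sel and "d5" not in sel

    def test_select_bands_missing_level_raises(self):
        bc = dwt_decompose(np.random.default_rng(3).normal(size=2048), fs=200.0, levels=8)
        with pytest.raises(ValueError):
            select_bands(bc)


class TestBandFeatures:
    def test_energy_is_sum_of_squares(self):
        assert band_features(np.array([1.0, 2.0, 3.0])).energy == 14.0

    def test_symmetric_coefficients(self):
        f = band_features(np.array([-1.0, 1.0]))
        assert f.mav == 0.0
        assert f.skewness == 0.0

    def test_entropy_degenerate_and_uniform(self):
        assert band_features(np.array([3.0, 0.0, 0.0, 0.0])).entropy == 0.0
        with pytest.warns(UserWarning):  # constant band also has zero variance
            assert band_features(np.array([2.0, 2.0, 2.0, 2.0])).entropy == pytest.approx(2.0)

    def test_zero_variance_skewness_warns(self):
        with pytest.warns(UserWarning, match="skewness"):
            f = band_features(np.array([2.0, 2.0]))
        assert f.skewness == 0.0

    def test_mav_conventions(self):
        x = np.array([-2.0, 4.0])
        assert band_features(x).mav == 1.0  # |mean|
        assert band_features(x, mav_convention="mean_of_abs").mav == 3.0

    def test_skewness_matches_population_moments(self):
        x = np.random.default_rng(4).exponential(size=500)
        from scipy.stats import skew

        assert band_features(x).skewness == pytest.approx(float(skew(x, bias=True)))

    @given(scale=st.floats(min_value=0.01, max_value=100.0),
           seed=st.integers(min_value=0, max_value=50))
    def test_scaling_laws(self, scale, seed):
        # entropy is scale-invariant; energy scales quadratically
        x = np.random.default_rng(seed).normal(size=64)
        f1, f2 = band_features(x), band_features(scale * x)
        assert f2.entropy == pytest.approx(f1.entropy, rel=1e-9, abs=1e-9)
        assert f2.energy == pytest.approx(scale**2 * f1.energy, rel=1e-9)


class TestParticipantFeatures:
    def test_vector_has_144_named_features(self, small_cohort_normalised):
        recs, _ = small_cohort_normalised
        fv = participant_features(recs[0])
        assert len(fv.values) == 144
        assert fv.names[0] == "right_ear.d6.energy"
        assert fv.names[-1] == "left_toe.ap.skewness"
        assert len(set(fv.names)) == 144

    def test_duplicate_recording_identical_vector(self, small_cohort_normalised):
        recs, _ = small_cohort_normalised
        a = participant_features(recs[0])
        b = participant_features(recs[0])
        np.testing.assert_array_equal(a.values, b.values)

    def test_channel_scaling_affects_only_that_channel(self, small_cohort_normalised):
        recs, _ = small_cohort_normalised
        rec = recs[1]
        scaled = rec.copy_with_channels(
            {ch: (3.0 * x if ch == "left_finger" else x) for ch, x in rec.channels.items()},
            dict(rec.channel_gains),
        )
        a = participant_features(rec)
        b = participant_features(scaled)
        for name, va, vb in zip(a.names, a.values, b.values):
            ch, band, feat = name.split(".")
            if ch != "left_finger":
                assert vb == pytest.approx(va, rel=1e-9, abs=1e-12)
            elif feat == "energy":
                assert vb == pytest.approx(9.0 * va, rel=1e-9)
            elif feat == "entropy":
                assert vb == pytest.approx(va, rel=1e-6, abs=1e-9)

    def test_feature_table_shape(self, small_cohort_normalised):
        recs, _ = small_cohort_normalised
        table = feature_table([participant_features(r) for r in recs[:4]])
        assert table.shape == (4, 146)  # id + label + 144 features
        assert table["class_label"].isin(["SSc", "Control"]).all()
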