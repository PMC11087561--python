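"""Feature extraction: counts, closed forms, invariances, oracle checks."""

import numpy as np
import pytest

from bgsleep.features import (
    CONNECTIVITY_NAMES,
    FEATURE_NAMES,
    EpochFeatureExtractor,
    FlatEpochError,
    build_feature_matrix,
    coherence_features,
    entropy_features,
    spectral_features,
    temporal_features,
)
from bgsleep.signal_io import EpochSet

from naive_oracle import naive_all_features

FS = 200.0
N = 6000


def sine(freq, amp=1.0, phase=0.0, n=N, fs=FS):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestFeatureCounts:
    def test_local_feature_blocks(self, rng):
        x = rng.standard_normal(N)
        assert len(spectral_features(x)) == 18
        assert len(temporal_features(x)) == 7
        assert len(entropy_features(x)) == 3
        assert len(FEATURE_NAMES) == 28
        ratios = [n for n in FEATURE_NAMES if n.startswith("ratio_")]
        assert len(ratios) == 10

    def test_connectivity_block(self, rng):
        a, b = rng.standard_normal((2, N))
        feats = coherence_features(a, b)
        assert len(feats) == 18
        assert len(CONNECTIVITY_NAMES) == 18


class TestSpectral:
    def test_single_band_concentration(self, rng):
        x = sine(2.0) + 1e-6 * rng.standard_normal(N)
        f = spectral_features(x)
        assert f["relpow_delta"] > 0.99
        for q in ("theta", "alpha", "beta", "gamma"):
            assert f[f"ratio_delta_{q}"] > 1.0

    def test_equal_power_sines_ratio_one(self):
        x = sine(2.0) + sine(6.0)
        f = spectral_features(x)
        assert f["ratio_delta_theta"] == pytest.approx(1.0, rel=0.05)

    def test_white_noise_flat_spectrum(self, rng):
        # mean relative powers approach bandwidth fractions
        widths = {"delta": 3, "theta": 4, "alpha": 5, "low_beta": 7,
                  "high_beta": 10, "low_gamma": 15, "high_gamma": 35}
        total = sum(widths.values())
        X = rng.standard_normal((100, N))
        df = EpochFeatureExtractor().transform(X)
        for band, w in widths.items():
            got = df[f"relpow_{band}"].mean()
            assert got == pytest.approx(w / total, rel=0.10)

    def test_relative_powers_sum_to_one(self, rng):
        df = EpochFeatureExtractor().transform(rng.standard_normal((20, N)))
        sums = df[[c for c in df.columns if c.startswith("relpow_")]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_flat_epoch_rejected(self):
        with pytest.raises(FlatEpochError):
            spectral_features(np.zeros(N))


class TestTemporal:
    def test_sine_rms(self):
        f = temporal_features(sine(7.0, amp=3.0))
        assert f["std"] == pytest.approx(3.0 / np.sqrt(2), rel=0.01)

    def test_positive_signal_no_crossings(self, rng):
        f = temporal_features(rng.uniform(0.5, 1.5, N))
        assert f["zero_crossings"] == 0

    def test_sine_mobility_closed_form(self):
        # long sine: the n-1-sample first difference spans a fractional
        # cycle whose bias decays as 1/n
        for freq in (5.0, 10.0, 25.0):
            f = temporal_features(sine(freq, n=400000))
            assert f["hjorth_mobility"] == pytest.approx(
                2.0 * np.sin(np.pi * freq / FS), abs=1e-6
            )


class TestEntropy:
    def test_ramp_closed_forms(self):
        f = entropy_features(np.arange(N, dtype=float))
        assert f["permutation_entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["petrosian_fd"] == pytest.approx(1.0, abs=1e-12)

    def test_iid_noise_entropy_near_one(self, rng):
        pes = [
            entropy_features(rng.standard_normal(N))["permutation_entropy"]
            for _ in range(100)
        ]
        assert min(pes) > 0.99

    def test_higuchi_extremes(self, rng):
        line = np.linspace(0.0, 1.0, N)
        assert entropy_features(line)["higuchi_fd"] == pytest.approx(1.0, abs=0.05)
        fds = [
            entropy_features(rng.standard_normal(N))["higuchi_fd"]
            for _ in range(20)
        ]
        assert np.mean(fds) == pytest.approx(2.0, abs=0.1)


class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(N)
        f = coherence_features(x, x)
        for band in ("delta", "theta", "alpha", "low_beta", "high_beta",
                     "low_gamma", "high_gamma"):
            assert f[f"coh_{band}"] == pytest.approx(1.0, abs=1e-6)
        assert f["cohratio_delta_theta"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_low_coherence(self, rng):
        vals = []
        for _ in range(100):
            a, b = rng.standard_normal((2, N))
            vals.append(coherence_features(a, b)["coh_alpha"])
        assert np.mean(vals) < 0.2

    def test_shared_theta_source_sets_peak(self, rng):
        shared = sine(6.0, amp=2.0)
        a = shared + 0.5 * rng.standard_normal(N)
        b = shared + 0.5 * rng.standard_normal(N)
        f = coherence_features(a, b)
        assert 4.0 <= f["peak_coherence_frequency"] <= 8.0

    def test_peak_skips_notch_gap(self, rng):
        shared = sine(50.0, amp=5.0)
        a = shared + 0.2 * rng.standard_normal(N)
        b = shared + 0.2 * rng.standard_normal(N)
        f = coherence_features(a, b)
        assert not (45.0 < f["peak_coherence_frequency"] < 55.0)


class TestInvariances:
    def test_negation_flips_only_skewness(self, rng):
        x = rng.standard_normal(N) ** 3  # skewed
        ext = EpochFeatureExtractor()
        a = ext.transform(x[None, :]).iloc[0]
        b = ext.transform(-x[None, :]).iloc[0]
        for name in FEATURE_NAMES:
            if name == "skewness":
                assert b[name] == pytest.approx(-a[name], rel=1e-9)
            else:
                assert b[name] == pytest.approx(a[name], rel=1e-6, abs=1e-9)

    @pytest.mark.parametrize("a", [0.1, 7.3])
    def test_amplitude_scaling(self, rng, a):
        x = rng.standard_normal(N)
        ext = EpochFeatureExtractor()
        f0 = ext.transform(x[None, :]).iloc[0]
        f1 = ext.transform(a * x[None, :]).iloc[0]
        assert f1["std"] == pytest.approx(a * f0["std"], rel=1e-9)
        assert f1["iqr"] == pytest.approx(a * f0["iqr"], rel=1e-9)
        assert f1["total_power"] == pytest.approx(
            f0["total_power"] + 2 * np.log10(a), rel=1e-9
        )
        for name in FEATURE_NAMES:
            if name in ("std", "iqr", "total_power"):
                continue
            assert f1[name] == pytest.approx(f0[name], rel=1e-8), name


def test_all_features_match_naive_oracle(rng):
    """Vectorised implementation equals the definitional formulas."""
    X = rng.standard_normal((100, N)) * rng.uniform(0.5, 5.0, size=(100, 1))
    df = EpochFeatureExtractor().transform(X)
    for i in range(100):
        ref = naive_all_features(X[i])
        for name in FEATURE_NAMES:
            rel = abs(df.iloc[i][name] - ref[name]) / max(abs(ref[name]), 1e-12)
            assert rel < 1e-8, f"{name} deviates at epoch {i}: {rel}"


class TestBuildFeatureMatrix:
    def _epochs(self, rng, n=10, n_chan=1):
        data = rng.standard_normal((n, n_chan, N))
        stages = np.array(["W", "NREM", "REM"] * (n // 3 + 1), dtype=object)[:n]
        return EpochSet(data=data, rate=FS, stages=stages,
                        channel_labels=[f"c{i}" for i in range(n_chan)])

    def test_single_site_28_columns(self, rng):
        fm = build_feature_matrix(self._epochs(rng), subject="s1")
        feat_cols = [c for c in fm.columns
                     if c not in ("subject", "channel", "disease", "target", "stage")]
        assert len(feat_cols) == 28
        assert len(fm) == 10

    def test_dual_site_74_columns(self, rng):
        bg, ctx = self._epochs(rng), self._epochs(rng)
        fm = build_feature_matrix((bg, ctx), mode="dual_site", subject="s1")
        feat_cols = [c for c in fm.columns
                     if c not in ("subject", "channel", "disease", "target", "stage")]
        assert len(feat_cols) == 74
        assert sum(c.startswith("bg_") for c in feat_cols) == 28
        assert sum(c.startswith("ctx_") for c in feat_cols) == 28
        assert sum(c.startswith("coh") or c == "peak_coherence_frequency"
                   for c in feat_cols) == 18

    def test_flat_epoch_dropped_and_logged(self, rng, caplog):
        es = self._epochs(rng, n=10)
        es.data[3, 0, :] = 7.0
        with caplog.at_level("WARNING"):
            fm = build_feature_matrix(es)
        assert len(fm) == 9
        assert "flat" in caplog.text

    def test_metadata_complete(self, rng):
        fm = build_feature_matrix(
            self._epochs(rng), subject="s1", channel="c0",
            disease="PD", target="STN",
        )
        assert (fm["disease"] == "PD").all()
        assert not fm.isna().any().any()
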