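"""Decoder: oversampling, training, metrics, LOSO evaluation, attribution."""

import numpy as np
import pandas as pd
import pytest

from bgsleep.decoder import (
    DecodingContext,
    SearchSpec,
    SleepStageDecoder,
    SmoteOversampler,
    compute_metrics,
    evaluate_loso,
    feature_importance,
    load_decoder,
    oversample_minority,
    predict_stages,
    save_decoder,
    tune_and_train,
)
from bgsleep.features import FEATURE_NAMES


def make_blobs(rng, counts, n_features=6, spread=0.3):
    """Linearly separable class blobs keyed by stage label."""
    X, y = [], []
    for k, (label, n) in enumerate(sorted(counts.items())):
        center = np.zeros(n_features)
        center[k % n_features] = 5.0
        X.append(center + spread * rng.standard_normal((n, n_features)))
        y.append(np.full(n, label, dtype=object))
    return np.vstack(X), np.concatenate(y)


def make_matrix(rng, n_subjects=6, epochs=60, n_features=6, spread=0.3,
                channels=("ch1",)):
    rows = []
    for s in range(n_subjects):
        for ch in channels:
            X, y = make_blobs(
                rng, {"W": epochs // 3, "NREM": epochs // 3, "REM": epochs // 3},
                n_features, spread,
            )
            df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
            df.insert(0, "subject", f"S{s}")
            df.insert(1, "channel", ch)
            df.insert(2, "disease", ["PD", "DYS"][s % 2])
            df.insert(3, "target", ["STN", "GPi"][(s // 2) % 2])
            df.insert(4, "stage", y)
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X, y = make_blobs(rng, {"W": 50, "NREM": 50, "REM": 50})
        Xr, yr = SmoteOversampler().fit_resample(X, y)
        assert len(yr) == 150

    def test_counts_equalized(self, rng):
        X, y = make_blobs(rng, {"W": 50, "NREM": 200, "REM": 30})
        Xr, yr = SmoteOversampler().fit_resample(X, y)
        _, counts = np.unique(yr, return_counts=True)
        assert list(counts) == [200, 200, 200]

    def test_synthetic_rows_on_segments(self, rng):
        X, y = make_blobs(rng, {"W": 8, "NREM": 40}, n_features=4)
        Xr, yr = SmoteOversampler(k_neighbors=5).fit_resample(X, y)
        originals = X[y == "W"]
        synth = Xr[len(X):]
        assert (yr[len(X):] == "W").all()
        for s in synth:
            on_segment = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    d = originals[j] - originals[i]
                    t = np.dot(s - originals[i], d) / np.dot(d, d)
                    if 0 <= t <= 1 and np.allclose(
                        s, originals[i] + t * d, atol=1e-8
                    ):
                        on_segment = True
            assert on_segment

    def test_small_class_reduces_k(self, rng, caplog):
        X, y = make_blobs(rng, {"W": 3, "NREM": 20})
        with caplog.at_level("WARNING"):
            _, yr = SmoteOversampler(k_neighbors=5).fit_resample(X, y)
        assert "reducing k" in caplog.text
        assert (yr == "W").sum() == 20

    def test_singleton_duplicated_with_jitter(self, rng, caplog):
        X, y = make_blobs(rng, {"W": 1, "NREM": 10})
        with caplog.at_level("WARNING"):
            Xr, yr = SmoteOversampler().fit_resample(X, y)
        assert "singleton" in caplog.text
        assert (yr == "W").sum() == 10

    def test_dataframe_wrapper_balances_stages(self, rng):
        fm = make_matrix(rng, n_subjects=1, epochs=30)
        fm = fm[fm["stage"] != "REM"].iloc[:25]
        out = oversample_minority(fm)
        counts = out["stage"].value_counts()
        assert counts.min() == counts.max()


class TestDecoder:
    def test_separable_training_accuracy(self, rng):
        X, y = make_blobs(rng, {"W": 40, "NREM": 40, "REM": 40})
        dec = SleepStageDecoder().fit(X, y)
        assert (dec.predict(X) == y).mean() == 1.0

    def test_probabilities_sum_to_one(self, rng):
        X, y = make_blobs(rng, {"W": 40, "NREM": 40, "REM": 40})
        dec = SleepStageDecoder().fit(X, y)
        np.testing.assert_allclose(dec.predict_proba(X).sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_deterministic_given_seed(self, rng):
        X, y = make_blobs(rng, {"W": 30, "NREM": 30, "REM": 30})
        a = SleepStageDecoder(search_rounds=3, random_state=7).fit(X, y)
        b = SleepStageDecoder(search_rounds=3, random_state=7).fit(X, y)
        assert a.best_params_ == b.best_params_
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_identical_rows_identical_labels(self, rng):
        X, y = make_blobs(rng, {"W": 30, "NREM": 30})
        dec = SleepStageDecoder().fit(X, y)
        Xq = np.tile(X[0], (5, 1))
        assert len(set(dec.predict(Xq))) == 1

    def test_feature_contract_enforced(self, rng):
        fm = make_matrix(rng, n_subjects=2)
        dec = tune_and_train(fm, SearchSpec(search_rounds=0))
        bad = fm.rename(columns={"f0": "banana"})
        with pytest.raises(ValueError, match="banana"):
            predict_stages(dec, bad)

    def test_pluggable_backend(self, rng):
        from sklearn.linear_model import LogisticRegression

        X, y = make_blobs(rng, {"W": 30, "NREM": 30, "REM": 30})
        dec = SleepStageDecoder(
            base_estimator=LogisticRegression(max_iter=200)
        ).fit(X, y)
        assert (dec.predict(X) == y).mean() > 0.95

    def test_predicts_only_trained_classes(self, rng):
        X, y = make_blobs(rng, {"W": 30, "NREM": 30})
        dec = SleepStageDecoder().fit(X, y)
        assert set(dec.predict(X)) <= {"W", "NREM"}


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics(["W", "NREM", "REM"], ["W", "NREM", "REM"])
        assert m.accuracy == 1.0
        assert m.mislabeling_rate == 0.0

    def test_mislabeling_rate_arithmetic(self):
        y = ["W"] * 90 + ["NREM"] * 10
        p = ["W"] * 90 + ["W"] * 10
        m = compute_metrics(y, p)
        assert m.accuracy == pytest.approx(0.9)
        assert m.mislabeling_rate == pytest.approx(6.0)

    def test_imbalanced_hand_case(self):
        # 10 W, 90 NREM, all predicted NREM
        y = ["W"] * 10 + ["NREM"] * 90
        m = compute_metrics(y, ["NREM"] * 100)
        assert m.accuracy == pytest.approx(0.9)
        assert m.balanced_accuracy == pytest.approx(0.5)
        assert m.per_class_recall == {"NREM": 1.0, "W": 0.0}

    def test_confusion_rows_sum_to_true_counts(self, rng):
        y = rng.choice(["W", "NREM", "REM"], 120)
        p = rng.choice(["W", "NREM", "REM"], 120)
        m = compute_metrics(y, p)
        for cls in ("W", "NREM", "REM"):
            assert m.confusion.loc[cls].sum() == (y == cls).sum()
        assert np.trace(m.confusion.to_numpy()) / 120 == pytest.approx(m.accuracy)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestEvaluateLoso:
    def test_partition_and_structure(self, rng):
        fm = make_matrix(rng, n_subjects=6, channels=("ch1", "ch2"))
        res = evaluate_loso(fm, DecodingContext(), SearchSpec(search_rounds=0))
        assert len(res["best_channel"]) == 6
        assert len(res["per_channel"]) == 12
        assert set(res["best_channel"]["subject"]) == set(fm["subject"])

    def test_best_channel_at_least_mean(self, rng):
        fm = make_matrix(rng, n_subjects=5, channels=("ch1", "ch2"), spread=2.0)
        res = evaluate_loso(fm, DecodingContext(), SearchSpec(search_rounds=0))
        mean_acc = res["per_channel"].groupby("subject")["accuracy"].mean()
        for _, row in res["best_channel"].iterrows():
            assert row["accuracy"] >= mean_acc[row["subject"]] - 1e-12

    def test_grouped_contexts_split_subjects(self, rng):
        fm = make_matrix(rng, n_subjects=12)
        ctx = DecodingContext(grouping="same_disease_cross_target")
        res = evaluate_loso(fm, ctx, SearchSpec(search_rounds=0))
        assert len(res["best_channel"]) == 12  # every subject still evaluated

    def test_too_few_subjects_in_group(self, rng):
        fm = make_matrix(rng, n_subjects=2)
        with pytest.raises(ValueError, match=">= 3"):
            evaluate_loso(fm, DecodingContext(), SearchSpec(search_rounds=0))

    def test_individualized_mode(self, rng):
        fm = make_matrix(rng, n_subjects=2, epochs=120)
        ctx = DecodingContext(mode="individualized")
        res = evaluate_loso(fm, ctx, SearchSpec(search_rounds=0))
        assert len(res["per_channel"]) == 2
        assert (res["per_channel"]["accuracy"] > 0.9).all()


class TestImportance:
    def test_attributions_sum_to_margin(self, rng):
        X, y = make_blobs(rng, {"W": 40, "NREM": 40, "REM": 40})
        dec = SleepStageDecoder().fit(X, y)
        contrib = dec.booster_.predict(X, pred_contrib=True)
        raw = dec.booster_.predict(X, raw_score=True)
        total = contrib.reshape(len(X), 3, -1).sum(axis=2)
        np.testing.assert_allclose(total, raw, atol=1e-6)

    def test_single_informative_feature_ranks_first(self, rng):
        n = 120
        y = np.repeat(["W", "NREM", "REM"], n)
        X = pd.DataFrame(
            rng.standard_normal((3 * n, len(FEATURE_NAMES))),
            columns=FEATURE_NAMES,
        )
        shift = {"W": 0.0, "NREM": 4.0, "REM": -4.0}
        X["ratio_delta_theta"] += [shift[c] for c in y]
        dec = SleepStageDecoder().fit(X, y)
        table = feature_importance(dec, X)
        assert table.index[0] == "ratio_delta_theta"

    def test_constant_feature_zero_attribution(self, rng):
        X, y = make_blobs(rng, {"W": 40, "NREM": 40})
        X = np.column_stack([X, np.full(len(X), 3.14)])
        dec = SleepStageDecoder().fit(X, y)
        table = feature_importance(dec, X)
        assert table["global"].loc["6"] == pytest.approx(0.0, abs=1e-12)


class TestPersistence:
    def test_round_trip_bit_identical(self, tmp_path, rng):
        fm = make_matrix(rng, n_subjects=3)
        dec = tune_and_train(fm, SearchSpec(search_rounds=0))
        labels0, proba0 = predict_stages(dec, fm)
        save_decoder(dec, tmp_path / "model.json")
        back = load_decoder(tmp_path / "model.json")
        labels1, proba1 = predict_stages(back, fm)
        np.testing.assert_array_equal(labels0, labels1)
        np.testing.assert_array_equal(proba0, proba1)
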