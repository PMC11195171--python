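"""Classifier architecture, training protocol, and statistical reports."""

import numpy as np
import pytest

from bcd.decode import (
    CNNClassifier,
    SVMClassifier,
    TrainingProtocol,
    balance_fold,
    build_dataset,
    cross_nucleus_test,
    stratified_split,
    train_once,
)
from bcd.timefreq import Spectrogram


def make_specs(n_airflow, n_touch, shape=(12, 8), nucleus="B", shift=0.0, rng=None):
    """Synthetic spectrogram stacks; `shift` displaces the touch class."""
    rng = rng or np.random.default_rng(0)
    out = []
    for label, n, s in (("airflow", n_airflow, 0.0), ("touch", n_touch, shift)):
        for _ in range(n):
            p = rng.random(shape).astype(np.float32) + s
            out.append(
                Spectrogram(
                    power=p, freqs=np.arange(1.0, shape[0] + 1),
                    times=np.arange(shape[1]) * 0.05, label=label, nucleus=nucleus,
                )
            )
    return out


class TestArchitecture:
    def test_parameter_shapes_match_architecture(self):
        """24 then 48 kernels of 3x3, fully connected 64 -> 2."""
        rng = np.random.default_rng(0)
        X = rng.random((40, 20, 10)).astype(np.float32)
        y = np.array(["airflow", "touch"] * 20)
        clf = CNNClassifier(n_epochs=1, random_state=0).fit(X, y)
        p = clf.params_
        assert p["W1"].shape == (24, 1, 3, 3)
        assert p["W2"].shape == (48, 24, 3, 3)
        # conv twice (valid) then 2x2 pool stride 1: (20,10)->(16,6)->(15,5)
        assert p["Wf1"].shape == (48 * 15 * 5, 64)
        assert p["Wf2"].shape == (64, 2)

    def test_cnn_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 10, 8)).astype(np.float32)
        y = np.array(["airflow", "touch"] * 20)
        a = CNNClassifier(n_epochs=2, random_state=5).fit(X, y).predict(X)
        b = CNNClassifier(n_epochs=2, random_state=5).fit(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_cnn_learns_separable_classes(self):
        rng = np.random.default_rng(2)
        X = rng.random((120, 16, 8)).astype(np.float32)
        y = np.array(["airflow", "touch"] * 60)
        X[y == "touch", 4:9, :] += 0.8
        clf = CNNClassifier(n_epochs=5, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.95

    def test_svm_beats_centroid_oracle_on_blobs(self):
        """Two shifted Gaussian blobs rendered as spectrograms: a brute-force
        nearest-centroid oracle reaches >=0.95 here, and the RBF-SVM must
        match that."""
        rng = np.random.default_rng(3)
        X = rng.normal(0, 0.3, (200, 6, 5)).astype(np.float32)
        y = np.array(["airflow", "touch"] * 100)
        X[y == "touch"] += 0.5
        Xtr, ytr, Xte, yte = X[:150], y[:150], X[150:], y[150:]
        # oracle: nearest class centroid in flattened pixel space
        f = lambda A: A.reshape(len(A), -1)
        cents = {lab: f(Xtr)[ytr == lab].mean(axis=0) for lab in ("airflow", "touch")}
        d = {lab: np.linalg.norm(f(Xte) - c, axis=1) for lab, c in cents.items()}
        oracle_pred = np.where(d["airflow"] < d["touch"], "airflow", "touch")
        assert (oracle_pred == yte).mean() >= 0.95
        svm = SVMClassifier(random_state=0).fit(Xtr, ytr)
        assert (svm.predict(Xte) == yte).mean() >= 0.95


class TestProtocol:
    def test_balancing_and_split_arithmetic(self):
        """Balanced 300+300 input: 480/60/60 with equal classes per fold.

        For unbalanced input (300 airflow + 200 touch) the training fold
        bootstraps the minority up (160 -> 240, train = 480) while the
        evaluation folds subsample the majority down (val = test = 40),
        keeping accuracy estimates over unique trials.
        """
        rng = np.random.default_rng(0)
        ds = build_dataset(make_specs(300, 300), nucleus="B", max_per_class=None)
        s_tr, s_va, s_te = stratified_split(ds.y, TrainingProtocol(), rng)
        folds = [
            balance_fold(s_tr, ds.y, rng),
            balance_fold(s_va, ds.y, rng, evaluation=True),
            balance_fold(s_te, ds.y, rng, evaluation=True),
        ]
        assert tuple(f.size for f in folds) == (480, 60, 60)
        for idx in folds:
            _, counts = np.unique(ds.y[idx], return_counts=True)
            assert counts[0] == counts[1]

        ds = build_dataset(make_specs(300, 200), nucleus="B", max_per_class=None)
        s_tr, s_va, s_te = stratified_split(ds.y, TrainingProtocol(), rng)
        assert balance_fold(s_tr, ds.y, rng).size == 480
        assert balance_fold(s_va, ds.y, rng, evaluation=True).size == 40
        assert balance_fold(s_te, ds.y, rng, evaluation=True).size == 40

    def test_no_trial_shared_across_folds(self):
        """Balancing happens inside each fold: no physical trial (index)
        may appear in more than one of train/validation/test."""
        specs = make_specs(120, 80)
        ds = build_dataset(specs, nucleus="B", max_per_class=None)
        rng = np.random.default_rng(1)
        s_tr, s_va, s_te = stratified_split(ds.y, TrainingProtocol(), rng)
        folds = [
            balance_fold(s_tr, ds.y, rng),
            balance_fold(s_va, ds.y, rng, evaluation=True),
            balance_fold(s_te, ds.y, rng, evaluation=True),
        ]
        sets = [set(f.tolist()) for f in folds]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])

    def test_balanced_input_still_resampled(self):
        specs = make_specs(50, 50)
        ds = build_dataset(specs, nucleus="B", max_per_class=None)
        rng = np.random.default_rng(0)
        tr = balance_fold(stratified_split(ds.y, TrainingProtocol(), rng)[0], ds.y, rng)
        assert (ds.y[tr] == "touch").sum() == (ds.y[tr] == "airflow").sum() == 40

    def test_absent_class_errors(self):
        specs = make_specs(40, 0)
        with pytest.raises(ValueError):
            build_dataset(specs, nucleus="B")

    def test_missing_nucleus_errors(self):
        specs = make_specs(30, 30, nucleus="B")
        with pytest.raises(ValueError):
            build_dataset(specs, nucleus="C")

    def test_max_per_class_caps_dataset(self):
        specs = make_specs(100, 60)
        ds = build_dataset(specs, nucleus="B", max_per_class=50, rng=0)
        assert ds.class_counts() == {"airflow": 50, "touch": 50}

    def test_train_once_deterministic(self):
        specs = make_specs(60, 60, shift=0.4)
        ds = build_dataset(specs, nucleus="B", max_per_class=None)
        proto = TrainingProtocol(n_repeats=1)
        a = train_once(ds, SVMClassifier(), proto, np.random.default_rng(42))
        b = train_once(ds, SVMClassifier(), proto, np.random.default_rng(42))
        assert a == b

    def test_separable_data_high_accuracy(self):
        specs = make_specs(60, 60, shift=0.6)
        ds = build_dataset(specs, nucleus="B", max_per_class=None)
        acc = train_once(ds, SVMClassifier(), TrainingProtocol(), np.random.default_rng(0))
        assert acc >= 0.9

    def test_quantiles_consistent_with_sample(self):
        from bcd.decode import AccuracyDistribution

        rng = np.random.default_rng(0)
        d = AccuracyDistribution(accuracies=rng.random(50), null_accuracies=rng.random(50))
        assert np.array_equal(d.quantiles, np.percentile(d.accuracies, [5, 50, 95]))


class TestEffectMonotonicity:
    def test_accuracy_nondecreasing_in_band_gain(self, null_dataset, signal_dataset):
        """Decoding accuracy grows with the injected band-power gain
        (1.0 -> 2.0 -> 3.0), within Monte-Carlo error."""
        from bcd.synthgen import BlockDesign, EffectSpec, simulate_session
        from bcd.baselines import extract_baselines, isi_segments
        from bcd.timefreq import WaveletConfig, spectrogram_stack

        strong = simulate_session(
            designs=[BlockDesign.airflow(), BlockDesign.touch()],
            effect=EffectSpec(touch_gain=3.0, airflow_gain=3.0),
            channel_nuclei=["B"] * 8, seed=31, n_units=2,
        )
        wins = extract_baselines(
            strong, isi_segments(strong, min_length=0.5), window_length=0.5
        )
        rng = np.random.default_rng(6)
        keep = []
        for lab in ("airflow", "touch"):
            idx = [i for i, w in enumerate(wins) if w.label == lab]
            keep.extend(rng.choice(idx, size=300, replace=False))
        specs = spectrogram_stack(
            [wins[i] for i in sorted(keep)], WaveletConfig(fs=strong.fs), time_decimation=50
        )
        strong_ds = build_dataset(specs, nucleus="B", max_per_class=300, rng=rng)

        proto = TrainingProtocol(n_repeats=1)
        rng = np.random.default_rng(77)
        means = [
            np.mean([train_once(ds, SVMClassifier(), proto, rng) for _ in range(5)])
            for ds in (null_dataset, signal_dataset, strong_ds)
        ]
        tol = 0.05  # Monte-Carlo slack at 5 repeats x 60 test items
        assert means[0] <= means[1] + tol
        assert means[1] <= means[2] + tol
        assert means[2] > means[0] + 0.1  # gain 3 is clearly decodable


class TestCrossNucleus:
    def test_identical_groups_h_zero(self):
        rng = np.random.default_rng(0)
        sample = rng.random(50)
        rep = cross_nucleus_test({n: sample for n in ("L", "B", "AB", "C")})
        assert rep["H"] == pytest.approx(0.0, abs=1e-9)
        assert rep["p"] > 0.99

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        groups = {n: rng.normal(0.7, 0.05, 50) for n in ("L", "B", "AB")}
        groups["C"] = rng.normal(0.9, 0.05, 50)
        rep = cross_nucleus_test(groups)
        assert rep["p"] < 0.01

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            cross_nucleus_test({"L": np.random.random(10)})

    def test_rank_correlation_with_contact_count(self):
        rng = np.random.default_rng(2)
        counts = {"L": 2, "B": 4, "AB": 8, "C": 16}
        groups = {
            n: rng.normal(0.5 + 0.02 * c, 0.001, 50) for n, c in counts.items()
        }
        rep = cross_nucleus_test(groups, channel_counts=counts)
        assert rep["spearman_rho"] == pytest.approx(1.0)
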