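"""Data model, EDF round trips, synthesis, and splitting."""

import numpy as np
import pytest
from scipy.signal import welch
from scipy.stats import ttest_ind

from eegens.eegdata import (
    EDFFormatError,
    EpochSet,
    SplitPlan,
    SynthSpec,
    generate_synthetic,
    make_folds,
    read_edf,
    split_train_test,
    write_epochs_edf,
)


def _band_power(data, lo=2.0, hi=8.0):
    f, p = welch(data.signals, fs=data.fs, nperseg=512, axis=-1)
    mask = (f >= lo) & (f <= hi)
    return np.trapezoid(p[..., mask], f[mask], axis=-1).mean(axis=1)


class TestEpoching:
    def test_edf_epoch_arithmetic(self, tmp_path):
        """A 60 s recording at 250 Hz cut into 10 s epochs gives 6 x 1 x 2500."""
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((6, 1, 2500)) * 20
        es = EpochSet(
            signals=sig, fs=250.0, labels=np.zeros(6, int),
            channel_names=["c0"], epoch_ids=[f"e{i}" for i in range(6)],
        )
        path = tmp_path / "a.edf"
        write_epochs_edf(es, path)
        back = read_edf(path, 10.0, 0)
        assert back.signals.shape == (6, 1, 2500)

    def test_trailing_partial_epoch_dropped(self, tmp_path):
        """65 s of signal with 10 s epochs: the 5 s remainder is dropped."""
        rng = np.random.default_rng(1)
        sig = rng.standard_normal((13, 1, 1250)) * 20  # 65 s at 250 Hz in 5 s blocks
        es = EpochSet(
            signals=sig, fs=250.0, labels=np.zeros(13, int),
            channel_names=["c0"], epoch_ids=[f"e{i}" for i in range(13)],
        )
        path = tmp_path / "b.edf"
        write_epochs_edf(es, path)
        back = read_edf(path, 10.0, 1)
        assert back.signals.shape[0] == 6
        assert (back.labels == 1).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_edf_round_trip_within_quantization(self, tmp_path, seed):
        """Write->read recovers signals within one 16-bit quantization step."""
        rng = np.random.default_rng(seed)
        n_e, n_c, n_t = rng.integers(2, 5), rng.integers(1, 4), 500
        sig = rng.standard_normal((n_e, n_c, n_t)) * rng.uniform(5, 200)
        es = EpochSet(
            signals=sig, fs=250.0, labels=rng.integers(0, 2, n_e),
            channel_names=[f"c{i}" for i in range(n_c)],
            epoch_ids=[f"e{i}" for i in range(n_e)],
        )
        path = tmp_path / f"r{seed}.edf"
        write_epochs_edf(es, path)
        back = read_edf(path, n_t / 250.0, 0)
        step = (sig.max() - sig.min()) / 65535
        assert np.abs(back.signals - sig).max() <= 1.5 * step

    def test_edf_matches_independent_reader(self, tmp_path):
        """Our EDF writer produces files that mne's reader decodes identically."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(3)
        sig = rng.standard_normal((4, 2, 500)) * 50
        es = EpochSet(
            signals=sig, fs=250.0, labels=np.zeros(4, int),
            channel_names=["EEG A", "EEG B"],
            epoch_ids=[f"e{i}" for i in range(4)],
        )
        path = tmp_path / "m.edf"
        write_epochs_edf(es, path)
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        theirs = raw.get_data() * 1e6  # volts -> microvolts
        ours = sig.transpose(1, 0, 2).reshape(2, -1)
        assert np.abs(theirs - ours).max() < 0.05

    def test_truncated_edf_names_byte_offset(self, tmp_path):
        rng = np.random.default_rng(4)
        sig = rng.standard_normal((2, 1, 500)) * 20
        es = EpochSet(
            signals=sig, fs=250.0, labels=np.zeros(2, int),
            channel_names=["c0"], epoch_ids=["a", "b"],
        )
        path = tmp_path / "t.edf"
        write_epochs_edf(es, path)
        blob = path.read_bytes()
        path.write_bytes(blob[: len(blob) // 2])
        with pytest.raises(EDFFormatError, match="byte"):
            read_edf(path, 1.0, 0)


class TestSynthesis:
    def test_seeded_determinism(self):
        spec = SynthSpec(n_epochs_per_class=5, n_channels=3, epoch_seconds=2.0, seed=1)
        a, b = generate_synthetic(spec), generate_synthetic(spec)
        assert np.array_equal(a.signals, b.signals)
        assert a.epoch_ids == b.epoch_ids

    def test_null_effect_classes_indistinguishable(self):
        """Burst multiplier 1 and band ratio 1 yields two identical
        distributions: the band-power t-test must not reject."""
        spec = SynthSpec(
            n_epochs_per_class=100, n_channels=2, epoch_seconds=5.0,
            burst_amplitude=1.0, low_band_ratio=1.0, seed=4,
        )
        d = generate_synthetic(spec)
        bp = _band_power(d)
        p = ttest_ind(bp[d.labels == 1], bp[d.labels == 0]).pvalue
        assert p > 0.01

    def test_band_power_ratio_matches_configuration(self):
        spec = SynthSpec(n_epochs_per_class=100, n_channels=2, seed=3)
        d = generate_synthetic(spec)
        bp = _band_power(d)
        ratio = bp[d.labels == 1].mean() / bp[d.labels == 0].mean()
        assert abs(ratio - spec.low_band_ratio) / spec.low_band_ratio < 0.15

    def test_effect_size_monotone_in_band_ratio(self):
        """Raising the band-power ratio strictly raises Cohen's d of the
        class band-power separation (averaged over seeded replicates)."""
        def cohens_d(ratio):
            ds = []
            for seed in range(5):
                spec = SynthSpec(
                    n_epochs_per_class=40, n_channels=2, epoch_seconds=4.0,
                    low_band_ratio=ratio, burst_amplitude=1.0, seed=seed,
                )
                d = generate_synthetic(spec)
                bp = _band_power(d)
                a, b = bp[d.labels == 1], bp[d.labels == 0]
                pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
                ds.append((a.mean() - b.mean()) / pooled)
            return np.mean(ds)

        values = [cohens_d(r) for r in (1.0, 1.5, 2.0, 3.0)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SynthSpec(n_epochs_per_class=0)
        with pytest.raises(ValueError):
            SynthSpec(low_band_ratio=-1.0)


class TestSplitting:
    def test_ninety_ten_split(self, small_epochs):
        plan = split_train_test(small_epochs, 0.9, seed=0)
        assert len(plan.train_indices) == 180
        assert len(plan.test_indices) == 20
        assert not set(plan.train_indices) & set(plan.test_indices)

    def test_split_preserves_class_ratio(self, small_epochs):
        plan = split_train_test(small_epochs, 0.5, seed=2)
        y = small_epochs.labels
        train_ratio = y[plan.train_indices].mean()
        assert abs(train_ratio - 0.5) <= 0.01

    def test_split_deterministic(self, small_epochs):
        a = split_train_test(small_epochs, 0.8, seed=5)
        b = split_train_test(small_epochs, 0.8, seed=5)
        assert a.train_indices == b.train_indices

    def test_folds_partition_training_set(self, small_epochs):
        plan = split_train_test(small_epochs, 0.9, seed=0)
        plan = make_folds(plan, small_epochs.labels, 10, seed=0)
        assert len(plan.folds) == 10
        seen = [v for _, va in plan.folds for v in va]
        assert sorted(seen) == sorted(plan.train_indices)
        for tr, va in plan.folds:
            assert sorted(tr + va) == sorted(plan.train_indices)

    @pytest.mark.parametrize("case", range(10))
    def test_fold_stratification_and_partition_random_cases(self, case):
        """Random sizes/k: folds partition and class ratios stay within
        one sample of the global ratio."""
        rng = np.random.default_rng(case)
        n0, n1 = rng.integers(20, 60), rng.integers(20, 60)
        labels = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        plan = SplitPlan(
            train_indices=list(range(n0 + n1)), test_indices=[], seed=case
        )
        k = int(rng.integers(2, 8))
        plan = make_folds(plan, labels, k, seed=case)
        seen = sorted(v for _, va in plan.folds for v in va)
        assert seen == list(range(n0 + n1))
        for _, va in plan.folds:
            ones = labels[va].sum()
            expect = len(va) * n1 / (n0 + n1)
            assert abs(ones - expect) <= 1.0

    def test_fold_validation_size(self, small_epochs):
        plan = split_train_test(small_epochs, 0.9, seed=0)
        plan = make_folds(plan, small_epochs.labels, 10, seed=1)
        sizes = [len(va) for _, va in plan.folds]
        assert all(s == 18 for s in sizes)

    def test_config_errors(self, small_epochs):
        with pytest.raises(ValueError):
            split_train_test(small_epochs, 1.5, seed=0)
        plan = split_train_test(small_epochs, 0.9, seed=0)
        with pytest.raises(ValueError):
            make_folds(plan, small_epochs.labels, 1, seed=0)
        with pytest.raises(ValueError):
            make_folds(plan, small_epochs.labels, 10_000, seed=0)

    def test_split_plan_json_round_trip(self, small_epochs):
        plan = split_train_test(small_epochs, 0.9, seed=0)
        plan = make_folds(plan, small_epochs.labels, 5, seed=0)
        back = SplitPlan.from_json(plan.to_json())
        assert back.train_indices == plan.train_indices
        assert back.folds == [
            (list(tr), list(va)) for tr, va in plan.folds
        ]
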