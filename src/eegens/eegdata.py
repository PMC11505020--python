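"""EEG data model, EDF ingestion, epoching, splitting, and synthesis.

The central container is :class:`EpochSet`: labeled fixed-length windows
("epochs") of multichannel EEG, the unit of classification throughout the
package.  Labels are binary — 0 for normal background activity, 1 for
abnormal (epileptiform) activity — and are inherited per recording.

Because clinical corpora are license-gated, the module also ships a
synthetic two-class generator.  Normal epochs are 1/f ("pink") background
plus a posterior-dominant alpha rhythm; abnormal epochs additionally carry
periodic spike-wave bursts and elevated 2-8 Hz (delta/theta) band power.
Both effect sizes are controllable, and setting the burst multiplier and
the band-power ratio to 1 yields two statistically identical classes — a
built-in null for sanity checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._edf import EDFRecording, EDFFormatError, read_edf_recording, write_edf

__all__ = [
    "EpochSet",
    "SplitPlan",
    "SynthSpec",
    "read_edf",
    "write_epochs_edf",
    "generate_synthetic",
    "split_train_test",
    "make_folds",
    "EDFFormatError",
]


@dataclass
class EpochSet:
    """Labeled multichannel EEG epochs.

    Parameters
    ----------
    signals
        Array of shape ``(n_epochs, n_channels, n_timepoints)`` in microvolts.
    fs
        Sampling rate in Hz.
    labels
        Binary vector, one entry per epoch (0 = normal, 1 = abnormal).
    channel_names
        Channel labels, e.g. ``["EEG FP1", ...]``.
    epoch_ids
        Stable string identifiers, one per epoch.
    """

    signals: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: list[str]
    epoch_ids: list[str]

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signals.ndim != 3:
            raise ValueError("signals must have shape (epochs, channels, time)")
        n = self.signals.shape[0]
        if len(self.labels) != n or len(self.epoch_ids) != n:
            raise ValueError("labels/epoch_ids must align with epochs")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signals.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must align with channels")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary, found {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    def subset(self, indices) -> "EpochSet":
        idx = np.asarray(indices, dtype=int)
        return EpochSet(
            signals=self.signals[idx],
            fs=self.fs,
            labels=self.labels[idx],
            channel_names=list(self.channel_names),
            epoch_ids=[self.epoch_ids[i] for i in idx],
        )


@dataclass
class SplitPlan:
    """Train/test split, optionally with stratified CV folds over the train set."""

    train_indices: list[int]
    test_indices: list[int]
    seed: int
    folds: list[tuple[list[int], list[int]]] | None = None

    def __post_init__(self):
        if set(self.train_indices) & set(self.test_indices):
            raise ValueError("train and test indices overlap")

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_indices": list(map(int, self.train_indices)),
                "test_indices": list(map(int, self.test_indices)),
                "seed": int(self.seed),
                "folds": None
                if self.folds is None
                else [
                    [list(map(int, tr)), list(map(int, va))]
                    for tr, va in self.folds
                ],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        obj = json.loads(text)
        folds = obj.get("folds")
        return cls(
            train_indices=obj["train_indices"],
            test_indices=obj["test_indices"],
            seed=obj["seed"],
            folds=None if folds is None else [(tr, va) for tr, va in folds],
        )


@dataclass
class SynthSpec:
    """Configuration of the synthetic two-class EEG generator.

    ``burst_amplitude`` is a multiplier on the background RMS: bursts have
    peak amplitude ``(burst_amplitude - 1) * background RMS``, so a value
    of 1 disables them.  ``low_band_ratio`` is the target ratio of 2-8 Hz
    band power (abnormal / normal); 1 disables the band-power effect.
    """

    n_epochs_per_class: int = 100
    n_channels: int = 24
    fs: float = 250.0
    epoch_seconds: float = 10.0
    pink_exponent: float = 1.0
    alpha_amplitude: float = 10.0
    burst_rate_hz: float = 3.0
    burst_amplitude: float = 3.0
    low_band_ratio: float = 2.0
    noise_sd: float = 2.0
    seed: int = 0

    # amplitude scale of the pink background, in microvolts RMS
    pink_rms: float = 15.0
    # band elevated in the abnormal class, Hz
    low_band: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self):
        for name in (
            "fs",
            "epoch_seconds",
            "alpha_amplitude",
            "burst_rate_hz",
            "burst_amplitude",
            "low_band_ratio",
            "noise_sd",
            "pink_rms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_epochs_per_class <= 0:
            raise ValueError("n_epochs_per_class must be positive")
        if self.n_channels <= 0:
            raise ValueError("n_channels must be positive")


def read_edf(path, epoch_seconds: float, label: int) -> EpochSet:
    """Read an EDF file and cut it into contiguous non-overlapping epochs.

    The trailing partial epoch is dropped.  All epochs inherit the
    per-recording ``label``.
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rec = read_edf_recording(path)
    n_ch, n_samp = rec.signals.shape
    if n_ch == 0:
        raise EDFFormatError("EDF file contains no channels")
    samples_per_epoch = int(round(epoch_seconds * rec.fs))
    n_epochs = n_samp // samples_per_epoch
    if n_epochs == 0:
        raise ValueError(
            f"recording shorter ({n_samp / rec.fs:.1f} s) than one epoch"
        )
    used = n_epochs * samples_per_epoch
    sig = rec.signals[:, :used].reshape(n_ch, n_epochs, samples_per_epoch)
    sig = sig.transpose(1, 0, 2)
    stem = str(path)
    return EpochSet(
        signals=sig,
        fs=rec.fs,
        labels=np.full(n_epochs, label, dtype=int),
        channel_names=list(rec.channel_names),
        epoch_ids=[f"{stem}#e{i:05d}" for i in range(n_epochs)],
    )


def write_epochs_edf(data: EpochSet, path) -> None:
    """Write an EpochSet back to EDF as one continuous recording.

    Epochs are concatenated in order; re-reading with the same epoch
    length recovers the signals up to 16-bit quantization.
    """
    n_epochs, n_ch, n_t = data.signals.shape
    continuous = data.signals.transpose(1, 0, 2).reshape(n_ch, n_epochs * n_t)
    write_edf(
        path,
        EDFRecording(
            signals=continuous,
            fs=data.fs,
            channel_names=list(data.channel_names),
        ),
    )


def _pink_noise(rng, n_t, fs, exponent, rms, n_sig):
    """1/f^exponent noise, returned with the requested RMS, plus the
    band-limited 2-8 Hz component handle used for effect calibration."""
    freqs = np.fft.rfftfreq(n_t, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nonzero = freqs > 0
    amp[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=(n_sig, freqs.size))
    spectrum = amp[None, :] * np.exp(1j * phases)
    spectrum[:, 0] = 0.0
    x = np.fft.irfft(spectrum, n=n_t, axis=-1)
    current_rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    x = x * (rms / np.maximum(current_rms, 1e-30))
    return x, freqs


def _band_component(x, freqs, band):
    """Split signals into within-band and out-of-band parts via the DFT."""
    spec = np.fft.rfft(x, axis=-1)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    inband = np.fft.irfft(np.where(mask[None, :], spec, 0), n=x.shape[-1], axis=-1)
    return inband, x - inband


def _band_power(x, freqs, band, fs):
    """Mean power of the in-band DFT component (Parseval)."""
    spec = np.fft.rfft(x, axis=-1)
    n = x.shape[-1]
    mask = (freqs >= band[0]) & (freqs <= band[1])
    # rfft Parseval with the one-sided doubling (DC/Nyquist excluded by band)
    return 2.0 * np.sum(np.abs(spec[..., mask]) ** 2, axis=-1) / n**2


def _spike_wave_kernel(fs, rate_hz):
    """One second of spike-and-wave discharge at ``rate_hz``, unit peak."""
    n = int(round(fs))
    t = np.arange(n) / fs
    period = 1.0 / max(rate_hz, 1e-6)
    phase = (t % period) / period
    # sharp triangular spike in the first 20% of each cycle,
    # slower negative half-wave over the following 50%
    spike = np.where(phase < 0.1, phase / 0.1, np.where(phase < 0.2, (0.2 - phase) / 0.1, 0.0))
    wave = np.where(
        (phase >= 0.2) & (phase < 0.7),
        -0.5 * np.sin(np.pi * (phase - 0.2) / 0.5),
        0.0,
    )
    kernel = spike + wave
    # taper the burst edges
    kernel *= np.hanning(n) ** 0.5
    return kernel


def generate_synthetic(spec: SynthSpec) -> EpochSet:
    """Generate a balanced two-class synthetic EEG EpochSet.

    Class 0: pink background + alpha rhythm + sensor noise.
    Class 1: the same background, its 2-8 Hz component scaled so the
    epoch's total in-band power (including the burst contribution) is
    ``low_band_ratio`` times the class-0 expectation, plus spike-wave
    bursts of peak amplitude ``(burst_amplitude - 1) * pink_rms``.

    Deterministic: the same spec (including seed) yields byte-identical
    arrays.
    """
    rng = np.random.default_rng(spec.seed)
    n_t = int(round(spec.epoch_seconds * spec.fs))
    n_per = spec.n_epochs_per_class
    n_ch = spec.n_channels
    n_sig = n_per * n_ch

    signals = []
    for cls in (0, 1):
        pink, freqs = _pink_noise(
            rng, n_t, spec.fs, spec.pink_exponent, spec.pink_rms, n_sig
        )
        phases = rng.uniform(0, 2 * np.pi, size=(n_sig, 1))
        t = np.arange(n_t) / spec.fs
        alpha = spec.alpha_amplitude * np.sin(
            2 * np.pi * 10.0 * t[None, :] + phases
        )
        white = rng.normal(0, spec.noise_sd, size=(n_sig, n_t))
        x = pink + alpha + white

        if cls == 1:
            burst_amp = max(spec.burst_amplitude - 1.0, 0.0) * spec.pink_rms
            bursts = np.zeros((n_per, n_t))
            if burst_amp > 0:
                kernel = _spike_wave_kernel(spec.fs, spec.burst_rate_hz)
                kn = kernel.size
                n_bursts = max(1, int(spec.epoch_seconds // 5))
                for e in range(n_per):
                    for _ in range(n_bursts):
                        start = rng.integers(0, max(n_t - kn, 1))
                        bursts[e, start : start + kn] += kernel[: n_t - start]
                bursts *= burst_amp
            # per-channel gain so the discharge is broadly but unevenly visible
            gains = rng.uniform(0.6, 1.0, size=(n_per, n_ch))
            burst_sig = bursts[:, None, :] * gains[:, :, None]
            burst_sig = burst_sig.reshape(n_sig, n_t)

            inband, outband = _band_component(pink, freqs, spec.low_band)
            p_in = np.mean(_band_power(pink, freqs, spec.low_band, spec.fs))
            p_burst = np.mean(
                _band_power(burst_sig, freqs, spec.low_band, spec.fs)
            )
            # scale the background's in-band part so that the epoch total
            # (background + burst) hits ratio * baseline in expectation
            target = spec.low_band_ratio * p_in
            residual = max(target - p_burst, 0.0)
            gain = np.sqrt(residual / max(p_in, 1e-30))
            x = outband + gain * inband + alpha + white + burst_sig
        signals.append(x.reshape(n_per, n_ch, n_t))

    sig = np.concatenate(signals, axis=0)
    labels = np.r_[np.zeros(n_per, dtype=int), np.ones(n_per, dtype=int)]
    ids = [f"synth-c{l}-{i:05d}" for i, l in enumerate(labels)]
    names = [f"EEG{c:02d}" for c in range(n_ch)]
    return EpochSet(
        signals=sig, fs=spec.fs, labels=labels, channel_names=names, epoch_ids=ids
    )


def split_train_test(
    data: EpochSet, train_fraction: float, seed: int
) -> SplitPlan:
    """Randomly sort and split into stratified train/test index sets."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(data.labels == cls)
        if idx.size and idx.size < 2:
            raise ValueError(
                f"class {cls} has fewer than 2 members; cannot stratify"
            )
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1) if idx.size else 0
        train.extend(idx[:n_train].tolist())
        test.extend(idx[n_train:].tolist())
    return SplitPlan(
        train_indices=sorted(train), test_indices=sorted(test), seed=seed
    )


def make_folds(
    plan: SplitPlan, labels, k: int, seed: int
) -> SplitPlan:
    """Attach k stratified CV folds partitioning the plan's training set.

    Each training index lands in exactly one validation fold; fold class
    ratios track the training-set ratio within one sample.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    train = np.asarray(plan.train_indices, dtype=int)
    if k > train.size:
        raise ValueError(f"k={k} exceeds training-set size {train.size}")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    fold_members: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in (0, 1):
        idx = rng.permutation(train[labels[train] == cls])
        # deal class members round-robin, rotating the starting fold so
        # remainders spread across folds rather than piling on fold 0
        for j, sample in enumerate(idx):
            fold_members[(offset + j) % k].append(int(sample))
        offset += idx.size % k
    folds = []
    for f in range(k):
        validate = sorted(fold_members[f])
        tr = sorted(set(train.tolist()) - set(validate))
        folds.append((tr, validate))
    return SplitPlan(
        train_indices=plan.train_indices,
        test_indices=plan.test_indices,
        seed=seed,
        folds=folds,
    )
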