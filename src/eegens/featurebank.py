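"""Per-channel EEG feature extraction.

Turns an :class:`~eegens.eegdata.EpochSet` into a named
:class:`FeatureTable` (samples x features).  The battery covers the
standard quantitative-EEG repertoire: moments, energy, line length,
zero crossings, Hjorth mobility/complexity, Welch band powers and
spectral entropy, discrete-wavelet sub-band energies, the FFT dominant
frequency, and the nonlinear trio (Higuchi fractal dimension, R/S Hurst
exponent, first-order DFA), plus one inter-channel mean-correlation
feature per channel.

Everything is vectorized over the (epoch, channel) axis; the nonlinear
estimators loop only over window/scale sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats

from .eegdata import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "BandScheme",
    "FeatureTable",
    "extract_features",
    "hjorth",
    "impute_failures",
]

DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class BandScheme:
    """Named, non-overlapping frequency intervals in Hz."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self):
        items = sorted(self.bands.items(), key=lambda kv: kv[1][0])
        prev_hi = 0.0
        for name, (lo, hi) in items:
            if lo >= hi or lo < 0:
                raise ValueError(f"band {name!r} has an invalid interval")
            if lo < prev_hi - 1e-12:
                raise ValueError(f"band {name!r} overlaps its neighbour")
            prev_hi = hi

    def validate_against(self, fs: float) -> None:
        nyq = fs / 2.0
        for name, (lo, hi) in self.bands.items():
            if hi > nyq + 1e-9:
                raise ValueError(
                    f"band {name!r} upper edge {hi} Hz exceeds Nyquist {nyq} Hz"
                )


@dataclass
class FeatureTable:
    """Samples x named features with binary labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must align with columns")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels must align with rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names) -> "FeatureTable":
        index = {n: i for i, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        cols = [index[n] for n in names]
        return FeatureTable(
            values=self.values[:, cols],
            feature_names=list(names),
            labels=self.labels,
            provenance={n: self.provenance.get(n, "") for n in names},
        )

    def subset_rows(self, indices) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            labels=self.labels[idx],
            provenance=dict(self.provenance),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("feature CSV must contain a 'label' column")
        labels = df.pop("label").to_numpy(dtype=int)
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=list(df.columns),
            labels=labels,
        )


# ---------------------------------------------------------------------------
# elementary features


def hjorth(x) -> tuple[float, float]:
    """Hjorth mobility and complexity of a 1-D signal.

    mobility = sqrt(var(dx)/var(x)); complexity = mobility(dx)/mobility(x),
    with first differences as the derivative.  A constant signal returns
    (0, 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("hjorth needs at least 3 samples")
    m, c = _hjorth_nd(x[None, :])
    return float(m[0]), float(c[0])


def _hjorth_nd(x):
    v0 = x.var(axis=-1)
    d1 = np.diff(x, axis=-1)
    v1 = d1.var(axis=-1)
    d2 = np.diff(d1, axis=-1)
    v2 = d2.var(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(np.where(v0 > 0, v1 / np.where(v0 > 0, v0, 1), 0.0))
        mob_d = np.sqrt(np.where(v1 > 0, v2 / np.where(v1 > 0, v1, 1), 0.0))
        comp = np.where(mob > 0, mob_d / np.where(mob > 0, mob, 1), 0.0)
    mob = np.where(v0 > 0, mob, 0.0)
    comp = np.where(v0 > 0, comp, 0.0)
    return mob, comp


def _zero_crossings(x):
    """Sign changes; a zero sample followed by a nonzero one counts."""
    a, b = x[..., :-1], x[..., 1:]
    crossing = (a * b < 0) | ((a == 0) & (b != 0))
    return crossing.sum(axis=-1).astype(float)


def _higuchi_fd(x, k_max=10):
    """Higuchi fractal dimension, vectorized over leading axes."""
    n = x.shape[-1]
    ks = np.arange(1, k_max + 1)
    lk = np.empty(x.shape[:-1] + (k_max,))
    for ki, k in enumerate(ks):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            d = np.abs(np.diff(x[..., idx], axis=-1)).sum(axis=-1)
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(d * norm / k)
        lk[..., ki] = np.mean(lengths, axis=0)
    logk = np.log(1.0 / ks)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglk = np.log(lk)
    flat = ~np.isfinite(loglk).all(axis=-1)
    loglk = np.where(np.isfinite(loglk), loglk, 0.0)
    # least-squares slope of log L(k) against log 1/k
    xk = logk - logk.mean()
    slope = (loglk * xk).sum(axis=-1) / (xk**2).sum()
    return np.where(flat, 0.0, slope)


def _hurst_rs(x, min_window=8):
    """Rescaled-range Hurst exponent, vectorized over leading axes."""
    n = x.shape[-1]
    sizes = np.unique(
        np.floor(np.logspace(np.log10(min_window), np.log10(n // 2), 8)).astype(int)
    )
    sizes = sizes[sizes >= min_window]
    rs_log = []
    for s in sizes:
        m = n // s
        seg = x[..., : m * s].reshape(x.shape[:-1] + (m, s))
        seg = seg - seg.mean(axis=-1, keepdims=True)
        z = np.cumsum(seg, axis=-1)
        r = z.max(axis=-1) - z.min(axis=-1)
        sd = seg.std(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rs = np.where(sd > 0, r / np.where(sd > 0, sd, 1), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rs_log.append(np.nanmean(rs, axis=-1))
    rs_log = np.stack(rs_log, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(rs_log)
    bad = ~np.isfinite(y).all(axis=-1)
    y = np.where(np.isfinite(y), y, 0.0)
    lx = np.log(sizes.astype(float))
    lx = lx - lx.mean()
    slope = ((y - y.mean(axis=-1, keepdims=True)) * lx).sum(axis=-1) / (lx**2).sum()
    return np.where(bad, 0.0, slope)


def _dfa(x, order=1):
    """First-order detrended fluctuation analysis scaling exponent."""
    n = x.shape[-1]
    profile = np.cumsum(x - x.mean(axis=-1, keepdims=True), axis=-1)
    sizes = np.unique(
        np.floor(np.logspace(np.log10(4), np.log10(max(n // 4, 5)), 8)).astype(int)
    )
    sizes = sizes[sizes >= 4]
    flucts = []
    for s in sizes:
        m = n // s
        seg = profile[..., : m * s].reshape(profile.shape[:-1] + (m, s))
        t = np.arange(s, dtype=float)
        design = np.vander(t, order + 1)  # [t, 1] for order 1
        pinv = np.linalg.pinv(design)
        coef = seg @ pinv.T
        resid = seg - coef @ design.T
        f2 = (resid**2).mean(axis=-1)
        flucts.append(np.sqrt(f2.mean(axis=-1)))
    flucts = np.stack(flucts, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(flucts)
    bad = ~np.isfinite(y).all(axis=-1)
    y = np.where(np.isfinite(y), y, 0.0)
    lx = np.log(sizes.astype(float))
    lx = lx - lx.mean()
    slope = ((y - y.mean(axis=-1, keepdims=True)) * lx).sum(axis=-1) / (lx**2).sum()
    return np.where(bad, 0.0, slope)


def _spectral_entropy(psd):
    """Shannon entropy (nats) of the normalized power spectrum."""
    total = psd.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, psd / np.where(total > 0, total, 1), 0.0)
        logp = np.where(p > 0, np.log(p), 0.0)
    ent = -(p * logp).sum(axis=-1)
    return np.where(total[..., 0] > 0, ent, 0.0)


# ---------------------------------------------------------------------------
# the battery


def extract_features(
    data: EpochSet,
    bands: BandScheme | None = None,
    selection="all",
    k_max: int = 10,
    wavelet: str = "db4",
    dwt_level: int = 4,
) -> FeatureTable:
    """Compute the full per-channel feature battery for every epoch.

    Feature names are channel-qualified, e.g. ``"ch03.line_length"``.
    ``selection`` may be ``"all"`` or an iterable of feature names to
    keep (order preserved).
    """
    if data.n_epochs == 0:
        raise ValueError("EpochSet is empty")
    bands = bands or BandScheme()
    bands.validate_against(data.fs)

    n_e, n_c, n_t = data.signals.shape
    x = data.signals.reshape(n_e * n_c, n_t)

    cols: dict[str, np.ndarray] = {}
    cols["mean"] = x.mean(axis=-1)
    cols["variance"] = x.var(axis=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cols["skewness"] = stats.skew(x, axis=-1)
        cols["kurtosis"] = stats.kurtosis(x, axis=-1)
    cols["energy"] = (x**2).sum(axis=-1)
    cols["peak_amplitude"] = np.abs(x).max(axis=-1)
    cols["abs_sum"] = np.abs(x).sum(axis=-1)
    cols["zero_crossings"] = _zero_crossings(x)
    cols["line_length"] = np.abs(np.diff(x, axis=-1)).sum(axis=-1)
    mob, comp = _hjorth_nd(x)
    cols["mobility"] = mob
    cols["complexity"] = comp

    nperseg = min(n_t, int(2 * data.fs)) or n_t
    freqs, psd = sps.welch(x, fs=data.fs, nperseg=nperseg, axis=-1)
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    cols["spectral_entropy"] = _spectral_entropy(psd)
    for name, (lo, hi) in bands.bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        cols[f"bandpower_{name}"] = psd[:, mask].sum(axis=-1) * df
    cols["avg_spectral_power"] = psd.sum(axis=-1) * df

    coeffs = pywt.wavedec(x, wavelet, level=dwt_level, axis=-1)
    # coeffs = [cA_L, cD_L, ..., cD_1]
    cols[f"dwt_a{dwt_level}_energy"] = (coeffs[0] ** 2).sum(axis=-1)
    for lev, cd in zip(range(dwt_level, 0, -1), coeffs[1:]):
        cols[f"dwt_d{lev}_energy"] = (cd**2).sum(axis=-1)

    spec = np.abs(np.fft.rfft(x - x.mean(axis=-1, keepdims=True), axis=-1))
    cols["fft_dominant_magnitude"] = spec.max(axis=-1)

    cols["higuchi_fd"] = _higuchi_fd(x, k_max=k_max)
    cols["hurst"] = _hurst_rs(x)
    cols["dfa"] = _dfa(x)

    # (near-)constant signals: force every variance-normalized shape
    # feature to 0 rather than letting floating-point residue through
    degenerate = cols["variance"] <= 1e-15 * ((x**2).mean(axis=-1) + 1e-30)
    if degenerate.any():
        for name in (
            "variance", "skewness", "kurtosis", "zero_crossings",
            "line_length", "mobility", "complexity", "spectral_entropy",
            "higuchi_fd", "hurst", "dfa", "fft_dominant_magnitude",
        ):
            if name in cols:
                cols[name] = np.where(degenerate, 0.0, cols[name])

    # inter-channel mean absolute Pearson correlation, one value per channel
    corr = np.zeros((n_e, n_c))
    if n_c > 1:
        for e in range(n_e):
            sd = data.signals[e].std(axis=-1)
            ok = sd > 0
            if ok.sum() > 1:
                c = np.corrcoef(data.signals[e][ok])
                np.fill_diagonal(c, np.nan)
                vals = np.nanmean(np.abs(c), axis=-1)
                corr[e, ok] = vals
    cols["corr_mean"] = corr.reshape(n_e * n_c)

    feature_names = []
    matrix = []
    provenance = {}
    for base, values in cols.items():
        arr = values.reshape(n_e, n_c)
        for c in range(n_c):
            name = f"ch{c:02d}.{base}"
            feature_names.append(name)
            matrix.append(arr[:, c])
            provenance[name] = f"featurebank.{base}"
    table = FeatureTable(
        values=np.column_stack(matrix),
        feature_names=feature_names,
        labels=data.labels,
        provenance=provenance,
    )
    table = impute_failures(table)
    if selection != "all":
        table = table.select(list(selection))
    return table


def impute_failures(table: FeatureTable) -> FeatureTable:
    """Replace non-finite entries by the column median of finite entries.

    A column with no finite entries is dropped with a logged warning.
    """
    values = table.values.copy()
    keep = []
    for j, name in enumerate(table.feature_names):
        col = values[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            logger.warning("dropping all-non-finite feature column %s", name)
            continue
        if not finite.all():
            col[~finite] = np.median(col[finite])
            values[:, j] = col
        keep.append(j)
    if len(keep) == table.n_features:
        return FeatureTable(
            values=values,
            feature_names=list(table.feature_names),
            labels=table.labels,
            provenance=dict(table.provenance),
        )
    names = [table.feature_names[j] for j in keep]
    return FeatureTable(
        values=values[:, keep],
        feature_names=names,
        labels=table.labels,
        provenance={n: table.provenance.get(n, "") for n in names},
    )
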