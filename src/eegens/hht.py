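"""Hilbert-Huang analysis: analytic signal, EMD, and HHT features.

The Hilbert transform is realized by the FFT method: zero the
negative-frequency bins, double the positive ones, keep DC and Nyquist,
and invert.  Empirical mode decomposition uses classic sifting with
cubic-spline envelopes through the local extrema (mirrored at the
boundaries); sifting stops on the Cauchy standard-deviation criterion,
additionally requiring the IMF property (extrema and zero-crossing
counts within one of each other).

``hht_features`` turns an EpochSet into a fixed-width feature table:
per-IMF energy fractions, instantaneous-frequency statistics and mean
envelope amplitude, plus marginal Hilbert-spectrum band energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .eegdata import EpochSet
from .featurebank import BandScheme, FeatureTable

__all__ = [
    "IMFSet",
    "HilbertSpectrum",
    "analytic_signal",
    "instantaneous_frequency",
    "emd",
    "hilbert_spectrum",
    "hht_features",
]


@dataclass
class IMFSet:
    """Intrinsic mode functions plus the monotone-ish residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    sift_counts: list[int]

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out = out + imf
        return out


@dataclass
class HilbertSpectrum:
    """Time-frequency energy distribution of a set of IMFs."""

    time: np.ndarray
    freqs: np.ndarray
    energy: np.ndarray  # (n_freq, n_time)
    marginal: np.ndarray  # row sums


def analytic_signal(x) -> np.ndarray:
    """Analytic signal x + i*HT(x) via the FFT method."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n == 0:
        raise ValueError("empty input")
    if n < 4:
        raise ValueError("analytic_signal needs at least 4 samples")
    spec = np.fft.fft(x, axis=-1)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.fft.ifft(spec * h, axis=-1)


def instantaneous_frequency(z, fs: float) -> np.ndarray:
    """Instantaneous frequency (Hz) from the analytic phase difference.

    Returns one value per sample gap (length n-1).
    """
    phase = np.unwrap(np.angle(z), axis=-1)
    return np.diff(phase, axis=-1) * fs / (2 * np.pi)


def _extrema(x):
    d = np.diff(x)
    # collapse plateaus so flat tops count once
    nz = np.flatnonzero(d != 0)
    if nz.size < 2:
        return np.array([], int), np.array([], int)
    sign = np.sign(d[nz])
    change = np.flatnonzero(sign[:-1] != sign[1:])
    idx = nz[change] + 1
    maxima = idx[sign[change] > 0]
    minima = idx[sign[change] < 0]
    return maxima, minima


def _envelope(x, idx, kind):
    """Cubic-spline envelope through extrema, mirror-extended at the ends."""
    n = x.size
    pts_i = idx.astype(float)
    pts_v = x[idx]
    # mirror the two outermost extrema around each boundary
    left_i = -pts_i[1::-1][: min(2, idx.size)]
    left_v = pts_v[1::-1][: min(2, idx.size)]
    right_i = 2 * (n - 1) - pts_i[-1:-3:-1]
    right_v = pts_v[-1:-3:-1]
    xi = np.concatenate([left_i, pts_i, right_i])
    vi = np.concatenate([left_v, pts_v, right_v])
    order = np.argsort(xi)
    xi, vi = xi[order], vi[order]
    keep = np.concatenate([[True], np.diff(xi) > 0])
    xi, vi = xi[keep], vi[keep]
    if xi.size < 2:
        return np.full(n, vi[0])
    spline = CubicSpline(xi, vi, bc_type="natural")
    return spline(np.arange(n))


def _count_zero_crossings(x):
    a, b = x[:-1], x[1:]
    return int((((a * b) < 0) | ((a == 0) & (b != 0))).sum())


def emd(
    x,
    max_imfs: int = 8,
    sd_tol: float = 0.2,
    max_sifts: int = 50,
) -> IMFSet:
    """Empirical mode decomposition by sifting.

    Sifting of each mode stops once the Cauchy criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2) < sd_tol`` is met and the
    candidate satisfies the IMF count property, or after ``max_sifts``
    iterations.  Decomposition stops at ``max_imfs`` or when the residual
    has fewer than 2 maxima or minima.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if x.size < 16:
        raise ValueError("emd needs at least 16 samples")
    if sd_tol <= 0:
        raise ValueError("sd_tol must be positive")

    imfs: list[np.ndarray] = []
    counts: list[int] = []
    residual = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        n_sifts = 0
        for _ in range(max_sifts):
            maxima, minima = _extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            upper = _envelope(h, maxima, "max")
            lower = _envelope(h, minima, "min")
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            n_sifts += 1
            if sd < sd_tol:
                mx, mn = _extrema(h)
                n_ext = mx.size + mn.size
                n_zc = _count_zero_crossings(h)
                if abs(n_ext - n_zc) <= 1:
                    break
        imfs.append(h)
        counts.append(n_sifts)
        residual = residual - h
    return IMFSet(imfs=imfs, residual=residual, sift_counts=counts)


def hilbert_spectrum(
    imfs: IMFSet,
    fs: float,
    n_freq_bins: int = 64,
    f_min: float = 0.5,
) -> HilbertSpectrum:
    """Amplitude-squared Hilbert spectrum on a log-spaced frequency grid."""
    n = imfs.residual.size
    nyq = fs / 2.0
    edges = np.logspace(np.log10(f_min), np.log10(nyq), n_freq_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    energy = np.zeros((n_freq_bins, n - 1))
    for imf in imfs.imfs:
        z = analytic_signal(imf)
        amp2 = np.abs(z[:-1]) ** 2
        freq = instantaneous_frequency(z, fs)
        bins = np.clip(np.searchsorted(edges, freq) - 1, 0, n_freq_bins - 1)
        valid = (freq > 0) & (freq <= nyq)
        np.add.at(energy, (bins[valid], np.flatnonzero(valid)), amp2[valid])
    time = np.arange(n - 1) / fs
    return HilbertSpectrum(
        time=time, freqs=centers, energy=energy, marginal=energy.sum(axis=1)
    )


def imf_energy_fractions(imfs: IMFSet) -> np.ndarray:
    """Energy fractions of each IMF plus the residual (sums to 1)."""
    energies = [float(np.sum(imf**2)) for imf in imfs.imfs]
    energies.append(float(np.sum(imfs.residual**2)))
    total = sum(energies)
    if total <= 0:
        return np.zeros(len(energies))
    return np.asarray(energies) / total


def hht_features(
    data: EpochSet,
    max_imfs: int = 5,
    bands: BandScheme | None = None,
    sd_tol: float = 0.2,
) -> FeatureTable:
    """Per-channel HHT feature battery.

    For each of the first ``max_imfs`` IMFs: energy fraction, mean and SD
    of instantaneous frequency (interior samples), and mean instantaneous
    amplitude; missing IMFs are zero-filled so width is constant.  Adds
    the residual energy fraction and marginal Hilbert-spectrum band
    energies (fractions of total).
    """
    bands = bands or BandScheme()
    bands.validate_against(data.fs)
    band_names = list(bands.bands)
    n_e, n_c, n_t = data.signals.shape
    per_imf = 4
    width = max_imfs * per_imf + 1 + len(band_names)
    out = np.zeros((n_e, n_c, width))
    trim = max(1, (n_t - 1) // 20)  # drop 5% each end of IF estimates

    for e in range(n_e):
        for c in range(n_c):
            x = data.signals[e, c]
            if np.allclose(x, x[0]):
                continue
            dec = emd(x, max_imfs=max_imfs, sd_tol=sd_tol)
            fracs = imf_energy_fractions(dec)
            col = 0
            for i in range(max_imfs):
                if i < len(dec.imfs):
                    imf = dec.imfs[i]
                    z = analytic_signal(imf)
                    freq = instantaneous_frequency(z, data.fs)[trim:-trim]
                    amp = np.abs(z)
                    out[e, c, col : col + per_imf] = (
                        fracs[i],
                        float(freq.mean()),
                        float(freq.std()),
                        float(amp.mean()),
                    )
                col += per_imf
            out[e, c, col] = fracs[-1]
            col += 1
            spectrum = hilbert_spectrum(dec, data.fs)
            total = spectrum.marginal.sum()
            for b, name in enumerate(band_names):
                lo, hi = bands.bands[name]
                mask = (spectrum.freqs >= lo) & (spectrum.freqs < hi)
                val = spectrum.marginal[mask].sum()
                out[e, c, col + b] = val / total if total > 0 else 0.0

    names = []
    for i in range(max_imfs):
        names += [
            f"imf{i + 1}.energy_frac",
            f"imf{i + 1}.if_mean",
            f"imf{i + 1}.if_sd",
            f"imf{i + 1}.amp_mean",
        ]
    names.append("residual.energy_frac")
    names += [f"hspec_{b}" for b in band_names]

    feature_names = []
    matrix = out.reshape(n_e, n_c * width)
    full_names = []
    for c in range(n_c):
        for nm in names:
            full_names.append(f"ch{c:02d}.{nm}")
    return FeatureTable(
        values=matrix,
        feature_names=full_names,
        labels=data.labels,
        provenance={nm: "hht" for nm in full_names},
    )
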