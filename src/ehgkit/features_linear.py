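"""Temporal and spectral characterization of EHG analysis windows.

As labor approaches, EHG amplitude grows (more cells recruited per
contraction) and spectral content shifts toward higher frequencies
(increased excitability).  The descriptors here quantify both phenomena:
peak-to-peak amplitude per bandwidth, Teager energy, mean and dominant
frequency, power-spectrum deciles, normalized sub-band energies, the
high/low energy ratio and the spectral moment ratio.

The spectral estimator is a Welch periodogram (1024-sample Hamming
segments, 50 % overlap, one-sided) computed on the whole-bandwidth
(0.1-4 Hz) filtered window; band-restricted quantities then integrate the
estimate over half-open frequency intervals [f_lo, f_hi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .features_nonlinear import FeatureError

__all__ = [
    "SpectralEstimate",
    "peak_to_peak",
    "teager_energy",
    "estimate_psd",
    "mean_frequency",
    "dominant_frequency",
    "spectrum_deciles",
    "normalized_energies",
    "hl_ratio",
    "spectral_moment_ratio",
    "SPECTRAL_FEATURES",
    "spectral_features",
]

#: names of the 18 spectral-set features computed once per window (from the
#: whole-bandwidth signal), in table order
SPECTRAL_FEATURES = (
    "teager",
    "meanf",
    "df_0p2_1",
    "df_0p34_1",
    "normen_0p2_0p34",
    "normen_0p34_0p6",
    "normen_0p6_1",
    "hl_ratio",
    "d1",
    "d2",
    "d3",
    "d4",
    "d5",
    "d6",
    "d7",
    "d8",
    "d9",
    "spmr",
)


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided power spectral density on a regular frequency grid."""

    freqs: np.ndarray  # Hz, strictly increasing, 0 .. fs/2
    psd: np.ndarray    # mV^2/Hz, >= 0

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.freqs >= lo) & (self.freqs < hi)

    def band_power(self, lo: float, hi: float) -> float:
        """In-band power as the bin sum times the grid spacing."""
        df = float(self.freqs[1] - self.freqs[0])
        return float(self.psd[self.band_mask(lo, hi)].sum() * df)


def peak_to_peak(samples) -> float:
    """max - min of the window (App), in mV."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise FeatureError("empty window for peak-to-peak amplitude")
    return float(np.max(x) - np.min(x))


def teager_energy(samples) -> float:
    """Mean Teager-Kaiser operator psi[n] = x[n]^2 - x[n-1]*x[n+1].

    Sensitive to both amplitude and instantaneous frequency: for a sine of
    amplitude A and digital frequency w, psi = A^2 sin^2(w) everywhere.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 3:
        raise FeatureError(f"need >= 3 samples for Teager energy, got {x.size}")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return float(np.mean(psi))


def estimate_psd(
    samples,
    fs: float,
    nperseg: int = 1024,
    expected_length: int | None = 2400,
) -> SpectralEstimate:
    """Welch PSD, Hamming taper, 50 % segment overlap, one-sided.

    ``expected_length`` enforces the analysis-window contract (2400 samples
    at 20 Hz); pass None for free-length use (oracles, spectral entropy of
    short inputs).  Power is conserved (Parseval within ~1 % for broadband
    signals).
    """
    x = np.asarray(samples, dtype=np.float64)
    if expected_length is not None and x.size != expected_length:
        raise ValueError(
            f"expected a {expected_length}-sample analysis window, got {x.size}"
        )
    nper = min(nperseg, x.size)
    freqs, psd = sps.welch(
        x, fs=fs, window="hamming", nperseg=nper, noverlap=nper // 2,
        detrend=False, return_onesided=True, scaling="density",
    )
    return SpectralEstimate(freqs=freqs, psd=psd)


def _check_band(spec: SpectralEstimate, band: tuple[float, float]) -> np.ndarray:
    mask = spec.band_mask(*band)
    if not mask.any() or spec.psd[mask].sum() <= 0:
        raise FeatureError(f"zero in-band power in {band[0]}-{band[1]} Hz")
    return mask


def mean_frequency(spec: SpectralEstimate, band=(0.1, 1.0)) -> float:
    """Power-weighted mean frequency sum(f P(f)) / sum(P(f)) over the band."""
    mask = _check_band(spec, band)
    f, p = spec.freqs[mask], spec.psd[mask]
    return float(np.sum(f * p) / np.sum(p))


def dominant_frequency(spec: SpectralEstimate, band) -> float:
    """Frequency of the maximal in-band PSD bin; ties go to the lowest bin."""
    mask = _check_band(spec, band)
    f, p = spec.freqs[mask], spec.psd[mask]
    return float(f[int(np.argmax(p))])  # argmax returns first (lowest-f) max


def spectrum_deciles(spec: SpectralEstimate, band=(0.34, 1.0)) -> np.ndarray:
    """Frequencies d1..d9 splitting the in-band power into tenths.

    d_k is the lowest grid frequency where the cumulative in-band power
    reaches k/10 of the in-band total; d5 is the median frequency.
    """
    mask = _check_band(spec, band)
    f, p = spec.freqs[mask], spec.psd[mask]
    cum = np.cumsum(p) / np.sum(p)
    ks = np.arange(1, 10) / 10.0
    idx = np.searchsorted(cum, ks - 1e-12)
    return f[np.minimum(idx, f.size - 1)]


def normalized_energies(spec: SpectralEstimate) -> tuple[float, float, float]:
    """Sub-band power fractions (0.2-0.34, 0.34-0.6, 0.6-1 Hz) of the total
    0.1-4 Hz power; each in [0, 1]."""
    total = spec.band_power(0.1, 4.0)
    if total <= 0:
        raise FeatureError("zero total power in 0.1-4 Hz")
    return (
        spec.band_power(0.2, 0.34) / total,
        spec.band_power(0.34, 0.6) / total,
        spec.band_power(0.6, 1.0) / total,
    )


def hl_ratio(spec: SpectralEstimate) -> float:
    """High-to-low frequency energy ratio: power(0.34-1 Hz) / power(0.2-0.34 Hz).

    A pure high-band line makes the denominator vanish up to spectral
    leakage; a strictly zero denominator raises :class:`FeatureError`
    (documented degenerate case), otherwise the finite ratio is returned.
    """
    low = spec.band_power(0.2, 0.34)
    if low <= 0:
        raise FeatureError("zero power in 0.2-0.34 Hz (H/L denominator)")
    return spec.band_power(0.34, 1.0) / low


def spectral_moment_ratio(spec: SpectralEstimate, band=(0.1, 1.0)) -> float:
    """Dimitrov-style spectral moment index M(-1)/M(5), M_k = sum f^k P(f).

    Strictly decreasing under any shift of in-band energy toward higher
    frequencies, hence sensitive to the excitability-related spectral shift.
    """
    mask = _check_band(spec, band)
    f, p = spec.freqs[mask], spec.psd[mask]
    keep = f > 0
    f, p = f[keep], p[keep]
    m_minus1 = float(np.sum(p / f))
    m_5 = float(np.sum(p * f**5))
    if m_5 <= 0:
        raise FeatureError("zero fifth spectral moment")
    return m_minus1 / m_5


def spectral_features(whole_band_samples, fs: float) -> dict[str, float]:
    """The 18 spectral-set descriptors of one whole-bandwidth (0.1-4 Hz)
    filtered window, keyed by :data:`SPECTRAL_FEATURES` names."""
    x = np.asarray(whole_band_samples, dtype=np.float64)
    spec = estimate_psd(x, fs, expected_length=None)
    deciles = spectrum_deciles(spec)
    ne = normalized_energies(spec)
    out = {
        "teager": teager_energy(x),
        "meanf": mean_frequency(spec),
        "df_0p2_1": dominant_frequency(spec, (0.2, 1.0)),
        "df_0p34_1": dominant_frequency(spec, (0.34, 1.0)),
        "normen_0p2_0p34": ne[0],
        "normen_0p34_0p6": ne[1],
        "normen_0p6_1": ne[2],
        "hl_ratio": hl_ratio(spec),
        "spmr": spectral_moment_ratio(spec),
    }
    for k in range(9):
        out[f"d{k + 1}"] = float(deciles[k])
    return out
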