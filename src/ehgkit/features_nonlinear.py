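"""Non-linear characterization of band-filtered EHG windows.

Uterine myoelectrical activity becomes more regular, less complex and less
random as labor approaches, so regularity/complexity descriptors carry
predictive information.  This module provides the full non-linear inventory
computed per analysis window and per bandwidth:

* sample entropy (SampEn) and fuzzy entropy (FuzEn) — template-matching
  regularity measures; lower values mean a more self-similar signal,
* spectral entropy (SpEn) — normalized Shannon entropy of the in-band power
  spectrum (spectral flatness),
* Lempel-Ziv complexity after binary (median split) and 6-state
  (equiprobable quantile) symbolization,
* time reversibility — third moment of lagged differences, zero for a
  time-symmetric process,
* Katz's fractal dimension — curve-length based waveform complexity,
* Poincaré-plot dispersions SD1/SD2/SDRR and the SD1/SD2 randomness ratio.

Entropy parameters default to the EHG-literature convention m = 2,
r = 0.15 x window SD, fuzzy exponent 2; all are exposed in
:class:`EntropyConfig`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "EntropyConfig",
    "PoincareDescriptors",
    "FeatureError",
    "sample_entropy",
    "fuzzy_entropy",
    "spectral_entropy",
    "lz76_complexity",
    "lempel_ziv",
    "time_reversibility",
    "katz_fd",
    "poincare",
    "NONLINEAR_FEATURES",
    "nonlinear_features",
]

#: names of the 11 per-band non-linear features, in table order
NONLINEAR_FEATURES = (
    "sampen",
    "fuzen",
    "spen",
    "lzbin",
    "lzmulti",
    "timerev",
    "kfd",
    "sd1",
    "sd2",
    "sdrr",
    "sdratio",
)


class FeatureError(ValueError):
    """Raised when a window is degenerate for a given feature (e.g. constant
    signal, zero in-band power).  Callers aggregating over windows treat it as
    'skip this window for this feature'."""


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters shared by sample and fuzzy entropy.

    m : embedding (template) dimension.
    r_factor : tolerance as a fraction of the window standard deviation.
    fuzzy_exponent : exponent n of the fuzzy membership exp(-d**n / r).
    """

    m: int = 2
    r_factor: float = 0.15
    fuzzy_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r_factor <= 0:
            raise ValueError(f"r_factor must be > 0, got {self.r_factor}")


@dataclass(frozen=True)
class PoincareDescriptors:
    """Dispersions of the lag-1 Poincaré plot (x[n] vs x[n-1]).

    SD1 is the short-term dispersion (minor ellipse axis), SD2 the long-term
    one (major axis), SDRR the overall dispersion with
    SDRR**2 = (SD1**2 + SD2**2) / 2, and sd_ratio = SD1/SD2 measures signal
    randomness (1 for white noise, 0 for a ramp).
    """

    sd1: float
    sd2: float
    sdrr: float
    sd_ratio: float


# ---------------------------------------------------------------------------
# Sample / fuzzy entropy kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sampen_counts(x, m, r):  # pragma: no cover - exercised via sample_entropy
    """Count Chebyshev template matches at lengths m (B) and m+1 (A).

    Pairs i < j over the N - m templates of length m; self-matches excluded.
    """
    n = x.shape[0]
    nt = n - m
    b = 0
    a = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
            if d <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


@njit(cache=True, fastmath=True)
def _fuzen_sums(tm, tm1, r, p):  # pragma: no cover - exercised via fuzzy_entropy
    """Sum fuzzy memberships exp(-d**p / r) over all template pairs.

    ``tm`` / ``tm1``: mean-centred template matrices of shape (nt, m) and
    (nt, m+1); d is the Chebyshev distance between centred templates.
    """
    nt, m = tm.shape
    phi_m = 0.0
    phi_m1 = 0.0
    # memberships with d**p/r > 45 are < 3e-20 and cannot move the double-
    # precision sums; skip their exp
    dthr = (45.0 * r) ** (1.0 / p)
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                t = abs(tm[i, k] - tm[j, k])
                if t > d:
                    d = t
            if d < dthr:
                phi_m += math.exp(-(d**p) / r)
            d1 = 0.0
            for k in range(m + 1):
                t = abs(tm1[i, k] - tm1[j, k])
                if t > d1:
                    d1 = t
            if d1 < dthr:
                phi_m1 += math.exp(-(d1**p) / r)
    return phi_m, phi_m1


@njit(cache=True, fastmath=True)
def _fuzen_sums_m2(a, tm1, r, p):  # pragma: no cover - via fuzzy_entropy
    """m = 2 specialization: a centred 2-template is (+h, -h) with h half
    the first difference, so its Chebyshev distance is the 1-D |h_i - h_j|."""
    nt = a.shape[0]
    phi_m = 0.0
    phi_m1 = 0.0
    dthr = (45.0 * r) ** (1.0 / p)
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = abs(a[i] - a[j])
            if d < dthr:
                phi_m += math.exp(-(d**p) / r)
            d1 = abs(tm1[i, 0] - tm1[j, 0])
            t = abs(tm1[i, 1] - tm1[j, 1])
            if t > d1:
                d1 = t
            t = abs(tm1[i, 2] - tm1[j, 2])
            if t > d1:
                d1 = t
            if d1 < dthr:
                phi_m1 += math.exp(-(d1**p) / r)
    return phi_m, phi_m1


def _centered_templates(x: np.ndarray, m: int, nt: int) -> np.ndarray:
    """(nt, m) matrix of length-m templates, each minus its own mean."""
    idx = np.arange(nt)[:, None] + np.arange(m)[None, :]
    t = x[idx]
    return t - t.mean(axis=1, keepdims=True)


def _window_sd(x: np.ndarray) -> float:
    sd = float(np.std(x))
    if sd <= 0:
        raise FeatureError("constant signal: zero standard deviation")
    return sd


def sample_entropy(samples, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Sample entropy -ln(A/B) with tolerance r = r_factor * SD.

    A and B are the counts of Chebyshev-matching template pairs at lengths
    m+1 and m (self-matches excluded).  Degenerate outcomes are handled as
    documented sentinels rather than silent NaN: when no template pair
    matches even at length m (B = 0) the window carries no regularity
    information and :class:`FeatureError` is raised; when B > 0 but A = 0 the
    theoretical upper bound ln(N-m) + ln(N-m-1) - ln 2 is returned.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 100:
        raise FeatureError(f"need >= 100 samples for sample entropy, got {x.size}")
    r = cfg.r_factor * _window_sd(x)
    a, b = _sampen_counts(x, cfg.m, r)
    if b == 0:
        raise FeatureError("no template matches at length m (B = 0)")
    if a == 0:
        n = x.size
        return math.log(n - cfg.m) + math.log(n - cfg.m - 1) - math.log(2.0)
    return -math.log(a / b)


def fuzzy_entropy(samples, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Fuzzy entropy -ln(phi_{m+1}/phi_m) with mean-centred templates and
    membership exp(-d**n / r), d the Chebyshev distance.

    Centring makes the value invariant to constant offsets; the smooth
    membership makes it well-defined even for constant windows (result 0).
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 100:
        raise FeatureError(f"need >= 100 samples for fuzzy entropy, got {x.size}")
    sd = float(np.std(x))
    if sd <= 0:
        # all centred templates identical: d = 0, membership 1 everywhere
        return 0.0
    r = cfg.r_factor * sd
    nt = x.size - cfg.m  # same template count at both lengths
    tm1 = _centered_templates(x, cfg.m + 1, nt)
    if cfg.m == 2:
        a = (x[:nt] - x[1 : nt + 1]) / 2.0  # centred 2-template first coord
        phi_m, phi_m1 = _fuzen_sums_m2(a, tm1, r, cfg.fuzzy_exponent)
    else:
        tm = _centered_templates(x, cfg.m, nt)
        phi_m, phi_m1 = _fuzen_sums(tm, tm1, r, cfg.fuzzy_exponent)
    return -math.log(phi_m1 / phi_m)


# ---------------------------------------------------------------------------
# Spectral entropy
# ---------------------------------------------------------------------------


def spectral_entropy(samples, fs: float, band: tuple[float, float]) -> float:
    """Normalized Shannon entropy of the in-band Welch spectrum, in [0, 1].

    0 for a pure tone (all mass in one bin), 1 for a perfectly flat in-band
    spectrum.  ``band`` is (f_lo, f_hi) in Hz, half-open [f_lo, f_hi).
    """
    from .features_linear import estimate_psd  # local import to avoid cycle

    spec = estimate_psd(samples, fs, expected_length=None)
    mask = (spec.freqs >= band[0]) & (spec.freqs < band[1])
    p = spec.psd[mask]
    total = p.sum()
    if total <= 0 or p.size < 2:
        raise FeatureError("zero in-band power for spectral entropy")
    p = p / total
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    return float(h / np.log(p.size))


# ---------------------------------------------------------------------------
# Lempel-Ziv complexity
# ---------------------------------------------------------------------------


def lz76_complexity(symbols) -> int:
    """Number of phrases c in the LZ76 exhaustive parse of a symbol sequence.

    Implements the Kaspar-Schuster scan: a new phrase ends whenever the
    current substring cannot be reproduced (with overlap) from the preceding
    text.  ``symbols`` may be a string or a sequence of small ints.
    """
    if isinstance(symbols, str):
        s = np.frombuffer(symbols.encode("ascii"), dtype=np.int8)
    else:
        s = np.asarray(symbols, dtype=np.int8)
    if s.size == 0:
        raise FeatureError("empty symbol sequence")
    if s.size == 1:
        return 1
    return int(_lz76_parse(s))


@njit(cache=True)
def _lz76_parse(s):  # pragma: no cover - exercised via lz76_complexity
    n = s.shape[0]
    c = 1       # phrase count (first symbol is always a phrase)
    l = 1       # start of the phrase currently being parsed
    i = 0       # candidate copy source within the preceding text
    k = 1       # current match length
    k_max = 1   # longest reproducible prefix found so far for this phrase
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def _symbolize(x: np.ndarray, n_states: int) -> np.ndarray:
    if np.ptp(x) == 0:
        raise FeatureError("degenerate quantization: all samples equal")
    if n_states == 2:
        # median threshold; ties (== median) assigned to the lower state
        return (x > np.median(x)).astype(np.int8)
    edges = np.quantile(x, np.arange(1, n_states) / n_states)
    # ties on an edge go to the lower bin (side='left')
    return np.searchsorted(edges, x, side="left").astype(np.int8)


def lempel_ziv(samples, n_states: int = 2) -> float:
    """Normalized LZ76 complexity C = c * log_alpha(N) / N, alpha = n_states.

    Binary symbolization splits at the median; the 6-state variant uses
    equiprobable quantile bins.  Normalizing by the alphabet size makes the
    binary and multistate indices comparable (iid symbols approach 1).
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 10:
        raise FeatureError(f"need >= 10 samples for Lempel-Ziv, got {x.size}")
    if n_states not in (2, 6):
        raise ValueError(f"n_states must be 2 or 6, got {n_states}")
    sym = _symbolize(x, n_states)
    c = lz76_complexity(sym)
    n = x.size
    return c * (math.log(n) / math.log(n_states)) / n


# ---------------------------------------------------------------------------
# Time reversibility, fractal dimension, Poincaré
# ---------------------------------------------------------------------------


def time_reversibility(samples, lag: int = 1) -> float:
    """Third moment of lagged differences, (1/(N-lag)) * sum (x[n]-x[n-lag])**3.

    Zero for any time-symmetric (e.g. linear Gaussian) process; the sign
    flips with the signal's sign (odd moment).  Units are mV**3.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size <= lag:
        raise FeatureError(f"need more than lag={lag} samples, got {x.size}")
    d = x[lag:] - x[:-lag]
    return float(np.mean(d**3))


def katz_fd(samples) -> float:
    """Katz's fractal dimension log10(n) / (log10(n) + log10(d/L)).

    L is the curve length (sum of Euclidean steps on points (i, x_i), one
    abscissa unit per sample), d the maximum distance from the first point,
    n = N - 1 the number of steps.  Exactly 1 for any straight line.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise FeatureError(f"need >= 2 samples for KFD, got {x.size}")
    if np.ptp(x) == 0:
        raise FeatureError("constant signal: KFD undefined (zero waveform extent)")
    n = x.size - 1
    dx = np.diff(x)
    length = float(np.sum(np.sqrt(1.0 + dx**2)))
    idx = np.arange(x.size, dtype=np.float64)
    d = float(np.max(np.sqrt(idx**2 + (x - x[0]) ** 2)))
    if d == 0:
        raise FeatureError("constant signal: zero extent for KFD")
    if x.size == 2:
        return 1.0
    return math.log10(n) / (math.log10(n) + math.log10(d / length))


def poincare(samples) -> PoincareDescriptors:
    """Poincaré-plot dispersions of consecutive amplitudes (x[n] vs x[n-1]).

    SD1**2 = var(successive differences)/2, SD2**2 = 2 var(x) - SD1**2,
    SDRR = sqrt((SD1**2 + SD2**2)/2); sd_ratio = SD1/SD2.  A zero SD2 (all
    long-term variation absent) yields sd_ratio = inf with a warning.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 3:
        raise FeatureError(f"need >= 3 samples for Poincaré, got {x.size}")
    if np.ptp(x) == 0:
        raise FeatureError("constant signal: Poincaré descriptors undefined")
    sd1_sq = float(np.var(np.diff(x), ddof=1)) / 2.0
    sd2_sq = 2.0 * float(np.var(x, ddof=1)) - sd1_sq
    sd2_sq = max(sd2_sq, 0.0)
    sd1 = math.sqrt(sd1_sq)
    sd2 = math.sqrt(sd2_sq)
    sdrr = math.sqrt((sd1_sq + sd2_sq) / 2.0)
    if sd2 == 0:
        warnings.warn("SD2 = 0: reporting sd_ratio as inf", RuntimeWarning)
        ratio = math.inf
    else:
        ratio = sd1 / sd2
    return PoincareDescriptors(sd1=sd1, sd2=sd2, sdrr=sdrr, sd_ratio=ratio)


def nonlinear_features(
    samples,
    fs: float,
    band: tuple[float, float],
    cfg: EntropyConfig = EntropyConfig(),
) -> dict[str, float]:
    """All 11 non-linear descriptors of one band-filtered window.

    Raises :class:`FeatureError` for degenerate windows (constant signal,
    zero in-band power); callers skip such windows per the aggregation
    policy.
    """
    x = np.asarray(samples, dtype=np.float64)
    pc = poincare(x)
    return {
        "sampen": sample_entropy(x, cfg),
        "fuzen": fuzzy_entropy(x, cfg),
        "spen": spectral_entropy(x, fs, band),
        "lzbin": lempel_ziv(x, 2),
        "lzmulti": lempel_ziv(x, 6),
        "timerev": time_reversibility(x),
        "kfd": katz_fd(x),
        "sd1": pc.sd1,
        "sd2": pc.sd2,
        "sdrr": pc.sdrr,
        "sdratio": pc.sd_ratio,
    }
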