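"""Synthetic EHG cohort generator.

Produces labelled 3-channel, 20-Hz surface-EHG-like recordings with
obstetric covariates so that the whole prediction pipeline can be exercised
and tested without access to clinical data.  The signal model is
phenomenological, not physiological:

* background: pink noise (power spectral slope -1), independent per channel,
  scaled to ``background_noise_level`` mV;
* activity bursts: band-limited filtered white noise under a Hanning
  envelope (duration uniform 30-90 s), arriving as a Poisson process at
  ``burst_rate`` per minute.  Bursts are shared across the three channels
  with per-channel multiplicative gain ~ N(1, channel_gain_spread),
  emulating the cross-channel complementarity of real multichannel EHG;
* class effects: preterm subjects draw burst amplitude and center frequency
  from the preterm parameters (higher frequency content mirroring the
  excitability shift reported as labor approaches);
* obstetric covariates: truncated Gaussians matching the demographics of
  the public term/preterm EHG databases; gestational week at recording
  (wog) additionally scales burst amplitude slightly (later wog => larger
  bursts), so wog carries class-relevant signal.

Identical config + seed gives bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from scipy import signal as sps

__all__ = [
    "SyntheticCohortConfig",
    "Recording",
    "ObstetricRecord",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "planted_feature_table",
]

#: Demographic means/SDs of the term and preterm groups (maternal age [y],
#: parity, abortions, weight [kg], gestational week at recording).
OBSTETRIC_MEANS = {
    "term": {"maternal_age": 29.33, "parity": 0.40, "abortions": 0.23,
             "weight": 68.55, "wog": 26.95},
    "preterm": {"maternal_age": 29.08, "parity": 0.41, "abortions": 0.26,
                "weight": 66.82, "wog": 27.59},
}
OBSTETRIC_SDS = {
    "term": {"maternal_age": 4.34, "parity": 0.74, "abortions": 0.61,
             "weight": 10.55, "wog": 4.19},
    "preterm": {"maternal_age": 5.26, "parity": 0.64, "abortions": 0.60,
                "weight": 11.24, "wog": 3.72},
}

OBSTETRIC_FIELDS = ("maternal_age", "parity", "abortions", "weight", "wog")


@dataclass(frozen=True)
class ObstetricRecord:
    """Obstetric covariates of one subject."""

    maternal_age: float
    parity: int
    abortions: int
    weight: float
    wog: float  # gestational week at recording


@dataclass
class Recording:
    """A 3-channel bipolar EHG recording (S1, S2, S3) in mV at ``fs`` Hz."""

    subject_id: str
    channels: np.ndarray  # shape (3, n_samples)
    fs: float
    usable_segments: list[tuple[float, float]]
    label: str  # 'term' | 'preterm'

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.shape[0] != 3:
            raise ValueError(
                f"recording {self.subject_id}: expected 3 channels, "
                f"got {self.channels.shape[0]}"
            )
        dur = self.channels.shape[1] / self.fs
        prev_hi = 0.0
        for lo, hi in self.usable_segments:
            if not (0 <= lo < hi <= dur + 1e-9):
                raise ValueError(
                    f"recording {self.subject_id}: segment [{lo}, {hi}) outside "
                    f"[0, {dur}]"
                )
            if lo < prev_hi:
                raise ValueError(
                    f"recording {self.subject_id}: segments overlap or unsorted"
                )
            prev_hi = hi

    @property
    def duration_s(self) -> float:
        return self.channels.shape[1] / self.fs


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Knobs of the synthetic cohort; defaults define the study conditions."""

    n_term: int = 275
    n_preterm: int = 51
    duration_s: float = 1800.0
    fs: float = 20.0
    burst_rate: float = 0.3  # bursts per minute
    burst_center_freq_term: float = 0.36  # Hz
    burst_center_freq_preterm: float = 0.44  # Hz
    burst_amplitude_term: float = 0.20  # mV
    burst_amplitude_preterm: float = 0.28  # mV
    background_noise_level: float = 0.05  # mV
    channel_gain_spread: float = 0.15
    obstetric_means: dict = field(default_factory=lambda: OBSTETRIC_MEANS)
    obstetric_sds: dict = field(default_factory=lambda: OBSTETRIC_SDS)
    n_artifact_gaps: int = 0  # optional non-usable gaps per recording
    artifact_gap_s: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_term < 1:
            raise ValueError(f"n_term must be >= 1, got {self.n_term}")
        if self.n_preterm < 1:
            raise ValueError(f"n_preterm must be >= 1, got {self.n_preterm}")
        if self.duration_s < 240:
            raise ValueError(
                f"duration_s must be >= 240 (two analysis windows), "
                f"got {self.duration_s}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name in ("burst_center_freq_term", "burst_center_freq_preterm"):
            f0 = getattr(self, name)
            if not (0 < f0 < self.fs / 2):
                raise ValueError(f"{name} must be in (0, fs/2), got {f0}")
        for name in (
            "burst_rate", "burst_amplitude_term", "burst_amplitude_preterm",
            "background_noise_level",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectral slope -1 (FFT shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid div by zero; DC handled below
    spec = spec / np.sqrt(f)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def _burst_carrier(n: int, fs: float, f0: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited noise centered at f0 (width +-0.08 Hz)."""
    half_bw = 0.08
    lo = max(f0 - half_bw, 0.02)
    hi = min(f0 + half_bw, fs / 2 * 0.98)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _draw_obstetrics(label: str, cfg: SyntheticCohortConfig,
                     rng: np.random.Generator) -> ObstetricRecord:
    mu, sd = cfg.obstetric_means[label], cfg.obstetric_sds[label]

    def trunc(name: str, lo: float, hi: float) -> float:
        for _ in range(100):
            v = rng.normal(mu[name], sd[name])
            if lo <= v <= hi:
                return v
        return float(np.clip(v, lo, hi))

    return ObstetricRecord(
        maternal_age=round(trunc("maternal_age", 15.0, 50.0), 1),
        parity=int(round(max(0.0, rng.normal(mu["parity"], sd["parity"])))),
        abortions=int(round(max(0.0, rng.normal(mu["abortions"], sd["abortions"])))),
        weight=round(trunc("weight", 40.0, 120.0), 1),
        wog=round(trunc("wog", 22.0, 37.0), 1),
    )


def _synthesize_recording(
    subject_id: str,
    label: str,
    obst: ObstetricRecord,
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> Recording:
    n = int(round(cfg.duration_s * cfg.fs))
    fs = cfg.fs
    if label == "preterm":
        f0 = cfg.burst_center_freq_preterm
        amp = cfg.burst_amplitude_preterm
    else:
        f0 = cfg.burst_center_freq_term
        amp = cfg.burst_amplitude_term
    # later gestational week => slightly larger bursts, so wog carries signal
    amp = amp * (1.0 + 0.03 * (obst.wog - 27.0))

    burst_sum = np.zeros(n)
    n_bursts = rng.poisson(cfg.burst_rate * cfg.duration_s / 60.0)
    for _ in range(n_bursts):
        dur_s = rng.uniform(30.0, 90.0)
        start_s = rng.uniform(0.0, cfg.duration_s)
        i0 = int(round(start_s * fs))
        nb = min(int(round(dur_s * fs)), n - i0)
        if nb < int(5 * fs):
            continue
        carrier = _burst_carrier(nb, fs, f0, rng)
        burst_sum[i0 : i0 + nb] += amp * np.hanning(nb) * carrier

    gains = 1.0 + cfg.channel_gain_spread * rng.standard_normal(3)
    channels = np.empty((3, n))
    for ch in range(3):
        bg = cfg.background_noise_level * _pink_noise(n, rng)
        channels[ch] = gains[ch] * burst_sum + bg

    segments: list[tuple[float, float]] = [(0.0, cfg.duration_s)]
    for _ in range(cfg.n_artifact_gaps):
        gap_start = rng.uniform(0.0, cfg.duration_s - cfg.artifact_gap_s)
        gap = (gap_start, gap_start + cfg.artifact_gap_s)
        new_segments: list[tuple[float, float]] = []
        for lo, hi in segments:
            if gap[1] <= lo or gap[0] >= hi:
                new_segments.append((lo, hi))
            else:
                if gap[0] > lo:
                    new_segments.append((lo, gap[0]))
                if gap[1] < hi:
                    new_segments.append((gap[1], hi))
        segments = new_segments

    return Recording(
        subject_id=subject_id,
        channels=channels,
        fs=fs,
        usable_segments=segments,
        label=label,
    )


def generate_cohort(
    config: SyntheticCohortConfig,
) -> list[tuple[Recording, ObstetricRecord]]:
    """Generate ``n_term + n_preterm`` labelled subjects deterministically.

    Each subject gets its own child RNG spawned from ``config.seed``, so the
    cohort is reproducible and individual subjects are independent.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_term + config.n_preterm
    children = root.spawn(n_total)
    cohort: list[tuple[Recording, ObstetricRecord]] = []
    for idx in range(n_total):
        label = "term" if idx < config.n_term else "preterm"
        rng = np.random.default_rng(children[idx])
        obst = _draw_obstetrics(label, config, rng)
        rec = _synthesize_recording(f"subj{idx:04d}", label, obst, config, rng)
        cohort.append((rec, obst))
    return cohort


# ---------------------------------------------------------------------------
# Delimited-text persistence
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.tsv"


def _segments_to_str(segments: list[tuple[float, float]]) -> str:
    return ";".join(f"{lo:.3f}:{hi:.3f}" for lo, hi in segments)


def _segments_from_str(s: str) -> list[tuple[float, float]]:
    out = []
    for part in s.split(";"):
        lo, hi = part.split(":")
        out.append((float(lo), float(hi)))
    return out


def write_cohort(cohort, directory) -> Path:
    """Write one TSV per subject (time_s, S1, S2, S3 in mV) plus a manifest
    indexing subject_id, label, obstetric covariates, segments and file path.
    Returns the manifest path.  Samples are stored at 1e-6 mV precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, obst in cohort:
        fname = f"{rec.subject_id}.tsv"
        n = rec.channels.shape[1]
        t = np.arange(n) / rec.fs
        data = np.column_stack([t, rec.channels.T])
        np.savetxt(
            directory / fname, data, fmt="%.6f", delimiter="\t",
            header="time_s\tS1\tS2\tS3", comments="",
        )
        rows.append({
            "subject_id": rec.subject_id,
            "label": rec.label,
            "fs": rec.fs,
            "maternal_age": obst.maternal_age,
            "parity": obst.parity,
            "abortions": obst.abortions,
            "weight": obst.weight,
            "wog": obst.wog,
            "usable_segments": _segments_to_str(rec.usable_segments),
            "path": fname,
        })
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(directory) -> list[tuple[Recording, ObstetricRecord]]:
    """Read a cohort written by :func:`write_cohort` (lossless round-trip)."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"cohort manifest not found: {manifest}")
    try:
        table = pd.read_csv(manifest, sep="\t")
    except Exception as exc:  # malformed manifest
        raise IOError(f"malformed cohort manifest {manifest}: {exc}") from exc
    required = {"subject_id", "label", "fs", "usable_segments", "path",
                *OBSTETRIC_FIELDS}
    missing = required - set(table.columns)
    if missing:
        raise IOError(f"manifest {manifest} lacks columns: {sorted(missing)}")
    cohort = []
    for row in table.itertuples(index=False):
        fpath = directory / row.path
        if not fpath.exists():
            raise FileNotFoundError(f"signal file listed in manifest missing: {fpath}")
        sig = pd.read_csv(fpath, sep="\t")
        rec = Recording(
            subject_id=str(row.subject_id),
            channels=sig[["S1", "S2", "S3"]].to_numpy().T,
            fs=float(row.fs),
            usable_segments=_segments_from_str(row.usable_segments),
            label=str(row.label),
        )
        obst = ObstetricRecord(
            maternal_age=float(row.maternal_age),
            parity=int(row.parity),
            abortions=int(row.abortions),
            weight=float(row.weight),
            wog=float(row.wog),
        )
        cohort.append((rec, obst))
    return cohort


# ---------------------------------------------------------------------------
# Planted feature-selection problem
# ---------------------------------------------------------------------------


def planted_feature_table(
    n_per_class: int = 75,
    n_features: int = 20,
    n_informative: int = 5,
    seed: int = 0,
    effect: float = 1.0,
    sigma_signal: float = 0.25,
    sigma_confound: float = 1.5,
) -> pd.DataFrame:
    """A small feature table with a known informative subset, for selection
    recovery experiments.

    The first ``n_informative`` features share the class signal along their
    common direction v = 1/sqrt(k): class mean +-effect*v, noise variance
    ``sigma_signal**2`` along v and ``sigma_confound**2`` orthogonal to it.
    A classifier using the full informative block can whiten away the
    confound (large separation); dropping informative features leaks
    confound variance into every direction, so discriminability increases
    steeply and monotonically with the number of informative features
    included.  The remaining features are iid standard normal noise.
    """
    rng = np.random.default_rng(seed)
    k = n_informative
    v = np.ones(k) / np.sqrt(k)
    n = 2 * n_per_class
    y = np.array([0] * n_per_class + [1] * n_per_class)
    sign = np.where(y == 1, 1.0, -1.0)

    along = rng.standard_normal(n)  # coefficient on v
    iso = rng.standard_normal((n, k))
    ortho = iso - np.outer(iso @ v, v)  # component orthogonal to v
    block = (
        np.outer(sign * effect + sigma_signal * along, v)
        + sigma_confound * ortho
    )
    noise = rng.standard_normal((n, n_features - k))
    X = np.hstack([block, noise])

    cols = [f"f{i + 1:02d}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = np.where(y == 1, "preterm", "term")
    df["subject_id"] = [f"p{i:03d}" for i in range(n)]
    # shuffle row order so class blocks are not contiguous
    perm = rng.permutation(n)
    return df.iloc[perm].reset_index(drop=True)
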