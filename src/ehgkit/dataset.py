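"""Per-recording feature vectors and univariate screening.

Each recording is summarized by 203 features: for every channel (S1, S2,
S3), 66 EHG descriptors — peak-to-peak amplitude in each of the four
bandwidths (4), the spectral set computed from the whole-bandwidth window
(18, incl. Teager energy), and the 11 non-linear descriptors in each of the
four bandwidths (44) — plus the 5 obstetric covariates.  Per-window values
are collapsed to the per-recording median, a robust single representative
value.

The Wilcoxon rank-sum screen compares term vs preterm per feature on the
original (pre-oversampling) table.  It is descriptive: results are reported
but never used to remove features before wrapper selection, since features
without individual significance can still contribute complementary
information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features_linear import FeatureError, peak_to_peak, spectral_features
from .features_nonlinear import (
    NONLINEAR_FEATURES,
    EntropyConfig,
    nonlinear_features,
)
from .preprocess import BAND_TOKENS, BANDS, segment_windows

__all__ = [
    "CHANNELS",
    "channel_feature_names",
    "feature_names",
    "extract_recording_features",
    "aggregate_windows",
    "build_table",
    "ScreeningResult",
    "ranksum_screen",
]

logger = logging.getLogger(__name__)

CHANNELS = ("S1", "S2", "S3")
OBSTETRIC_COLUMNS = ("maternal_age", "parity", "abortions", "weight", "wog")
META_COLUMNS = ("label", "subject_id")


def channel_feature_names() -> list[str]:
    """The 66 per-channel feature names (without channel prefix), in the
    documented order: App x 4 bands, spectral set (18), non-linear set x 4
    bands (44)."""
    names = [f"app_{BAND_TOKENS[b]}" for b in BANDS]
    from .features_linear import SPECTRAL_FEATURES

    names.extend(SPECTRAL_FEATURES)
    for b in BANDS:
        token = BAND_TOKENS[b]
        names.extend(f"{feat}_{token}" for feat in NONLINEAR_FEATURES)
    return names


def feature_names() -> list[str]:
    """All 203 feature names: S1 block, S2 block, S3 block, obstetric block."""
    per_channel = channel_feature_names()
    names = [f"{ch}_{n}" for ch in CHANNELS for n in per_channel]
    names.extend(OBSTETRIC_COLUMNS)
    return names


def _window_features(window, fs: float, cfg: EntropyConfig) -> dict[str, float]:
    """All 66 descriptors of one multi-band analysis window (one channel)."""
    out: dict[str, float] = {}
    for band_name in BANDS:
        token = BAND_TOKENS[band_name]
        x = window.band_samples[band_name]
        try:
            out[f"app_{token}"] = peak_to_peak(x)
        except FeatureError:
            pass
    try:
        out.update(spectral_features(window.band_samples["whole"], fs))
    except FeatureError as exc:
        logger.warning("window %s/%d: spectral set skipped (%s)",
                       window.channel_id, window.window_index, exc)
    for band_name, band in BANDS.items():
        token = BAND_TOKENS[band_name]
        x = window.band_samples[band_name]
        try:
            nl = nonlinear_features(x, fs, (band.f_lo, band.f_hi), cfg)
        except FeatureError as exc:
            logger.warning("window %s/%d band %s: non-linear set skipped (%s)",
                           window.channel_id, window.window_index, band_name, exc)
            continue
        out.update({f"{k}_{token}": v for k, v in nl.items()})
    return out


def aggregate_windows(window_feature_rows: list[dict[str, float]]) -> dict[str, float]:
    """Median of each feature across a channel's windows.

    Windows missing a feature (degenerate for that descriptor) are skipped
    per feature; a feature with zero valid windows is absent from the result
    (missing-value flag for the caller).
    """
    if not window_feature_rows:
        raise ValueError("no analysis windows to aggregate")
    frame = pd.DataFrame(window_feature_rows)
    med = frame.median(skipna=True)
    return {k: float(v) for k, v in med.items() if np.isfinite(v)}


def extract_recording_features(
    rec,
    entropy_cfg: EntropyConfig = EntropyConfig(),
    window_s: float = 120.0,
    overlap: float = 0.5,
) -> dict[str, float]:
    """The 198 EHG features of one recording (66 medians per channel,
    channel-prefixed names)."""
    per_channel_windows = segment_windows(rec, window_s=window_s, overlap=overlap)
    out: dict[str, float] = {}
    for ch in CHANNELS:
        rows = [_window_features(w, rec.fs, entropy_cfg)
                for w in per_channel_windows[ch]]
        agg = aggregate_windows(rows)
        out.update({f"{ch}_{k}": v for k, v in agg.items()})
    return out


def build_table(
    cohort,
    entropy_cfg: EntropyConfig = EntropyConfig(),
    window_s: float = 120.0,
    overlap: float = 0.5,
) -> pd.DataFrame:
    """Assemble the cohort feature table: one row per subject, 203 feature
    columns in fixed order plus ``label`` and ``subject_id``.

    Subjects with any missing aggregated feature are dropped with a logged
    warning.
    """
    expected = feature_names()
    rows = []
    for rec, obst in cohort:
        feats = extract_recording_features(
            rec, entropy_cfg, window_s=window_s, overlap=overlap
        )
        for col in OBSTETRIC_COLUMNS:
            feats[col] = float(getattr(obst, col))
        missing = [n for n in expected if n not in feats]
        if missing:
            logger.warning(
                "subject %s dropped: %d missing features (e.g. %s)",
                rec.subject_id, len(missing), missing[:3],
            )
            continue
        row = {n: feats[n] for n in expected}
        row["label"] = rec.label
        row["subject_id"] = rec.subject_id
        rows.append(row)
    if not rows:
        raise ValueError("no subject produced a complete feature vector")
    table = pd.DataFrame(rows, columns=expected + list(META_COLUMNS))
    n_feat = table.shape[1] - len(META_COLUMNS)
    assert n_feat == 203, f"feature table has {n_feat} features, expected 203"
    return table


@dataclass
class ScreeningResult:
    """Per-feature two-sided rank-sum p-values and significance flags."""

    p_values: pd.Series  # indexed by feature name
    significant: pd.Series  # boolean at the chosen alpha
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        stars = pd.cut(
            self.p_values,
            bins=[-np.inf, 0.0005, 0.005, 0.05, np.inf],
            labels=["***", "**", "*", ""],
        ).astype(str)
        return pd.DataFrame({
            "p_value": self.p_values,
            "significant": self.significant,
            "stars": stars,
        })


def ranksum_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    correction: str | None = None,
) -> ScreeningResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test per feature, term vs
    preterm, on the original unbalanced table.

    No multiple-testing correction by default (the screen is descriptive);
    ``correction='bh'`` applies Benjamini-Hochberg for users who want
    FDR-controlled flags.  Synthetic (oversampled) rows must never enter the
    screen; an ``is_synthetic`` column, if present, is enforced to be all
    False.
    """
    if "is_synthetic" in table.columns and table["is_synthetic"].any():
        raise ValueError("screening must run on original rows only (leakage guard)")
    labels = table["label"]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes for screening, got {classes}")
    cols = [c for c in table.columns
            if c not in META_COLUMNS and c != "is_synthetic"]
    grp_a = table.loc[labels == classes[0], cols].to_numpy()
    grp_b = table.loc[labels == classes[1], cols].to_numpy()
    if min(len(grp_a), len(grp_b)) < 2:
        raise ValueError("need >= 2 subjects per class for screening")
    pvals = np.empty(len(cols))
    for j in range(len(cols)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals[j] = stats.mannwhitneyu(
                grp_a[:, j], grp_b[:, j], alternative="two-sided", method="auto"
            ).pvalue
    p = pd.Series(pvals, index=cols, name="p_value")
    if correction == "bh":
        adjusted = stats.false_discovery_control(p.to_numpy(), method="bh")
        flags = pd.Series(adjusted < alpha, index=cols)
    else:
        flags = p < alpha
    return ScreeningResult(p_values=p, significant=flags, alpha=alpha)
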