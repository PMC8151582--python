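"""Band filtering and windowing of EHG recordings.

The EHG carries two physiological components: Fast Wave Low (FWL,
propagation-related, energy around 0.2-0.34 Hz) and Fast Wave High (FWH,
excitability-related, 0.34-4 Hz).  Characterization uses four canonical
bandwidths:

====== ============ =======================================
name   band (Hz)    role
====== ============ =======================================
whole  0.1 - 4      whole EHG bandwidth
fwh    0.34 - 4     FWH component
fwl    0.2 - 0.34   FWL component
fwh1   0.34 - 1     FWH restricted below 1 Hz (better SNR)
====== ============ =======================================

Filtering is a 4th-order Butterworth applied forward-backward (zero phase)
to each usable segment as a whole; windows of 120 s with 50 % overlap are
then cut from the filtered segment, so no window carries its own filter
edge transients.  Windows that would cross a non-usable gap are dropped,
not shortened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "BANDS",
    "AnalysisWindow",
    "bandpass",
    "segment_windows",
    "window_count",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named analysis bandwidth [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def validate(self, fs: float) -> None:
        if not (0 < self.f_lo < self.f_hi < fs / 2):
            raise ValueError(
                f"band {self.name}: need 0 < {self.f_lo} < {self.f_hi} < fs/2={fs / 2}"
            )


#: the canonical four-band set, keyed by short name
BANDS: dict[str, BandDefinition] = {
    "whole": BandDefinition("whole", 0.1, 4.0),
    "fwh": BandDefinition("fwh", 0.34, 4.0),
    "fwl": BandDefinition("fwl", 0.2, 0.34),
    "fwh1": BandDefinition("fwh1", 0.34, 1.0),
}

#: band-name token used in feature names, e.g. S1_sampen_0p34_4
BAND_TOKENS: dict[str, str] = {
    "whole": "0p1_4",
    "fwh": "0p34_4",
    "fwl": "0p2_0p34",
    "fwh1": "0p34_1",
}

_FILTER_ORDER = 4


@dataclass
class AnalysisWindow:
    """One 120-s analysis window of one channel, with all four band-filtered
    versions (each ``round(120*fs)`` samples)."""

    channel_id: str
    window_index: int
    start_s: float
    band_samples: dict[str, np.ndarray] = field(default_factory=dict)


def bandpass(samples, fs: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass; output length = input length."""
    band.validate(fs)
    x = np.asarray(samples, dtype=np.float64)
    sos = sps.butter(
        _FILTER_ORDER, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos"
    )
    # sosfiltfilt needs padding headroom; 3x the effective impulse settling
    min_len = 3 * (2 * _FILTER_ORDER + 1)
    if x.size <= min_len:
        raise ValueError(
            f"signal too short for band-pass filtering: {x.size} <= {min_len} samples"
        )
    return sps.sosfiltfilt(sos, x)


def window_count(segment_s: float, window_s: float = 120.0, step_s: float = 60.0) -> int:
    """Closed-form number of windows fitting a segment of given duration."""
    if segment_s < window_s:
        return 0
    return int(np.floor((segment_s - window_s) / step_s)) + 1


def segment_windows(
    rec,
    window_s: float = 120.0,
    overlap: float = 0.5,
    bands: dict[str, BandDefinition] = BANDS,
) -> dict[str, list[AnalysisWindow]]:
    """Cut band-filtered analysis windows from a recording's usable segments.

    Returns ``{channel_id: [AnalysisWindow, ...]}``.  Each usable segment is
    filtered whole (per band) and windows of ``window_s`` seconds advancing
    by ``window_s * (1 - overlap)`` are cut inside it; windows never span a
    gap between segments.  Raises ValueError when no segment can host a
    single window.
    """
    fs = rec.fs
    nwin = int(round(window_s * fs))
    step_s = window_s * (1.0 - overlap)
    nstep = int(round(step_s * fs))
    seg_lengths = [hi - lo for lo, hi in rec.usable_segments]
    total = sum(window_count(sl, window_s, step_s) for sl in seg_lengths)
    if total == 0:
        raise ValueError(
            f"no usable segment can fit a {window_s}-s window; "
            f"segment lengths (s): {seg_lengths}"
        )
    out: dict[str, list[AnalysisWindow]] = {}
    for ch_idx, ch_name in enumerate(("S1", "S2", "S3")):
        x = np.asarray(rec.channels[ch_idx], dtype=np.float64)
        windows: list[AnalysisWindow] = []
        widx = 0
        for lo_s, hi_s in rec.usable_segments:
            i0, i1 = int(round(lo_s * fs)), int(round(hi_s * fs))
            seg = x[i0:i1]
            if seg.size < nwin:
                continue
            filtered = {name: bandpass(seg, fs, band) for name, band in bands.items()}
            n_here = window_count(hi_s - lo_s, window_s, step_s)
            for w in range(n_here):
                a = w * nstep
                windows.append(
                    AnalysisWindow(
                        channel_id=ch_name,
                        window_index=widx,
                        start_s=lo_s + w * step_s,
                        band_samples={
                            name: filtered[name][a : a + nwin] for name in bands
                        },
                    )
                )
                widx += 1
        out[ch_name] = windows
    return out
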