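"""HRV metric panel for one protocol phase.

Covers the standard short-term panel: mean heart rate; time-domain SDNN,
RMSSD, pNN50; the geometric triangular index; Welch band powers of the
cubic-spline-resampled tachogram (VLF/LF/HF, total power, normalized
units, LF/HF); Poincaré descriptors SD1/SD2 with the derived SDR, cardiac
sympathetic index (CSI) and cardiac vagal index (CVI); and sample entropy.

Undefined results are reported as NaN ("undefined marker"), never as a
silent zero or infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist

from .io_protocol import PhaseSegment

#: canonical panel column order
METRIC_NAMES = [
    "hr_bpm", "sdnn_ms", "rmssd_ms", "pnn50_pct", "tidx",
    "vlf_ms2", "lf_ms2", "hf_ms2", "tp_ms2", "lf_nu", "hf_nu", "lf_hf",
    "sd1_ms", "sd2_ms", "sdr", "csi", "cvi", "sampen",
]

#: default spectral bands, Hz (half-open [lo, hi))
DEFAULT_BANDS = {"vlf": (0.0033, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.40)}

#: histogram bin width for the triangular index: 1/128 s
TIDX_BIN_MS = 1000.0 / 128.0


@dataclass
class HRVPanel:
    """The per-phase metric vector (heart rate plus 17 HRV indices)."""

    subject_id: str = ""
    phase_name: str = ""
    hr_bpm: float = np.nan
    sdnn_ms: float = np.nan
    rmssd_ms: float = np.nan
    pnn50_pct: float = np.nan
    tidx: float = np.nan
    vlf_ms2: float = np.nan
    lf_ms2: float = np.nan
    hf_ms2: float = np.nan
    tp_ms2: float = np.nan
    lf_nu: float = np.nan
    hf_nu: float = np.nan
    lf_hf: float = np.nan
    sd1_ms: float = np.nan
    sd2_ms: float = np.nan
    sdr: float = np.nan
    csi: float = np.nan
    cvi: float = np.nan
    sampen: float = np.nan
    insufficient_reason: str = ""

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _rr(segment: PhaseSegment | np.ndarray) -> np.ndarray:
    if isinstance(segment, PhaseSegment):
        return np.asarray(segment.rr_ms, dtype=float)
    return np.asarray(segment, dtype=float)


def mean_heart_rate(segment: PhaseSegment | np.ndarray) -> float:
    """Mean heart rate in bpm, as 60000 / mean(RR in ms)."""
    rr = _rr(segment)
    if len(rr) < 2:
        return np.nan
    return 60000.0 / float(np.mean(rr))


def time_domain(segment: PhaseSegment | np.ndarray) -> tuple[float, float, float]:
    """(SDNN, RMSSD, pNN50).

    SDNN is the sample (n-1) standard deviation of the intervals; RMSSD the
    root mean square of successive differences; pNN50 the percentage of
    successive differences exceeding 50 ms in magnitude.
    """
    rr = _rr(segment)
    if len(rr) < 2:
        return np.nan, np.nan, np.nan
    sdnn = float(np.std(rr, ddof=1))
    d = np.diff(rr)
    if len(d) < 2:
        return sdnn, np.nan, np.nan
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    pnn50 = 100.0 * float(np.mean(np.abs(d) > 50.0))
    return sdnn, rmssd, pnn50


def triangular_index(segment: PhaseSegment | np.ndarray) -> float:
    """N / (height of the modal bin) of the RR histogram at 1/128-s bins."""
    rr = _rr(segment)
    if len(rr) == 0:
        return np.nan
    bins = np.floor(rr / TIDX_BIN_MS).astype(np.int64)
    counts = np.bincount(bins - bins.min())
    return len(rr) / float(counts.max())


def spectral_powers(segment: PhaseSegment, bands: dict | None = None, *,
                    fs: float = 4.0, window_s: float = 120.0,
                    warn_short: bool = True) -> dict:
    """Welch band powers of the evenly resampled tachogram.

    The irregular tachogram (terminating beat times, RR in ms) is
    cubic-spline resampled at ``fs`` Hz, linearly detrended, and its PSD
    estimated by Welch with Hann windows of ``min(window_s, span)`` seconds
    at 50% overlap.  Band powers are trapezoidal integrals over the VLF,
    LF and HF bands; total power is their sum, so the normalized units
    satisfy lf_nu + hf_nu = 100 exactly whenever tp > vlf.
    """
    bands = bands or DEFAULT_BANDS
    nan = {k: np.nan for k in ("vlf_ms2", "lf_ms2", "hf_ms2", "tp_ms2",
                               "lf_nu", "hf_nu", "lf_hf")}
    t = np.asarray(segment.beat_times, dtype=float)
    x = np.asarray(segment.rr_ms, dtype=float)
    if len(x) < 4:
        return nan
    span = t[-1] - t[0]
    if warn_short and span < 120.0:
        warnings.warn(f"{segment.subject_id}/{segment.phase_name}: segment "
                      f"spans only {span:.0f} s; spectral estimates unstable",
                      stacklevel=2)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    tach = CubicSpline(t, x)(grid)
    tach = signal.detrend(tach, type="linear")
    nperseg = min(int(round(window_s * fs)), len(grid))
    freqs, psd = signal.welch(tach, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend=False)

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    vlf = band_power(*bands["vlf"])
    lf = band_power(*bands["lf"])
    hf = band_power(*bands["hf"])
    tp = vlf + lf + hf
    denom = tp - vlf
    lf_nu = 100.0 * lf / denom if denom > 0 else np.nan
    hf_nu = 100.0 * hf / denom if denom > 0 else np.nan
    lf_hf = lf / hf if hf > 0 else np.nan
    return {"vlf_ms2": vlf, "lf_ms2": lf, "hf_ms2": hf, "tp_ms2": tp,
            "lf_nu": lf_nu, "hf_nu": hf_nu, "lf_hf": lf_hf}


def poincare(segment: PhaseSegment | np.ndarray) -> tuple[float, float, float, float, float]:
    """(SD1, SD2, SDR, CSI, CVI) from the lag-1 Poincaré plot.

    SD1 is the dispersion perpendicular to the identity line,
    ``sqrt(var(diff(rr)) / 2)``; SD2 the dispersion along it, via
    ``2·SDNN² = SD1² + SD2²``.  SDR = SD1/SD2, CSI = (4·SD2)/(4·SD1),
    CVI = log10((4·SD1)·(4·SD2)).  Sample (n-1) variances throughout.
    """
    rr = _rr(segment)
    if len(rr) < 3:
        return (np.nan,) * 5
    d = np.diff(rr)
    sd1 = float(np.sqrt(0.5 * np.var(d, ddof=1)))
    sdnn = float(np.std(rr, ddof=1))
    sd2 = float(np.sqrt(max(0.0, 2.0 * sdnn ** 2 - sd1 ** 2)))
    if sd1 == 0.0 or sd2 == 0.0:
        return sd1, sd2, np.nan, np.nan, np.nan
    sdr = sd1 / sd2
    csi = sd2 / sd1
    cvi = float(np.log10(16.0 * sd1 * sd2))
    return sd1, sd2, sdr, csi, cvi


def sample_entropy(segment: PhaseSegment | np.ndarray, m: int = 2,
                   r: float | None = None, r_frac: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) with template length ``m``, tolerance ``r``.

    B counts pairs of length-``m`` templates within Chebyshev distance
    ``r`` (self-matches excluded, both template sets truncated to the first
    ``n - m`` windows); A counts the same for length ``m + 1``.  Default
    tolerance is ``r_frac`` times the sample SD of the series.
    """
    x = _rr(segment)
    n = len(x)
    if n < m + 2:
        return np.nan
    if r is None:
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            return np.nan
        r = r_frac * sd
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[: n - m]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    b = int(np.count_nonzero(pdist(tm, metric="chebyshev") <= r))
    a = int(np.count_nonzero(pdist(tm1, metric="chebyshev") <= r))
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


_METRIC_GROUPS = {
    "hr": ["hr_bpm"],
    "time": ["sdnn_ms", "rmssd_ms", "pnn50_pct"],
    "tidx": ["tidx"],
    "spectral": ["vlf_ms2", "lf_ms2", "hf_ms2", "tp_ms2", "lf_nu", "hf_nu", "lf_hf"],
    "poincare": ["sd1_ms", "sd2_ms", "sdr", "csi", "cvi"],
    "sampen": ["sampen"],
}


def compute_panel(segment: PhaseSegment, *, metrics: Sequence[str] | None = None,
                  bands: dict | None = None, sampen_m: int = 2,
                  sampen_r_frac: float = 0.2,
                  warn_short_spectral: bool = False) -> HRVPanel:
    """Compute the full (or a filtered) HRV panel for one phase segment.

    An insufficient segment (fewer than its minimum beat count) yields a
    panel of NaNs with ``insufficient_reason`` set.  ``metrics`` restricts
    computation to the named panel columns; the rest stay NaN.
    """
    panel = HRVPanel(subject_id=segment.subject_id, phase_name=segment.phase_name)
    if not segment.sufficient:
        panel.insufficient_reason = (
            f"only {segment.n_beats} beats (< {segment.min_beats})")
        return panel

    wanted = set(METRIC_NAMES if metrics is None else metrics)

    def want(group: str) -> bool:
        return bool(wanted & set(_METRIC_GROUPS[group]))

    if want("hr"):
        panel.hr_bpm = mean_heart_rate(segment)
    if want("time"):
        panel.sdnn_ms, panel.rmssd_ms, panel.pnn50_pct = time_domain(segment)
    if want("tidx"):
        panel.tidx = triangular_index(segment)
    if want("spectral"):
        sp = spectral_powers(segment, bands, warn_short=warn_short_spectral)
        for k, v in sp.items():
            setattr(panel, k, v)
    if want("poincare"):
        (panel.sd1_ms, panel.sd2_ms, panel.sdr,
         panel.csi, panel.cvi) = poincare(segment)
    if want("sampen"):
        panel.sampen = sample_entropy(segment, m=sampen_m, r_frac=sampen_r_frac)
    return panel


def panel_frame(panels: Iterable[HRVPanel]) -> pd.DataFrame:
    """Stack panels into a DataFrame (subject_id, phase_name, metrics...)."""
    return pd.DataFrame([p.to_dict() for p in panels])
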