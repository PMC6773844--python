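"""From clean recordings to the windowed band-power table.

The dependent variable of the downstream mixed models is the RMS of log
spectral power: within each non-overlapping 30-s window the one-sided
Welch spectrum (1-s Hann segments, 50% overlap, 1-Hz bins) is reduced,
per frequency band, to ``sqrt(mean(log(power)^2))``.  Windows with more
than 5 s of marked artifact are rejected before any spectral estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .recording import Recording, Span

logger = logging.getLogger(__name__)

MAX_ARTIFACT_S = 5.0
PSD_FLOOR = 1e-12


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class BandDef:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise SpectralError(f"band {self.name}: need 0 < lo < hi")


#: Bands of the primary analysis (chosen against the 1/f background):
#: low delta, alpha, low beta.
METHODS_BANDS = (
    BandDef("delta", 0.5, 3.5),
    BandDef("alpha", 9.5, 11.5),
    BandDef("low_beta", 16.5, 19.5),
)

#: Bands of the topographic contrast figures: delta, theta and a narrow
#: alpha whose difference with theta isolates "specific alpha".
RESULTS_BANDS = (
    BandDef("delta", 0.5, 3.5),
    BandDef("theta", 7.0, 8.0),
    BandDef("alpha", 10.0, 11.0),
)

BAND_PRESETS = {"methods": METHODS_BANDS, "results": RESULTS_BANDS}


@dataclass(frozen=True)
class Window:
    """One 30-s analysis window with its condition labels."""

    data: np.ndarray  # (n_channels, n_samples), not copied
    onset_s: float
    duration_s: float
    block: int
    window_index: int
    state: str
    memory: str
    phase: str


def segment_windows(rec: Recording, window_s: float = 30.0) -> list[Window]:
    """Consecutive non-overlapping windows per condition block; trailing
    partial windows are dropped."""
    if rec.duration_s < window_s:
        logger.warning("recording shorter than one %.0f-s window", window_s)
        return []
    fs = rec.sfreq
    n_per = int(round(window_s * fs))
    out: list[Window] = []
    for bi, block in enumerate(rec.condition_annotations):
        n_win = int(block.duration_s // window_s)
        start = int(round(block.onset_s * fs))
        for w in range(n_win):
            i0 = start + w * n_per
            out.append(Window(rec.data[:, i0:i0 + n_per],
                              onset_s=block.onset_s + w * window_s,
                              duration_s=window_s, block=bi, window_index=w,
                              state=block.state, memory=block.memory,
                              phase=block.phase))
    return out


class WindowPartition(NamedTuple):
    retained: list[Window]
    rejected: list[Window]


def reject_artifact_windows(windows: Sequence[Window],
                            artifact_annotations: Sequence[Span],
                            max_artifact_s: float = MAX_ARTIFACT_S,
                            ) -> WindowPartition:
    """Drop every window whose overlap with artifact annotations strictly
    exceeds ``max_artifact_s`` seconds (a window with exactly that much
    overlap is retained)."""
    retained, rejected = [], []
    for w in windows:
        ov = sum(a.overlap(w.onset_s, w.onset_s + w.duration_s)
                 for a in artifact_annotations)
        (rejected if ov > max_artifact_s else retained).append(w)
    if rejected:
        logger.info("rejected %d of %d windows (>%g s artifact)",
                    len(rejected), len(windows), max_artifact_s)
    return WindowPartition(retained, rejected)


def welch_psd(data: np.ndarray, fs: float, seg_s: float = 1.0,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Averaged modified periodogram (Hann taper) per channel.

    Returns ``(freqs, psd)`` with ``psd`` shaped ``(n_channels, n_freqs)``
    in uV^2/Hz; with the 1-s default segments the frequency axis has
    1-Hz spacing from 0 to the Nyquist frequency.
    """
    data = np.atleast_2d(np.asarray(data, float))
    nperseg = int(round(seg_s * fs))
    if data.shape[1] < nperseg:
        raise SpectralError("window shorter than one Welch segment")
    if not 0 <= overlap < 1:
        raise SpectralError("overlap must be in [0, 1)")
    freqs, psd = sp_signal.welch(data, fs=fs, window="hann", nperseg=nperseg,
                                 noverlap=int(round(nperseg * overlap)),
                                 axis=1, detrend=False)
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDef,
               floor: float | None = PSD_FLOOR) -> np.ndarray:
    """RMS of log power over the band's bins, per channel:
    ``sqrt(mean(log(psd)^2))``.

    ``floor`` clips the PSD from below before the (natural) log; pass
    ``None`` to make non-positive bins an error instead.
    """
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not mask.any():
        raise SpectralError(f"band {band.name} outside frequency axis")
    vals = np.atleast_2d(psd)[:, mask]
    if floor is None:
        if (vals <= 0).any():
            raise SpectralError("non-positive PSD bin: log power undefined")
    else:
        vals = np.maximum(vals, floor)
    return np.sqrt(np.mean(np.log(vals) ** 2, axis=1))


def window_table(rec: Recording, participant: str, age: float, shss: int,
                 bands: Sequence[BandDef] = METHODS_BANDS,
                 window_s: float = 30.0, seg_s: float = 1.0,
                 overlap: float = 0.5) -> pd.DataFrame:
    """Segment, reject, estimate: the per-window band-power table for one
    recording (one row per retained window x channel x band)."""
    windows = segment_windows(rec, window_s)
    retained, _ = reject_artifact_windows(windows, rec.artifact_annotations)
    rows = []
    for w in retained:
        freqs, psd = welch_psd(w.data, rec.sfreq, seg_s, overlap)
        for band in bands:
            power = band_power(freqs, psd, band)
            for ci, ch in enumerate(rec.channel_ids):
                rows.append((participant, ch, band.name, w.block,
                             w.window_index, power[ci], w.state, w.memory,
                             w.phase, age, shss))
    return pd.DataFrame(rows, columns=[
        "participant", "channel", "band", "block", "window_index", "power",
        "state", "memory", "phase", "age", "shss"])


_ROW_KEYS = ["participant", "channel", "block", "window_index",
             "state", "memory", "phase", "age", "shss"]


def band_difference(table: pd.DataFrame, band_a: str,
                    band_b: str) -> pd.DataFrame:
    """Per-row band contrast: a new band ``specific_<band_a>`` whose power
    is ``power(band_a) - power(band_b)`` for every
    (participant, channel, window) key."""
    a = table[table["band"] == band_a].set_index(_ROW_KEYS)["power"]
    b = table[table["band"] == band_b].set_index(_ROW_KEYS)["power"]
    if (len(a.index.difference(b.index)) or len(b.index.difference(a.index))
            or len(a) != len(b)):
        raise SpectralError(
            f"bands {band_a!r}/{band_b!r} have mismatched row keys")
    diff = (a - b.reindex(a.index)).reset_index()
    diff["band"] = f"specific_{band_a}"
    return diff[["participant", "channel", "band", "block", "window_index",
                 "power", "state", "memory", "phase", "age", "shss"]]


def fit_one_over_f(freqs: np.ndarray, psd: np.ndarray,
                   fmin: float = 0.5, fmax: float = 30.0,
                   ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Least-squares log-log linear background fit.

    Returns ``(intercept, slope, residuals, mask)`` where the model is
    ``log psd = intercept + slope * log f`` over ``fmin <= f <= fmax``.
    """
    psd = np.asarray(psd, float)
    if (psd <= 0).any():
        raise SpectralError("non-positive spectrum")
    mask = (freqs >= fmin) & (freqs <= fmax)
    x, y = np.log(freqs[mask]), np.log(psd[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return float(intercept), float(slope), resid, mask


def propose_bands(freqs: np.ndarray, psd_by_region: dict[str, np.ndarray],
                  margin_sd: float = 2.0, min_excess: float = 0.05,
                  fmin: float = 0.5, fmax: float = 30.0) -> list[BandDef]:
    """Data-driven band selection against the 1/f background.

    For each region's mean spectrum a log-log linear background is fit;
    bins whose region-averaged residual exceeds ``margin_sd`` robust
    standard deviations of the residuals (and at least ``min_excess``
    log units, so an exactly 1/f spectrum proposes nothing) form
    contiguous candidate bands.
    """
    zs = []
    mask_ref = None
    for region, psd in psd_by_region.items():
        _, _, resid, mask = fit_one_over_f(freqs, psd, fmin, fmax)
        mask_ref = mask
        sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        thresh = max(margin_sd * sd, min_excess)
        zs.append(resid / thresh)
    excess = np.mean(zs, axis=0) > 1.0
    f_used = freqs[mask_ref]
    df = np.median(np.diff(f_used)) if len(f_used) > 1 else 1.0

    bands: list[BandDef] = []
    i = 0
    while i < len(excess):
        if excess[i]:
            j = i
            while j + 1 < len(excess) and excess[j + 1]:
                j += 1
            lo = max(f_used[i] - df / 2, df / 4)
            hi = f_used[j] + df / 2
            bands.append(BandDef(f"band{len(bands) + 1}", float(lo), float(hi)))
            i = j + 1
        else:
            i += 1
    return bands
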