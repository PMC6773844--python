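"""Deterministic signal conditioning: filters, bad-channel interpolation,
average re-referencing and session cropping.

The conditioning order mirrors standard dense-array practice: first-order
high-pass (drift removal), narrow Butterworth band-stop around the mains
frequency, spherical-spline re-interpolation of channels marked bad, and
finally average re-referencing with recovery of the original reference
channel.  All filters are applied forward-backward (zero phase), so
annotation timestamps keep their meaning.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .layout import SensorLayout
from .recording import ConditionSpan, Recording

logger = logging.getLogger(__name__)


class FilterError(ValueError):
    """Invalid filter specification."""


class MontageError(ValueError):
    """Operation impossible on this montage."""


def highpass(rec: Recording, cutoff: float = 0.1) -> Recording:
    """First-order Butterworth high-pass, zero phase, per channel."""
    nyq = rec.sfreq / 2.0
    if not 0 < cutoff < nyq:
        raise FilterError(f"cutoff {cutoff} Hz outside (0, {nyq}) Hz")
    sos = signal.butter(1, cutoff, btype="highpass", fs=rec.sfreq, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def line_noise_filter(rec: Recording, stop_lo: float = 48.0,
                      stop_hi: float = 52.0, order: int = 2) -> Recording:
    """Second-order Butterworth band-stop (mains-noise notch), zero phase."""
    nyq = rec.sfreq / 2.0
    if not 0 < stop_lo < stop_hi < nyq:
        raise FilterError(
            f"stop band ({stop_lo}, {stop_hi}) Hz malformed for fs={rec.sfreq}")
    sos = signal.butter(order, [stop_lo, stop_hi], btype="bandstop",
                        fs=rec.sfreq, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


# ------------------------------------------------------- spherical splines
def _g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical-spline kernel g(cos angle) as a truncated Legendre series.

    g(x) = (1/4pi) * sum_{n=1..N} (2n+1) / (n (n+1))^m * P_n(x)
    """
    out = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n * (n + 1)) ** m * eval_legendre(n, cosang)
    return out / (4 * np.pi)


def spline_interpolation_matrix(good_pos: np.ndarray, bad_pos: np.ndarray,
                                m: int = 4, reg: float = 1e-5,
                                n_terms: int = 50) -> np.ndarray:
    """Matrix mapping good-channel potentials to spherical-spline estimates
    at the bad-channel positions.

    Positions are projected onto the unit sphere.  ``reg`` is a ridge
    term on the kernel matrix diagonal (numerical conditioning).
    """
    gu = good_pos / np.linalg.norm(good_pos, axis=1, keepdims=True)
    bu = bad_pos / np.linalg.norm(bad_pos, axis=1, keepdims=True)
    G = _g_matrix(np.clip(gu @ gu.T, -1, 1), m, n_terms)
    Gb = _g_matrix(np.clip(bu @ gu.T, -1, 1), m, n_terms)
    n = len(gu)
    # solve [[G + reg*I, 1], [1', 0]] [c; d] = [v; 0] for every unit vector v
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    inv = np.linalg.solve(A, np.eye(n + 1))
    # interpolation at bad sites: Gb @ c + d
    mapping = np.hstack([Gb, np.ones((len(bu), 1))]) @ inv[:, :n]
    return mapping


def interpolate_bad_channels(rec: Recording, layout: SensorLayout,
                             m: int = 4, reg: float = 1e-5) -> Recording:
    """Replace channels marked bad by spherical-spline estimates from the
    good channels; refuses if more than half of the montage is bad."""
    if not rec.bad_channels:
        return rec
    missing = set(rec.channel_ids) - set(layout.channels)
    if missing:
        raise MontageError(f"layout lacks positions for {sorted(missing)}")
    bad = [c for c in rec.channel_ids if c in rec.bad_channels]
    good = [c for c in rec.channel_ids if c not in rec.bad_channels]
    if len(bad) > len(rec.channel_ids) / 2:
        raise MontageError(
            f"{len(bad)} of {len(rec.channel_ids)} channels bad: "
            "interpolation would be unreliable")
    pos = {c: layout.positions[layout.index(c)] for c in rec.channel_ids}
    mapping = spline_interpolation_matrix(
        np.array([pos[c] for c in good]), np.array([pos[c] for c in bad]),
        m=m, reg=reg)
    data = rec.data.copy()
    gi = [rec.channel_ids.index(c) for c in good]
    bi = [rec.channel_ids.index(c) for c in bad]
    data[bi] = mapping @ data[gi]
    logger.info("interpolated %d bad channels: %s", len(bad), bad)
    return rec.with_data(data, bad_channels=set())


def average_reference(rec: Recording,
                      restore_reference: str | None = None) -> Recording:
    """Subtract the instantaneous mean over channels from every channel.

    If ``restore_reference`` names a channel absent from the montage,
    the original reference channel (flat zero before re-referencing) is
    appended first, so the output carries the full montage.  The
    operation is idempotent.
    """
    data = rec.data
    channel_ids = list(rec.channel_ids)
    if restore_reference is not None and restore_reference not in channel_ids:
        data = np.vstack([data, np.zeros((1, rec.n_samples))])
        channel_ids.append(restore_reference)
    if len(channel_ids) < 2:
        raise MontageError("average reference needs at least 2 channels")
    data = data - data.mean(axis=0, keepdims=True)
    return rec.with_data(data, channel_ids=channel_ids, reference="average")


def crop_to_conditions(rec: Recording) -> Recording:
    """Remove non-session data: keep only samples inside condition blocks,
    remapping all annotations onto the concatenated timeline."""
    if not rec.condition_annotations:
        raise MontageError("recording has no condition annotations to crop to")
    spans = sorted(rec.condition_annotations, key=lambda s: s.onset_s)
    fs = rec.sfreq
    pieces, new_conds, new_artifacts = [], [], []
    t_out = 0.0
    for span in spans:
        i0, i1 = int(round(span.onset_s * fs)), int(round(span.end_s * fs))
        pieces.append(rec.data[:, i0:i1])
        dur = (i1 - i0) / fs
        new_conds.append(ConditionSpan(t_out, dur, span.state, span.memory,
                                       span.phase))
        for art in rec.artifact_annotations:
            ov = art.overlap(span.onset_s, span.end_s)
            if ov > 0:
                onset = t_out + max(art.onset_s - span.onset_s, 0.0)
                new_artifacts.append(type(art)(onset, ov))
        t_out += dur
    data = np.concatenate(pieces, axis=1)
    return rec.with_data(data, condition_annotations=new_conds,
                         artifact_annotations=new_artifacts)


def preprocess_pipeline(rec: Recording, layout: SensorLayout,
                        highpass_hz: float = 0.1,
                        stop_band: tuple[float, float] = (48.0, 52.0),
                        restore_reference: str | None = None) -> Recording:
    """The enforced conditioning order: high-pass -> mains band-stop ->
    crop to sessions -> interpolate bad channels -> average reference."""
    rec = highpass(rec, highpass_hz)
    rec = line_noise_filter(rec, *stop_band)
    if rec.condition_annotations:
        rec = crop_to_conditions(rec)
    if rec.bad_channels:
        rec = interpolate_bad_channels(rec, layout)
    return average_reference(rec, restore_reference=restore_reference)
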