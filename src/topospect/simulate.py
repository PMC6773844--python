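"""Synthetic recordings and window tables with known statistical structure.

The generator emulates a 5-participant, within-subject recall study:
each participant contributes condition blocks crossing hypnotic state
(HY vs NC), recalled memory (NDE vs AUTOBIO) and recall phase
(OBE / PE / KS), recorded on a dense hemispherical sensor grid at
250 Hz.  Log band power follows the same linear mixed model the
analysis assumes::

    log-power[p, c, b, w] = mu_b + u_p + sum(matching effects) + eps

with ``u_p ~ N(0, participant_sd^2)`` a participant random intercept and
``eps ~ N(0, window_noise_sd^2)`` per 30-s window.  ``mu_b`` is the band
baseline implied by a 1/f^slope background.  Two paths are provided:

* :func:`simulate_window_table` draws rows directly from this equation
  (fast path, no signal synthesis);
* :func:`simulate_recording` synthesises a continuous signal whose
  Welch band power realises the same draws, so the spectral stage can
  be tested against known ground truth.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import study_participants
from .layout import SensorLayout, build_layout
from .recording import ConditionSpan, Recording, RecordingError, Span

WINDOW_S = 30.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# --------------------------------------------------------------------- design
@dataclass(frozen=True)
class Participant:
    id: str
    age: float
    shss: int

    def __post_init__(self) -> None:
        if not 0 <= self.shss <= 12:
            raise ConfigError(f"SHSS score {self.shss} outside 0-12")


@dataclass(frozen=True)
class BlockDef:
    """One condition block of the session."""

    state: str
    memory: str
    phase: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("block duration must be positive")
        # level validation shared with the annotation type
        ConditionSpan(0.0, self.duration_s, self.state, self.memory, self.phase)

    def matches(self, when: dict[str, str]) -> bool:
        return all(getattr(self, k) == v for k, v in when.items())


@dataclass(frozen=True)
class StudyDesign:
    participants: tuple[Participant, ...]
    blocks: tuple[BlockDef, ...]
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(ids) != len(set(ids)):
            raise ConfigError("participant ids must be unique")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling rate must be positive")

    @property
    def session_duration_s(self) -> float:
        return sum(b.duration_s for b in self.blocks)

    def participant(self, pid: str) -> Participant:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)


def _default_participants() -> tuple[Participant, ...]:
    df = study_participants()
    return tuple(Participant(r.participant, float(r.age), int(r.shss))
                 for r in df.itertuples())


def emulation_design(block_minutes: float = 10.0,
                     sampling_rate: float = 250.0,
                     participants: tuple[Participant, ...] | None = None,
                     ) -> StudyDesign:
    """The study's session structure: NC then HY; within each state the
    NDE recall splits into PE and OBE phases and the autobiographical
    recall into PE and KS phases (each recall ~20 min, i.e. two
    ``block_minutes``-long phase blocks at the default).
    """
    if participants is None:
        participants = _default_participants()
    blocks = []
    for state in ("NC", "HY"):
        for memory, phases in (("NDE", ("PE", "OBE")), ("AUTOBIO", ("PE", "KS"))):
            for phase in phases:
                blocks.append(BlockDef(state, memory, phase, block_minutes * 60.0))
    return StudyDesign(participants, tuple(blocks), sampling_rate)


def scaled_design(block_minutes: float = 2.0,
                  sampling_rate: float = 250.0) -> StudyDesign:
    """Scaled-down emulation preset used by the test-bench simulations."""
    return emulation_design(block_minutes=block_minutes,
                            sampling_rate=sampling_rate)


# ------------------------------------------------------------------ parameters
@dataclass(frozen=True)
class EffectSpec:
    """An additive shift on log band power for matching condition blocks.

    ``when`` maps factor names (``state``/``memory``/``phase``) to the
    level that must hold, e.g. ``{"memory": "NDE"}``; ``channels`` is the
    set of channel ids carrying the effect (``None`` = all channels).
    """

    band: str
    shift: float
    when: dict[str, str] = field(default_factory=dict)
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        levels = {"state": ConditionSpan.STATES,
                  "memory": ConditionSpan.MEMORIES,
                  "phase": ConditionSpan.PHASES}
        for k, v in self.when.items():
            if k not in levels:
                raise ConfigError(f"unknown factor {k!r}")
            if v not in levels[k]:
                raise ConfigError(f"unknown level {v!r} for factor {k!r}")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generative model (log-power scale throughout)."""

    background_slope: float = 1.0
    level_at_10hz: float = 3.0      # ln(uV^2/Hz) of the background-implied baseline
    band_effects: tuple[EffectSpec, ...] = ()
    participant_sd: float = 0.3
    window_noise_sd: float = 0.5
    artifact_rate: float = 2.0      # expected artifact seconds per minute
    artifact_duration_mean_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participant_sd < 0 or self.window_noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.artifact_rate < 0:
            raise ConfigError("artifact_rate must be >= 0")

    def validate_against(self, layout: SensorLayout,
                         band_names: set[str]) -> None:
        chans = set(layout.channels)
        for eff in self.band_effects:
            if eff.band not in band_names:
                raise ConfigError(f"effect refers to unknown band {eff.band!r}")
            if eff.channels is not None and not set(eff.channels) <= chans:
                missing = set(eff.channels) - chans
                raise ConfigError(f"effect channels not in layout: {sorted(missing)}")


def band_baseline(band, slope: float, level_at_10hz: float) -> float:
    """Baseline log power of a band under a 1/f^slope background:
    the background log density evaluated at the band's geometric-mean
    frequency."""
    f_geo = math.sqrt(band.lo * band.hi)
    return level_at_10hz + slope * (math.log(10.0) - math.log(f_geo))


# -------------------------------------------------------------------- artifacts
def draw_artifact_spans(total_duration_s: float, rate_s_per_min: float,
                        mean_duration_s: float,
                        rng: np.random.Generator) -> list[Span]:
    """Contiguous artifact segments with exponential inter-arrival times.

    Event rate is chosen so the expected artifact coverage equals
    ``rate_s_per_min`` seconds per minute of recording.
    """
    if rate_s_per_min <= 0:
        return []
    event_rate = rate_s_per_min / (60.0 * mean_duration_s)  # events per second
    spans: list[Span] = []
    t = float(rng.exponential(1.0 / event_rate))
    while t < total_duration_s:
        dur = float(rng.exponential(mean_duration_s))
        dur = min(dur, total_duration_s - t)
        if dur > 0:
            spans.append(Span(t, dur))
        t = t + dur + float(rng.exponential(1.0 / event_rate))
    return spans


def _window_artifact_overlap(spans: list[Span], onset: float, end: float) -> float:
    return sum(s.overlap(onset, end) for s in spans)


# ---------------------------------------------------------------- fast path
def simulate_window_table(design: StudyDesign, layout: SensorLayout,
                          params: SimulationParams,
                          bands=None) -> pd.DataFrame:
    """Draw a window-power table directly from the generative equation.

    One row per retained 30-s window x channel x band; windows whose
    overlap with simulated artifact segments exceeds 5 s are dropped,
    mirroring the analysis' rejection rule.
    """
    from .spectral import METHODS_BANDS  # late import avoids a cycle

    bands = list(METHODS_BANDS if bands is None else bands)
    params.validate_against(layout, {b.name for b in bands})
    rng = np.random.default_rng(params.seed)

    mu = {b.name: band_baseline(b, params.background_slope, params.level_at_10hz)
          for b in bands}
    # per-channel effect totals per (band, block)
    chan_idx = {c: i for i, c in enumerate(layout.channels)}
    shift = {}  # (band, block_index) -> (n_channels,) vector
    for bi, block in enumerate(design.blocks):
        for b in bands:
            v = np.zeros(layout.n_channels)
            for eff in params.band_effects:
                if eff.band == b.name and block.matches(eff.when):
                    if eff.channels is None:
                        v += eff.shift
                    else:
                        v[[chan_idx[c] for c in eff.channels]] += eff.shift
            shift[(b.name, bi)] = v

    rows = []
    for part in design.participants:
        u = rng.normal(0.0, params.participant_sd)
        artifacts = draw_artifact_spans(design.session_duration_s,
                                        params.artifact_rate,
                                        params.artifact_duration_mean_s, rng)
        t0 = 0.0
        for bi, block in enumerate(design.blocks):
            n_win = int(block.duration_s // WINDOW_S)
            for w in range(n_win):
                onset = t0 + w * WINDOW_S
                rejected = _window_artifact_overlap(
                    artifacts, onset, onset + WINDOW_S) > 5.0
                eps = rng.normal(0.0, params.window_noise_sd,
                                 size=(len(bands), layout.n_channels))
                if rejected:
                    continue
                for k, b in enumerate(bands):
                    power = mu[b.name] + u + shift[(b.name, bi)] + eps[k]
                    for ci, ch in enumerate(layout.channels):
                        rows.append((part.id, ch, b.name, bi, w, power[ci],
                                     block.state, block.memory, block.phase,
                                     part.age, part.shss))
            t0 += block.duration_s

    return pd.DataFrame(rows, columns=[
        "participant", "channel", "band", "block", "window_index", "power",
        "state", "memory", "phase", "age", "shss"])


# -------------------------------------------------------------- signal path
def _synth_window(n: int, fs: float, psd_fn, rng: np.random.Generator,
                  n_channels: int) -> np.ndarray:
    """Gaussian signals with prescribed one-sided PSD via random-phase rfft.

    ``psd_fn(freqs)`` returns a ``(n_channels, n_freqs)`` array of
    one-sided spectral densities (uV^2/Hz).
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    S = psd_fn(freqs)
    amp = np.sqrt(S * fs * n / 2.0)
    re = rng.standard_normal((n_channels, len(freqs)))
    im = rng.standard_normal((n_channels, len(freqs)))
    X = (re + 1j * im) / np.sqrt(2.0) * amp
    X[:, 0] = 0.0
    if n % 2 == 0:
        X[:, -1] = X[:, -1].real * np.sqrt(2.0)
    return np.fft.irfft(X, n=n, axis=1)


def simulate_recording(design: StudyDesign, layout: SensorLayout,
                       params: SimulationParams, participant: str | None = None,
                       bands=None,
                       rng: np.random.Generator | None = None) -> Recording:
    """Synthesize one participant's continuous recording.

    Per 30-s window and channel, the total one-sided PSD inside each
    analysis band equals ``exp(target log power)`` where the target is a
    draw from the generative equation; outside the bands a 1/f^slope
    background remains.  Artifact segments are realised as large
    low-frequency excursions and annotated.
    """
    from .spectral import METHODS_BANDS

    bands = list(METHODS_BANDS if bands is None else bands)
    params.validate_against(layout, {b.name for b in bands})
    if participant is None:
        if len(design.participants) != 1:
            raise ConfigError("specify participant= for multi-participant designs")
        participant = design.participants[0].id
    part = design.participant(participant)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    fs = design.sampling_rate
    mu = {b.name: band_baseline(b, params.background_slope, params.level_at_10hz)
          for b in bands}
    chan_idx = {c: i for i, c in enumerate(layout.channels)}
    n_ch = layout.n_channels

    u = rng.normal(0.0, params.participant_sd)
    total_dur = design.session_duration_s
    artifacts = draw_artifact_spans(total_dur, params.artifact_rate,
                                    params.artifact_duration_mean_s, rng)

    def background_psd(freqs: np.ndarray) -> np.ndarray:
        S = np.zeros_like(freqs)
        nz = freqs > 0
        S[nz] = np.exp(params.level_at_10hz) * (10.0 / freqs[nz]) ** params.background_slope
        return np.broadcast_to(S, (n_ch, len(freqs)))

    pieces = []
    conditions = []
    t0 = 0.0
    for bi, block in enumerate(design.blocks):
        n_samp_block = int(round(block.duration_s * fs))
        conditions.append(ConditionSpan(t0, block.duration_s,
                                        block.state, block.memory, block.phase))
        shifts = {}
        for b in bands:
            v = np.zeros(n_ch)
            for eff in params.band_effects:
                if eff.band == b.name and block.matches(eff.when):
                    if eff.channels is None:
                        v += eff.shift
                    else:
                        v[[chan_idx[c] for c in eff.channels]] += eff.shift
            shifts[b.name] = v

        n_win = int(math.ceil(n_samp_block / (WINDOW_S * fs)))
        block_sig = np.empty((n_ch, 0))
        for w in range(n_win):
            n = min(int(WINDOW_S * fs), n_samp_block - w * int(WINDOW_S * fs))
            if n <= 0:
                break
            targets = {b.name: mu[b.name] + u + shifts[b.name]
                       + rng.normal(0.0, params.window_noise_sd, n_ch)
                       for b in bands}

            def psd_fn(freqs: np.ndarray) -> np.ndarray:
                S = np.array(background_psd(freqs))
                for b in bands:
                    in_band = (freqs >= b.lo) & (freqs <= b.hi)
                    if in_band.any():
                        target = np.exp(targets[b.name])[:, None]
                        S[:, in_band] = np.maximum(target, 1e-12)
                return S

            block_sig = np.concatenate(
                [block_sig, _synth_window(n, fs, psd_fn, rng, n_ch)], axis=1)
        pieces.append(block_sig)
        t0 += block.duration_s

    data = np.concatenate(pieces, axis=1)
    # artifacts: broadband high-amplitude excursions
    for span in artifacts:
        i0 = int(span.onset_s * fs)
        i1 = min(int(span.end_s * fs), data.shape[1])
        if i1 > i0:
            data[:, i0:i1] += rng.normal(0.0, 200.0, (n_ch, i1 - i0))

    return Recording(data=data, sfreq=fs, channel_ids=list(layout.channels),
                     condition_annotations=conditions,
                     artifact_annotations=artifacts,
                     participant=part.id)


def simulate_recordings(design: StudyDesign, layout: SensorLayout,
                        params: SimulationParams,
                        bands=None) -> dict[str, Recording]:
    """All participants' recordings; seeds derived per participant."""
    ss = np.random.SeedSequence(params.seed)
    out = {}
    for child, part in zip(ss.spawn(len(design.participants)), design.participants):
        rng = np.random.default_rng(child)
        out[part.id] = simulate_recording(design, layout, params,
                                          participant=part.id, bands=bands,
                                          rng=rng)
    return out
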