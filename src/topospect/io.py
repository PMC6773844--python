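"""Readers and writers for the pipeline's on-disk artifacts.

Window tables, layouts, annotations and statistic maps travel as CSV;
recordings can additionally be read from EDF (via MNE) with a CSV
annotation sidecar (columns ``onset_s, duration_s, label`` where
condition labels are ``STATE/MEMORY/PHASE`` and artifacts are
``artifact``).  EDF export requires the optional ``edfio`` backend; a
plain-text wide CSV round-trip is always available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .recording import ConditionSpan, Recording, Span

TABLE_COLUMNS = ["participant", "channel", "band", "block", "window_index",
                 "power", "state", "memory", "phase", "age", "shss"]


def write_window_table(table: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table.to_csv(path, index=False, sep=sep)


def read_window_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table = pd.read_csv(path, sep=sep)
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"window table missing columns: {sorted(missing)}")
    return table


def write_annotations(rec: Recording, path: str | Path) -> None:
    rows = [(c.onset_s, c.duration_s, f"{c.state}/{c.memory}/{c.phase}")
            for c in rec.condition_annotations]
    rows += [(a.onset_s, a.duration_s, "artifact")
             for a in rec.artifact_annotations]
    pd.DataFrame(rows, columns=["onset_s", "duration_s", "label"]).to_csv(
        path, index=False)


def read_annotations(path: str | Path) -> tuple[list[ConditionSpan], list[Span]]:
    df = pd.read_csv(path)
    conditions, artifacts = [], []
    for row in df.itertuples(index=False):
        if row.label == "artifact":
            artifacts.append(Span(row.onset_s, row.duration_s))
        else:
            state, memory, phase = row.label.split("/")
            conditions.append(ConditionSpan(row.onset_s, row.duration_s,
                                            state, memory, phase))
    return conditions, artifacts


def write_bad_channels(bad: set[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\n" for c in sorted(bad)))


def read_bad_channels(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()}


# --------------------------------------------------------------- recordings
def write_recording_csv(rec: Recording, signal_path: str | Path,
                        annotations_path: str | Path | None = None) -> None:
    """Wide CSV: one row per sample, one column per channel (uV)."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_ids)
    df.insert(0, "time_s", np.arange(rec.n_samples) / rec.sfreq)
    df.to_csv(signal_path, index=False, float_format="%.4f")
    if annotations_path is not None:
        write_annotations(rec, annotations_path)


def read_recording_csv(signal_path: str | Path, sfreq: float | None = None,
                       annotations_path: str | Path | None = None,
                       participant: str | None = None) -> Recording:
    df = pd.read_csv(signal_path)
    t = df.pop("time_s").to_numpy(float)
    if sfreq is None:
        sfreq = 1.0 / float(np.median(np.diff(t)))
    conditions, artifacts = ([], [])
    if annotations_path is not None:
        conditions, artifacts = read_annotations(annotations_path)
    return Recording(data=df.to_numpy(float).T, sfreq=float(round(sfreq, 6)),
                     channel_ids=list(df.columns),
                     condition_annotations=conditions,
                     artifact_annotations=artifacts, participant=participant)


def read_recording_edf(path: str | Path,
                       annotations_path: str | Path | None = None,
                       bad_channels_path: str | Path | None = None,
                       participant: str | None = None) -> Recording:
    """Load an EDF recording (potentials converted to uV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    conditions, artifacts = ([], [])
    if annotations_path is not None:
        conditions, artifacts = read_annotations(annotations_path)
    bad = read_bad_channels(bad_channels_path) if bad_channels_path else set()
    return Recording(data=raw.get_data() * 1e6, sfreq=float(raw.info["sfreq"]),
                     channel_ids=list(raw.ch_names),
                     condition_annotations=conditions,
                     artifact_annotations=artifacts,
                     bad_channels=bad, participant=participant)


def write_recording_edf(rec: Recording, path: str | Path,
                        annotations_path: str | Path | None = None) -> None:
    """Export to EDF through MNE; needs the optional ``edfio`` package."""
    import mne

    info = mne.create_info(rec.channel_ids, rec.sfreq, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    try:
        mne.export.export_raw(str(path), raw, fmt="edf", verbose="error")
    except (ImportError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise RuntimeError(
            "EDF export needs the optional 'edfio' backend; use "
            "write_recording_csv for a plain-text round trip") from exc
    if annotations_path is not None:
        write_annotations(rec, annotations_path)
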