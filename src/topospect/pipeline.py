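"""End-to-end orchestration: one configuration, one reproducible run.

A run executes simulate/load -> (preprocess -> spectral) -> per-channel
mixed models -> TFCE permutation inference -> behavioural statistics,
writing every artifact plus a self-contained machine-readable report.
A single global seed deterministically derives each stochastic stage's
seed, so one integer reproduces the whole run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import study_participants
from .layout import SensorLayout, build_layout
from .mixed import ModelSpec, default_ladder, fit_all_channels, select_model
from .phenom import elapsed_years, wilcoxon_signed_rank
from .simulate import (WINDOW_S, EffectSpec, SimulationParams, StudyDesign,
                       emulation_design, simulate_window_table)
from .spectral import BAND_PRESETS, BandDef
from .tfce import (PermutationScheme, TFCEParams, per_band_threshold,
                   permutation_test)

logger = logging.getLogger(__name__)

FULL_MODEL_TERMS = ("HY_NC", "NDE_AUTOBIO", "OBE_PE",
                    "HY_NC:NDE_AUTOBIO", "HY_NC:OBE_PE", "NDE_AUTOBIO:OBE_PE",
                    "HY_NC:NDE_AUTOBIO:OBE_PE", "age", "shss")


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``from_yaml``)."""

    seed: int = 0
    outdir: str = "topospect_out"
    simulate: dict = field(default_factory=lambda: {"preset": "study_emulation_small"})
    table_path: str | None = None
    layout_path: tuple[str, str] | None = None
    bands: str = "methods"
    model: dict = field(default_factory=lambda: {"terms": "full"})
    tfce: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)
    threshold: float | str = "auto"
    phenom_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.bands not in BAND_PRESETS:
            raise ConfigurationError(f"unknown band preset {self.bands!r}")
        if self.threshold != "auto" and not 0 < float(self.threshold) < 1:
            raise ConfigurationError("threshold must lie in (0, 1)")
        for path in filter(None, [self.table_path, self.phenom_path,
                                  *(self.layout_path or ())]):
            if not Path(path).exists():
                raise ConfigurationError(f"referenced file missing: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


#: Presets mirroring the emulated study at full and bench scale.
SIMULATE_PRESETS = {
    "study_emulation": {"n_channels": 257, "block_minutes": 10.0},
    "study_emulation_small": {"n_channels": 8, "block_minutes": 2.0},
}


def _stage_log(handle, stage: str, **payload) -> None:
    line = json.dumps({"stage": stage, **payload}, sort_keys=True)
    logger.info("%s", line)
    if handle is not None:
        handle.write(line + "\n")


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def vertex_channel(layout: SensorLayout) -> str:
    """The channel closest to the top of the head (the Cz analogue)."""
    return layout.channels[int(np.argmax(layout.positions[:, 2]))]


def _build_effects(spec_list) -> tuple[EffectSpec, ...]:
    effects = []
    for e in spec_list or []:
        effects.append(EffectSpec(band=e["band"], shift=float(e["shift"]),
                                  when=dict(e.get("when", {})),
                                  channels=tuple(e["channels"])
                                  if e.get("channels") else None))
    return tuple(effects)


def run(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns (and writes) the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log_handle = open(outdir / "stages.jsonl", "w")
    sim_seed, perm_seed = _derive_seeds(config.seed, 2)
    report: dict[str, Any] = {"software": {"name": "topospect",
                                           "version": __version__},
                              "seed": config.seed}
    bands = BAND_PRESETS[config.bands]

    # ---- layout -----------------------------------------------------
    sim_cfg = dict(config.simulate or {})
    preset = SIMULATE_PRESETS.get(sim_cfg.pop("preset", "study_emulation_small"), {})
    merged = {**preset, **sim_cfg}
    if config.layout_path:
        layout = SensorLayout.from_csv(*config.layout_path)
    else:
        layout = build_layout(int(merged.get("n_channels", 8)))
    layout.to_csv(outdir / "layout_positions.csv", outdir / "layout_edges.csv")

    # ---- table: simulate or load ------------------------------------
    if config.table_path:
        from .io import read_window_table
        table = read_window_table(config.table_path)
        design = None
        counts = {"windows_retained": int(
            len(table) / max(table["channel"].nunique(), 1)
            / max(table["band"].nunique(), 1))}
    else:
        design = emulation_design(block_minutes=float(merged.get("block_minutes", 2.0)))
        params = SimulationParams(
            background_slope=float(merged.get("background_slope", 1.0)),
            band_effects=_build_effects(merged.get("effects")),
            participant_sd=float(merged.get("participant_sd", 0.3)),
            window_noise_sd=float(merged.get("window_noise_sd", 0.5)),
            artifact_rate=float(merged.get("artifact_rate", 2.0)),
            seed=sim_seed)
        table = simulate_window_table(design, layout, params, bands)
        segmented = len(design.participants) * sum(
            int(b.duration_s // WINDOW_S) for b in design.blocks)
        retained = len(table) // (layout.n_channels * len(bands))
        counts = {"windows_segmented": segmented,
                  "windows_retained": retained,
                  "windows_rejected": segmented - retained}
        assert counts["windows_segmented"] == (counts["windows_retained"]
                                               + counts["windows_rejected"])
    table.to_csv(outdir / "window_table.csv", index=False)
    _stage_log(log_handle, "table", rows=len(table), **counts)
    report["windows"] = counts

    # ---- model ------------------------------------------------------
    primary_band = "alpha"
    ref = config.model.get("reference_channel", "vertex")
    ref = vertex_channel(layout) if ref == "vertex" else ref
    terms = config.model.get("terms", "full")
    if terms == "full":
        spec = ModelSpec(FULL_MODEL_TERMS)
    elif terms == "select":
        spec = select_model(table, ref, primary_band, default_ladder())
    else:
        spec = ModelSpec(tuple(terms))
    report["model"] = {"terms": list(spec.fixed_terms),
                       "reference_channel": ref}
    _stage_log(log_handle, "model", terms=list(spec.fixed_terms))

    # ---- inference per band -----------------------------------------
    tfce_params = TFCEParams(**{k: config.tfce[k] for k in config.tfce})
    n_perm = int(config.permutation.get("n_permutations", 200))
    factor = config.permutation.get("factor", "NDE_AUTOBIO")
    threshold = (per_band_threshold(0.05, len(bands))
                 if config.threshold == "auto" else float(config.threshold))
    scheme = PermutationScheme(factor=factor, n_permutations=n_perm,
                               seed=perm_seed)
    report["bands"] = {}
    for band in bands:
        fits = fit_all_channels(table, band.name, spec)
        res = permutation_test(table, band.name, spec, layout,
                               tfce_params, scheme, threshold=threshold,
                               channel_fits=fits)
        res.to_frame().to_csv(outdir / f"map_{band.name}.csv", index=False)
        pd.DataFrame({"max_tfce": res.null_maxima}).to_csv(
            outdir / f"null_{band.name}.csv", index=False)
        try:
            from .viz import plot_topomap
            plot_topomap(layout, res.tvalues,
                         outdir / f"topomap_{band.name}.png",
                         significant=res.pvalues < threshold,
                         title=f"{band.name}: {res.term}")
        except Exception as exc:  # plotting is best-effort
            logger.warning("topomap export failed: %s", exc)
        report["bands"][band.name] = {
            "term": res.term, "n_permutations": res.n_permutations,
            "exhaustive": res.exhaustive, "channels_fit": len(fits.fits),
            "channels_failed": len(fits.failed), **res.summary}
        _stage_log(log_handle, "permutation", band=band.name,
                   n_significant=res.summary["n_significant"])

    # ---- behavioural -------------------------------------------------
    phenom: dict[str, Any] = {}
    demo = study_participants()
    phenom["elapsed_years"] = elapsed_years(demo)
    if config.phenom_path:
        vas = pd.read_csv(config.phenom_path)
        tests = {}
        for measure, grp in vas.groupby("measure"):
            w = wilcoxon_signed_rank(grp["hy"].to_numpy(), grp["nc"].to_numpy())
            tests[measure] = {"W": w.W, "Z": w.Z, "p": w.p_two_sided,
                              "p_exact": w.p_exact, "r": w.r, "n": w.n_pairs}
        phenom["wilcoxon_hy_vs_nc"] = tests
    report["phenomenology"] = phenom
    _stage_log(log_handle, "phenom", measures=len(phenom))

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    log_handle.close()
    return report
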