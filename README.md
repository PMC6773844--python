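# topospect

Sensor-space spectral statistics for dense-array EEG: Welch band power
over 30-second windows, per-channel linear mixed models with a
participant random intercept, threshold-free cluster enhancement (TFCE)
of the resulting T-maps, and family-wise inference through
max-statistic block permutation — together with the small-sample
phenomenology statistics (Wilcoxon signed-rank tests, instrument
scoring) of the within-subject recall study the package emulates.

It is written for EEG researchers analysing condition contrasts of
spectral power in small within-subject designs, where per-channel tests
over hundreds of sensors require family-wise error control but
cluster-forming thresholds are unwanted. Because studies of this kind
rarely deposit raw recordings, the package ships a synthetic-data
generator that reproduces the design — 5 participants, hypnosis (HY) vs
normal consciousness (NC) crossed with near-death-experience (NDE) vs
autobiographical (AUTOBIO) memory recall and recall phase (OBE/PE/KS),
257 channels at 250 Hz — so every stage is testable against known
ground truth.

## The statistics in brief

For each channel *c* and band *b*, window powers (RMS of log Welch
power) follow a linear mixed model

```
power_ij = x_ij' β + u_i + ε_ij,   u_i ~ N(0, τ²),   ε_ij ~ N(0, σ²)
```

with participant random intercepts, condition factors and their
interactions plus age and hypnotic-susceptibility covariates in
`x_ij`. The per-channel T-map of a parameter is enhanced by TFCE,

```
TFCE(c) = Σ_h extent(c, h)^E · h^H · Δh        (E = 0.666, H = 2)
```

over the sensor adjacency graph, and compared against the distribution
of the maximum enhanced statistic across channels under block-wise
relabelling of the memory factor within participant:
`p(c) = (1 + #{max_k ≥ TFCE(c)}) / (1 + n_perm)`. Testing three bands
as a family reduces the per-band cut-off to 0.05/3 → 0.016.
See `docs/methods.md` for the full account.

## Worked example

```python
import topospect as ts
from topospect.pipeline import FULL_MODEL_TERMS
from topospect.tfce import PermutationScheme

layout = ts.build_layout(8)                       # hemispherical bench cap
design = ts.scaled_design(block_minutes=2.0)      # 5 participants, 8 blocks
effect = ts.EffectSpec("alpha", 0.8, {"memory": "NDE"},
                       ("E1", "E4", "E6", "E2"))  # frontal-patch alpha boost
table = ts.simulate_window_table(
    design, layout, ts.SimulationParams(seed=2, band_effects=(effect,)))

spec = ts.ModelSpec(FULL_MODEL_TERMS)             # 3-way model + covariates
fits = ts.fit_all_channels(table, "alpha", spec)
result = ts.permutation_test(
    table, "alpha", spec, layout,
    scheme=PermutationScheme(n_permutations=200, seed=3),
    threshold=0.05, channel_fits=fits)
print(result.summary["n_significant"], result.summary["peak_channel"],
      round(result.summary["peak_T"], 2), round(result.summary["peak_p"], 4))
```

prints

```
3 E6 6.9 0.005
```

three channels of the injected patch survive the max-statistic
threshold; the peak channel E6 carries T = 6.9 for the NDE-vs-AUTOBIO
parameter with permutation p ≈ 0.005 (200 relabelled datasets, add-one
estimator). The behavioural side works the same way:

```python
>>> import topospect as ts
>>> from topospect.datasets import study_participants
>>> ts.elapsed_years(study_participants())["median"]
32.0
>>> round(ts.normal_p_from_z(2.03), 3)
0.042
```

A complete run — simulate, fit every band, permute, summarize, write a
`report.json` — is driven by one YAML file:

```
topospect run -c config.yaml --seed 123 --permutations 200
```

with stage subcommands (`simulate`, `preprocess`, `spectra`, `fit`,
`permute`, `phenom`) operating on each other's CSV artifacts.

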