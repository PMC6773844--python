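"""Threshold-free cluster enhancement and max-statistic permutation
inference over channel statistic maps.

TFCE integrates, over all thresholds h, each channel's suprathreshold
cluster extent (to the power E) times the threshold height (to the power
H).  Family-wise error is controlled by comparing the observed enhanced
map against the distribution of the per-permutation maximum enhanced
value, where permutations relabel the memory factor block-wise within
participant (the exchangeability unit: windows within a block are
autocorrelated, so whole blocks swap labels together).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .layout import SensorLayout
from .mixed import ChannelFits, ModelSpec, TopoStatMap, fit_all_channels

logger = logging.getLogger(__name__)


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class TFCEParams:
    """Enhancement exponents (EEG convention: E = 2/3, H = 2) and the
    number of threshold-integration steps."""

    E: float = 0.666
    H: float = 2.0
    n_steps: int = 100
    two_sided: bool = True
    #: optional fixed upper integration limit; by default the step size
    #: adapts to each map's maximum
    h_max: float | None = None

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise InferenceError("exponents must be >= 0")
        if self.n_steps < 10:
            raise InferenceError("n_steps must be >= 10")
        if self.h_max is not None and self.h_max <= 0:
            raise InferenceError("h_max must be positive")


def _enhance_positive(values: np.ndarray, neighbours: list[np.ndarray],
                      params: TFCEParams) -> np.ndarray:
    """One-sided TFCE of the positive part of ``values``.

    Midpoint-rule integration over ``n_steps`` thresholds between 0 and
    the map maximum; suprathreshold components are maintained
    incrementally (union-find over descending thresholds).
    """
    n = len(values)
    out = np.zeros(n)
    vmax = values.max(initial=0.0)
    if vmax <= 0:
        return out
    dh = (params.h_max if params.h_max is not None else vmax) / params.n_steps
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    active = np.zeros(n, dtype=bool)
    order = np.argsort(values)[::-1]  # activate from the top down
    pos = 0
    for k in range(params.n_steps - 1, -1, -1):
        h = (k + 0.5) * dh
        while pos < n and values[order[pos]] > h:
            i = order[pos]
            active[i] = True
            for j in neighbours[i]:
                if active[j]:
                    parent[find(i)] = find(j)
            pos += 1
        if pos == 0:
            continue
        idx = order[:pos]
        roots = np.fromiter((find(i) for i in idx), dtype=int, count=pos)
        sizes = np.bincount(roots, minlength=n)
        out[idx] += sizes[roots] ** params.E * h ** params.H * dh
    return out


def _neighbour_lists(adjacency: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(adjacency[i]) for i in range(adjacency.shape[0])]


def tfce_transform(tmap: TopoStatMap | np.ndarray, layout: SensorLayout,
                   params: TFCEParams = TFCEParams()) -> np.ndarray:
    """Enhanced map, channel-aligned with ``layout``.

    With ``two_sided`` the negative part is enhanced separately on the
    negated map and re-signed, so effects in either direction survive.
    """
    if isinstance(tmap, TopoStatMap):
        if set(tmap.channels) != set(layout.channels):
            raise InferenceError("statistic map channels do not match layout")
        order = [tmap.channels.index(c) for c in layout.channels]
        values = tmap.values[order]
    else:
        values = np.asarray(tmap, float)
        if values.shape != (layout.n_channels,):
            raise InferenceError("map length does not match layout")
    neighbours = _neighbour_lists(layout.adjacency_matrix())
    enhanced = _enhance_positive(values, neighbours, params)
    if params.two_sided:
        enhanced = enhanced - _enhance_positive(-values, neighbours, params)
    return enhanced


@dataclass(frozen=True)
class PermutationScheme:
    """Block-wise relabelling of one factor within participant."""

    factor: str = "NDE_AUTOBIO"
    n_permutations: int = 2200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor != "NDE_AUTOBIO":
            raise InferenceError(
                "only the memory factor (NDE_AUTOBIO) is relabelled")
        if self.n_permutations < 100:
            raise InferenceError("need at least 100 permutations")


@dataclass
class PermutationResult:
    """Observed and null statistics of one TFCE permutation test."""

    term: str
    band: str
    channels: list[str]
    tvalues: np.ndarray
    enhanced: np.ndarray
    null_maxima: np.ndarray
    pvalues: np.ndarray
    threshold: float
    n_permutations: int
    exhaustive: bool
    seed: int
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "T": self.tvalues,
                             "tfce": self.enhanced, "p": self.pvalues,
                             "significant": self.pvalues < self.threshold})


def channel_pvalues(enhanced: np.ndarray,
                    null_maxima: np.ndarray) -> np.ndarray:
    """Add-one permutation p-values against the max-statistic null:
    ``p(c) = (1 + #{max_k >= obs_c}) / (1 + n_permutations)``.

    Two-sided maps are compared on magnitude.
    """
    if len(null_maxima) == 0:
        raise InferenceError("empty null distribution")
    obs = np.abs(np.asarray(enhanced, float))
    null = np.abs(np.asarray(null_maxima, float))
    ge = (null[None, :] >= obs[:, None]).sum(axis=1)
    return (1.0 + ge) / (1.0 + len(null))


def per_band_threshold(alpha: float = 0.05, n_tests: int = 3,
                       decimals: int = 3) -> float:
    """Per-band significance cut-off: the family alpha divided by the
    number of bands, truncated (floored) to ``decimals`` decimals —
    0.05 over 3 bands gives 0.016."""
    scale = 10 ** decimals
    return math.floor(alpha / n_tests * scale) / scale


def significance_summary(result_or_pvals, tvalues: np.ndarray | None = None,
                         layout: SensorLayout | None = None,
                         threshold: float = 0.05) -> dict:
    """Significant set, its connected-cluster decomposition, and peak
    channel statistics."""
    if isinstance(result_or_pvals, PermutationResult):
        res = result_or_pvals
        pvals, tvalues, threshold = res.pvalues, res.tvalues, res.threshold
        channels = res.channels
        if layout is None:
            raise InferenceError("layout required")
    else:
        pvals = np.asarray(result_or_pvals, float)
        channels = layout.channels
    if not 0 < threshold < 1:
        raise InferenceError("threshold must be in (0, 1)")
    sig_mask = pvals < threshold
    sig_channels = [c for c, s in zip(channels, sig_mask) if s]
    clusters: list[dict] = []
    if sig_channels:
        sub = layout.graph.subgraph(sig_channels)
        import networkx as nx
        for comp in nx.connected_components(sub):
            comp = sorted(comp)
            idx = [channels.index(c) for c in comp]
            k = idx[int(np.argmax(np.abs(tvalues[idx])))]
            clusters.append({"channels": comp, "size": len(comp),
                             "peak_channel": channels[k],
                             "peak_T": float(tvalues[k]),
                             "peak_p": float(pvals[k])})
        clusters.sort(key=lambda c: -c["size"])
    if sig_channels:
        idx = np.where(sig_mask)[0]
        k = idx[int(np.argmax(np.abs(tvalues[idx])))]
        peak = {"peak_channel": channels[k], "peak_T": float(tvalues[k]),
                "peak_p": float(pvals[k])}
    else:
        peak = {"peak_channel": None, "peak_T": None, "peak_p": None}
    return {"n_significant": int(sig_mask.sum()), "threshold": float(threshold),
            "significant_channels": sig_channels, "clusters": clusters, **peak}


# --------------------------------------------------------------- null engine
def _block_structure(df: pd.DataFrame):
    """Per-participant block list with memory labels, plus per-row block ids."""
    keys = df[["participant", "block"]].drop_duplicates().sort_values(
        ["participant", "block"])
    block_ids = list(keys.itertuples(index=False, name=None))
    block_index = {k: i for i, k in enumerate(block_ids)}
    row_block = np.array([block_index[k] for k in
                          zip(df["participant"], df["block"])])
    labels = np.empty(len(block_ids), dtype=object)
    for (p, b), i in block_index.items():
        labels[i] = df.loc[(df["participant"] == p) & (df["block"] == b),
                           "memory"].iloc[0]
    by_participant: dict[str, list[int]] = {}
    for (p, _), i in block_index.items():
        by_participant.setdefault(p, []).append(i)
    return labels, row_block, by_participant


def _count_distinct_relabelings(labels: np.ndarray,
                                by_participant: dict[str, list[int]]) -> int:
    total = 1
    for p, idxs in by_participant.items():
        n = len(idxs)
        k = sum(1 for i in idxs if labels[i] == "NDE")
        total *= math.comb(n, k)
        if total > 10**9:
            break
    return total


def _distinct_assignments(labels_p: list[str]) -> list[tuple[str, ...]]:
    """All distinct orderings of one participant's block-label multiset."""
    return sorted(set(itertools.permutations(labels_p)))


def build_null(table: pd.DataFrame, band: str, spec: ModelSpec,
               layout: SensorLayout,
               tfce_params: TFCEParams = TFCEParams(),
               scheme: PermutationScheme = PermutationScheme(),
               term: str | None = None,
               channel_fits: ChannelFits | None = None,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Max-statistic TFCE null for one model term.

    Every permutation relabels the memory factor block-wise within each
    participant, refits the per-channel GLS (variance ratio frozen at
    each channel's observed estimate, residual variance re-estimated),
    enhances the resulting T-map and records its maximum magnitude.
    Designs with fewer distinct relabelings than requested permutations
    are enumerated exhaustively instead.

    Returns ``(null_maxima, observed_T, observed_enhanced, exhaustive)``.
    """
    if term is None:
        term = scheme.factor
    df = table[table["band"] == band]
    channels = layout.channels
    if set(pd.unique(df["channel"])) != set(channels):
        raise InferenceError("table channels do not match layout")
    if channel_fits is None:
        channel_fits = fit_all_channels(table, band, spec)
    if channel_fits.failed:
        raise InferenceError(
            f"cannot permute with non-converged channels: {channel_fits.failed}")

    # reference frame: rows of the first channel (all channels share the
    # same design rows ordering once sorted)
    df = df.sort_values(["participant", "block", "window_index", "channel"],
                        kind="mergesort")
    one = df[df["channel"] == channels[0]].reset_index(drop=True)
    n = len(one)
    codes, parts = pd.factorize(one["participant"], sort=True)
    n_groups = len(parts)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    # (G, n) group-mean operator
    M = np.zeros((n_groups, n))
    M[codes, np.arange(n)] = 1.0
    M /= counts[:, None]

    # per-channel outcome vectors aligned with `one`'s rows
    Y = np.empty((len(channels), n))
    piv = df.pivot_table(index=["participant", "block", "window_index"],
                         columns="channel", values="power", sort=True)
    key = pd.MultiIndex.from_frame(one[["participant", "block", "window_index"]])
    piv = piv.reindex(key)
    for ci, ch in enumerate(channels):
        Y[ci] = piv[ch].to_numpy(float)

    # frozen variance ratios and whitening weights per channel
    thetas = np.empty((len(channels), n_groups))
    for ci, ch in enumerate(channels):
        f = channel_fits.fits[ch].fit
        lam = f.tau2 / f.sigma2 if f.sigma2 > 0 else 0.0
        thetas[ci] = 1.0 - 1.0 / np.sqrt(1.0 + counts * lam)
    Yw = np.empty_like(Y)
    for ci in range(len(channels)):
        gm = M @ Y[ci]
        Yw[ci] = Y[ci] - thetas[ci][codes] * gm[codes]

    # fixed design atoms; only memory-derived columns change under permutation
    labels, row_block, by_participant = _block_structure(one)
    spec_terms = ["Intercept", *spec.fixed_terms]
    if term not in spec.fixed_terms:
        raise InferenceError(f"term {term!r} not in the model")
    t_idx = spec_terms.index(term)
    p = len(spec_terms)

    atom_fixed = {"HY_NC": (one["state"].to_numpy() == "HY").astype(float),
                  "OBE_PE": (one["phase"].to_numpy() == "PE").astype(float)}
    for cov in ("age", "shss"):
        v = one[cov].to_numpy(float)
        if spec.standardize_covariates:
            sd = v.std()
            v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
        atom_fixed[cov] = v

    def make_X(nde: np.ndarray) -> np.ndarray:
        cols = [np.ones(n)]
        for t in spec.fixed_terms:
            v = np.ones(n)
            for comp in t.split(":"):
                v = v * (nde if comp == "NDE_AUTOBIO" else atom_fixed[comp])
            cols.append(v)
        return np.column_stack(cols)

    def tmap_for(block_labels: np.ndarray) -> np.ndarray:
        nde = (np.asarray(block_labels, dtype=object)[row_block]
               == "NDE").astype(float)
        X = make_X(nde)
        gmX = M @ X
        ts = np.empty(len(channels))
        for ci in range(len(channels)):
            Xw = X - thetas[ci][codes, None] * gmX[codes]
            XtX = Xw.T @ Xw
            XtY = Xw.T @ Yw[ci]
            beta, _, rank, _ = np.linalg.lstsq(XtX, XtY, rcond=1e-10)
            if rank < p:
                # term unidentifiable under this relabelling
                ts[ci] = 0.0
                continue
            dvar = float(np.linalg.inv(XtX)[t_idx, t_idx])
            if not np.isfinite(dvar) or dvar <= 0:
                ts[ci] = 0.0
                continue
            rss = float(Yw[ci] @ Yw[ci] - XtY @ beta)
            sigma2 = max(rss, 1e-300) / n
            ts[ci] = beta[t_idx] / math.sqrt(sigma2 * dvar)
        return ts

    neighbours = _neighbour_lists(layout.adjacency_matrix())

    def enhance(vals: np.ndarray) -> np.ndarray:
        e = _enhance_positive(vals, neighbours, tfce_params)
        if tfce_params.two_sided:
            e = e - _enhance_positive(-vals, neighbours, tfce_params)
        return e

    observed_T = tmap_for(labels)
    observed_enh = enhance(observed_T)

    n_distinct = _count_distinct_relabelings(labels, by_participant)
    exhaustive = n_distinct <= scheme.n_permutations
    rng = np.random.default_rng(scheme.seed)
    maxima = []
    if exhaustive:
        logger.warning("only %d distinct relabelings (< %d requested): "
                       "enumerating exhaustively", n_distinct,
                       scheme.n_permutations)
        per_part = [(_distinct_assignments([labels[i] for i in idxs]), idxs)
                    for idxs in by_participant.values()]
        for combo in itertools.product(*[a for a, _ in per_part]):
            lab = labels.copy()
            for assignment, (_, idxs) in zip(combo, per_part):
                for val, i in zip(assignment, idxs):
                    lab[i] = val
            maxima.append(np.abs(enhance(tmap_for(lab))).max())
    else:
        for _ in range(scheme.n_permutations):
            lab = labels.copy()
            for idxs in by_participant.values():
                perm = rng.permutation(len(idxs))
                vals = [labels[i] for i in idxs]
                for j, i in enumerate(idxs):
                    lab[i] = vals[perm[j]]
            maxima.append(np.abs(enhance(tmap_for(lab))).max())
    return np.asarray(maxima), observed_T, observed_enh, exhaustive


def permutation_test(table: pd.DataFrame, band: str, spec: ModelSpec,
                     layout: SensorLayout,
                     tfce_params: TFCEParams = TFCEParams(),
                     scheme: PermutationScheme = PermutationScheme(),
                     term: str | None = None,
                     threshold: float = per_band_threshold(),
                     channel_fits: ChannelFits | None = None,
                     ) -> PermutationResult:
    """End-to-end family-wise inference for one band and model term."""
    if term is None:
        term = scheme.factor
    null, obs_T, obs_enh, exhaustive = build_null(
        table, band, spec, layout, tfce_params, scheme, term, channel_fits)
    pvals = channel_pvalues(obs_enh, null)
    result = PermutationResult(
        term=term, band=band, channels=list(layout.channels),
        tvalues=obs_T, enhanced=obs_enh, null_maxima=null, pvalues=pvals,
        threshold=threshold, n_permutations=len(null), exhaustive=exhaustive,
        seed=scheme.seed)
    result.summary = significance_summary(result, layout=layout)
    return result
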