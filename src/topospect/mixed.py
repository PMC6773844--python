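"""Per-channel linear mixed models on windowed band power.

Model: for one channel and band, the window powers follow

    power ~ fixed effects (condition factors, interactions, covariates)
            + participant random intercept + residual

Fits maximise the full (not restricted) likelihood so nested models can
be compared by likelihood-ratio tests and AIC.  With a single random
intercept the likelihood can be profiled down to one scalar — the
variance ratio tau^2/sigma^2 — which this module optimises directly;
that keeps per-channel fits fast and boundary-safe, and makes the exact
same GLS machinery reusable under permutation with frozen variance
components.  The three condition factors are coded HY_NC (HY = 1),
NDE_AUTOBIO (NDE = 1) and OBE_PE (PE = 1, i.e. peacefulness vs the
OBE/KS phases); the covariates age and SHSS enter z-scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

FACTOR_CODING = {
    "HY_NC": ("state", "HY"),
    "NDE_AUTOBIO": ("memory", "NDE"),
    "OBE_PE": ("phase", "PE"),
}
COVARIATES = ("age", "shss")


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


def _components(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure (the participant intercept is always random).

    ``fixed_terms`` may contain the three factors, their ``:``-joined
    interactions, and the covariates ``age``/``shss``.  Interactions
    require all their lower-order terms (model hierarchy).
    """

    fixed_terms: tuple[str, ...] = ()
    standardize_covariates: bool = True

    def __post_init__(self) -> None:
        valid_atoms = set(FACTOR_CODING) | set(COVARIATES)
        seen = set(self.fixed_terms)
        if len(seen) != len(self.fixed_terms):
            raise ModelError("duplicate fixed terms")
        for term in self.fixed_terms:
            comps = _components(term)
            if not set(comps) <= valid_atoms:
                raise ModelError(f"unknown term {term!r}")
            if len(comps) > 1 and any(c in COVARIATES for c in comps):
                raise ModelError(f"covariate interactions unsupported: {term!r}")
            for k in range(1, len(comps)):
                for sub in _subsets(comps, k):
                    if ":".join(sub) not in seen:
                        raise ModelError(
                            f"{term!r} requires lower-order term {':'.join(sub)!r}")

    @property
    def n_fixed_params(self) -> int:
        return 1 + len(self.fixed_terms)  # + intercept

    def drop(self, term: str) -> "ModelSpec":
        """Spec without ``term`` and every interaction containing it."""
        if term not in self.fixed_terms:
            raise ModelError(f"term {term!r} not in model")
        comps = set(_components(term))
        kept = tuple(t for t in self.fixed_terms
                     if not comps <= set(_components(t)))
        return ModelSpec(kept, self.standardize_covariates)

    def describe(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "1"


def _subsets(comps: tuple[str, ...], k: int):
    import itertools
    return itertools.combinations(comps, k)


def default_ladder(covariates: bool = True) -> list[ModelSpec]:
    """Candidate models from simplest to fullest, hierarchy-respecting."""
    mains = ("HY_NC", "NDE_AUTOBIO", "OBE_PE")
    twoways = mains + ("HY_NC:NDE_AUTOBIO", "HY_NC:OBE_PE", "NDE_AUTOBIO:OBE_PE")
    full = twoways + ("HY_NC:NDE_AUTOBIO:OBE_PE",)
    cov = COVARIATES if covariates else ()
    ladder = [ModelSpec(()), ModelSpec(("NDE_AUTOBIO",)), ModelSpec(mains),
              ModelSpec(mains + cov), ModelSpec(twoways + cov),
              ModelSpec(full + cov)]
    return ladder


# ------------------------------------------------------------ design matrix
def design_matrix(df: pd.DataFrame, spec: ModelSpec,
                  ) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix (intercept first) for a table subset."""
    n = len(df)
    cols = {"Intercept": np.ones(n)}
    atoms: dict[str, np.ndarray] = {}
    for name, (col, level) in FACTOR_CODING.items():
        atoms[name] = (df[col].to_numpy() == level).astype(float)
    for cov in COVARIATES:
        v = df[cov].to_numpy(float)
        if spec.standardize_covariates:
            sd = v.std()
            v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
        atoms[cov] = v
    for term in spec.fixed_terms:
        val = np.ones(n)
        for comp in _components(term):
            val = val * atoms[comp]
        cols[term] = val
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def whiten(arr: np.ndarray, codes: np.ndarray, theta: np.ndarray,
           n_groups: int) -> np.ndarray:
    """Partial group-demeaning GLS transform: subtract ``theta_g`` times
    the group mean from every observation of group ``g``."""
    arr2 = arr if arr.ndim == 2 else arr[:, None]
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.zeros((n_groups, arr2.shape[1]))
    np.add.at(sums, codes, arr2)
    means = sums / counts[:, None]
    out = arr2 - theta[codes, None] * means[codes]
    return out if arr.ndim == 2 else out[:, 0]


@dataclass
class RandomInterceptFit:
    """ML fit of the one-random-intercept linear mixed model."""

    beta: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    exog_names: list[str]
    sigma2: float
    tau2: float
    llf: float
    aic: float
    nobs: int
    converged: bool

    def coef(self, term: str) -> float:
        return float(self.beta[self.exog_names.index(term)])

    def tvalue(self, term: str) -> float:
        return float(self.tvalues[self.exog_names.index(term)])


def fit_random_intercept(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                         exog_names: Sequence[str] | None = None,
                         ) -> RandomInterceptFit:
    """Maximum-likelihood fit by profiling the variance ratio.

    For a fixed ratio ``lam = tau^2/sigma^2`` the GLS solution and the
    residual variance are closed-form; the concentrated log-likelihood
    is maximised over ``log lam`` by bounded scalar optimisation, with
    the boundary ``lam = 0`` checked explicitly.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    n_groups = int(codes.max()) + 1
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if n_groups < 2:
        raise ModelError("random intercept needs >= 2 participants")
    if exog_names is None:
        exog_names = [f"x{j}" for j in range(p)]

    def profile(lam: float):
        theta = 1.0 - 1.0 / np.sqrt(1.0 + counts * lam)
        Xw = whiten(X, codes, theta, n_groups)
        yw = whiten(y, codes, theta, n_groups)
        XtX = Xw.T @ Xw
        try:
            beta = np.linalg.solve(XtX, Xw.T @ yw)
        except np.linalg.LinAlgError:
            return None
        rss = float(np.sum((yw - Xw @ beta) ** 2))
        if rss <= n * 1e-12:  # zero-variance outcome: model degenerate
            return None
        sigma2 = rss / n
        llf = (-0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
               - 0.5 * float(np.sum(np.log1p(counts * lam))))
        return llf, beta, sigma2, XtX

    res0 = profile(0.0)
    opt = optimize.minimize_scalar(
        lambda u: (lambda r: np.inf if r is None else -r[0])(profile(np.exp(u))),
        bounds=(-15.0, 8.0), method="bounded",
        options={"xatol": 1e-8})
    best_lam, best = 0.0, res0
    if opt.success and np.isfinite(opt.fun):
        res_opt = profile(float(np.exp(opt.x)))
        if res_opt is not None and (best is None or res_opt[0] > best[0]):
            best_lam, best = float(np.exp(opt.x)), res_opt
    if best is None:
        raise ConvergenceError("degenerate fit (singular design or zero variance)")
    llf, beta, sigma2, XtX = best
    cov = sigma2 * np.linalg.inv(XtX)
    bse = np.sqrt(np.diag(cov))
    aic = -2.0 * llf + 2.0 * (p + 2)  # fixed effects + sigma^2 + tau^2
    return RandomInterceptFit(beta=beta, bse=bse, tvalues=beta / bse,
                              exog_names=list(exog_names), sigma2=sigma2,
                              tau2=best_lam * sigma2, llf=llf, aic=aic,
                              nobs=n, converged=True)


# ------------------------------------------------------------- channel fits
@dataclass
class FitResult:
    """One channel's fit plus what is needed to test its terms."""

    channel: str
    band: str
    spec: ModelSpec
    fit: RandomInterceptFit
    _df: pd.DataFrame = field(repr=False)

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def llf(self) -> float:
        return self.fit.llf

    @property
    def n_windows(self) -> int:
        return self.fit.nobs // 1

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.fit.exog_names,
                             "estimate": self.fit.beta,
                             "se": self.fit.bse,
                             "T": self.fit.tvalues})

    def effect_test(self, term: str) -> tuple[float, int, float]:
        """Likelihood-ratio test of ``term`` (with its dependents) against
        the nested model; returns ``(chi2, df, p)``."""
        return effect_test(self, term)


def _subset(table: pd.DataFrame, channel: str, band: str) -> pd.DataFrame:
    df = table[(table["channel"] == channel) & (table["band"] == band)]
    if df.empty:
        raise ModelError(f"no rows for channel {channel!r}, band {band!r}")
    return df


def _group_codes(df: pd.DataFrame) -> np.ndarray:
    codes, _ = pd.factorize(df["participant"], sort=True)
    return codes


def fit_channel(table: pd.DataFrame, channel: str, band: str,
                spec: ModelSpec) -> FitResult:
    """ML mixed-model fit for one channel and band."""
    df = _subset(table, channel, band)
    codes = _group_codes(df)
    if codes.max() + 1 < 2:
        raise ModelError("a single participant cannot identify the random intercept")
    for term in spec.fixed_terms:
        for comp in _components(term):
            if comp in FACTOR_CODING:
                col, _ = FACTOR_CODING[comp]
                if df[col].nunique() < 2:
                    raise ModelError(
                        f"factor {comp} has a single level in the data")
    X, names = design_matrix(df, spec)
    y = df["power"].to_numpy(float)
    fit = fit_random_intercept(y, X, codes, names)
    return FitResult(channel=channel, band=band, spec=spec, fit=fit, _df=df)


def lrt_pvalue(chi2: float, dof: int) -> float:
    """Upper-tail chi-square p-value of a likelihood-ratio statistic."""
    if dof < 1:
        raise ModelError("LRT needs at least 1 degree of freedom")
    if chi2 < 0:
        raise ModelError("chi-square statistic cannot be negative")
    return float(stats.chi2.sf(chi2, dof)) if chi2 > 0 else 1.0


def effect_test(result: FitResult, term: str) -> tuple[float, int, float]:
    if term not in result.spec.fixed_terms:
        raise ModelError(f"term {term!r} not in fitted model")
    nested_spec = result.spec.drop(term)
    df = result._df
    codes = _group_codes(df)
    Xn, names_n = design_matrix(df, nested_spec)
    nested = fit_random_intercept(df["power"].to_numpy(float), Xn, codes, names_n)
    chi2 = max(0.0, 2.0 * (result.fit.llf - nested.llf))
    dof = result.spec.n_fixed_params - nested_spec.n_fixed_params
    return chi2, dof, lrt_pvalue(chi2, dof)


def select_model(table: pd.DataFrame, reference_channel: str, band: str,
                 ladder: Sequence[ModelSpec] | None = None,
                 margin: float = 2.0) -> ModelSpec:
    """AIC model selection at an a-priori reference channel.

    Returns the simplest candidate whose AIC is within ``margin`` of the
    ladder minimum (equal-AIC ties go to the model with fewer
    parameters, i.e. the earlier ladder entry).
    """
    if ladder is None:
        ladder = default_ladder()
    aics = []
    for spec in ladder:
        try:
            aics.append(fit_channel(table, reference_channel, band, spec).aic)
        except (ModelError, ConvergenceError) as exc:
            logger.warning("candidate %s failed: %s", spec.describe(), exc)
            aics.append(np.inf)
    if not np.isfinite(aics).any():
        raise ConvergenceError("every candidate model failed to fit")
    best = float(np.min(aics))
    for spec, aic in zip(ladder, aics):
        if aic <= best + margin:
            return spec
    raise AssertionError("unreachable")


@dataclass
class TopoStatMap:
    """Per-channel statistic values for one model parameter."""

    term: str
    channels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.channels),):
            raise ModelError("one value per channel required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "T": self.values})


@dataclass
class ChannelFits:
    """All per-channel fits of one band under a common model."""

    band: str
    spec: ModelSpec
    fits: dict[str, FitResult]
    failed: list[str]

    def tmap(self, term: str) -> TopoStatMap:
        channels = list(self.fits)
        vals = [self.fits[c].fit.tvalue(term) for c in channels]
        return TopoStatMap(term, channels, np.array(vals))

    def tmaps(self) -> dict[str, TopoStatMap]:
        terms = next(iter(self.fits.values())).fit.exog_names
        return {t: self.tmap(t) for t in terms if t != "Intercept"}


def fit_all_channels(table: pd.DataFrame, band: str,
                     spec: ModelSpec,
                     max_failed_fraction: float = 0.1) -> ChannelFits:
    """The same mixed model on every channel independently."""
    channels = list(pd.unique(table.loc[table["band"] == band, "channel"]))
    if not channels:
        raise ModelError(f"no channels for band {band!r}")
    fits, failed = {}, []
    for ch in channels:
        try:
            fits[ch] = fit_channel(table, ch, band, spec)
        except (ModelError, ConvergenceError) as exc:
            logger.warning("channel %s excluded: %s", ch, exc)
            failed.append(ch)
    if len(failed) > max_failed_fraction * len(channels):
        raise ConvergenceError(
            f"{len(failed)}/{len(channels)} channels failed to fit "
            "— data pathology")
    return ChannelFits(band=band, spec=spec, fits=fits, failed=failed)
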