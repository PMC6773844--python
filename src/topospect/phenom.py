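"""Phenomenology instruments and small-sample behavioural statistics.

Covers the study's self-report side: Greyson NDE-scale scoring (16
ordinal items, total 0-32, NDE cut-off >= 7), SHSS:C hypnotisability
categories, Memory Characteristics Questionnaire totals, 100-mm visual
analogue scales, elapsed-years descriptives, and paired Wilcoxon
signed-rank tests with the normal-approximation Z, two-sided p and the
effect size r = Z / sqrt(N) (N counting both paired observations).

With five pairs an exact two-sided signed-rank p cannot fall below
1/16 = 0.0625, so printed p-values near 0.04 in studies of this size
necessarily come from the normal approximation; both are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


def normal_p_from_z(z: float) -> float:
    """Two-sided normal-approximation p-value: ``2 * (1 - Phi(|Z|))``."""
    return float(min(2.0 * stats.norm.sf(abs(z)), 1.0))


def effect_size_r(z: float, n_pairs: int) -> float:
    """Effect size ``r = Z / sqrt(N)`` with N counting both paired
    observations (``N = 2 * n_pairs``)."""
    if n_pairs < 1:
        raise ValidationError("need at least one pair")
    return float(z / math.sqrt(2 * n_pairs))


@dataclass
class WilcoxonResult:
    W: float                 # signed-rank statistic (sum of positive ranks)
    Z: float                 # normal approximation with tie correction
    p_two_sided: float       # 2 * (1 - Phi(|Z|))
    p_exact: float | None    # exact two-sided p (None when zeros dropped all)
    r: float                 # Z / sqrt(N), N = 2 * n_pairs
    n_pairs: int
    n_used: int              # pairs remaining after zero differences dropped
    degenerate: bool = False


def wilcoxon_signed_rank(x, y, zero_method: str = "wilcox",
                         continuity: bool = False) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test with normal-approximation Z.

    ``zero_method="wilcox"`` drops zero differences before ranking (the
    default); ``"pratt"`` keeps them in the ranking and then drops their
    ranks.  ``continuity`` applies the 0.5 correction to |W - mu| (off by
    default).  The sign of Z follows ``x - y``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D samples")
    n_pairs = len(x)
    if n_pairs < 3:
        raise ValidationError("need at least 3 pairs")
    d = x - y
    if zero_method == "wilcox":
        d_used = d[d != 0]
        ranks = stats.rankdata(np.abs(d_used)) if len(d_used) else np.array([])
    elif zero_method == "pratt":
        ranks_all = stats.rankdata(np.abs(d))
        keep = d != 0
        d_used = d[keep]
        ranks = ranks_all[keep]
    else:
        raise ValidationError(f"unknown zero_method {zero_method!r}")
    n = len(d_used)
    if n == 0:
        return WilcoxonResult(W=0.0, Z=0.0, p_two_sided=1.0, p_exact=1.0,
                              r=0.0, n_pairs=n_pairs, n_used=0, degenerate=True)

    w_plus = float(ranks[d_used > 0].sum())
    if zero_method == "pratt":
        n_zero = n_pairs - n
        mu = (n_pairs * (n_pairs + 1) - n_zero * (n_zero + 1)) / 4.0
        var = (n_pairs * (n_pairs + 1) * (2 * n_pairs + 1)
               - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the magnitudes actually ranked
    _, tie_counts = np.unique(np.abs(d_used), return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return WilcoxonResult(W=w_plus, Z=0.0, p_two_sided=1.0, p_exact=1.0,
                              r=0.0, n_pairs=n_pairs, n_used=n, degenerate=True)
    diff = w_plus - mu
    if continuity:
        diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
    z = diff / math.sqrt(var)
    p = normal_p_from_z(z)
    p_exact = _exact_signed_rank_p(np.abs(d_used) * np.sign(d_used))
    r = effect_size_r(z, n_pairs)
    return WilcoxonResult(W=w_plus, Z=float(z), p_two_sided=p,
                          p_exact=p_exact, r=r, n_pairs=n_pairs,
                          n_used=n)


def _exact_signed_rank_p(d: np.ndarray, max_n: int = 16) -> float | None:
    """Exact two-sided p by enumerating all sign assignments (small n)."""
    n = len(d)
    if n == 0:
        return 1.0
    if n > max_n:
        return None
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    obs_dev = abs(w_obs - mu)
    count = 0
    for signs in product((0.0, 1.0), repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w - mu) >= obs_dev - 1e-12:
            count += 1
    return count / 2.0**n


# ----------------------------------------------------------- questionnaires
def greyson_total(items) -> dict:
    """Greyson NDE-scale total and NDE classification (cut-off 7/32)."""
    items = list(items)
    if len(items) != 16:
        raise ValidationError(f"expected 16 items, got {len(items)}")
    if any(i not in (0, 1, 2) for i in items):
        raise ValidationError("Greyson items must be 0, 1 or 2")
    total = int(sum(items))
    return {"total": total, "is_nde": total >= 7}


def shss_category(score: int) -> str:
    """SHSS:C hypnotisability band: low (<=4), medium (5-7), high (>=8)."""
    if not 0 <= score <= 12:
        raise ValidationError(f"SHSS score {score} outside 0-12")
    if score <= 4:
        return "low"
    if score <= 7:
        return "medium"
    return "high"


def mcq_total(items) -> int:
    """Memory Characteristics Questionnaire total (16 Likert items, 1-7)."""
    items = list(items)
    if len(items) != 16:
        raise ValidationError(f"expected 16 items, got {len(items)}")
    if any(not 1 <= i <= 7 for i in items):
        raise ValidationError("MCQ items must lie in [1, 7]")
    return int(sum(items))


def vas_from_mm(position_mm: float) -> float:
    """Visual-analogue scale: cursor position on a 100-mm rule -> 0-10."""
    if not 0 <= position_mm <= 100:
        raise ValidationError(f"VAS position {position_mm} outside [0, 100] mm")
    return position_mm / 10.0


def elapsed_years(table: pd.DataFrame) -> dict:
    """Years between each participant's original event and the session:
    per-participant differences plus median and (min, max) range.

    Expects columns ``age`` and ``age_at_nde``.
    """
    age = table["age"].to_numpy(float)
    age_at = table["age_at_nde"].to_numpy(float)
    if (age_at > age).any():
        raise ValidationError("age_at_nde exceeds current age")
    diff = age - age_at
    return {"per_participant": diff.tolist(),
            "median": float(np.median(diff)),
            "range": (float(diff.min()), float(diff.max()))}
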