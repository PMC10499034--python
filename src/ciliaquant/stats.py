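"""Replicate aggregation and the statistical procedures applied to pipeline
outputs: technical-replicate averaging, ROUT outlier exclusion (Q-level FDR),
Brown–Forsythe + Welch heteroscedastic ANOVA, Dunnett's T3 pairwise
comparisons via the studentized maximum modulus, the one-sample t-test, and
densitometry normalization.

The ROUT method (Motulsky & Brown 2006), specialized to a one-sample
location fit: the robust center is the median, the robust scale (RSDR) is
the 68.27th percentile of absolute residuals with the N/(N−K) small-sample
correction (K=1), residual t statistics get two-sided p-values from the t
distribution with N−K df, and outliers are flagged by a
Benjamini–Hochberg-style step-up test at FDR level Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, InvalidParameterError, UndefinedStatisticError

# ---------------------------------------------------------------------------
# replicate table


def validate_replicate_table(table: pd.DataFrame) -> None:
    required = {"condition", "bio_rep", "tech_rep", "value"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"replicate table missing columns {sorted(missing)}")
    if table.duplicated(["condition", "bio_rep", "tech_rep"]).any():
        raise InvalidInputError("(condition, bio_rep, tech_rep) must be unique")


def replicate_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of the technical replicates for each biological replicate."""
    validate_replicate_table(table)
    if table.empty:
        raise InvalidInputError("replicate table is empty")
    out = (
        table.groupby(["condition", "bio_rep"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# ROUT outlier exclusion


@dataclass
class RoutResult:
    kept: np.ndarray
    excluded: np.ndarray
    excluded_indices: np.ndarray
    q: float


def rout_exclude(values: Sequence[float], q: float = 0.02) -> RoutResult:
    """Flag outliers among per-bio-rep means at FDR level ``q``.

    Fewer than 3 values: nothing is excluded.  A zero RSDR with nonzero
    residuals (a zero-spread core plus deviants) flags every nonzero
    residual.
    """
    if not (0.0 < q < 0.5):
        raise InvalidParameterError("q must be in (0, 0.5)")
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        return RoutResult(values.copy(), values[:0], np.array([], int), q)

    resid = values - np.median(values)
    absr = np.abs(resid)
    # linear-interpolation percentile; N/(N-K) small-sample correction, K=1
    rsdr = float(np.percentile(absr, 68.27)) * n / (n - 1)
    if rsdr == 0.0:
        p = np.where(absr > 0, 0.0, 1.0)
    else:
        t = absr / rsdr
        p = 2.0 * sps.t.sf(t, df=n - 1)

    order = np.argsort(p, kind="stable")
    flagged = np.zeros(n, dtype=bool)
    # BH step-up over the ascending p-values
    thresholds = q * (np.arange(1, n + 1)) / n
    below = p[order] <= thresholds
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        flagged[order[: k + 1]] = True
    idx = np.nonzero(flagged)[0]
    return RoutResult(values[~flagged], values[flagged], idx, q)


# ---------------------------------------------------------------------------
# Welch / Brown-Forsythe ANOVA


@dataclass
class WelchAnovaResult:
    statistic: float  # Welch F*
    df1: float
    df2: float
    p_value: float
    brown_forsythe_statistic: float
    brown_forsythe_df1: float
    brown_forsythe_df2: float
    brown_forsythe_p: float


def _check_groups(groups: Sequence[Sequence[float]]) -> List[np.ndarray]:
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if g.size < 2:
            raise InvalidInputError("every group needs n ≥ 2")
    return arrs


def welch_anova(groups: Sequence[Sequence[float]]) -> WelchAnovaResult:
    """Welch's heteroscedastic F* with the Brown–Forsythe companion test.

    Identical groups return statistic 0 with p = 1.  A zero-variance group
    in otherwise non-identical data is an error (the weights are undefined).
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    n = np.array([g.size for g in arrs], dtype=float)
    means = np.array([g.mean() for g in arrs])
    variances = np.array([g.var(ddof=1) for g in arrs])

    if np.all(variances == 0):
        if np.all(means == means[0]):
            return WelchAnovaResult(0.0, k - 1.0, math.inf, 1.0,
                                    0.0, k - 1.0, math.inf, 1.0)
        raise UndefinedStatisticError("zero within-group variance with unequal means")
    if np.any(variances == 0):
        raise UndefinedStatisticError("a group has zero variance; Welch weights undefined")

    w = n / variances
    W = w.sum()
    mw = (w * means).sum() / W
    num = (w * (means - mw) ** 2).sum() / (k - 1)
    lam = ((1 - w / W) ** 2 / (n - 1)).sum()
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f_star = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(sps.f.sf(f_star, df1, df2))

    # Brown-Forsythe test of equal means (variance-weighted denominator)
    N = n.sum()
    grand = np.concatenate(arrs).mean()
    bf_num = (n * (means - grand) ** 2).sum()
    bf_den_terms = (1 - n / N) * variances
    bf_den = bf_den_terms.sum()
    if bf_den == 0:
        bf_stat, bf_df2, bf_p = 0.0, math.inf, 1.0
    else:
        bf_stat = bf_num / bf_den
        c = bf_den_terms / bf_den
        bf_df2 = 1.0 / ((c**2 / (n - 1)).sum())
        bf_p = float(sps.f.sf(bf_stat, k - 1.0, bf_df2))
    return WelchAnovaResult(
        float(f_star), df1, float(df2), p,
        float(bf_stat), k - 1.0, float(bf_df2), float(bf_p),
    )


# ---------------------------------------------------------------------------
# Dunnett's T3 (studentized maximum modulus)


@lru_cache(maxsize=8)
def _gauss_legendre(order: int):
    return np.polynomial.legendre.leggauss(order)


def smm_cdf(x: float, m: int, df: float, order: int = 200) -> float:
    """P(max of m independent |t_df| variates ≤ x), the studentized maximum
    modulus distribution with common denominator chi.

    Evaluated as E[(2Φ(xW) − 1)^m] over W = χ_df/√df by Gauss–Legendre
    quadrature on the central mass of W (absolute accuracy well below 1e-6).
    """
    if x <= 0:
        return 0.0
    if m < 1:
        raise InvalidParameterError("family size m must be ≥ 1")
    chi = sps.chi(df=df, scale=1.0 / math.sqrt(df))
    lo, hi = chi.ppf(1e-12), chi.isf(1e-12)
    nodes, weights = _gauss_legendre(order)
    w_nodes = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    integrand = (2.0 * sps.norm.cdf(x * w_nodes) - 1.0) ** m * chi.pdf(w_nodes)
    return float(np.clip(0.5 * (hi - lo) * np.sum(weights * integrand), 0.0, 1.0))


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    t3_statistic: float
    df: float
    p_adjusted: float
    p_unadjusted: float


def dunnett_t3(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    comparisons: str = "all-pairs",
    control: int = 0,
) -> List[PairwiseComparison]:
    """Dunnett's T3 multiple comparisons for unequal variances.

    Each comparison uses a Welch-type t with Welch–Satterthwaite df; the
    adjusted p-value comes from the studentized maximum modulus with family
    size equal to the number of comparisons.  ``comparisons`` is
    ``"all-pairs"`` or ``"vs-control"`` (with ``control`` the index of the
    control group).
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if comparisons == "all-pairs":
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    elif comparisons == "vs-control":
        if not (0 <= control < k):
            raise InvalidParameterError("control index out of range")
        pairs = [(control, j) for j in range(k) if j != control]
    else:
        raise InvalidParameterError("comparisons must be 'all-pairs' or 'vs-control'")
    m = len(pairs)

    out = []
    for i, j in pairs:
        a, b = arrs[i], arrs[j]
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        diff = a.mean() - b.mean()
        se2 = va + vb
        if se2 == 0:
            t_stat, df, p_un, p_adj = 0.0, a.size + b.size - 2.0, 1.0, 1.0
        else:
            t_stat = diff / math.sqrt(se2)
            df = se2**2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
            p_un = float(2.0 * sps.t.sf(abs(t_stat), df))
            p_adj = float(np.clip(1.0 - smm_cdf(abs(t_stat), m, df), 0.0, 1.0))
            p_adj = max(p_adj, p_un)  # guards quadrature round-off at m == 1
        out.append(
            PairwiseComparison(labels[i], labels[j], float(diff), float(t_stat),
                               float(df), p_adj, p_un)
        )
    return out


# ---------------------------------------------------------------------------
# one-sample t and densitometry


def one_sample_t(values: Sequence[float], mu0: float) -> Tuple[float, float, float]:
    """Two-sided one-sample t-test of mean(values) against mu0."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidInputError("one-sample t needs n ≥ 2")
    sd = values.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("zero variance; t statistic undefined")
    n = values.size
    t = (values.mean() - mu0) / (sd / math.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return float(t), float(n - 1), p


def densitometry_normalize(
    target_signal: float, loading_signal: float, wt_reference: float
) -> float:
    """Loading-control-normalized band intensity relative to the WT lane.

    (target/loading) / wt_reference, where ``wt_reference`` is the WT lane's
    own loading-normalized value from the same blot.
    """
    if loading_signal <= 0 or wt_reference <= 0:
        raise InvalidParameterError("loading_signal and wt_reference must be > 0")
    return (target_signal / loading_signal) / wt_reference
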