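"""Two-group one-sided moderated t-tests with empirical-Bayes shrinkage.

Per-protein residual variances s_g^2 (with common residual df d) are
shrunk toward a prior (d0, s0^2) estimated from all proteins by the
method of moments on log variances: under the scaled-inverse-chi-square
hierarchy, e_g = ln s_g^2 - psi(d/2) + ln(d/2) has mean ln s0^2 +
psi(d0/2) - ln(d0/2) and excess variance trigamma(d0/2) beyond the
sampling term trigamma(d/2); inverting the trigamma gives d0.  The
moderated statistic

    t~_g = (meanA - meanB) / (s~_g * sqrt(1/nA + 1/nB)),
    s~_g^2 = (d0*s0^2 + d*s_g^2) / (d0 + d)

follows a t distribution with d0 + d degrees of freedom under the null,
from which one-sided p-values are taken in the requested direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
from scipy.special import polygamma, psi

from .iofmt import logger
from .preprocess import ContractError

_EPS = 1e-8


@dataclass
class GroupFit:
    """Per-protein summary of a two-group fit (shared residual df)."""

    group_ids: list[str]
    fc: np.ndarray       # log2 fold change, meanA - meanB
    s2: np.ndarray       # pooled within-group variance
    df: int              # residual df, nA + nB - 2
    n_a: int
    n_b: int


@dataclass
class Prior:
    d0: float            # prior df (may be inf)
    s02: float           # prior variance


@dataclass
class ComparisonResult:
    """One-sided moderated test results for one contrast."""

    group_ids: list[str]
    fc: np.ndarray
    s2: np.ndarray
    s2_post: np.ndarray
    t_mod: np.ndarray
    p: np.ndarray        # one-sided, in the requested direction
    direction: str       # "A_greater" or "B_greater"
    prior: Prior
    df_total: float


def fit_groups(
    values_a: np.ndarray, values_b: np.ndarray, group_ids: list[str],
) -> GroupFit:
    """Per-protein fold change and pooled variance for two complete groups."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    n_a, n_b = values_a.shape[1], values_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ContractError(
            f"each group needs >= 2 columns (got {n_a} and {n_b})"
        )
    if np.isnan(values_a).any() or np.isnan(values_b).any():
        raise ContractError("fit_groups requires complete matrices")
    fc = values_a.mean(axis=1) - values_b.mean(axis=1)
    ss_a = ((values_a - values_a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_b = ((values_b - values_b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n_a + n_b - 2
    s2 = (ss_a + ss_b) / df
    return GroupFit(group_ids=list(group_ids), fc=fc, s2=s2, df=df,
                    n_a=n_a, n_b=n_b)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection on x in (1e-3, 1e3)."""
    lo, hi = 1e-3, 1e3
    tri = lambda x: float(polygamma(1, x))
    if y >= tri(lo):
        return lo
    if y <= tri(hi):
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if tri(mid) > y:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return 0.5 * (lo + hi)


def estimate_prior(s2: np.ndarray, df: int) -> Prior:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Zero or non-finite variances are excluded from the moment equations
    (they carry no information about the prior on the log scale).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise ContractError("all residual variances are zero or non-finite")
    if ok.sum() < 50:
        logger.warning(
            "estimate_prior: only %d usable variances; the prior fit "
            "may be unstable", int(ok.sum()),
        )
    e = np.log(s2[ok]) - psi(df / 2.0) + math.log(df / 2.0)
    n = e.size
    e_bar = float(e.mean())
    if n < 2:
        return Prior(d0=math.inf, s02=float(math.exp(e_bar)))
    var_e = float(((e - e_bar) ** 2).mean() * n / (n - 1))
    target = var_e - float(polygamma(1, df / 2.0))
    if target <= _EPS:
        return Prior(d0=math.inf, s02=float(math.exp(e_bar)))
    half_d0 = _trigamma_inverse(target)
    d0 = 2.0 * half_d0
    s02 = math.exp(e_bar + float(psi(half_d0)) - math.log(half_d0))
    return Prior(d0=d0, s02=s02)


def moderated_test(
    fit: GroupFit, prior: Prior, direction: str = "A_greater",
) -> ComparisonResult:
    """One-sided moderated t-test for one contrast.

    ``direction="A_greater"`` tests enrichment in group A (upper tail of
    the moderated statistic); ``"B_greater"`` the opposite tail.
    """
    if direction not in ("A_greater", "B_greater"):
        raise ContractError(f"unknown direction {direction!r}")
    d0, s02, d = prior.d0, prior.s02, fit.df
    if math.isinf(d0):
        s2_post = np.full_like(fit.s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + d * fit.s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / fit.n_a + 1.0 / fit.n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, fit.fc / se, np.sign(fit.fc) * np.inf)
    t_mod = np.where(fit.fc == 0, 0.0, t_mod)
    stat = t_mod if direction == "A_greater" else -t_mod
    if math.isinf(df_total):
        p = scipy.stats.norm.sf(stat)
    else:
        p = scipy.stats.t.sf(stat, df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return ComparisonResult(
        group_ids=list(fit.group_ids), fc=fit.fc, s2=fit.s2,
        s2_post=s2_post, t_mod=t_mod, p=p, direction=direction,
        prior=prior, df_total=df_total,
    )


def run_comparison(
    values_a: np.ndarray, values_b: np.ndarray, group_ids: list[str],
    prior: Prior | None = None,
) -> tuple[ComparisonResult, ComparisonResult]:
    """Fit one contrast and return both one-sided results (A>, B>).

    The prior is estimated from this comparison's variances unless one is
    supplied.
    """
    fit = fit_groups(values_a, values_b, group_ids)
    if prior is None:
        prior = estimate_prior(fit.s2, fit.df)
    return (
        moderated_test(fit, prior, "A_greater"),
        moderated_test(fit, prior, "B_greater"),
    )
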