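"""Univariable MR estimators and diagnostics.

All estimators operate on harmonized instruments and express the causal
effect on the log-odds scale per SD of exposure.  The IVW estimator is
the primary method; weighted median, Egger regression, Cochran's Q, and
leave-one-out provide robustness and diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import CollinearityError, ComputationError, InputError, InsufficientInstrumentsError
from .sumstats import HarmonizedIV

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MRResult:
    """One estimator's output for one exposure-outcome pair."""

    method: str
    n_iv: int
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _finish(method, n_iv, beta, se, pvalue, ci_half=None, **extra) -> MRResult:
    half = Z95 * se if ci_half is None else ci_half
    return MRResult(
        method=method, n_iv=n_iv, beta=beta, se=se, pvalue=float(pvalue),
        or_=math.exp(beta), ci_low=math.exp(beta - half), ci_high=math.exp(beta + half),
        **extra,
    )


def _ratios(ivs: Sequence[HarmonizedIV]) -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios and their first-order delta-method SEs."""
    be = np.array([iv.beta_exp for iv in ivs], dtype=float)
    bo = np.array([iv.beta_out for iv in ivs], dtype=float)
    so = np.array([iv.se_out for iv in ivs], dtype=float)
    if np.any(be == 0):
        raise ComputationError("beta_exp = 0 yields an undefined Wald ratio")
    return bo / be, so / np.abs(be)


def wald_ratio(iv: HarmonizedIV) -> MRResult:
    """Single-variant causal estimate beta_out / beta_exp."""
    if iv.beta_exp == 0:
        raise ComputationError(f"{iv.variant_id}: beta_exp = 0, Wald ratio undefined")
    beta = iv.beta_out / iv.beta_exp
    se = iv.se_out / abs(iv.beta_exp)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return _finish("wald", 1, beta, se, p)


def ivw(ivs: Sequence[HarmonizedIV], effects_model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted combination of Wald ratios.

    Point estimate is identical under both effects models; the
    multiplicative-random model inflates the SE by max(1, sqrt(Q/(k-1))).
    """
    if not ivs:
        raise InputError("ivw requires at least one instrument")
    if effects_model not in ("fixed", "multiplicative_random"):
        raise InputError(f"unknown effects_model {effects_model!r}")
    r, s = _ratios(ivs)
    w = 1.0 / s ** 2
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    k = len(ivs)
    q = float(np.sum(w * (r - beta) ** 2))
    q_df, q_p = (k - 1, float(stats.chi2.sf(q, k - 1))) if k >= 2 else (None, None)
    if effects_model == "multiplicative_random" and k >= 2:
        se *= max(1.0, math.sqrt(q / (k - 1)))
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return _finish("ivw", k, beta, se, p, q_stat=q if k >= 2 else None, q_df=q_df, q_p=q_p)


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(r)
    r, w = r[order], w[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(ivs: Sequence[HarmonizedIV], n_boot: int = 1000, seed: int | None = None) -> MRResult:
    """Weighted-median estimator (consistent if valid IVs carry >= half the weight).

    SE comes from a parametric bootstrap: each ratio is resampled from
    Normal(r_j, se_wald_j) ``n_boot`` times with the given seed, and the SD of
    the re-estimated medians is reported.  Bit-reproducible given (n_boot, seed).
    """
    if len(ivs) < 3:
        raise InsufficientInstrumentsError("weighted_median requires >= 3 instruments")
    if seed is None:
        raise InputError("weighted_median requires an explicit seed")
    r, s = _ratios(ivs)
    w = 1.0 / s ** 2
    beta = _weighted_median(r, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=r, scale=s, size=(n_boot, len(r)))
    boot = np.array([_weighted_median(d, w) for d in draws])
    se = float(np.std(boot, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return _finish("weighted_median", len(ivs), beta, se, p)


def egger(ivs: Sequence[HarmonizedIV]) -> MRResult:
    """MR-Egger: weighted regression of beta_out on beta_exp with an intercept.

    The intercept estimates average directional pleiotropy.  SEs are scaled
    by max(1, sqrt(Q/(k-2))); p-values use the t distribution with k-2 df.
    Instruments must be oriented beta_exp >= 0 upstream.
    """
    k = len(ivs)
    if k < 3:
        raise InsufficientInstrumentsError("egger requires >= 3 instruments")
    be = np.array([iv.beta_exp for iv in ivs], dtype=float)
    bo = np.array([iv.beta_out for iv in ivs], dtype=float)
    so = np.array([iv.se_out for iv in ivs], dtype=float)
    if np.allclose(be, be[0]):
        raise CollinearityError("all beta_exp identical; Egger slope not identifiable")
    w = 1.0 / so ** 2
    X = np.column_stack([np.ones(k), be])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ bo)
    resid = bo - X @ coef
    q = float(np.sum(w * resid ** 2))
    df = k - 2
    scale = max(1.0, math.sqrt(q / df))
    cov = np.linalg.inv(xtwx) * scale ** 2
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    intercept, slope = float(coef[0]), float(coef[1])
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), df)
    half = stats.t.ppf(0.975, df) * se_slope
    return _finish(
        "egger", k, slope, se_slope, p_slope, ci_half=half,
        egger_intercept=intercept, egger_intercept_p=p_int,
        q_stat=q, q_df=df, q_p=float(stats.chi2.sf(q, df)),
    )


def cochran_q(ivs: Sequence[HarmonizedIV], beta_ref: float) -> tuple[float, int, float]:
    """Heterogeneity of Wald ratios around a reference causal estimate."""
    if len(ivs) < 2:
        raise InsufficientInstrumentsError("cochran_q requires >= 2 instruments")
    r, s = _ratios(ivs)
    w = 1.0 / s ** 2
    q = float(np.sum(w * (r - beta_ref) ** 2))
    df = len(ivs) - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(ivs: Sequence[HarmonizedIV], effects_model: str = "multiplicative_random") \
        -> tuple[list[tuple[str, MRResult]], bool]:
    """IVW re-estimated with each instrument excluded in turn.

    The dominance flag is raised when any exclusion flips the sign of beta or
    moves the 95% CI across OR = 1 relative to the full-set estimate.
    """
    if len(ivs) < 3:
        raise InsufficientInstrumentsError("leave_one_out requires >= 3 instruments")
    full = ivw(ivs, effects_model)
    full_crosses = full.ci_low <= 1.0 <= full.ci_high
    results = []
    flag = False
    for i, iv in enumerate(ivs):
        sub = list(ivs[:i]) + list(ivs[i + 1:])
        res = ivw(sub, effects_model)
        results.append((iv.variant_id, res))
        sign_flip = (res.beta > 0) != (full.beta > 0) and res.beta != 0 and full.beta != 0
        crossing_change = (res.ci_low <= 1.0 <= res.ci_high) != full_crosses
        if sign_flip or crossing_change:
            flag = True
    return results, flag
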