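"""Simulation-based pleiotropy residual-sum-of-squares testing (MR-PRESSO style).

Three stages share one simulation scheme: a global test of the weighted
leave-one-out residual sum of squares, a per-instrument outlier test with
Bonferroni correction, and a distortion test comparing raw and
outlier-corrected IVW estimates.  Every p-value is a seeded simulation
tail proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .estimators import MRResult, ivw
from .exceptions import ComputationError, InputError, InsufficientInstrumentsError
from .sumstats import HarmonizedIV

DEFAULT_N_SIM = 5000


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_p: float
    outliers: list  # (variant_id, p_raw, p_bonferroni)
    outlier_ids: list
    corrected: MRResult | None
    distortion_p: float | None
    n_sim: int
    seed: int


def _arrays(ivs: Sequence[HarmonizedIV]):
    be = np.array([iv.beta_exp for iv in ivs], dtype=float)
    se = np.array([iv.se_exp for iv in ivs], dtype=float)
    bo = np.array([iv.beta_out for iv in ivs], dtype=float)
    so = np.array([iv.se_out for iv in ivs], dtype=float)
    return be, se, bo, so


def _loo_slopes(be: np.ndarray, bo: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Zero-intercept weighted LOO slopes: IVW(fixed) fit excluding each variant.

    Works on 1-D observed arrays or (n_sim, k) simulated arrays; weights stay
    the observed 1/se_out^2 in both cases.
    """
    sxx = np.sum(w * be * be, axis=-1, keepdims=True)
    sxy = np.sum(w * be * bo, axis=-1, keepdims=True)
    return (sxy - w * be * bo) / (sxx - w * be * be)


def _simulate(ivs: Sequence[HarmonizedIV], n_sim: int, seed: int):
    """Observed and null weighted squared LOO residuals, shared by global/outlier tests."""
    if len(ivs) < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires >= 4 instruments")
    if n_sim < 1000:
        raise InputError("n_sim must be >= 1000")
    be, se, bo, so = _arrays(ivs)
    w = 1.0 / so ** 2

    slopes = _loo_slopes(be, bo, w)
    resid2_obs = w * (bo - slopes * be) ** 2
    rss_obs = float(resid2_obs.sum())

    rng = np.random.default_rng(seed)
    be_sim = rng.normal(loc=be, scale=se, size=(n_sim, be.size))
    bo_sim = rng.normal(loc=slopes * be, scale=so, size=(n_sim, be.size))
    slopes_sim = _loo_slopes(be_sim, bo_sim, w)
    resid2_sim = w * (bo_sim - slopes_sim * be_sim) ** 2
    return rss_obs, resid2_obs, resid2_sim


def presso_global(ivs: Sequence[HarmonizedIV], n_sim: int = DEFAULT_N_SIM, seed: int = 0):
    """Global pleiotropy test.

    Returns (rss_obs, global_p, per_iv_obs).  The p-value uses the add-one
    estimator, so its floor is 1/(n_sim+1).
    """
    rss_obs, resid2_obs, resid2_sim = _simulate(ivs, n_sim, seed)
    rss_sim = resid2_sim.sum(axis=1)
    global_p = (1.0 + np.count_nonzero(rss_sim >= rss_obs)) / (n_sim + 1.0)
    return rss_obs, float(global_p), resid2_obs.tolist()


def presso_outlier(ivs: Sequence[HarmonizedIV], n_sim: int = DEFAULT_N_SIM, seed: int = 0):
    """Per-instrument outlier test: (variant_id, p_raw, p_bonferroni) per IV.

    p_raw is the tail proportion of the simulated weighted squared residual
    for that IV; the Bonferroni correction multiplies by the number of IVs
    and caps at 1.
    """
    _, resid2_obs, resid2_sim = _simulate(ivs, n_sim, seed)
    k = len(ivs)
    out = []
    for j, iv in enumerate(ivs):
        p_raw = np.count_nonzero(resid2_sim[:, j] >= resid2_obs[j]) / n_sim
        out.append((iv.variant_id, float(p_raw), float(min(1.0, p_raw * k))))
    return out


def presso_distortion(
    ivs: Sequence[HarmonizedIV],
    outlier_ids: Sequence[str],
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
) -> float:
    """Distortion test for the outlier-corrected estimate.

    The distortion coefficient is (beta_raw - beta_corrected) /
    |beta_corrected| * 100; its null is rebuilt by removing random index
    sets of the same size.
    """
    if not outlier_ids:
        raise InputError("distortion test requires a nonempty outlier set")
    outset = set(outlier_ids)
    inliers = [iv for iv in ivs if iv.variant_id not in outset]
    if not inliers:
        raise ComputationError("all instruments flagged as outliers; corrected estimate undefined")
    beta_raw = ivw(ivs, "fixed").beta
    beta_corr = ivw(inliers, "fixed").beta
    if beta_corr == 0:
        raise ComputationError("corrected estimate is exactly 0; distortion coefficient undefined")
    coef_obs = (beta_raw - beta_corr) / abs(beta_corr) * 100.0

    rng = np.random.default_rng(seed)
    k, m = len(ivs), len(outset)
    coefs = np.empty(n_sim)
    ivs = list(ivs)
    for s in range(n_sim):
        drop = set(rng.choice(k, size=m, replace=False))
        sub = [iv for j, iv in enumerate(ivs) if j not in drop]
        b = ivw(sub, "fixed").beta
        coefs[s] = (beta_raw - b) / abs(b) * 100.0 if b != 0 else np.inf
    p = (1.0 + np.count_nonzero(np.abs(coefs) >= abs(coef_obs))) / (n_sim + 1.0)
    return float(p)


def run_presso(
    ivs: Sequence[HarmonizedIV],
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Global + outlier + (if needed) corrected-estimate and distortion stages."""
    rss_obs, global_p, _ = presso_global(ivs, n_sim, seed)
    per_iv = presso_outlier(ivs, n_sim, seed)
    outlier_ids = [vid for vid, _raw, p_b in per_iv if p_b < outlier_alpha]
    corrected = None
    distortion_p = None
    if outlier_ids:
        outset = set(outlier_ids)
        inliers = [iv for iv in ivs if iv.variant_id not in outset]
        if inliers:
            corrected = ivw(inliers)
            distortion_p = presso_distortion(ivs, outlier_ids, n_sim, seed)
    return PressoResult(
        rss_obs=rss_obs, global_p=global_p, outliers=per_iv,
        outlier_ids=outlier_ids, corrected=corrected,
        distortion_p=distortion_p, n_sim=n_sim, seed=seed,
    )
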