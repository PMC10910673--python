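"""Multivariable IVW: direct effects of co-instrumented exposures.

The union of instruments across a cancer's significant metabolites is
regressed jointly — outcome betas on the exposure-beta matrix, zero
intercept, weights 1/se_out^2 — giving each exposure's direct effect
conditional on the others.  Instruments missing an exposure beta are
zero-imputed (logged), a documented assumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .estimators import MRResult, Z95, _finish
from .exceptions import CollinearityError, InputError

logger = logging.getLogger(__name__)


@dataclass
class MVMRInput:
    """Instrument-by-exposure design for one outcome."""

    iv_ids: list
    exposure_ids: list
    exposure_betas: np.ndarray   # (n_iv, n_exposures)
    exposure_ses: np.ndarray     # (n_iv, n_exposures)
    outcome_betas: np.ndarray    # (n_iv,)
    outcome_ses: np.ndarray      # (n_iv,)

    def __post_init__(self):
        self.exposure_betas = np.asarray(self.exposure_betas, dtype=float)
        self.exposure_ses = np.asarray(self.exposure_ses, dtype=float)
        self.outcome_betas = np.asarray(self.outcome_betas, dtype=float)
        self.outcome_ses = np.asarray(self.outcome_ses, dtype=float)
        k, p = self.exposure_betas.shape
        if len(self.iv_ids) != k or len(self.exposure_ids) != p:
            raise InputError("MVMRInput dimensions inconsistent")
        if len(set(self.iv_ids)) != k:
            raise InputError("duplicate variant ids in MVMRInput")
        if np.any(np.all(self.exposure_betas == 0, axis=0)):
            raise InputError("an exposure column is all zeros")

    @classmethod
    def from_iv_union(cls, exposure_tables: dict, outcome_lookup: dict) -> "MVMRInput":
        """Assemble the union-of-IVs design from per-exposure instrument lists.

        ``exposure_tables`` maps exposure_id -> list of HarmonizedIV;
        ``outcome_lookup`` maps variant_id -> (beta_out, se_out).  Exposure
        betas absent for a variant are set to 0 with a logged count.
        """
        exposure_ids = sorted(exposure_tables)
        iv_ids = sorted({iv.variant_id for ivs in exposure_tables.values() for iv in ivs})
        idx = {v: i for i, v in enumerate(iv_ids)}
        k, p = len(iv_ids), len(exposure_ids)
        bx = np.zeros((k, p))
        sx = np.zeros((k, p))
        n_imputed = 0
        for j, eid in enumerate(exposure_ids):
            seen = set()
            for iv in exposure_tables[eid]:
                bx[idx[iv.variant_id], j] = iv.beta_exp
                sx[idx[iv.variant_id], j] = iv.se_exp
                seen.add(iv.variant_id)
            n_imputed += k - len(seen)
        if n_imputed:
            logger.info("MVMRInput: zero-imputed %d missing exposure beta(s)", n_imputed)
        by = np.array([outcome_lookup[v][0] for v in iv_ids])
        sy = np.array([outcome_lookup[v][1] for v in iv_ids])
        return cls(iv_ids, exposure_ids, bx, sx, by, sy)


def _check_rank(X: np.ndarray, exposure_ids) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via pivoted QR
        _q, r, piv = linalg.qr(X, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        dependent = [exposure_ids[piv[i]] for i in range(len(exposure_ids)) if i >= rank or diag[i] <= tol]
        raise CollinearityError(f"exposure matrix rank {rank} < {X.shape[1]}; dependent columns: {sorted(set(dependent))}")


def mvmr_ivw(inp: MVMRInput) -> list[tuple[str, MRResult]]:
    """Multivariable IVW direct effects, one MRResult per exposure.

    SEs use a multiplicative-random scaling by max(1, sqrt(Q/(k-p))) of the
    weighted-least-squares covariance.
    """
    X, y = inp.exposure_betas, inp.outcome_betas
    k, p = X.shape
    if k <= p + 1:
        raise InputError(f"need n_iv > n_exposures + 1 (got {k} IVs, {p} exposures)")
    _check_rank(X, inp.exposure_ids)
    w = 1.0 / inp.outcome_ses ** 2
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid ** 2))
    df = k - p
    scale = max(1.0, math.sqrt(q / df))
    cov = np.linalg.inv(xtwx) * scale ** 2
    out = []
    for j, eid in enumerate(inp.exposure_ids):
        beta, se = float(coef[j]), float(math.sqrt(cov[j, j]))
        pv = 2.0 * stats.norm.sf(abs(beta / se))
        res = _finish("mvmr_ivw", k, beta, se, pv,
                      q_stat=q, q_df=df, q_p=float(stats.chi2.sf(q, df)))
        out.append((eid, res))
    return out


def conditional_f(inp: MVMRInput) -> list[tuple[str, float]]:
    """Conditional instrument strength per exposure.

    Each exposure's instrument betas are regressed on all the others'; the
    mean of squared residuals standardized by that exposure's SEs measures
    the signal left after conditioning.  Orthogonal strong instruments give
    roughly the univariable mean F; perfectly collinear exposures give 0.
    """
    X = inp.exposure_betas
    k, p = X.shape
    if k <= p + 1:
        raise InputError(f"need n_iv > n_exposures + 1 (got {k} IVs, {p} exposures)")
    out = []
    for j, eid in enumerate(inp.exposure_ids):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            resid = xj
        else:
            coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
            resid = xj - others @ coef
        se = inp.exposure_ses[:, j]
        se = np.where(se > 0, se, np.nan)  # zero-imputed rows carry no strength information
        with np.errstate(invalid="ignore"):
            contrib = resid ** 2 / se ** 2
        cf = float(np.nanmean(contrib)) if np.any(np.isfinite(contrib)) else 0.0
        out.append((eid, cf))
    return out
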