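"""Approximate-Bayes-factor colocalization over the five configuration hypotheses.

For each locus, per-variant evidence for association with each trait is
summarized by a Wakefield asymptotic Bayes factor, and the posterior mass
over H0 (no association), H1/H2 (one trait only), H3 (two distinct causal
variants), and H4 (one shared causal variant) is computed with log-sum-exp
arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import ComputationError, InputError
from .sumstats import HarmonizedIV

#: default prior probabilities (per variant): trait-1 only, trait-2 only, shared
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
#: default prior effect SDs: quantitative trait, binary trait (log-odds)
PRIOR_SD_QUANT = 0.15
PRIOR_SD_BINARY = 0.2


@dataclass(frozen=True)
class ColocResult:
    locus_id: str
    pp: tuple  # (PP0, PP1, PP2, PP3, PP4)
    n_variants: int
    priors: tuple

    @property
    def pp4(self) -> float:
        return self.pp[4]


def wakefield_log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for association at one variant.

    With z = beta/se, V = se^2, W = prior_sd^2 and r = W/(V+W):
    log ABF = 0.5 log(1-r) + 0.5 r z^2.
    """
    if se <= 0 or prior_sd <= 0:
        raise ComputationError("se and prior_sd must be positive")
    z = beta / se
    r = prior_sd ** 2 / (se ** 2 + prior_sd ** 2)
    return 0.5 * math.log1p(-r) + 0.5 * r * z * z


def coloc_abf(
    trait1: dict,
    trait2: dict,
    priors: tuple = DEFAULT_PRIORS,
    prior_sd1: float = PRIOR_SD_QUANT,
    prior_sd2: float = PRIOR_SD_BINARY,
    locus_id: str = "locus",
) -> ColocResult:
    """Colocalization posteriors for one locus.

    ``trait1``/``trait2`` map variant_id -> (beta, se); the variant
    intersection is analyzed.  Sums over single-variant configurations give
    H1, H2, and H4; the H3 sum over ordered distinct pairs is computed as
    exp(logsum1 + logsum2) - exp(logsum12) in log space.
    """
    shared = sorted(set(trait1) & set(trait2))
    if not shared:
        raise InputError("no shared variants between traits at this locus")
    p1, p2, p12 = priors
    l1 = np.array([wakefield_log_abf(*trait1[v], prior_sd1) for v in shared])
    l2 = np.array([wakefield_log_abf(*trait2[v], prior_sd2) for v in shared])

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)

    lh0 = 0.0
    lh1 = math.log(p1) + lsum1
    lh2 = math.log(p2) + lsum2
    # sum over i != j of ABF1_i * ABF2_j
    pair_sum, sign = logsumexp([lsum1 + lsum2, lsum12], b=[1.0, -1.0], return_sign=True)
    lh3 = math.log(p1) + math.log(p2) + (pair_sum if sign > 0 else -np.inf)
    lh4 = math.log(p12) + lsum12

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(locus_id=locus_id, pp=tuple(float(x) for x in pp),
                       n_variants=len(shared), priors=tuple(priors))


def coloc_at_ivs(
    ivs: Sequence[HarmonizedIV],
    exposure_region_stats: dict,
    outcome_region_stats: dict,
    priors: tuple = DEFAULT_PRIORS,
    pp4_threshold: float = 0.5,
    window_kb: float = 500.0,
) -> tuple[list[ColocResult], dict]:
    """One colocalization per instrument locus plus an association-level summary.

    ``exposure_region_stats``/``outcome_region_stats`` map each IV's
    variant_id to the regional statistics around it (variant_id -> (beta,
    se) dicts, expected to span +-``window_kb``).  The summary reports
    whether any locus exceeds the PP4 threshold and the fraction that do.
    """
    results = []
    for iv in ivs:
        t1 = exposure_region_stats[iv.variant_id]
        t2 = outcome_region_stats[iv.variant_id]
        results.append(coloc_abf(t1, t2, priors=priors, locus_id=iv.variant_id))
    n_hit = sum(1 for r in results if r.pp4 > pp4_threshold)
    summary = {
        "any_colocalized": n_hit > 0,
        "fraction_colocalized": n_hit / len(results) if results else 0.0,
        "n_loci": len(results),
        "pp4_threshold": pp4_threshold,
    }
    return results, summary
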