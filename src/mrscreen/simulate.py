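"""Synthetic paired GWAS summary statistics with fully known truth.

The generator works directly on the summary-statistic scale: per-variant
exposure effects gamma_j (SD units) receive sampling noise at the
quantitative-trait standard error 1/sqrt(n_exp * 2 eaf (1-eaf)), and
outcome effects theta * gamma_j + alpha_j receive case-control log-odds
noise at 1/sqrt(n_out * k(1-k) * 2 eaf (1-eaf)).  Pleiotropy alpha_j can
be balanced or directional, a controllable fraction of instruments is
displaced as outliers, and a reverse mode swaps the causal arrow.  Every
draw is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InputError
from .instruments import LDPanel
from .sumstats import VariantAssociation


@dataclass(frozen=True)
class Pleiotropy:
    """Per-variant direct effects on the outcome: kind in {none, balanced, directional}."""

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(n)
        if self.kind == "balanced":
            return rng.normal(0.0, self.sd, n)
        if self.kind == "directional":
            return rng.normal(self.mean, self.sd, n)
        raise InputError(f"unknown pleiotropy kind {self.kind!r}")


@dataclass(frozen=True)
class LDBlocks:
    """Optional block LD structure: variants grouped into blocks of
    ``block_size`` with constant within-block r2 and zero between blocks."""

    block_size: int = 5
    r2_within: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    n_snps: int = 50
    n_exp: int = 14000
    n_out: int = 100000
    k_cases: float = 0.3
    theta: float = 0.0
    gamma_mean: float = 0.1
    gamma_sd: float = 0.02
    gamma_min_abs: float = 0.05
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    outlier_frac: float = 0.0
    outlier_shift: float = 0.0  # displacement of beta_out in units of se_out
    reverse: bool = False
    ld_blocks: LDBlocks | None = None
    eaf_range: tuple = (0.1, 0.5)
    noise_scale: float = 1.0  # 0 forces beta = expectation exactly (SEs still reported)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.outlier_frac < 0.5:
            raise InputError("outlier_frac must lie in [0, 0.5)")
        if not 0.0 < self.k_cases < 1.0:
            raise InputError("k_cases must lie in (0,1)")
        if self.seed is None:
            raise InputError("seed is mandatory")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters recorded before noise; sufficient for every oracle."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    outlier_ids: list
    expected_r2: np.ndarray
    eaf: np.ndarray
    variant_ids: list
    reverse: bool
    seed: int


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


def _positions(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    """Chromosome 1 layout: blocks 10 Mb apart, 10 kb spacing inside a block."""
    if cfg.ld_blocks is None:
        pos = 10_000_000 * (1 + np.arange(cfg.n_snps))
    else:
        bs = cfg.ld_blocks.block_size
        block = np.arange(cfg.n_snps) // bs
        within = np.arange(cfg.n_snps) % bs
        pos = 10_000_000 * (1 + block) + 10_000 * within
    return ["1"] * cfg.n_snps, pos.astype(int)


def _panel(cfg: SimConfig, variant_ids: Sequence[str]) -> LDPanel:
    if cfg.ld_blocks is None:
        return LDPanel.identity(variant_ids)
    n = len(variant_ids)
    mat = np.eye(n)
    bs = cfg.ld_blocks.block_size
    for i in range(n):
        for j in range(i + 1, n):
            if i // bs == j // bs:
                mat[i, j] = mat[j, i] = cfg.ld_blocks.r2_within
    return LDPanel(variant_ids, mat)


def simulate_pair(cfg: SimConfig):
    """Generate one (exposure table, outcome table, LDPanel, SyntheticTruth) draw.

    With noise SDs at their analytic values, beta_exp_j = gamma_j + e_j and
    beta_out_j = theta*gamma_j + alpha_j + u_j (+ outlier shift); in reverse
    mode the causal arrow points outcome -> exposure instead.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    vids = [f"rs{cfg.seed}_{i}" for i in range(n)]
    chroms, pos = _positions(cfg)
    eaf = rng.uniform(*cfg.eaf_range, n)
    het = 2.0 * eaf * (1.0 - eaf)

    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, n)
    # sign-preserving floor keeps every instrument genome-wide significant by design
    small = np.abs(gamma) < cfg.gamma_min_abs
    gamma[small] = np.where(gamma[small] >= 0, cfg.gamma_min_abs, -cfg.gamma_min_abs)

    alpha = cfg.pleiotropy.draw(rng, n)

    se_exp = 1.0 / np.sqrt(cfg.n_exp * het)
    se_out = 1.0 / np.sqrt(cfg.n_out * cfg.k_cases * (1.0 - cfg.k_cases) * het)

    n_outlier = int(round(cfg.outlier_frac * n))
    outlier_idx = rng.choice(n, size=n_outlier, replace=False) if n_outlier else np.array([], dtype=int)

    if not cfg.reverse:
        mean_exp = gamma
        mean_out = cfg.theta * gamma + alpha
    else:
        # SNPs act on the outcome; the exposure inherits theta-scaled effects
        mean_out = gamma
        mean_exp = cfg.theta * gamma + alpha

    beta_exp = mean_exp + cfg.noise_scale * rng.normal(0.0, se_exp)
    beta_out = mean_out + cfg.noise_scale * rng.normal(0.0, se_out)
    if n_outlier:
        beta_out[outlier_idx] += cfg.outlier_shift * se_out[outlier_idx]

    p_exp = 2.0 * stats.norm.sf(np.abs(beta_exp / se_exp))
    p_out = 2.0 * stats.norm.sf(np.abs(beta_out / se_out))
    p_exp = np.clip(p_exp, np.finfo(float).tiny, 1.0)
    p_out = np.clip(p_out, np.finfo(float).tiny, 1.0)

    ea = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n)]
    exposure = [
        VariantAssociation(
            variant_id=vids[i], effect_allele=ea[i][0], other_allele=ea[i][1],
            eaf=float(eaf[i]), beta=float(beta_exp[i]), se=float(se_exp[i]),
            pvalue=float(p_exp[i]), n=cfg.n_exp, chrom=chroms[i], pos=int(pos[i]),
        ) for i in range(n)
    ]
    outcome = [
        VariantAssociation(
            variant_id=vids[i], effect_allele=ea[i][0], other_allele=ea[i][1],
            eaf=float(eaf[i]), beta=float(beta_out[i]), se=float(se_out[i]),
            pvalue=float(p_out[i]), n=cfg.n_out, chrom=chroms[i], pos=int(pos[i]),
        ) for i in range(n)
    ]

    expected_r2 = gamma ** 2 * het / (gamma ** 2 * het + 1.0)
    truth = SyntheticTruth(
        theta=cfg.theta, gamma=gamma, alpha=alpha,
        outlier_ids=[vids[i] for i in outlier_idx],
        expected_r2=expected_r2, eaf=eaf, variant_ids=vids,
        reverse=cfg.reverse, seed=cfg.seed,
    )
    return exposure, outcome, _panel(cfg, vids), truth


def simulate_region(
    shared_causal: bool,
    n_variants: int = 200,
    z_causal: float = 12.0,
    ld_decay: float = 0.05,
    n1: int = 14000,
    n2: int = 100000,
    seed: int = 0,
):
    """Regional summary statistics for a colocalization locus.

    One causal variant per trait (the same index iff ``shared_causal``);
    marginal z-scores decay into neighbors through exp(-ld_decay * distance)
    LD correlation, with sampling noise sharing the same correlation (as
    marginal GWAS z-scores do under LD).  Returns (trait1, trait2) maps of
    variant_id -> (beta, se).
    """
    if n_variants < 10:
        raise InputError("simulate_region requires n_variants >= 10")
    rng = np.random.default_rng(seed)
    vids = [f"locus{seed}_{i}" for i in range(n_variants)]
    idx = np.arange(n_variants)
    c1 = n_variants // 2
    c2 = c1 if shared_causal else (c1 + n_variants // 3) % n_variants

    corr = np.exp(-ld_decay * np.abs(idx[:, None] - idx[None, :]))
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_variants))

    def marginal(causal_idx, n_gwas):
        z = z_causal * corr[:, causal_idx] + chol @ rng.standard_normal(n_variants)
        se = np.full(n_variants, 1.0 / math.sqrt(n_gwas))
        return {vids[i]: (float(z[i] * se[i]), float(se[i])) for i in range(n_variants)}

    return marginal(c1, n1), marginal(c2, n2)


def scenario_presets(seed: int = 0) -> dict[str, SimConfig]:
    """Named generator scenarios with documented expected pipeline behavior.

    null: theta=0, valid IVs (calibration); causal: theta=0.2 (recovery);
    balanced_pleiotropy: Egger intercept centered at 0; directional_pleiotropy:
    intercept centered at the configured mean; outliers: 10% of IVs displaced
    8 outcome SEs; weak_instruments: most SNPs fail F >= 10; reverse_causal:
    outcome drives exposure; two_cohort_replication: same truth re-noised for
    a replication cohort.
    """
    base = SimConfig(seed=seed)
    # Egger presets need a wide gamma spread, negligible exposure-side noise
    # (high I^2_GX), and essentially no negative gammas: orientation flips
    # negate a flipped variant's pleiotropy and would dilute the intercept
    egger_base = replace(base, gamma_mean=0.2, gamma_sd=0.04, n_exp=500000)
    return {
        "null": replace(base, theta=0.0),
        "causal": replace(egger_base, theta=0.2),
        "balanced_pleiotropy": replace(
            egger_base, theta=0.2, pleiotropy=Pleiotropy("balanced", sd=0.01)),
        "directional_pleiotropy": replace(
            egger_base, theta=0.2, pleiotropy=Pleiotropy("directional", mean=0.04, sd=0.005)),
        "outliers": replace(base, theta=0.2, outlier_frac=0.1, outlier_shift=8.0),
        "weak_instruments": replace(
            base, theta=0.2, gamma_mean=0.0, gamma_sd=0.004, gamma_min_abs=0.0,
            n_exp=2000),
        "reverse_causal": replace(base, theta=0.2, reverse=True),
        "two_cohort_replication": replace(base, theta=0.2, n_exp=8000),
    }


def simulate_replication(cfg: SimConfig, truth: SyntheticTruth, seed: int):
    """Re-noise an existing truth as an independent exposure cohort.

    Returns (exposure table, outcome table, LDPanel, truth) with the same
    gamma/alpha/theta but fresh sampling noise and the replication seed.
    """
    # rebuild deterministic structure, then overwrite the noise draws
    rng = np.random.default_rng(seed)
    n = len(truth.variant_ids)
    het = 2.0 * truth.eaf * (1.0 - truth.eaf)
    se_exp = 1.0 / np.sqrt(cfg.n_exp * het)
    se_out = 1.0 / np.sqrt(cfg.n_out * cfg.k_cases * (1.0 - cfg.k_cases) * het)
    if not truth.reverse:
        mean_exp, mean_out = truth.gamma, truth.theta * truth.gamma + truth.alpha
    else:
        mean_out, mean_exp = truth.gamma, truth.theta * truth.gamma + truth.alpha
    beta_exp = mean_exp + rng.normal(0.0, se_exp)
    beta_out = mean_out + rng.normal(0.0, se_out)
    p_exp = np.clip(2.0 * stats.norm.sf(np.abs(beta_exp / se_exp)), np.finfo(float).tiny, 1.0)
    p_out = np.clip(2.0 * stats.norm.sf(np.abs(beta_out / se_out)), np.finfo(float).tiny, 1.0)
    chroms, pos = _positions(replace(cfg, n_snps=n))
    ea = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n)]
    exposure = [
        VariantAssociation(truth.variant_ids[i], ea[i][0], ea[i][1], float(beta_exp[i]),
                           float(se_exp[i]), float(p_exp[i]), cfg.n_exp,
                           eaf=float(truth.eaf[i]), chrom=chroms[i], pos=int(pos[i]))
        for i in range(n)
    ]
    outcome = [
        VariantAssociation(truth.variant_ids[i], ea[i][0], ea[i][1], float(beta_out[i]),
                           float(se_out[i]), float(p_out[i]), cfg.n_out,
                           eaf=float(truth.eaf[i]), chrom=chroms[i], pos=int(pos[i]))
        for i in range(n)
    ]
    return exposure, outcome, _panel(replace(cfg, n_snps=n), truth.variant_ids), replace(truth, seed=seed)
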