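"""Instrument selection: MAF filtering, LD clumping, strength and directionality.

The selection cascade mirrors a standard two-sample MR workflow: keep
common, non-palindromic variants present in the outcome GWAS, clump to
approximate independence by p-value within distance windows, and drop
weak (F < 10) or wrong-direction (Steiger) instruments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ComputationError, InputError
from .sumstats import HarmonizedIV, HarmonizeLog, VariantAssociation, harmonize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClumpConfig:
    """Thresholds governing one instrument-selection pass.

    The primary configuration clumps at pairwise LD r2 < 0.1 within 500 kb
    at p < 1e-6; the stringent and reverse-MR configurations use r2 < 0.001
    within 1000 kb at p < 5e-8.
    """

    p_threshold: float = 1e-6
    r2_threshold: float = 0.1
    window_kb: float = 500.0
    maf_min: float = 0.05
    f_min: float = 10.0
    min_ivs: int = 3

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise InputError(f"p_threshold {self.p_threshold} outside (0,1)")
        if not 0 <= self.r2_threshold <= 1:
            raise InputError(f"r2_threshold {self.r2_threshold} outside [0,1]")
        if not self.window_kb > 0:
            raise InputError("window_kb must be positive")


#: primary discovery configuration
PRIMARY = ClumpConfig()
#: stringent sensitivity configuration
STRINGENT = ClumpConfig(p_threshold=5e-8, r2_threshold=0.001, window_kb=1000.0)
#: reverse-MR configuration (cancer as exposure)
REVERSE = ClumpConfig(p_threshold=5e-8, r2_threshold=0.001, window_kb=1000.0)


class LDPanel:
    """Pairwise LD r2 lookup over an ordered variant list.

    Backed by a dense symmetric matrix with unit diagonal.  Variants
    absent from the panel are treated as independent by callers.
    """

    def __init__(self, variant_ids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(variant_ids), len(variant_ids)):
            raise InputError("LD matrix shape does not match variant list")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise InputError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise InputError("LD r2 values must lie in [0,1]")
        self.variant_ids = list(variant_ids)
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDPanel":
        """An LD-free panel (all off-diagonal r2 = 0)."""
        return cls(variant_ids, np.eye(len(variant_ids)))

    @classmethod
    def from_dosages(cls, variant_ids: Sequence[str], dosages: np.ndarray) -> "LDPanel":
        """Compute r2 as squared Pearson correlation of genotype dosages (samples x variants)."""
        corr = np.corrcoef(np.asarray(dosages, dtype=float), rowvar=False)
        return cls(variant_ids, corr ** 2)

    @classmethod
    def read(cls, path) -> "LDPanel":
        """Read a square TSV (header row and index column of ids) or 3-column long format."""
        df = pd.read_csv(path, sep="\t")
        is_square = set(df.iloc[:, 0].astype(str)) == set(map(str, df.columns[1:]))
        if df.shape[1] == 3 and not is_square:
            ids = sorted(set(df.iloc[:, 0].astype(str)) | set(df.iloc[:, 1].astype(str)))
            idx = {v: i for i, v in enumerate(ids)}
            mat = np.eye(len(ids))
            for a, b, r in df.itertuples(index=False):
                mat[idx[str(a)], idx[str(b)]] = mat[idx[str(b)], idx[str(a)]] = float(r)
            return cls(ids, mat)
        df = df.set_index(df.columns[0])
        return cls([str(v) for v in df.index], df.to_numpy(dtype=float))

    def write(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids) \
            .rename_axis("variant_id").to_csv(path, sep="\t")


@dataclass
class SelectionLog:
    """Counts surviving each stage of :func:`select_instruments`."""

    n_input: int = 0
    n_after_maf: int = 0
    n_after_harmonize: int = 0
    n_after_p: int = 0
    n_after_clump: int = 0
    n_after_f: int = 0
    n_after_steiger: int = 0
    harmonize: HarmonizeLog = field(default_factory=HarmonizeLog)
    reason: str | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "harmonize"}
        d["harmonize"] = dict(self.harmonize.__dict__)
        return d


def compute_r2(beta: float, eaf: float, se: float, n: float) -> float:
    """Variance in the trait explained by one variant.

    (2 b^2 EAF (1-EAF)) / (2 b^2 EAF (1-EAF) + 2 N EAF (1-EAF) SE^2),
    which cancels to b^2 / (b^2 + N SE^2); independent of EAF.
    """
    for v in (beta, eaf, se, n):
        if not math.isfinite(v):
            raise ComputationError("non-finite input to compute_r2")
    if not 0 < eaf < 1:
        raise ComputationError(f"eaf {eaf} outside (0,1)")
    if se <= 0:
        raise ComputationError("se must be > 0")
    if n <= 2:
        raise ComputationError("n must exceed 2")
    het = 2.0 * eaf * (1.0 - eaf)
    num = het * beta * beta
    return num / (num + het * n * se * se)


def compute_f(r2: float, n: float) -> float:
    """Instrument-strength F-statistic: R2 (N-2) / (1 - R2)."""
    if not math.isfinite(r2) or r2 >= 1 or r2 < 0:
        raise ComputationError(f"r2 {r2} outside [0,1)")
    if n <= 2:
        raise ComputationError("n must exceed 2")
    return r2 * (n - 2.0) / (1.0 - r2)


def ld_clump(
    candidates: Sequence[VariantAssociation] | Sequence[HarmonizedIV],
    panel: LDPanel,
    cfg: ClumpConfig,
) -> list[str]:
    """Greedy p-value-ordered clumping.

    A candidate is accepted iff its r2 with every already-accepted variant on
    the same chromosome within ``window_kb`` is below ``r2_threshold``.
    Candidates absent from the panel are treated as independent (logged).
    Ties in p are broken by (chrom, pos, variant_id) for determinism.
    Returns accepted variant ids in acceptance order.
    """

    def pval(c):
        return c.pvalue if isinstance(c, VariantAssociation) else c.pvalue_exp

    eligible = [c for c in candidates if pval(c) is not None and pval(c) < cfg.p_threshold]
    eligible.sort(key=lambda c: (pval(c), str(c.chrom), -1 if c.pos is None else c.pos, c.variant_id))

    missing = [c.variant_id for c in eligible if c.variant_id not in panel]
    if missing:
        logger.info("ld_clump: %d candidate(s) absent from LD panel, treated as independent", len(missing))

    window_bp = cfg.window_kb * 1000.0
    accepted: list = []
    for cand in eligible:
        ok = True
        for acc in accepted:
            if cand.chrom != acc.chrom:
                continue  # cross-chromosome pairs are independent by definition
            if cand.pos is not None and acc.pos is not None and abs(cand.pos - acc.pos) > window_bp:
                continue
            if cand.variant_id in panel and acc.variant_id in panel:
                if panel.r2_between(cand.variant_id, acc.variant_id) >= cfg.r2_threshold:
                    ok = False
                    break
        if ok:
            accepted.append(cand)
    return [c.variant_id for c in accepted]


def steiger_filter(
    ivs: Sequence[HarmonizedIV],
    n_exp: float | None = None,
    n_out: float | None = None,
    alpha: float = 0.05,
) -> tuple[list[HarmonizedIV], list[str]]:
    """Directionality filter comparing variance explained in exposure vs outcome.

    An IV is kept iff r2_exp > r2_out and the one-sided independent-samples
    Fisher-z test on sqrt(r2) correlations is significant at ``alpha``
    (exposure and outcome GWAS are distinct cohorts).  Returns (kept,
    removed ids).
    """
    kept, removed = [], []
    for iv in ivs:
        ne = n_exp if n_exp is not None else iv.n_exp
        no = n_out if n_out is not None else iv.n_out
        if ne is None or no is None:
            raise InputError(f"{iv.variant_id}: sample sizes required for Steiger test")
        if iv.r2_exp > iv.r2_out:
            z_e = math.atanh(min(math.sqrt(iv.r2_exp), 1 - 1e-15))
            z_o = math.atanh(min(math.sqrt(iv.r2_out), 1 - 1e-15))
            z = (z_e - z_o) / math.sqrt(1.0 / (ne - 3) + 1.0 / (no - 3))
            p = stats.norm.sf(z)
            if p < alpha:
                kept.append(iv)
                continue
        removed.append(iv.variant_id)
    if removed:
        logger.info("steiger_filter: removed %d IV(s): %s", len(removed), removed)
    return kept, removed


def select_instruments(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    panel: LDPanel,
    cfg: ClumpConfig = PRIMARY,
    log: SelectionLog | None = None,
) -> list[HarmonizedIV]:
    """Full selection cascade for one exposure against one outcome.

    Order: MAF filter on min(eaf, 1-eaf) > maf_min; harmonization
    (palindrome/outcome-presence/allele resolution); exposure p-value
    threshold; LD clumping; F >= f_min; Steiger directionality.  Returns []
    (with a logged reason) when fewer than ``min_ivs`` instruments survive.
    """
    log = log if log is not None else SelectionLog()
    log.n_input = len(exposure)

    common = [v for v in exposure
              if v.eaf is not None and min(v.eaf, 1.0 - v.eaf) > cfg.maf_min]
    log.n_after_maf = len(common)

    ivs = harmonize(common, outcome, log=log.harmonize)
    log.n_after_harmonize = len(ivs)

    sig = [iv for iv in ivs if iv.pvalue_exp is not None and iv.pvalue_exp < cfg.p_threshold]
    log.n_after_p = len(sig)
    if not sig:
        log.reason = "no significant variants"
        logger.info("select_instruments: %s", log.reason)
        return []

    keep_ids = set(ld_clump(sig, panel, cfg))
    clumped = [iv for iv in sig if iv.variant_id in keep_ids]
    log.n_after_clump = len(clumped)

    strong = [iv for iv in clumped if iv.f_stat >= cfg.f_min]
    log.n_after_f = len(strong)

    kept, _removed = steiger_filter(strong)
    log.n_after_steiger = len(kept)

    if len(kept) < cfg.min_ivs:
        log.reason = f"only {len(kept)} IV(s) survive selection (min {cfg.min_ivs})"
        logger.info("select_instruments: %s", log.reason)
        return []
    return kept
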