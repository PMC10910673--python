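"""Reading, validation, and harmonization of GWAS summary-statistic tables.

Exposure tables carry per-variant effects on a quantitative trait (SD
units); outcome tables carry log-odds effects on a binary trait.  The
harmonization step aligns the two tables on shared variants, resolves
allele orientation (including strand flips), removes palindromic
variants, and orients every instrument so that the exposure effect is
non-negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)

#: canonical column names understood by :func:`read_sumstats`
REQUIRED_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue", "n")
OPTIONAL_COLUMNS = ("chrom", "pos", "eaf")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: int
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def validate(self) -> None:
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.variant_id}: identical alleles")
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise InputError(f"{self.variant_id}: non-ACGT allele")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise InputError(f"{self.variant_id}: eaf {self.eaf} outside (0,1)")
        if not self.se > 0:
            raise InputError(f"{self.variant_id}: se must be > 0")
        if not 0.0 < self.pvalue <= 1.0:
            raise InputError(f"{self.variant_id}: pvalue outside (0,1]")
        if self.n <= 0:
            raise InputError(f"{self.variant_id}: non-positive sample size")
        if self.pos is not None and self.pos < 1:
            raise InputError(f"{self.variant_id}: position must be >= 1")


@dataclass(frozen=True)
class HarmonizedIV:
    """An exposure/outcome-aligned instrument with derived strength statistics.

    Oriented so ``beta_exp >= 0``; ``eaf`` is the exposure-study effect-allele
    frequency after orientation.  Positional fields are carried through for
    LD-clumping windows.
    """

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float
    r2_exp: float
    r2_out: float
    f_stat: float
    pvalue_exp: float | None = None
    n_exp: int | None = None
    n_out: int | None = None
    chrom: str | None = None
    pos: int | None = None

    #: column order of the serialized instrument table
    TSV_COLUMNS = ("variant_id", "beta_exp", "se_exp", "beta_out", "se_out",
                   "eaf", "r2_exp", "r2_out", "f_stat")


@dataclass
class HarmonizeLog:
    """Per-step drop counts recorded by :func:`harmonize`."""

    n_exposure: int = 0
    n_outcome: int = 0
    n_shared: int = 0
    n_palindromic: int = 0
    n_allele_mismatch: int = 0
    n_strand_flipped: int = 0
    n_missing_eaf: int = 0
    n_kept: int = 0


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_kind: str = "quantitative",
    sep: str | None = None,
) -> list[VariantAssociation]:
    """Read a delimited summary-statistic table into validated records.

    ``column_map`` maps canonical names (``variant_id``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``n``, ``chrom``,
    ``pos``) to the file's column names; canonical names already present in
    the header need no entry.  Rows violating record invariants are dropped
    and counted.  Gzip input is accepted transparently.
    """
    if trait_kind not in ("quantitative", "binary"):
        raise ConfigurationError(f"unknown trait_kind {trait_kind!r}")
    column_map = dict(column_map or {})
    import csv

    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty summary-statistic file") from None
    except csv.Error as exc:  # sniffer cannot handle single-column/blank input
        raise InputError(f"{path}: unreadable summary-statistic file ({exc})") from None
    if df.empty:
        raise InputError(f"{path}: no data rows")

    rename = {}
    for canonical in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            raise ConfigurationError(
                f"{path}: required column {canonical!r} not found "
                f"(looked for {source!r}); fix the column_map"
            )
    df = df.rename(columns=rename)

    records: list[VariantAssociation] = []
    dropped = 0
    for row in df.itertuples(index=False):
        try:
            eaf = getattr(row, "eaf", None)
            if eaf is not None and (isinstance(eaf, float) and math.isnan(eaf)):
                eaf = None
            pos = getattr(row, "pos", None)
            if pos is not None and not (isinstance(pos, float) and math.isnan(pos)):
                pos = int(pos)
            else:
                pos = None
            chrom = getattr(row, "chrom", None)
            chrom = None if chrom is None or (isinstance(chrom, float) and math.isnan(chrom)) else str(chrom)
            rec = VariantAssociation(
                variant_id=str(row.variant_id),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                eaf=None if eaf is None else float(eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=int(row.n),
                chrom=chrom,
                pos=pos,
            )
            for v in (rec.beta, rec.se, rec.pvalue):
                if not math.isfinite(v):
                    raise InputError(f"{rec.variant_id}: non-finite value")
            rec.validate()
        except (InputError, ValueError):
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.info("read_sumstats(%s): dropped %d invalid row(s)", path, dropped)
    return records


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-ambiguous)."""
    return {effect_allele.upper(), other_allele.upper()} in ({"A", "T"}, {"C", "G"})


def _check_duplicates(records: Sequence[VariantAssociation], label: str) -> dict[str, VariantAssociation]:
    index: dict[str, VariantAssociation] = {}
    dupes = []
    for rec in records:
        if rec.variant_id in index:
            dupes.append(rec.variant_id)
        index[rec.variant_id] = rec
    if dupes:
        raise InputError(f"duplicate variant_id in {label} table: {sorted(set(dupes))}")
    return index


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    log: HarmonizeLog | None = None,
) -> list[HarmonizedIV]:
    """Align exposure and outcome associations on shared, strand-resolvable variants.

    Only variants present in both tables are retained.  Palindromic variants
    are excluded.  When outcome alleles are swapped relative to the exposure,
    the outcome beta is sign-flipped; when they match only after strand
    complementation, the flip is applied first.  Output is oriented so
    ``beta_exp >= 0`` and carries instrument R2 on both sides plus the
    F-statistic (exposure-study N and EAF).
    """
    from .instruments import compute_f, compute_r2  # local import avoids a cycle

    log = log if log is not None else HarmonizeLog()
    exp_index = _check_duplicates(exposure, "exposure")
    out_index = _check_duplicates(outcome, "outcome")
    log.n_exposure = len(exp_index)
    log.n_outcome = len(out_index)

    ivs: list[HarmonizedIV] = []
    for vid, e in exp_index.items():
        o = out_index.get(vid)
        if o is None:
            continue
        log.n_shared += 1
        if is_palindromic(e.effect_allele, e.other_allele):
            log.n_palindromic += 1
            continue
        if e.eaf is None:
            log.n_missing_eaf += 1
            continue

        oa, ob = o.effect_allele, o.other_allele
        if (oa, ob) == (e.effect_allele, e.other_allele):
            beta_out, flipped = o.beta, False
        elif (ob, oa) == (e.effect_allele, e.other_allele):
            beta_out, flipped = -o.beta, False
        else:
            # strand-flip rescue before dropping
            ca, cb = _COMPLEMENT[oa], _COMPLEMENT[ob]
            if (ca, cb) == (e.effect_allele, e.other_allele):
                beta_out, flipped = o.beta, True
            elif (cb, ca) == (e.effect_allele, e.other_allele):
                beta_out, flipped = -o.beta, True
            else:
                log.n_allele_mismatch += 1
                continue
        if flipped:
            log.n_strand_flipped += 1

        beta_exp, eaf = e.beta, e.eaf
        if beta_exp < 0:
            beta_exp, beta_out, eaf = -beta_exp, -beta_out, 1.0 - eaf

        r2_exp = compute_r2(beta_exp, eaf, e.se, e.n)
        r2_out = compute_r2(beta_out, eaf, o.se, o.n)
        ivs.append(HarmonizedIV(
            variant_id=vid,
            beta_exp=beta_exp, se_exp=e.se,
            beta_out=beta_out, se_out=o.se,
            eaf=eaf,
            r2_exp=r2_exp, r2_out=r2_out,
            f_stat=compute_f(r2_exp, e.n),
            pvalue_exp=e.pvalue, n_exp=e.n, n_out=o.n,
            chrom=e.chrom, pos=e.pos,
        ))
    log.n_kept = len(ivs)
    logger.info(
        "harmonize: %d shared, %d palindromic, %d allele-mismatch, %d missing-eaf, %d kept",
        log.n_shared, log.n_palindromic, log.n_allele_mismatch, log.n_missing_eaf, log.n_kept,
    )
    return ivs


def ivs_to_frame(ivs: Iterable[HarmonizedIV]) -> pd.DataFrame:
    """Serialize instruments with the fixed public column order."""
    rows = [{c: getattr(iv, c) for c in HarmonizedIV.TSV_COLUMNS} for iv in ivs]
    return pd.DataFrame(rows, columns=list(HarmonizedIV.TSV_COLUMNS))


def write_ivs(ivs: Iterable[HarmonizedIV], path) -> None:
    ivs_to_frame(ivs).to_csv(path, sep="\t", index=False)
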