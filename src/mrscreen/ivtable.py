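"""Loader for published per-association instrument tables.

Reproduces headline odds ratios from an instrument-level table of the kind
distributed as a supplementary spreadsheet: one row per (metabolite,
cancer, variant) with the variant's exposure and outcome associations.
The expected canonical columns are

    metabolite, cancer, variant_id, beta_exp, se_exp, beta_out, se_out,
    eaf, n_exp

(case-insensitive; a column_map may rename).  TSV/CSV is read directly;
.xlsx is read through pandas/openpyxl.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .estimators import ivw
from .exceptions import ConfigurationError, InputError
from .instruments import compute_r2
from .sumstats import HarmonizedIV

CANONICAL = ("metabolite", "cancer", "variant_id", "beta_exp", "se_exp",
             "beta_out", "se_out", "eaf", "n_exp")

_ALIASES = {
    "metabolite": {"metabolite", "metabolite_id", "exposure", "metabolite_name"},
    "cancer": {"cancer", "cancer_id", "outcome", "cancer_type"},
    "variant_id": {"variant_id", "snp", "rsid", "variant"},
    "beta_exp": {"beta_exp", "beta_exposure", "beta_metabolite", "beta.exposure"},
    "se_exp": {"se_exp", "se_exposure", "se_metabolite", "se.exposure"},
    "beta_out": {"beta_out", "beta_outcome", "beta_cancer", "beta.outcome"},
    "se_out": {"se_out", "se_outcome", "se_cancer", "se.outcome"},
    "eaf": {"eaf", "eaf_exp", "effect_allele_frequency", "eaf.exposure"},
    "n_exp": {"n_exp", "n", "samplesize_exposure", "n_exposure", "samplesize.exposure"},
}


def load_iv_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an instrument-level association table and normalize its columns."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"instrument table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower().strip(): c for c in df.columns}
    column_map = {k: v for k, v in (column_map or {}).items()}
    rename = {}
    for canon in CANONICAL:
        if canon in column_map:
            src = column_map[canon]
            if src not in df.columns:
                raise ConfigurationError(f"{path}: mapped column {src!r} not found")
            rename[src] = canon
            continue
        hit = next((lower[a] for a in _ALIASES[canon] if a in lower), None)
        if hit is None:
            raise ConfigurationError(f"{path}: cannot resolve column {canon!r}")
        rename[hit] = canon
    return df.rename(columns=rename)[list(CANONICAL)]


def ivs_for_pair(df: pd.DataFrame, metabolite: str, cancer: str) -> list[HarmonizedIV]:
    """Instrument records for one metabolite-cancer association."""
    sub = df[(df["metabolite"] == metabolite) & (df["cancer"] == cancer)]
    if sub.empty:
        raise InputError(f"no instruments for ({metabolite!r}, {cancer!r})")
    ivs = []
    for row in sub.itertuples(index=False):
        r2 = compute_r2(row.beta_exp, row.eaf, row.se_exp, row.n_exp)
        ivs.append(HarmonizedIV(
            variant_id=str(row.variant_id),
            beta_exp=float(row.beta_exp), se_exp=float(row.se_exp),
            beta_out=float(row.beta_out), se_out=float(row.se_out),
            eaf=float(row.eaf), r2_exp=r2,
            r2_out=0.0, f_stat=r2 * (row.n_exp - 2) / (1 - r2),
            n_exp=int(row.n_exp),
        ))
    return ivs


def reproduce_or(df: pd.DataFrame, metabolite: str, cancer: str) -> float:
    """IVW odds ratio for one association, recomputed from its instruments."""
    return ivw(ivs_for_pair(df, metabolite, cancer)).or_


def association_r2(df: pd.DataFrame) -> pd.Series:
    """Total instrument R2 (percent) per (metabolite, cancer) association."""
    def total(sub: pd.DataFrame) -> float:
        return 100.0 * sum(
            compute_r2(b, e, s, n)
            for b, e, s, n in zip(sub.beta_exp, sub.eaf, sub.se_exp, sub.n_exp)
        )
    return df.groupby(["metabolite", "cancer"]).apply(total, include_groups=False)


def median_association_r2(df: pd.DataFrame) -> float:
    """Median over associations of the summed instrument R2, in percent."""
    return float(association_r2(df).median())
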