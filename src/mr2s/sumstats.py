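"""Reading, validating and quality-filtering GWAS summary statistics.

A summary-statistics table is held as a plain :class:`pandas.DataFrame`
with canonical column names::

    variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval
    [info]  [n]

``beta`` is the per-allele effect of the effect allele on the trait
(log-odds for case-control traits), ``se`` its standard error, ``eaf``
the effect-allele frequency.  ``info`` (imputation quality) and ``n``
(sample size) are optional.  Positions are 1-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical name -> default source-file column header (PLINK-style)
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "FRQ",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "info": "INFO",
    "n": "N",
}

MANDATORY_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval",
)
OPTIONAL_COLUMNS = ("info", "n")

_VALID_ALLELES = frozenset("ACGT")
#: strand-ambiguous (palindromic) allele pairs
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


@dataclass
class QCReport:
    """Per-filter attrition bookkeeping for :func:`qc_filter`.

    Each removed variant is attributed to the first filter that removes
    it, in the fixed order MAF -> biallelic -> ambiguous -> INFO, so
    ``n_output == n_input - sum(removals)`` always holds.
    """

    n_input: int = 0
    n_removed_maf: int = 0
    n_removed_nonbiallelic: int = 0
    n_removed_ambiguous: int = 0
    n_removed_info: int = 0
    n_output: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        return "\n".join(f"{k}: {v}" for k, v in self.to_dict().items())


def validate_sumstats(df: pd.DataFrame, name: str = "table") -> None:
    """Check structural invariants of a canonical summary-statistics table.

    Raises ``ValueError`` on duplicated variant ids, identical allele
    pairs, or non-positive standard errors.  A reported p-value that
    disagrees with the two-sided normal approximation from beta/se by
    more than a factor of 2 triggers a warning only (meta-analysed or
    genomic-control-corrected GWAS legitimately deviate).
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing mandatory column(s) {missing}")
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].head().tolist()
        raise ValueError(f"{name}: duplicated variant_id values, e.g. {dups}")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValueError(f"{name}: effect_allele equals other_allele for some rows")
    if (df["se"] <= 0).any():
        raise ValueError(f"{name}: non-positive se values present")
    with np.errstate(divide="ignore"):
        p_expect = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    p_obs = df["pval"].to_numpy(float)
    ok = (p_obs >= p_expect / 2.0) & (p_obs <= np.minimum(1.0, p_expect * 2.0))
    # extremely small p underflows; treat both-tiny as consistent
    ok |= (p_obs < 1e-300) & (p_expect < 1e-300)
    if not ok.all():
        logger.warning(
            "%s: %d/%d rows have pval inconsistent with beta/se beyond a "
            "factor of 2 (normal approximation)", name, int((~ok).sum()), len(df)
        )


def read_sumstats(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a whitespace/tab-delimited GWAS summary-statistics file.

    Parameters
    ----------
    path : str or path-like
        Text file with one header line; gzip is handled transparently.
    column_map : dict, optional
        Mapping of canonical name -> source header, overriding entries of
        :data:`DEFAULT_COLUMN_MAP`.

    Returns
    -------
    pandas.DataFrame
        Canonical table. Alleles are upper-cased; rows with missing or
        unparseable beta/se/alleles, or non-SNP (multi-character)
        alleles, are dropped and the count logged.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=r"\s+", dtype=str, compression="infer")
    for canon in MANDATORY_COLUMNS:
        if cmap[canon] not in raw.columns:
            raise ValueError(
                f"{path}: mandatory column '{canon}' "
                f"(source header '{cmap[canon]}') not found in file header"
            )
    cols = {canon: raw[cmap[canon]] for canon in MANDATORY_COLUMNS}
    for canon in OPTIONAL_COLUMNS:
        if cmap[canon] in raw.columns:
            cols[canon] = raw[cmap[canon]]
    df = pd.DataFrame(cols)

    n0 = len(df)
    for col in ("pos", "eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("info", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    keep = (
        df["beta"].notna() & df["se"].notna() & df["pval"].notna()
        & df["pos"].notna() & df["eaf"].notna()
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["se"] > 0)
    )
    df = df.loc[keep].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    dropped = n0 - len(df)
    if dropped:
        logger.info("%s: dropped %d malformed/non-SNP rows of %d", path, dropped, n0)
    validate_sumstats(df, name=str(path))
    return df


def write_sumstats(df: pd.DataFrame, path, column_map: dict[str, str] | None = None) -> None:
    """Write a canonical table back to the default tab-delimited dialect."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = df.rename(columns={k: v for k, v in cmap.items() if k in df.columns})
    out.to_csv(path, sep="\t", index=False)


def qc_filter(
    tab: pd.DataFrame,
    biallelic_ids: set | None = None,
    maf_min: float = 0.05,
    info_min: float = 0.6,
    external_freq: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the standard instrument-selection QC filters.

    Filters in fixed order, each variant attributed to the first filter
    that removes it:

    1. MAF: ``min(eaf, 1-eaf) >= maf_min`` (frequency taken from
       ``external_freq`` — columns variant_id, eaf — when supplied, a
       reference panel stand-in; otherwise the table's own ``eaf``);
    2. biallelic: ``variant_id in biallelic_ids`` (skipped when no set
       is supplied);
    3. strand-ambiguous allele pairs A/T and C/G removed;
    4. INFO: ``info >= info_min`` where an info value is available
       (rows with no info value pass).
    """
    n_input = len(tab)
    eaf = tab["eaf"].to_numpy(float)
    if external_freq is not None:
        ref = external_freq.set_index("variant_id")["eaf"]
        mapped = tab["variant_id"].map(ref)
        eaf = mapped.fillna(pd.Series(eaf, index=tab.index)).to_numpy(float)
    maf_ok = np.minimum(eaf, 1.0 - eaf) >= maf_min

    if biallelic_ids is not None:
        bi_ok = tab["variant_id"].isin(biallelic_ids).to_numpy()
    else:
        bi_ok = np.ones(n_input, dtype=bool)

    pairs = list(zip(tab["effect_allele"], tab["other_allele"]))
    amb_ok = np.array([p not in AMBIGUOUS_PAIRS for p in pairs])

    if "info" in tab.columns:
        info = tab["info"].to_numpy(float)
        info_ok = np.isnan(info) | (info >= info_min)
    else:
        info_ok = np.ones(n_input, dtype=bool)

    removed_maf = ~maf_ok
    removed_bi = maf_ok & ~bi_ok
    removed_amb = maf_ok & bi_ok & ~amb_ok
    removed_info = maf_ok & bi_ok & amb_ok & ~info_ok
    keep = maf_ok & bi_ok & amb_ok & info_ok

    out = tab.loc[keep].reset_index(drop=True)
    report = QCReport(
        n_input=n_input,
        n_removed_maf=int(removed_maf.sum()),
        n_removed_nonbiallelic=int(removed_bi.sum()),
        n_removed_ambiguous=int(removed_amb.sum()),
        n_removed_info=int(removed_info.sum()),
        n_output=len(out),
    )
    logger.info("qc_filter: %s", report.to_dict())
    return out, report


def intersect_variants(tables: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict every table to the variant ids common to all of them.

    Row order within each table is preserved.  Raises ``ValueError`` on
    fewer than two tables or an empty intersection (no shared variants
    means the studies cannot be analysed jointly).
    """
    if len(tables) < 2:
        raise ValueError("intersect_variants requires at least two tables")
    common = set(tables[0]["variant_id"])
    for t in tables[1:]:
        common &= set(t["variant_id"])
    if not common:
        raise ValueError("no variants shared by all input tables")
    return [t.loc[t["variant_id"].isin(common)].reset_index(drop=True) for t in tables]
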