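"""Allele harmonization of exposure and outcome effect estimates.

Every MR estimator needs the exposure and outcome betas of each
instrument expressed for the same effect allele.  The exposure
orientation is the reference: outcome rows whose alleles are swapped
relative to the exposure get their beta negated (and eaf reflected);
rows coded on the opposite strand are resolved by complementing both
outcome alleles, which is unambiguous once palindromic (A/T, C/G)
variants have been removed by QC.  Rows whose allele pairs cannot be
reconciled are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import InstrumentSet

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the harmonized interchange table
HARMONIZED_COLUMNS = (
    "variant_id", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "pval_exp",
)


@dataclass
class HarmonizedInstruments:
    """Aligned per-instrument effect quadruples plus attrition counts.

    ``df`` holds one row per retained instrument with exposure-oriented
    betas; ``provenance`` counts input/kept/flipped/dropped rows
    (kept + dropped = input; flipped is a subset of kept).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        d = self.df
        return (d["beta_exp"].to_numpy(float), d["se_exp"].to_numpy(float),
                d["beta_out"].to_numpy(float), d["se_out"].to_numpy(float))

    def subset(self, mask_or_ids) -> "HarmonizedInstruments":
        if isinstance(mask_or_ids, (list, set, frozenset)):
            mask = self.df["variant_id"].isin(set(mask_or_ids)).to_numpy()
        else:
            mask = np.asarray(mask_or_ids)
        return HarmonizedInstruments(
            self.df.loc[mask].reset_index(drop=True), dict(self.provenance)
        )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HarmonizedInstruments":
        return cls(pd.read_csv(path, sep="\t"))


def harmonize(exp: pd.DataFrame, out: pd.DataFrame,
              instr: InstrumentSet) -> HarmonizedInstruments:
    """Align outcome effects to the exposure effect allele per instrument.

    For each instrument: identical allele pairs are kept as-is; swapped
    pairs (effect <-> other) negate ``beta_out`` and reflect ``eaf_out``;
    pairs matching only after complementing both outcome alleles are
    treated as strand flips and resolved the same way; anything else is
    dropped.  Instruments absent from either table are dropped and
    counted, not an error (real outcome GWAS routinely lack variants).
    """
    exp_by = exp.set_index("variant_id")
    out_by = out.set_index("variant_id")

    rows = []
    n_flipped = n_dropped_missing = n_dropped_strand = 0
    for v in instr.index_snps:
        if v not in exp_by.index or v not in out_by.index:
            n_dropped_missing += 1
            continue
        e = exp_by.loc[v]
        o = out_by.loc[v]
        ea, oa = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]

        sign = None
        if (ea_o, oa_o) == (ea, oa):
            sign = 1.0
        elif (ea_o, oa_o) == (oa, ea):
            sign = -1.0
        else:
            cea, coa = _COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)
            if (cea, coa) == (ea, oa):
                sign = 1.0
            elif (cea, coa) == (oa, ea):
                sign = -1.0
        if sign is None:
            n_dropped_strand += 1
            logger.debug("harmonize: dropping %s (%s/%s vs %s/%s)", v, ea, oa, ea_o, oa_o)
            continue
        if sign < 0:
            n_flipped += 1
        eaf_out = o.get("eaf", np.nan)
        rows.append({
            "variant_id": v,
            "effect_allele": ea,
            "other_allele": oa,
            "beta_exp": float(e["beta"]),
            "se_exp": float(e["se"]),
            "beta_out": sign * float(o["beta"]),
            "se_out": float(o["se"]),
            "eaf_exp": float(e.get("eaf", np.nan)),
            "eaf_out": float(1.0 - eaf_out if sign < 0 else eaf_out),
            "pval_exp": float(e["pval"]),
        })

    df = pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS))
    prov = {
        "n_input": len(instr.index_snps),
        "n_kept": len(df),
        "n_flipped": n_flipped,
        "n_dropped_missing": n_dropped_missing,
        "n_dropped_strand": n_dropped_strand,
    }
    logger.info("harmonize: %s", prov)
    return HarmonizedInstruments(df, prov)
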