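"""Instrument selection: greedy LD clumping and weak-instrument screening.

Clumping follows the PLINK convention: among variants passing the
significance threshold, repeatedly promote the smallest-p unclaimed
variant to index SNP and discard every unclaimed variant on the same
chromosome within the window that is in LD (r² at or above the
threshold) with it.  Instrument strength is screened with the
single-SNP F-statistic (beta/se)², keeping F strictly greater than the
conventional cutoff of 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ClumpParams:
    """Clumping thresholds (defaults: 10 Mb window, p ≤ 1e-6, r² < 0.05)."""

    window_kb: int = 10_000
    p1: float = 1e-6
    r2_max: float = 0.05

    def __post_init__(self):
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0 < self.p1 <= 1:
            raise ValueError("p1 must be in (0, 1]")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must be in [0, 1]")


class LDReference:
    """Pairwise r² lookup among variants, plus their genomic positions.

    ``pairs`` maps unordered id pairs to squared correlation; ``positions``
    maps variant_id -> (chrom, pos).  A pair absent from ``pairs`` is
    treated as unlinked (r² = 0); variants on different chromosomes are
    always unlinked; r²(v, v) = 1.
    """

    def __init__(self, pairs, positions):
        self._pairs: dict[tuple[str, str], float] = {}
        for (a, b), r2 in dict(pairs).items():
            if not 0 <= r2 <= 1:
                raise ValueError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
            self._pairs[self._key(a, b)] = float(r2)
        self.positions: dict[str, tuple[str, int]] = {
            v: (str(c), int(p)) for v, (c, p) in dict(positions).items()
        }

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        ca = self.positions.get(a)
        cb = self.positions.get(b)
        if ca is not None and cb is not None and ca[0] != cb[0]:
            return 0.0
        return self._pairs.get(self._key(a, b), 0.0)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.positions

    @classmethod
    def from_long(cls, source, positions) -> "LDReference":
        """Build from long-format (id1, id2, r2) table or file path.

        Compatible with PLINK ``--r2`` output using headers SNP_A, SNP_B,
        R2, or plain id1/id2/r2.
        """
        if isinstance(source, pd.DataFrame):
            df = source
        else:
            df = pd.read_csv(source, sep=r"\s+", compression="infer")
        cols = {c.lower(): c for c in df.columns}
        a = cols.get("snp_a") or cols.get("id1")
        b = cols.get("snp_b") or cols.get("id2")
        r = cols.get("r2")
        if not (a and b and r):
            raise ValueError("long-format LD input needs columns id1,id2,r2 (or SNP_A,SNP_B,R2)")
        pairs = {
            (str(ra), str(rb)): float(rr)
            for ra, rb, rr in zip(df[a], df[b], df[r])
        }
        return cls(pairs, positions)

    @classmethod
    def from_matrix(cls, source, positions) -> "LDReference":
        """Build from a square r² matrix with variant ids as header/index."""
        if isinstance(source, pd.DataFrame):
            mat = source
        else:
            mat = pd.read_csv(source, sep=r"\s+", index_col=0, compression="infer")
        ids = [str(c) for c in mat.columns]
        m = mat.to_numpy(float)
        pairs = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if m[i, j] > 0:
                    pairs[(ids[i], ids[j])] = m[i, j]
        return cls(pairs, positions)

    def to_long_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._pairs.items())]
        return pd.DataFrame(rows, columns=["id1", "id2", "r2"])


@dataclass
class InstrumentSet:
    """Index SNPs surviving clumping (in selection order) with F-statistics."""

    index_snps: list[str] = field(default_factory=list)
    f_stats: dict[str, float] = field(default_factory=dict)
    n_discarded: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.index_snps)


def f_statistic(beta, se):
    """Single-SNP instrument-strength F-statistic, (beta/se)².

    Accepts scalars or arrays; se must be strictly positive.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("f_statistic: se must be > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def clump(tab: pd.DataFrame, ld: LDReference, params: ClumpParams | None = None) -> InstrumentSet:
    """Greedy LD clumping of a summary-statistics table.

    Ties in p-value are broken by (chrom, pos, variant_id) so the result
    is invariant to input row order.  Every significant variant must be
    present in ``ld.positions``; silently assuming independence for
    unknown variants would fake instrument validity, so missing ids are
    a hard error.
    """
    params = params or ClumpParams()
    sig = tab.loc[tab["pval"] <= params.p1]
    if sig.empty:
        return InstrumentSet()

    missing = [v for v in sig["variant_id"] if v not in ld]
    if missing:
        raise ValueError(
            f"clump: {len(missing)} significant variant(s) absent from LD "
            f"reference positions: {missing[:10]}"
        )

    order = sig.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    )
    ids = order["variant_id"].tolist()
    chrom = dict(zip(order["variant_id"], order["chrom"].astype(str)))
    pos = dict(zip(order["variant_id"], order["pos"].astype(int)))
    fstat = dict(zip(order["variant_id"],
                     f_statistic(order["beta"], order["se"])))

    window_bp = params.window_kb * 1000
    claimed: set[str] = set()
    result = InstrumentSet()
    for v in ids:
        if v in claimed:
            continue
        claimed.add(v)
        discarded = 0
        for u in ids:
            if u in claimed:
                continue
            if chrom[u] != chrom[v]:
                continue
            if abs(pos[u] - pos[v]) > window_bp:
                continue
            if ld.r2(v, u) >= params.r2_max:
                claimed.add(u)
                discarded += 1
        result.index_snps.append(v)
        result.f_stats[v] = float(fstat[v])
        result.n_discarded[v] = discarded
    logger.info("clump: %d significant -> %d index SNPs", len(ids), len(result))
    return result


def screen_strength(instr: InstrumentSet, tab: pd.DataFrame, f_min: float = 10.0) -> InstrumentSet:
    """Keep index SNPs with F strictly greater than ``f_min``.

    F is recomputed from ``tab`` (the exposure table) for every index
    SNP; an index SNP missing from ``tab`` is an error.
    """
    by_id = tab.set_index("variant_id")
    missing = [v for v in instr.index_snps if v not in by_id.index]
    if missing:
        raise ValueError(f"screen_strength: index SNP(s) absent from table: {missing}")
    out = InstrumentSet()
    for v in instr.index_snps:
        f = f_statistic(by_id.at[v, "beta"], by_id.at[v, "se"])
        if f > f_min:
            out.index_snps.append(v)
            out.f_stats[v] = float(f)
            out.n_discarded[v] = instr.n_discarded.get(v, 0)
    return out


def write_clumped(instr: InstrumentSet, tab: pd.DataFrame, path) -> None:
    """Write a PLINK-.clumped-spirit text table of index SNPs."""
    by_id = tab.set_index("variant_id")
    rows = []
    for v in instr.index_snps:
        rows.append({
            "SNP": v,
            "CHR": by_id.at[v, "chrom"],
            "BP": by_id.at[v, "pos"],
            "P": by_id.at[v, "pval"],
            "F": instr.f_stats.get(v, np.nan),
            "N_DISCARDED": instr.n_discarded.get(v, 0),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
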