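"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the ingredients a summary-level MR analysis
actually consumes: per-variant instrument effects on a continuous
exposure (an S100B-like blood biomarker measured in SD units), a true
causal effect of the exposure on a binary outcome (a case-control GWAS
reported on the log-odds scale), balanced or directional horizontal
pleiotropy on a chosen fraction of instruments, block-structured LD so
clumping has real work to do, random allele coding / allele swaps /
strand flips so harmonization has real work to do, and independent
two-sample estimation noise.

Effect sizes are generated directly on the summary scale:
``se_exp_j = 1/sqrt(n_exp * 2 eaf_j (1 - eaf_j))`` for a unit-variance
exposure, and for the binary outcome
``se_out_j = 1/sqrt(n_out * v (1 - v) * 2 eaf_j (1 - eaf_j))`` with case
fraction ``v`` — the standard large-sample approximations, avoiding
individual-level simulation that summary-level MR never sees.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDReference

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimTruth:
    """Ground-truth parameters of one simulated exposure/outcome pair.

    The default configuration emulates the scale of a neonatal-biomarker
    MR study: an exposure GWAS of ~8,000 subjects yielding ~35
    independent genome-wide-suggestive instruments, against a large
    case-control outcome GWAS.  ``gamma``, ``alpha``, ``ld_blocks`` and
    ``instrument_ids`` start empty and are filled in by
    :func:`simulate_pair` when the truth is realized.
    """

    theta: float = 0.0                  # causal log-odds per SD exposure
    n_instruments: int = 35             # LD-independent causal signals
    prop_invalid: float = 0.0           # fraction of instruments with pleiotropy
    pleiotropy_mode: str = "balanced"   # "balanced" | "directional"
    gamma_sd: float = 0.25              # SD of true instrument effects (SD units)
    alpha_mean: float = 0.05            # mean pleiotropic effect (directional mode)
    alpha_sd: float = 0.02              # spread of pleiotropic effects
    n_exp: int = 8138                   # exposure GWAS sample size
    n_out: int = 100_000                # outcome GWAS effective sample size
    case_fraction: float = 0.5
    block_size: int = 5                 # variants per LD block
    block_r2: float = 0.8               # proxy-to-index r²
    frac_allele_swap: float = 0.3       # outcome rows with swapped allele coding
    frac_strand_flip: float = 0.3       # outcome rows coded on the other strand
    frac_palindromic: float = 0.02      # variants given A/T or C/G alleles
    seed: int = 0
    # realized ground truth (filled by simulate_pair)
    gamma: np.ndarray | None = field(default=None, repr=False)
    alpha: np.ndarray | None = field(default=None, repr=False)
    ld_blocks: list[list[str]] | None = field(default=None, repr=False)
    instrument_ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0 <= self.prop_invalid <= 1:
            raise ValueError("prop_invalid must be in [0, 1]")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_instruments < 1 or self.block_size < 1:
            raise ValueError("n_instruments and block_size must be >= 1")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        for name in ("frac_allele_swap", "frac_strand_flip", "frac_palindromic"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_invalid(self) -> int:
        """Deterministic invalid-instrument count.

        round(prop_invalid * n_instruments), rounded down to an even
        number in balanced mode so antithetic pairing makes the mean
        pleiotropic effect exactly zero.
        """
        k = int(round(self.prop_invalid * self.n_instruments))
        if self.pleiotropy_mode == "balanced" and k % 2 == 1:
            k -= 1
        return k

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("gamma", "alpha"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        for key in ("gamma", "alpha"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def truth_report(truth: SimTruth, path=None) -> str:
    """Serialize all ground-truth parameters to JSON (for recovery tests)."""
    s = json.dumps(truth.to_dict(), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def load_truth(path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))


def _pvals(beta, se):
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny)


def simulate_pair(truth: SimTruth, n_variants: int = 1000
                  ) -> tuple[pd.DataFrame, pd.DataFrame, LDReference]:
    """Generate one exposure table, one outcome table and their LD reference.

    Variants are laid out in LD blocks of ``truth.block_size`` placed 20 Mb
    apart across chromosomes 1-22; ``truth.n_instruments`` blocks carry a
    causal signal whose index variant has effect ``gamma_b ~
    N(0, gamma_sd²)`` and whose proxies carry ``r * gamma_b`` with
    ``r = sqrt(block_r2)``, so clumping should recover one index per
    signal block.  Pleiotropic (direct-on-outcome) effects attach to
    ``truth.n_invalid`` instrument blocks, antithetically paired in
    balanced mode, drawn N(alpha_mean, alpha_sd²) relative to the
    exposure-increasing allele in directional mode, with magnitudes
    independent of gamma (InSIDE holds).  Sampling noise is independent
    between the two tables and across variants.

    Realized ground truth (gamma, alpha per variant, block membership,
    causal-block index ids) is written back onto ``truth``.
    """
    n_blocks = n_variants // truth.block_size
    if n_blocks < truth.n_instruments:
        raise ValueError(
            f"n_variants={n_variants} gives {n_blocks} blocks of "
            f"{truth.block_size}; need >= n_instruments={truth.n_instruments}")
    rng = np.random.default_rng(truth.seed)
    n = n_blocks * truth.block_size

    ids = np.array([f"rs{i + 1}" for i in range(n)])
    block_of = np.repeat(np.arange(n_blocks), truth.block_size)
    chrom = np.array([str(b % 22 + 1) for b in block_of])
    # blocks 20 Mb apart (well beyond the clump window across blocks on
    # the same chromosome is NOT guaranteed at 10 Mb window; 20 Mb is),
    # members 2 kb apart within a block
    pos = (block_of // 22) * 20_000_000 + 1 + (np.arange(n) % truth.block_size) * 2000

    eaf = rng.uniform(0.05, 0.5, size=n)

    causal_blocks = rng.choice(n_blocks, size=truth.n_instruments, replace=False)
    gamma_block = np.zeros(n_blocks)
    gamma_block[causal_blocks] = rng.normal(0.0, truth.gamma_sd,
                                            size=truth.n_instruments)

    k_invalid = truth.n_invalid
    alpha_block = np.zeros(n_blocks)
    invalid_blocks = rng.choice(causal_blocks, size=k_invalid, replace=False)
    if k_invalid:
        if truth.pleiotropy_mode == "balanced":
            mags = np.abs(rng.normal(truth.alpha_mean, truth.alpha_sd,
                                     size=k_invalid // 2))
            mags = np.maximum(mags, 1e-6)  # alpha must be nonzero for invalids
            alpha_block[invalid_blocks] = np.concatenate([mags, -mags])
        else:
            # directional effects are expressed relative to the
            # exposure-increasing allele: a positive alpha_mean pushes the
            # outcome up wherever the instrument pushes the exposure up,
            # which is what biases IVW and what the Egger intercept targets
            draw = rng.normal(truth.alpha_mean, truth.alpha_sd, size=k_invalid)
            alpha_block[invalid_blocks] = draw * np.where(
                gamma_block[invalid_blocks] >= 0, 1.0, -1.0)

    is_index = (np.arange(n) % truth.block_size) == 0
    r = np.sqrt(truth.block_r2)
    gamma = gamma_block[block_of] * np.where(is_index, 1.0, r)
    alpha = alpha_block[block_of] * np.where(is_index, 1.0, r)

    het = 2.0 * eaf * (1.0 - eaf)
    se_exp = 1.0 / np.sqrt(truth.n_exp * het)
    v = truth.case_fraction
    se_out = 1.0 / np.sqrt(truth.n_out * v * (1.0 - v) * het)

    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(truth.theta * gamma + alpha, se_out)

    # allele coding
    pal = rng.random(n) < truth.frac_palindromic
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    ea = np.array([
        _PALINDROMIC_PAIRS[pal_idx[i]][0] if pal[i]
        else _NONPALINDROMIC_PAIRS[pair_idx[i]][0] for i in range(n)])
    oa = np.array([
        _PALINDROMIC_PAIRS[pal_idx[i]][1] if pal[i]
        else _NONPALINDROMIC_PAIRS[pair_idx[i]][1] for i in range(n)])

    info_exp = rng.uniform(0.6, 1.0, size=n)
    low = rng.random(n) < 0.02  # a sprinkle of poorly imputed variants
    info_exp[low] = rng.uniform(0.3, 0.6, size=int(low.sum()))

    exp_df = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta_exp, "se": se_exp, "pval": _pvals(beta_exp, se_exp),
        "info": info_exp, "n": truth.n_exp,
    })

    # outcome table: same variants, independently mangled allele coding
    swap = rng.random(n) < truth.frac_allele_swap
    flip = rng.random(n) < truth.frac_strand_flip
    ea_o = ea.copy()
    oa_o = oa.copy()
    beta_out_coded = beta_out.copy()
    eaf_o = eaf.copy()
    ea_o[swap], oa_o[swap] = oa[swap], ea[swap]
    beta_out_coded[swap] *= -1.0
    eaf_o[swap] = 1.0 - eaf_o[swap]
    ea_o[flip] = [_COMPLEMENT[a] for a in ea_o[flip]]
    oa_o[flip] = [_COMPLEMENT[a] for a in oa_o[flip]]

    out_df = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea_o, "other_allele": oa_o, "eaf": eaf_o,
        "beta": beta_out_coded, "se": se_out,
        "pval": _pvals(beta_out_coded, se_out),
        "info": rng.uniform(0.6, 1.0, size=n), "n": truth.n_out,
    })

    # LD reference: within-block proxy-index r² = block_r2, proxy-proxy
    # r² = block_r2² (single shared haplotype factor); cross-block 0
    pairs = {}
    blocks: list[list[str]] = []
    for b in range(n_blocks):
        members = ids[block_of == b].tolist()
        blocks.append(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                both_proxy = i > 0 and j > 0
                pairs[(members[i], members[j])] = (
                    truth.block_r2 ** 2 if both_proxy else truth.block_r2)
    positions = {ids[i]: (chrom[i], int(pos[i])) for i in range(n)}
    ld = LDReference(pairs, positions)

    truth.gamma = gamma
    truth.alpha = alpha
    truth.ld_blocks = blocks
    truth.instrument_ids = [blocks[b][0] for b in sorted(causal_blocks)]
    logger.info("simulate_pair: %d variants, %d blocks, %d causal, %d invalid",
                n, n_blocks, truth.n_instruments, k_invalid)
    return exp_df, out_df, ld
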