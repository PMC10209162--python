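"""Full bidirectional two-sample MR workflow.

Orchestrates, for every exposure-outcome pair: QC and variant
intersection, LD clumping on the exposure p-values, F-statistic
screening, allele harmonization, the MR-PRESSO global test with outlier
trimming when it is significant, the primary IVW estimate with
Cochran's Q, and Benjamini-Hochberg FDR correction of the IVW p-values
across outcomes within a direction.  The reverse direction treats each
disorder GWAS as the exposure; because those betas are log-odds, the
reverse causal effect is reported on the beta scale (exposure-SD per
unit log-odds liability) rather than as an odds ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import estimators as est
from .harmonize import HarmonizedInstruments, harmonize
from .instruments import ClumpParams, LDReference, clump, screen_strength
from .presso import presso_global, presso_outlier, trim_and_refit
from .sumstats import intersect_variants, qc_filter, read_sumstats

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "raps")


@dataclass
class AnalysisConfig:
    """Configuration of a bidirectional MR analysis (YAML-mappable)."""

    exposure: str = ""                       # path to exposure sumstats
    outcomes: dict = field(default_factory=dict)   # label -> path
    ld: str = ""                             # path to long-format LD table
    clump: ClumpParams = field(default_factory=ClumpParams)
    thresholds: tuple = (1e-6, 5e-8)         # instrument p-value thresholds
    methods: tuple = DEFAULT_METHODS
    f_min: float = 10.0
    maf_min: float = 0.05
    info_min: float = 0.6
    re_mode: str = "multiplicative"
    presso_n_sim: int = 1000
    presso_correction: str | None = None
    n_boot: int = 1000
    fdr_method: str = "benjamini-hochberg"
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.clump, dict):
            self.clump = ClumpParams(**self.clump)
        for t in self.thresholds:
            if not 0 < t < 1:
                raise ValueError(f"instrument threshold {t} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["methods"] = list(self.methods)
        return yaml.safe_dump(d, sort_keys=False)


@dataclass
class ReportRow:
    """One Table-1-style line: causal estimate of exposure on one outcome."""

    outcome: str
    nsnp: int
    beta: float = float("nan")
    se: float = float("nan")
    or_: float = float("nan")
    or_ci: tuple = (float("nan"), float("nan"))
    het_p: float = float("nan")
    presso_p: float = float("nan")
    pval: float = float("nan")
    padj: float = float("nan")
    scale: str = "or"          # "or" (binary outcome) or "beta" (reverse)
    note: str = ""

    def to_dict(self) -> dict:
        if self.scale == "or":
            eff, lo, hi = self.or_, self.or_ci[0], self.or_ci[1]
            cols = ("OR", "OR_95%CI")
        else:
            eff = self.beta
            lo, hi = self.beta - est.Z95 * self.se, self.beta + est.Z95 * self.se
            cols = ("beta", "beta_95%CI")
        return {
            "Outcome": self.outcome, "NSNP": self.nsnp,
            cols[0]: eff,
            cols[1]: f"{lo:.3f}-{hi:.3f}" if np.isfinite(lo) else "NA",
            "Het_p": self.het_p, "MR-PRESSO": self.presso_p,
            "pval": self.pval, "padj": self.padj, "note": self.note,
        }


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("fdr_adjust: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spawn_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


def _select_instruments(exposure, ld, cfg: AnalysisConfig, p1: float):
    params = ClumpParams(window_kb=cfg.clump.window_kb, p1=p1,
                         r2_max=cfg.clump.r2_max)
    instr = clump(exposure, ld, params)
    return screen_strength(instr, exposure, f_min=cfg.f_min)


def _presso_step(h: HarmonizedInstruments, cfg: AnalysisConfig, seed: int):
    """Global test; trim outliers when significant. Returns (h, global_p, note)."""
    if h.n_snps < 4:
        return h, float("nan"), "too few instruments for PRESSO"
    res = presso_global(h, n_sim=cfg.presso_n_sim, seed=seed)
    if res.global_p >= 0.05:
        return h, res.global_p, ""
    res = presso_outlier(res, h, correction=cfg.presso_correction)
    if not res.flagged:
        return h, res.global_p, "global test significant, no outlier flagged"
    try:
        h2 = trim_and_refit(h, res)
    except ValueError as e:
        return h, res.global_p, str(e)
    res2 = presso_global(h2, n_sim=cfg.presso_n_sim, seed=seed + 1)
    note = "" if res2.global_p > 0.05 else "pleiotropy persists after trimming"
    logger.info("presso trim: %d removed, global_p %.3g -> %.3g",
                len(res.flagged), res.global_p, res2.global_p)
    return h2, res2.global_p, note


def run_direction(exposure: pd.DataFrame, outcomes: dict[str, pd.DataFrame],
                  ld: LDReference, cfg: AnalysisConfig,
                  scale: str = "or") -> list[ReportRow]:
    """One MR direction: the exposure against every outcome table.

    Inputs are expected QC'd and intersected.  Instruments come from
    clumping on the exposure p-values at the primary threshold
    (``cfg.thresholds[0]``).  PRESSO trimming is applied when the global
    test is significant at 0.05.  ``padj`` is BH across the outcomes'
    IVW p-values within this direction.
    """
    try:
        instr = _select_instruments(exposure, ld, cfg, cfg.thresholds[0])
    except ValueError as e:
        return [ReportRow(outcome=lbl, nsnp=0, scale=scale, note=str(e))
                for lbl in outcomes]
    rows: list[ReportRow] = []
    for k, (label, out_tab) in enumerate(outcomes.items()):
        seed = _spawn_seed(cfg.seed, k)
        h = harmonize(exposure, out_tab, instr)
        if h.n_snps < 2:
            rows.append(ReportRow(outcome=label, nsnp=h.n_snps, scale=scale,
                                  note="too few harmonized instruments"))
            continue
        h, presso_p, note = _presso_step(h, cfg, seed)
        try:
            e = est.ivw(h, re_mode=cfg.re_mode)
        except ValueError as exc:
            rows.append(ReportRow(outcome=label, nsnp=h.n_snps, scale=scale,
                                  note=str(exc)))
            continue
        rows.append(ReportRow(
            outcome=label, nsnp=e.n_snps, beta=e.beta, se=e.se,
            or_=e.or_, or_ci=e.or_ci, het_p=e.extra.get("het_p", float("nan")),
            presso_p=presso_p, pval=e.pval, scale=scale, note=note,
        ))
    ok = [i for i, r in enumerate(rows) if np.isfinite(r.pval)]
    if ok:
        padj = fdr_adjust([rows[i].pval for i in ok])
        for i, a in zip(ok, padj):
            rows[i].padj = float(a)
    return rows


def prepare_tables(cfg: AnalysisConfig) -> dict:
    """Read, QC and intersect the configured tables; build the LD lookup.

    Returns {"exposure": DataFrame, "outcomes": {label: DataFrame},
    "ld": LDReference} ready for :func:`run_direction` and friends.
    """
    exposure = read_sumstats(cfg.exposure)
    outcomes = {lbl: read_sumstats(p) for lbl, p in cfg.outcomes.items()}
    exposure, _ = qc_filter(exposure, maf_min=cfg.maf_min, info_min=cfg.info_min)
    outcomes = {lbl: qc_filter(t, maf_min=cfg.maf_min, info_min=cfg.info_min)[0]
                for lbl, t in outcomes.items()}
    inter = intersect_variants([exposure, *outcomes.values()])
    exposure = inter[0]
    outcomes = dict(zip(outcomes.keys(), inter[1:]))
    positions = dict(zip(exposure["variant_id"],
                         zip(exposure["chrom"], exposure["pos"])))
    ld = LDReference.from_long(cfg.ld, positions)
    return {"exposure": exposure, "outcomes": outcomes, "ld": ld}


def run_bidirectional(cfg: AnalysisConfig,
                      tables: dict | None = None
                      ) -> tuple[list[ReportRow], list[ReportRow]]:
    """Forward (exposure -> each outcome) and reverse (outcome -> exposure) MR.

    ``tables``, when given, bypasses file I/O: a dict with keys
    ``exposure`` (DataFrame), ``outcomes`` (label -> DataFrame) and
    ``ld`` (LDReference), already QC'd and intersected.  Otherwise the
    paths in ``cfg`` are read, QC'd and intersected here.  Reverse rows
    are on the beta scale and FDR-corrected separately.
    """
    if tables is None:
        tables = prepare_tables(cfg)
    exposure = tables["exposure"]
    outcomes = tables["outcomes"]
    ld = tables["ld"]

    forward = run_direction(exposure, outcomes, ld, cfg, scale="or")
    reverse: list[ReportRow] = []
    for k, (label, disorder) in enumerate(outcomes.items()):
        rev_cfg = AnalysisConfig(**{**asdict_shallow(cfg), "seed": _spawn_seed(cfg.seed, 1000 + k)})
        row = run_direction(disorder, {label: exposure}, ld, rev_cfg, scale="beta")[0]
        reverse.append(row)
    ok = [i for i, r in enumerate(reverse) if np.isfinite(r.pval)]
    if ok:
        padj = fdr_adjust([reverse[i].pval for i in ok])
        for i, a in zip(ok, padj):
            reverse[i].padj = float(a)
    return forward, reverse


def asdict_shallow(cfg: AnalysisConfig) -> dict:
    d = dict(cfg.__dict__)
    d["clump"] = ClumpParams(**asdict(cfg.clump)) if not isinstance(cfg.clump, dict) else cfg.clump
    return d


def sensitivity_grid(exposure: pd.DataFrame, outcomes: dict[str, pd.DataFrame],
                     ld: LDReference, cfg: AnalysisConfig) -> pd.DataFrame:
    """Full sensitivity cross: thresholds x methods x directions x outcomes.

    For each instrument-significance threshold the instrument set is
    rebuilt, PRESSO-trimmed once, and shared by all estimators at that
    threshold.  Cells that cannot be estimated (too few instruments)
    become NA rows with the reason recorded.
    """
    records = []
    cell = 0
    for p1 in cfg.thresholds:
        for direction in ("forward", "reverse"):
            pairs = (list(outcomes.items()) if direction == "forward"
                     else [(lbl, exposure) for lbl in outcomes])
            for k, (label, out_tab) in enumerate(pairs):
                exp_tab = exposure if direction == "forward" else outcomes[label]
                cell += 1
                seed = _spawn_seed(cfg.seed, 5000 + cell)
                try:
                    instr = _select_instruments(exp_tab, ld, cfg, p1)
                    h = harmonize(exp_tab, out_tab, instr)
                    if h.n_snps < 2:
                        raise ValueError("too few harmonized instruments")
                    h, _, _ = _presso_step(h, cfg, seed)
                except ValueError as e:
                    for m in cfg.methods:
                        records.append(dict(direction=direction, outcome=label,
                                            threshold=p1, method=m, nsnp=0,
                                            beta=np.nan, se=np.nan, ci_low=np.nan,
                                            ci_high=np.nan, pval=np.nan, note=str(e)))
                    continue
                for m in cfg.methods:
                    try:
                        e = _run_method(m, h, cfg, seed)
                        records.append(dict(direction=direction, outcome=label,
                                            threshold=p1, method=m, nsnp=e.n_snps,
                                            beta=e.beta, se=e.se, ci_low=e.ci_low,
                                            ci_high=e.ci_high, pval=e.pval, note=""))
                    except (ValueError, est.ConvergenceError) as exc:
                        records.append(dict(direction=direction, outcome=label,
                                            threshold=p1, method=m, nsnp=h.n_snps,
                                            beta=np.nan, se=np.nan, ci_low=np.nan,
                                            ci_high=np.nan, pval=np.nan, note=str(exc)))
    return pd.DataFrame.from_records(records)


def _run_method(name: str, h: HarmonizedInstruments, cfg: AnalysisConfig,
                seed: int) -> est.MREstimate:
    if name == "ivw":
        return est.ivw(h, re_mode=cfg.re_mode)
    if name == "egger":
        return est.egger(h)
    if name == "weighted_median":
        return est.weighted_median(h, n_boot=cfg.n_boot, seed=seed)
    if name == "raps":
        return est.raps(h)
    raise ValueError(f"unknown method {name!r}")


def effect_concordance(a: pd.DataFrame, b: pd.DataFrame,
                       sig_p: float = 5e-8) -> tuple[int, float]:
    """Cross-cohort sign agreement among table-a-significant variants.

    Restricts to variants with ``pval < sig_p`` in table ``a`` that are
    also present in ``b``; aligns ``b``'s betas to ``a``'s effect allele
    (allele swap and strand complement resolved as in harmonization,
    irreconcilable rows skipped) and returns the count of shared
    significant variants and the fraction whose aligned betas agree in
    sign.  (0, nan) when nothing is significant.
    """
    sel = a.loc[a["pval"] < sig_p]
    if sel.empty:
        return 0, float("nan")
    b_by = b.set_index("variant_id")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    n = 0
    agree = 0
    for _, row in sel.iterrows():
        v = row["variant_id"]
        if v not in b_by.index:
            continue
        o = b_by.loc[v]
        ea, oa = row["effect_allele"], row["other_allele"]
        pair = (o["effect_allele"], o["other_allele"])
        cpair = (comp.get(pair[0]), comp.get(pair[1]))
        if pair == (ea, oa) or cpair == (ea, oa):
            sign = 1.0
        elif pair == (oa, ea) or cpair == (oa, ea):
            sign = -1.0
        else:
            continue
        n += 1
        if np.sign(row["beta"]) == np.sign(sign * o["beta"]):
            agree += 1
    return n, (agree / n if n else float("nan"))


def report_to_frame(rows: list[ReportRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def write_report(rows: list[ReportRow], path) -> None:
    report_to_frame(rows).to_csv(path, sep="\t", index=False)
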