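"""MR-PRESSO: pleiotropy residual sum of squares and outlier detection.

The global test compares the observed leave-one-out residual sum of
squares

    RSS = sum_j w_j (beta_out_j - bhat_(-j) * beta_exp_j)^2,
    w_j = 1 / se_out_j^2,

where ``bhat_(-j)`` is the fixed-effect IVW estimate with instrument j
held out, against a Monte-Carlo null built by redrawing
``beta_out*_j ~ N(bhat_(-j) beta_exp_j, se_out_j)`` and
``beta_exp*_j ~ N(beta_exp_j, se_exp_j)`` and recomputing RSS on each
replicate.  The per-SNP outlier test compares each observed weighted
residual against its own simulated distribution.  Monte-Carlo p-values
use the add-one estimator (1 + #{>= obs}) / (n_sim + 1), so they are
never zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .estimators import _extract
from .harmonize import HarmonizedInstruments

logger = logging.getLogger(__name__)


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    n_sim: int
    seed: int
    outlier_p: dict[str, float] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)
    # per-replicate per-SNP simulated weighted residuals and the observed
    # ones, retained so presso_outlier can run without re-simulating
    _sim_resid: np.ndarray | None = field(default=None, repr=False)
    _obs_resid: np.ndarray | None = field(default=None, repr=False)
    _ids: list[str] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_p": self.global_p,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "outlier_p": self.outlier_p,
            "flagged": self.flagged,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _loo_ivw_beta(w, bx, by):
    """Vectorized leave-one-out fixed-effect IVW estimates.

    Accepts (n,) or (m, n) arrays for bx/by; returns estimates of the
    same shape, entry j computed with instrument j excluded.
    """
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx ** 2, axis=-1, keepdims=True)
    denom = s_xx - w * bx ** 2
    if np.any(denom == 0):
        raise ValueError("presso: leave-one-out IVW undefined (zero exposure signal)")
    return (s_xy - w * bx * by) / denom


def presso_global(h, n_sim: int = 1000, seed: int | None = None) -> PressoResult:
    """MR-PRESSO global horizontal-pleiotropy test.

    Requires at least 4 instruments and n_sim >= 1000; ``seed`` is
    mandatory so results are reproducible.  The returned result carries
    the simulated per-SNP residuals needed by :func:`presso_outlier`.
    """
    bx, sx, by, sy = _extract(h)
    n = len(bx)
    if n < 4:
        raise ValueError("too few instruments for PRESSO (need >= 4)")
    if n_sim < 1000:
        raise ValueError("presso_global: n_sim must be >= 1000")
    if seed is None:
        raise ValueError("presso_global: seed is required")
    ids = (h.df["variant_id"].tolist() if isinstance(h, HarmonizedInstruments)
           else [str(i) for i in range(n)])

    w = 1.0 / sy ** 2
    loo = _loo_ivw_beta(w, bx, by)
    obs_resid = w * (by - loo * bx) ** 2
    rss_obs = float(np.sum(obs_resid))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, n))
    by_star = rng.normal(loo * bx, sy, size=(n_sim, n))
    loo_star = _loo_ivw_beta(w, bx_star, by_star)
    sim_resid = w * (by_star - loo_star * bx_star) ** 2
    rss_star = sim_resid.sum(axis=1)
    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    logger.info("presso_global: RSS=%.4g global_p=%.4g (n=%d, n_sim=%d)",
                rss_obs, global_p, n, n_sim)
    return PressoResult(
        rss_obs=rss_obs, global_p=global_p, n_sim=n_sim, seed=seed,
        _sim_resid=sim_resid, _obs_resid=obs_resid, _ids=ids,
    )


def presso_outlier(res: PressoResult, h, alpha: float = 0.05,
                   correction: str | None = None) -> PressoResult:
    """Per-SNP outlier test from the stored global-test simulations.

    Flags instruments whose observed weighted residual is extreme
    relative to its simulated null (Monte-Carlo p < ``alpha``,
    uncorrected by default; ``correction="bonferroni"`` divides alpha by
    the instrument count, the original method's default).
    """
    if res._sim_resid is None or res._obs_resid is None:
        raise ValueError("presso_outlier: run presso_global first (simulations not stored)")
    n = len(res._obs_resid)
    counts = np.sum(res._sim_resid >= res._obs_resid[None, :], axis=0)
    pvals = (1 + counts) / (res.n_sim + 1)
    thr = alpha / n if correction == "bonferroni" else alpha
    res.outlier_p = {vid: float(p) for vid, p in zip(res._ids, pvals)}
    res.flagged = [vid for vid, p in res.outlier_p.items() if p < thr]
    logger.info("presso_outlier: flagged %d/%d at p<%g", len(res.flagged), n, thr)
    return res


def trim_and_refit(h: HarmonizedInstruments, res: PressoResult) -> HarmonizedInstruments:
    """Remove PRESSO-flagged instruments from a harmonized set.

    The caller is expected to re-run :func:`presso_global` on the result
    to confirm the global test is no longer significant.  Refuses to
    trim below 2 instruments.
    """
    flagged = set(res.flagged)
    if not flagged:
        return h
    keep = ~h.df["variant_id"].isin(flagged)
    if int(keep.sum()) < 2:
        raise ValueError("trim_and_refit: trimming would leave fewer than 2 instruments")
    return h.subset(keep.to_numpy())
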