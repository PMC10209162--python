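"""Two-sample MR causal-effect estimators and diagnostics.

All estimators consume harmonized per-instrument summary data: exposure
beta/se and outcome beta/se aligned to a shared effect allele.  They are
written as scikit-learn style estimators — construct with options, call
``fit(X)``, read fitted attributes (``beta_``, ``se_``, ``pval_``, ...)
— where ``X`` is a :class:`~mr2s.harmonize.HarmonizedInstruments`, a
DataFrame with columns beta_exp/se_exp/beta_out/se_out, or an (n, 4)
array in that column order.  Module-level functions (:func:`ivw`,
:func:`egger`, :func:`weighted_median`, :func:`raps`) are thin wrappers
returning an :class:`MREstimate`.

Methods
-------
IVW
    Inverse-variance weighted meta-analysis of Wald ratios, i.e.
    weighted regression of beta_out on beta_exp through the origin with
    weights 1/se_out².  Fixed-effect or multiplicative random-effects
    standard errors.
Egger
    WLS with intercept after orienting instruments to non-negative
    beta_exp; the intercept estimates the mean directional pleiotropic
    effect (valid under InSIDE), the slope the causal effect.
Weighted median
    Median of the weighted empirical distribution of per-SNP Wald
    ratios; consistent when valid instruments carry a majority of the
    weight.  SE by seeded parametric bootstrap.
RAPS
    Robust adjusted profile score: solves the profile estimating
    equation for the causal effect accounting for measurement error in
    both beta_exp and beta_out, with optional Huber robustification and
    a profiled overdispersion parameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .harmonize import HarmonizedInstruments

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile, used for every confidence interval
Z95 = 1.959964

_TINY_P = np.finfo(float).tiny


class ConvergenceError(RuntimeError):
    pass


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-odds (or beta) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_ci: tuple[float, float]
    n_snps: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pval, "or": self.or_,
            "or_ci_low": self.or_ci[0], "or_ci_high": self.or_ci[1],
            "n_snps": self.n_snps,
        }
        d.update(self.extra)
        return d


@dataclass
class LeaveOneOutResult:
    per_snp: dict[str, MREstimate]
    overall: MREstimate

    def to_frame(self) -> pd.DataFrame:
        rows = [{"excluded": k, **v.to_dict()} for k, v in self.per_snp.items()]
        rows.append({"excluded": "All", **self.overall.to_dict()})
        return pd.DataFrame(rows)


def _extract(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coerce any accepted input shape to (bx, sx, by, sy) float arrays."""
    if isinstance(X, HarmonizedInstruments):
        bx, sx, by, sy = X.arrays()
    elif isinstance(X, pd.DataFrame):
        bx = X["beta_exp"].to_numpy(float)
        sx = X["se_exp"].to_numpy(float)
        by = X["beta_out"].to_numpy(float)
        sy = X["se_out"].to_numpy(float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError(
                "array input must be (n, 4): beta_exp, se_exp, beta_out, se_out")
        bx, sx, by, sy = arr.T
    if not (np.isfinite(bx).all() and np.isfinite(by).all()):
        raise ValueError("non-finite betas in input")
    if np.any(sy <= 0) or np.any(sx < 0):
        raise ValueError("se_out must be > 0 and se_exp >= 0")
    return bx, sx, by, sy


def _two_sided_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _TINY_P)


class _BaseMR(BaseEstimator):
    """Shared fit plumbing: input coercion, CI/p/OR derivation."""

    method: str = "base"
    _min_snps: int = 2

    def fit(self, X, y=None):
        bx, sx, by, sy = _extract(X)
        n = len(bx)
        if n < self._min_snps:
            raise ValueError(
                f"{self.method}: needs at least {self._min_snps} instruments, got {n}")
        self.n_snps_ = n
        self.extra_ = {}
        self._fit(bx, sx, by, sy)
        self.ci_low_ = self.beta_ - Z95 * self.se_
        self.ci_high_ = self.beta_ + Z95 * self.se_
        self.pval_ = _two_sided_p(self.beta_ / self.se_) if self.se_ > 0 else (
            1.0 if self.beta_ == 0 else _TINY_P)
        self.or_ = float(np.exp(self.beta_))
        self.or_ci_ = (float(np.exp(self.ci_low_)), float(np.exp(self.ci_high_)))
        return self

    def _fit(self, bx, sx, by, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def estimate_(self) -> MREstimate:
        return MREstimate(
            method=self.method, beta=float(self.beta_), se=float(self.se_),
            ci_low=float(self.ci_low_), ci_high=float(self.ci_high_),
            pval=float(self.pval_), or_=self.or_, or_ci=self.or_ci_,
            n_snps=self.n_snps_, extra=dict(self.extra_),
        )


def _ivw_core(bx, by, sy):
    """Fixed-effect IVW point estimate, SE and Cochran's Q (closed form)."""
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * bx ** 2))
    if denom == 0:
        raise ValueError("ivw: all beta_exp are zero; causal effect not identified")
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


class IVWEstimator(_BaseMR):
    """Inverse-variance weighted estimator.

    Parameters
    ----------
    re_mode : {"multiplicative", "fixed"}
        "fixed" uses the analytic weighted-regression SE; the default
        multiplicative random-effects model inflates it by
        max(1, sqrt(Q / (n - 1))), guarding against mild heterogeneity
        without ever shrinking the SE below the fixed-effect one.
    """

    method = "ivw"
    _min_snps = 1

    def __init__(self, re_mode: str = "multiplicative"):
        self.re_mode = re_mode

    def _fit(self, bx, sx, by, sy):
        if self.re_mode not in ("fixed", "multiplicative"):
            raise ValueError(f"unknown re_mode {self.re_mode!r}")
        if self.re_mode == "multiplicative" and self.n_snps_ < 2:
            raise ValueError("multiplicative IVW needs >= 2 instruments")
        beta, se, q = _ivw_core(bx, by, sy)
        n = self.n_snps_
        het_p = float(stats.chi2.sf(q, n - 1)) if n >= 2 else float("nan")
        if self.re_mode == "multiplicative":
            se *= max(1.0, np.sqrt(q / (n - 1)))
        self.beta_, self.se_ = beta, float(se)
        self.extra_ = {"Q": q, "het_p": het_p}


class EggerEstimator(_BaseMR):
    """MR-Egger regression: WLS of beta_out on beta_exp with intercept.

    Instruments are first oriented so beta_exp >= 0 (negating both betas
    where needed), which the intercept's identifiability requires.  SEs
    carry a multiplicative overdispersion factor max(1, residual scale).
    The fitted intercept and its p-value (``intercept_``,
    ``intercept_pval_``) are the directional-pleiotropy test.
    """

    method = "egger"
    _min_snps = 3

    def _fit(self, bx, sx, by, sy):
        sign = np.where(bx < 0, -1.0, 1.0)
        bx = bx * sign
        by = by * sign
        if np.ptp(bx) == 0:
            raise ValueError("egger: zero variance in |beta_exp|; slope not identified")
        w = 1.0 / sy ** 2
        res = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        infl = np.sqrt(max(1.0, float(res.scale)))
        # fixed-effect SEs: unscaled (X' W X)^-1, robust to a zero residual scale
        bse_fixed = np.sqrt(np.diag(res.normalized_cov_params))
        self.beta_ = float(res.params[1])
        self.se_ = float(bse_fixed[1] * infl)
        icpt_se = float(bse_fixed[0] * infl)
        icpt = float(res.params[0])
        self.extra_ = {
            "intercept": icpt,
            "intercept_se": icpt_se,
            "intercept_pval": _two_sided_p(icpt / icpt_se),
            "overdispersion": float(res.scale),
        }
        self.intercept_ = icpt
        self.intercept_se_ = icpt_se
        self.intercept_pval_ = self.extra_["intercept_pval"]


def _weighted_median_1d(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated median of a weighted empirical distribution.

    Cumulative probability of the j-th sorted value is
    p_j = (sum_{i<=j} w_i - w_j / 2) / sum_i w_i; the estimate is the
    linear interpolation of (p, value) at p = 0.5.
    """
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    p = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(0.5, p, v))


class WeightedMedianEstimator(_BaseMR):
    """Weighted-median of per-SNP Wald ratios with bootstrap SE.

    Weights are beta_exp² / se_out² (inverse variance of each ratio
    under a first-order delta approximation).  The SE comes from a
    seeded parametric bootstrap that redraws beta_exp and beta_out from
    normal distributions centred on the observed values.
    """

    method = "weighted_median"
    _min_snps = 3

    def __init__(self, n_boot: int = 1000, seed: int | None = None):
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, bx, sx, by, sy):
        if self.seed is None:
            raise ValueError("weighted_median: seed is required for the bootstrap")
        nz = bx != 0
        if not nz.all():
            warnings.warn(
                f"weighted_median: excluding {int((~nz).sum())} instrument(s) "
                "with beta_exp == 0", stacklevel=2)
            bx, sx, by, sy = bx[nz], sx[nz], by[nz], sy[nz]
            if len(bx) < self._min_snps:
                raise ValueError("weighted_median: fewer than 3 usable instruments")
            self.n_snps_ = len(bx)
        ratios = by / bx
        weights = bx ** 2 / sy ** 2
        self.beta_ = _weighted_median_1d(ratios, weights)

        rng = np.random.default_rng(self.seed)
        n = len(bx)
        bx_star = rng.normal(bx, sx, size=(self.n_boot, n))
        by_star = rng.normal(by, sy, size=(self.n_boot, n))
        with np.errstate(divide="ignore", invalid="ignore"):
            r_star = by_star / bx_star
            w_star = bx_star ** 2 / sy ** 2
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            ok = np.isfinite(r_star[i])
            boots[i] = _weighted_median_1d(r_star[i][ok], w_star[i][ok])
        self.se_ = float(np.std(boots, ddof=1))
        if self.se_ == 0:  # degenerate: all ratios identical, zero noise
            self.se_ = _TINY_P
        self.extra_ = {"n_boot": self.n_boot, "seed": self.seed}


def _huber_psi(t: np.ndarray, c: float = 1.345) -> np.ndarray:
    return np.clip(t, -c, c)


def _psi_expectation(loss: str, c: float = 1.345) -> float:
    """E[psi(Z) Z] for Z ~ N(0,1); calibrates the overdispersion moment."""
    if loss == "l2":
        return 1.0
    # closed form: E[Z^2; |Z|<c] + c E[|Z|; |Z|>=c] = 1 - 2 Phi(-c)
    return 1.0 - 2.0 * stats.norm.cdf(-c)


class RAPSEstimator(_BaseMR):
    """Robust adjusted profile score estimator.

    Solves the profile estimating equation
    ``sum_j psi(t_j(beta)) * d t_j / d beta = 0`` with standardized
    residuals ``t_j = (beta_out_j - beta * beta_exp_j) /
    sqrt(se_out_j² + beta² se_exp_j² + tau²)``, so measurement error on
    the exposure side is accounted for (no NOME assumption).

    Parameters
    ----------
    loss : {"huber", "l2"}
        psi is the identity for "l2", the Huber score (c = 1.345) for
        "huber".
    overdispersion : bool
        Profile a systematic-pleiotropy variance tau² >= 0 via the
        moment condition mean(psi(t) t) = E[psi(Z) Z].
    """

    method = "raps"
    _min_snps = 3
    _huber_c = 1.345

    def __init__(self, loss: str = "huber", overdispersion: bool = True):
        self.loss = loss
        self.overdispersion = overdispersion

    def _psi(self, t):
        if self.loss == "l2":
            return t
        if self.loss == "huber":
            return _huber_psi(t, self._huber_c)
        raise ValueError(f"unknown loss {self.loss!r}")

    @staticmethod
    def _t_and_grad(beta, bx, sx, by, sy, tau2):
        var = sy ** 2 + beta ** 2 * sx ** 2 + tau2
        sd = np.sqrt(var)
        t = (by - beta * bx) / sd
        dt = -(bx / sd) - t * beta * sx ** 2 / var
        return t, dt

    def _score(self, beta, bx, sx, by, sy, tau2):
        t, dt = self._t_and_grad(beta, bx, sx, by, sy, tau2)
        return float(np.sum(self._psi(t) * dt))

    def _solve_beta(self, bx, sx, by, sy, tau2, center):
        f = lambda b: self._score(b, bx, sx, by, sy, tau2)
        half = 0.5
        for _ in range(12):
            lo, hi = center - half, center + half
            flo, fhi = f(lo), f(hi)
            if np.sign(flo) != np.sign(fhi):
                return float(optimize.brentq(f, lo, hi, xtol=1e-12))
            half *= 2.0
        raise ConvergenceError("raps: estimate did not converge (no score sign change)")

    def _solve_tau2(self, beta, bx, sx, by, sy):
        target = len(bx) * _psi_expectation(self.loss, self._huber_c)

        def g(tau2):
            t, _ = self._t_and_grad(beta, bx, sx, by, sy, tau2)
            return float(np.sum(self._psi(t) * t)) - target

        if g(0.0) <= 0:
            return 0.0
        hi = 1.0
        for _ in range(60):
            if g(hi) < 0:
                break
            hi *= 4.0
        else:  # pragma: no cover - pathological scale
            raise ConvergenceError("raps: overdispersion profiling failed")
        return float(optimize.brentq(g, 0.0, hi, xtol=1e-14))

    def _fit(self, bx, sx, by, sy):
        center, _, _ = _ivw_core(bx, by, sy)
        tau2 = 0.0
        beta = self._solve_beta(bx, sx, by, sy, tau2, center)
        if self.overdispersion:
            for _ in range(100):
                tau2_new = self._solve_tau2(beta, bx, sx, by, sy)
                beta_new = self._solve_beta(bx, sx, by, sy, tau2_new, beta)
                if (abs(beta_new - beta) < 1e-10 * max(1.0, abs(beta))
                        and abs(tau2_new - tau2) < 1e-12 * max(1.0, tau2)):
                    beta, tau2 = beta_new, tau2_new
                    break
                beta, tau2 = beta_new, tau2_new

        # sandwich variance: Var = sum(s_j^2) / (dS/dbeta)^2
        t, dt = self._t_and_grad(beta, bx, sx, by, sy, tau2)
        s_j = self._psi(t) * dt
        h = 1e-6 * max(1.0, abs(beta))
        dS = (self._score(beta + h, bx, sx, by, sy, tau2)
              - self._score(beta - h, bx, sx, by, sy, tau2)) / (2 * h)
        if dS == 0:
            raise ConvergenceError("raps: flat score; SE undefined")
        self.beta_ = float(beta)
        self.se_ = float(np.sqrt(np.sum(s_j ** 2)) / abs(dS))
        self.extra_ = {"tau2": float(tau2), "loss": self.loss}
        self.tau2_ = float(tau2)


# ---------------------------------------------------------------------------
# functional wrappers and diagnostics


def ivw(h, re_mode: str = "multiplicative") -> MREstimate:
    return IVWEstimator(re_mode=re_mode).fit(h).estimate_


def egger(h) -> MREstimate:
    return EggerEstimator().fit(h).estimate_


def weighted_median(h, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(h).estimate_


def raps(h, loss: str = "huber", overdispersion: bool = True) -> MREstimate:
    return RAPSEstimator(loss=loss, overdispersion=overdispersion).fit(h).estimate_


def cochran_q(h, beta: float) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic of per-SNP Wald ratios.

    Q = sum_j w_j (ratio_j - beta)² with w_j = (se_out_j / beta_exp_j)^-2,
    computed in the algebraically identical residual form
    ((beta_out_j - beta * beta_exp_j) / se_out_j)², which stays defined
    when beta_exp_j = 0.  Returns (Q, p) with p from chi²(n-1).
    """
    bx, _, by, sy = _extract(h)
    if len(bx) < 2:
        raise ValueError("cochran_q: needs at least 2 instruments")
    q = float(np.sum(((by - beta * bx) / sy) ** 2))
    return q, float(stats.chi2.sf(q, len(bx) - 1))


def leave_one_out(h, re_mode: str = "multiplicative") -> LeaveOneOutResult:
    """IVW re-estimated with each instrument excluded in turn."""
    if isinstance(h, HarmonizedInstruments):
        ids = h.df["variant_id"].tolist()
    else:
        bx0, _, _, _ = _extract(h)
        ids = [str(i) for i in range(len(bx0))]
    bx, sx, by, sy = _extract(h)
    n = len(bx)
    if n < 3:
        raise ValueError("leave_one_out: needs at least 3 instruments")
    per = {}
    for j, vid in enumerate(ids):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        per[vid] = IVWEstimator(re_mode=re_mode).fit(
            np.column_stack([bx[mask], sx[mask], by[mask], sy[mask]])).estimate_
    overall = IVWEstimator(re_mode=re_mode).fit(
        np.column_stack([bx, sx, by, sy])).estimate_
    return LeaveOneOutResult(per_snp=per, overall=overall)


def estimates_to_frame(estimates: list[MREstimate]) -> pd.DataFrame:
    """Flat results table for serialization (tab-delimited or JSON)."""
    return pd.DataFrame([e.to_dict() for e in estimates])
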