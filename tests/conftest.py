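"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths:
clumping is checked against an exhaustive subset-enumeration oracle,
IVW/Egger against explicit normal-equation matrix algebra.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mr2s.harmonize import HarmonizedInstruments


# ---------------------------------------------------------------------------
# instrument-level data generation (summary scale, strong valid instruments)

def draw_instruments(rng, n, theta, alpha=None, n_exp=8138, n_out=100_000,
                     case_fraction=0.5):
    """Draw one two-sample summary dataset with known causal effect.

    True instrument effects are strong (|gamma| uniform on [0.12, 0.5]),
    emulating post-selection instruments; sampling noise is independent
    between the exposure and outcome sides.  Returns an (n, 4) array of
    (beta_exp, se_exp, beta_out, se_out).
    """
    gamma = rng.uniform(0.12, 0.5, size=n) * rng.choice([-1.0, 1.0], size=n)
    if alpha is None:
        alpha = np.zeros(n)
    eaf = rng.uniform(0.05, 0.5, size=n)
    het = 2 * eaf * (1 - eaf)
    se_exp = 1.0 / np.sqrt(n_exp * het)
    v = case_fraction
    se_out = 1.0 / np.sqrt(n_out * v * (1 - v) * het)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(theta * gamma + alpha, se_out)
    return np.column_stack([beta_exp, se_exp, beta_out, se_out])


def as_harmonized(arr, ids=None) -> HarmonizedInstruments:
    n = len(arr)
    ids = ids or [f"rs{i+1}" for i in range(n)]
    df = pd.DataFrame({
        "variant_id": ids,
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": arr[:, 0], "se_exp": arr[:, 1],
        "beta_out": arr[:, 2], "se_out": arr[:, 3],
        "eaf_exp": 0.3, "eaf_out": 0.3, "pval_exp": 1e-8,
    })
    return HarmonizedInstruments(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


# ---------------------------------------------------------------------------
# independent oracles

def wls_oracle(x, y, w, intercept: bool):
    """Weighted least squares by explicit normal equations.

    Returns (coefs, fixed_se, scale) where scale is the weighted
    residual mean square (df = n - p) and fixed_se the unscaled
    sqrt(diag((X' W X)^-1)).
    """
    x = np.asarray(x, float)
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    W = np.diag(np.asarray(w, float))
    xtwx = X.T @ W @ X
    coefs = np.linalg.solve(xtwx, X.T @ W @ np.asarray(y, float))
    resid = y - X @ coefs
    dof = len(x) - X.shape[1]
    scale = float(resid @ W @ resid / dof) if dof > 0 else float("nan")
    fixed_se = np.sqrt(np.diag(np.linalg.inv(xtwx)))
    return coefs, fixed_se, scale


def clump_oracle(sig: pd.DataFrame, ld, params):
    """Exhaustive clumping oracle: enumerate subsets, keep the unique one
    satisfying the greedy fixed point.

    A set S of significant variants is the clumping result iff, scanning
    variants in (p, chrom, pos, id) order, each variant is in S exactly
    when no earlier member of S claims it (same chromosome, within the
    window, r² at/above threshold).
    """
    order = sig.sort_values(["pval", "chrom", "pos", "variant_id"],
                            kind="mergesort")
    ids = order["variant_id"].tolist()
    chrom = dict(zip(order["variant_id"], order["chrom"].astype(str)))
    pos = dict(zip(order["variant_id"], order["pos"].astype(int)))
    window = params.window_kb * 1000

    def claims(u, v):
        return (chrom[u] == chrom[v] and abs(pos[u] - pos[v]) <= window
                and ld.r2(u, v) >= params.r2_max)

    n = len(ids)
    assert n <= 14, "oracle is exponential; keep instances small"
    valid = []
    for mask in range(1, 2 ** n):
        S = {ids[i] for i in range(n) if mask >> i & 1}
        ok = True
        for i, v in enumerate(ids):
            claimed = any(ids[j] in S and claims(ids[j], v) for j in range(i))
            if (v in S) == claimed:
                ok = False
                break
        if ok:
            valid.append(S)
    assert len(valid) == 1, f"greedy fixed point not unique: {valid}"
    return valid[0]
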