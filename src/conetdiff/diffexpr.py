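"""Per-gene two-group differential expression with q-value FDR control.

The model is a completely randomized two-group design on normalized log2
values: y_ij = mu + G_i + eps_ij, tested per gene with a pooled-variance
two-sample t.  By default the gene-wise variances are shrunk toward an
empirical-Bayes prior (moderated t with augmented degrees of freedom), which
stabilizes the statistic at small replicate numbers; the plain t is
available by flag.

Fold changes are reported on the linear scale as A/B = 2^(mean_A - mean_B),
with condition A the wild-type-like reference, so fold change > 1 means
higher expression in A ("Up").

False-discovery control follows either plain Benjamini-Hochberg or Storey's
q-values (BH scaled by an estimate of the null proportion pi0).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DesignError
from .matrixio import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = ["differential_expression", "estimate_qvalues"]

_PI0_LAMBDA_GRID = np.arange(0.05, 0.951, 0.05)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _estimate_pi0(p: np.ndarray) -> float:
    """Storey's pi0: pi0(lambda) on a grid, cubic-polynomial extrapolation to 1.

    Falls back to pi0 = 1 (pure BH) whenever the extrapolation leaves (0, 1].
    """
    m = p.size
    grid = _PI0_LAMBDA_GRID
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if np.allclose(pi0_lam, pi0_lam[0]):
        pi0 = float(pi0_lam[0])
    else:
        coeffs = np.polyfit(grid, pi0_lam, deg=3)
        pi0 = float(np.polyval(coeffs, 1.0))
    if not (0.0 < pi0 <= 1.0):
        return 1.0
    return pi0


def estimate_qvalues(p_values, method: str = "bh") -> np.ndarray:
    """FDR-adjust p-values; ``method`` is "bh" or "storey".

    Output order matches input order.  Storey q-values equal BH times the
    estimated null proportion pi0 (hence are never larger than BH).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return _bh(p)
    if method == "storey":
        pi0 = _estimate_pi0(p)
        return np.minimum(pi0 * _bh(p), 1.0)
    raise ValueError(f"unknown FDR method {method!r} (use 'bh' or 'storey')")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi^2 variance prior.

    Returns (d0, s0^2): prior degrees of freedom (may be inf) and prior
    variance, estimated from the log sample variances.
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return d0, s02
    return np.inf, float(np.exp(emean))


def differential_expression(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    moderated: bool = True,
    fdr: str = "storey",
) -> pd.DataFrame:
    """Two-group DE table for every gene.

    Returns a DataFrame indexed by gene id with columns ``mean_A``,
    ``mean_B``, ``fold_change`` (A/B, linear scale), ``direction`` (Up iff
    fold change > 1), ``t_stat``, ``p_value``, ``q_value`` and ``is_de``
    (q < alpha).  Genes with zero pooled variance get t = 0, p = 1 (logged);
    they cannot be assessed and must not abort a pipeline run.
    """
    lab_a, lab_b = matrix.conditions
    ia, ib = matrix.column_indices(lab_a), matrix.column_indices(lab_b)
    na, nb = ia.size, ib.size
    if na < 2 or nb < 2:
        raise DesignError("each condition needs >= 2 samples for a t-test")
    va = matrix.values[:, ia]
    vb = matrix.values[:, ib]
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    diff = mean_a - mean_b

    df_resid = float(na + nb - 2)
    sse = ((va - mean_a[:, None]) ** 2).sum(axis=1) + (
        (vb - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = sse / df_resid
    zero_var = s2 == 0.0
    if zero_var.any():
        log.warning(
            "%d gene(s) with zero pooled variance: t set to 0, p to 1",
            int(zero_var.sum()),
        )

    if moderated and (~zero_var).sum() >= 2:
        d0, s02 = _fit_variance_prior(s2[~zero_var], df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
        else:
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    else:
        s2_post = s2
        df_total = df_resid

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    t[zero_var] = 0.0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)
    p[zero_var] = 1.0

    q = estimate_qvalues(p, method=fdr)
    fc = 2.0 ** diff
    table = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "fold_change": fc,
            "direction": np.where(fc > 1.0, "Up", "Down"),
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "is_de": q < alpha,
        },
        index=matrix.data.index,
    )
    return table
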