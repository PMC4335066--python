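"""Per-condition Pearson correlation and PCIT significance filtering.

PCIT (partial correlation and information theory) decides, for every gene
pair, whether its correlation can be explained away by some third gene.  For
each ordered trio (x, y, z) the three first-order partial correlations are
computed; the trio's tolerance epsilon is the mean ratio of partial to
direct correlation over the trio's pairs with non-degenerate direct
correlation.  The edge (x, y) is *locally dominated* in the trio if

    |r_xy| < |eps * r_xz|   and   |r_xy| < |eps * r_yz|

and an edge is significant iff it is dominated for no third gene z.  Ties
retain the edge; with fewer than three genes every off-diagonal edge is
significant.

Two interchangeable implementations are provided:

* :func:`pcit_significant_edges` — the production path, vectorized over all
  pairs for each conditioning gene z (O(G^3) work in O(G) numpy slices);
* :func:`pcit_reference` — a naive scalar triple loop over trios, used as
  the independent validation oracle at small G.

Both evaluate the identical arithmetic in the identical order, so their edge
sets agree exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError
from .matrixio import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ConditionNetwork",
    "correlation_matrix",
    "partial_correlation",
    "pcit_significant_edges",
    "pcit_reference",
    "edge_list",
]

#: direct correlations below this magnitude do not contribute tolerance ratios
_DEGENERATE_R = 1e-8
#: lower clamp for the partial-correlation denominator
_DENOM_FLOOR = 1e-12


@dataclass
class ConditionNetwork:
    """All-pairs Pearson correlations of one condition, plus PCIT flags.

    ``r`` is symmetric with unit diagonal; ``significant`` (once filled) is a
    symmetric boolean matrix with a False diagonal marking PCIT-retained
    edges.  Genes whose expression had zero variance in this condition are
    listed in ``zero_variance`` and correlate 0 with everything.
    """

    condition: str
    gene_ids: list[str]
    r: np.ndarray
    significant: np.ndarray | None = None
    zero_variance: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        g = len(self.gene_ids)
        if self.r.shape != (g, g):
            raise ValueError("correlation matrix shape does not match gene_ids")


def correlation_matrix(matrix: ExpressionMatrix, condition: str) -> ConditionNetwork:
    """Pearson correlation of every gene pair across one condition's samples.

    Requires >= 3 samples in the condition.  Zero-variance genes are flagged
    and given r = 0 to all other genes (diagonal stays 1).
    """
    if condition not in matrix.conditions:
        raise DesignError(f"unknown condition {condition!r}")
    cols = matrix.column_indices(condition)
    if cols.size < 3:
        raise DesignError(
            f"condition {condition!r} has {cols.size} samples; correlation needs >= 3"
        )
    v = matrix.values[:, cols]
    sd = v.std(axis=1)
    zero = sd == 0.0
    if v.shape[0] == 1:
        r = np.ones((1, 1))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(v)
        r = np.asarray(r, dtype=float)
    if zero.any():
        r[zero, :] = 0.0
        r[:, zero] = 0.0
        log.warning(
            "%d zero-variance gene(s) in condition %s set to r = 0",
            int(zero.sum()), condition,
        )
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return ConditionNetwork(
        condition=condition,
        gene_ids=matrix.gene_ids,
        r=r,
        zero_variance=frozenset(np.array(matrix.gene_ids)[zero]),
    )


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z.

    (r_xy - r_xz*r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), with the
    denominator clamped below at 1e-12 so degenerate trios stay finite.
    """
    denom = math.sqrt((1.0 - r_xz * r_xz) * (1.0 - r_yz * r_yz))
    if denom < _DENOM_FLOOR:
        denom = _DENOM_FLOOR
    return (r_xy - r_xz * r_yz) / denom


def pcit_significant_edges(network: ConditionNetwork) -> ConditionNetwork:
    """Fill ``significant`` with the PCIT-retained edge set (vectorized path).

    For each conditioning gene z the partial correlations of all pairs and
    the per-trio tolerances are evaluated as whole-matrix slices; an edge
    survives iff no z locally dominates it.
    """
    r = np.asarray(network.r, dtype=float)
    g = r.shape[0]
    if g < 3:
        sig = ~np.eye(g, dtype=bool)
        return ConditionNetwork(
            network.condition, network.gene_ids, r, sig, network.zero_variance
        )

    abs_r = np.abs(r)
    one_minus_r2 = 1.0 - r * r  # (1 - r_xy^2), reused for every z
    q_xy = abs_r > _DEGENERATE_R
    dominated = np.zeros((g, g), dtype=bool)
    idx = np.arange(g)

    # preallocated work buffers (the loop runs G times over G x G slices)
    den = np.empty((g, g))
    p_xy = np.empty((g, g))
    p_xz = np.empty((g, g))
    total = np.empty((g, g))
    tmp = np.empty((g, g))
    eps = np.empty((g, g))
    count = np.empty((g, g), dtype=np.int8)
    has_ratio = np.empty((g, g), dtype=bool)
    dom = np.empty((g, g), dtype=bool)
    dom2 = np.empty((g, g), dtype=bool)

    for z in range(g):
        rz = r[:, z]
        cz = 1.0 - rz * rz
        # pc(x, y | z)
        np.outer(cz, cz, out=den)
        np.sqrt(den, out=den)
        np.maximum(den, _DENOM_FLOOR, out=den)
        np.outer(rz, rz, out=p_xy)
        np.subtract(r, p_xy, out=p_xy)
        np.divide(p_xy, den, out=p_xy)
        # pc(x, z | y) at [x, y]; pc(y, z | x) is its transpose
        np.multiply(one_minus_r2, cz[None, :], out=den)
        np.sqrt(den, out=den)
        np.maximum(den, _DENOM_FLOOR, out=den)
        np.multiply(r, rz[None, :], out=p_xz)
        np.subtract(rz[:, None], p_xz, out=p_xz)
        np.divide(p_xz, den, out=p_xz)
        p_yz = p_xz.T

        qz = np.abs(rz) > _DEGENERATE_R
        q_xz = np.broadcast_to(qz[:, None], (g, g))
        q_yz = q_xz.T

        # tolerance: mean of partial/direct over qualifying pairs,
        # accumulated in the fixed order (xy, xz, yz)
        total.fill(0.0)
        np.divide(p_xy, r, out=total, where=q_xy)
        tmp.fill(0.0)
        np.divide(p_xz, np.broadcast_to(rz[:, None], (g, g)), out=tmp, where=q_xz)
        total += tmp
        tmp.fill(0.0)
        np.divide(p_yz, np.broadcast_to(rz[None, :], (g, g)), out=tmp, where=q_yz)
        total += tmp
        count[...] = q_xy
        count += q_xz
        count += q_yz
        np.greater(count, 0, out=has_ratio)
        eps.fill(0.0)
        np.divide(total, count, out=eps, where=has_ratio)

        np.multiply(eps, rz[:, None], out=tmp)
        np.abs(tmp, out=tmp)
        np.less(abs_r, tmp, out=dom)
        np.multiply(eps, rz[None, :], out=tmp)
        np.abs(tmp, out=tmp)
        np.less(abs_r, tmp, out=dom2)
        dom &= dom2
        dom &= has_ratio
        dom[z, :] = False
        dom[:, z] = False
        dom[idx, idx] = False
        dominated |= dom

    sig = ~dominated
    np.fill_diagonal(sig, False)
    return ConditionNetwork(
        network.condition, network.gene_ids, r, sig, network.zero_variance
    )


def pcit_reference(r: np.ndarray) -> np.ndarray:
    """Naive scalar triple-loop PCIT over all trios; the validation oracle.

    Evaluates the same contract as :func:`pcit_significant_edges` one trio at
    a time and is only meant for small G.  Returns the boolean significance
    matrix.
    """
    r = np.asarray(r, dtype=float)
    g = r.shape[0]
    sig = ~np.eye(g, dtype=bool)
    if g < 3:
        return sig
    dominated = np.zeros((g, g), dtype=bool)
    for x in range(g):
        for y in range(x + 1, g):
            r_xy = r[x, y]
            for z in range(g):
                if z == x or z == y:
                    continue
                r_xz = r[x, z]
                r_yz = r[y, z]
                ratios = []
                if abs(r_xy) > _DEGENERATE_R:
                    ratios.append(partial_correlation(r_xy, r_xz, r_yz) / r_xy)
                if abs(r_xz) > _DEGENERATE_R:
                    ratios.append(partial_correlation(r_xz, r_xy, r_yz) / r_xz)
                if abs(r_yz) > _DEGENERATE_R:
                    ratios.append(partial_correlation(r_yz, r_xy, r_xz) / r_yz)
                if not ratios:
                    continue
                eps = sum(ratios) / len(ratios)
                if abs(r_xy) < abs(eps * r_xz) and abs(r_xy) < abs(eps * r_yz):
                    dominated[x, y] = dominated[y, x] = True
                    break
    out = ~dominated
    np.fill_diagonal(out, False)
    return out


def edge_list(network: ConditionNetwork, significant_only: bool = False) -> pd.DataFrame:
    """Flatten a network into a (gene_a, gene_b, r, significant) table."""
    if network.significant is None:
        raise DesignError("run pcit_significant_edges before exporting edges")
    g = len(network.gene_ids)
    iu = np.triu_indices(g, k=1)
    df = pd.DataFrame(
        {
            "gene_a": np.array(network.gene_ids)[iu[0]],
            "gene_b": np.array(network.gene_ids)[iu[1]],
            "r": network.r[iu],
            "significant": network.significant[iu],
        }
    )
    if significant_only:
        df = df[df["significant"]].reset_index(drop=True)
    return df
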