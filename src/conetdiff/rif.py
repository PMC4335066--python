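"""Phenotypic (PIF) and regulatory (RIF1/RIF2) impact factors.

For a gene j with mean log2 expression e_jA and e_jB in the two conditions,

    PIF_j = ((e_jA + e_jB) / 2) * (e_jA - e_jB)

combines overall abundance with differential expression.  For a candidate
regulator i and a set T of differentially expressed target genes, the
differential wiring to target j is DW_ij = r_ijA - r_ijB (difference of the
raw Pearson correlations between conditions; self-pairs excluded), and

    RIF1_i = (1 / |T_i|) * sum_j  PIF_j * DW_ij^2
    RIF2_i = (1 / |T_i|) * sum_j  (e_jA * r_ijA)^2 - (e_jB * r_ijB)^2

RIF1 rewards regulators whose wiring to high-impact targets changes most;
RIF2 rewards regulators whose expression predicts target expression in one
condition but not the other.  Every gene is a candidate regulator by
default, so novel regulators outside the annotated transcription-factor
catalogue can surface.  Raw scores are Z-standardized over the regulator
universe and ranked by the most extreme Z in either direction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DesignError
from .pcit import ConditionNetwork

log = logging.getLogger(__name__)

__all__ = ["compute_pif", "compute_rif", "rank_extreme"]


def compute_pif(mean_A, mean_B):
    """PIF_j = average expression times log2 differential expression (A minus B)."""
    mean_A = np.asarray(mean_A, dtype=float)
    mean_B = np.asarray(mean_B, dtype=float)
    return 0.5 * (mean_A + mean_B) * (mean_A - mean_B)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1) if x.size > 1 else 0.0
    if sd == 0.0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def compute_rif(
    net_A: ConditionNetwork,
    net_B: ConditionNetwork,
    mean_A,
    mean_B,
    targets,
    regulators=None,
) -> pd.DataFrame:
    """RIF table over the candidate-regulator universe.

    Parameters
    ----------
    net_A, net_B : ConditionNetwork
        Per-condition correlation networks over the same gene universe
        (raw Pearson r; PCIT flags are not used here — differential wiring
        is defined on all pairs).
    mean_A, mean_B : array-like or pandas.Series
        Per-gene mean log2 expression in each condition, aligned with the
        networks' gene order.
    targets : iterable of gene ids
        The differentially expressed target set; must be nonempty.
    regulators : iterable of gene ids, optional
        Candidate regulators; defaults to every gene in the networks.

    Returns a DataFrame indexed by regulator with columns ``pif``,
    ``rif1_raw``, ``rif2_raw``, ``rif1_z``, ``rif2_z`` and
    ``target_set_size``.  A regulator that is itself a target contributes
    over the targets excluding itself.
    """
    if net_A.gene_ids != net_B.gene_ids:
        raise DesignError("the two condition networks must share the gene universe")
    genes = net_A.gene_ids
    pos = {g: i for i, g in enumerate(genes)}

    targets = [t for t in targets]
    unknown = [t for t in targets if t not in pos]
    if unknown:
        raise DesignError(f"targets not in the gene universe: {unknown[:5]}")
    if not targets:
        raise DesignError("RIF needs a nonempty differentially-expressed target set")
    if regulators is None:
        regulators = list(genes)
    else:
        regulators = list(regulators)
        unknown = [g for g in regulators if g not in pos]
        if unknown:
            raise DesignError(f"regulators not in the gene universe: {unknown[:5]}")

    e_a = _aligned(mean_A, genes)
    e_b = _aligned(mean_B, genes)

    t_idx = np.array([pos[t] for t in targets], dtype=int)
    r_idx = np.array([pos[g] for g in regulators], dtype=int)

    ra = net_A.r[np.ix_(r_idx, t_idx)]
    rb = net_B.r[np.ix_(r_idx, t_idx)]
    dw = ra - rb
    pif_t = compute_pif(e_a[t_idx], e_b[t_idx])
    term1 = pif_t[None, :] * dw * dw
    term2 = (e_a[t_idx][None, :] * ra) ** 2 - (e_b[t_idx][None, :] * rb) ** 2

    # exclude self-pairs: a regulator that is a target skips its own column
    self_mask = r_idx[:, None] == t_idx[None, :]
    term1 = np.where(self_mask, 0.0, term1)
    term2 = np.where(self_mask, 0.0, term2)
    sizes = t_idx.size - self_mask.sum(axis=1)
    degenerate = sizes == 0
    if degenerate.any():
        log.warning(
            "%d regulator(s) have an empty effective target set; RIF set to 0",
            int(degenerate.sum()),
        )
    denom = np.where(degenerate, 1, sizes)
    rif1 = term1.sum(axis=1) / denom
    rif2 = term2.sum(axis=1) / denom
    rif1[degenerate] = 0.0
    rif2[degenerate] = 0.0

    table = pd.DataFrame(
        {
            "pif": compute_pif(e_a[r_idx], e_b[r_idx]),
            "rif1_raw": rif1,
            "rif2_raw": rif2,
            "rif1_z": _zscore(rif1),
            "rif2_z": _zscore(rif2),
            "target_set_size": sizes,
        },
        index=pd.Index(regulators, name="gene"),
    )
    return table


def _aligned(values, genes) -> np.ndarray:
    if isinstance(values, pd.Series):
        return values.reindex(genes).to_numpy(dtype=float)
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(genes),):
        raise DesignError("mean vector length does not match the gene universe")
    return arr


def rank_extreme(table: pd.DataFrame, column: str, k: int) -> tuple[list[str], list[str]]:
    """Top-k positive and top-k negative genes by a signed Z column.

    Returns ``(positive_extremes, negative_extremes)``: the k largest values
    in descending order and the k smallest in ascending order, ties broken
    by input order.  k larger than the universe is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if column not in table.columns:
        raise ValueError(f"no column {column!r} in RIF table")
    n = len(table)
    if k > n:
        log.warning("k=%d exceeds the universe (%d); truncating", k, n)
        k = n
    z = table[column].to_numpy(dtype=float)
    desc = np.argsort(-z, kind="stable")
    asc = np.argsort(z, kind="stable")
    idx = table.index.to_numpy()
    return list(idx[desc[:k]]), list(idx[asc[:k]])
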