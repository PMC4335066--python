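"""Differential hubbing: per-condition connectivity of strong, retained edges.

A gene's connectivity k in one condition counts its partners h with a
PCIT-significant edge whose correlation magnitude clears a threshold
(default |r| >= 0.90, a deliberately strict cut given small replicate
numbers).  Differential hubbing contrasts the two conditions per gene:

    dh = k_A - k_B     (A = wild-type-like reference)

A differentially hubbed gene is highly connected in one condition and
sparsely connected in the other even if its own expression does not change,
so this view surfaces regulators invisible to differential expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DesignError
from .pcit import ConditionNetwork

__all__ = ["hub_counts", "differential_hubbing", "ranked_hub_table"]


def hub_counts(
    network: ConditionNetwork,
    r_threshold: float = 0.90,
    require_significant: bool = True,
) -> pd.Series:
    """Qualified-edge count per gene in one condition.

    An edge qualifies when |r| >= ``r_threshold`` and (by default) it was
    retained by PCIT; ``require_significant=False`` gives the |r|-only
    variant for sensitivity analysis.
    """
    if not 0.0 <= r_threshold <= 1.0:
        raise ValueError(f"r_threshold must be in [0, 1], got {r_threshold}")
    mask = np.abs(network.r) >= r_threshold
    if require_significant:
        if network.significant is None:
            raise DesignError("hub_counts needs PCIT flags; run pcit_significant_edges")
        mask = mask & network.significant
    np.fill_diagonal(mask, False)
    return pd.Series(mask.sum(axis=1), index=network.gene_ids, name=f"k_{network.condition}")


def differential_hubbing(counts_A: pd.Series, counts_B: pd.Series) -> pd.DataFrame:
    """Per-gene hub-count contrast dh = k_A - k_B over a shared gene universe."""
    if set(counts_A.index) != set(counts_B.index):
        raise DesignError("hub-count universes differ between conditions")
    counts_B = counts_B.reindex(counts_A.index)
    table = pd.DataFrame(
        {
            "k_A": counts_A.astype(int),
            "k_B": counts_B.astype(int),
        },
        index=counts_A.index,
    )
    table["dh"] = table["k_A"] - table["k_B"]
    table.index.name = "gene"
    return table


def ranked_hub_table(table: pd.DataFrame) -> pd.DataFrame:
    """The hub table sorted by |dh| descending (stable, ties keep input order)."""
    order = np.argsort(-table["dh"].abs().to_numpy(), kind="stable")
    return table.iloc[order]
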