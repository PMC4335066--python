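"""Gene-set over-representation with fold enrichment and Benjamini adjustment.

Given a gene list (DE genes, the correlates of a top regulator, a
differentially hubbed gene's neighbours, ...), a background universe and a
GMT collection, each set is tested on the 2x2 membership table with the
hypergeometric upper tail.  Two modes:

* ``fisher`` — the one-tailed Fisher exact test, P(X >= count);
* ``ease`` (default) — the conservative variant that decrements the overlap
  count by one before testing, so singleton overlaps are never significant.

Reported per set: Count, List Total (annotated list genes), Pop Hits
(background genes in the set), Pop Total (annotated background genes),

    fold enrichment = (count / list_total) / (pop_hits / pop_total)

and the Benjamini(-Hochberg) adjusted p over all tested sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import estimate_qvalues
from .errors import DesignError

__all__ = ["fold_enrichment", "overrepresentation_test", "benjamini_adjust"]


def fold_enrichment(count: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """(count/list_total) / (pop_hits/pop_total); raises on zero denominators."""
    if list_total == 0 or pop_hits == 0 or pop_total == 0:
        raise ValueError("fold enrichment is undefined with zero denominators")
    return (count / list_total) / (pop_hits / pop_total)


def benjamini_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (same contract as the DE stage's BH)."""
    return estimate_qvalues(p_values, method="bh")


def _upper_tail(count: int, pop_total: int, pop_hits: int, list_total: int,
                mode: str) -> float:
    x = count - 1 if mode == "ease" else count
    if x <= 0:
        return 1.0
    # P(X >= x) for X ~ Hypergeom(pop_total, pop_hits, list_total)
    return float(stats.hypergeom.sf(x - 1, pop_total, pop_hits, list_total))


def overrepresentation_test(
    list_genes,
    background,
    sets: dict,
    mode: str = "ease",
) -> pd.DataFrame:
    """Test every gene set for over-representation in ``list_genes``.

    ``sets`` maps a term name to either a member set or a
    ``(description, members)`` pair (the shape :func:`~conetdiff.matrixio.read_gmt`
    returns).  Totals follow the annotated-universe convention: List Total
    and Pop Total count only genes covered by at least one set.  Rows are
    sorted by p-value; sets with no background member are dropped.
    """
    if mode not in ("fisher", "ease"):
        raise ValueError(f"mode must be 'fisher' or 'ease', got {mode!r}")
    if not sets:
        raise DesignError("the gene-set collection is empty")
    list_genes = set(list_genes)
    background = set(background)
    if not list_genes <= background:
        raise DesignError("the gene list must be a subset of the background")

    members_of = {}
    for name, value in sets.items():
        members = value[1] if isinstance(value, tuple) else value
        members_of[name] = frozenset(members)

    annotated = set().union(*members_of.values()) & background
    pop_total = len(annotated)
    list_annot = list_genes & annotated
    list_total = len(list_annot)
    if list_total == 0:
        raise DesignError("no gene in the list is annotated by any set")

    rows = []
    for name, members in members_of.items():
        set_bg = members & background
        pop_hits = len(set_bg)
        if pop_hits == 0:
            continue
        count = len(set_bg & list_genes)
        rows.append(
            {
                "term": name,
                "count": count,
                "list_total": list_total,
                "pop_hits": pop_hits,
                "pop_total": pop_total,
                "p_value": _upper_tail(count, pop_total, pop_hits, list_total, mode),
                "fold_enrichment": fold_enrichment(count, list_total, pop_hits, pop_total)
                if count > 0
                else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    table["benjamini"] = benjamini_adjust(table["p_value"].to_numpy())
    table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return table
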