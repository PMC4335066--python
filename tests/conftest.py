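import numpy as np
import pandas as pd
import pytest

from conetdiff import ExpressionMatrix


def make_matrix(values, gene_ids=None, n_a=None, label_a="WT", label_b="null"):
    """Small helper: build an ExpressionMatrix from a 2-D array, first n_a
    columns condition A."""
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    if n_a is None:
        n_a = s // 2
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    samples = [f"{label_a}_{i}" for i in range(n_a)] + [
        f"{label_b}_{i}" for i in range(s - n_a)
    ]
    cond = {sid: (label_a if i < n_a else label_b) for i, sid in enumerate(samples)}
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=samples),
                            cond, reference=label_a)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(11)
    return make_matrix(rng.normal(8, 1, (6, 10)))


@pytest.fixture
def swap_pair():
    """The same data with the two condition labels swapped (reference flips)."""
    rng = np.random.default_rng(23)
    vals = rng.normal(8, 1, (12, 10))
    vals[:3, :5] += 1.2
    fwd = make_matrix(vals)
    # swapped: B columns first, labelled as the reference
    swapped_vals = np.concatenate([vals[:, 5:], vals[:, :5]], axis=1)
    rev = make_matrix(swapped_vals, n_a=5, label_a="null", label_b="WT")
    return fwd, rev
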