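"""Expression-matrix, sample-map, annotation and gene-set (GMT) I/O.

The substrate of every analysis stage is a normalized log2 expression matrix
(genes x samples) together with a map assigning each sample to one of exactly
two conditions.  One condition is designated the *reference* (condition A,
the wild-type-like group); all signed quantities downstream (fold change,
PIF, RIF, differential hubbing) are computed as A-minus-B or A/B.

Files are plain UTF-8 TSV: the expression matrix has a header row of sample
ids and gene ids in the first column; the sample map has columns
``sample_id``, ``condition`` and an optional truthy ``is_reference`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "read_gmt",
    "exclude_probes",
    "collapse_by_annotation",
]


@dataclass
class ExpressionMatrix:
    """A validated genes x samples log2 expression matrix with a two-condition design.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes in rows, samples in columns, log2-scale values, no missing cells.
    condition_of : dict
        Maps every sample id to one of exactly two condition labels.
    reference : str
        The condition label designated A (the wild-type-like reference group).
    """

    data: pd.DataFrame
    condition_of: dict[str, str]
    reference: str

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate gene ids in expression matrix")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        if self.data.isna().to_numpy().any():
            raise FormatError("expression matrix contains missing values")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric expression value: {exc}") from exc
        missing = [s for s in self.data.columns if s not in self.condition_of]
        if missing:
            raise DesignError(f"samples without a condition assignment: {missing}")
        labels = sorted({self.condition_of[s] for s in self.data.columns})
        if len(labels) != 2:
            raise DesignError(
                f"expected exactly 2 conditions, found {len(labels)}: {labels}"
            )
        if self.reference not in labels:
            raise DesignError(
                f"reference condition {self.reference!r} not among {labels}"
            )
        # correlation_matrix additionally requires >= 3; DE requires >= 2
        for lab in labels:
            n = sum(1 for s in self.data.columns if self.condition_of[s] == lab)
            if n < 2:
                raise DesignError(f"condition {lab!r} has {n} sample(s), need >= 2")

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def conditions(self) -> tuple[str, str]:
        """(A, B) with the reference condition first."""
        labels = {self.condition_of[s] for s in self.data.columns}
        other = next(iter(labels - {self.reference}))
        return self.reference, other

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.data.columns if self.condition_of[s] == condition]

    def column_indices(self, condition: str) -> np.ndarray:
        cond = np.array([self.condition_of[s] for s in self.data.columns])
        return np.flatnonzero(cond == condition)

    def condition_means(self) -> tuple[pd.Series, pd.Series]:
        """Per-gene mean log2 expression in (A, B)."""
        a, b = self.conditions
        return (
            self.data[self.samples_in(a)].mean(axis=1),
            self.data[self.samples_in(b)].mean(axis=1),
        )

    def restrict_genes(self, gene_ids) -> "ExpressionMatrix":
        """Submatrix keeping the given genes in their original order."""
        keep = [g for g in self.data.index if g in set(gene_ids)]
        return ExpressionMatrix(self.data.loc[keep], dict(self.condition_of), self.reference)


@dataclass
class GeneAnnotation:
    """Probe-to-symbol map plus a set of probes to exclude from network stages.

    The exclusion set holds array control probes and housekeeping genes, which
    carry no treatment signal yet correlate strongly with everything; which
    probes those are is platform-specific and therefore a user input.
    """

    probe_to_symbol: dict[str, str] = field(default_factory=dict)
    exclusion_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.exclusion_set = frozenset(self.exclusion_set)


def read_expression_matrix(path, sample_map_path) -> ExpressionMatrix:
    """Read an expression TSV and a sample-map TSV into an :class:`ExpressionMatrix`.

    Row and column order are preserved from the file.  Raises
    :class:`FormatError` for malformed files and :class:`DesignError` when the
    sample map does not describe exactly two conditions.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    smap = pd.read_csv(sample_map_path, sep="\t", dtype=str,
                       keep_default_na=False)
    required = {"sample_id", "condition"}
    if not required.issubset(smap.columns):
        raise FormatError(
            f"sample map {sample_map_path} must have columns {sorted(required)}"
        )
    if smap["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in sample map")
    condition_of = dict(zip(smap["sample_id"], smap["condition"]))
    reference = _reference_from_map(smap)
    return ExpressionMatrix(df, condition_of, reference)


def _reference_from_map(smap: pd.DataFrame) -> str:
    if "is_reference" in smap.columns:
        truthy = smap["is_reference"].astype(str).str.lower().isin(
            ["1", "true", "yes", "y"]
        )
        ref_conditions = set(smap.loc[truthy, "condition"])
        if len(ref_conditions) == 1:
            return next(iter(ref_conditions))
        if len(ref_conditions) > 1:
            raise DesignError(
                f"is_reference flags mark more than one condition: {sorted(ref_conditions)}"
            )
    # fall back: the condition of the first row is the reference
    return str(smap["condition"].iloc[0])


def write_expression_matrix(matrix: ExpressionMatrix, path, sample_map_path=None) -> None:
    """Write the matrix (and optionally its sample map) as TSV.

    Values are written with 10 significant digits so that a read-write-read
    cycle round-trips to that precision.
    """
    matrix.data.to_csv(path, sep="\t", float_format="%.10g", index_label="gene_id")
    if sample_map_path is not None:
        rows = [
            {
                "sample_id": s,
                "condition": matrix.condition_of[s],
                "is_reference": int(matrix.condition_of[s] == matrix.reference),
            }
            for s in matrix.sample_ids
        ]
        pd.DataFrame(rows).to_csv(sample_map_path, sep="\t", index=False)


def read_annotation(path) -> GeneAnnotation:
    """Read a two-column (probe_id, symbol) TSV; empty symbols mean 'unannotated'."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"annotation {path} needs two columns (probe_id, symbol)")
    probe_col, sym_col = df.columns[:2]
    mapping = {
        str(p): str(s) for p, s in zip(df[probe_col], df[sym_col]) if str(s) != ""
    }
    return GeneAnnotation(probe_to_symbol=mapping)


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT gene-set file: name <tab> description <tab> member genes."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = (desc, frozenset(m for m in members if m))
    return sets


def exclude_probes(matrix: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Drop control/housekeeping probes before the network stages.

    Returns a matrix restricted to genes not in the exclusion set, original
    order preserved.  An empty result is allowed (and logged).
    """
    keep = [g for g in matrix.gene_ids if g not in annotation.exclusion_set]
    if not keep:
        log.warning("exclude_probes removed every gene; result has 0 rows")
        return ExpressionMatrix(
            matrix.data.iloc[0:0], dict(matrix.condition_of), matrix.reference
        )
    dropped = len(matrix.gene_ids) - len(keep)
    if dropped:
        log.info("exclude_probes dropped %d of %d genes", dropped, len(matrix.gene_ids))
    return ExpressionMatrix(matrix.data.loc[keep], dict(matrix.condition_of), matrix.reference)


def collapse_by_annotation(table: pd.DataFrame, annotation: GeneAnnotation) -> pd.DataFrame:
    """Collapse a probe-level result table to one row per gene symbol.

    For multiple probes mapping to the same symbol, the row with the smallest
    q-value is kept (ties broken by first occurrence in input order).  Probes
    without a symbol are kept as their own rows.  The output preserves the
    input's relative row order and gains a ``gene_symbol`` column.
    """
    if "q_value" not in table.columns:
        raise FormatError("collapse_by_annotation requires a 'q_value' column")
    out = table.copy()
    symbols = [annotation.probe_to_symbol.get(p, "") for p in out.index]
    out["gene_symbol"] = symbols
    # unannotated probes collapse only with themselves
    group_key = [s if s else f"__probe__{p}" for s, p in zip(symbols, out.index)]
    out["_group"] = group_key
    out["_order"] = np.arange(len(out))
    # stable sort by q keeps input order among exact ties
    best = (
        out.sort_values("q_value", kind="stable")
        .drop_duplicates("_group", keep="first")
        .sort_values("_order", kind="stable")
    )
    return best.drop(columns=["_group", "_order"])
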