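"""Run the whole chain — simulate/load -> DE -> PCIT -> RIF -> DH -> enrichment —
as one configured, logged, seed-reproducible job writing TSV tables plus a
manifest.

Stage behaviour mirrors the two-condition study the pipeline serves: RIF is
only defined when differential expression found targets, so an empty DE set
skips the RIF stage with a logged reason instead of aborting (secondary
timepoints in such designs can legitimately yield zero DE genes), and every
downstream stage that can still run does.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import differential_expression
from .diffhub import differential_hubbing, hub_counts, ranked_hub_table
from .enrichment import overrepresentation_test
from .errors import ConetdiffError, DesignError, StageError
from .matrixio import (
    ExpressionMatrix,
    GeneAnnotation,
    collapse_by_annotation,
    exclude_probes,
    read_annotation,
    read_expression_matrix,
    read_gmt,
    write_expression_matrix,
)
from .pcit import correlation_matrix, edge_list, pcit_significant_edges
from .rif import compute_rif
from .simulate import SimulationDesign, simulate_expression

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("input", "de", "pcit", "rif", "diffhub", "enrich")


@dataclass
class PipelineConfig:
    """Everything one run needs; either a pair of input paths or a simulation design."""

    outdir: str
    expression_path: str | None = None
    sample_map_path: str | None = None
    simulation: SimulationDesign | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    alpha: float = 0.05
    r_threshold: float = 0.90
    fdr_method: str = "storey"
    moderated: bool = True
    rif_regulators: str = "all"  # all genes as candidate regulators
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DesignError("alpha must be in (0, 1)")
        if not 0 <= self.r_threshold <= 1:
            raise DesignError("r_threshold must be in [0, 1]")
        if self.fdr_method not in ("storey", "bh"):
            raise DesignError("fdr_method must be 'storey' or 'bh'")
        has_files = self.expression_path is not None and self.sample_map_path is not None
        if has_files == (self.simulation is not None):
            raise DesignError(
                "provide either expression_path+sample_map_path or a simulation design"
            )
        for p in (self.expression_path, self.sample_map_path,
                  self.annotation_path, self.gmt_path):
            if p is not None and not Path(p).exists():
                raise DesignError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationDesign.from_dict(sim)
        return cls(simulation=sim, **raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return (and write) the run manifest.

    The manifest records the package version, the config echo, per-stage
    status and row counts, and a sha256 checksum of every written table.  A
    stage error aborts the run with the stage named; partial outputs are
    retained next to a ``FAILED`` marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "conetdiff",
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, status: str, rows: int | None = None, reason: str | None = None):
        entry: dict = {"status": status}
        if rows is not None:
            entry["rows"] = int(rows)
        if reason:
            entry["reason"] = reason
        manifest["stages"][stage] = entry

    def register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    def fail(stage: str, exc: Exception) -> StageError:
        record(stage, "failed", reason=str(exc))
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        _dump_manifest(manifest, outdir)
        log.error("stage %s failed: %s", stage, exc)
        return StageError(stage, str(exc))

    annotation = GeneAnnotation()
    if config.annotation_path:
        annotation = read_annotation(config.annotation_path)

    # ---- input -----------------------------------------------------------
    try:
        if config.simulation is not None:
            design = dataclasses.replace(config.simulation, seed=config.seed)
            matrix, truth = simulate_expression(design)
            write_expression_matrix(
                matrix, outdir / "expression.tsv", outdir / "sample_map.tsv"
            )
            truth.to_json(outdir / "truth.json")
            register("truth", outdir / "truth.json")
        else:
            matrix = read_expression_matrix(config.expression_path, config.sample_map_path)
            write_expression_matrix(
                matrix, outdir / "expression.tsv", outdir / "sample_map.tsv"
            )
        if annotation.exclusion_set:
            matrix = exclude_probes(matrix, annotation)
        register("expression", outdir / "expression.tsv")
        register("sample_map", outdir / "sample_map.tsv")
        record("input", "done", rows=len(matrix.gene_ids))
    except ConetdiffError as exc:
        raise fail("input", exc) from exc

    # ---- differential expression ----------------------------------------
    try:
        de_table = differential_expression(
            matrix, alpha=config.alpha, moderated=config.moderated, fdr=config.fdr_method
        )
        if annotation.probe_to_symbol:
            de_out = collapse_by_annotation(de_table, annotation)
        else:
            de_out = de_table
        _write(de_out, outdir / "de_table.tsv", index_label="gene")
        register("de_table", outdir / "de_table.tsv")
        record("de", "done", rows=len(de_out))
    except ConetdiffError as exc:
        raise fail("de", exc) from exc

    # ---- per-condition PCIT networks ------------------------------------
    try:
        lab_a, lab_b = matrix.conditions
        nets = {}
        for lab in (lab_a, lab_b):
            net = pcit_significant_edges(correlation_matrix(matrix, lab))
            nets[lab] = net
            edges = edge_list(net, significant_only=True)
            path = outdir / f"edges_{lab}.tsv"
            _write(edges, path, index=False)
            register(f"edges_{lab}", path)
        record("pcit", "done",
               rows=sum(int(n.significant.sum()) // 2 for n in nets.values()))
    except ConetdiffError as exc:
        raise fail("pcit", exc) from exc

    # ---- RIF -------------------------------------------------------------
    de_genes = list(de_table.index[de_table["is_de"]])
    mean_a, mean_b = matrix.condition_means()
    if not de_genes:
        record("rif", "skipped", reason="no differentially expressed target genes")
        log.info("rif: skipped (no DE genes at q < %g)", config.alpha)
    else:
        try:
            rif_table = compute_rif(
                nets[lab_a], nets[lab_b], mean_a, mean_b, targets=de_genes
            )
            _write(rif_table, outdir / "rif_table.tsv")
            register("rif_table", outdir / "rif_table.tsv")
            record("rif", "done", rows=len(rif_table))
        except ConetdiffError as exc:
            raise fail("rif", exc) from exc

    # ---- differential hubbing -------------------------------------------
    try:
        k_a = hub_counts(nets[lab_a], r_threshold=config.r_threshold)
        k_b = hub_counts(nets[lab_b], r_threshold=config.r_threshold)
        hub_table = ranked_hub_table(differential_hubbing(k_a, k_b))
        _write(hub_table, outdir / "hub_table.tsv")
        register("hub_table", outdir / "hub_table.tsv")
        record("diffhub", "done", rows=len(hub_table))
    except ConetdiffError as exc:
        raise fail("diffhub", exc) from exc

    # ---- enrichment ------------------------------------------------------
    if config.gmt_path is None:
        record("enrich", "skipped", reason="no gene-set collection (GMT) provided")
    elif not de_genes:
        record("enrich", "skipped", reason="no differentially expressed genes to test")
    else:
        try:
            sets = read_gmt(config.gmt_path)
            sym = annotation.probe_to_symbol
            genes = [sym.get(g, g) for g in de_genes]
            background = [sym.get(g, g) for g in matrix.gene_ids]
            enr = overrepresentation_test(set(genes), set(background), sets)
            _write(enr, outdir / "enrichment.tsv", index=False)
            register("enrichment", outdir / "enrichment.tsv")
            record("enrich", "done", rows=len(enr))
        except ConetdiffError as exc:
            raise fail("enrich", exc) from exc

    _dump_manifest(manifest, outdir)
    return manifest


def _dump_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
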