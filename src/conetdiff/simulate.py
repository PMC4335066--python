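"""Synthetic two-condition expression data with planted, recoverable structure.

The generator emulates a two-genotype microarray study after upstream
normalization: a log2 matrix of ``n_genes`` genes by ``2 * n_per_condition``
samples (default 5 per condition, mirroring a pooled-replicate design), with

* gene baselines  mu_g ~ Normal(baseline_mean, baseline_sd^2),
* i.i.d. replicate noise  eps ~ Normal(0, noise_sd^2)  on every gene,
* an optional planted differential-expression set (a log2 shift ``delta``
  added to condition A),
* optional planted co-expression structure: a differentially wired regulator
  and/or a condition-specific hub.

Planted wiring uses one latent factor per structure.  The driver gene's
expression *is* the factor (x_driver = mu + f, f ~ Normal(0, 1) per sample;
its replicate variation is absorbed into f), and each target gene loads on f
so that its population correlation with the factor equals the requested
loading lambda for the active condition:

    x_target = mu + delta*[DE] + b_c * f + eps,   b_c = noise_sd * l_c / sqrt(1 - l_c^2)

which gives corr(driver, target) = l_c and corr(target, target') = l_c^2
within condition c.  Driver-target edges are therefore systematically
stronger than target-target edges, so the driver — and only the driver — is
recoverable as the wired regulator (RIF) or the hub (differential hubbing).

Identical seeds give bitwise-identical matrices.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .matrixio import ExpressionMatrix

__all__ = [
    "RegulatorWiring",
    "PlantedHub",
    "SimulationDesign",
    "SimulationTruth",
    "simulate_expression",
]


@dataclass(frozen=True)
class RegulatorWiring:
    """A regulator differentially wired to a target set.

    ``loading_A``/``loading_B`` are the population driver-target correlations
    in each condition (absolute value < 1); a differentially wired regulator
    has them differ, e.g. 0.85 in A and 0 in B.
    """

    regulator: int
    targets: tuple[int, ...]
    loading_A: float
    loading_B: float


@dataclass(frozen=True)
class PlantedHub:
    """A gene hubbed (highly connected) in exactly one condition.

    ``condition`` is "A" or "B"; ``loading`` is the population hub-target
    correlation in the active condition (0 in the other).
    """

    hub: int
    targets: tuple[int, ...]
    condition: str
    loading: float


@dataclass
class SimulationDesign:
    """All knobs of the generator; defaults mirror the emulated study design
    (two genotypes, five pooled replicates each, log2 scale around 8)."""

    n_genes: int
    n_per_condition: int = 5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    de_genes: tuple[int, ...] = ()
    delta: float = 1.5
    wired_regulator: RegulatorWiring | None = None
    hub: PlantedHub | None = None
    label_A: str = "WT"
    label_B: str = "null"
    seed: int = 0

    def __post_init__(self) -> None:
        self.de_genes = tuple(self.de_genes)
        if self.n_genes < 1 or self.n_per_condition < 1:
            raise DesignError("n_genes and n_per_condition must be positive")
        if self.noise_sd <= 0:
            raise DesignError("noise_sd must be > 0")
        if self.baseline_sd < 0:
            raise DesignError("baseline_sd must be >= 0")
        if self.label_A == self.label_B:
            raise DesignError("condition labels must differ")
        self._check_indices("de_genes", self.de_genes)
        reg_genes: set[int] = set()
        hub_genes: set[int] = set()
        if self.wired_regulator is not None:
            w = self.wired_regulator
            self._check_indices("wired_regulator", (w.regulator, *w.targets))
            for lam in (w.loading_A, w.loading_B):
                if not abs(lam) < 1:
                    raise DesignError("|loading| must be < 1")
            if w.regulator in w.targets:
                raise DesignError("regulator cannot be its own target")
            if not w.targets:
                raise DesignError("wired_regulator needs a nonempty target set")
            reg_genes = {w.regulator, *w.targets}
        if self.hub is not None:
            h = self.hub
            self._check_indices("hub", (h.hub, *h.targets))
            if not abs(h.loading) < 1:
                raise DesignError("|loading| must be < 1")
            if h.condition not in ("A", "B"):
                raise DesignError("hub.condition must be 'A' or 'B'")
            if h.hub in h.targets:
                raise DesignError("hub cannot be its own target")
            if not h.targets:
                raise DesignError("hub needs a nonempty target set")
            hub_genes = {h.hub, *h.targets}
        if reg_genes & hub_genes:
            raise DesignError("regulator wiring and hub structures must be disjoint")

    def _check_indices(self, name: str, idx) -> None:
        for i in idx:
            if not (0 <= int(i) < self.n_genes):
                raise DesignError(f"{name}: index {i} out of range [0, {self.n_genes})")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        d = dict(d)
        if d.get("wired_regulator") is not None:
            w = dict(d["wired_regulator"])
            w["targets"] = tuple(w["targets"])
            d["wired_regulator"] = RegulatorWiring(**w)
        if d.get("hub") is not None:
            h = dict(d["hub"])
            h["targets"] = tuple(h["targets"])
            d["hub"] = PlantedHub(**h)
        d["de_genes"] = tuple(d.get("de_genes", ()))
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset, the oracle for recovery benchmarks."""

    de_genes: frozenset[str]
    regulator_id: str | None
    hub_id: str | None
    true_means: pd.DataFrame  # genes x (mean_A, mean_B), noise-free expectations

    def to_json(self, path) -> None:
        payload = {
            "de_genes": sorted(self.de_genes),
            "regulator_id": self.regulator_id,
            "hub_id": self.hub_id,
            "true_means": {
                g: [float(a), float(b)]
                for g, (a, b) in self.true_means.iterrows()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _target_loading_sd(lam: float, noise_sd: float) -> float:
    """Signal sd giving a target population correlation ``lam`` with the factor."""
    if lam == 0.0:
        return 0.0
    return noise_sd * lam / math.sqrt(1.0 - lam * lam)


def simulate_expression(design: SimulationDesign) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Draw one dataset from the generative model; returns (matrix, truth)."""
    g, n = design.n_genes, design.n_per_condition
    s = 2 * n
    rng = np.random.default_rng(design.seed)

    # fixed draw order: baselines, noise, then one factor per planted structure
    mu = rng.normal(design.baseline_mean, design.baseline_sd, size=g)
    x = mu[:, None] + rng.normal(0.0, design.noise_sd, size=(g, s))
    in_a = np.zeros(s, dtype=bool)
    in_a[:n] = True

    de = np.array(sorted(set(design.de_genes)), dtype=int)
    if de.size:
        x[np.ix_(de, np.flatnonzero(in_a))] += design.delta

    structures: list[tuple[int, tuple[int, ...], float, float]] = []
    if design.wired_regulator is not None:
        w = design.wired_regulator
        structures.append((w.regulator, w.targets, w.loading_A, w.loading_B))
    if design.hub is not None:
        h = design.hub
        la = h.loading if h.condition == "A" else 0.0
        lb = h.loading if h.condition == "B" else 0.0
        structures.append((h.hub, h.targets, la, lb))

    for driver, targets, lam_a, lam_b in structures:
        f = rng.standard_normal(s)
        # the driver's expression is the latent factor itself
        x[driver] = mu[driver] + f
        if driver in de:
            x[driver, in_a] += design.delta
        b = np.where(in_a, _target_loading_sd(lam_a, design.noise_sd),
                     _target_loading_sd(lam_b, design.noise_sd))
        for t in targets:
            x[t] += b * f

    gene_ids = [f"g{i:05d}" for i in range(g)]
    sample_ids = [f"{design.label_A}_{j + 1}" for j in range(n)] + [
        f"{design.label_B}_{j + 1}" for j in range(n)
    ]
    data = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    condition_of = {sid: (design.label_A if i < n else design.label_B)
                    for i, sid in enumerate(sample_ids)}
    matrix = ExpressionMatrix(data, condition_of, reference=design.label_A)

    mean_a = mu.copy()
    if de.size:
        mean_a[de] += design.delta
    truth = SimulationTruth(
        de_genes=frozenset(gene_ids[i] for i in de),
        regulator_id=(gene_ids[design.wired_regulator.regulator]
                      if design.wired_regulator is not None else None),
        hub_id=gene_ids[design.hub.hub] if design.hub is not None else None,
        true_means=pd.DataFrame(
            {"mean_A": mean_a, "mean_B": mu}, index=gene_ids
        ),
    )
    return matrix, truth
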