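"""Synthetic expression data with known ground truth.

The generator emulates the carbon-source transfer experiment the framework
is built around: six carbon sources (three monosaccharides — glucose,
xylose, arabinose — and three defined polysaccharides — starch, arabinan,
xylan), biological triplicates except a starch duplicate, and log2
expression indices in which condition-specific *regulons* (sets of genes,
typically the genes behind a structure's required activities) are induced
by a fixed log2 effect on their inducing conditions.  Noise is additive
Gaussian on the log2 scale, which is the appropriate error model for
microarray expression indices.

Everything is seeded and the emitted :class:`GroundTruth` is consistent
with the matrix by construction, so downstream stages (differential
expression, clustering, coverage overlays) can be tested end to end
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .activities import required_activities
from .catalog import Catalog
from .mapping import StatusMap
from .structures import StructureGraph, load_structure

__all__ = [
    "CONDITIONS",
    "Regulon",
    "RegulonDesign",
    "GroundTruth",
    "simulate_expression",
    "make_status_fixture",
    "regulon_from_structure",
    "xylan_regulon_design",
]

#: the six carbon sources of the emulated design
CONDITIONS: tuple[str, ...] = (
    "glucose", "xylose", "arabinose", "starch", "arabinan", "xylan",
)

#: replicates per condition: biological triplicates except the starch duplicate
DEFAULT_REPLICATES: Mapping[str, int] = {
    "glucose": 3, "xylose": 3, "arabinose": 3,
    "starch": 2, "arabinan": 3, "xylan": 3,
}


@dataclass(frozen=True)
class Regulon:
    """A gene set induced on specific conditions by a fixed log2 effect."""

    name: str
    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    effect: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError(f"regulon {self.name}: effect must be finite")


@dataclass
class RegulonDesign:
    """Full specification of one synthetic experiment."""

    conditions: tuple[str, ...] = CONDITIONS
    replicates: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    regulons: list[Regulon] = field(default_factory=list)
    n_decoys: int = 100
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for cond, n in self.replicates.items():
            if cond not in self.conditions:
                raise ValueError(f"replicates for unknown condition {cond!r}")
        for cond in self.conditions:
            if self.replicates.get(cond, 0) < 2:
                raise ValueError(
                    f"condition {cond!r} needs >= 2 replicates"
                )
        for reg in self.regulons:
            for cond in reg.conditions:
                if cond not in self.conditions:
                    raise ValueError(
                        f"regulon {reg.name}: unknown condition {cond!r}"
                    )


@dataclass
class GroundTruth:
    """What was planted: induced conditions and effects per gene."""

    effects: pd.DataFrame  # genes x conditions, true added log2 effect
    regulon_of: dict[str, str]  # gene -> regulon name (decoys absent)

    def true_sign(self, cond_a: str, cond_b: str) -> pd.Series:
        """+1/-1/0 per gene: sign of the true mean difference a - b."""
        diff = self.effects[cond_a] - self.effects[cond_b]
        return np.sign(diff).astype(int)

    def true_de_genes(self, cond_a: str, cond_b: str) -> list[str]:
        s = self.true_sign(cond_a, cond_b)
        return list(s.index[s != 0])

    def archetype(self, gene: str) -> frozenset[str]:
        """The set of conditions on which a gene is induced."""
        row = self.effects.loc[gene]
        return frozenset(row.index[row != 0])


def simulate_expression(
    design: RegulonDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a log2 expression matrix from a regulon design.

    Returns ``(matrix, design_table, truth)``: the gene x sample matrix,
    the sample -> (condition, replicate) table, and the planted truth.
    Values are ``baseline_g + effect * [condition induced] + N(0, noise_sd)``
    with a per-gene baseline drawn once.  Deterministic given
    ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    genes: list[str] = []
    regulon_of: dict[str, str] = {}
    for reg in design.regulons:
        for g in reg.genes:
            if g not in regulon_of:
                genes.append(g)
                regulon_of[g] = reg.name
    genes += [f"decoy_{i:04d}" for i in range(design.n_decoys)]

    effects = pd.DataFrame(
        0.0, index=genes, columns=list(design.conditions)
    )
    for reg in design.regulons:
        for cond in reg.conditions:
            effects.loc[list(reg.genes), cond] += reg.effect

    samples = []
    sample_cond = []
    for cond in design.conditions:
        for r in range(1, design.replicates[cond] + 1):
            samples.append(f"{cond}_{r}")
            sample_cond.append((cond, r))

    baseline = rng.normal(design.baseline_mean, design.baseline_sd,
                          size=len(genes))
    values = np.empty((len(genes), len(samples)))
    for j, (cond, _r) in enumerate(sample_cond):
        values[:, j] = (
            baseline
            + effects[cond].to_numpy()
            + rng.normal(0.0, design.noise_sd, size=len(genes))
        )
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    design_table = pd.DataFrame(
        {
            "sample": samples,
            "condition": [c for c, _ in sample_cond],
            "replicate": [r for _, r in sample_cond],
        }
    )
    truth = GroundTruth(effects=effects, regulon_of=regulon_of)
    return matrix, design_table, truth


def make_status_fixture(
    truth: GroundTruth, comparison: tuple[str, str]
) -> StatusMap:
    """Status labels derived from the planted truth for one comparison.

    Lets the coverage overlay be exercised independently of the statistics
    stage: a gene is ``up`` if its true mean is higher on ``comparison[0]``
    than on ``comparison[1]``, ``down`` for the opposite, ``ns`` otherwise.
    """
    cond_a, cond_b = comparison
    for cond in comparison:
        if cond not in truth.effects.columns:
            raise KeyError(f"unknown condition {cond!r} in comparison")
    sign = truth.true_sign(cond_a, cond_b)
    labels = {
        gene: ("up" if s > 0 else "down")
        for gene, s in sign.items()
        if s != 0
    }
    return StatusMap(labels, provenance=f"truth:{cond_a}-vs-{cond_b}")


# ---------------------------------------------------------------------------
# convenience builders


def regulon_from_structure(
    structure: StructureGraph | str,
    catalog: Catalog,
    conditions: Sequence[str],
    effect: float = 2.0,
    name: str | None = None,
) -> Regulon:
    """The genes behind a structure's required activities, as a regulon."""
    if isinstance(structure, str):
        structure = load_structure(structure)
    req = required_activities(structure)
    genes: list[str] = []
    for act in req.activities:
        for rec in catalog.for_activity(act):
            genes.append(rec.key)
    return Regulon(
        name=name or f"{structure.name}_regulon",
        genes=tuple(dict.fromkeys(genes)),
        conditions=tuple(conditions),
        effect=effect,
    )


def xylan_regulon_design(
    catalog: Catalog,
    effect: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    n_decoys: int = 100,
) -> RegulonDesign:
    """The emulated arabinose/xylan cross-induction scenario.

    The xylan regulon (genes of all activities required to degrade oat-spelt
    xylan) is induced on xylan *and* arabinose, emulating the observation
    that arabinose alone can switch on the entire xylanolytic complex; the
    starch regulon is induced on starch only.
    """
    xylan_reg = regulon_from_structure(
        "xylan", catalog, ("xylan", "arabinose"), effect=effect
    )
    starch_reg = regulon_from_structure(
        "starch", catalog, ("starch",), effect=effect
    )
    return RegulonDesign(
        regulons=[xylan_reg, starch_reg],
        noise_sd=noise_sd,
        seed=seed,
        n_decoys=n_decoys,
    )
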