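"""Parametric generators for the sixteen packaged polysaccharide types.

Each generator emulates the repeating unit drawn in the corresponding
schematic: a decorated backbone whose branch and ester frequencies are
tunable.  Defaults follow the substrate descriptions where the source
substrates are chemically defined:

* sugar-beet arabinan: a 1,5-α-L-arabinan in which about 50 % of main-chain
  residues carry a single 1,2- or 1,3-linked arabinofuranosyl branch, with
  arabinose:galactose:rhamnose:galacturonic acid pooled at 88:4:2:6 (the
  minor sugars ride on a rhamnogalacturonan-like reducing-end stub);
* oat-spelt xylan: ≥70 % D-xylose with arabinosyl and (4-O-methyl-)
  glucuronosyl side groups and acetyl esters.

All randomness flows through a :class:`numpy.random.Generator` seeded from
``GeneratorParams.seed``, so identical parameters give byte-identical
serialized structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .structures import (
    Linkage,
    Modification,
    Residue,
    StructureGraph,
    ANOMERIC_CARBON,
    SUGAR_CARBONS,
)

__all__ = [
    "GeneratorParams",
    "default_params",
    "generate_structure",
    "generate_ensemble",
    "GENERATOR_TYPES",
]


@dataclass
class GeneratorParams:
    """Parameters of a structure generator.

    ``substitution``, ``composition`` and ``modification`` override the
    per-type defaults field by field; probabilities must lie in [0, 1] and
    composition ratios must be non-negative.
    """

    structure_type: str
    backbone_length: int = 20
    substitution: dict[str, float] = field(default_factory=dict)
    composition: dict[str, float] = field(default_factory=dict)
    modification: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.structure_type not in GENERATOR_TYPES:
            raise ValueError(
                f"unknown structure type {self.structure_type!r}; "
                f"known: {', '.join(sorted(GENERATOR_TYPES))}"
            )
        if self.backbone_length < 1:
            raise ValueError("backbone_length must be >= 1")
        for name, table in (
            ("substitution", self.substitution),
            ("modification", self.modification),
        ):
            for key, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{key!r}]={p} outside [0, 1]")
        for key, r in self.composition.items():
            if r < 0:
                raise ValueError(f"composition[{key!r}]={r} must be >= 0")


# --------------------------------------------------------------------------
# small builder helper


class _Builder:
    """Incrementally assemble a residue tree."""

    def __init__(self, name: str) -> None:
        self.name = name
        self.residues: list[Residue] = []
        self.linkages: list[Linkage] = []
        self._next = 0

    def add(
        self,
        sugar: str,
        parent: int | None = None,
        config: str = "alpha",
        parent_carbon: int = 4,
        backbone: bool = True,
        mods: Iterable[Modification] = (),
    ) -> int:
        rid = self._next
        self._next += 1
        self.residues.append(Residue.make(rid, sugar, backbone, mods))
        if parent is not None:
            self.linkages.append(
                Linkage(
                    parent_id=parent,
                    child_id=rid,
                    config=config,
                    parent_carbon=parent_carbon,
                    child_carbon=ANOMERIC_CARBON[sugar],
                )
            )
        return rid

    def add_mod(self, rid: int, kind: str, carbon: int) -> None:
        res = self.residues[rid]
        self.residues[rid] = Residue(
            id=res.id,
            sugar=res.sugar,
            ring_carbons=res.ring_carbons,
            anomeric_carbon=res.anomeric_carbon,
            backbone=res.backbone,
            modifications=res.modifications + (Modification(kind, carbon),),
        )

    def build(self) -> StructureGraph:
        return StructureGraph(self.name, self.residues, self.linkages, 0)


def _stochastic_round(rng: np.random.Generator, x: float) -> int:
    """Integer with expectation exactly ``x`` (floor plus Bernoulli)."""
    lo = int(np.floor(x))
    return lo + int(rng.random() < (x - lo))


# --------------------------------------------------------------------------
# per-type builders
#
# Every builder returns a StructureGraph rooted at the reducing end, with the
# main chain flagged backbone=True and branches backbone=False.


def _linear(name: str, sugar: str, length: int, config: str,
            parent_carbon: int) -> StructureGraph:
    b = _Builder(name)
    prev = b.add(sugar)
    for _ in range(length - 1):
        prev = b.add(sugar, prev, config, parent_carbon)
    return b.build()


def _build_starch(rng, length, sub, comp, mod) -> StructureGraph:
    # amylose chain: (Glc-α-1,4-Glc-α-1,4-)n
    return _linear("starch", "Glc", length, "alpha", 4)


def _build_cellulose(rng, length, sub, comp, mod) -> StructureGraph:
    return _linear("cellulose", "Glc", length, "beta", 4)


def _build_pullulan(rng, length, sub, comp, mod) -> StructureGraph:
    # maltotriose units joined α-1,6: bond pattern cycles 4,4,6
    b = _Builder("pullulan")
    prev = b.add("Glc")
    carbons = [4, 4, 6]
    for i in range(length - 1):
        prev = b.add("Glc", prev, "alpha", carbons[i % 3])
    return b.build()


def _build_inulin(rng, length, sub, comp, mod) -> StructureGraph:
    # terminal Glc at the (formally) reducing end, then a β-2,1 fructan chain
    b = _Builder("inulin")
    prev = b.add("Glc")
    for _ in range(length - 1):
        prev = b.add("Fru", prev, "beta", 1)
    return b.build()


def _build_galactomannan(rng, length, sub, comp, mod) -> StructureGraph:
    b = _Builder("galactomannan")
    prev = None
    for _ in range(length):
        prev = b.add("Man") if prev is None else b.add("Man", prev, "beta", 4)
        if rng.random() < sub["gal_6"]:
            b.add("Gal", prev, "alpha", 6, backbone=False)
    return b.build()


def _build_ggm(name: str, rng, length, sub, mod) -> StructureGraph:
    """Galactoglucomannan: β-1,4 Man/Glc backbone, α-1,6 Gal branches,
    acetyl esters on mannose.

    Glucosyl units are placed non-adjacently so the backbone never contains
    a Glc-β-1,4-Glc (cellulosic) bond class.
    """
    b = _Builder(name)
    prev = None
    prev_sugar = None
    for _ in range(length):
        if prev_sugar != "Glc" and rng.random() < sub["glc_frac"]:
            sugar = "Glc"
        else:
            sugar = "Man"
        prev = b.add(sugar) if prev is None else b.add(sugar, prev, "beta", 4)
        if sugar == "Man":
            if rng.random() < sub["gal_6"]:
                gal = b.add("Gal", prev, "alpha", 6, backbone=False)
                if rng.random() < sub["gal_ext"]:
                    b.add("Gal", gal, "beta", 2, backbone=False)
            if rng.random() < mod["acetyl"]:
                b.add_mod(prev, "acetyl", int(rng.choice([2, 3])))
        prev_sugar = sugar
    return b.build()


def _build_insoluble_ggm(rng, length, sub, comp, mod) -> StructureGraph:
    return _build_ggm("insoluble_galactoglucomannan", rng, length, sub, mod)


def _build_soluble_ggm(rng, length, sub, comp, mod) -> StructureGraph:
    return _build_ggm("soluble_galactoglucomannan", rng, length, sub, mod)


def _build_smooth_pectin(rng, length, sub, comp, mod) -> StructureGraph:
    b = _Builder("smooth_pectin")
    prev = None
    for _ in range(length):
        prev = b.add("GalA") if prev is None else b.add("GalA", prev, "alpha", 4)
        if rng.random() < mod["methyl"]:
            b.add_mod(prev, "methyl", 6)
    return b.build()


def _build_xylogalacturonan(rng, length, sub, comp, mod) -> StructureGraph:
    b = _Builder("xylogalacturonan")
    prev = None
    for _ in range(length):
        prev = b.add("GalA") if prev is None else b.add("GalA", prev, "alpha", 4)
        if rng.random() < sub["xyl_3"]:
            b.add("Xyl", prev, "beta", 3, backbone=False)
        if rng.random() < mod["methyl"]:
            b.add_mod(prev, "methyl", 6)
    return b.build()


def _build_xylan(rng, length, sub, comp, mod) -> StructureGraph:
    """Oat-spelt style arabinoglucuronoxylan.

    Per backbone xylose, carbon 2 carries an arabinofuranosyl branch or a
    4-O-methyl-glucuronosyl branch (or nothing), and carbon 3 carries an
    arabinofuranosyl branch or an acetyl ester (or nothing).
    """
    b = _Builder("xylan")
    prev = None
    for _ in range(length):
        prev = b.add("Xyl") if prev is None else b.add("Xyl", prev, "beta", 4)
        u = rng.random()
        if u < sub["ara_2"]:
            b.add("Ara", prev, "alpha", 2, backbone=False)
        elif u < sub["ara_2"] + sub["meglca_2"]:
            b.add("MeGlcA", prev, "alpha", 2, backbone=False)
        v = rng.random()
        if v < sub["ara_3"]:
            b.add("Ara", prev, "alpha", 3, backbone=False)
        elif v < sub["ara_3"] + mod["acetyl_3"]:
            b.add_mod(prev, "acetyl", 3)
    return b.build()


def _build_xyloglucan(name: str, rng, length, sub, xylosylated) -> StructureGraph:
    b = _Builder(name)
    prev = None
    for i in range(length):
        prev = b.add("Glc") if prev is None else b.add("Glc", prev, "beta", 4)
        if (i % 4) in xylosylated:
            xyl = b.add("Xyl", prev, "alpha", 6, backbone=False)
            if rng.random() < sub.get("gal_ext", 0.0):
                gal = b.add("Gal", xyl, "beta", 2, backbone=False)
                if rng.random() < sub.get("fuc_ext", 0.0):
                    b.add("Fuc", gal, "alpha", 2, backbone=False)
    return b.build()


def _build_xxgg(rng, length, sub, comp, mod) -> StructureGraph:
    return _build_xyloglucan("xyloglucan_xxgg", rng, length, sub, {0, 1})


def _build_xxxg(rng, length, sub, comp, mod) -> StructureGraph:
    return _build_xyloglucan("xyloglucan_xxxg", rng, length, sub, {0, 1, 2})


def _build_agi(rng, length, sub, comp, mod) -> StructureGraph:
    b = _Builder("arabinogalactan_i")
    prev = None
    for _ in range(length):
        prev = b.add("Gal") if prev is None else b.add("Gal", prev, "beta", 4)
        if rng.random() < sub["ara_3"]:
            b.add("Ara", prev, "alpha", 3, backbone=False)
    return b.build()


def _build_agii(rng, length, sub, comp, mod) -> StructureGraph:
    b = _Builder("arabinogalactan_ii")
    prev = None
    for _ in range(length):
        prev = b.add("Gal") if prev is None else b.add("Gal", prev, "beta", 3)
        u = rng.random()
        if u < sub["gal_6"]:
            gal = b.add("Gal", prev, "beta", 6, backbone=False)
            if rng.random() < sub["ara_on_gal"]:
                b.add("Ara", gal, "alpha", 3, backbone=False)
        elif u < sub["gal_6"] + sub["glca_6"]:
            b.add("GlcA", prev, "beta", 6, backbone=False)
    return b.build()


def _build_arabinan(rng, length, sub, comp, mod) -> StructureGraph:
    """Sugar-beet arabinan.

    Main chain of 1,5-α-L-arabinofuranose; each main-chain residue is
    substituted with probability ``branch`` by a single 1,2- or 1,3-linked
    arabinofuranosyl residue (equal odds).  The galactose, rhamnose and
    galacturonic acid of the preparation sit on a short rhamnogalacturonan-
    like stub at the reducing end, with counts stochastically rounded so the
    pooled composition matches ``composition`` in expectation.
    """
    branch_p = sub["branch"]
    branched = rng.random(length) < branch_p
    branch_carbon = np.where(rng.random(length) < 0.5, 2, 3)
    n_ara = length + int(branched.sum())

    ratios = dict(comp)
    r_ara = ratios.get("Ara", 88.0)
    n_rha = _stochastic_round(rng, n_ara * ratios.get("Rha", 0.0) / r_ara)
    n_gala_extra = _stochastic_round(
        rng, n_ara * max(ratios.get("GalA", 0.0) - ratios.get("Rha", 0.0), 0.0) / r_ara
    )
    n_gal = _stochastic_round(rng, n_ara * ratios.get("Gal", 0.0) / r_ara)

    b = _Builder("arabinan")
    # reducing-end stub: GalA run, then alternating (GalA, Rha) pairs;
    # galactan side chain hangs off the root galacturonate
    stub_seq = ["GalA"] * n_gala_extra
    for _ in range(n_rha):
        stub_seq += ["GalA", "Rha"]
    prev = None
    prev_sugar = None
    for sugar in stub_seq:
        if prev is None:
            prev = b.add(sugar)
        elif sugar == "Rha":  # Rha-α-1,4-GalA
            prev = b.add("Rha", prev, "alpha", 4)
        elif prev_sugar == "Rha":  # GalA-α-1,2-Rha
            prev = b.add("GalA", prev, "alpha", 2)
        else:  # GalA-α-1,4-GalA
            prev = b.add("GalA", prev, "alpha", 4)
        prev_sugar = sugar
    if stub_seq and n_gal:
        gprev = b.add("Gal", 0, "beta", 3, backbone=False)
        for _ in range(n_gal - 1):
            gprev = b.add("Gal", gprev, "beta", 4, backbone=False)

    fer_p = mod.get("feruloyl", 0.0)
    for i in range(length):
        if prev is None:
            prev = b.add("Ara")
        elif prev_sugar in ("GalA", "Rha"):
            prev = b.add("Ara", prev, "alpha", 4)  # attachment to the stub
        else:
            prev = b.add("Ara", prev, "alpha", 5)
        prev_sugar = "Ara"
        if branched[i]:
            b.add("Ara", prev, "alpha", int(branch_carbon[i]), backbone=False)
            free = 5 - branch_carbon[i]  # the other of C2/C3
        else:
            free = 2
        if rng.random() < fer_p:
            b.add_mod(prev, "feruloyl", int(free))
    return b.build()


def _build_rg1(rng, length, sub, comp, mod) -> StructureGraph:
    """Rhamnogalacturonan I: alternating GalA/Rha backbone, galactosyl and
    arabinosyl side groups on rhamnose, acetyl esters on galacturonate."""
    b = _Builder("rhamnogalacturonan_i")
    prev = None
    for i in range(length):
        if i % 2 == 0:
            if prev is None:
                prev = b.add("GalA")
            else:
                prev = b.add("GalA", prev, "alpha", 2)  # GalA-α-1,2-Rha
            if rng.random() < mod["acetyl"]:
                b.add_mod(prev, "acetyl", 3)
        else:
            prev = b.add("Rha", prev, "alpha", 4)  # Rha-α-1,4-GalA
            u = rng.random()
            if u < sub["gal_4"]:
                b.add("Gal", prev, "beta", 4, backbone=False)
            elif u < sub["gal_4"] + sub["ara_4"]:
                b.add("Ara", prev, "alpha", 4, backbone=False)
    return b.build()


# --------------------------------------------------------------------------
# registry and public API

_Builders = Callable[..., StructureGraph]

GENERATOR_TYPES: Mapping[str, _Builders] = {
    "starch": _build_starch,
    "cellulose": _build_cellulose,
    "pullulan": _build_pullulan,
    "inulin": _build_inulin,
    "galactomannan": _build_galactomannan,
    "insoluble_galactoglucomannan": _build_insoluble_ggm,
    "soluble_galactoglucomannan": _build_soluble_ggm,
    "smooth_pectin": _build_smooth_pectin,
    "xylogalacturonan": _build_xylogalacturonan,
    "xylan": _build_xylan,
    "xyloglucan_xxgg": _build_xxgg,
    "xyloglucan_xxxg": _build_xxxg,
    "arabinogalactan_i": _build_agi,
    "arabinogalactan_ii": _build_agii,
    "arabinan": _build_arabinan,
    "rhamnogalacturonan_i": _build_rg1,
}

_DEFAULT_SUBSTITUTION: dict[str, dict[str, float]] = {
    "galactomannan": {"gal_6": 0.5},
    "insoluble_galactoglucomannan": {"glc_frac": 0.3, "gal_6": 0.1,
                                     "gal_ext": 0.0},
    "soluble_galactoglucomannan": {"glc_frac": 0.3, "gal_6": 0.35,
                                   "gal_ext": 0.4},
    "xylogalacturonan": {"xyl_3": 0.4},
    "xylan": {"ara_2": 0.1, "meglca_2": 0.1, "ara_3": 0.1},
    "xyloglucan_xxxg": {"gal_ext": 0.3, "fuc_ext": 0.3},
    "xyloglucan_xxgg": {},
    "arabinogalactan_i": {"ara_3": 0.25},
    "arabinogalactan_ii": {"gal_6": 0.3, "glca_6": 0.1, "ara_on_gal": 0.34},
    "arabinan": {"branch": 0.5},
    "rhamnogalacturonan_i": {"gal_4": 0.35, "ara_4": 0.25},
}

_DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    # Methods-stated ratios of the sugar-beet arabinan preparation
    "arabinan": {"Ara": 88.0, "Gal": 4.0, "Rha": 2.0, "GalA": 6.0},
}

_DEFAULT_MODIFICATION: dict[str, dict[str, float]] = {
    "insoluble_galactoglucomannan": {"acetyl": 0.2},
    "soluble_galactoglucomannan": {"acetyl": 0.3},
    "smooth_pectin": {"methyl": 0.5},
    "xylogalacturonan": {"methyl": 0.3},
    "xylan": {"acetyl_3": 0.15},
    "arabinan": {"feruloyl": 0.05},
    "rhamnogalacturonan_i": {"acetyl": 0.3},
}


def default_params(structure_type: str, seed: int = 0,
                   backbone_length: int = 20) -> GeneratorParams:
    """Default generator parameters for a packaged structure type."""
    return GeneratorParams(
        structure_type=structure_type,
        backbone_length=backbone_length,
        substitution=dict(_DEFAULT_SUBSTITUTION.get(structure_type, {})),
        composition=dict(_DEFAULT_COMPOSITION.get(structure_type, {})),
        modification=dict(_DEFAULT_MODIFICATION.get(structure_type, {})),
        seed=seed,
    )


def generate_structure(params: GeneratorParams) -> StructureGraph:
    """Generate one structure; identical ``params`` give identical output."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    sub = {**_DEFAULT_SUBSTITUTION.get(params.structure_type, {}),
           **params.substitution}
    comp = {**_DEFAULT_COMPOSITION.get(params.structure_type, {}),
            **params.composition}
    mod = {**_DEFAULT_MODIFICATION.get(params.structure_type, {}),
           **params.modification}
    builder = GENERATOR_TYPES[params.structure_type]
    return builder(rng, params.backbone_length, sub, comp, mod)


def generate_ensemble(
    structure_type: str,
    n: int,
    seed: int = 0,
    backbone_length: int = 20,
    **overrides,
) -> list[StructureGraph]:
    """Generate ``n`` independent structures from one master seed."""
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    out = []
    for s in seeds:
        p = default_params(structure_type, seed=int(s),
                           backbone_length=backbone_length)
        for key, val in overrides.items():
            getattr(p, key).update(val) if isinstance(val, dict) else setattr(p, key, val)
        out.append(generate_structure(p))
    return out
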