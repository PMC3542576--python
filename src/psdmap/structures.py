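"""Tree model of plant polysaccharide structures.

A polysaccharide is represented as a rooted tree of sugar residues joined by
typed glycosidic linkages, with optional ester/ether substituents (acetyl,
methyl, feruloyl) attached to individual ring carbons.  The root is the
reducing-end residue; exo-acting glycosidases operate from the non-reducing
ends, i.e. the leaves of the tree.

Sixteen representative structures are packaged with the library (see
:func:`list_structures`); arbitrary structures can be loaded from JSON files
with the same schema, generated parametrically (:mod:`psdmap.generators`) or
built in code.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ALPHA",
    "BETA",
    "SUGAR_CARBONS",
    "ANOMERIC_CARBON",
    "MODIFICATION_KINDS",
    "Modification",
    "Residue",
    "Linkage",
    "LinkClass",
    "ModClass",
    "StructureGraph",
    "StructureValidationError",
    "list_structures",
    "load_structure",
    "save_structure",
    "residue_composition",
    "enumerate_bond_classes",
    "bond_classes",
    "backbone_substitution_fraction",
    "structure_to_dot",
]

ALPHA = "α"  # α
BETA = "β"  # β

#: monosaccharide code -> number of carbons (drawn as polygon sides)
SUGAR_CARBONS: Mapping[str, int] = {
    "Glc": 6,
    "Gal": 6,
    "Man": 6,
    "Xyl": 5,
    "Ara": 5,
    "Fru": 6,
    "Rha": 6,
    "Fuc": 6,
    "GalA": 6,
    "GlcA": 6,
    "MeGlcA": 6,
}

#: anomeric carbon per sugar; ketoses (fructose) use carbon 2, all others 1
ANOMERIC_CARBON: Mapping[str, int] = {sugar: 1 for sugar in SUGAR_CARBONS}
ANOMERIC_CARBON = {**ANOMERIC_CARBON, "Fru": 2}

MODIFICATION_KINDS = frozenset({"acetyl", "methyl", "feruloyl"})

_CONFIG_SYMBOL = {"alpha": ALPHA, "beta": BETA}


class StructureValidationError(ValueError):
    """A structure file or object violates the tree/residue invariants."""


@dataclass(frozen=True)
class Modification:
    """Ester or ether substituent on a single ring carbon."""

    kind: str
    carbon: int

    def __post_init__(self) -> None:
        if self.kind not in MODIFICATION_KINDS:
            raise StructureValidationError(
                f"unknown modification kind {self.kind!r}"
            )


@dataclass(frozen=True)
class Residue:
    """One sugar residue.

    ``backbone`` marks main-chain residues; side-chain residues carry
    ``backbone=False``.  ``ring_carbons`` is the number of carbons (pentose 5,
    hexose 6) and ``anomeric_carbon`` is 1 for aldoses and 2 for ketoses.
    """

    id: int
    sugar: str
    ring_carbons: int
    anomeric_carbon: int
    backbone: bool = True
    modifications: tuple[Modification, ...] = ()

    @classmethod
    def make(
        cls,
        id: int,
        sugar: str,
        backbone: bool = True,
        modifications: Iterable[Modification] = (),
    ) -> "Residue":
        """Build a residue with carbon counts taken from the sugar tables."""
        if sugar not in SUGAR_CARBONS:
            raise StructureValidationError(f"unknown sugar code {sugar!r}")
        return cls(
            id=id,
            sugar=sugar,
            ring_carbons=SUGAR_CARBONS[sugar],
            anomeric_carbon=ANOMERIC_CARBON[sugar],
            backbone=backbone,
            modifications=tuple(modifications),
        )


@dataclass(frozen=True)
class Linkage:
    """Glycosidic bond: the child's anomeric carbon bonds a parent carbon."""

    parent_id: int
    child_id: int
    config: str  # "alpha" | "beta"
    parent_carbon: int
    child_carbon: int

    def __post_init__(self) -> None:
        if self.config not in ("alpha", "beta"):
            raise StructureValidationError(
                f"linkage {self.parent_id}->{self.child_id}: "
                f"config must be 'alpha' or 'beta', got {self.config!r}"
            )


@dataclass(frozen=True)
class LinkClass:
    """Equivalence class of a linkage: what an enzyme pattern can see."""

    child_sugar: str
    config: str
    child_carbon: int
    parent_carbon: int
    parent_sugar: str
    role: str  # "backbone" | "side"

    @property
    def label(self) -> str:
        sym = _CONFIG_SYMBOL[self.config]
        return (
            f"{self.child_sugar}-{sym}-{self.child_carbon},"
            f"{self.parent_carbon}-{self.parent_sugar}"
        )


@dataclass(frozen=True)
class ModClass:
    """Equivalence class of a modification: kind plus host sugar."""

    kind: str
    host_sugar: str

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.host_sugar}"


class StructureGraph:
    """Rooted residue tree with typed linkages.

    The constructor validates all invariants (tree shape, carbon usage,
    anomeric consistency) and raises :class:`StructureValidationError` naming
    the offending record on failure.
    """

    def __init__(
        self,
        name: str,
        residues: Sequence[Residue],
        linkages: Sequence[Linkage],
        root_id: int,
    ) -> None:
        self.name = name
        self.residues: tuple[Residue, ...] = tuple(residues)
        self.linkages: tuple[Linkage, ...] = tuple(linkages)
        self.root_id = root_id
        self._res: dict[int, Residue] = {}
        self._children: dict[int, list[Linkage]] = {}
        self._parent_link: dict[int, Linkage] = {}
        self._validate()

    # -- accessors ---------------------------------------------------------

    def residue(self, rid: int) -> Residue:
        return self._res[rid]

    def children(self, rid: int) -> list[Linkage]:
        return self._children.get(rid, [])

    def parent_link(self, rid: int) -> Linkage | None:
        return self._parent_link.get(rid)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureGraph):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"StructureGraph({self.name!r}, {len(self.residues)} residues, "
            f"{len(self.linkages)} linkages)"
        )

    def linkage_role(self, link: Linkage) -> str:
        parent = self._res[link.parent_id]
        child = self._res[link.child_id]
        return "backbone" if parent.backbone and child.backbone else "side"

    def bond_label(self, link: Linkage) -> str:
        return self.link_class(link).label

    def link_class(self, link: Linkage) -> LinkClass:
        parent = self._res[link.parent_id]
        child = self._res[link.child_id]
        return LinkClass(
            child_sugar=child.sugar,
            config=link.config,
            child_carbon=link.child_carbon,
            parent_carbon=link.parent_carbon,
            parent_sugar=parent.sugar,
            role=self.linkage_role(link),
        )

    def mod_classes_of(self, rid: int) -> list[ModClass]:
        res = self._res[rid]
        return [ModClass(m.kind, res.sugar) for m in res.modifications]

    def backbone_interior_ids(self) -> frozenset[int]:
        """Backbone residues with a backbone parent and a backbone child.

        These are the residues an endo-acting enzyme regards as interior to
        the original main chain; chain-terminal residues are excluded.
        """
        interior = set()
        for res in self.residues:
            if not res.backbone:
                continue
            plink = self._parent_link.get(res.id)
            has_bb_parent = (
                plink is not None and self._res[plink.parent_id].backbone
            )
            has_bb_child = any(
                self._res[l.child_id].backbone for l in self.children(res.id)
            )
            if has_bb_parent and has_bb_child:
                interior.add(res.id)
        return frozenset(interior)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        if not self.residues:
            raise StructureValidationError("structure has no residues")
        for res in self.residues:
            if res.id in self._res:
                raise StructureValidationError(
                    f"duplicate residue id {res.id}"
                )
            if res.sugar not in SUGAR_CARBONS:
                raise StructureValidationError(
                    f"residue {res.id}: unknown sugar {res.sugar!r}"
                )
            if res.ring_carbons not in (5, 6):
                raise StructureValidationError(
                    f"residue {res.id}: ring_carbons must be 5 or 6"
                )
            if res.anomeric_carbon not in (1, 2):
                raise StructureValidationError(
                    f"residue {res.id}: anomeric_carbon must be 1 or 2"
                )
            self._res[res.id] = res
        if self.root_id not in self._res:
            raise StructureValidationError(
                f"root id {self.root_id} is not a residue"
            )

        if len(self.linkages) != len(self.residues) - 1:
            raise StructureValidationError(
                f"{len(self.linkages)} linkages for {len(self.residues)} "
                "residues; a tree needs |residues| - 1"
            )

        used_carbons: dict[int, set[int]] = {r.id: set() for r in self.residues}
        for link in self.linkages:
            for rid in (link.parent_id, link.child_id):
                if rid not in self._res:
                    raise StructureValidationError(
                        f"linkage {link.parent_id}->{link.child_id}: "
                        f"dangling residue id {rid}"
                    )
            child = self._res[link.child_id]
            parent = self._res[link.parent_id]
            if link.child_carbon != child.anomeric_carbon:
                raise StructureValidationError(
                    f"linkage {link.parent_id}->{link.child_id}: child carbon "
                    f"{link.child_carbon} is not the anomeric carbon "
                    f"({child.anomeric_carbon}) of {child.sugar}"
                )
            if not 1 <= link.parent_carbon <= parent.ring_carbons:
                raise StructureValidationError(
                    f"linkage {link.parent_id}->{link.child_id}: parent carbon "
                    f"{link.parent_carbon} outside 1..{parent.ring_carbons}"
                )
            if link.parent_carbon in used_carbons[link.parent_id]:
                raise StructureValidationError(
                    f"residue {link.parent_id}: carbon {link.parent_carbon} "
                    "carries more than one child"
                )
            used_carbons[link.parent_id].add(link.parent_carbon)
            used_carbons[link.child_id].add(link.child_carbon)
            if link.child_id in self._parent_link:
                raise StructureValidationError(
                    f"residue {link.child_id} is a child in two linkages"
                )
            self._parent_link[link.child_id] = link
            self._children.setdefault(link.parent_id, []).append(link)

        if self.root_id in self._parent_link:
            raise StructureValidationError(
                f"root {self.root_id} must not be a child"
            )

        for res in self.residues:
            seen = set()
            for mod in res.modifications:
                if mod.carbon in seen:
                    raise StructureValidationError(
                        f"residue {res.id}: duplicate modification carbon "
                        f"{mod.carbon}"
                    )
                seen.add(mod.carbon)
                if mod.carbon in used_carbons[res.id]:
                    raise StructureValidationError(
                        f"residue {res.id}: modification carbon {mod.carbon} "
                        "is already used by a linkage"
                    )
                if not 1 <= mod.carbon <= res.ring_carbons:
                    raise StructureValidationError(
                        f"residue {res.id}: modification carbon {mod.carbon} "
                        f"outside 1..{res.ring_carbons}"
                    )

        # connectivity: every residue reachable from the root
        reached = {self.root_id}
        stack = [self.root_id]
        while stack:
            rid = stack.pop()
            for link in self.children(rid):
                if link.child_id in reached:
                    raise StructureValidationError(
                        f"cycle through residue {link.child_id}"
                    )
                reached.add(link.child_id)
                stack.append(link.child_id)
        if len(reached) != len(self.residues):
            missing = sorted(set(self._res) - reached)
            raise StructureValidationError(
                f"residues not connected to the root: {missing}"
            )

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "root": self.root_id,
            "residues": [
                {
                    "id": r.id,
                    "sugar": r.sugar,
                    "ring_carbons": r.ring_carbons,
                    "anomeric_carbon": r.anomeric_carbon,
                    "backbone": r.backbone,
                    "modifications": [
                        {"kind": m.kind, "carbon": m.carbon}
                        for m in r.modifications
                    ],
                }
                for r in self.residues
            ],
            "linkages": [
                {
                    "parent": l.parent_id,
                    "child": l.child_id,
                    "config": l.config,
                    "parent_carbon": l.parent_carbon,
                    "child_carbon": l.child_carbon,
                }
                for l in self.linkages
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "StructureGraph":
        try:
            residues = [
                Residue(
                    id=r["id"],
                    sugar=r["sugar"],
                    ring_carbons=r["ring_carbons"],
                    anomeric_carbon=r["anomeric_carbon"],
                    backbone=bool(r.get("backbone", True)),
                    modifications=tuple(
                        Modification(m["kind"], m["carbon"])
                        for m in r.get("modifications", ())
                    ),
                )
                for r in data["residues"]
            ]
            linkages = [
                Linkage(
                    parent_id=l["parent"],
                    child_id=l["child"],
                    config=l["config"],
                    parent_carbon=l["parent_carbon"],
                    child_carbon=l["child_carbon"],
                )
                for l in data["linkages"]
            ]
            return cls(data["name"], residues, linkages, data["root"])
        except KeyError as exc:  # missing field -> validation error
            raise StructureValidationError(
                f"missing field {exc} in structure record"
            ) from exc

    def to_json(self) -> str:
        """Canonical JSON text; byte-identical across round trips."""
        return json.dumps(self.to_dict(), indent=1, sort_keys=True,
                          ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# packaged structures

#: the sixteen packaged structure types, in catalog order
PACKAGED_STRUCTURES: tuple[str, ...] = (
    "starch",
    "cellulose",
    "pullulan",
    "inulin",
    "galactomannan",
    "insoluble_galactoglucomannan",
    "soluble_galactoglucomannan",
    "smooth_pectin",
    "xylogalacturonan",
    "xylan",
    "xyloglucan_xxgg",
    "xyloglucan_xxxg",
    "arabinogalactan_i",
    "arabinogalactan_ii",
    "arabinan",
    "rhamnogalacturonan_i",
)


def list_structures() -> list[str]:
    """Names of the packaged polysaccharide structures (16 types)."""
    return list(PACKAGED_STRUCTURES)


def _packaged_path(name: str):
    return resources.files("psdmap").joinpath("data", "structures",
                                              f"{name}.json")


def load_structure(path_or_name: str | Path) -> StructureGraph:
    """Load a packaged structure by name, or any structure JSON by path."""
    name = str(path_or_name)
    if name in PACKAGED_STRUCTURES:
        text = _packaged_path(name).read_text(encoding="utf-8")
    else:
        p = Path(path_or_name)
        if not p.exists():
            raise StructureValidationError(
                f"{name!r} is neither a packaged structure name nor an "
                f"existing file; packaged names: {', '.join(PACKAGED_STRUCTURES)}"
            )
        text = p.read_text(encoding="utf-8")
    return StructureGraph.from_dict(json.loads(text))


def save_structure(structure: StructureGraph, path: str | Path) -> Path:
    """Write canonical JSON; ``save -> load -> save`` is byte-identical."""
    p = Path(path)
    p.write_text(structure.to_json(), encoding="utf-8")
    return p


# ---------------------------------------------------------------------------
# derived quantities


def residue_composition(
    structures: StructureGraph | Iterable[StructureGraph],
) -> dict[str, float]:
    """Fraction of residues per monosaccharide code, pooled over the input.

    Accepts a single structure or an ensemble; fractions sum to 1.
    """
    if isinstance(structures, StructureGraph):
        structures = [structures]
    counts: Counter[str] = Counter()
    for s in structures:
        for res in s:
            counts[res.sugar] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty structure ensemble")
    return {sugar: n / total for sugar, n in sorted(counts.items())}


def bond_classes(structure: StructureGraph) -> set[LinkClass | ModClass]:
    """Internal typed bond/modification classes of a structure."""
    classes: set[LinkClass | ModClass] = set()
    for link in structure.linkages:
        classes.add(structure.link_class(link))
    for res in structure:
        for mc in structure.mod_classes_of(res.id):
            classes.add(mc)
    return classes


def enumerate_bond_classes(structure: StructureGraph) -> set[tuple[str, str]]:
    """Public view of the bond classes: ``(label, context)`` pairs.

    Context is ``backbone``/``side`` for linkages and ``modification`` for
    ester/ether substituents.  This set is the join key between a structure
    and the enzymatic activities required to degrade it.
    """
    out: set[tuple[str, str]] = set()
    for cls in bond_classes(structure):
        if isinstance(cls, LinkClass):
            out.add((cls.label, cls.role))
        else:
            out.add((cls.label, "modification"))
    return out


def backbone_substitution_fraction(
    structures: StructureGraph | Iterable[StructureGraph],
    sugar: str | None = None,
) -> float:
    """Fraction of backbone residues carrying at least one side-chain branch.

    ``sugar`` restricts the denominator to backbone residues of that
    monosaccharide (e.g. the 1,5-linked arabinosyl main chain of arabinan).
    Modifications (esters) do not count as branches.
    """
    if isinstance(structures, StructureGraph):
        structures = [structures]
    n_backbone = 0
    n_substituted = 0
    for s in structures:
        for res in s:
            if not res.backbone:
                continue
            if sugar is not None and res.sugar != sugar:
                continue
            n_backbone += 1
            if any(not s.residue(l.child_id).backbone for l in s.children(res.id)):
                n_substituted += 1
    if n_backbone == 0:
        raise ValueError("no matching backbone residues")
    return n_substituted / n_backbone


# ---------------------------------------------------------------------------
# DOT export


def _dot_quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def structure_to_dot(structure: StructureGraph) -> str:
    """Raw structure as Graphviz DOT.

    Residues become polygon nodes whose number of sides equals the carbon
    count of the sugar; edges carry the bond label.
    """
    lines = [f"digraph {_dot_quote(structure.name)} {{"]
    lines.append("  rankdir=RL;")
    for res in structure.residues:
        label = f"{res.sugar}{res.id}"
        if res.modifications:
            mods = ",".join(f"{m.kind}@C{m.carbon}" for m in res.modifications)
            label += f"\\n{mods}"
        style = "filled" if res.backbone else "solid"
        lines.append(
            f"  r{res.id} [shape=polygon sides={res.ring_carbons} "
            f"label={_dot_quote(label)} style={style} fillcolor=lightgrey];"
        )
    for link in structure.linkages:
        lines.append(
            f"  r{link.parent_id} -> r{link.child_id} "
            f"[label={_dot_quote(structure.bond_label(link))} dir=back];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
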