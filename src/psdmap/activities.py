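"""Enzymatic activities and the structure -> required-activity join.

An :class:`ActivitySpec` describes one catalytic activity (EC number where
one exists, otherwise just a name) with a mode of action and a set of bond
patterns.  Modes:

``endo``
    cleaves internal main-chain glycosidic bonds;
``exo_nonreducing``
    removes the terminal residue at a non-reducing end (a leaf of the tree);
``debranching``
    removes single-residue side chains only;
``esterase``
    removes an ester/ether substituent (acetyl, methyl, feruloyl).

Matching is by (child sugar, anomeric configuration, linkage carbons,
backbone/side role), not by CAZy family: the same activity may be carried by
several families and vice versa.

:func:`required_activities` joins a structure's bond classes against the
registry and returns every activity with a matching pattern.  Bond classes
with no known activity are reported as unmapped rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .structures import LinkClass, ModClass, StructureGraph, bond_classes

__all__ = [
    "LinkPattern",
    "EsterPattern",
    "ActivitySpec",
    "RequiredActivities",
    "REGISTRY",
    "get_activity",
    "activities_by_ec",
    "required_activities",
]

_ANY = None  # wildcard marker in patterns


@dataclass(frozen=True)
class LinkPattern:
    """Glycosidic-bond pattern; ``None`` fields are wildcards."""

    child: frozenset[str] | None
    config: str | None
    parent_carbon: frozenset[int] | None
    parent: frozenset[str] | None
    role: str | None = None  # "backbone" | "side" | None (any)

    def matches(self, cls: LinkClass) -> bool:
        if self.child is not None and cls.child_sugar not in self.child:
            return False
        if self.config is not None and cls.config != self.config:
            return False
        if (
            self.parent_carbon is not None
            and cls.parent_carbon not in self.parent_carbon
        ):
            return False
        if self.parent is not None and cls.parent_sugar not in self.parent:
            return False
        if self.role is not None and cls.role != self.role:
            return False
        return True


@dataclass(frozen=True)
class EsterPattern:
    """Substituent pattern: modification kind plus (optional) host sugar."""

    kind: str
    host: frozenset[str] | None = None

    def matches(self, cls: ModClass) -> bool:
        if cls.kind != self.kind:
            return False
        return self.host is None or cls.host_sugar in self.host


@dataclass(frozen=True)
class ActivitySpec:
    """One enzymatic activity with its bond-pattern matching rule."""

    ec: str  # may be empty when no EC number exists
    name: str
    mode: str  # endo | exo_nonreducing | debranching | esterase
    patterns: tuple[LinkPattern | EsterPattern, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("endo", "exo_nonreducing", "debranching",
                             "esterase"):
            raise ValueError(f"{self.name}: unknown mode {self.mode!r}")
        for p in self.patterns:
            if self.mode == "esterase" and not isinstance(p, EsterPattern):
                raise ValueError(
                    f"{self.name}: esterase patterns must name a "
                    "modification class"
                )
            if self.mode != "esterase" and not isinstance(p, LinkPattern):
                raise ValueError(
                    f"{self.name}: glycosidase patterns must be bond patterns"
                )

    # -- matching ----------------------------------------------------------

    def matches_linkage(self, cls: LinkClass) -> bool:
        """Can this activity cleave bonds of the given class at all?

        Mode semantics: endo acts on backbone classes only, debranching on
        side classes only, exo wherever its patterns allow.
        """
        if self.mode == "esterase":
            return False
        if self.mode == "endo" and cls.role != "backbone":
            return False
        if self.mode == "debranching" and cls.role != "side":
            return False
        return any(
            p.matches(cls) for p in self.patterns if isinstance(p, LinkPattern)
        )

    def matches_modification(self, cls: ModClass) -> bool:
        if self.mode != "esterase":
            return False
        return any(
            p.matches(cls) for p in self.patterns if isinstance(p, EsterPattern)
        )

    def removes_terminal(self, cls: LinkClass) -> bool:
        """True if the activity can release a leaf residue bound by ``cls``."""
        return (
            self.mode in ("exo_nonreducing", "debranching")
            and self.matches_linkage(cls)
        )

    def __str__(self) -> str:
        return f"{self.name}" + (f" (EC {self.ec})" if self.ec else "")


# ---------------------------------------------------------------------------
# registry


def _lp(child, config, parent_carbon, parent, role=None) -> LinkPattern:
    fs = lambda x: None if x is None else frozenset(
        x if isinstance(x, (set, frozenset, list, tuple)) else [x]
    )
    return LinkPattern(fs(child), config, fs(parent_carbon), fs(parent), role)


def _ep(kind, host=None) -> EsterPattern:
    host_fs = None if host is None else frozenset(
        host if isinstance(host, (set, frozenset, list, tuple)) else [host]
    )
    return EsterPattern(kind, host_fs)


def _act(ec, name, mode, *patterns) -> ActivitySpec:
    return ActivitySpec(ec, name, mode, tuple(patterns))


_ACTIVITIES: tuple[ActivitySpec, ...] = (
    # -- starch / pullulan
    _act("3.2.1.1", "α-amylase", "endo",
         _lp("Glc", "alpha", 4, "Glc", "backbone")),
    _act("3.2.1.41", "pullulanase", "endo",
         _lp("Glc", "alpha", 6, "Glc", "backbone")),
    _act("3.2.1.3", "glucoamylase", "exo_nonreducing",
         _lp("Glc", "alpha", {4, 6}, _ANY)),
    _act("3.2.1.20", "α-glucosidase", "exo_nonreducing",
         _lp("Glc", "alpha", {4, 6}, _ANY)),
    # -- inulin
    _act("3.2.1.7", "endo-inulinase", "endo",
         _lp("Fru", "beta", 1, {"Fru", "Glc"}, "backbone")),
    _act("3.2.1.80", "exo-inulinase", "exo_nonreducing",
         _lp("Fru", "beta", 1, _ANY)),
    # -- cellulose / xyloglucan backbone
    _act("3.2.1.4", "endo-1,4-β-glucanase", "endo",
         _lp("Glc", "beta", 4, "Glc", "backbone")),
    _act("3.2.1.21", "β-glucosidase", "exo_nonreducing",
         _lp("Glc", "beta", 4, _ANY)),
    # -- mannans
    _act("3.2.1.78", "endo-1,4-β-D-mannanase", "endo",
         _lp("Man", "beta", 4, {"Man", "Glc"}, "backbone"),
         _lp("Glc", "beta", 4, "Man", "backbone")),
    _act("3.2.1.25", "β-mannosidase", "exo_nonreducing",
         _lp("Man", "beta", 4, _ANY)),
    _act("3.2.1.22", "α-galactosidase", "debranching",
         _lp("Gal", "alpha", 6, _ANY)),
    _act("3.2.1.23", "β-galactosidase", "exo_nonreducing",
         _lp("Gal", "beta", {2, 3, 4, 6}, _ANY)),
    _act("3.1.1.6", "acetyl esterase", "esterase",
         _ep("acetyl", {"Man", "Glc"})),
    # -- xylan
    _act("3.2.1.8", "endo-1,4-β-xylanase", "endo",
         _lp("Xyl", "beta", 4, "Xyl", "backbone")),
    _act("3.2.1.37", "β-xylosidase", "exo_nonreducing",
         _lp("Xyl", "beta", {3, 4}, _ANY)),
    _act("3.2.1.55", "α-arabinofuranosidase", "exo_nonreducing",
         _lp("Ara", "alpha", {2, 3, 4, 5}, {"Ara", "Gal", "Rha", "GalA"})),
    _act("3.2.1.55", "arabinoxylan arabinofuranohydrolase", "debranching",
         _lp("Ara", "alpha", {2, 3}, "Xyl")),
    _act("3.2.1.139", "α-glucuronidase", "debranching",
         _lp({"MeGlcA", "GlcA"}, "alpha", 2, "Xyl")),
    _act("3.1.1.72", "acetyl xylan esterase", "esterase",
         _ep("acetyl", "Xyl")),
    # -- arabinan / galactans
    _act("3.2.1.99", "endo-1,5-α-arabinanase", "endo",
         _lp("Ara", "alpha", 5, "Ara", "backbone")),
    _act("3.2.1.89", "endo-1,4-β-galactanase", "endo",
         _lp("Gal", "beta", 4, "Gal", "backbone")),
    _act("", "endo-1,3-β-galactanase", "endo",
         _lp("Gal", "beta", 3, "Gal", "backbone")),
    _act("3.2.1.31", "β-glucuronidase", "debranching",
         _lp("GlcA", "beta", 6, "Gal")),
    _act("3.1.1.73", "feruloyl esterase", "esterase",
         _ep("feruloyl", "Ara")),
    # -- pectins
    _act("3.2.1.15", "endo-polygalacturonase", "endo",
         _lp("GalA", "alpha", 4, "GalA", "backbone")),
    _act("3.2.1.67", "exo-polygalacturonase", "exo_nonreducing",
         _lp("GalA", "alpha", {2, 4}, _ANY)),
    _act("3.1.1.11", "pectin methyl esterase", "esterase",
         _ep("methyl", "GalA")),
    _act("3.2.1.171", "endo-rhamnogalacturonase", "endo",
         _lp("Rha", "alpha", 4, "GalA", "backbone"),
         _lp("GalA", "alpha", 2, "Rha", "backbone")),
    _act("3.2.1.40", "α-rhamnosidase", "exo_nonreducing",
         _lp("Rha", "alpha", {2, 4}, _ANY)),
    _act("3.1.1.86", "rhamnogalacturonan acetyl esterase", "esterase",
         _ep("acetyl", "GalA")),
    # -- xyloglucan side chains
    _act("3.2.1.177", "α-xylosidase", "debranching",
         _lp("Xyl", "alpha", 6, "Glc")),
    _act("3.2.1.51", "α-fucosidase", "debranching",
         _lp("Fuc", "alpha", 2, "Gal")),
)

#: canonical activity registry, keyed by lower-cased activity name
REGISTRY: dict[str, ActivitySpec] = {a.name.lower(): a for a in _ACTIVITIES}


def get_activity(name: str) -> ActivitySpec:
    """Look an activity up by (case-insensitive) name."""
    try:
        return REGISTRY[name.strip().lower()]
    except KeyError:
        raise KeyError(f"unknown activity name {name!r}") from None


def activities_by_ec(ec: str) -> list[ActivitySpec]:
    """All registry activities sharing an EC number (may be several)."""
    return [a for a in _ACTIVITIES if a.ec == ec and ec]


# ---------------------------------------------------------------------------
# structure -> required activities


@dataclass(frozen=True)
class RequiredActivities:
    """Outcome of joining a structure against the activity registry."""

    structure: str
    activities: tuple[ActivitySpec, ...]
    by_class: tuple[tuple[str, tuple[str, ...]], ...]  # (class label, names)
    unmapped: tuple[str, ...]  # class labels with no known activity

    @property
    def names(self) -> frozenset[str]:
        return frozenset(a.name for a in self.activities)

    @property
    def ecs(self) -> frozenset[str]:
        return frozenset(a.ec for a in self.activities if a.ec)

    def __iter__(self):
        return iter(self.activities)

    def __len__(self) -> int:
        return len(self.activities)


def required_activities(structure: StructureGraph) -> RequiredActivities:
    """Every registry activity needed to degrade ``structure``.

    For each backbone linkage class the result carries the matching endo and
    exo activities; for each side-chain class the matching debranching/exo
    activities; for each modification class the matching esterases.  Classes
    that match nothing are listed in ``unmapped`` (never silently dropped).
    The result is a pure function of the structure's bond-class set.
    """
    found: dict[str, ActivitySpec] = {}
    per_class: list[tuple[str, tuple[str, ...]]] = []
    unmapped: list[str] = []
    for cls in sorted(
        bond_classes(structure),
        key=lambda c: (isinstance(c, ModClass), c.label),
    ):
        if isinstance(cls, ModClass):
            hits = [a for a in _ACTIVITIES if a.matches_modification(cls)]
        else:
            hits = [a for a in _ACTIVITIES if a.matches_linkage(cls)]
        if hits:
            for a in hits:
                found[a.name] = a
            per_class.append((cls.label, tuple(a.name for a in hits)))
        else:
            unmapped.append(cls.label)
    ordered = tuple(sorted(found.values(), key=lambda a: a.name))
    return RequiredActivities(
        structure=structure.name,
        activities=ordered,
        by_class=tuple(per_class),
        unmapped=tuple(unmapped),
    )
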