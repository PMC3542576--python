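"""Deterministic closure simulation of enzymatic depolymerization.

Digestion is a reachability computation, not a kinetic model: given a
structure and a set of activities, the engine applies four cleavage rules to
a fixpoint and reports the released products.

R1 (esterase)
    remove any ester/ether substituent matched by an esterase.
R2/R4 (terminal removal)
    an exo-acting or debranching activity releases a leaf residue (a current
    non-reducing end) as a free monomer, provided the residue carries no
    substituent and the linkage matches; debranching activities act on
    side-chain linkages only.
R3 (endo)
    an endo activity cleaves a backbone linkage when both flanking residues
    were interior in the original backbone and both are currently free of
    substituents (branches and esters block cleavage).

Because substituents are only ever removed and the endo interiority test is
a static property of the input, the rule system is monotone and therefore
confluent: the fixpoint does not depend on rule application order.  A
fragment reduced to a single residue is a free monomer.  Completeness is the
fraction of input residues released as free monomers; oligomeric products
(cellobiose and the like) count as incomplete degradation.

The optional processive mode re-evaluates endo interiority against the
current fragment instead of the original backbone; it applies rules in a
canonical deterministic order (leftmost bond first, non-reducing to
reducing) and is order-sensitive by construction.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .activities import ActivitySpec, RequiredActivities
from .structures import LinkClass, Linkage, ModClass, StructureGraph

__all__ = [
    "DigestOptions",
    "DigestResult",
    "digest",
    "minimal_sufficient_sets",
    "explain_blockers",
]


@dataclass(frozen=True)
class DigestOptions:
    processive: bool = False


@dataclass
class DigestResult:
    """Outcome of a digestion run."""

    structure: str
    n_residues: int
    dp_histogram: dict[int, int]  # degree of polymerization -> fragment count
    monomer_yield: dict[str, int]  # sugar -> free monomers released
    completeness: float
    fragments: tuple[tuple[int, ...], ...]  # residue ids of leftover fragments
    remaining_linkages: tuple[LinkClass, ...]
    remaining_modifications: tuple[ModClass, ...]
    cleavage_log: tuple[tuple[str, str], ...]  # (rule, description)
    activity_names: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "n_residues": self.n_residues,
            "dp_histogram": {str(k): v for k, v in
                             sorted(self.dp_histogram.items())},
            "monomer_yield": dict(sorted(self.monomer_yield.items())),
            "completeness": self.completeness,
            "blockers": explain_blockers(self),
        }


class _State:
    """Mutable digestion state over one structure."""

    def __init__(self, structure: StructureGraph) -> None:
        self.s = structure
        self.alive: set[int] = {r.id for r in structure}
        self.mods: dict[int, list] = {
            r.id: list(r.modifications) for r in structure
        }
        self.children: dict[int, set[int]] = {r.id: set() for r in structure}
        self.parent: dict[int, Linkage] = {}
        for link in structure.linkages:
            self.children[link.parent_id].add(link.child_id)
            self.parent[link.child_id] = link
        self.roots: set[int] = {structure.root_id}
        self.monomers: Counter[str] = Counter()
        self.log: list[tuple[str, str]] = []
        self.interior = structure.backbone_interior_ids()

    # -- predicates --------------------------------------------------------

    def unsubstituted(self, rid: int) -> bool:
        """No ester and no side-chain child remains on the residue."""
        if self.mods[rid]:
            return False
        return all(
            self.s.residue(c).backbone for c in self.children[rid]
        )

    def link_class(self, link: Linkage) -> LinkClass:
        return self.s.link_class(link)

    # -- mutations ---------------------------------------------------------

    def remove_mod(self, rid: int, mod) -> None:
        self.mods[rid].remove(mod)

    def release_leaf(self, rid: int) -> None:
        link = self.parent.pop(rid)
        self.children[link.parent_id].discard(rid)
        self.alive.discard(rid)
        self.monomers[self.s.residue(rid).sugar] += 1

    def cut(self, link: Linkage) -> None:
        self.children[link.parent_id].discard(link.child_id)
        del self.parent[link.child_id]
        self.roots.add(link.child_id)

    def liberate_singletons(self) -> bool:
        changed = False
        for rid in [r for r in self.roots if r in self.alive]:
            if not self.children[rid]:
                self.roots.discard(rid)
                self.alive.discard(rid)
                self.monomers[self.s.residue(rid).sugar] += 1
                self.log.append(("free", f"residue {rid} liberated as "
                                 f"{self.s.residue(rid).sugar}"))
                changed = True
        return changed

    def fragment_members(self) -> list[list[int]]:
        out = []
        for root in sorted(self.roots & self.alive):
            members, stack = [], [root]
            while stack:
                rid = stack.pop()
                members.append(rid)
                stack.extend(self.children[rid])
            out.append(sorted(members))
        return out


def _iter_activities(
    activities: Iterable[ActivitySpec] | RequiredActivities,
) -> tuple[ActivitySpec, ...]:
    if isinstance(activities, RequiredActivities):
        return activities.activities
    acts = tuple(activities)
    for a in acts:
        if not isinstance(a, ActivitySpec):
            raise TypeError(f"not an ActivitySpec: {a!r}")
    return acts


def digest(
    structure: StructureGraph,
    activities: Iterable[ActivitySpec] | RequiredActivities,
    options: DigestOptions = DigestOptions(),
) -> DigestResult:
    """Run the cleavage rule system to its fixpoint.

    Residues are conserved: fragments plus released monomers always account
    for the full input.  Under the default (non-processive) semantics the
    result is independent of rule application order.
    """
    acts = _iter_activities(activities)
    esterases = [a for a in acts if a.mode == "esterase"]
    removers = [a for a in acts if a.mode in ("exo_nonreducing", "debranching")]
    endos = [a for a in acts if a.mode == "endo"]

    st = _State(structure)
    st.liberate_singletons()
    changed = True
    while changed:
        changed = False
        # R1: esterases
        for rid in sorted(st.alive):
            res = structure.residue(rid)
            for mod in list(st.mods[rid]):
                mc = ModClass(mod.kind, res.sugar)
                hit = next(
                    (a for a in esterases if a.matches_modification(mc)), None
                )
                if hit is not None:
                    st.remove_mod(rid, mod)
                    st.log.append(
                        ("R1", f"{hit.name} removed {mc.label} at residue {rid}")
                    )
                    changed = True
        # R2/R4: terminal removal at non-reducing ends
        for rid in sorted(st.alive):
            if st.children[rid] or rid not in st.parent:
                continue  # not a leaf with a parent
            if st.mods[rid]:
                continue
            lc = st.link_class(st.parent[rid])
            hit = next((a for a in removers if a.removes_terminal(lc)), None)
            if hit is not None:
                st.log.append(
                    ("R2/R4", f"{hit.name} released residue {rid} "
                     f"({lc.label})")
                )
                st.release_leaf(rid)
                changed = True
        # R3: endo cleavage of interior backbone bonds
        for link in structure.linkages:
            if link.child_id not in st.parent:
                continue  # already cut or released
            if st.parent[link.child_id] is not link:
                continue
            lc = st.link_class(link)
            if lc.role != "backbone":
                continue
            if options.processive:
                interior_ok = _fragment_interior(st, link)
            else:
                interior_ok = (
                    link.parent_id in st.interior
                    and link.child_id in st.interior
                )
            if not interior_ok:
                continue
            if not (st.unsubstituted(link.parent_id)
                    and st.unsubstituted(link.child_id)):
                continue
            hit = next((a for a in endos if a.matches_linkage(lc)), None)
            if hit is not None:
                st.cut(link)
                st.log.append(
                    ("R3", f"{hit.name} cleaved {lc.label} between "
                     f"{link.parent_id} and {link.child_id}")
                )
                changed = True
        if st.liberate_singletons():
            changed = True

    # assemble result
    fragments = st.fragment_members()
    dp_hist: Counter[int] = Counter(len(f) for f in fragments)
    n_mono = sum(st.monomers.values())
    if n_mono:
        dp_hist[1] += n_mono
    remaining_links = []
    for link in structure.linkages:
        if link.child_id in st.parent and st.parent[link.child_id] is link:
            remaining_links.append(st.link_class(link))
    remaining_mods = [
        ModClass(m.kind, structure.residue(rid).sugar)
        for rid in sorted(st.alive)
        for m in st.mods[rid]
    ]
    n = len(structure)
    # conservation check (defensive; the rules cannot violate it)
    assert sum(len(f) for f in fragments) + n_mono == n
    return DigestResult(
        structure=structure.name,
        n_residues=n,
        dp_histogram=dict(dp_hist),
        monomer_yield=dict(st.monomers),
        completeness=n_mono / n,
        fragments=tuple(tuple(f) for f in fragments),
        remaining_linkages=tuple(remaining_links),
        remaining_modifications=tuple(remaining_mods),
        cleavage_log=tuple(st.log),
        activity_names=frozenset(a.name for a in acts),
    )


def _fragment_interior(st: _State, link: Linkage) -> bool:
    """Processive-mode interiority: judged within the current fragment."""
    parent_has_bb_parent = (
        link.parent_id in st.parent
        and st.s.residue(st.parent[link.parent_id].parent_id).backbone
    )
    child_has_bb_child = any(
        st.s.residue(c).backbone for c in st.children[link.child_id]
    )
    return parent_has_bb_parent and child_has_bb_child


def minimal_sufficient_sets(
    structure: StructureGraph,
    candidate_activities: Sequence[ActivitySpec],
    max_size: int | None = None,
) -> list[tuple[ActivitySpec, ...]]:
    """Minimal activity subsets reaching completeness 1.0.

    Exhaustive subset enumeration for up to 15 candidates (smallest subsets
    first; supersets of a sufficient set are skipped); above that a single
    greedy pruning of the full set is returned.  An empty list means no
    subset suffices.
    """
    cands = list(candidate_activities)
    limit = max_size if max_size is not None else len(cands)

    def complete(subset) -> bool:
        return digest(structure, subset).completeness == 1.0

    if len(cands) > 15:
        if not complete(cands):
            return []
        kept = list(cands)
        for a in list(kept):
            trial = [x for x in kept if x is not a]
            if complete(trial):
                kept = trial
        return [tuple(kept)]

    minimal: list[tuple[ActivitySpec, ...]] = []
    for size in range(0, limit + 1):
        for combo in itertools.combinations(cands, size):
            names = frozenset(a.name for a in combo)
            if any(
                frozenset(a.name for a in m) <= names for m in minimal
            ):
                continue
            if complete(combo):
                minimal.append(combo)
    return minimal


def explain_blockers(result: DigestResult) -> list[str]:
    """Human-readable account of why residues were not released.

    Every leftover fragment is attributed to at least one uncleaved bond or
    unremoved substituent; a complete digest yields an empty report.
    """
    if result.completeness == 1.0:
        return []
    msgs: list[str] = []
    seen: set[str] = set()
    for mc in result.remaining_modifications:
        msg = (f"{mc.label} ester blocks release of {mc.host_sugar} "
               "(missing esterase activity)")
        if msg not in seen:
            seen.add(msg)
            msgs.append(msg)
    for lc in result.remaining_linkages:
        if lc.role == "side":
            msg = (f"{lc.label} side chain blocks {lc.parent_sugar} release "
                   "(missing debranching/exo activity)")
        else:
            msg = (f"backbone bond {lc.label} uncleaved "
                   "(missing endo/exo activity)")
        if msg not in seen:
            seen.add(msg)
            msgs.append(msg)
    return msgs
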