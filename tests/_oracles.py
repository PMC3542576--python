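"""Independent oracles used by the test suite.

These re-derive expected results through routes separate from the library
implementation: a one-rule-at-a-time digestion closure with randomized rule
order, a plain-Python median polish, and the textbook Benjamini-Hochberg
step-up definition.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from psdmap.structures import LinkClass, ModClass, StructureGraph


def closure_digest_oracle(
    structure: StructureGraph,
    activities,
    rng: np.random.Generator,
):
    """Apply one applicable cleavage rule at a time, in random order.

    Returns ``(monomer Counter, sorted fragment sizes)``.  Independent
    state handling from the engine: plain dicts, no worklist, full rescan
    of every rule instance after each single application.
    """
    acts = list(activities)
    parent = {}
    children = {r.id: set() for r in structure}
    for link in structure.linkages:
        parent[link.child_id] = link
        children[link.parent_id].add(link.child_id)
    mods = {r.id: list(r.modifications) for r in structure}
    alive = {r.id for r in structure}
    roots = {structure.root_id}
    monomers = Counter()

    bb = {r.id: r.backbone for r in structure}
    interior = set()
    for r in structure:
        if not r.backbone:
            continue
        pl = parent.get(r.id)
        if pl is None or not bb[pl.parent_id]:
            continue
        if any(bb[c] for c in children[r.id]):
            interior.add(r.id)

    def link_class(link):
        p = structure.residue(link.parent_id)
        c = structure.residue(link.child_id)
        role = "backbone" if p.backbone and c.backbone else "side"
        return LinkClass(c.sugar, link.config, link.child_carbon,
                         link.parent_carbon, p.sugar, role)

    def unsub(rid):
        return not mods[rid] and all(bb[c] for c in children[rid])

    def applicable():
        inst = []
        for rid in alive:
            sugar = structure.residue(rid).sugar
            for mod in mods[rid]:
                for a in acts:
                    if a.matches_modification(ModClass(mod.kind, sugar)):
                        inst.append(("ester", rid, mod))
                        break
            if not children[rid] and rid in parent and not mods[rid]:
                lc = link_class(parent[rid])
                if any(a.removes_terminal(lc) for a in acts):
                    inst.append(("leaf", rid, None))
            if rid in roots and not children[rid]:
                inst.append(("free", rid, None))
        for link in structure.linkages:
            if parent.get(link.child_id) is not link:
                continue
            lc = link_class(link)
            if lc.role != "backbone":
                continue
            if link.parent_id in interior and link.child_id in interior \
                    and unsub(link.parent_id) and unsub(link.child_id) \
                    and any(a.mode == "endo" and a.matches_linkage(lc)
                            for a in acts):
                inst.append(("endo", link.child_id, link))
        return inst

    while True:
        inst = applicable()
        if not inst:
            break
        kind, rid, extra = inst[rng.integers(len(inst))]
        if kind == "ester":
            mods[rid].remove(extra)
        elif kind == "leaf":
            link = parent.pop(rid)
            children[link.parent_id].discard(rid)
            alive.discard(rid)
            monomers[structure.residue(rid).sugar] += 1
        elif kind == "free":
            roots.discard(rid)
            alive.discard(rid)
            monomers[structure.residue(rid).sugar] += 1
        else:  # endo cut
            link = extra
            children[link.parent_id].discard(link.child_id)
            del parent[link.child_id]
            roots.add(link.child_id)

    sizes = []
    for root in roots & alive:
        n, stack = 0, [root]
        while stack:
            x = stack.pop()
            n += 1
            stack.extend(children[x])
        sizes.append(n)
    return monomers, sorted(sizes)


def median_polish_oracle(matrix, tol=0.01, max_iter=10):
    """Plain-Python Tukey median polish; returns per-column summaries."""
    Z = [list(map(float, row)) for row in matrix]
    nr, nc = len(Z), len(Z[0])

    def med(values):
        v = sorted(values)
        k = len(v)
        return v[k // 2] if k % 2 else 0.5 * (v[k // 2 - 1] + v[k // 2])

    overall = 0.0
    row_eff = [0.0] * nr
    col_eff = [0.0] * nc
    for _ in range(max_iter):
        delta = 0.0
        for i in range(nr):
            m = med(Z[i])
            for j in range(nc):
                Z[i][j] -= m
            row_eff[i] += m
            delta = max(delta, abs(m))
        shift = med(row_eff)
        row_eff = [r - shift for r in row_eff]
        overall += shift
        for j in range(nc):
            m = med([Z[i][j] for i in range(nr)])
            for i in range(nr):
                Z[i][j] -= m
            col_eff[j] += m
            delta = max(delta, abs(m))
        shift = med(col_eff)
        col_eff = [c - shift for c in col_eff]
        overall += shift
        if delta < tol:
            break
    return [overall + c for c in col_eff]


def bh_stepup_oracle(pvalues):
    """Textbook step-up definition evaluated directly."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        adjusted[i] = min(1.0, running)
    return adjusted
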