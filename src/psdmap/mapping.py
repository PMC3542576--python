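"""Overlay gene expression statuses on polysaccharide structures.

Given a structure, a gene catalog and per-gene statuses (``up``, ``down``,
``ns`` or ``absent_in_other_genome``), :func:`overlay` computes which of the
structure's required enzymatic activities have at least one up-regulated
gene.  A polysaccharide whose every required activity is covered carries a
*full set* of induced degradation genes — the coordinated-induction signal
the framework is built to detect.  :func:`full_set_scan` applies the overlay
across all packaged structures, and :func:`render_map` draws an annotated
structure as Graphviz DOT (red box = up, green = down, gray = no
counterpart in the second genome, no box = not significant).

Conventions: coverage counts activities, not genes ("all of the activities
required"), so one induced isoenzyme suffices; genes sharing an
``ambiguous_probe_group`` (arrays cannot tell them apart) contribute
jointly; activities with no catalog gene are excluded from the denominator
but reported prominently as unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .activities import ActivitySpec, required_activities
from .catalog import Catalog, GeneRecord
from .digestion import digest
from .structures import (
    StructureGraph,
    list_structures,
    load_structure,
    structure_to_dot,
    _dot_quote,
)

__all__ = [
    "StatusMap",
    "ActivityCoverage",
    "CoverageReport",
    "read_status",
    "write_status",
    "overlay",
    "full_set_scan",
    "render_map",
]

_LABELS = ("up", "down", "ns", "absent_in_other_genome")


@dataclass(frozen=True)
class StatusMap:
    """Per-gene regulation labels from one comparison or cluster."""

    labels: Mapping[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = {l for l in self.labels.values() if l not in _LABELS}
        if bad:
            raise ValueError(f"unknown status labels: {sorted(bad)}")

    def get(self, *gene_ids: str) -> str:
        """Status for a gene under any of its identifiers (first hit wins)."""
        for gid in gene_ids:
            if gid and gid in self.labels:
                return self.labels[gid]
        return "ns"

    def __len__(self) -> int:
        return len(self.labels)


def read_status(path: str | Path) -> StatusMap:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"gene", "label"} <= set(df.columns):
        raise ValueError("status TSV needs columns: gene, label")
    prov = df["provenance"].iloc[0] if "provenance" in df.columns and len(df) \
        else ""
    return StatusMap(dict(zip(df["gene"], df["label"])), provenance=prov)


def write_status(status: StatusMap, path: str | Path) -> Path:
    p = Path(path)
    df = pd.DataFrame(
        {"gene": list(status.labels), "label": list(status.labels.values())}
    )
    df["provenance"] = status.provenance
    df.to_csv(p, sep="\t", index=False)
    return p


@dataclass
class ActivityCoverage:
    """One required activity with the statuses of its genes."""

    activity: ActivitySpec
    genes: list[tuple[GeneRecord, str]]  # (record, status label)
    covered: bool  # >= `require_n` genes/probe-groups labelled "up"


@dataclass
class CoverageReport:
    """Required-activity induction status for one polysaccharide."""

    structure: str
    entries: list[ActivityCoverage]
    unmapped_activities: list[ActivitySpec]  # no catalog gene
    unmapped_classes: list[str]  # bond classes with no known activity
    unknown_genes: list[str]  # statuses referencing genes outside the catalog
    coverage: float
    full_set: bool

    def covered_activity_names(self) -> list[str]:
        return [e.activity.name for e in self.entries if e.covered]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append({
                "structure": self.structure,
                "activity": e.activity.name,
                "ec": e.activity.ec,
                "covered": e.covered,
                "genes": ";".join(
                    f"{r.gene_name or r.key}:{s}" for r, s in e.genes
                ),
            })
        return pd.DataFrame(rows)


def _probe_group_covered(genes: list[tuple[GeneRecord, str]],
                         require_n: int) -> bool:
    """Count induced genes, merging ambiguous probe groups into one unit."""
    up_units: set[str] = set()
    for rec, status in genes:
        if status != "up":
            continue
        unit = (
            f"group:{rec.ambiguous_probe_group}"
            if rec.ambiguous_probe_group
            else f"gene:{rec.key}"
        )
        up_units.add(unit)
    return len(up_units) >= require_n


def overlay(
    catalog: Catalog,
    structure: StructureGraph | str,
    statuses: StatusMap,
    require_n: int = 1,
) -> CoverageReport:
    """Coverage of a structure's required activities by induced genes.

    Deterministic; every required activity appears exactly once.  Statuses
    referencing genes absent from the catalog are collected as warnings,
    not failures.
    """
    if isinstance(structure, str):
        structure = load_structure(structure)
    req = required_activities(structure)
    entries: list[ActivityCoverage] = []
    unmapped_acts: list[ActivitySpec] = []
    for act in req.activities:
        recs = catalog.for_activity(act)
        if not recs:
            unmapped_acts.append(act)
            continue
        genes = [
            (rec, statuses.get(rec.cbs_id, rec.atcc_id, rec.gene_name))
            for rec in recs
        ]
        entries.append(ActivityCoverage(
            activity=act,
            genes=genes,
            covered=_probe_group_covered(genes, require_n),
        ))
    n_req = len(entries)
    n_cov = sum(e.covered for e in entries)
    coverage = n_cov / n_req if n_req else 0.0
    unknown = sorted(g for g in statuses.labels if g not in catalog)
    return CoverageReport(
        structure=structure.name,
        entries=entries,
        unmapped_activities=unmapped_acts,
        unmapped_classes=list(req.unmapped),
        unknown_genes=unknown,
        coverage=coverage,
        full_set=bool(n_req) and n_cov == n_req,
    )


def full_set_scan(
    catalog: Catalog,
    statuses: StatusMap,
    structures: Iterable[StructureGraph | str] | None = None,
    require_n: int = 1,
) -> tuple[list[str], dict[str, CoverageReport]]:
    """Overlay every structure; return the full-set hits and all reports.

    The hit list is sorted by name; reports carry coverage fractions for
    every structure scanned (default: the sixteen packaged types).
    """
    if structures is None:
        structures = list_structures()
    reports: dict[str, CoverageReport] = {}
    for s in structures:
        rep = overlay(catalog, s, statuses, require_n=require_n)
        reports[rep.structure] = rep
    hits = sorted(name for name, rep in reports.items() if rep.full_set)
    return hits, reports


# ---------------------------------------------------------------------------
# DOT rendering

_STATUS_COLOR = {
    "up": "red",
    "down": "green",
    "absent_in_other_genome": "gray",
    "ns": "white",
}


def render_map(
    structure: StructureGraph | str,
    catalog: Catalog,
    statuses: StatusMap,
    out: str | Path,
) -> Path:
    """Write an annotated structure map as a Graphviz DOT file.

    Residues are polygons (sides = carbon count), linkages labelled edges;
    each gene becomes a box attached to a bond its activity cleaves, filled
    red/green/gray by status.  A gene present in CBS 513.88 but with no
    ATCC 1015 counterpart renders gray regardless of status.
    """
    if isinstance(structure, str):
        structure = load_structure(structure)
    base = structure_to_dot(structure).rstrip()[:-1]  # strip closing brace
    lines = [base]
    req = required_activities(structure)

    # representative anchor per class label: first matching linkage/residue
    anchors: dict[str, int] = {}
    for link in structure.linkages:
        lc = structure.link_class(link)
        anchors.setdefault(lc.label, link.child_id)
    for res in structure:
        for mc in structure.mod_classes_of(res.id):
            anchors.setdefault(mc.label, res.id)

    class_of_activity: dict[str, str] = {}
    for label, names in req.by_class:
        for name in names:
            class_of_activity.setdefault(name, label)

    box_id = 0
    for act in req.activities:
        anchor = anchors.get(class_of_activity.get(act.name, ""), None)
        for rec in catalog.for_activity(act):
            status = statuses.get(rec.cbs_id, rec.atcc_id, rec.gene_name)
            if not rec.atcc_id:
                color = _STATUS_COLOR["absent_in_other_genome"]
            else:
                color = _STATUS_COLOR.get(status, "white")
            label = rec.gene_name or rec.key
            title = f"{label}\\n{act.name}"
            lines.append(
                f"  g{box_id} [shape=box label={_dot_quote(title)} "
                f"style=filled fillcolor={color} fontsize=9];"
            )
            if anchor is not None:
                lines.append(
                    f"  g{box_id} -> r{anchor} [style=dashed arrowhead=none];"
                )
            box_id += 1
    lines.append("}")
    p = Path(out)
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return p


def check_full_set_consistency(
    structure: StructureGraph | str,
    catalog: Catalog,
    statuses: StatusMap,
) -> bool:
    """Cross-check: a full-set structure digests completely with the
    activities of its up-regulated genes."""
    if isinstance(structure, str):
        structure = load_structure(structure)
    rep = overlay(catalog, structure, statuses)
    if not rep.full_set:
        return True
    up_acts = {
        e.activity for e in rep.entries
        if any(s == "up" for _, s in e.genes)
    }
    return digest(structure, up_acts).completeness == 1.0
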