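"""Gene catalog: the gene <-> activity mapping for *Aspergillus niger*.

A :class:`Catalog` holds :class:`GeneRecord` rows read from a TSV with the
columns ``ec, name, cazy, mode, gene_name, uniprot, cbs_id, atcc_id,
characterized, refs, ambiguous_probe_group`` (plus optional free-text
``tags`` and ``note``).  Each row references an activity from the registry
in :mod:`psdmap.activities`, resolved by name (case-insensitive) with an EC
fallback when the EC is unambiguous.

Two catalogs ship with the package:

* ``soluble_ggm_genes.tsv`` — the fifteen soluble-galactoglucomannan gene
  records with their published identifiers;
* ``framework_catalog_synthetic.tsv`` — one-to-three genes per registry
  activity so that every packaged structure can be overlaid; gene names are
  the published ones where known, but sequence identifiers outside the
  fifteen records above are synthetic placeholders (the file says so).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .activities import ActivitySpec, REGISTRY, activities_by_ec, get_activity

__all__ = [
    "GeneRecord",
    "Catalog",
    "CatalogError",
    "CatalogLookupError",
    "read_catalog",
    "write_catalog",
    "load_ggm_catalog",
    "load_framework_catalog",
    "genes_for_activity",
    "activity_for_gene",
]

COLUMNS = (
    "ec", "name", "cazy", "mode", "gene_name", "uniprot", "cbs_id",
    "atcc_id", "characterized", "refs", "ambiguous_probe_group",
)
_OPTIONAL_COLUMNS = ("tags", "note")
_MISSING = {"", "n/a", "na", "-", "none"}


class CatalogError(ValueError):
    """Catalog file violates the schema or record invariants."""


class CatalogLookupError(KeyError):
    """Requested gene or activity is not in the catalog."""


def _clean(cell: str) -> str:
    cell = (cell or "").strip()
    return "" if cell.lower() in _MISSING else cell


def _parse_bool(cell: str, row: int) -> bool:
    v = _clean(cell).lower()
    if v in ("yes", "true", "1", "y"):
        return True
    if v in ("no", "false", "0", ""):
        return False
    raise CatalogError(f"row {row}: cannot parse characterized flag {cell!r}")


@dataclass(frozen=True)
class GeneRecord:
    """One gene linked to one enzymatic activity."""

    activity: ActivitySpec
    cazy_family: str = ""
    gene_name: str = ""
    uniprot: str = ""
    cbs_id: str = ""
    atcc_id: str = ""
    characterized: bool = False
    references: tuple[str, ...] = ()
    ambiguous_probe_group: str = ""
    tags: frozenset[str] = frozenset()
    note: str = ""

    def __post_init__(self) -> None:
        if not (self.cbs_id or self.atcc_id):
            raise CatalogError(
                f"gene record {self.gene_name or self.uniprot or '<anonymous>'}"
                " has neither a CBS 513.88 nor an ATCC 1015 id"
            )
        if self.characterized and not self.references:
            raise CatalogError(
                f"characterized record {self.key} lacks references"
            )

    @property
    def key(self) -> str:
        """Primary identifier: CBS id where present, else ATCC id."""
        return self.cbs_id or self.atcc_id


class Catalog:
    """Indexed collection of gene records."""

    def __init__(self, records: Iterable[GeneRecord]) -> None:
        self.records: tuple[GeneRecord, ...] = tuple(records)
        self._by_activity: dict[str, list[GeneRecord]] = {}
        self._by_id: dict[str, GeneRecord] = {}
        seen_cbs: dict[str, int] = {}
        seen_atcc: dict[str, int] = {}
        dups: list[str] = []
        for i, rec in enumerate(self.records):
            self._by_activity.setdefault(rec.activity.name, []).append(rec)
            if rec.cbs_id:
                if rec.cbs_id in seen_cbs:
                    dups.append(
                        f"cbs_id {rec.cbs_id} in rows "
                        f"{seen_cbs[rec.cbs_id]} and {i}"
                    )
                seen_cbs[rec.cbs_id] = i
            if rec.atcc_id:
                if rec.atcc_id in seen_atcc:
                    dups.append(
                        f"atcc_id {rec.atcc_id} in rows "
                        f"{seen_atcc[rec.atcc_id]} and {i}"
                    )
                seen_atcc[rec.atcc_id] = i
            for ident in filter(None, (rec.cbs_id, rec.atcc_id,
                                       rec.gene_name)):
                self._by_id.setdefault(ident, rec)
        if dups:
            raise CatalogError("duplicate gene ids: " + "; ".join(dups))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    @property
    def activities(self) -> list[ActivitySpec]:
        return sorted(
            {r.activity.name: r.activity for r in self.records}.values(),
            key=lambda a: a.name,
        )

    @property
    def ecs(self) -> frozenset[str]:
        return frozenset(r.activity.ec for r in self.records if r.activity.ec)

    def lookup(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise CatalogLookupError(
                f"gene id {gene_id!r} not in catalog"
            ) from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def for_activity(self, activity: ActivitySpec | str) -> list[GeneRecord]:
        name = activity.name if isinstance(activity, ActivitySpec) else activity
        return list(self._by_activity.get(name, []))


# ---------------------------------------------------------------------------
# TSV I/O


def _resolve_activity(ec: str, name: str, mode: str, row: int) -> ActivitySpec:
    if name and name.strip().lower() in REGISTRY:
        act = REGISTRY[name.strip().lower()]
    elif ec:
        hits = activities_by_ec(ec)
        if len(hits) != 1:
            raise CatalogError(
                f"row {row}: cannot resolve activity (name {name!r}, "
                f"EC {ec!r} matches {len(hits)} registry activities)"
            )
        act = hits[0]
    else:
        raise CatalogError(f"row {row}: record has neither name nor EC")
    if mode and act.mode != mode:
        raise CatalogError(
            f"row {row}: mode {mode!r} disagrees with registry mode "
            f"{act.mode!r} for {act.name}"
        )
    if ec and act.ec and ec != act.ec:
        raise CatalogError(
            f"row {row}: EC {ec} disagrees with registry EC {act.ec} "
            f"for {act.name}"
        )
    return act


def read_catalog(path: str | Path | io.TextIOBase) -> Catalog:
    """Read a catalog TSV.  Empty/``N/A`` cells become empty fields."""
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [l for l in text.splitlines() if l.strip() and
             not l.lstrip().startswith("#")]
    if not lines:
        raise CatalogError("empty catalog file (no header)")
    reader = csv.DictReader(lines, delimiter="\t")
    header = tuple(reader.fieldnames or ())
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise CatalogError(f"missing mandatory columns: {', '.join(missing)}")
    records = []
    for i, row in enumerate(reader, start=2):
        act = _resolve_activity(
            _clean(row["ec"]), _clean(row["name"]), _clean(row["mode"]), i
        )
        refs = tuple(
            r.strip() for r in _clean(row["refs"]).split(";") if r.strip()
        )
        tags = frozenset(
            t.strip() for t in _clean(row.get("tags", "")).split(";")
            if t.strip()
        )
        records.append(
            GeneRecord(
                activity=act,
                cazy_family=_clean(row["cazy"]),
                gene_name=_clean(row["gene_name"]),
                uniprot=_clean(row["uniprot"]),
                cbs_id=_clean(row["cbs_id"]),
                atcc_id=_clean(row["atcc_id"]),
                characterized=_parse_bool(row["characterized"], i),
                references=refs,
                ambiguous_probe_group=_clean(row["ambiguous_probe_group"]),
                tags=tags,
                note=_clean(row.get("note", "")),
            )
        )
    return Catalog(records)


def write_catalog(catalog: Catalog, path: str | Path) -> Path:
    """Write the canonical TSV form; read -> write -> read is stable."""
    p = Path(path)
    with p.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS + _OPTIONAL_COLUMNS)
        for rec in catalog:
            writer.writerow([
                rec.activity.ec,
                rec.activity.name,
                rec.cazy_family,
                rec.activity.mode,
                rec.gene_name,
                rec.uniprot,
                rec.cbs_id,
                rec.atcc_id,
                "yes" if rec.characterized else "no",
                ";".join(rec.references),
                rec.ambiguous_probe_group,
                ";".join(sorted(rec.tags)),
                rec.note,
            ])
    return p


def _packaged(name: str) -> Catalog:
    text = resources.files("psdmap").joinpath("data", name).read_text(
        encoding="utf-8"
    )
    return read_catalog(io.StringIO(text))


def load_ggm_catalog() -> Catalog:
    """The fifteen published soluble-galactoglucomannan gene records."""
    return _packaged("soluble_ggm_genes.tsv")


def load_framework_catalog() -> Catalog:
    """Framework-wide catalog covering every registry activity.

    Identifiers outside the fifteen published records are synthetic
    placeholders; see the file header.
    """
    return _packaged("framework_catalog_synthetic.tsv")


# ---------------------------------------------------------------------------
# module-level lookups (inverse-consistent by construction)


def genes_for_activity(
    catalog: Catalog, activity: ActivitySpec | str
) -> list[GeneRecord]:
    """All gene records carrying an activity; error if the activity is
    unknown to the registry."""
    name = activity.name if isinstance(activity, ActivitySpec) else activity
    get_activity(name)  # raises KeyError for unknown activities
    return catalog.for_activity(name)


def activity_for_gene(catalog: Catalog, gene_id: str) -> ActivitySpec:
    """The activity of a gene, addressed by CBS id, ATCC id or gene name."""
    return catalog.lookup(gene_id).activity
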