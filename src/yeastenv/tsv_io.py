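"""Flat TSV dialect for ontologies: hand-editable counterpart of the OWL subset.

Three UTF-8 tab-separated files share a stem.  For ``<stem>.tsv`` (the
assignments file) the class table lives at ``<stem>.classes.tsv`` and the
property table at ``<stem>.properties.tsv``:

``<stem>.classes.tsv``    columns ``class_id  label  parent_id  description``
                          (``parent_id`` empty for roots; file order fixes
                          root order)
``<stem>.properties.tsv`` columns ``property_id  label  kind``
``<stem>.tsv``            columns ``strain_id  species  order
                          direct_classes  relations  isolation_text``

Multi-valued cells use ``|`` as separator; a relation triple is encoded
``property_id->target_class_id``.  Round trips are lossless against the
OWL representation.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .ontology import (
    ClassNode,
    EcologyOntology,
    PropertyDef,
    RelationAssertion,
    StrainInstance,
    ValidationError,
)

__all__ = ["read_assignments_tsv", "write_assignments_tsv", "companion_paths"]

_ASSIGN_COLS = ["strain_id", "species", "order", "direct_classes", "relations", "isolation_text"]
_CLASS_COLS = ["class_id", "label", "parent_id", "description"]
_PROP_COLS = ["property_id", "label", "kind"]


def companion_paths(path) -> tuple[Path, Path, Path]:
    """(assignments, classes, properties) paths for a given assignments path."""
    p = Path(path)
    stem = p.with_suffix("")
    return p, Path(f"{stem}.classes.tsv"), Path(f"{stem}.properties.tsv")


def _read_rows(path: Path, expected: list[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, header {expected} required")
        if header != expected:
            raise ValidationError(f"{path}: header must be {expected}, got {header}")
        rows = []
        for i, raw in enumerate(reader, start=2):
            if not raw or all(not c for c in raw):
                continue
            if len(raw) != len(expected):
                raise ValidationError(
                    f"{path} row {i}: expected {len(expected)} columns, got {len(raw)}"
                )
            rows.append(dict(zip(expected, raw)))
    return rows


def _split_multi(cell: str) -> list[str]:
    return [v for v in (s.strip() for s in cell.split("|")) if v]


def read_assignments_tsv(path) -> EcologyOntology:
    """Read the three-file TSV dialect rooted at the assignments ``path``."""
    apath, cpath, ppath = companion_paths(path)
    classes: list[ClassNode] = []
    roots: list[str] = []
    for row in _read_rows(cpath, _CLASS_COLS):
        parent = row["parent_id"].strip() or None
        node = ClassNode(
            id=row["class_id"],
            label=row["label"],
            parent_id=parent,
            description=row["description"],
        )
        classes.append(node)
        if parent is None:
            roots.append(node.id)

    properties = [
        PropertyDef(id=row["property_id"], label=row["label"], kind=row["kind"])
        for row in _read_rows(ppath, _PROP_COLS)
    ]

    class_ids = {c.id for c in classes}
    prop_ids = {p.id for p in properties}
    instances: list[StrainInstance] = []
    seen: set[str] = set()
    for i, row in enumerate(_read_rows(apath, _ASSIGN_COLS), start=2):
        sid = row["strain_id"].strip()
        if sid in seen:
            raise ValidationError(f"{apath} row {i}: duplicate strain id {sid!r}")
        seen.add(sid)
        direct = _split_multi(row["direct_classes"])
        for c in direct:
            if c not in class_ids:
                raise ValidationError(
                    f"{apath} row {i}: unknown class id {c!r} for strain {sid!r}"
                )
        relations = []
        for triple in _split_multi(row["relations"]):
            if "->" not in triple:
                raise ValidationError(
                    f"{apath} row {i}: malformed relation triple {triple!r} "
                    "(expected 'property_id->target_class_id')"
                )
            prop, _, target = triple.partition("->")
            prop, target = prop.strip(), target.strip()
            if prop not in prop_ids:
                raise ValidationError(
                    f"{apath} row {i}: unknown property id {prop!r}"
                )
            if target not in class_ids:
                raise ValidationError(
                    f"{apath} row {i}: unknown relation target {target!r}"
                )
            relations.append(RelationAssertion(property_id=prop, target_class_id=target))
        instances.append(
            StrainInstance(
                id=sid,
                species=row["species"],
                order=row["order"],
                direct_class_ids=frozenset(direct),
                relations=tuple(relations),
                isolation_text=row["isolation_text"],
            )
        )

    return EcologyOntology(
        classes=classes, properties=properties, instances=instances, roots=roots
    )


def write_assignments_tsv(ontology: EcologyOntology, path) -> None:
    """Write the ontology as the three-file TSV dialect (lossless round trip)."""
    apath, cpath, ppath = companion_paths(path)

    def _writer(fh):
        return csv.writer(fh, delimiter="\t", lineterminator="\n")

    with open(cpath, "w", newline="", encoding="utf-8") as fh:
        w = _writer(fh)
        w.writerow(_CLASS_COLS)
        # roots first in declared order, then the rest sorted, so root order
        # survives the round trip
        rest = sorted(c for c in ontology.classes if c not in ontology.roots)
        for cid in [*ontology.roots, *rest]:
            node = ontology.classes[cid]
            w.writerow([node.id, node.label, node.parent_id or "", node.description])

    with open(ppath, "w", newline="", encoding="utf-8") as fh:
        w = _writer(fh)
        w.writerow(_PROP_COLS)
        for pid in sorted(ontology.properties):
            prop = ontology.properties[pid]
            w.writerow([prop.id, prop.label, prop.kind])

    with open(apath, "w", newline="", encoding="utf-8") as fh:
        w = _writer(fh)
        w.writerow(_ASSIGN_COLS)
        for sid in sorted(ontology.instances):
            s = ontology.instances[sid]
            rels = "|".join(
                f"{r.property_id}->{r.target_class_id}"
                for r in sorted(s.relations, key=lambda r: (r.property_id, r.target_class_id))
            )
            w.writerow(
                [
                    s.id,
                    s.species,
                    s.order,
                    "|".join(sorted(s.direct_class_ids)),
                    rels,
                    s.isolation_text,
                ]
            )
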