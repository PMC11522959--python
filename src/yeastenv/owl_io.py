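"""OWL (RDF/XML) subset reader and writer for ecology ontologies.

The dialect covers exactly what the data model needs: ``owl:Class``
declarations with a single ``rdfs:subClassOf`` per non-root class,
``owl:ObjectProperty`` declarations annotated with their kind
(relational vs modifier), and ``owl:NamedIndividual`` strains typed with
their direct classes and linked to secondary environments through object
properties.  Constructs outside the subset (restrictions, equivalence
axioms, multiple inheritance) are surfaced, never silently dropped:
multiple inheritance is a hard error, other unknown constructs are
collected as warnings on the returned report.
"""

from __future__ import annotations

import warnings
from urllib.parse import quote, unquote

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL

from .ontology import (
    ClassNode,
    EcologyOntology,
    PropertyDef,
    RelationAssertion,
    StrainInstance,
    ValidationError,
)

__all__ = ["parse_owl", "write_owl", "OwlFormatError", "OwlParseWarning"]

BASE = "http://yeast-environments.org/ontology#"
YE = Namespace(BASE)

_CLASS_NS = Namespace(BASE + "class/")
_PROP_NS = Namespace(BASE + "property/")
_STRAIN_NS = Namespace(BASE + "strain/")

_ONT_NODE = URIRef(BASE + "ontology")

# annotation properties of the dialect
_KIND = YE["propertyKind"]
_ROOT_ORDER = YE["rootOrder"]
_SPECIES = YE["species"]
_ORDER = YE["taxonOrder"]
_ISOLATION = YE["isolationText"]


class OwlFormatError(ValidationError):
    """The file is not parseable as the supported RDF/XML subset."""


class OwlParseWarning(UserWarning):
    """A construct outside the supported OWL subset was encountered."""


def _iri(ns: Namespace, local: str) -> URIRef:
    return ns[quote(local, safe="")]


def _local(ns: Namespace, iri: URIRef) -> str:
    return unquote(str(iri)[len(str(ns)) :])


def _in_ns(ns: Namespace, node) -> bool:
    return isinstance(node, URIRef) and str(node).startswith(str(ns))


def write_owl(ontology: EcologyOntology, path) -> None:
    """Serialise ``ontology`` as RDF/XML.

    The triple set is built in sorted order so two writes of equal
    ontologies produce identical bytes.
    """
    g = Graph()
    g.bind("owl", OWL)
    g.bind("ye", YE)
    g.add((_ONT_NODE, RDF.type, OWL.Ontology))
    g.add((_ONT_NODE, _ROOT_ORDER, Literal("|".join(ontology.roots))))

    for cid in sorted(ontology.classes):
        node = ontology.classes[cid]
        iri = _iri(_CLASS_NS, cid)
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, Literal(node.label)))
        if node.parent_id is not None:
            g.add((iri, RDFS.subClassOf, _iri(_CLASS_NS, node.parent_id)))
        if node.description:
            g.add((iri, RDFS.comment, Literal(node.description)))

    for pid in sorted(ontology.properties):
        prop = ontology.properties[pid]
        iri = _iri(_PROP_NS, pid)
        g.add((iri, RDF.type, OWL.ObjectProperty))
        g.add((iri, RDFS.label, Literal(prop.label)))
        g.add((iri, _KIND, Literal(prop.kind)))

    for sid in sorted(ontology.instances):
        strain = ontology.instances[sid]
        iri = _iri(_STRAIN_NS, sid)
        g.add((iri, RDF.type, OWL.NamedIndividual))
        for cid in sorted(strain.direct_class_ids):
            g.add((iri, RDF.type, _iri(_CLASS_NS, cid)))
        if strain.species:
            g.add((iri, _SPECIES, Literal(strain.species)))
        if strain.order:
            g.add((iri, _ORDER, Literal(strain.order)))
        if strain.isolation_text:
            g.add((iri, _ISOLATION, Literal(strain.isolation_text)))
        for rel in sorted(
            strain.relations, key=lambda r: (r.property_id, r.target_class_id)
        ):
            g.add(
                (iri, _iri(_PROP_NS, rel.property_id), _iri(_CLASS_NS, rel.target_class_id))
            )

    data = g.serialize(format="xml", encoding="utf-8")
    with open(path, "wb") as fh:
        fh.write(data)


def parse_owl(path) -> EcologyOntology:
    """Parse an RDF/XML ontology file into an :class:`EcologyOntology`.

    Raises
    ------
    OwlFormatError
        If the file is not RDF/XML.
    ValidationError
        If a class declares more than one named superclass, or a
        reference does not resolve.

    Warns with :class:`OwlParseWarning` on constructs outside the subset
    (``owl:Restriction`` superclasses, equivalence axioms, unrecognised
    typed nodes).
    """
    g = Graph()
    try:
        g.parse(str(path), format="xml")
    except Exception as exc:  # rdflib raises many concrete types here
        raise OwlFormatError(f"cannot parse {path} as RDF/XML: {exc}") from exc

    unknown: list[str] = []

    class_iris = set(g.subjects(RDF.type, OWL.Class))
    classes: dict[str, ClassNode] = {}
    for iri in class_iris:
        if isinstance(iri, BNode):
            unknown.append("anonymous class (blank node) skipped")
            continue
        cid = _local(_CLASS_NS, iri) if _in_ns(_CLASS_NS, iri) else str(iri)
        parents = []
        for sup in g.objects(iri, RDFS.subClassOf):
            if isinstance(sup, BNode) or (sup, RDF.type, OWL.Restriction) in g:
                unknown.append(f"restriction superclass on class {cid!r} ignored")
                continue
            parents.append(sup)
        if len(parents) > 1:
            names = sorted(_local(_CLASS_NS, p) for p in parents)
            raise ValidationError(
                f"class {cid!r} has multiple parents {names}; the class graph "
                "must be a forest (single inheritance)"
            )
        parent_id = None
        if parents:
            p = parents[0]
            if p not in class_iris:
                raise ValidationError(
                    f"class {cid!r}: parent {p} is not a declared class"
                )
            parent_id = _local(_CLASS_NS, p) if _in_ns(_CLASS_NS, p) else str(p)
        label = g.value(iri, RDFS.label)
        comment = g.value(iri, RDFS.comment)
        classes[cid] = ClassNode(
            id=cid,
            label=str(label) if label else cid,
            parent_id=parent_id,
            description=str(comment) if comment else "",
        )

    for s, o in g.subject_objects(OWL.equivalentClass):
        unknown.append(f"owl:equivalentClass axiom on {s} ignored")

    properties: dict[str, PropertyDef] = {}
    prop_iris = set(g.subjects(RDF.type, OWL.ObjectProperty))
    for iri in prop_iris:
        pid = _local(_PROP_NS, iri) if _in_ns(_PROP_NS, iri) else str(iri)
        label = g.value(iri, RDFS.label)
        kind = g.value(iri, _KIND)
        properties[pid] = PropertyDef(
            id=pid,
            label=str(label) if label else pid,
            kind=str(kind) if kind else "relational",
        )

    instances: dict[str, StrainInstance] = {}
    for iri in g.subjects(RDF.type, OWL.NamedIndividual):
        sid = _local(_STRAIN_NS, iri) if _in_ns(_STRAIN_NS, iri) else str(iri)
        direct: set[str] = set()
        for t in g.objects(iri, RDF.type):
            if t == OWL.NamedIndividual:
                continue
            if t in class_iris:
                direct.add(_local(_CLASS_NS, t) if _in_ns(_CLASS_NS, t) else str(t))
            else:
                unknown.append(f"individual {sid!r}: unrecognised type {t} ignored")
        relations = []
        for p, o in g.predicate_objects(iri):
            if p in prop_iris:
                if o not in class_iris:
                    raise ValidationError(
                        f"strain {sid!r}: relation {p} targets {o}, which is "
                        "not a declared class"
                    )
                relations.append(
                    RelationAssertion(
                        property_id=_local(_PROP_NS, p) if _in_ns(_PROP_NS, p) else str(p),
                        target_class_id=_local(_CLASS_NS, o)
                        if _in_ns(_CLASS_NS, o)
                        else str(o),
                    )
                )
        relations.sort(key=lambda r: (r.property_id, r.target_class_id))
        species = g.value(iri, _SPECIES)
        order = g.value(iri, _ORDER)
        iso = g.value(iri, _ISOLATION)
        instances[sid] = StrainInstance(
            id=sid,
            species=str(species) if species else "",
            order=str(order) if order else "",
            direct_class_ids=frozenset(direct),
            relations=tuple(relations),
            isolation_text=str(iso) if iso else "",
        )

    root_order = g.value(_ONT_NODE, _ROOT_ORDER)
    if root_order is not None and str(root_order):
        roots = [r for r in str(root_order).split("|") if r]
    else:
        roots = sorted(c.id for c in classes.values() if c.parent_id is None)

    for msg in unknown:
        warnings.warn(msg, OwlParseWarning, stacklevel=2)

    return EcologyOntology(
        classes=sorted(classes.values(), key=lambda c: c.id),
        properties=sorted(properties.values(), key=lambda p: p.id),
        instances=sorted(instances.values(), key=lambda s: s.id),
        roots=roots,
    )
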