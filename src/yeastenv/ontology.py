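"""Core data model and query engine for isolation-environment ontologies.

An :class:`EcologyOntology` holds a forest of environment classes (each
non-root class is a subclass of exactly one parent), typed object
properties (relational links between environments, and modifier
annotations such as microbe association), and strain instances.  A strain
is assigned to the *most specific* class(es) describing the substrate it
was isolated from — its *direct* classes — and memberships in ancestor
classes are always derived by transitive closure, never materialised.

The six canonical top-level categories for yeast isolation environments
are animal, plant, environmental, fungal, industrial products, and
victuals; they are the default roots but any forest is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_ROOTS",
    "ClassNode",
    "PropertyDef",
    "RelationAssertion",
    "StrainInstance",
    "ClassTask",
    "EcologyOntology",
    "OntologyError",
    "ValidationError",
    "UnknownIdError",
    "ancestors",
    "members",
    "relational_members",
    "class_size_query",
    "order_distribution",
    "build_labels",
]

#: Canonical exclusive top-level isolation-environment categories.
DEFAULT_ROOTS = (
    "animal",
    "plant",
    "environmental",
    "fungal",
    "industrial products",
    "victuals",
)

RELATIONAL = "relational"
MODIFIER = "modifier"

#: Wildcard accepted in :class:`ClassTask` relational terms in place of a
#: property id, meaning "any relational or modifier property".
ANY_PROPERTY = "*"


class OntologyError(Exception):
    """Base class for ontology model errors."""


class ValidationError(OntologyError):
    """An ontology invariant is violated (cycle, multi-parent, dangling id...)."""


class UnknownIdError(OntologyError, KeyError):
    """A class, property or strain id does not resolve in the ontology."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


def _norm_id(raw: str) -> str:
    """Identifier normalisation: whitespace-trimmed, case-sensitive."""
    s = str(raw).strip()
    if not s:
        raise ValidationError("empty identifier")
    return s


@dataclass
class ClassNode:
    """One environment class: a node in the subclass forest.

    ``parent_id`` is ``None`` only for roots.  Labels may repeat across
    classes; ids may not.
    """

    id: str
    label: str = ""
    parent_id: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.id = _norm_id(self.id)
        if self.parent_id is not None:
            self.parent_id = _norm_id(self.parent_id)
        if not self.label:
            self.label = self.id


@dataclass
class PropertyDef:
    """A typed object property.

    ``kind`` is ``"relational"`` (links a strain's primary environment to a
    secondary one, e.g. *is from animal on plant*) or ``"modifier"``
    (annotates a feature of the environment, e.g. *has microbe
    association*).
    """

    id: str
    label: str = ""
    kind: str = RELATIONAL

    def __post_init__(self) -> None:
        self.id = _norm_id(self.id)
        # property ids become RDF/XML predicates, which must be XML names;
        # the human-readable form belongs in the label
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.-]*", self.id):
            raise ValidationError(
                f"property id {self.id!r} must be an XML-name-safe slug "
                "(letters, digits, '_', '-', '.'; not starting with a digit)"
            )
        if not self.label:
            self.label = self.id
        if self.kind not in (RELATIONAL, MODIFIER):
            raise ValidationError(
                f"property {self.id!r}: kind must be {RELATIONAL!r} or "
                f"{MODIFIER!r}, got {self.kind!r}"
            )


@dataclass(frozen=True)
class RelationAssertion:
    """A strain-level assertion ``property(strain, target_class)``."""

    property_id: str
    target_class_id: str


@dataclass
class StrainInstance:
    """One yeast strain with its direct classes and relational assertions."""

    id: str
    species: str = ""
    order: str = ""
    direct_class_ids: frozenset[str] = field(default_factory=frozenset)
    relations: tuple[RelationAssertion, ...] = ()
    isolation_text: str = ""

    def __post_init__(self) -> None:
        self.id = _norm_id(self.id)
        self.direct_class_ids = frozenset(_norm_id(c) for c in self.direct_class_ids)
        # canonical order so in-memory and round-tripped instances compare equal
        self.relations = tuple(
            sorted(self.relations, key=lambda r: (r.property_id, r.target_class_id))
        )
        if not self.direct_class_ids:
            raise ValidationError(f"strain {self.id!r}: at least one direct class required")


@dataclass
class ClassTask:
    """A binary labelling task over the ontology.

    A strain is positive iff it is a (closure) member of any include class
    or matches any include relational term, and matches no exclude term.
    Relational terms are ``(property_id, target_class_id)`` pairs;
    ``property_id`` may be the wildcard ``"*"``.
    """

    name: str
    include_class_ids: frozenset[str] = field(default_factory=frozenset)
    include_relational: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    exclude_class_ids: frozenset[str] = field(default_factory=frozenset)
    exclude_relational: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.include_class_ids = frozenset(self.include_class_ids)
        self.include_relational = frozenset(tuple(t) for t in self.include_relational)
        self.exclude_class_ids = frozenset(self.exclude_class_ids)
        self.exclude_relational = frozenset(tuple(t) for t in self.exclude_relational)
        if not (self.include_class_ids or self.include_relational):
            raise ValidationError(f"task {self.name!r}: include sets are empty")


class EcologyOntology:
    """The class forest, property definitions, and strain instances.

    Parameters
    ----------
    classes, properties, instances
        Iterables of :class:`ClassNode`, :class:`PropertyDef`,
        :class:`StrainInstance`.
    roots
        Optional explicit ordering of root class ids.  Defaults to the
        parentless classes in insertion order.
    """

    def __init__(
        self,
        classes: Iterable[ClassNode] = (),
        properties: Iterable[PropertyDef] = (),
        instances: Iterable[StrainInstance] = (),
        roots: Sequence[str] | None = None,
    ) -> None:
        self.classes: dict[str, ClassNode] = {}
        self.properties: dict[str, PropertyDef] = {}
        self.instances: dict[str, StrainInstance] = {}
        for c in classes:
            if c.id in self.classes:
                raise ValidationError(f"duplicate class id {c.id!r}")
            self.classes[c.id] = c
        for p in properties:
            if p.id in self.properties:
                raise ValidationError(f"duplicate property id {p.id!r}")
            self.properties[p.id] = p
        for s in instances:
            if s.id in self.instances:
                raise ValidationError(f"duplicate strain id {s.id!r}")
            self.instances[s.id] = s
        parentless = [c.id for c in self.classes.values() if c.parent_id is None]
        if roots is None:
            self.roots: list[str] = parentless
        else:
            self.roots = [_norm_id(r) for r in roots]
            if set(self.roots) != set(parentless):
                raise ValidationError(
                    f"declared roots {sorted(self.roots)} do not match parentless "
                    f"classes {sorted(parentless)}"
                )
        self._children: dict[str, list[str]] = {}
        self._rebuild_index()
        self.validate()

    # ------------------------------------------------------------------ #
    # structure maintenance

    def _rebuild_index(self) -> None:
        self._children = {cid: [] for cid in self.classes}
        for c in self.classes.values():
            if c.parent_id is not None:
                if c.parent_id not in self.classes:
                    raise ValidationError(
                        f"class {c.id!r}: parent {c.parent_id!r} not in ontology"
                    )
                self._children[c.parent_id].append(c.id)
        for kids in self._children.values():
            kids.sort()

    def validate(self) -> None:
        """Check all structural invariants; raise :class:`ValidationError`."""
        # acyclicity: walk to a root from every class, bounded by class count
        limit = len(self.classes)
        for cid in self.classes:
            seen = set()
            cur: str | None = cid
            for _ in range(limit + 1):
                if cur is None:
                    break
                if cur in seen:
                    raise ValidationError(f"cycle in parent links at class {cur!r}")
                seen.add(cur)
                cur = self.classes[cur].parent_id
            else:
                raise ValidationError(f"parent chain from {cid!r} does not terminate")
        for strain in self.instances.values():
            for c in strain.direct_class_ids:
                if c not in self.classes:
                    raise ValidationError(
                        f"strain {strain.id!r}: direct class {c!r} not in ontology"
                    )
            for rel in strain.relations:
                if rel.property_id not in self.properties:
                    raise ValidationError(
                        f"strain {strain.id!r}: unknown property {rel.property_id!r}"
                    )
                if rel.target_class_id not in self.classes:
                    raise ValidationError(
                        f"strain {strain.id!r}: unknown relation target "
                        f"{rel.target_class_id!r}"
                    )
            self._check_direct_set(strain)

    def _check_direct_set(self, strain: StrainInstance) -> None:
        """A strain has one direct set of classes: all on a single
        root-to-leaf path, or co-asserted leaves of one description."""
        ids = sorted(strain.direct_class_ids)
        if len(ids) == 1:
            return
        if all(not self._children[c] for c in ids):
            return  # co-asserted leaves
        # otherwise require pairwise ancestor/descendant comparability
        chains = {c: set(self.ancestors(c)) | {c} for c in ids}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if a not in chains[b] and b not in chains[a]:
                    raise ValidationError(
                        f"strain {strain.id!r}: direct classes {a!r} and {b!r} "
                        "are neither on one root-to-leaf path nor both leaves"
                    )

    def add_class(self, node: ClassNode) -> None:
        if node.id in self.classes:
            raise ValidationError(f"duplicate class id {node.id!r}")
        self.classes[node.id] = node
        if node.parent_id is None:
            self.roots.append(node.id)
        self._rebuild_index()

    def add_instance(self, strain: StrainInstance) -> None:
        if strain.id in self.instances:
            raise ValidationError(f"duplicate strain id {strain.id!r}")
        self.instances[strain.id] = strain

    # ------------------------------------------------------------------ #
    # resolution helpers

    def _require_class(self, class_id: str) -> str:
        if class_id not in self.classes:
            raise UnknownIdError(f"unknown class id {class_id!r}")
        return class_id

    def _require_property(self, property_id: str) -> str:
        if property_id not in self.properties:
            raise UnknownIdError(f"unknown property id {property_id!r}")
        return property_id

    def children(self, class_id: str) -> list[str]:
        self._require_class(class_id)
        return list(self._children[class_id])

    def leaves(self, under: str | None = None) -> list[str]:
        """Class ids with no subclasses, optionally restricted to a subtree."""
        pool = self.subtree(under) if under is not None else set(self.classes)
        return sorted(c for c in pool if not self._children[c])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EcologyOntology):
            return NotImplemented
        return (
            self.classes == other.classes
            and self.properties == other.properties
            and self.instances == other.instances
            and self.roots == other.roots
        )

    def __repr__(self) -> str:
        return (
            f"EcologyOntology({len(self.classes)} classes, "
            f"{len(self.properties)} properties, {len(self.instances)} instances)"
        )

    # ------------------------------------------------------------------ #
    # queries

    def ancestors(self, class_id: str) -> list[str]:
        """Proper ancestors of ``class_id``, root first.

        Empty for roots.  The query class itself is excluded.
        """
        self._require_class(class_id)
        chain: list[str] = []
        cur = self.classes[class_id].parent_id
        while cur is not None:
            chain.append(cur)
            cur = self.classes[cur].parent_id
        chain.reverse()
        return chain

    def root_of(self, class_id: str) -> str:
        """The root of the tree containing ``class_id``."""
        anc = self.ancestors(class_id)
        return anc[0] if anc else class_id

    def depth(self, class_id: str) -> int:
        return len(self.ancestors(class_id))

    def subtree(self, class_id: str) -> set[str]:
        """``class_id`` plus all of its descendants."""
        self._require_class(class_id)
        out: set[str] = set()
        stack = [class_id]
        while stack:
            c = stack.pop()
            out.add(c)
            stack.extend(self._children[c])
        return out

    def members(self, class_id: str) -> set[str]:
        """Strains whose direct classes fall in the closure of ``class_id``.

        A strain is a member iff some direct class equals ``class_id`` or is
        a descendant of it; membership is therefore monotone up the tree
        and non-exclusive (a strain directly on *Angiosperm* is a member of
        both *Angiosperm* and *Plant*).
        """
        sub = self.subtree(class_id)
        return {s.id for s in self.instances.values() if s.direct_class_ids & sub}

    def relational_members(
        self, target_class_id: str, property_id: str | None = None
    ) -> set[str]:
        """Strains connected to ``target_class_id`` (or a descendant) by a
        relational/modifier assertion, optionally restricted to one
        property."""
        sub = self.subtree(target_class_id)
        if property_id is not None:
            self._require_property(property_id)
        out: set[str] = set()
        for s in self.instances.values():
            for rel in s.relations:
                if property_id is not None and rel.property_id != property_id:
                    continue
                if rel.target_class_id in sub:
                    out.add(s.id)
                    break
        return out

    def class_size_query(
        self, min_count: int, max_count: int
    ) -> list[tuple[str, int]]:
        """All classes whose closure membership count lies in
        ``[min_count, max_count]`` (inclusive), sorted by id."""
        if min_count > max_count:
            raise ValueError(f"min_count {min_count} > max_count {max_count}")
        out = []
        for cid in sorted(self.classes):
            n = len(self.members(cid))
            if min_count <= n <= max_count:
                out.append((cid, n))
        return out

    def order_distribution(
        self,
        category_class_ids: Sequence[str],
        use_modifiers: bool = False,
        exclusive: bool = True,
    ) -> list[tuple[str, str, int, int, float]]:
        """Distribution of taxonomic orders over environment categories.

        Returns rows ``(order, category, numerator, denominator, fraction)``.

        In exclusive mode each strain is counted at most once, via the root
        category of its direct classes, and the denominator is the number
        of strains of that order falling in *any* of the given categories.
        In non-exclusive mode closure membership is used, the denominator
        is the full order size, and with ``use_modifiers`` additional
        ``"<category> (modifier)"`` rows count relational membership.
        """
        cats = [self._require_class(c) for c in category_class_ids]
        orders = sorted({s.order for s in self.instances.values()})
        by_order: dict[str, list[StrainInstance]] = {o: [] for o in orders}
        for s in self.instances.values():
            by_order[s.order].append(s)
        rows: list[tuple[str, str, int, int, float]] = []
        if exclusive:
            closures = {c: self.subtree(c) for c in cats}
            for a, ca in closures.items():
                for b, cb in closures.items():
                    if a < b and (ca & cb):
                        raise ValidationError(
                            f"exclusive categories {a!r} and {b!r} overlap"
                        )

            def cat_of(s: StrainInstance) -> str | None:
                for c in cats:
                    if s.direct_class_ids & closures[c]:
                        return c
                return None

            for o in orders:
                assigned = [cat_of(s) for s in by_order[o]]
                denom = sum(a is not None for a in assigned)
                for c in cats:
                    num = sum(a == c for a in assigned)
                    frac = num / denom if denom else 0.0
                    rows.append((o, c, num, denom, frac))
        else:
            for o in orders:
                ids = {s.id for s in by_order[o]}
                denom = len(ids)
                for c in cats:
                    num = len(self.members(c) & ids)
                    rows.append((o, c, num, denom, num / denom if denom else 0.0))
                    if use_modifiers:
                        num_m = len(self.relational_members(c) & ids)
                        rows.append(
                            (
                                o,
                                f"{c} (modifier)",
                                num_m,
                                denom,
                                num_m / denom if denom else 0.0,
                            )
                        )
        return rows

    # ------------------------------------------------------------------ #
    # labelling

    def _task_positive_set(self, task: ClassTask) -> set[str]:
        def resolve_rel(term: tuple[str, str]) -> set[str]:
            prop, target = term
            self._require_class(target)
            if prop == ANY_PROPERTY:
                return self.relational_members(target)
            return self.relational_members(target, self._require_property(prop))

        included: set[str] = set()
        for c in task.include_class_ids:
            included |= self.members(self._require_class(c))
        for term in task.include_relational:
            included |= resolve_rel(term)
        for c in task.exclude_class_ids:
            included -= self.members(self._require_class(c))
        for term in task.exclude_relational:
            included -= resolve_rel(term)
        return included

    def build_labels(
        self, task: ClassTask, strain_order: Sequence[str]
    ) -> np.ndarray:
        """Binary label vector for ``task`` aligned to ``strain_order``.

        ``strain_order`` must cover every instance exactly once.
        """
        if len(set(strain_order)) != len(strain_order):
            raise ValidationError("strain_order contains duplicates")
        if set(strain_order) != set(self.instances):
            missing = set(self.instances) - set(strain_order)
            extra = set(strain_order) - set(self.instances)
            raise ValidationError(
                f"strain_order must cover all instances exactly once "
                f"(missing {sorted(missing)[:5]}, unknown {sorted(extra)[:5]})"
            )
        pos = self._task_positive_set(task)
        return np.array([1 if s in pos else 0 for s in strain_order], dtype=np.int64)


# ---------------------------------------------------------------------- #
# functional façade


def ancestors(ontology: EcologyOntology, class_id: str) -> list[str]:
    return ontology.ancestors(class_id)


def members(ontology: EcologyOntology, class_id: str) -> set[str]:
    return ontology.members(class_id)


def relational_members(
    ontology: EcologyOntology, target_class_id: str, property_id: str | None = None
) -> set[str]:
    return ontology.relational_members(target_class_id, property_id)


def class_size_query(
    ontology: EcologyOntology, min_count: int, max_count: int
) -> list[tuple[str, int]]:
    return ontology.class_size_query(min_count, max_count)


def order_distribution(
    ontology: EcologyOntology,
    category_class_ids: Sequence[str],
    use_modifiers: bool = False,
    exclusive: bool = True,
) -> list[tuple[str, str, int, int, float]]:
    return ontology.order_distribution(category_class_ids, use_modifiers, exclusive)


def build_labels(
    ontology: EcologyOntology, task: ClassTask, strain_order: Sequence[str]
) -> np.ndarray:
    return ontology.build_labels(task, strain_order)
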