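"""Ontology model invariants and closure-query semantics."""

import numpy as np
import pytest

from yeastenv import (
    ANY_PROPERTY,
    ClassNode,
    ClassTask,
    EcologyOntology,
    PropertyDef,
    RelationAssertion,
    StrainInstance,
    UnknownIdError,
    ValidationError,
)

from conftest import (
    oracle_ancestors,
    oracle_members,
    oracle_relational_members,
    random_ontology,
)


class TestStructureInvariants:
    def test_duplicate_class_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate class id"):
            EcologyOntology(classes=[ClassNode("a"), ClassNode("a")])

    def test_missing_parent_rejected(self):
        with pytest.raises(ValidationError, match="parent"):
            EcologyOntology(classes=[ClassNode("a", parent_id="ghost")])

    def test_cycle_rejected(self):
        ont = EcologyOntology(classes=[ClassNode("a"), ClassNode("b", parent_id="a")])
        ont.classes["a"].parent_id = "b"  # corrupt in place
        with pytest.raises(ValidationError, match="cycle|terminate"):
            ont.validate()

    def test_strain_needs_direct_class(self):
        with pytest.raises(ValidationError, match="direct class"):
            StrainInstance("s", direct_class_ids=frozenset())

    def test_direct_classes_must_share_a_path_or_be_leaves(self):
        classes = [
            ClassNode("r"),
            ClassNode("x", parent_id="r"),
            ClassNode("x1", parent_id="x"),
            ClassNode("y", parent_id="r"),
        ]
        # x has a child, y is a leaf: {x, y} is neither one path nor all leaves
        with pytest.raises(ValidationError, match="root-to-leaf"):
            EcologyOntology(
                classes=classes,
                instances=[StrainInstance("s", direct_class_ids=frozenset(["x", "y"]))],
            )
        # {x1, y} are both leaves: allowed as co-asserted leaves
        EcologyOntology(
            classes=classes,
            instances=[StrainInstance("s", direct_class_ids=frozenset(["x1", "y"]))],
        )

    def test_property_kind_restricted(self):
        with pytest.raises(ValidationError, match="kind"):
            PropertyDef("p", kind="frobnicating")

    def test_ids_are_whitespace_trimmed_and_case_sensitive(self):
        node = ClassNode("  Soil ")
        assert node.id == "Soil"
        ont = EcologyOntology(classes=[ClassNode("Soil"), ClassNode("soil")])
        assert set(ont.classes) == {"Soil", "soil"}


class TestAncestors:
    def test_pollen_chain(self, toy_ontology):
        assert toy_ontology.ancestors("pollen") == ["plant", "plant parts", "flower"]

    def test_root_has_no_ancestors(self, toy_ontology):
        assert toy_ontology.ancestors("plant") == []

    def test_unknown_id(self, toy_ontology):
        with pytest.raises(UnknownIdError):
            toy_ontology.ancestors("nope")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_parent_walk_oracle(self, seed):
        ont = random_ontology(seed, n_classes=40 + 7 * seed)
        for cid in ont.classes:
            chain = ont.ancestors(cid)
            assert chain == oracle_ancestors(ont, cid)
            if chain:
                assert chain[0] in ont.roots
            assert cid not in chain


class TestMembers:
    def test_member_of_class_and_every_ancestor(self, two_root_ontology):
        ont = two_root_ontology
        assert "p1" in ont.members("angiosperm")
        assert "p1" in ont.members("plant")  # counted in both, non-exclusive
        assert "p1" not in ont.members("animal")

    def test_empty_leaf(self, two_root_ontology):
        assert two_root_ontology.members("morning glory") == set()

    def test_closure_monotone_up_the_tree(self):
        for seed in range(10):
            ont = random_ontology(seed)
            for cid, node in ont.classes.items():
                if node.parent_id is not None:
                    assert ont.members(cid) <= ont.members(node.parent_id)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_closure_oracle(self, seed):
        ont = random_ontology(1000 + seed)
        for cid in ont.classes:
            assert ont.members(cid) == oracle_members(ont, cid)


class TestRelationalMembers:
    def test_relation_targeting_descendant_counts_for_ancestor(self, two_root_ontology):
        ont = two_root_ontology
        # rel1 relates to "morning glory", a descendant of plant
        assert "rel1" in ont.relational_members("plant")
        assert "rel1" in ont.relational_members("plant", "is_from_animal_on_plant")
        assert "rel1" not in ont.relational_members("plant", "decayed_microbe_association")

    def test_no_assertions_no_members(self, toy_ontology):
        for cid in toy_ontology.classes:
            assert toy_ontology.relational_members(cid) == set()

    def test_unknown_property(self, two_root_ontology):
        with pytest.raises(UnknownIdError):
            two_root_ontology.relational_members("plant", "ghost_property")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_assertion_scan_oracle(self, seed):
        ont = random_ontology(2000 + seed, relation_rate=0.7)
        props = list(ont.properties) + [None]
        for cid in ont.classes:
            for prop in props[:3]:
                assert ont.relational_members(cid, prop) == oracle_relational_members(
                    ont, cid, prop
                )


class TestClassSizeQuery:
    def test_counts_use_closure(self, two_root_ontology):
        sizes = dict(two_root_ontology.class_size_query(0, 100))
        assert sizes["plant"] == 2  # p1 + dec1, not rel1
        assert sizes["animal"] == 2  # rel1 + a1

    def test_named_class_with_five_strains(self):
        """A class holding five order-mates is found by a [5, 10] query."""
        classes = [ClassNode("fungal"), ClassNode("mushroom fruiting bodies", parent_id="fungal")]
        instances = [
            StrainInstance(name, order="Serinales",
                           direct_class_ids=frozenset(["mushroom fruiting bodies"]))
            for name in ("Candida inulinophila", "Candida morakotiae", "Candida smagusa",
                         "Kodamaea fukazawae", "Kodamaea fungicola")
        ]
        ont = EcologyOntology(classes=classes, instances=instances)
        hits = dict(ont.class_size_query(5, 10))
        assert hits["mushroom fruiting bodies"] == 5

    def test_empty_ontology(self):
        assert EcologyOntology().class_size_query(1, 5) == []

    def test_bad_bounds(self, toy_ontology):
        with pytest.raises(ValueError):
            toy_ontology.class_size_query(5, 2)


class TestOrderDistribution:
    def test_single_strain_fraction_one(self, toy_ontology):
        rows = toy_ontology.order_distribution(["plant"])
        assert rows == [("Serinales", "plant", 1, 1, 1.0)]

    def test_exclusive_partition(self, two_root_ontology):
        rows = two_root_ontology.order_distribution(["animal", "plant"])
        by = {(o, c): (n, d, f) for o, c, n, d, f in rows}
        # Serinales: p1 plant, rel1 animal (direct class wins in exclusive mode)
        assert by[("Serinales", "plant")] == (1, 2, 0.5)
        assert by[("Serinales", "animal")] == (1, 2, 0.5)
        # each order's numerators sum to its denominator
        for o in {r[0] for r in rows}:
            nums = [n for oo, c, n, d, f in rows if oo == o]
            denom = next(d for oo, c, n, d, f in rows if oo == o)
            assert sum(nums) == denom

    def test_exclusive_mode_rejects_overlapping_categories(self, two_root_ontology):
        with pytest.raises(ValidationError, match="overlap"):
            two_root_ontology.order_distribution(["plant", "angiosperm"])

    def test_modifier_rows_in_nonexclusive_mode(self, two_root_ontology):
        rows = two_root_ontology.order_distribution(
            ["plant"], use_modifiers=True, exclusive=False
        )
        by = {(o, c): n for o, c, n, d, f in rows}
        assert by[("Serinales", "plant")] == 1  # p1 by closure
        assert by[("Serinales", "plant (modifier)")] == 1  # rel1 by relation

    def test_reported_fraction_matches_counts(self):
        """Counts like 136-of-329 reproduce their printed percentage."""
        classes = [ClassNode("Arthropoda"), ClassNode("other")]
        instances = [
            StrainInstance(f"s{i}", order="Serinales",
                           direct_class_ids=frozenset(
                               ["Arthropoda" if i < 136 else "other"]))
            for i in range(329)
        ]
        ont = EcologyOntology(classes=classes, instances=instances)
        rows = ont.order_distribution(["Arthropoda", "other"])
        frac = next(f for o, c, n, d, f in rows if c == "Arthropoda")
        assert round(100 * frac) == 41


class TestBuildLabels:
    def _task(self, **kw):
        defaults = dict(name="plant-task", include_class_ids=frozenset(["plant"]))
        defaults.update(kw)
        return ClassTask(**defaults)

    def test_relational_inclusion_flips_insect_strain(self, two_root_ontology):
        ont = two_root_ontology
        order = sorted(ont.instances)
        plain = ont.build_labels(self._task(), order)
        revised = ont.build_labels(
            self._task(include_relational=frozenset([(ANY_PROPERTY, "plant")])), order
        )
        i = order.index("rel1")
        assert plain[i] == 0 and revised[i] == 1

    def test_decay_exclusion_flips_decayed_wood_strain(self, two_root_ontology):
        ont = two_root_ontology
        order = sorted(ont.instances)
        plain = ont.build_labels(self._task(), order)
        excluded = ont.build_labels(
            self._task(
                exclude_relational=frozenset([("decayed_microbe_association", "plant")])
            ),
            order,
        )
        i = order.index("dec1")
        assert plain[i] == 1 and excluded[i] == 0

    def test_root_task_labels_everything_positive(self):
        ont = random_ontology(7)
        order = sorted(ont.instances)
        task = ClassTask(name="all", include_class_ids=frozenset(ont.roots))
        assert ont.build_labels(task, order).sum() == len(order)

    def test_shuffling_strain_order_permutes_labels_identically(self, rng):
        ont = random_ontology(8)
        order = sorted(ont.instances)
        task = ClassTask(name="t", include_class_ids=frozenset([ont.roots[0]]))
        y = ont.build_labels(task, order)
        perm = rng.permutation(len(order))
        shuffled = [order[i] for i in perm]
        y2 = ont.build_labels(task, shuffled)
        assert np.array_equal(y2, y[perm])
        # idempotent
        assert np.array_equal(ont.build_labels(task, order), y)

    def test_incomplete_strain_order_rejected(self, two_root_ontology):
        with pytest.raises(ValidationError, match="exactly once"):
            two_root_ontology.build_labels(self._task(), ["p1"])

    def test_empty_task_rejected(self):
        with pytest.raises(ValidationError, match="include"):
            ClassTask(name="empty")
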