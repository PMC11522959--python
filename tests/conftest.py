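import numpy as np
import pytest

from yeastenv import (
    ClassNode,
    EcologyOntology,
    PropertyDef,
    RelationAssertion,
    StrainInstance,
    SimulationConfig,
)
from yeastenv.simulate import generate_ontology, generate_strains


@pytest.fixture
def toy_ontology() -> EcologyOntology:
    """plant > plant parts > flower > pollen, one strain on pollen."""
    return EcologyOntology(
        classes=[
            ClassNode("plant"),
            ClassNode("plant parts", parent_id="plant"),
            ClassNode("flower", parent_id="plant parts"),
            ClassNode("pollen", parent_id="flower"),
        ],
        properties=[
            PropertyDef("is_from_animal_on_plant", label="is from animal on plant"),
        ],
        instances=[
            StrainInstance("s1", species="Metschnikowia sp.", order="Serinales",
                           direct_class_ids=frozenset(["pollen"]))
        ],
    )


@pytest.fixture
def two_root_ontology() -> EcologyOntology:
    """animal and plant subtrees with relational/modifier properties and a
    small strain panel exercising closure, relations and exclusions."""
    classes = [
        ClassNode("animal"),
        ClassNode("arthropod", parent_id="animal"),
        ClassNode("beetle", parent_id="arthropod"),
        ClassNode("plant"),
        ClassNode("angiosperm", parent_id="plant"),
        ClassNode("morning glory", parent_id="angiosperm"),
        ClassNode("wood", parent_id="plant"),
    ]
    properties = [
        PropertyDef("is_from_animal_on_plant", kind="relational"),
        PropertyDef("decayed_microbe_association", kind="modifier"),
    ]
    instances = [
        # direct plant strain
        StrainInstance("p1", order="Serinales",
                       direct_class_ids=frozenset(["angiosperm"])),
        # insect strain relationally linked to a plant (insects of morning glories)
        StrainInstance("rel1", order="Serinales",
                       direct_class_ids=frozenset(["beetle"]),
                       relations=(RelationAssertion("is_from_animal_on_plant",
                                                    "morning glory"),)),
        # decayed-wood strain: plant class plus decay modifier
        StrainInstance("dec1", order="Dipodascales",
                       direct_class_ids=frozenset(["wood"]),
                       relations=(RelationAssertion("decayed_microbe_association",
                                                    "wood"),)),
        # plain animal strain
        StrainInstance("a1", order="Pichiales",
                       direct_class_ids=frozenset(["beetle"])),
    ]
    return EcologyOntology(classes=classes, properties=properties, instances=instances)


def random_ontology(seed: int, n_classes: int = 60, n_strains: int = 30,
                    relation_rate: float = 0.5) -> EcologyOntology:
    """Small random ontology with strains, for oracle/property tests."""
    config = SimulationConfig(
        n_strains=max(20, n_strains),
        n_classes=n_classes,
        relation_rate=relation_rate,
        seed=seed,
    )
    ont = generate_ontology(config)
    return generate_strains(ont, config.n_strains, config)


# ---------------------------------------------------------------------- #
# brute-force oracles, independent of the library's traversal code


def oracle_ancestors(ont: EcologyOntology, class_id: str) -> list[str]:
    chain = []
    cur = ont.classes[class_id].parent_id
    while cur is not None:
        chain.append(cur)
        cur = ont.classes[cur].parent_id
    return list(reversed(chain))


def oracle_members(ont: EcologyOntology, class_id: str) -> set[str]:
    out = set()
    for s in ont.instances.values():
        for direct in s.direct_class_ids:
            if direct == class_id or class_id in oracle_ancestors(ont, direct):
                out.add(s.id)
    return out


def oracle_relational_members(ont: EcologyOntology, class_id: str,
                              property_id=None) -> set[str]:
    out = set()
    for s in ont.instances.values():
        for rel in s.relations:
            if property_id is not None and rel.property_id != property_id:
                continue
            t = rel.target_class_id
            if t == class_id or class_id in oracle_ancestors(ont, t):
                out.add(s.id)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
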