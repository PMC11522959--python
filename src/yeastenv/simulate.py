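"""Synthetic ontologies, strain assignments, and KO matrices with known truth.

The generator emulates the structure of a subphylum-scale isolation
survey: roughly a thousand strain instances placed on a ~1500-class
single-parent hierarchy under six exclusive roots (animal, plant,
environmental, fungal, industrial products, victuals), cross-root
relational assertions at a configurable rate, and a strain × KO binary
matrix in which most KOs carry a baseline prevalence drawn uniformly
from [0.25, 0.95] while *planted* KOs have class-conditional carrier
rates.  The default planted effect is the template contrast of 87%
carriers in the positive class versus 66% outside it.

Ground truth (true labels, planted KOs, planted pathway) is returned
alongside every artifact so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import KOMatrix
from .ontology import (
    ANY_PROPERTY,
    ClassNode,
    ClassTask,
    DEFAULT_ROOTS,
    EcologyOntology,
    PropertyDef,
    RelationAssertion,
    StrainInstance,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationBundle",
    "generate_ontology",
    "generate_strains",
    "generate_ko_matrix",
    "simulate_bundle",
]

def _slug(name: str) -> str:
    return name.replace(" ", "_")


_ORDERS = (
    "Serinales",
    "Pichiales",
    "Saccharomycetales",
    "Phaffomycetales",
    "Dipodascales",
    "Lipomycetales",
)


@dataclass
class SimulationConfig:
    """Knobs of the simulated study.

    ``planted_effects`` lists ``(ko_id, prevalence_positive,
    prevalence_negative)`` triples; the default single effect uses the
    87%/66% template contrast.  ``root_counts`` (exact strains per root,
    aligned with ``roots``) overrides ``root_mixture``.
    """

    n_strains: int = 1000
    n_kos: int = 2000
    roots: tuple[str, ...] = DEFAULT_ROOTS
    n_classes: int = 1500
    max_depth: int = 6
    relation_rate: float = 0.30
    root_mixture: tuple[float, ...] | None = None
    root_counts: tuple[int, ...] | None = None
    baseline_prevalence: tuple[float, float] = (0.25, 0.95)
    planted_effects: tuple[tuple[str, float, float], ...] = (("K90001", 0.87, 0.66),)
    n_pathways: int = 150
    pathway_size_range: tuple[int, int] = (4, 24)
    planted_pathway_fraction: float = 1.0
    positive_root: str = "animal"
    relational_positive_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 20:
            raise ValueError("n_strains must be at least 20")
        for ko, p1, p0 in self.planted_effects:
            if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                raise ValueError(f"planted prevalences for {ko} outside [0, 1]")
        kos = [k for k, _, _ in self.planted_effects]
        if len(set(kos)) != len(kos):
            raise ValueError("planted KO ids must be distinct")
        if len(kos) > self.n_kos:
            raise ValueError("more planted KOs than n_kos")
        if self.n_classes < len(self.roots):
            raise ValueError("n_classes smaller than the number of roots")
        if self.positive_root not in self.roots:
            raise ValueError(f"positive_root {self.positive_root!r} not among roots")


@dataclass
class GroundTruth:
    """What was planted: true per-strain labels, effect KOs, pathway."""

    labels: dict[str, int]
    planted_kos: tuple[tuple[str, float, float], ...]
    planted_pathway_id: str | None


@dataclass
class SimulationBundle:
    ontology: EcologyOntology
    matrix: KOMatrix
    truth: GroundTruth
    task: ClassTask
    config: SimulationConfig = field(repr=False, default=None)


def generate_ontology(config: SimulationConfig, seed: int | None = None) -> EcologyOntology:
    """Random single-parent forest with the configured roots and size.

    Non-root classes are attached to a uniformly random class in the same
    root's subtree, subject to the depth cap, which yields the broad,
    shallow shape of curated environment hierarchies.  Cross-root
    relational properties ("is from <a> on <b>") and two modifier
    properties are declared.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    roots = list(config.roots)
    classes = [ClassNode(id=r, label=r) for r in roots]
    depth = {r: 0 for r in roots}
    per_root: dict[str, list[str]] = {r: [r] for r in roots}
    n_internal = config.n_classes - len(roots)
    counts = np.bincount(
        rng.integers(0, len(roots), size=n_internal), minlength=len(roots)
    )
    for root, n_under in zip(roots, counts):
        for j in range(int(n_under)):
            cid = f"{root}:c{j:04d}"
            candidates = [c for c in per_root[root] if depth[c] < config.max_depth - 1]
            parent = candidates[rng.integers(0, len(candidates))]
            classes.append(ClassNode(id=cid, label=cid.replace(":", " "), parent_id=parent))
            depth[cid] = depth[parent] + 1
            per_root[root].append(cid)
    properties = [
        PropertyDef(
            id=f"is_from_{_slug(a)}_on_{_slug(b)}",
            label=f"is from {a} on {b}",
            kind="relational",
        )
        for a in roots
        for b in roots
        if a != b
    ]
    properties += [
        PropertyDef(id="has_microbe_association", label="has microbe association", kind="modifier"),
        PropertyDef(id="decayed_microbe_association", label="decayed microbe association", kind="modifier"),
    ]
    return EcologyOntology(classes=classes, properties=properties, roots=roots)


def _root_counts(config: SimulationConfig, n: int, rng) -> np.ndarray:
    if config.root_counts is not None:
        counts = np.asarray(config.root_counts, dtype=int)
        if counts.sum() != n or len(counts) != len(config.roots):
            raise ValueError("root_counts must align with roots and sum to n_strains")
        return counts
    if config.root_mixture is not None:
        mix = np.asarray(config.root_mixture, dtype=float)
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("root_mixture must sum to 1")
    else:
        mix = np.full(len(config.roots), 1.0 / len(config.roots))
    return rng.multinomial(n, mix)


def generate_strains(
    ontology: EcologyOntology,
    n: int,
    config: SimulationConfig,
    seed: int | None = None,
) -> EcologyOntology:
    """Add ``n`` strain instances to the ontology.

    Each strain receives one direct class sampled uniformly from the
    classes under its root (leaning on specific classes, as curated
    assignments do), a taxonomic order, and cross-root relational
    assertions at ``config.relation_rate``.  A
    ``relational_positive_fraction`` of positive-root strains is instead
    placed under a *different* root but linked to the positive root
    relationally, so their positive status is visible only through
    relational membership.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    roots = list(config.roots)
    counts = _root_counts(config, n, rng)
    under: dict[str, list[str]] = {
        r: sorted(ontology.subtree(r) - {r}) or [r] for r in roots
    }
    strain_no = 0
    for root, n_under in zip(roots, counts):
        n_relational = 0
        if root == config.positive_root:
            n_relational = int(round(config.relational_positive_fraction * n_under))
        for j in range(int(n_under)):
            sid = f"strain{strain_no:04d}"
            strain_no += 1
            relational_only = j < n_relational
            if relational_only:
                other = [r for r in roots if r != root]
                home = other[rng.integers(0, len(other))]
                direct = under[home][rng.integers(0, len(under[home]))]
                prop = f"is_from_{_slug(home)}_on_{_slug(root)}"
                target = under[root][rng.integers(0, len(under[root]))]
                relations = [RelationAssertion(prop, target)]
            else:
                direct = under[root][rng.integers(0, len(under[root]))]
                relations = []
                if rng.random() < config.relation_rate:
                    other = [r for r in roots if r != root and r != config.positive_root]
                    tgt_root = other[rng.integers(0, len(other))]
                    prop = f"is_from_{_slug(root)}_on_{_slug(tgt_root)}"
                    target = under[tgt_root][rng.integers(0, len(under[tgt_root]))]
                    relations.append(RelationAssertion(prop, target))
            order = _ORDERS[rng.integers(0, len(_ORDERS))]
            ontology.add_instance(
                StrainInstance(
                    id=sid,
                    species=f"Synthetica sp. {strain_no}",
                    order=order,
                    direct_class_ids=frozenset([direct]),
                    relations=tuple(relations),
                    isolation_text=f"synthetic isolate under {root}",
                )
            )
    ontology.validate()
    return ontology


def generate_ko_matrix(
    strain_ids,
    labels,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[KOMatrix, GroundTruth]:
    """Class-conditional Bernoulli KO matrix plus pathway map.

    Non-planted KO j is carried by every strain with a single baseline
    prevalence drawn once per KO (presence/absence is a species-level
    trait); planted KOs switch prevalence on the strain's class label.
    Every KO belongs to at least one pathway; planted KOs are
    concentrated in the planted pathway per
    ``config.planted_pathway_fraction``.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    strain_ids = list(strain_ids)
    y = np.asarray(labels)
    if len(y) != len(strain_ids):
        raise ValueError("labels must align with strain_ids")
    planted = {ko: (p1, p0) for ko, p1, p0 in config.planted_effects}
    n_background = config.n_kos - len(planted)
    ko_ids = [f"K{j:05d}" for j in range(1, n_background + 1)]
    clash = set(ko_ids) & set(planted)
    if clash:
        raise ValueError(f"planted KO ids collide with background ids: {sorted(clash)}")
    ko_ids += sorted(planted)

    lo, hi = config.baseline_prevalence
    baseline = rng.uniform(lo, hi, size=config.n_kos)
    cols = np.empty((len(strain_ids), config.n_kos), dtype=np.int8)
    for j, ko in enumerate(ko_ids):
        if ko in planted:
            p1, p0 = planted[ko]
            prob = np.where(y == 1, p1, p0)
        else:
            prob = np.full(len(y), baseline[j])
        cols[:, j] = rng.random(len(y)) < prob

    # pathway map: contiguous blocks of background KOs, sizes drawn from the
    # configured range; planted KOs concentrated in one extra pathway
    ko_to_pathways: dict[str, set[str]] = {}
    pathway_labels: dict[str, str] = {}
    sizes = rng.integers(
        config.pathway_size_range[0],
        config.pathway_size_range[1] + 1,
        size=config.n_pathways,
    )
    pool = [k for k in ko_ids if k not in planted]
    pos = 0
    for i, size in enumerate(sizes):
        pid = f"pw{i:04d}"
        pathway_labels[pid] = f"Synthetic pathway {i:04d}"
        for _ in range(int(size)):
            ko = pool[pos % len(pool)]
            pos += 1
            ko_to_pathways.setdefault(ko, set()).add(pid)
    planted_pathway_id = None
    if planted:
        planted_pathway_id = "pw_planted"
        pathway_labels[planted_pathway_id] = "Planted effect pathway"
        planted_list = sorted(planted)
        n_in = max(1, int(round(config.planted_pathway_fraction * len(planted_list))))
        for ko in planted_list[:n_in]:
            ko_to_pathways.setdefault(ko, set()).add(planted_pathway_id)
        for ko in planted_list[n_in:]:
            pid = f"pw{int(rng.integers(0, config.n_pathways)):04d}"
            ko_to_pathways.setdefault(ko, set()).add(pid)
        # pad the planted pathway with background KOs so it has a
        # realistic size relative to the others
        target = max(int(sizes.mean()), n_in)
        fill = [k for k in pool if planted_pathway_id not in ko_to_pathways.get(k, ())]
        for ko in fill[: max(0, target - n_in)]:
            ko_to_pathways.setdefault(ko, set()).add(planted_pathway_id)
    for ko in ko_ids:  # every KO gets at least one pathway
        if ko not in ko_to_pathways:
            ko_to_pathways[ko] = {f"pw{int(rng.integers(0, config.n_pathways)):04d}"}

    matrix = KOMatrix(
        data=pd.DataFrame(cols, index=strain_ids, columns=ko_ids),
        ko_to_pathways={k: frozenset(v) for k, v in ko_to_pathways.items()},
        pathway_labels=pathway_labels,
    )
    truth = GroundTruth(
        labels={s: int(v) for s, v in zip(strain_ids, y)},
        planted_kos=tuple(config.planted_effects),
        planted_pathway_id=planted_pathway_id,
    )
    return matrix, truth


def simulate_bundle(config: SimulationConfig) -> SimulationBundle:
    """Full synthetic study: ontology, strains, labels via the ontology
    closure (exercising the labelling machinery, not bypassing it), and a
    KO matrix conditioned on those labels.

    The task labels strains positive when they are closure members of the
    positive root *or* relationally linked to it, matching how the
    relational-only positives are planted.
    """
    ontology = generate_ontology(config)
    generate_strains(ontology, config.n_strains, config)
    task = ClassTask(
        name=f"{config.positive_root}-associated",
        include_class_ids=frozenset([config.positive_root]),
        include_relational=frozenset([(ANY_PROPERTY, config.positive_root)]),
    )
    strain_ids = sorted(ontology.instances)
    labels = ontology.build_labels(task, strain_ids)
    matrix, truth = generate_ko_matrix(strain_ids, labels, config)
    return SimulationBundle(
        ontology=ontology, matrix=matrix, truth=truth, task=task, config=config
    )
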