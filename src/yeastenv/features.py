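"""KO presence/absence matrices and balanced, stratified dataset construction.

Features are binary: a strain either carries at least one gene assigned to
a KEGG Ortholog (KO) family or it does not.  Copy number is deliberately
not modelled.  Low-prevalence KOs (carried by fewer than a configurable
fraction of strains, default 20%) are removed before modelling.
Classification datasets are balanced by random downsampling of the
majority class and split 80/20 with stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "KOMatrix",
    "SplitPlan",
    "load_ko_table",
    "write_ko_table",
    "load_pathway_map",
    "write_pathway_map",
    "filter_low_prevalence",
    "balance_downsample",
    "make_split",
]


@dataclass
class KOMatrix:
    """Strain × KO binary matrix with an optional KO→pathway map.

    ``data`` is a pandas DataFrame indexed by strain id with KO-id columns
    and values in {0, 1}.
    """

    data: pd.DataFrame
    ko_to_pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    pathway_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate strain ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate KO ids: {dupes[:5]}")
        values = self.data.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at strain {self.data.index[r]!r}, "
                f"KO {self.data.columns[c]!r}: {values[r, c]!r}"
            )
        self.data = self.data.astype(np.int8)
        self.data.index.name = "strain_id"
        self.data.columns.name = None

    @property
    def strain_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def ko_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)

    def prevalence(self) -> pd.Series:
        """Fraction of strains carrying each KO."""
        return self.data.mean(axis=0)

    def subset(self, strain_ids=None, ko_ids=None) -> "KOMatrix":
        data = self.data
        if strain_ids is not None:
            data = data.loc[list(strain_ids)]
        if ko_ids is not None:
            data = data[list(ko_ids)]
        return KOMatrix(
            data=data.copy(),
            ko_to_pathways=self.ko_to_pathways,
            pathway_labels=self.pathway_labels,
        )


@dataclass(frozen=True)
class SplitPlan:
    """A balanced index set partitioned into train and test rows.

    Indices are positions into the full matrix row order.  Invariants:
    train and test are disjoint, their union is the balanced set, and
    ``len(test) == round(test_fraction * len(balanced))``.
    """

    balanced: tuple[int, ...]
    train: tuple[int, ...]
    test: tuple[int, ...]
    seed: int
    test_fraction: float

    def __post_init__(self) -> None:
        tr, te, ba = set(self.train), set(self.test), set(self.balanced)
        if tr & te:
            raise ValueError("train and test overlap")
        if tr | te != ba:
            raise ValueError("train ∪ test must equal the balanced set")
        if len(self.test) != round(self.test_fraction * len(self.balanced)):
            raise ValueError("test size does not match test_fraction")


def load_ko_table(path, pathway_map_path=None) -> KOMatrix:
    """Read a strain × KO TSV: first column strain ids, remaining columns
    KO ids, cells 0/1."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell in KO table: {exc}") from exc
    matrix = KOMatrix(data=numeric)
    if pathway_map_path is not None:
        ko_to_pathways, pathway_labels = load_pathway_map(pathway_map_path)
        matrix.ko_to_pathways = ko_to_pathways
        matrix.pathway_labels = pathway_labels
    return matrix


def write_ko_table(matrix: KOMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="strain_id")


def load_pathway_map(path) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Read a KO→pathway TSV with columns ``ko_id``, ``pathway_id``,
    ``pathway_label`` (one row per KO–pathway membership)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["ko_id", "pathway_id", "pathway_label"]
    if list(df.columns) != required:
        raise ValueError(f"{path}: columns must be {required}, got {list(df.columns)}")
    ko_to_pathways: dict[str, set[str]] = {}
    pathway_labels: dict[str, str] = {}
    for row in df.itertuples(index=False):
        ko_to_pathways.setdefault(row.ko_id, set()).add(row.pathway_id)
        pathway_labels[row.pathway_id] = row.pathway_label
    return (
        {k: frozenset(v) for k, v in ko_to_pathways.items()},
        pathway_labels,
    )


def write_pathway_map(
    ko_to_pathways: dict[str, frozenset[str]], pathway_labels: dict[str, str], path
) -> None:
    rows = [
        {"ko_id": ko, "pathway_id": pw, "pathway_label": pathway_labels.get(pw, pw)}
        for ko in sorted(ko_to_pathways)
        for pw in sorted(ko_to_pathways[ko])
    ]
    pd.DataFrame(rows, columns=["ko_id", "pathway_id", "pathway_label"]).to_csv(
        path, sep="\t", index=False
    )


def filter_low_prevalence(
    matrix: KOMatrix,
    threshold: float = 0.20,
    species_map: Mapping[str, str] | None = None,
) -> KOMatrix:
    """Remove KOs present in strictly less than ``threshold`` of strains.

    Columns with prevalence exactly at the threshold are kept; column
    order of survivors is preserved and rows are untouched.  With a
    ``species_map`` (strain id → species name) prevalence is computed
    per species instead of per strain: a species carries a KO if any of
    its strains does.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if species_map is not None:
        species = matrix.data.index.map(lambda s: species_map.get(s, s))
        keep = matrix.data.groupby(species).max().mean(axis=0) >= threshold
    else:
        keep = matrix.prevalence() >= threshold
    if not keep.any():
        warnings.warn(
            f"prevalence filter at {threshold} removed every KO", stacklevel=2
        )
    return KOMatrix(
        data=matrix.data.loc[:, keep].copy(),
        ko_to_pathways=matrix.ko_to_pathways,
        pathway_labels=matrix.pathway_labels,
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def balance_downsample(labels, seed) -> np.ndarray:
    """Equalise class sizes by sampling the majority class without
    replacement; the minority class is fully retained.

    Returns sorted row positions. Deterministic given ``seed``.
    """
    y = np.asarray(labels)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            f"both classes must be non-empty (positives={len(pos)}, "
            f"negatives={len(neg)})"
        )
    rng = _as_rng(seed)
    if len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    elif len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, neg]))


def make_split(
    indices, labels, test_fraction: float = 0.20, seed: int = 0
) -> SplitPlan:
    """Stratified train/test split of a (typically balanced) index set.

    ``len(test) = round(test_fraction * len(indices))``; both classes are
    guaranteed in the test set by stratification.
    """
    idx = np.asarray(indices)
    if len(idx) < 10:
        raise ValueError(f"need at least 10 samples to split, got {len(idx)}")
    y = np.asarray(labels)[idx]
    n_test = int(round(test_fraction * len(idx)))
    if n_test < len(np.unique(y)) or len(idx) - n_test < len(np.unique(y)):
        raise ValueError("too few samples to stratify the split")
    train, test = train_test_split(
        idx, test_size=n_test, stratify=y, random_state=int(seed) % (2**32)
    )
    return SplitPlan(
        balanced=tuple(int(i) for i in np.sort(idx)),
        train=tuple(int(i) for i in np.sort(train)),
        test=tuple(int(i) for i in np.sort(test)),
        seed=int(seed),
        test_fraction=test_fraction,
    )
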