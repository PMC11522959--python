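"""Per-KO contingency statistics and pathway over-representation.

Each consensus-selected KO is re-analysed with a two-sided Fisher exact
test on its 2×2 presence × class-membership table; raw p-values and the
unconditional (cross-product) odds ratio are reported.  Pathway
enrichment of the selected KO set against the annotated-KO universe uses
the one-sided hypergeometric tail with Benjamini–Hochberg adjustment
across pathways; KEGG pathways whose labels carry the "– yeast" suffix
are excluded beforehand (they are narrowly defined on Saccharomycetales
and under-annotated elsewhere).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .features import KOMatrix

__all__ = [
    "AssociationRecord",
    "EnrichmentRecord",
    "fisher_exact_2x2",
    "ko_association_table",
    "bh_adjust",
    "filter_yeast_pathways",
    "pathway_enrichment",
    "association_frame",
    "enrichment_frame",
]


@dataclass
class AssociationRecord:
    """One KO's 2×2 association with a class label.

    Counts: a present/in-class, b absent/in-class, c present/out-of-class,
    d absent/out-of-class.
    """

    ko_id: str
    a: int
    b: int
    c: int
    d: int
    pct_in_class: float
    pct_out_class: float
    odds_ratio: float
    p_value: float
    median_importance: float | None = None
    zero_cell: bool = False


@dataclass
class EnrichmentRecord:
    """Pathway over-representation among selected KOs.

    k selected KOs in the pathway, n selected KOs total, K universe KOs
    in the pathway, N universe size.
    """

    pathway_id: str
    pathway_label: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError(f"pathway {self.pathway_id}: k exceeds min(n, K)")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, p)`` where the odds ratio is the unconditional
    cross-product ratio ``(a·d)/(b·c)`` (``inf`` when only ``b·c`` is
    zero, ``nan`` for the degenerate 0/0 case) and the p-value sums the
    probabilities of all tables, at fixed margins, no more likely than
    the observed one.
    """
    counts = np.array([[a, b], [c, d]])
    if (counts < 0).any():
        raise ValueError(f"counts must be non-negative, got {counts.tolist()}")
    if counts.sum() == 0:
        raise ValueError("all four cells are zero")
    _, p = fisher_exact(counts, alternative="two-sided")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = np.nan if ad == 0 else np.inf
    else:
        odds = ad / bc
    return float(odds), float(p)


def ko_association_table(
    matrix: KOMatrix,
    labels,
    ko_ids,
    median_importance: dict[str, float] | pd.Series | None = None,
) -> list[AssociationRecord]:
    """Fisher-test every KO in ``ko_ids`` against the binary ``labels``
    (aligned to the matrix rows).

    Sorted by median consensus importance (descending) when supplied,
    else by raw p.
    """
    y = np.asarray(labels)
    if len(y) != matrix.shape[0]:
        raise ValueError("labels length does not match matrix rows")
    missing = [k for k in ko_ids if k not in matrix.data.columns]
    if missing:
        raise KeyError(f"KOs not in matrix: {missing[:10]}")
    records = []
    for ko in ko_ids:
        col = matrix.data[ko].to_numpy()
        a = int(np.sum((col == 1) & (y == 1)))
        b = int(np.sum((col == 0) & (y == 1)))
        c = int(np.sum((col == 1) & (y == 0)))
        d = int(np.sum((col == 0) & (y == 0)))
        odds, p = fisher_exact_2x2(a, b, c, d)
        imp = None
        if median_importance is not None:
            imp = float(median_importance[ko])
        records.append(
            AssociationRecord(
                ko_id=ko,
                a=a,
                b=b,
                c=c,
                d=d,
                pct_in_class=a / (a + b) if a + b else float("nan"),
                pct_out_class=c / (c + d) if c + d else float("nan"),
                odds_ratio=odds,
                p_value=p,
                median_importance=imp,
                zero_cell=(b * c == 0 or a * d == 0),
            )
        )
    if median_importance is not None:
        records.sort(key=lambda r: -(r.median_importance or 0.0))
    else:
        records.sort(key=lambda r: (r.p_value, r.ko_id))
    return records


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


_YEAST_SUFFIX = re.compile(r"[\s ]*[-‐‒–—][\s ]*yeast[\s ]*$", re.IGNORECASE)


def filter_yeast_pathways(
    pathway_labels: dict[str, str],
) -> tuple[dict[str, str], list[str]]:
    """Drop pathways whose label ends in a "– yeast" suffix (any dash
    variant, surrounding whitespace ignored).

    Returns the filtered label map and the list of removed pathway ids.
    """
    removed = [pid for pid, lab in pathway_labels.items() if _YEAST_SUFFIX.search(lab)]
    kept = {pid: lab for pid, lab in pathway_labels.items() if pid not in set(removed)}
    return kept, sorted(removed)


def pathway_enrichment(
    selected_kos,
    universe_kos,
    ko_to_pathways: dict[str, frozenset[str]],
    pathway_labels: dict[str, str] | None = None,
    min_pathway_size: int = 3,
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation of each pathway in the
    selected KO set.

    The universe is all annotated KOs; pathways with no universe KOs, or
    with fewer than ``min_pathway_size``, are skipped.  BH adjustment is
    applied across the tested pathways.  Sorted by adjusted p, then raw
    p, then pathway id.
    """
    selected = set(selected_kos)
    universe = set(universe_kos)
    offenders = sorted(selected - universe)
    if offenders:
        raise ValueError(f"selected KOs outside the universe: {offenders[:10]}")
    pathway_labels = pathway_labels or {}
    by_pathway: dict[str, set[str]] = {}
    for ko in universe:
        for pw in ko_to_pathways.get(ko, ()):
            by_pathway.setdefault(pw, set()).add(ko)
    N = len(universe)
    n = len(selected)
    rows = []
    for pw in sorted(by_pathway):
        pw_kos = by_pathway[pw]
        K = len(pw_kos)
        if K < min_pathway_size:
            continue
        k = len(pw_kos & selected)
        # P(X >= k) under sampling n of N with K marked
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((pw, k, K, p))
    if not rows:
        return []
    adjusted = bh_adjust([r[3] for r in rows])
    records = [
        EnrichmentRecord(
            pathway_id=pw,
            pathway_label=pathway_labels.get(pw, pw),
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            p_adjusted=float(adj),
        )
        for (pw, k, K, p), adj in zip(rows, adjusted)
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.p_value, r.pathway_id))
    return records


def association_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Figure-style report: percentages on the 0–100 scale, rounded to
    integers in dedicated columns alongside the exact values."""
    columns = [f.name for f in dataclasses.fields(AssociationRecord)]
    df = pd.DataFrame([vars(r) for r in records], columns=columns)
    for col in ("pct_in_class", "pct_out_class"):
        df[f"{col}_display"] = (
            (pd.to_numeric(df[col]) * 100).round().astype("Int64")
        )
    return df


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    columns = [f.name for f in dataclasses.fields(EnrichmentRecord)]
    return pd.DataFrame([vars(r) for r in records], columns=columns)
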