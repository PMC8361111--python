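"""Cultivar-level summaries of annotated flavonoid profiles.

Operates on an abundance matrix (compounds x samples, non-negative peak
areas or intensities, as a pandas DataFrame) and the annotation records:
percent composition per cultivar, aglycone- and acylation-class area
ratios, Euclidean hierarchical clustering of profiles, and presence/
absence set arithmetic for Venn-style reporting.
"""

from __future__ import annotations

import itertools
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .annotate import AnnotationRecord, classify_acylation

__all__ = [
    "percent_composition",
    "group_ratios",
    "cluster_profiles",
    "presence_sets",
    "log10_mean_transform",
]


def _validate_matrix(m: pd.DataFrame) -> None:
    if (m.to_numpy() < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    if m.index.has_duplicates or m.columns.has_duplicates:
        raise ValueError("abundance matrix labels must be unique")


def percent_composition(areas: pd.DataFrame) -> pd.DataFrame:
    """Each value as percent of its column (cultivar) total.

    Columns sum to 100 exactly; a zero column total is a fatal error for
    that cultivar.  Scale-invariant per column.
    """
    _validate_matrix(areas)
    totals = areas.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total abundance for cultivar(s): {list(zero.index)}")
    return areas.div(totals, axis=1) * 100.0


def group_ratios(
    annotations: Sequence[AnnotationRecord],
    areas: pd.DataFrame,
    group_by: Literal["aglycone", "acylation"],
) -> pd.DataFrame:
    """Fraction of summed area per group (rows) per cultivar (columns).

    ``group_by='aglycone'`` groups by the annotated core; entries whose core
    is ambiguous form their own category (joined candidate names).
    ``group_by='acylation'`` groups by acylation class (Non/Mono/Di/Poly).
    Every annotated compound must be a row of ``areas``.
    """
    _validate_matrix(areas)
    groups: dict[str, str] = {}
    for rec in annotations:
        if rec.entry is None:
            continue
        if rec.spectrum_id not in areas.index:
            raise KeyError(f"annotated compound {rec.spectrum_id!r} missing from areas")
        if group_by == "aglycone":
            if rec.entry.ambiguous_core:
                group = "ambiguous(" + "/".join(sorted(rec.entry.ambiguous_core)) + ")"
            else:
                group = rec.entry.composition.core.name
        elif group_by == "acylation":
            group = classify_acylation(rec.entry.composition)
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
        groups[rec.spectrum_id] = group
    sub = areas.loc[sorted(groups)]
    summed = sub.groupby([groups[i] for i in sub.index]).sum()
    return summed.div(summed.sum(axis=0), axis=1)


def cluster_profiles(
    m: pd.DataFrame,
    axis: Literal["rows", "columns"] = "columns",
    method: str = "complete",
) -> tuple[np.ndarray, list[str], str]:
    """Agglomerative Euclidean clustering of profiles on one axis.

    Returns ``(linkage_matrix, leaf_order, newick)`` where ``linkage_matrix``
    is the SciPy linkage encoding, ``leaf_order`` the deterministic leaf
    labels left-to-right, and ``newick`` a Newick rendering of the merge
    tree with branch lengths (for text-level inspection).  A single item
    yields a one-leaf tree.
    """
    _validate_matrix(m)
    data = m if axis == "rows" else m.T
    labels = [str(x) for x in data.index]
    if len(labels) < 1:
        raise ValueError("nothing to cluster")
    if len(labels) == 1:
        return np.empty((0, 4)), labels, f"{labels[0]};"
    z = hierarchy.linkage(data.to_numpy(dtype=float), method=method, metric="euclidean")
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    tree = hierarchy.to_tree(z)

    def newick(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return z, order, newick(tree, tree.dist) + ";"


def presence_sets(
    m: pd.DataFrame, presence_floor: float = 0.0
) -> tuple[dict[str, set[str]], dict[frozenset[str], int]]:
    """Presence/absence sets per sample and all intersection cardinalities.

    A compound is present in a sample iff its abundance exceeds
    ``presence_floor``.  Returns ``(sets, intersections)`` where ``sets``
    maps each sample label to its compound set and ``intersections`` maps
    every non-empty subset of labels to the size of the intersection of
    those sets.  Counts are monotone non-increasing in the floor.
    """
    if presence_floor < 0:
        raise ValueError("presence_floor must be >= 0")
    _validate_matrix(m)
    sets = {
        str(col): set(m.index[m[col] > presence_floor].astype(str)) for col in m.columns
    }
    labels = sorted(sets)
    intersections: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            common = set.intersection(*(sets[c] for c in combo))
            intersections[frozenset(combo)] = len(common)
    return sets, intersections


def log10_mean_transform(m: pd.DataFrame) -> pd.DataFrame:
    """log10(abundance + 1) display transform; zeros map to zero."""
    _validate_matrix(m)
    return np.log10(m + 1.0)
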