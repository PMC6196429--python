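"""Merging of overlapping significant gene sets into non-redundant supersets.

Two sets qualify for merging when their gene overlap ratio (intersection
over the smaller set) exceeds 0.33 AND the Bonferroni-corrected one-sided
Fisher's exact P of the overlap is below 0.05.  Qualifying pairs define a
graph whose connected components become the supersets, so the output
partition is transitive and supersets are pairwise non-qualifying.  Sets
annotated with the same biological term but failing the quantitative
criteria are deliberately kept separate (and reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import DataError


@dataclass
class Superset:
    superset_id: str
    member_set_ids: list[str]
    genes: set[str]
    annotation: str


def overlap_ratio(a: set[str], b: set[str]) -> float:
    """|a & b| / min(|a|, |b|) — overlap relative to the smaller set."""
    if not a or not b:
        raise DataError("overlap_ratio of an empty set")
    return len(a & b) / min(len(a), len(b))


def fisher_pair_p(a: set[str], b: set[str], universe_size: int) -> float:
    """One-sided Fisher's exact P for joint membership of two sets."""
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))


def merge_pass(
    sets: Mapping[str, set[str]],
    universe_size: int,
    ratio_cut: float = 0.33,
    alpha: float = 0.05,
) -> list[Superset]:
    """One merging pass over significant gene sets.

    Bonferroni divides ``alpha`` by the number of set pairs tested (all
    pairs).  Singleton components pass through unchanged.  Superset ids are
    deterministic: ordered by gene count descending, then lexicographically
    by member ids.
    """
    names = list(sets.keys())
    for name in names:
        if not sets[name]:
            raise DataError(f"set {name!r} is empty")
        if len(sets[name]) > universe_size:
            raise DataError(f"set {name!r} larger than the universe")
    n_pairs = len(names) * (len(names) - 1) // 2
    threshold = alpha / n_pairs if n_pairs else alpha

    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in combinations(names, 2):
        if overlap_ratio(sets[a], sets[b]) > ratio_cut \
                and fisher_pair_p(sets[a], sets[b], universe_size) < threshold:
            g.add_edge(a, b)

    components = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        genes: set[str] = set()
        for name in members:
            genes |= sets[name]
        components.append((members, genes))
    components.sort(key=lambda c: (-len(c[1]), c[0]))
    return [
        Superset(f"SS{i + 1:02d}", members, genes, "+".join(members))
        for i, (members, genes) in enumerate(components)
    ]


def keep_same_name_separate(
    supersets: list[Superset],
    annotations: Mapping[str, str],
) -> tuple[list[Superset], pd.DataFrame]:
    """Assert that merging used only the quantitative criteria.

    Identity on the supersets; emits a report of set pairs sharing the same
    annotation term that ended up in different supersets (kept independent).
    """
    home = {m: ss.superset_id for ss in supersets for m in ss.member_set_ids}
    rows = []
    annotated = [m for m in home if m in annotations]
    for a, b in combinations(sorted(annotated), 2):
        if annotations[a] == annotations[b] and home[a] != home[b]:
            rows.append((a, b, annotations[a]))
    report = pd.DataFrame(rows, columns=["set_a", "set_b", "shared_term"])
    return supersets, report


def supersets_to_gmt(supersets: list[Superset]) -> dict[str, set[str]]:
    return {ss.superset_id: ss.genes for ss in supersets}


def membership_table(supersets: list[Superset]) -> pd.DataFrame:
    rows = [(ss.superset_id, m) for ss in supersets for m in ss.member_set_ids]
    return pd.DataFrame(rows, columns=["superset_id", "member_set_id"])
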