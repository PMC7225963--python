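"""Species dendrograms from cleavage-site profiles, and their comparison.

Even though cleavage octamers are short and only weakly conserved, the
substitutions they accumulate are phylogenetically structured: species can
be clustered into vertebrate classes from the concatenation of their
orthologous cleavage sites alone.  This module builds a species x character
matrix (concatenated octamers, concatenated 60-mers, or per-site Hamming
distance codes), clusters it hierarchically on normalised Hamming distance,
and compares two dendrograms with Baker's Gamma — the Goodman-Kruskal gamma
over, for every leaf pair, the merge level at which the pair first
co-clusters in each tree (1 = identical hierarchies, -1 = inverted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from skbio import TreeNode

from .conservation import STANDARD_AA

_STD = np.zeros(256, dtype=bool)
for _aa in STANDARD_AA:
    _STD[ord(_aa)] = True


@dataclass
class SpeciesMatrix:
    """Species x character matrix; '-' marks missing sites / gap columns."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("row ids must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows must have equal length")


@dataclass
class Dendrogram:
    """Agglomerative clustering result: a scipy linkage plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


def build_species_matrix(
    hits: pd.DataFrame, site_ids: list[str], mode: str = "octamer"
) -> SpeciesMatrix:
    """Concatenate per-site profiles into one string per species.

    ``mode``: 'octamer' (anchored ortholog octamers), 'window' (anchored
    60-mers), or 'hd' (one digit per site, the octamer Hamming distance).
    Sites a species has no hit for contribute '-' runs.
    """
    if mode == "octamer":
        col, width = "ortho_octamer", 8
    elif mode == "window":
        col, width = "anchored_window", None
    elif mode == "hd":
        col, width = "octamer_hd", 1
    else:
        raise ValueError(f"unknown mode: {mode}")
    widths = {}
    for sid in site_ids:
        if width is not None:
            widths[sid] = width
        else:
            lens = hits.loc[hits["site_id"] == sid, col].str.len()
            widths[sid] = int(lens.iloc[0]) if len(lens) else 0
    lookup = {}
    for r in hits.itertuples(index=False):
        value = getattr(r, col)
        text = str(int(value)) if mode == "hd" else str(value)
        lookup[(r.site_id, r.species_name)] = text
    species = sorted(hits["species_name"].unique())
    rows = []
    for sp in species:
        parts = [
            lookup.get((sid, sp), "-" * widths[sid]).ljust(widths[sid], "-")
            for sid in site_ids
        ]
        rows.append("".join(parts))
    return SpeciesMatrix(ids=species, rows=rows)


def pairwise_distances(matrix: SpeciesMatrix) -> np.ndarray:
    """Condensed normalised-Hamming distances between species rows.

    Only columns where both rows are non-missing (not '-') are compared;
    within those, ambiguity characters mismatch everything.  A pair with no
    comparable column raises, naming the pair.
    """
    enc = np.array(
        [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in matrix.rows]
    )
    n = len(matrix.ids)
    gap = ord("-")
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            comparable = (enc[i] != gap) & (enc[j] != gap)
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {matrix.ids[i]!r} and {matrix.ids[j]!r}"
                )
            match = (enc[i] == enc[j]) & _STD[enc[i]]
            out[k] = 1.0 - match[comparable].sum() / m
            k += 1
    return out


def cluster_species(matrix: SpeciesMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of species rows (default average linkage)."""
    if len(matrix.ids) < 2:
        raise ValueError("need at least 2 species")
    dists = pairwise_distances(matrix)
    Z = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(linkage=Z, labels=list(matrix.ids))


def _merge_levels_from_linkage(dend: Dendrogram) -> tuple[list[str], np.ndarray]:
    """For every unordered leaf pair, the level of the first co-clustering merge.

    Levels are dense ranks of merge heights, so merges at identical heights
    (star-like joins) share a level and produce ties.
    """
    Z = dend.linkage
    n = len(dend.labels)
    heights = Z[:, 2]
    level_of_step = np.searchsorted(np.unique(heights), heights) + 1
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    pair_level = np.zeros((n, n))
    for step in range(len(Z)):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        for x in members[a]:
            for y in members[b]:
                pair_level[x, y] = pair_level[y, x] = level_of_step[step]
        members[n + step] = members.pop(a) + members.pop(b)
    iu = np.triu_indices(n, k=1)
    return list(dend.labels), pair_level[iu]


def _merge_levels_from_tree(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-pair cophenetic distances of an ultrametric tree as merge levels."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    return ids, np.round(dm.data[iu], 10)


def _merge_levels(obj) -> tuple[list[str], np.ndarray]:
    if isinstance(obj, Dendrogram):
        return _merge_levels_from_linkage(obj)
    if isinstance(obj, TreeNode):
        return _merge_levels_from_tree(obj)
    if isinstance(obj, str):
        return _merge_levels_from_tree(TreeNode.read([obj]))
    raise TypeError(f"cannot extract merge levels from {type(obj)!r}")


def _gamma(x: np.ndarray, y: np.ndarray) -> float:
    """Goodman-Kruskal gamma: (C - D) / (C + D), ties excluded."""
    m = len(x)
    total = m * (m - 1) // 2

    def tie_pairs(v: np.ndarray) -> int:
        _, counts = np.unique(v, return_counts=True)
        return int((counts * (counts - 1) // 2).sum())

    tx, ty = tie_pairs(x), tie_pairs(y)
    txy = tie_pairs(np.round(x, 10) + 1j * np.round(y, 10))
    tau = stats.kendalltau(x, y)
    c_minus_d = tau.statistic * np.sqrt((total - tx) * (total - ty))
    c_plus_d = total - tx - ty + txy
    if c_plus_d <= 0:
        return float("nan")
    return float(np.clip(c_minus_d / c_plus_d, -1.0, 1.0))


def bakers_gamma(tree_a, tree_b) -> float:
    """Baker's Gamma between two dendrograms on the same leaves.

    Accepts :class:`Dendrogram`, an skbio ``TreeNode``, or a Newick string.
    For every unordered leaf pair the merge level at which the pair first
    co-clusters is computed in each tree; the result is the Goodman-Kruskal
    gamma over all pairs of leaf pairs (ties contribute to neither
    concordance nor discordance).

    Raises
    ------
    ValueError
        If the two trees have different leaf sets or fewer than 3 leaves.
    """
    ids_a, lev_a = _merge_levels(tree_a)
    ids_b, lev_b = _merge_levels(tree_b)
    if set(ids_a) != set(ids_b):
        raise ValueError("leaf sets differ")
    n = len(ids_a)
    if n < 3:
        raise ValueError("need at least 3 leaves")
    # align pair vectors via a common leaf order
    def pair_series(ids: list[str], levels: np.ndarray) -> dict:
        keys = [
            (ids[i], ids[j]) if ids[i] < ids[j] else (ids[j], ids[i])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        return dict(zip(keys, levels))

    da = pair_series(ids_a, lev_a)
    db = pair_series(ids_b, lev_b)
    keys = sorted(da)
    x = np.array([da[k] for k in keys])
    y = np.array([db[k] for k in keys])
    return _gamma(x, y)
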