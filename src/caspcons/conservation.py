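"""Conservation statistics for caspase cleavage sites and their orthologs.

Caspases cut after an aspartate (P1) inside an eight-residue motif
(P4-P3-P2-P1-P1'-P2'-P3'-P4').  Conservation of a human cleavage site across
vertebrates is summarised here at two levels:

* corpus-wide distributions — which residue sits at P1 in ortholog hits, and
  how many positions of the octamer differ from the human motif (Hamming
  distance, 0..8);
* per-target aggregates (:class:`TargetMetrics`) — the median octamer Hamming
  distance over D-cut orthologs, the fraction of the species universe with a
  hit, and the vertebrate classes covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 20 standard amino acids.  Anything else (gaps, X/B/Z/U ambiguity
#: codes) never matches in Hamming comparisons, not even itself.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Display categories for non-residue characters in distribution tables.
_CATEGORY_OF = {"-": "Gap", "X": "Unknown", "B": "D_or_N", "Z": "E_or_Q"}


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length residue strings.

    A position matches only when both characters are identical *and* are one
    of the 20 standard residues; gaps and ambiguity codes always mismatch,
    including against an identical character ('X' vs 'X' counts as differing
    because the underlying residues are unknown).

    Raises
    ------
    ValueError
        If the strings differ in length.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(
        0 if (x == y and x in STANDARD_AA) else 1 for x, y in zip(a, b)
    )


def p1_category(ch: str) -> str:
    """Map a P1 character to its distribution category.

    Standard residues map to themselves; '-' -> 'Gap', 'X' -> 'Unknown',
    'B' -> 'D_or_N', 'Z' -> 'E_or_Q'; anything else -> 'Unknown'.
    """
    if ch in STANDARD_AA:
        return ch
    return _CATEGORY_OF.get(ch, "Unknown")


def distribution_from_counts(counts: pd.Series | dict) -> pd.DataFrame:
    """Turn a category -> count mapping into a count/percent table.

    Percentages are of the grand total, rounded to two decimals in the
    ``percent`` column (the unrounded value is kept in ``percent_raw``).
    """
    s = pd.Series(counts, dtype="int64")
    total = int(s.sum())
    if total == 0:
        raise ValueError("empty distribution")
    out = pd.DataFrame({"count": s})
    out["percent_raw"] = 100.0 * out["count"] / total
    out["percent"] = out["percent_raw"].round(2)
    out.index.name = "category"
    return out.sort_values("count", ascending=False)


def p1_distribution(hits: pd.DataFrame) -> pd.DataFrame:
    """Distribution of the residue found at the anchored P1 position.

    ``hits`` must carry a ``p1_residue`` column (one character per best-hit
    ortholog).  Gap and ambiguity characters are counted in their own
    categories.
    """
    cats = hits["p1_residue"].map(p1_category)
    return distribution_from_counts(cats.value_counts())


def hd_distribution(hits: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate hits by P1-aspartate retention and octamer distance.

    Returns a table indexed by ``(p1_is_d, hd)`` with counts and percents of
    the grand total, mirroring the census layout.
    """
    df = pd.DataFrame(
        {
            "p1_is_d": hits["p1_residue"] == "D",
            "hd": hits["octamer_hd"].astype(int),
        }
    )
    counts = df.value_counts(["p1_is_d", "hd"]).sort_index()
    return hd_distribution_from_counts(counts)


def hd_distribution_from_counts(counts: pd.Series) -> pd.DataFrame:
    """Percent table from a ``(p1_is_d, hd) -> count`` series."""
    total = int(counts.sum())
    if total == 0:
        raise ValueError("empty distribution")
    out = counts.to_frame("count")
    out["percent_raw"] = 100.0 * out["count"] / total
    out["percent"] = out["percent_raw"].round(2)
    return out


@dataclass
class TargetMetrics:
    """Per-site aggregate used by the selection filter.

    ``median_hd`` is the median octamer Hamming distance over ortholog hits
    that retain aspartate at P1 (NaN when no such hit exists — the site then
    cannot pass selection).  ``pct_species`` is 100 * n_species / |universe|.
    Structure, hydrophobicity and N-degron summaries are filled by their
    modules and default to NaN.
    """

    site_id: str
    n_species: int = 0
    pct_species: float = float("nan")
    median_hd: float = float("nan")
    classes_present: frozenset = field(default_factory=frozenset)
    p1_d_fraction: float = float("nan")
    coil_prevalence: float = float("nan")
    hydro_prevalence_median: float = float("nan")
    destab_fraction: float = float("nan")


def target_conservation(
    site_id: str,
    hits: pd.DataFrame,
    species_universe: set,
    lineage: pd.DataFrame | None = None,
) -> TargetMetrics:
    """Conservation summary for one site from its best-per-species hits.

    ``hits`` are the annotated best hits for this site only.  The median HD
    uses only hits with 'D' at P1; species and class coverage use all hits
    (presence of an ortholog does not require P1 retention).  Hits whose
    taxon is absent from ``lineage`` count toward species coverage but not
    class coverage.
    """
    sub = hits[hits["site_id"] == site_id] if "site_id" in hits else hits
    n_species = int(sub["taxon_id"].nunique())
    pct = 100.0 * n_species / len(species_universe) if species_universe else float("nan")
    d_hits = sub[sub["p1_residue"] == "D"]
    median_hd = float(np.median(d_hits["octamer_hd"])) if len(d_hits) else float("nan")
    p1_d_fraction = len(d_hits) / len(sub) if len(sub) else float("nan")
    if "class_label" in sub:
        classes = frozenset(
            c for c in sub["class_label"].dropna().unique() if c != "unclassified"
        )
    elif lineage is not None:
        merged = sub.merge(lineage, on="taxon_id", how="inner")
        classes = frozenset(merged["class_label"].dropna().unique())
    else:
        classes = frozenset()
    return TargetMetrics(
        site_id=site_id,
        n_species=n_species,
        pct_species=pct,
        median_hd=median_hd,
        classes_present=classes,
        p1_d_fraction=p1_d_fraction,
    )
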