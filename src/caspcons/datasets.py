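"""Loaders for the small reference datasets shipped with the package.

The census tables summarise a published survey of vertebrate orthologs of
human apoptotic caspase cleavage sites (328 species with well-represented
proteomes, ~610k best-per-species hits): residue counts at P1, octamer
Hamming distances stratified by P1 aspartate retention, P1' residue counts
for human sites and vertebrate hits, and the single-criterion validation
counts for the 24-site reference set of proven proapoptotic targets.
They serve as fixed inputs for desk-checking the distribution and
validation arithmetic; the pipeline itself recomputes all of these
quantities from raw hit tables.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("caspcons.data") / "census" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def p1_census() -> pd.Series:
    """P1 category -> hit count over the vertebrate ortholog census."""
    df = _read("p1_counts.tsv", dtype={"category": str})
    return df.set_index("category")["count"]


def hd_census() -> pd.Series:
    """(p1_is_d, hd) -> hit count over the vertebrate ortholog census."""
    df = _read("hd_counts.tsv")
    df["p1_is_d"] = df["p1_is_d"].astype(bool)
    return df.set_index(["p1_is_d", "hd"])["count"]


def p1prime_census() -> pd.DataFrame:
    """Per-residue P1' counts (human and vertebrate) with N-degron nature."""
    return _read("p1prime_counts.tsv", dtype={"residue": str}).set_index("residue")


def reference_validation_census() -> pd.DataFrame:
    """Single-criterion pass counts for all targets and the reference set."""
    return _read("reference_validation_counts.tsv").set_index("criterion")
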