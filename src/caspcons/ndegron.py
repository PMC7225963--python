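"""Arg/N-degron fate of the P1' residue.

Caspase cleavage exposes the P1' residue as the nascent N-terminus of the
C-terminal fragment.  If that residue is recognised by the Arg/N-degron
pathway — directly (R, K, H, L, F, Y, W, I), after ATE1 arginylation
(D, E, C), or after deamidation then arginylation (N, Q) — the fragment is
destabilizing-tagged and subject to fast degradation.  G, S, A, T, V, M and
P are not recognised and count as stabilizing here (Nt-acetylation-dependent
fates are out of scope).  Conservation of a destabilizing P1' across
orthologs marks fragments whose turnover is likely regulatory.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .conservation import distribution_from_counts


def _load_table() -> pd.DataFrame:
    ref = resources.files("caspcons.data") / "ndegron_classes.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    natures = df.set_index("residue")["nature"]
    assert len(natures) == 20 and set(natures.index) == set("ACDEFGHIKLMNPQRSTVWY"), (
        "N-degron table must cover exactly the 20 standard residues"
    )
    assert set(natures.unique()) == {"stabilizing", "destabilizing"}
    return df


_TABLE = _load_table()
NATURE: dict[str, str] = _TABLE.set_index("residue")["nature"].to_dict()
MECHANISM: dict[str, str] = _TABLE.set_index("residue")["mechanism"].to_dict()
DESTABILIZING = frozenset(r for r, n in NATURE.items() if n == "destabilizing")
STABILIZING = frozenset(r for r, n in NATURE.items() if n == "stabilizing")


def classify_p1prime(residue: str) -> str:
    """'stabilizing' / 'destabilizing' per the Arg/N-degron table.

    Gaps and ambiguity codes return 'undefined'.
    """
    return NATURE.get(residue, "undefined")


def destab_fraction(hits) -> float:
    """Fraction of destabilizing P1' natures among hits with a defined one.

    ``hits`` is a DataFrame with a ``p1prime_nature`` column or any iterable
    of nature labels.  Undefined natures (gap/ambiguity at P1') are excluded
    from the denominator; NaN is returned when nothing is defined.
    """
    if isinstance(hits, pd.DataFrame):
        natures = hits["p1prime_nature"]
    else:
        natures = pd.Series(list(hits), dtype=object)
    defined = natures[natures.isin(["stabilizing", "destabilizing"])]
    if defined.empty:
        return float("nan")
    return float((defined == "destabilizing").mean())


def p1prime_distribution(hits) -> pd.DataFrame:
    """Per-residue counts and percents at P1', with nature annotations.

    ``hits`` is a DataFrame with ``p1prime_residue`` or an iterable of
    characters.  Non-standard characters are pooled under 'undefined'.
    """
    if isinstance(hits, pd.DataFrame):
        residues = hits["p1prime_residue"]
    else:
        residues = pd.Series(list(hits), dtype=object)
    cats = residues.map(lambda r: r if r in NATURE else "undefined")
    out = distribution_from_counts(cats.value_counts())
    out["nature"] = [NATURE.get(r, "undefined") for r in out.index]
    return out


def nature_subtotals(dist: pd.DataFrame) -> pd.DataFrame:
    """Stabilizing / destabilizing / undefined subtotals of a distribution."""
    g = dist.groupby("nature")[["count"]].sum()
    g["percent"] = (100.0 * g["count"] / g["count"].sum()).round(2)
    return g
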