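"""Coil prevalence of the cleavage-site region from Q3 strings.

Caspases cleave in extended conformations, so cleavage sites sit mostly in
coils, and preferentially in a coiled loop *between* structured flanks.
Given a three-state secondary-structure string (H = helix, E = strand,
C = coil) aligned 1:1 with the 60-residue query window, the coil prevalence

    prevalence = 2 c / (l + r)

compares the percentage of coil in the central 20 residues (``c``, P1 at
position 10 of the block) with the left and right 20-residue flanks
(``l``, ``r``).  Values above 1 mark sites whose immediate surroundings are
more coiled than their context.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

_Q3 = {"H", "E", "C"}
FULL_LEN = 60
_BLOCKS = ((0, 20), (20, 40), (40, 60))  # left, central, right


def _block_coil_percent(q3: str, frame_start: int, lo: int, hi: int) -> float | None:
    """Percent coil in window-frame positions [lo, hi); None if empty.

    ``frame_start`` maps string index i to frame position frame_start + i,
    so truncated windows renormalise by the residues actually present.
    """
    chars = [
        ch
        for i, ch in enumerate(q3)
        if lo <= frame_start + i < hi
    ]
    if not chars:
        return None
    return 100.0 * sum(ch == "C" for ch in chars) / len(chars)


def coil_prevalence(q3: str, p1_index: int = 29) -> float:
    """Coil prevalence 2c/(l+r) of a Q3 string.

    ``p1_index`` is the 0-based position of P1 in the string; for truncated
    windows it places the string within the canonical 60-position frame and
    each 20-position block is renormalised by its actual length.  Flank
    blocks with no residues are ignored; if both are empty the prevalence is
    undefined (NaN).  Fully structured flanks (l + r = 0) with a coiled
    centre return +inf — such sites pass any ">1" threshold; with c = 0 the
    prevalence is 1 (no contrast).
    """
    bad = set(q3) - _Q3
    if bad:
        raise ValueError(f"non-Q3 characters: {sorted(bad)}")
    frame_start = 29 - p1_index
    (l_lo, l_hi), (c_lo, c_hi), (r_lo, r_hi) = _BLOCKS
    c = _block_coil_percent(q3, frame_start, c_lo, c_hi)
    l = _block_coil_percent(q3, frame_start, l_lo, l_hi)
    r = _block_coil_percent(q3, frame_start, r_lo, r_hi)
    if c is None:
        return float("nan")
    flanks = [x for x in (l, r) if x is not None]
    if not flanks:
        return float("nan")
    flank_mean = sum(flanks) / len(flanks)
    if flank_mean == 0.0:
        return math.inf if c > 0 else 1.0
    return c / flank_mean


def structure_frequency_matrix(
    profiles: list[str], span: tuple[int, int] = (0, FULL_LEN)
) -> pd.DataFrame:
    """Per-position H/E/C frequencies over equal-length Q3 strings.

    ``span`` selects 0-based window positions [start, stop).  Column
    frequencies sum to 1 at every position.
    """
    start, stop = span
    if not profiles:
        raise ValueError("no profiles")
    rows = []
    for pos in range(start, stop):
        col = [p[pos] for p in profiles]
        n = len(col)
        rows.append(
            {
                "position": pos + 1,
                "H": col.count("H") / n,
                "E": col.count("E") / n,
                "C": col.count("C") / n,
            }
        )
    return pd.DataFrame(rows).set_index("position")


def read_q3_table(path: str | Path) -> pd.DataFrame:
    """Read a (site_id, q3) table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"site_id": str, "q3": str})
    missing = {"site_id", "q3"} - set(df.columns)
    if missing:
        raise ValueError(f"Q3 table missing columns: {sorted(missing)}")
    return df
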