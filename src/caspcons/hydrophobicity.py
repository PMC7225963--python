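"""Hydrophobicity of the cleavage-site region.

Residues are scored by the free energy of transferring their side chain
from cyclohexane to water (kcal/mol, pH 7): negative values are hydrophilic,
positive hydrophobic.  The scale spans polyarginine-20 (-298.4, hydrophilic
limit) to polyisoleucine-20 (98.4, hydrophobic limit), with glycine (0.94)
closest to the scale median (0.4).

Cleavage sites on protein surfaces sit in hydrophilic stretches.  Two
statistics capture this:

* ``hydro_sum`` — the summed index over the central 20 residues around P1;
* ``hydro_prevalence`` — the centre-over-flanks ratio of block sums, after
  a corpus-wide positivity shift

      shift = |min over the corpus of all (l+r)/2 and c block values| + 1

  so the ratio (c + shift) / ((l+r)/2 + shift) is well defined; values
  below 1 mean the cleavage region is more hydrophilic than its flanks.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_BLOCKS = ((0, 20), (20, 40), (40, 60))  # left, central, right in window frame
BLOCK_LEN = 20


def load_scale() -> dict[str, float]:
    """The packaged cyclohexane->water scale, validated at load.

    Validation pins the published anchors: Arg -14.92, Ile 4.92, Gly 0.94,
    and the 20-value median 0.4.
    """
    ref = resources.files("caspcons.data") / "hydrophobicity_cyclohexane_water.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    scale = df.set_index("residue")["dg_kcal_mol"].astype(float).to_dict()
    if set(scale) != set("ACDEFGHIKLMNPQRSTVWY"):
        raise ValueError("scale must cover exactly the 20 standard residues")
    anchors = {"R": -14.92, "I": 4.92, "G": 0.94}
    for res, expect in anchors.items():
        if abs(scale[res] - expect) > 1e-9:
            raise ValueError(f"scale anchor mismatch for {res}: {scale[res]}")
    if abs(float(np.median(list(scale.values()))) - 0.4) > 1e-9:
        raise ValueError("scale median must be 0.4")
    return scale


_SCALE = load_scale()
SCALE_MEDIAN = float(np.median(list(_SCALE.values())))


def hydro_sum(segment: str, scale: Mapping[str, float] | None = None) -> float:
    """Sum of per-residue indices over a segment (kcal/mol).

    Gap and ambiguity characters contribute the scale median (logged), so a
    partially gapped ortholog window still scores without biasing either
    direction.
    """
    if not segment:
        raise ValueError("empty segment")
    scale = _SCALE if scale is None else scale
    total = 0.0
    for ch in segment:
        if ch in scale:
            total += scale[ch]
        else:
            logger.debug("non-scale character %r scored at scale median", ch)
            total += SCALE_MEDIAN
    return total


def block_values(
    window: str, p1_index: int = 29, scale: Mapping[str, float] | None = None
) -> tuple[float, float]:
    """(flank_mean, central) block sums of a window, in the 60-frame.

    Truncated blocks are rescaled to a 20-residue equivalent (sum * 20/n) so
    sites near a terminus remain comparable; a block with no residues is
    NaN, and the flank mean uses whichever flanks exist.
    """
    frame_start = 29 - p1_index
    sums = []
    for lo, hi in _BLOCKS:
        chars = [ch for i, ch in enumerate(window) if lo <= frame_start + i < hi]
        if not chars:
            sums.append(float("nan"))
        else:
            sums.append(hydro_sum("".join(chars), scale) * BLOCK_LEN / len(chars))
    l, c, r = sums
    flanks = [x for x in (l, r) if not np.isnan(x)]
    flank_mean = sum(flanks) / len(flanks) if flanks else float("nan")
    return flank_mean, c


def hydro_shift(pairs: Iterable[tuple[float, float]]) -> float:
    """Positivity shift from all corpus (flank_mean, central) pairs.

    shift = |minimum over every value in the corpus| + 1; adding it makes
    every shifted block value at least 1.
    """
    values = [v for pair in pairs for v in pair if not np.isnan(v)]
    if not values:
        raise ValueError("empty corpus")
    return abs(min(values)) + 1.0


def hydro_prevalence(
    window: str,
    shift: float,
    p1_index: int = 29,
    scale: Mapping[str, float] | None = None,
) -> float:
    """Centre-over-flanks hydrophobicity ratio after the corpus shift.

    Returns (c + shift) / (flank_mean + shift); NaN when the central block
    or both flanks are missing.  Values < 1: the cleavage region is more
    hydrophilic than its flanks.
    """
    flank_mean, c = block_values(window, p1_index, scale)
    if np.isnan(c) or np.isnan(flank_mean):
        return float("nan")
    return (c + shift) / (flank_mean + shift)


def hydro_rate_correlation(
    sums: Iterable[float], rates: Iterable[float]
) -> tuple[float, float]:
    """Kendall tau-b between per-site hydrophobicity sums and cleavage rates.

    Tie-corrected (tau-b) with a two-sided p-value; hydrophilic sites being
    cut faster shows up as a negative tau.  Requires at least 3 pairs;
    constant input yields (nan, nan).
    """
    x = np.asarray(list(sums), dtype=float)
    y = np.asarray(list(rates), dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input: correlation undefined")
        return float("nan"), float("nan")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)
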