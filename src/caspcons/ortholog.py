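"""Ortholog hit processing: species filter, best hit, Hamming anchoring.

Ortholog hits come from a protein-BLAST-style tabular file (one row per hit:
query site id, subject taxon, e-value, subject segment, optionally the
aligned query/subject strings).  Processing follows three steps:

1. keep only species with a well-represented proteome (strictly more than
   8000 annotated proteins by default) — sparse proteomes produce false
   negatives in ortholog counts;
2. keep one hit per (site, species): the best e-value, deterministically
   tie-broken;
3. locate the cleavage site inside the subject segment by sliding the human
   60-residue window over every offset and minimising the Hamming distance
   — cheaper than alignment, with the P1 aspartate acting as the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .conservation import STANDARD_AA, hamming
from .ndegron import classify_p1prime
from .sites import CleavageSite

DEFAULT_EVALUE_CUTOFF = 1e-16
DEFAULT_PROTEOME_THRESHOLD = 8000

_STD_BYTES = np.zeros(256, dtype=bool)
for _aa in STANDARD_AA:
    _STD_BYTES[ord(_aa)] = True


@dataclass(frozen=True)
class OrthologHit:
    """One species' best match to a human cleavage site, anchored.

    ``anchor_offset`` is the 0-based offset of the human window within the
    subject segment (negative when the subject starts inside the window).
    ``anchored_window`` has the human window's length, '-'-padded where the
    subject does not reach.
    """

    site_id: str
    taxon_id: int
    species_name: str
    class_label: str
    evalue: float
    subject_segment: str
    anchor_offset: int
    anchored_window: str
    p1_residue: str
    ortho_octamer: str
    octamer_hd: int
    p1prime_residue: str
    p1prime_nature: str


def filter_species(
    proteome_sizes: Mapping[int, int] | pd.DataFrame,
    threshold: int = DEFAULT_PROTEOME_THRESHOLD,
) -> set[int]:
    """Taxa with strictly more than ``threshold`` annotated proteins."""
    if isinstance(proteome_sizes, pd.DataFrame):
        items = zip(proteome_sizes["taxon_id"], proteome_sizes["n_proteins"])
    else:
        items = proteome_sizes.items()
    out = set()
    for taxon, count in items:
        if count < 0:
            raise ValueError(f"negative protein count for taxon {taxon}")
        if count > threshold:
            out.add(int(taxon))
    return out


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a BLAST-outfmt-6-like hit table (TSV with header).

    Required columns: site_id, taxon_id, evalue, sseq; optional qseq for
    gapped (pre-aligned) input.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"site_id": str, "sseq": str})
    required = {"site_id", "taxon_id", "evalue", "sseq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    df["taxon_id"] = df["taxon_id"].astype(int)
    return df


def best_hit_per_species(
    hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> pd.DataFrame:
    """One hit per (site_id, taxon_id): minimal e-value below the cut-off.

    E-value ties break on longer subject segment, then lexicographically
    smallest segment, so the result is independent of input row order.
    """
    kept = hits[hits["evalue"] <= evalue_cutoff].copy()
    if kept.empty:
        return kept
    kept["_len"] = -kept["sseq"].str.len()
    kept = kept.sort_values(
        ["site_id", "taxon_id", "evalue", "_len", "sseq"], kind="mergesort"
    )
    best = kept.drop_duplicates(["site_id", "taxon_id"], keep="first")
    return best.drop(columns="_len").reset_index(drop=True)


def anchor_p1(
    human_window: str, subject_segment: str, p1_index: int = 29
) -> tuple[int, str, str]:
    """Slide the human window over the subject; keep the min-Hamming offset.

    Every placement with at least one overlapping character is scored;
    subject positions missing under a placement count as '-' (mismatch).
    Ties prefer an offset putting 'D' under the window's P1 position
    (``p1_index``, 0-based), then the leftmost offset.

    Returns ``(anchor_offset, anchored_window, p1_residue)``.
    """
    if not subject_segment:
        raise ValueError("empty subject segment")
    w = np.frombuffer(human_window.encode("ascii"), dtype=np.uint8)
    s = np.frombuffer(subject_segment.encode("ascii"), dtype=np.uint8)
    W, S = len(w), len(s)
    pad = np.full(W - 1, ord("-"), dtype=np.uint8)
    padded = np.concatenate([pad, s, pad])
    # row o of this view = subject chars under window placed at offset o-(W-1)
    views = np.lib.stride_tricks.sliding_window_view(padded, W)
    match = (views == w) & _STD_BYTES[views]
    hd = W - match.sum(axis=1)
    best = hd.min()
    candidates = np.flatnonzero(hd == best)
    with_d = candidates[views[candidates, p1_index] == ord("D")]
    row = int(with_d[0] if len(with_d) else candidates[0])
    offset = row - (W - 1)
    anchored = views[row].tobytes().decode("ascii")
    return offset, anchored, anchored[p1_index]


def project_alignment(qseq: str, sseq: str) -> str:
    """Subject characters mapped onto ungapped query positions.

    For pre-aligned BLAST strings: columns where the query has '-'
    (insertions in the subject) are skipped; deletion columns keep their
    '-' so gaps land in the gap category downstream.
    """
    if len(qseq) != len(sseq):
        raise ValueError("aligned strings differ in length")
    return "".join(s for q, s in zip(qseq, sseq) if q != "-")


def _pad_slice(text: str, start: int, stop: int) -> str:
    left = "-" * max(0, -start)
    right = "-" * max(0, stop - len(text))
    return left + text[max(0, start) : min(len(text), stop)] + right


def annotate_hit(
    site: CleavageSite,
    hit: Mapping,
    lineage: Mapping[int, tuple[str, str]],
) -> OrthologHit:
    """Anchor one raw hit and fill octamer distance, P1/P1' and class.

    ``lineage`` maps taxon_id -> (species_name, class_label); missing taxa
    are flagged "unclassified" (excluded from class coverage only).  When
    the hit carries an aligned query string (``qseq``), gap columns are
    honoured instead of running the Hamming scan.
    """
    sseq = hit["sseq"]
    qseq = hit.get("qseq") if hasattr(hit, "get") else None
    if isinstance(qseq, str) and "-" in qseq + sseq and len(project_alignment(qseq, sseq)) == len(site.window):
        anchored = project_alignment(qseq, sseq)
        offset = 0
        p1_residue = anchored[site.p1_index]
    else:
        offset, anchored, p1_residue = anchor_p1(site.window, sseq, site.p1_index)
    i = site.p1_index
    ortho_octamer = _pad_slice(anchored, i - 3, i + 5)
    p1prime = anchored[i + 1] if i + 1 < len(anchored) else "-"
    taxon = int(hit["taxon_id"])
    species, class_label = lineage.get(taxon, (f"taxon_{taxon}", "unclassified"))
    return OrthologHit(
        site_id=site.site_id,
        taxon_id=taxon,
        species_name=species,
        class_label=class_label,
        evalue=float(hit["evalue"]),
        subject_segment=sseq,
        anchor_offset=offset,
        anchored_window=anchored,
        p1_residue=p1_residue,
        ortho_octamer=ortho_octamer,
        octamer_hd=hamming(site.octamer, ortho_octamer),
        p1prime_residue=p1prime,
        p1prime_nature=classify_p1prime(p1prime),
    )


def lineage_map(lineage: pd.DataFrame) -> dict[int, tuple[str, str]]:
    """taxon_id -> (species_name, class_label) from a lineage table."""
    return {
        int(r.taxon_id): (str(r.species_name), str(r.class_label))
        for r in lineage.itertuples(index=False)
    }


def annotate_hits(
    sites: list[CleavageSite],
    hits: pd.DataFrame,
    lineage: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate best-per-species hits for all sites; returns one row per hit."""
    lmap = lineage_map(lineage)
    by_id = {s.site_id: s for s in sites}
    rows = []
    for hit in hits.to_dict("records"):
        site = by_id.get(str(hit["site_id"]))
        if site is None:
            continue
        rows.append(annotate_hit(site, hit, lmap).__dict__)
    cols = [f.name for f in OrthologHit.__dataclass_fields__.values()]
    return pd.DataFrame(rows, columns=cols)
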