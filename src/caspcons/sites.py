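"""Curation of the human caspase cleavage-site catalogue.

The catalogue is a tab-separated table (site_id, accession, gene, p1_pos)
referencing protein sequences in a FASTA file.  Curation keeps only sites
whose P1 residue is aspartate, collapses duplicate (accession, p1_pos) rows,
and drops rows whose accession is missing or whose position is out of
bounds, recording a reason for every dropped row.

Each retained site carries its octamer (P4..P4') and a query window of the
octamer plus 26 flanking residues on each side — 60 residues when the site
is far enough from both termini, truncated otherwise (the start offset
records the truncation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

WINDOW_LEFT = 29   # residues before P1 in a full window
WINDOW_RIGHT = 30  # residues after P1 in a full window
WINDOW_LEN = WINDOW_LEFT + 1 + WINDOW_RIGHT  # 60


@dataclass(frozen=True)
class CleavageSite:
    """One human caspase cut: P1 position, octamer and query window.

    ``p1_pos`` is 1-based in the full protein.  ``window_start`` is the
    1-based protein position of the first window residue, so the 0-based
    index of P1 inside the window is ``p1_pos - window_start`` (29 for a
    full 60-mer).  Octamers at a terminus are '-'-padded to 8 characters.
    """

    site_id: str
    accession: str
    gene: str
    p1_pos: int
    octamer: str
    window: str
    window_start: int

    @property
    def p1_index(self) -> int:
        """0-based index of P1 within the window."""
        return self.p1_pos - self.window_start

    @property
    def is_full_window(self) -> bool:
        return len(self.window) == WINDOW_LEN


def extract_window(sequence: str, p1_pos: int) -> tuple[str, int]:
    """Query window around P1: protein span [p1_pos-29, p1_pos+30], clipped.

    Returns the window string and its 1-based start position.  Full-length
    windows are exactly 60 residues with P1 at window position 30 (1-based).

    Raises
    ------
    ValueError
        If ``p1_pos`` is outside the sequence.
    """
    if not 1 <= p1_pos <= len(sequence):
        raise ValueError(f"p1_pos {p1_pos} out of range 1..{len(sequence)}")
    start = max(1, p1_pos - WINDOW_LEFT)
    end = min(len(sequence), p1_pos + WINDOW_RIGHT)
    return sequence[start - 1 : end], start


def extract_octamer(sequence: str, p1_pos: int) -> str:
    """P4..P4' octamer around P1, '-'-padded at the termini."""
    left = "-" * max(0, 4 - p1_pos)
    right = "-" * max(0, p1_pos + 4 - len(sequence))
    core = sequence[max(0, p1_pos - 4) : min(len(sequence), p1_pos + 4)]
    return left + core + right


def read_catalogue(path: str | Path) -> pd.DataFrame:
    """Read the cleavage-site catalogue (TSV with header)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"site_id": str, "accession": str})
    required = {"site_id", "accession", "gene", "p1_pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalogue missing columns: {sorted(missing)}")
    df["p1_pos"] = df["p1_pos"].astype(int)
    return df


def read_proteome(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA, keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_sites(
    catalogue: str | Path | pd.DataFrame,
    proteome: str | Path | dict,
    exclude_accessions: set[str] | None = None,
) -> tuple[list[CleavageSite], pd.DataFrame]:
    """Load and curate the catalogue against the proteome.

    Rules applied per row, in order:

    1. accession on the exclusion list (obsolete/readthrough ids) -> dropped;
    2. accession absent from the FASTA -> dropped;
    3. ``p1_pos`` outside the sequence -> dropped;
    4. residue at ``p1_pos`` not 'D' -> dropped ("non-D P1");
    5. duplicate (accession, p1_pos) -> collapsed to the first occurrence.

    Returns the curated site list and a per-row curation report
    (site_id, accession, p1_pos, status, reason) whose kept rows match the
    site list one-to-one.  Re-running on the kept rows is idempotent.
    """
    cat = catalogue if isinstance(catalogue, pd.DataFrame) else read_catalogue(catalogue)
    seqs = proteome if isinstance(proteome, dict) else read_proteome(proteome)
    excluded = exclude_accessions or set()

    sites: list[CleavageSite] = []
    report_rows = []
    seen: set[tuple[str, int]] = set()
    for row in cat.itertuples(index=False):
        status, reason = "kept", ""
        acc, pos = row.accession, int(row.p1_pos)
        if acc in excluded:
            status, reason = "dropped", "excluded accession"
        elif acc not in seqs:
            status, reason = "dropped", "accession not in FASTA"
        elif not 1 <= pos <= len(seqs[acc]):
            status, reason = "dropped", "p1_pos out of bounds"
        elif seqs[acc][pos - 1] != "D":
            status, reason = "dropped", "non-D P1"
        elif (acc, pos) in seen:
            status, reason = "dropped", "duplicate"
        if status == "kept":
            seen.add((acc, pos))
            seq = seqs[acc]
            window, start = extract_window(seq, pos)
            sites.append(
                CleavageSite(
                    site_id=str(row.site_id),
                    accession=acc,
                    gene=str(row.gene),
                    p1_pos=pos,
                    octamer=extract_octamer(seq, pos),
                    window=window,
                    window_start=start,
                )
            )
        report_rows.append(
            {
                "site_id": str(row.site_id),
                "accession": acc,
                "p1_pos": pos,
                "status": status,
                "reason": reason,
            }
        )
    report = pd.DataFrame(
        report_rows, columns=["site_id", "accession", "p1_pos", "status", "reason"]
    )
    return sites, report


def sites_to_frame(sites: list[CleavageSite]) -> pd.DataFrame:
    """Tabular view of curated sites (one row per site)."""
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "accession": [s.accession for s in sites],
            "gene": [s.gene for s in sites],
            "p1_pos": [s.p1_pos for s in sites],
            "octamer": [s.octamer for s in sites],
            "window": [s.window for s in sites],
            "window_start": [s.window_start for s in sites],
        }
    )
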