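"""End-to-end orchestration: catalogue -> annotated hits -> metrics -> selection.

``run_pipeline`` wires the stage modules together and writes every
intermediate table, so a run is fully auditable: curation report, annotated
hit table, P1 / Hamming-distance / P1' distributions, per-target metrics,
the selection pass/fail matrix and, when a reference set is configured, the
validation table.  All tabular output is tab-separated with headers and
deterministic row order; reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation, hydrophobicity, ndegron, ortholog, sites, structure
from .selection import SelectionConfig, apply_criteria, validate_reference

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input paths and thresholds for one pipeline run."""

    catalogue: Path
    fasta: Path
    hits: Path
    lineage: Path
    proteome_sizes: Path
    q3: Path | None = None
    outdir: Path = Path("pipeline_out")
    evalue_cutoff: float = ortholog.DEFAULT_EVALUE_CUTOFF
    proteome_threshold: int = ortholog.DEFAULT_PROTEOME_THRESHOLD
    selection: SelectionConfig = field(default_factory=SelectionConfig)

    def validate_paths(self) -> None:
        for name in ("catalogue", "fasta", "hits", "lineage", "proteome_sizes", "q3"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def compute_metrics(
    site_list: list[sites.CleavageSite],
    annotated: pd.DataFrame,
    universe: set[int],
    q3_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site TargetMetrics table from annotated best-per-species hits.

    The hydrophobicity positivity shift is computed once over all ortholog
    windows in this corpus, then applied per hit; the per-site statistic is
    the median prevalence over the site's hits (the human window's own
    prevalence is reported alongside).
    """
    scale = hydrophobicity.load_scale()
    q3_of = (
        {}
        if q3_table is None
        else dict(zip(q3_table["site_id"].astype(str), q3_table["q3"]))
    )
    p1_index_of = {s.site_id: s.p1_index for s in site_list}

    pair_cols = []
    for hit in annotated.itertuples(index=False):
        idx = p1_index_of.get(hit.site_id, 29)
        pair_cols.append(hydrophobicity.block_values(hit.anchored_window, idx, scale))
    shift = hydrophobicity.hydro_shift(pair_cols) if pair_cols else float("nan")

    rows = []
    for s in site_list:
        sub = annotated[annotated["site_id"] == s.site_id]
        tm = conservation.target_conservation(s.site_id, sub, universe)
        tm.destab_fraction = ndegron.destab_fraction(sub) if len(sub) else float("nan")
        if s.site_id in q3_of:
            tm.coil_prevalence = structure.coil_prevalence(q3_of[s.site_id], s.p1_index)
        prevs = [
            hydrophobicity.hydro_prevalence(w, shift, p1_index_of[s.site_id], scale)
            for w in sub["anchored_window"]
        ]
        prevs = [p for p in prevs if not np.isnan(p)]
        tm.hydro_prevalence_median = float(np.median(prevs)) if prevs else float("nan")
        row = tm.__dict__.copy()
        row["hydro_prevalence_human"] = hydrophobicity.hydro_prevalence(
            s.window, shift, s.p1_index, scale
        )
        row["hydro_shift"] = shift
        rows.append(row)
    return pd.DataFrame(rows)


def write_metrics(metrics: pd.DataFrame, path: Path) -> None:
    """Serialize metrics (classes_present as a comma-joined sorted list)."""
    out = metrics.copy()
    out["classes_present"] = out["classes_present"].map(
        lambda cs: ",".join(sorted(cs))
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_metrics(path: Path) -> pd.DataFrame:
    """Read a metrics table written by :func:`write_metrics`."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    df["classes_present"] = df["classes_present"].map(
        lambda s: frozenset() if pd.isna(s) or s == "" else frozenset(str(s).split(","))
    )
    return df


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute every stage and write the output bundle under ``config.outdir``."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    site_list, curation = sites.load_sites(config.catalogue, config.fasta)
    logger.info("curated %d sites (%d rows dropped)",
                len(site_list), int((curation["status"] == "dropped").sum()))

    proteome_sizes = pd.read_csv(config.proteome_sizes, sep="\t", comment="#")
    universe = ortholog.filter_species(proteome_sizes, config.proteome_threshold)
    lineage = pd.read_csv(config.lineage, sep="\t", comment="#")

    raw_hits = ortholog.read_hit_table(config.hits)
    raw_hits = raw_hits[raw_hits["taxon_id"].isin(universe)]
    best = ortholog.best_hit_per_species(raw_hits, config.evalue_cutoff)
    annotated = ortholog.annotate_hits(site_list, best, lineage)
    if annotated.empty:
        logger.warning("no hits survive the species and e-value filters")

    outputs: dict[str, pd.DataFrame] = {
        "curation_report": curation,
        "sites": sites.sites_to_frame(site_list),
        "annotated_hits": annotated,
    }
    if len(annotated):
        outputs["p1_distribution"] = conservation.p1_distribution(annotated)
        outputs["hd_distribution"] = conservation.hd_distribution(annotated).reset_index()
        outputs["p1prime_distribution"] = ndegron.p1prime_distribution(annotated)

    q3_table = structure.read_q3_table(config.q3) if config.q3 else None
    metrics = compute_metrics(site_list, annotated, universe, q3_table)
    outputs["metrics"] = metrics

    if len(metrics):
        selected, matrix = apply_criteria(metrics, config.selection)
        outputs["selection_matrix"] = matrix
        outputs["selected"] = metrics[metrics["site_id"].isin(selected)]
        if config.selection.reference_site_ids:
            outputs["validation"] = validate_reference(
                metrics, config.selection
            ).reset_index()

    for name, df in outputs.items():
        path = outdir / f"{name}.tsv"
        if name == "metrics" or name == "selected":
            write_metrics(df, path)
        elif name in ("p1_distribution", "p1prime_distribution"):
            df.to_csv(path, sep="\t", float_format="%.6g")
        else:
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return outputs
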