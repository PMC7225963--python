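"""Five-criterion selection of conserved caspase targets.

A target passes when, over its vertebrate orthologs (all comparisons
strict):

1. median octamer Hamming distance among D-cut orthologs < 2;
2. coil prevalence of the human window > 1;
3. median hydrophobicity prevalence < 1;
4. orthologs found in > 96% of the species universe;
5. orthologs present in every vertebrate class.

A sixth criterion — destabilizing P1' nature in > 50% of orthologs — is
computed and reported in the validation table but disabled in selection by
default: only 4 of the 24 reference proapoptotic targets satisfy it, too
few to justify imposing it.

The reference set (24 cleavage sites in 11 proteins whose C-terminal
fragments have proven proapoptotic activity) calibrates the criteria:
``validate_reference`` reports, per single criterion, how many of all
targets and of the reference targets pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Vertebrate classes used for the every-class criterion.  The subphylum is
#: taken as seven classes; this enumeration is an explicit assumption and
#: is configurable.
DEFAULT_CLASSES = (
    "Mammalia",
    "Aves",
    "Reptilia",
    "Amphibia",
    "Actinopterygii",
    "Chondrichthyes",
    "Coelacanthimorpha",
)

#: Criterion key -> (metrics column, direction, config threshold attribute).
CRITERIA = {
    "median_hd": ("median_hd", "lt", "median_hd_max"),
    "coil_prevalence": ("coil_prevalence", "gt", "coil_prev_min"),
    "hydro_prevalence": ("hydro_prevalence_median", "lt", "hydro_prev_max"),
    "pct_species": ("pct_species", "gt", "pct_species_min"),
    "destab_fraction": ("destab_fraction", "gt", "destab_min"),
}


@dataclass
class SelectionConfig:
    """Thresholds of the selection filter (all strict inequalities)."""

    median_hd_max: float = 2.0
    coil_prev_min: float = 1.0
    hydro_prev_max: float = 1.0
    pct_species_min: float = 96.0
    require_all_classes: bool = True
    class_list: tuple[str, ...] = DEFAULT_CLASSES
    destab_min: float = 0.5
    use_destab: bool = False
    reference_site_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("median_hd_max", "coil_prev_min", "hydro_prev_max",
                     "pct_species_min", "destab_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.class_list:
            raise ValueError("class_list must be non-empty")


def _passes(values: pd.Series, direction: str, threshold: float) -> pd.Series:
    # NaN (undefined metric) fails its criterion in either direction
    if direction == "lt":
        return values < threshold
    return values > threshold


def criteria_matrix(metrics: pd.DataFrame, config: SelectionConfig) -> pd.DataFrame:
    """Per-site pass/fail verdict for every criterion (including disabled ones)."""
    out = pd.DataFrame(index=metrics.index)
    out["site_id"] = metrics["site_id"]
    for key, (col, direction, attr) in CRITERIA.items():
        out[key] = _passes(metrics[col], direction, getattr(config, attr))
    if config.require_all_classes:
        required = set(config.class_list)
        out["all_classes"] = metrics["classes_present"].map(
            lambda cs: required <= set(cs) if cs is not None else False
        )
    else:
        out["all_classes"] = True
    return out


def apply_criteria(
    metrics: pd.DataFrame, config: SelectionConfig | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Selected site ids and the full pass/fail matrix.

    Selection is the conjunction of the enabled criteria: median HD, coil
    prevalence, hydrophobicity prevalence, species coverage, class coverage,
    and (only when ``config.use_destab``) the P1' destabilization criterion.
    """
    config = config or SelectionConfig()
    matrix = criteria_matrix(metrics, config)
    enabled = ["median_hd", "coil_prevalence", "hydro_prevalence",
               "pct_species", "all_classes"]
    if config.use_destab:
        enabled.append("destab_fraction")
    matrix["selected"] = matrix[enabled].all(axis=1)
    selected = matrix.loc[matrix["selected"], "site_id"].tolist()
    return selected, matrix


#: Criteria reported in the validation table, in its column order.
VALIDATION_CRITERIA = ("median_hd", "coil_prevalence", "hydro_prevalence",
                       "destab_fraction")


def validate_reference(
    metrics: pd.DataFrame, config: SelectionConfig
) -> pd.DataFrame:
    """Single-criterion validation against the reference target set.

    For each of the four per-site criteria, counts and percentages of all
    targets and of the reference targets passing that criterion alone.
    Percentages are rounded to two decimals.

    Raises
    ------
    KeyError
        If a reference site id is absent from the metrics, listing the ids.
    """
    ref_ids = list(config.reference_site_ids)
    known = set(metrics["site_id"])
    missing = [r for r in ref_ids if r not in known]
    if missing:
        raise KeyError(f"reference site ids missing from metrics: {missing}")
    matrix = criteria_matrix(metrics, config)
    is_ref = matrix["site_id"].isin(ref_ids)
    rows = {}
    for key in VALIDATION_CRITERIA:
        n_all = int(matrix[key].sum())
        n_ref = int(matrix.loc[is_ref, key].sum())
        rows[key] = {
            "n_targets_pass": n_all,
            "n_reference_pass": n_ref,
            "pct_targets": round(100.0 * n_all / len(matrix), 2),
            "pct_reference": round(100.0 * n_ref / len(ref_ids), 2) if ref_ids else float("nan"),
        }
    return pd.DataFrame(rows).T.rename_axis("criterion")


def validation_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validation-table percentages from a published count table.

    ``counts`` has columns n_targets_pass, n_reference_pass, n_targets_total,
    n_reference_total indexed by criterion.
    """
    out = counts.copy()
    out["pct_targets"] = (100.0 * out["n_targets_pass"] / out["n_targets_total"]).round(2)
    out["pct_reference"] = (
        100.0 * out["n_reference_pass"] / out["n_reference_total"]
    ).round(2)
    return out
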