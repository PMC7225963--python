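"""Shared fixtures: tiny hand-built inputs and a small synthetic corpus."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from caspcons import pipeline, synthetic

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(RESIDUES[i] for i in rng.integers(0, 20, size=n))


@pytest.fixture(scope="session")
def rfc1_sequence():
    """A protein carrying the RFC1 cleavage octamer DEVDGMAG at P1=100."""
    rng = np.random.default_rng(42)
    seq = list(random_protein(rng, 200))
    seq[96:104] = "DEVDGMAG"  # P1 (the second D) at 1-based position 100
    return "".join(seq)


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic synthetic corpus (12 sites, 47 species)."""
    cfg = synthetic.SyntheticConfig(
        seed=5,
        n_sites=12,
        n_species_per_class={
            "Mammalia": 12,
            "Aves": 8,
            "Actinopterygii": 10,
            "Reptilia": 5,
            "Amphibia": 4,
            "Chondrichthyes": 5,
            "Coelacanthimorpha": 3,
        },
        n_poor_species=5,
    )
    return synthetic.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_run(small_corpus, tmp_path_factory):
    """The small corpus written to disk and run through the full pipeline."""
    d = tmp_path_factory.mktemp("small_run")
    paths = small_corpus.write(d / "corpus")
    rc = pipeline.RunConfig(
        catalogue=paths["catalogue"],
        fasta=paths["fasta"],
        hits=paths["hits"],
        lineage=paths["lineage"],
        proteome_sizes=paths["proteome_sizes"],
        q3=paths["q3"],
        outdir=d / "out",
    )
    outputs = pipeline.run_pipeline(rc)
    return {"corpus": small_corpus, "paths": paths, "outputs": outputs, "outdir": d / "out"}


def make_metrics(rows: list[dict]) -> pd.DataFrame:
    """Metrics frame with sane defaults, overridden per row."""
    defaults = {
        "n_species": 320,
        "pct_species": 98.0,
        "median_hd": 0.0,
        "classes_present": frozenset(
            ["Mammalia", "Aves", "Reptilia", "Amphibia", "Actinopterygii",
             "Chondrichthyes", "Coelacanthimorpha"]
        ),
        "p1_d_fraction": 0.95,
        "coil_prevalence": 1.5,
        "hydro_prevalence_median": 0.8,
        "destab_fraction": 0.6,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"site_id": row.get("site_id", f"T{i + 1:03d}"), **defaults}
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)
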