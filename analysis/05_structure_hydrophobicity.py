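#!/usr/bin/env python
"""Structural and hydrophobicity context of the cleavage sites.

Coil prevalence (centre-over-flanks coil ratio) per human site from the Q3
strings, the per-position H/E/C frequency matrix, the corpus positivity
shift, per-hit hydrophobicity prevalence with its per-site median, and a
demonstration of the hydrophobicity/cleavage-rate Kendall correlation on
synthetic rates (real rate data is an external input).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from caspcons import hydrophobicity as hp
from caspcons import sites, structure

CORPUS = Path("results/corpus")
OUT = Path("results")


def main() -> None:
    site_list, _ = sites.load_sites(CORPUS / "catalogue.tsv", CORPUS / "proteins.fasta")
    q3 = structure.read_q3_table(CORPUS / "q3.tsv")
    ann = pd.read_csv(OUT / "annotated_hits.tsv", sep="\t", dtype={"site_id": str})
    p1_index = {s.site_id: s.p1_index for s in site_list}

    coil = pd.DataFrame(
        {
            "site_id": q3["site_id"],
            "coil_prevalence": [
                structure.coil_prevalence(row.q3, p1_index.get(row.site_id, 29))
                for row in q3.itertuples(index=False)
            ],
        }
    )
    coil.to_csv(OUT / "coil_prevalence.tsv", sep="\t", index=False)
    freq = structure.structure_frequency_matrix(list(q3["q3"]), span=(20, 40))
    freq.to_csv(OUT / "structure_frequency_central20.tsv", sep="\t")
    print(f"coil prevalence: median {coil['coil_prevalence'].median():.3f}, "
          f"{(coil['coil_prevalence'] > 1).mean() * 100:.0f}% of sites above 1")
    print(f"central-20 composition: C {freq['C'].mean() * 100:.0f}%  "
          f"H {freq['H'].mean() * 100:.0f}%  E {freq['E'].mean() * 100:.0f}%")

    pairs = [
        hp.block_values(w, p1_index.get(s, 29))
        for s, w in zip(ann["site_id"], ann["anchored_window"])
    ]
    shift = hp.hydro_shift(pairs)
    prev = pd.DataFrame(
        {
            "site_id": ann["site_id"],
            "hydro_prevalence": [
                hp.hydro_prevalence(w, shift, p1_index.get(s, 29))
                for s, w in zip(ann["site_id"], ann["anchored_window"])
            ],
        }
    )
    per_site = prev.groupby("site_id")["hydro_prevalence"].median()
    per_site.rename("hydro_prevalence_median").reset_index().to_csv(
        OUT / "hydro_prevalence_median.tsv", sep="\t", index=False
    )
    print(f"hydrophobicity shift: {shift:.2f} kcal/mol; per-site median "
          f"prevalence < 1 for {(per_site < 1).mean() * 100:.0f}% of sites")

    # rate correlation demo: SYNTHETIC rates, faster cleavage for more
    # hydrophilic sites plus noise — exercises the statistic only
    rng = np.random.default_rng(1)
    sums = np.array([hp.hydro_sum(s.window[20:40]) for s in site_list])
    rates = -0.01 * sums + rng.normal(0, 0.3, size=len(sums))
    tau, p = hp.hydro_rate_correlation(sums, rates)
    print(f"synthetic-rate Kendall correlation: tau {tau:.3f} (p {p:.2g}) — "
          f"hydrophilic sites cut faster by construction")


if __name__ == "__main__":
    main()
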