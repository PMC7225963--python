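#!/usr/bin/env python
"""Corpus-wide conservation distributions (P1, octamer HD, P1').

Computes the three summary distributions from the annotated synthetic hits
and, alongside, re-derives the published percentages from the packaged
census count columns (the desk check: P1-D 92%, P1-E 5%, ideal octamer 57%,
one substitution 18%, P1' glycine 33% human / 30% vertebrate).
"""

from pathlib import Path

import pandas as pd

from caspcons import conservation, datasets, ndegron

OUT = Path("results")


def main() -> None:
    ann = pd.read_csv(OUT / "annotated_hits.tsv", sep="\t", dtype={"site_id": str})

    p1 = conservation.p1_distribution(ann)
    hd = conservation.hd_distribution(ann)
    p1p = ndegron.p1prime_distribution(ann)
    p1.to_csv(OUT / "p1_distribution.tsv", sep="\t")
    hd.reset_index().to_csv(OUT / "hd_distribution.tsv", sep="\t", index=False)
    p1p.to_csv(OUT / "p1prime_distribution.tsv", sep="\t")

    print("synthetic corpus:")
    print(f"  P1 aspartate: {p1.loc['D', 'percent']}%   "
          f"glutamate: {p1.loc['E', 'percent'] if 'E' in p1.index else 0}%")
    ideal = hd.loc[(True, 0), "percent"] if (True, 0) in hd.index else 0.0
    print(f"  identical octamer among all hits: {ideal}%")
    destab = ndegron.nature_subtotals(p1p)
    print(f"  destabilizing P1' share: "
          f"{destab.loc['destabilizing', 'percent'] if 'destabilizing' in destab.index else 0}%")

    print("published census (desk re-derivation from count columns):")
    census_p1 = conservation.distribution_from_counts(datasets.p1_census())
    census_hd = conservation.hd_distribution_from_counts(datasets.hd_census())
    census_pp = datasets.p1prime_census()
    human = conservation.distribution_from_counts(census_pp["human_count"])
    vert = conservation.distribution_from_counts(census_pp["vertebrate_count"])
    print(f"  P1-D {round(census_p1.loc['D', 'percent_raw'])}%, "
          f"P1-E {round(census_p1.loc['E', 'percent_raw'])}%, "
          f"HD0 {round(census_hd.loc[(True, 0), 'percent_raw'])}%, "
          f"HD1 {round(census_hd.loc[(True, 1), 'percent_raw'])}%, "
          f"P1'-G {round(human.loc['G', 'percent_raw'])}% (human) / "
          f"{round(vert.loc['G', 'percent_raw'])}% (vertebrates)")


if __name__ == "__main__":
    main()
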