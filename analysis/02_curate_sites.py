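#!/usr/bin/env python
"""Curate the cleavage-site catalogue against the proteome FASTA.

Applies the keep-only-P1-aspartate rule, collapses duplicate
(accession, position) rows and drops unresolvable rows, writing the curated
site table and a per-row curation report under results/.
"""

from pathlib import Path

from caspcons import sites

CORPUS = Path("results/corpus")
OUT = Path("results")


def main() -> None:
    site_list, report = sites.load_sites(
        CORPUS / "catalogue.tsv", CORPUS / "proteins.fasta"
    )
    OUT.mkdir(exist_ok=True)
    sites.sites_to_frame(site_list).to_csv(OUT / "sites.tsv", sep="\t", index=False)
    report.to_csv(OUT / "curation_report.tsv", sep="\t", index=False)
    kept = int((report["status"] == "kept").sum())
    dropped = report.loc[report["status"] == "dropped", "reason"].value_counts()
    print(f"kept {kept} / {len(report)} catalogue rows")
    for reason, n in dropped.items():
        print(f"  dropped {n}: {reason}")
    full = sum(s.is_full_window for s in site_list)
    print(f"{full} sites have full 60-residue windows "
          f"({len(site_list) - full} truncated near a terminus)")


if __name__ == "__main__":
    main()
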