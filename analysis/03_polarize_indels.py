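#!/usr/bin/env python
"""Polarize the panel's indel loci against the outgroup with the staged
lineage rules, map insertions/deletions onto tree branches, and tabulate
the indel size spectrum."""

import argparse
from pathlib import Path

from plastdiverge import (GroupLabels, assign_events_to_branches,
                          indel_size_spectrum, multi_taxon_indel_loci,
                          polarize_indels)
from plastdiverge.indels import polarized_table
from plastdiverge.io import read_alignment, read_tree
from plastdiverge.pipeline import _read_group_labels


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", default="results/dataset")
    ap.add_argument("--out", default="results/tables")
    args = ap.parse_args()
    ds, out = Path(args.dataset), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    aln = read_alignment(ds / "alignment.fasta")
    tree = read_tree(ds / "tree.nwk")
    groups = GroupLabels(_read_group_labels(ds / "groups.tsv"))

    loci = multi_taxon_indel_loci(aln)
    polarized = polarize_indels(loci, groups)
    polarized_table(polarized).to_csv(out / "polarized_indels.tsv", sep="\t",
                                      index=False)
    branches = assign_events_to_branches(polarized, tree)
    branches.to_csv(out / "branch_counts.tsv", sep="\t", index=False)

    n_pol = sum(1 for p in polarized if p.polarity != "unpolarized")
    print(f"{len(loci)} indel loci; {n_pol} polarized "
          f"({100 * n_pol / len(loci):.1f}%)")
    print(branches.to_string(index=False))

    spectrum = indel_size_spectrum([l.length for l in loci])
    spectrum.to_csv(out / "indel_spectrum.tsv", sep="\t", index=False)
    one = spectrum.loc[spectrum["length"] == 1, "fraction"]
    five = spectrum.loc[spectrum["length"] == 5, "fraction"]
    print(f"1-bp fraction {float(one.iloc[0]):.2f}; "
          f"5-bp fraction {float(five.iloc[0]):.2f}")


if __name__ == "__main__":
    main()
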