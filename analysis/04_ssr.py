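#!/usr/bin/env python
"""cpSSR analysis of the panel: per-genome perfect-microsatellite counts
under both threshold sets, cross-genome locus homology, pairwise
polymorphism, conservation rates, and attribution of 1-3 bp indels to
polymorphic SSR loci."""

import argparse
from pathlib import Path

from plastdiverge import (THRESHOLDS_A, THRESHOLDS_B, attribute_short_indels,
                          extract_indels, find_ssrs, polymorphism_stats,
                          project_pairwise, ssr_locus_homology)
from plastdiverge.io import read_alignment, read_genomes, read_regions
from plastdiverge.ssr import loci_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", default="results/dataset")
    ap.add_argument("--out", default="results/tables")
    args = ap.parse_args()
    ds, out = Path(args.dataset), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    aln = read_alignment(ds / "alignment.fasta")
    genomes = read_genomes(ds / "genomes.fasta")
    regions = read_regions(ds / "regions.tsv")
    for t, g in genomes.items():
        g.regions.update(regions.get(t, {}))

    loci_a = {t: find_ssrs(g, THRESHOLDS_A) for t, g in genomes.items()}
    loci_b = {t: find_ssrs(g, THRESHOLDS_B) for t, g in genomes.items()}
    loci_table([l for ls in loci_a.values() for l in ls]).to_csv(
        out / "ssr_loci_setA.tsv", sep="\t", index=False)
    counts = {t: (len(loci_a[t]), len(loci_b[t])) for t in genomes}
    print("per-genome SSR loci (set A / set B):")
    for t, (na, nb) in counts.items():
        print(f"  {t}: {na} / {nb}")

    groups = ssr_locus_homology(aln, loci_a)
    matrix, classes = polymorphism_stats(groups, aln.taxa)
    matrix.to_csv(out / "ssr_polymorphism_matrix.tsv", sep="\t")
    classes.to_csv(out / "ssr_conservation.tsv", sep="\t", index=False)
    print(f"{len(groups)} homologous locus groups")
    print(classes.to_string(index=False))

    attributed = total = 0
    taxa = aln.taxa
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            events = extract_indels(project_pairwise(aln, a, b))
            att, unatt, _ = attribute_short_indels(events, groups, (a, b))
            attributed += att
            total += att + unatt
    if total:
        print(f"1-3 bp indels attributed to polymorphic SSRs: "
              f"{attributed}/{total} ({100 * attributed / total:.1f}%)")


if __name__ == "__main__":
    main()
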