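"""Indel size spectra, tandem-duplication detection, and staged
outgroup-based polarization of indels onto a fixed species tree.

Polarization logic
------------------
With one outgroup and ingroup taxa partitioned into A-genome diploids,
D-genome diploids and allotetraploids (whose plastome is maternally
A-derived), an indel locus is a maximal column span over which the set of
gapped taxa is constant. The taxa whose state differs from the outgroup's
carry the derived state; if they form exactly one of the recognized
lineage/stage configurations the locus is polarized (derived gap ->
deletion, derived sequence -> insertion):

===========  =======  =====================================================
lineage      stage    derived-state taxa
===========  =======  =====================================================
D            1        both D genomes (after the A/D split, before D1/D2)
D            2        exactly one D genome
A            1        both A genomes plus all allotetraploids (before
                      allotetraploid formation)
A            2        both A genomes only (after formation, before A1/A2)
A            3        exactly one A genome
AD           1        all allotetraploids (before their radiation)
AD           2        a proper, non-empty allotetraploid subset; assigned
                      to a branch only if the subset is a clade
===========  =======  =====================================================

Every other presence/absence pattern — including ragged gap boundaries,
which split into separate loci by construction — is left unpolarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import GAP, MultipleAlignment
from .synthetic import node_label

GROUPS = ("A_diploid", "D_diploid", "allotetraploid", "outgroup")


@dataclass
class GroupLabels:
    """taxon -> group mapping with exactly one outgroup."""

    labels: Mapping[str, str]

    def __post_init__(self):
        bad = set(self.labels.values()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        if len(self.outgroup_all) != 1:
            raise ValueError("exactly one outgroup taxon required")
        for g in ("A_diploid", "D_diploid", "allotetraploid"):
            if not self.taxa_in(g):
                raise ValueError(f"group {g} is empty")

    def taxa_in(self, group: str) -> frozenset:
        return frozenset(t for t, g in self.labels.items() if g == group)

    @property
    def outgroup_all(self) -> frozenset:
        return self.taxa_in("outgroup")

    @property
    def outgroup(self) -> str:
        return next(iter(self.outgroup_all))

    @property
    def a_taxa(self) -> frozenset:
        return self.taxa_in("A_diploid")

    @property
    def d_taxa(self) -> frozenset:
        return self.taxa_in("D_diploid")

    @property
    def ad_taxa(self) -> frozenset:
        return self.taxa_in("allotetraploid")


@dataclass
class GapLocus:
    """Maximal column span with a constant set of gapped taxa."""

    col_start: int
    col_end: int
    gapped_taxa: frozenset

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


@dataclass
class PolarizedIndel:
    locus: GapLocus
    polarity: str               # insertion | deletion | unpolarized
    lineage: str = ""           # A | D | AD | terminal taxon, "" if unpolarized
    stage: int = 0
    derived_taxa: frozenset = frozenset()
    ssr_associated: bool = False
    reason: str = ""            # why unpolarized, when it is

    @property
    def length(self) -> int:
        return self.locus.length


def multi_taxon_indel_loci(aln: MultipleAlignment) -> list[GapLocus]:
    """Split the alignment into maximal spans of constant gapped-taxon
    pattern, keeping spans where at least one (but not every) taxon is
    gapped."""
    M = aln.matrix
    isgap = M == GAP
    ncol = M.shape[1]
    if ncol == 0:
        return []
    change = np.flatnonzero((isgap[:, 1:] != isgap[:, :-1]).any(axis=0)) + 1
    bounds = np.concatenate(([0], change, [ncol]))
    loci = []
    ntaxa = M.shape[0]
    for s, e in zip(bounds[:-1], bounds[1:]):
        col = isgap[:, s]
        k = int(col.sum())
        if 0 < k < ntaxa:
            gapped = frozenset(aln.taxa[i] for i in np.flatnonzero(col))
            loci.append(GapLocus(int(s), int(e), gapped))
    return loci


def classify_pattern(gapped: frozenset, groups: GroupLabels,
                     present: frozenset | None = None):
    """Apply the staged rules to one presence/absence pattern.

    ``present`` defaults to all labelled taxa minus the gapped set. Returns
    (polarity, lineage, stage, derived_taxa) or None if no rule matches.
    """
    out = groups.outgroup
    all_taxa = frozenset(groups.labels)
    if present is None:
        present = all_taxa - gapped
    if out in gapped:
        derived = present - {out}
        polarity = "insertion"   # derived taxa carry sequence the outgroup lacks
    else:
        derived = gapped
        polarity = "deletion"
    A, D, AD = groups.a_taxa, groups.d_taxa, groups.ad_taxa
    if not derived:
        return None
    if derived == D:
        return polarity, "D", 1, derived
    if len(derived) == 1 and derived < D:
        return polarity, "D", 2, derived
    if derived == A | AD:
        return polarity, "A", 1, derived
    if derived == A:
        return polarity, "A", 2, derived
    if len(derived) == 1 and derived < A:
        return polarity, "A", 3, derived
    if derived == AD:
        return polarity, "AD", 1, derived
    if derived and derived < AD:
        return polarity, "AD", 2, derived
    return None


def polarize_indels(loci: Sequence[GapLocus], groups: GroupLabels,
                    ssr_mask: Sequence[tuple[int, int]] = (),
                    ) -> list[PolarizedIndel]:
    """Stage-rule polarization; loci matching no rule — or missing the
    outgroup's state — stay unpolarized with the reason recorded. Loci
    overlapping the SSR mask are flagged and still polarized only when a
    single stage rule matches (which the rule set guarantees)."""
    mask = sorted(ssr_mask)
    starts = np.array([s for s, _ in mask], dtype=int)
    ends = np.array([e for _, e in mask], dtype=int)
    labelled = frozenset(groups.labels)
    out = []
    for locus in loci:
        i = np.searchsorted(starts, locus.col_end)
        in_ssr = bool(np.any(ends[:i] > locus.col_start))
        gapped = locus.gapped_taxa & labelled
        verdict = classify_pattern(gapped, groups)
        if verdict is None:
            reason = ("whole-ingroup pattern: side of the root unknowable"
                      if gapped in (labelled - groups.outgroup_all,
                                    groups.outgroup_all)
                      else "no stage rule matches")
            out.append(PolarizedIndel(locus, "unpolarized",
                                      ssr_associated=in_ssr, reason=reason))
        else:
            polarity, lineage, stage, derived = verdict
            out.append(PolarizedIndel(locus, polarity, lineage, stage,
                                      derived, ssr_associated=in_ssr))
    return out


# ---------------------------------------------------------------------------
# Branch assignment


def _clade_index(tree: dendropy.Tree) -> dict[frozenset, str]:
    """leafset -> label of the node subtending exactly that leafset."""
    idx = {}
    for nd in tree.postorder_node_iter():
        leaves = frozenset(node_label(lf) for lf in nd.leaf_iter())
        idx[leaves] = node_label(nd)
    return idx


def branch_for_event(pol: PolarizedIndel, tree: dendropy.Tree,
                     clades: dict[frozenset, str] | None = None) -> str | None:
    """The tree edge (named by its child node) on which a polarized event
    arose; None for unpolarized events or non-clade tetraploid subsets."""
    if pol.polarity == "unpolarized":
        return None
    if clades is None:
        clades = _clade_index(tree)
    return clades.get(frozenset(pol.derived_taxa))


def assign_events_to_branches(polarized: Sequence[PolarizedIndel],
                              tree: dendropy.Tree) -> pd.DataFrame:
    """Per-branch insertion/deletion tallies (event counts and summed bp).

    Events whose derived tetraploid subset is not a clade of the tree are
    flagged as homoplasy candidates under branch label ``(non-clade)``.
    """
    clades = _clade_index(tree)
    rows: dict[str, dict] = {}
    for pol in polarized:
        if pol.polarity == "unpolarized":
            continue
        branch = branch_for_event(pol, tree, clades) or "(non-clade)"
        rec = rows.setdefault(branch, {
            "branch": branch, "n_insertions": 0, "insertion_bp": 0,
            "n_deletions": 0, "deletion_bp": 0})
        if pol.polarity == "insertion":
            rec["n_insertions"] += 1
            rec["insertion_bp"] += pol.length
        else:
            rec["n_deletions"] += 1
            rec["deletion_bp"] += pol.length
    return pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["branch"]),
        columns=["branch", "n_insertions", "insertion_bp",
                 "n_deletions", "deletion_bp"])


# ---------------------------------------------------------------------------
# Size spectrum and rates


def indel_size_spectrum(lengths: Iterable[int]) -> pd.DataFrame:
    """Histogram over exact lengths plus the fractions the comparative
    analyses report (share of each 1..10 bp class and of all <=10 bp)."""
    lengths = list(lengths)
    if not lengths:
        return pd.DataFrame(columns=["length", "count", "fraction"])
    ser = pd.Series(lengths).value_counts().sort_index()
    total = len(lengths)
    return pd.DataFrame({"length": ser.index.astype(int),
                         "count": ser.values,
                         "fraction": ser.values / total})


def spectrum_summary(spectrum: pd.DataFrame) -> dict:
    if spectrum.empty:
        return {"n": 0}
    total = int(spectrum["count"].sum())
    short = int(spectrum.loc[spectrum["length"] <= 10, "count"].sum())
    out = {"n": total, "frac_le_10bp": short / total}
    for L in range(1, 11):
        row = spectrum.loc[spectrum["length"] == L, "count"]
        out[f"frac_{L}bp"] = (int(row.iloc[0]) if len(row) else 0) / total
    return out


def tandem_dup_check(bases: str, upstream: str, downstream: str) -> bool:
    """True iff the indel's bases equal the immediately adjacent upstream
    or downstream segment of equal length (slipped-strand signature)."""
    n = len(bases)
    if n == 0:
        raise ValueError("empty indel")
    return (len(upstream) >= n and upstream[-n:] == bases) or \
           (len(downstream) >= n and downstream[:n] == bases)


def indel_ratio(indel_count: int, divergence_time_my: float,
                n_lineages: int = 2) -> float:
    """Indels per lineage per million years."""
    if divergence_time_my <= 0:
        raise ValueError("divergence time must be positive")
    return indel_count / (n_lineages * divergence_time_my)


def polarized_table(polarized: Sequence[PolarizedIndel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"col_start": p.locus.col_start, "col_end": p.locus.col_end,
          "length": p.length, "polarity": p.polarity, "lineage": p.lineage,
          "stage": p.stage,
          "derived_taxa": ",".join(sorted(p.derived_taxa)),
          "ssr_associated": p.ssr_associated, "reason": p.reason}
         for p in polarized],
        columns=["col_start", "col_end", "length", "polarity", "lineage",
                 "stage", "derived_taxa", "ssr_associated", "reason"])
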