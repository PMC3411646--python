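"""Perfect-microsatellite (cpSSR) detection and polymorphism analysis.

A locus is a maximal perfect tandem repeat of a primitive 1-5 bp motif,
reported at the smallest unit length that generates it, with any trailing
partial unit truncated. Two threshold presets are provided giving the
minimum locus length in bp per motif unit length:

* set A: mono >=8, di >=8, tri >=9, tetra >=12, penta >=15
* set B: mono >=10, di >=10, tri >=12, tetra >=16, penta >=20

Motifs are canonicalized to their lexicographically smallest rotation on
the given strand; reverse complements are *not* collapsed (an AT repeat and
a TA repeat are the same locus class, an AG and a CT repeat are not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomeRecord, MultipleAlignment

_ACGT = set("ACGT")


@dataclass(frozen=True)
class ThresholdSet:
    min_len: Mapping[int, int]

    def __post_init__(self):
        if set(self.min_len) != {1, 2, 3, 4, 5}:
            raise ValueError("threshold set must cover unit lengths 1..5")
        if any(v <= 0 for v in self.min_len.values()):
            raise ValueError("thresholds must be positive")


THRESHOLDS_A = ThresholdSet({1: 8, 2: 8, 3: 9, 4: 12, 5: 15})
THRESHOLDS_B = ThresholdSet({1: 10, 2: 10, 3: 12, 4: 16, 5: 20})

THRESHOLD_PRESETS = {"A": THRESHOLDS_A, "B": THRESHOLDS_B}


@dataclass(frozen=True)
class SSRLocus:
    taxon: str
    motif: str           # canonical form
    unit_len: int
    start: int           # 0-based half-open, ungapped coordinates
    end: int
    region: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def units(self) -> int:
        return self.length // self.unit_len


def canonical_motif(raw: str) -> str:
    """Lexicographically smallest rotation of the motif (strand preserved)."""
    return min(raw[i:] + raw[:i] for i in range(len(raw)))


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_ssrs_in_seq(seq: str, thresholds: ThresholdSet,
                     taxon: str = "") -> list[SSRLocus]:
    """Deterministic scan for maximal perfect repeats of unit length 1-5.

    For each unit length u, positions where ``seq[j] == seq[j-u]`` form
    match runs; a maximal run over match indices [a, b) is the repeat
    region [a, b+u). Non-ACGT characters break every run.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.shape[0]
    is_acgt = ((arr == 65) | (arr == 67) | (arr == 71) | (arr == 84))
    loci: list[SSRLocus] = []
    for u in range(1, 6):
        if n <= u:
            continue
        min_bp = thresholds.min_len[u]
        m = (arr[u:] == arr[:-u]) & is_acgt[u:] & is_acgt[:-u]
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([False], m, [False])).astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        # need >=2 full units and >= threshold bp after truncation
        totals = ends - starts + u
        units = totals // u
        keep = (units >= 2) & (units * u >= min_bp)
        for a, total_units in zip(starts[keep], units[keep]):
            a = int(a)
            motif = seq[a:a + u]
            if _is_primitive(motif):
                loci.append(SSRLocus(taxon, canonical_motif(motif), u,
                                     a, a + int(total_units) * u))
    loci.sort(key=lambda l: (l.start, l.unit_len))
    return loci


def find_ssrs(genome: GenomeRecord,
              thresholds: ThresholdSet = THRESHOLDS_A) -> list[SSRLocus]:
    loci = find_ssrs_in_seq(genome.sequence, thresholds, genome.taxon_id)
    if genome.regions:
        loci = [SSRLocus(l.taxon, l.motif, l.unit_len, l.start, l.end,
                         genome.region_of(l.start)) for l in loci]
    return loci


# ---------------------------------------------------------------------------
# Cross-genome locus homology via the master alignment


@dataclass
class SSRGroup:
    """Homologous SSR loci across taxa: same canonical motif, overlapping
    alignment columns."""

    motif: str
    unit_len: int
    members: dict[str, SSRLocus] = field(default_factory=dict)
    col_start: int = 0
    col_end: int = 0

    def length_of(self, taxon: str) -> int:
        """Repeat length carried by ``taxon``; absence counts as 0."""
        loc = self.members.get(taxon)
        return loc.length if loc is not None else 0


def ssr_locus_homology(aln: MultipleAlignment,
                       loci_by_taxon: Mapping[str, Sequence[SSRLocus]],
                       ) -> list[SSRGroup]:
    """Group loci whose alignment-column spans overlap and whose canonical
    motifs match. Single-linkage over column overlap; each locus ends up in
    exactly one group."""
    items = []  # (motif, unit, col_start, col_end, taxon, locus)
    for taxon, loci in loci_by_taxon.items():
        p2c = aln.pos_to_column(taxon)
        for loc in loci:
            if loc.end > p2c.shape[0]:
                raise ValueError(
                    f"locus {loc} outside sequence of {taxon}")
            items.append((loc.motif, loc.unit_len,
                          int(p2c[loc.start]), int(p2c[loc.end - 1]) + 1,
                          taxon, loc))
    groups: list[SSRGroup] = []
    items.sort(key=lambda it: (it[0], it[1], it[2]))
    open_group: SSRGroup | None = None
    for motif, unit, cs, ce, taxon, loc in items:
        if (open_group is not None and open_group.motif == motif
                and open_group.unit_len == unit and cs < open_group.col_end):
            g = open_group
            g.col_end = max(g.col_end, ce)
        else:
            g = SSRGroup(motif, unit, {}, cs, ce)
            groups.append(g)
            open_group = g
        if taxon in g.members:
            # keep the longer of two same-motif runs mapping to one span
            if loc.length > g.members[taxon].length:
                g.members[taxon] = loc
        else:
            g.members[taxon] = loc
    groups.sort(key=lambda g: g.col_start)
    return groups


# ---------------------------------------------------------------------------
# Polymorphism / conservation accounting


def group_is_polymorphic(group: SSRGroup, a: str, b: str) -> bool:
    return group.length_of(a) != group.length_of(b)


def polymorphism_stats(groups: Sequence[SSRGroup], taxa: Sequence[str]):
    """Per-pair polymorphic locus counts plus per-unit-length conservation.

    Returns (pair_matrix: DataFrame, class_summary: DataFrame). A group is
    conserved iff every taxon carries the locus at identical length.
    """
    taxa = list(taxa)
    n = len(taxa)
    mat = np.zeros((n, n), dtype=int)
    for g in groups:
        lengths = [g.length_of(t) for t in taxa]
        for i in range(n):
            for j in range(i + 1, n):
                if lengths[i] != lengths[j]:
                    mat[i, j] += 1
                    mat[j, i] += 1
    pair_matrix = pd.DataFrame(mat, index=taxa, columns=taxa)

    rows = []
    for u in range(1, 6):
        sub = [g for g in groups if g.unit_len == u]
        conserved = sum(
            1 for g in sub
            if len({g.length_of(t) for t in taxa}) == 1 and g.length_of(taxa[0]) > 0
        )
        rows.append({
            "unit_len": u,
            "n_groups": len(sub),
            "n_conserved": conserved,
            "conserved_rate": conserved / len(sub) if sub else float("nan"),
        })
    total = len(groups)
    conserved_total = int(sum(r["n_conserved"] for r in rows))
    rows.append({"unit_len": 0, "n_groups": total, "n_conserved": conserved_total,
                 "conserved_rate": conserved_total / total if total else float("nan")})
    return pair_matrix, pd.DataFrame(rows)


def attribute_short_indels(indel_events, groups: Sequence[SSRGroup],
                           pair: tuple[str, str], max_len: int = 3):
    """Fraction of 1..max_len bp indels of a pair overlapping a group that is
    polymorphic for that pair.

    ``indel_events`` supplies master-column spans via attributes
    ``col_start``/``col_end`` and ``length`` (see divergence.IndelEvent).
    Returns (attributed, unattributed, fraction).
    """
    a, b = pair
    poly_spans = [(g.col_start, g.col_end) for g in groups
                  if group_is_polymorphic(g, a, b)]
    poly_spans.sort()
    starts = np.array([s for s, _ in poly_spans], dtype=int)
    ends = np.array([e for _, e in poly_spans], dtype=int)
    attributed = unattributed = 0
    for ev in indel_events:
        if not (1 <= ev.length <= max_len):
            continue
        # overlap with any polymorphic span? spans sorted; binary search
        i = np.searchsorted(starts, ev.col_end)
        hit = bool(np.any(ends[:i] > ev.col_start))
        if hit:
            attributed += 1
        else:
            unattributed += 1
    total = attributed + unattributed
    frac = attributed / total if total else float("nan")
    return attributed, unattributed, frac


def loci_table(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"taxon": l.taxon, "motif": l.motif, "unit_len": l.unit_len,
          "start": l.start, "end": l.end, "length": l.length,
          "region": l.region} for l in loci],
        columns=["taxon", "motif", "unit_len", "start", "end", "length", "region"])
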