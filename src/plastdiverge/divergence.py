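"""Substitution and indel accounting between genome pairs.

Counts, Si/Sv, divergence percentages, per-region per-kb rates, S/I
ratios, sliding AT/divergence profiles, IR junction distances and the
indels-above / substitutions-below pairwise matrix.

Conventions: columns where either taxon carries N contribute to neither
numerator nor denominator; alignment-terminal gap runs are not indel
events; the two IR copies are pooled and reported once; substitution
columns adjacent to indels still count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (GAP, GenomeRecord, MultipleAlignment, PairwiseView,
                 project_pairwise)

_N = ord("N")
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}
PAIR_TYPES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")


@dataclass(frozen=True)
class SubstitutionEvent:
    column: int              # master alignment column
    base_a: str
    base_b: str
    region: str

    @property
    def is_transition(self) -> bool:
        return frozenset((self.base_a, self.base_b)) in _TRANSITION_PAIRS

    @property
    def pair_type(self) -> str:
        pair = "".join(sorted((self.base_a, self.base_b)))
        return f"{pair[0]}/{pair[1]}"


@dataclass(frozen=True)
class IndelEvent:
    col_start: int           # master column span, half-open
    col_end: int
    length: int
    gapped_taxon: str        # which of the pair carries the gap
    region: str
    bases: str               # bases retained/inserted in the ungapped taxon
    ssr_associated: bool = False
    tandem_dup: bool = False


@dataclass
class SubstitutionSummary:
    n_total: int
    n_transitions: int
    n_transversions: int
    pair_type_counts: dict

    @property
    def si_sv(self) -> float:
        if self.n_transversions == 0:
            return float("nan")
        return self.n_transitions / self.n_transversions


@dataclass
class PairwiseDivergence:
    taxon_a: str
    taxon_b: str
    alignment_length: int
    n_substitutions: int
    n_transitions: int
    n_transversions: int
    total_indel_events: int
    total_indel_length: int
    si_sv: float
    s_i: float
    subst_divergence_pct: float
    indel_divergence_pct: float
    region_stats: pd.DataFrame | None = None


def divergence_percent(total_bp: int, alignment_len: int) -> float:
    """100 * total_bp / alignment_len. Reported to 3 decimals downstream."""
    if alignment_len <= 0:
        raise ValueError("alignment length must be positive")
    return 100.0 * total_bp / alignment_len


def s_i_ratio(n_substitutions: int, n_indel_events: int) -> float:
    if n_indel_events == 0:
        return float("nan")
    return n_substitutions / n_indel_events


def at_content(seq: str) -> float:
    """(A+T)/(A+C+G+T); Ns excluded from both numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["A"] + counts["T"]) / denom


# ---------------------------------------------------------------------------
# Region labelling of alignment columns


def region_labels_for_columns(aln: MultipleAlignment, taxon: str,
                              regions: Mapping[str, tuple[int, int]],
                              columns: np.ndarray) -> np.ndarray:
    """Region of each requested master column, by the reference taxon's
    sequence position at or left of the column (gap columns inherit the
    left flank's region)."""
    pos = aln.column_to_seq_pos(taxon)
    filled = np.maximum.accumulate(np.where(pos >= 0, pos, -1))
    filled = np.clip(filled, 0, None)
    names = sorted(regions, key=lambda r: regions[r][0])
    bounds = np.array([regions[r][0] for r in names])
    idx = np.searchsorted(bounds, filled[columns], side="right") - 1
    return np.array(names, dtype=object)[np.clip(idx, 0, None)]


# ---------------------------------------------------------------------------
# Substitutions


def count_substitutions(view: PairwiseView,
                        regions: Mapping[str, tuple[int, int]] | None = None,
                        aln: MultipleAlignment | None = None,
                        ) -> tuple[list[SubstitutionEvent], SubstitutionSummary]:
    ra, rb = view.row_a, view.row_b
    ok = (ra != GAP) & (rb != GAP) & (ra != _N) & (rb != _N)
    diff = np.flatnonzero(ok & (ra != rb))
    if regions is not None and aln is not None and diff.size:
        labels = region_labels_for_columns(
            aln, view.taxon_a, regions, view.master_columns[diff])
    else:
        labels = np.full(diff.shape[0], "", dtype=object)
    events = [
        SubstitutionEvent(int(view.master_columns[i]), chr(ra[i]), chr(rb[i]),
                          str(lab))
        for i, lab in zip(diff, labels)
    ]
    n_ti = sum(1 for e in events if e.is_transition)
    counts = {p: 0 for p in PAIR_TYPES}
    for e in events:
        counts[e.pair_type] += 1
    summary = SubstitutionSummary(len(events), n_ti, len(events) - n_ti, counts)
    return events, summary


# ---------------------------------------------------------------------------
# Indels


def extract_indels(view: PairwiseView,
                   regions: Mapping[str, tuple[int, int]] | None = None,
                   aln: MultipleAlignment | None = None) -> list[IndelEvent]:
    """Each maximal run of gap in exactly one taxon is one event;
    alignment-terminal runs are excluded. N columns break no run but
    contribute no event on their own."""
    events: list[IndelEvent] = []
    for gapped, other, gtaxon in ((view.row_a, view.row_b, view.taxon_a),
                                  (view.row_b, view.row_a, view.taxon_b)):
        isgap = gapped == GAP
        if not isgap.any():
            continue
        edges = np.flatnonzero(np.diff(
            np.concatenate(([False], isgap, [False])).astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            s, e = int(s), int(e)
            if s == 0 or e == view.length:
                continue  # terminal run: linearization artifact
            bases = other[s:e].tobytes().decode()
            events.append(IndelEvent(
                int(view.master_columns[s]),
                int(view.master_columns[e - 1]) + 1,
                e - s, gtaxon, "", bases))
    events.sort(key=lambda ev: ev.col_start)
    if regions is not None and aln is not None and events:
        cols = np.array([ev.col_start for ev in events])
        labels = region_labels_for_columns(aln, view.taxon_a, regions, cols)
        events = [
            IndelEvent(ev.col_start, ev.col_end, ev.length, ev.gapped_taxon,
                       str(lab), ev.bases, ev.ssr_associated, ev.tandem_dup)
            for ev, lab in zip(events, labels)
        ]
    return events


# ---------------------------------------------------------------------------
# Combined pairwise summaries


def pairwise_divergence(aln: MultipleAlignment, a: str, b: str,
                        regions: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
                        ) -> PairwiseDivergence:
    """Full substitution/indel accounting for one pair on the master
    alignment. ``regions`` maps taxon -> region table; the first taxon of
    the pair with a table becomes the region reference."""
    view = project_pairwise(aln, a, b)
    ref_regions = None
    if regions:
        for t in (a, b):
            if t in regions:
                ref_regions = regions[t]
                break
    events, summary = count_substitutions(view, ref_regions, aln)
    indels = extract_indels(view, ref_regions, aln)
    total_indel_len = sum(ev.length for ev in indels)
    L = aln.length
    region_stats = None
    if ref_regions is not None:
        ref_taxon = a if a in regions else b
        region_stats = per_region_stats(events, indels,
                                        aln, ref_taxon, ref_regions)
    return PairwiseDivergence(
        taxon_a=a, taxon_b=b, alignment_length=L,
        n_substitutions=summary.n_total,
        n_transitions=summary.n_transitions,
        n_transversions=summary.n_transversions,
        total_indel_events=len(indels),
        total_indel_length=total_indel_len,
        si_sv=summary.si_sv,
        s_i=s_i_ratio(summary.n_total, len(indels)),
        subst_divergence_pct=divergence_percent(summary.n_total, L),
        indel_divergence_pct=divergence_percent(total_indel_len, L),
        region_stats=region_stats,
    )


def per_region_stats(sub_events: Sequence[SubstitutionEvent],
                     indel_events: Sequence[IndelEvent],
                     aln: MultipleAlignment, ref_taxon: str,
                     regions: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Substitutions/kb and indels/kb per LSC, SSC and IR.

    The two IR copies are pooled and reported once: counts summed over IRb
    and IRa then halved, lengths averaged.
    """
    sub_counts = {r: 0 for r in ("LSC", "IRb", "SSC", "IRa")}
    for e in sub_events:
        if e.region in sub_counts:
            sub_counts[e.region] += 1
    ind_counts = {r: 0 for r in ("LSC", "IRb", "SSC", "IRa")}
    for e in indel_events:
        if e.region in ind_counts:
            ind_counts[e.region] += 1
    span_len = {r: e - s for r, (s, e) in regions.items()}
    rows = []
    for r in ("LSC", "SSC"):
        if r not in span_len:
            continue
        kb = span_len[r] / 1000.0
        rows.append({"region": r,
                     "length_bp": span_len[r],
                     "n_substitutions": sub_counts[r],
                     "n_indels": ind_counts[r],
                     "sub_per_kb": sub_counts[r] / kb,
                     "indel_per_kb": ind_counts[r] / kb})
    if "IRb" in span_len and "IRa" in span_len:
        n_sub = (sub_counts["IRb"] + sub_counts["IRa"]) / 2.0
        n_ind = (ind_counts["IRb"] + ind_counts["IRa"]) / 2.0
        length = (span_len["IRb"] + span_len["IRa"]) / 2.0
        kb = length / 1000.0
        rows.append({"region": "IR", "length_bp": length,
                     "n_substitutions": n_sub, "n_indels": n_ind,
                     "sub_per_kb": n_sub / kb, "indel_per_kb": n_ind / kb})
    return pd.DataFrame(rows)


def region_rate(n_events: float, region_len_bp: float) -> float:
    """Events per kb: n / (length/1000). Zero events -> 0.0/kb."""
    if region_len_bp <= 0:
        raise ValueError("region length must be positive")
    return n_events / (region_len_bp / 1000.0)


def pairwise_matrix(aln: MultipleAlignment,
                    taxa: Sequence[str] | None = None,
                    regions=None) -> pd.DataFrame:
    """Indel event counts above the diagonal, substitution totals below."""
    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    mat = pd.DataFrame("", index=taxa, columns=taxa, dtype=object)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            view = project_pairwise(aln, a, b)
            _, summary = count_substitutions(view)
            indels = extract_indels(view)
            mat.loc[a, b] = len(indels)          # upper: indel events
            mat.loc[b, a] = summary.n_total      # lower: substitutions
    return mat


# ---------------------------------------------------------------------------
# Sliding AT vs divergence profile


def sliding_at_vs_divergence(aln: MultipleAlignment, at_window: int = 100,
                             div_step: int = 10) -> pd.DataFrame:
    """Per-window AT fraction (gaps/N excluded from the denominator) and
    column divergence (fraction of gap-free, N-free columns showing >=2
    states) on a shared grid stepping by ``div_step``."""
    L = aln.length
    if at_window > L:
        raise ValueError("window larger than alignment")
    M = aln.matrix
    is_gap = M == GAP
    is_n = M == _N
    is_at = (M == ord("A")) | (M == ord("T"))
    clean_col = ~(is_gap | is_n).any(axis=0)
    # column is variable if >=2 distinct bases among taxa
    first = M[0]
    variable = clean_col & (M != first[None, :]).any(axis=0)

    at_num = is_at.sum(axis=0).astype(float)
    at_den = (~(is_gap | is_n)).sum(axis=0).astype(float)

    rows = []
    for start in range(0, L - at_window + 1, div_step):
        end = start + at_window
        den = at_den[start:end].sum()
        at = at_num[start:end].sum() / den if den else float("nan")
        n_clean = int(clean_col[start:end].sum())
        div = (variable[start:end].sum() / n_clean) if n_clean else float("nan")
        rows.append({"col_start": start, "col_end": end,
                     "at_fraction": at, "divergence": div})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IR junction distances


def junction_distances(genome: GenomeRecord,
                       boundary_genes: Sequence[str]) -> pd.DataFrame:
    """Signed distance from each named gene to its nearest region junction.

    Positive: bp between the gene's nearer endpoint and the junction.
    Negative: the gene crosses the junction; the magnitude is the overlap
    into the adjacent region. Zero: the gene ends exactly at the junction.
    """
    if not genome.regions:
        raise ValueError("genome lacks a region table")
    spans = sorted(genome.regions.items(), key=lambda kv: kv[1][0])
    junctions = []  # (name, position)
    for (r0, (s0, e0)), (r1, (s1, e1)) in zip(spans, spans[1:]):
        junctions.append((f"{r0}/{r1}", e0))
    by_name = {g.name: g for g in genome.genes}
    rows = []
    for name in boundary_genes:
        if name not in by_name:
            raise KeyError(f"gene {name!r} not annotated")
        g = by_name[name]
        jname, jpos = min(junctions,
                          key=lambda j: min(abs(g.start - j[1]),
                                            abs(g.end - j[1])))
        if g.start < jpos < g.end:
            dist = -min(jpos - g.start, g.end - jpos)
        else:
            dist = min(abs(g.start - jpos), abs(g.end - jpos))
        rows.append({"gene": name, "junction": jname, "distance_bp": dist})
    return pd.DataFrame(rows)
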