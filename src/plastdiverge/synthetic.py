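"""Synthetic quadripartite plastomes evolved along a fixed species tree.

The generator builds a circular-genome stand-in linearized at LSC position 0
(region order LSC, IRb, SSC, IRa; IRa is the reverse complement of IRb) and
evolves it under a substitution / indel / SSR-slippage model, emitting tip
genomes, a truth multiple alignment and a complete event log that replays
byte-identically.

Column identity scheme
----------------------
Every site carries an immutable *order key*, a tuple of ints whose sort
order equals sequence order in every lineage:

* ancestral non-IRa site at linear position ``i`` has key ``(i,)``;
* an insertion (event id ``e``) after the site with key ``K`` creates sites
  ``K + (-e, m)`` for ``m = 0..len-1`` — later events nest closer to their
  flank, which is exactly the sequential-application semantics;
* an IRa site is the image of its IRb partner under an order-reversing
  involution (negate elements, append a sentinel, prefix a large base), so
  concerted IR evolution is "rebuild IRa from IRb" with no bookkeeping.

The master truth alignment is the key-sorted union of all tip sites.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import (Gene, GenomeRecord, MultipleAlignment, GAP,
                 tree_from_string, write_alignment, write_event_table,
                 write_features, write_genomes, write_regions, write_tree)
from .ssr import THRESHOLDS_A, find_ssrs_in_seq

_IRA_BASE = 10**9
_SENT = 2**62
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")
_MARGIN = 10  # indels keep clear of the linearization origin / genome end


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def ira_key(k: tuple) -> tuple:
    """Order-reversing involution mapping an IRb site key to its IRa partner."""
    return (_IRA_BASE,) + tuple(-x for x in k) + (_SENT,)


def _region_of_key(k: tuple, region_by_key: dict) -> str:
    if k[0] == _IRA_BASE:
        return "IRa"
    return region_by_key[k]


# ---------------------------------------------------------------------------
# Ancestral genome


class SizingError(ValueError):
    """Region lengths cannot host the requested features."""


def _default_ssr_seed_loci() -> list[tuple[str, int, str]]:
    """Seed repertoire emulating a cpSSR-rich plastome: mostly A/T
    mononucleotide runs, some AT dinucleotides, a few longer motifs."""
    loci: list[tuple[str, int, str]] = []
    units_cycle = itertools.cycle([10, 11, 12, 13, 14, 9])
    for i in range(40):
        loci.append(("A" if i % 2 == 0 else "T", next(units_cycle), "LSC"))
    for i in range(8):
        loci.append(("A" if i % 2 == 0 else "T", next(units_cycle), "SSC"))
    for i in range(4):
        loci.append(("T" if i % 2 == 0 else "A", next(units_cycle), "IR"))
    for i in range(10):
        loci.append(("AT", 5 + i % 3, "LSC"))
    loci += [("AT", 5, "SSC"), ("AT", 6, "SSC")]
    loci += [("AAT", 4, "LSC"), ("AAT", 5, "LSC"), ("ATT", 4, "LSC"),
             ("AAG", 4, "SSC")]
    loci += [("AAAT", 3, "LSC"), ("AATAT", 3, "LSC")]
    return loci


@dataclass
class AncestralSpec:
    """Ancestral quadripartite genome blueprint.

    Sizes default to the observed plastome architecture (~160 kb total:
    LSC ~88.8 kb, SSC ~20.3 kb, IR ~25.6 kb per copy) with the region-wise
    AT fractions of those genomes (LSC 64.8%, SSC 68.3%, IR 57.0%).
    """

    lsc_len: int = 88_800
    ssc_len: int = 20_300
    ir_len: int = 25_600
    at_content_by_region: dict = field(
        default_factory=lambda: {"LSC": 0.648, "SSC": 0.683, "IR": 0.570})
    n_genes: int = 30
    ssr_seed_loci: list = field(default_factory=_default_ssr_seed_loci)
    rng_seed: int = 0

    def __post_init__(self):
        for v in (self.lsc_len, self.ssc_len, self.ir_len):
            if v <= 0:
                raise ValueError("region lengths must be positive")
        for r, at in self.at_content_by_region.items():
            if not 0 < at < 1:
                raise ValueError(f"AT fraction for {r} must be in (0,1)")
        for motif, units, region in self.ssr_seed_loci:
            if not 1 <= len(motif) <= 5:
                raise ValueError(f"seed motif {motif!r} must have unit length 1-5")

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


def _random_bases(rng, n, at):
    return rng.choice(np.frombuffer(b"ATCG", dtype=np.uint8), size=n,
                      p=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])


def build_ancestral_genome(spec: AncestralSpec) -> GenomeRecord:
    rng = np.random.default_rng(spec.rng_seed)
    at = spec.at_content_by_region
    lsc = _random_bases(rng, spec.lsc_len, at["LSC"])
    irb = _random_bases(rng, spec.ir_len, at["IR"])
    ssc = _random_bases(rng, spec.ssc_len, at["SSC"])
    prefix = bytearray(bytes(lsc) + bytes(irb) + bytes(ssc))

    b0 = spec.lsc_len
    s0 = b0 + spec.ir_len
    s1 = s0 + spec.ssc_len
    region_span = {"LSC": (0, b0), "IRb": (b0, s0), "SSC": (s0, s1),
                   "IRa": (s1, s1 + spec.ir_len)}

    genes: list[Gene] = []
    occupied: list[tuple[int, int]] = []

    def claim(start, end, pad=10) -> bool:
        for s, e in occupied:
            if start - pad < e and s < end + pad:
                return False
        occupied.append((start, end))
        return True

    # boundary genes used by junction analysis; the quadripartite junction
    # neighbourhood of real plastomes (rps19 at LSC/IRb, ycf1 into IRa)
    if spec.lsc_len > 400 and spec.ssc_len > 1700:
        g = Gene("rps19", b0 - 290, b0 - 11)
        genes.append(g); claim(g.start, g.end)
        # crosses SSC/IRa, so its tail is rewritten by IR mirroring:
        # junction annotation only, not a codon-model substrate
        g = Gene("ycf1", s1 - 1500, s1 + 55, is_cds=False)
        genes.append(g); claim(g.start, g.end)
        g = Gene("ndhF", s0 + 60, s0 + 60 + 2220)
        genes.append(g); claim(g.start, g.end)

    n_filler = max(0, spec.n_genes - len(genes))
    tries = 0
    while n_filler > 0:
        tries += 1
        if tries > 200 * spec.n_genes:
            raise SizingError("cannot place the requested gene complement")
        length = 3 * int(rng.integers(100, 400))
        start = int(rng.integers(400, max(401, spec.lsc_len - length - 400)))
        if claim(start, start + length):
            genes.append(Gene(f"gene{len(genes):03d}", start, start + length))
            n_filler -= 1

    # keep plus-strand CDS intervals free of in-frame stop codons so that
    # codon-level analyses of simulated data are well posed
    for g in genes:
        if g.is_cds and g.end <= len(prefix):
            for i in range(g.start, g.end - 2, 3):
                if bytes(prefix[i:i + 3]) in (b"TAA", b"TAG", b"TGA"):
                    prefix[i + 2] = ord("C")

    for motif, units, region in spec.ssr_seed_loci:
        span = region_span["IRb"] if region == "IR" else region_span[region]
        length = len(motif) * units
        placed = False
        for _ in range(500):
            start = int(rng.integers(span[0] + 50, span[1] - length - 50))
            if claim(start, start + length):
                prefix[start:start + length] = (motif * units).encode()
                # break the flanks so the planted unit count is exact
                others = [b for b in b"ACGT" if b != ord(motif[-1])]
                prefix[start - 1] = others[int(rng.integers(len(others)))]
                others = [b for b in b"ACGT" if b != ord(motif[0])]
                prefix[start + length] = others[int(rng.integers(len(others)))]
                placed = True
                break
        if not placed:
            raise SizingError(
                f"region {region} cannot host seeded SSR ({motif},{units})")

    ira = bytes(prefix[b0:s0]).translate(_COMPLEMENT)[::-1]
    seq = (bytes(prefix) + ira).decode()
    genes.sort(key=lambda g: g.start)
    return GenomeRecord("ancestor", seq, dict(region_span), genes)


# ---------------------------------------------------------------------------
# Evolution model


@dataclass
class EvolutionModel:
    """Branch-length units are millions of years under the default tree.

    Defaults reproduce the study conditions: ~0.53% substitution divergence
    across the deepest ingroup split (rate 6.8e-4 per site per MY of path),
    a transversion-rich spectrum (Si/Sv target 0.45), an S/I event ratio
    near 3.2, an indel size spectrum enriched at 1 bp (~32%) and 5-6 bp,
    a deletion bias, and slippage-mutable SSR loci.
    """

    sub_rate: float = 6.8e-4
    ti_tv_bias: float = 0.45
    indel_rate: float = 6.8e-4 / 3.2
    indel_size_dist: dict = field(default_factory=lambda: {
        1: 0.32, 2: 0.10, 3: 0.06, 4: 0.04, 5: 0.20, 6: 0.10, 7: 0.04,
        8: 0.03, 9: 0.02, 10: 0.02, 11: 0.014, 12: 0.014, 13: 0.014,
        14: 0.014, 15: 0.014})
    tandem_dup_fraction: float = 0.3
    ssr_slippage_rate: float = 0.04
    ins_del_bias: float = 0.8
    rng_seed: int = 0

    def __post_init__(self):
        total = sum(self.indel_size_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("indel_size_dist must sum to 1")
        if self.ti_tv_bias <= 0:
            raise ValueError("ti_tv_bias must be positive")
        for r in (self.sub_rate, self.indel_rate, self.ssr_slippage_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")


# ---------------------------------------------------------------------------
# Event log


@dataclass
class Event:
    event_id: int
    branch: str
    kind: str    # substitution | insertion | deletion | ssr_expansion | ssr_contraction
    region: str
    length: int
    payload: str
    # replay/identity fields
    site_key: tuple | None = None      # substitution site or insertion flank
    new_base: str = ""
    del_keys: tuple = ()
    new_keys: tuple = ()
    column: int = -1                   # master column, resolved post hoc

    @property
    def is_indel(self) -> bool:
        return self.kind in ("insertion", "deletion",
                             "ssr_expansion", "ssr_contraction")

    @property
    def polarity(self) -> str:
        if self.kind in ("insertion", "ssr_expansion"):
            return "insertion"
        if self.kind in ("deletion", "ssr_contraction"):
            return "deletion"
        return ""

    @property
    def keys(self) -> tuple:
        return self.new_keys if self.polarity == "insertion" else self.del_keys


@dataclass
class TrueEventLog:
    events: list
    mirror_ir: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"event_id": e.event_id, "branch": e.branch, "kind": e.kind,
              "column": e.column, "length": e.length, "region": e.region,
              "payload": e.payload} for e in self.events],
            columns=["event_id", "branch", "kind", "column", "length",
                     "region", "payload"])

    def indel_events(self) -> list:
        return [e for e in self.events if e.is_indel]


# ---------------------------------------------------------------------------
# Mutable per-node state


class _State:
    __slots__ = ("keys", "chars", "counts")

    def __init__(self, keys, chars, counts):
        self.keys = keys          # list of tuples, strictly increasing
        self.chars = chars        # bytearray parallel to keys
        self.counts = counts      # region -> site count

    def clone(self) -> "_State":
        return _State(list(self.keys), bytearray(self.chars),
                      dict(self.counts))

    @property
    def n(self) -> int:
        return len(self.keys)

    def non_ira_limit(self) -> int:
        return self.n - self.counts.get("IRa", 0)


def _ancestor_state(ancestor: GenomeRecord) -> tuple[_State, dict]:
    regions = ancestor.regions
    n = len(ancestor)
    keys: list[tuple] = []
    region_by_key: dict = {}
    for name in ("LSC", "IRb", "SSC"):
        s, e = regions[name]
        for i in range(s, e):
            k = (i,)
            keys.append(k)
            region_by_key[k] = name
    b0, b1 = regions["IRb"]
    keys.extend(ira_key((i,)) for i in range(b1 - 1, b0 - 1, -1))
    chars = bytearray(ancestor.sequence.encode())
    counts = {name: e - s for name, (s, e) in regions.items()}
    return _State(keys, chars, counts), region_by_key


def _rebuild_ira(state: _State) -> None:
    """Concerted evolution: overwrite IRa with the mirror image of IRb."""
    irb0 = state.counts["LSC"]
    irb1 = irb0 + state.counts["IRb"]
    ira0 = state.n - state.counts["IRa"]
    irb_keys = state.keys[irb0:irb1]
    irb_chars = bytes(state.chars[irb0:irb1])
    state.keys[ira0:] = [ira_key(k) for k in reversed(irb_keys)]
    state.chars[ira0:] = irb_chars.translate(_COMPLEMENT)[::-1]
    state.counts["IRa"] = irb1 - irb0


# ---------------------------------------------------------------------------
# Branch mutation machinery (shared by simulation and replay)


def _insert(state, idx_after, new_keys, payload: bytes, region,
            region_by_key) -> None:
    at = idx_after + 1
    state.keys[at:at] = new_keys
    state.chars[at:at] = payload
    for k in new_keys:
        region_by_key[k] = region
    state.counts[region] = state.counts.get(region, 0) + len(new_keys)


def _delete(state, i0, i1, region) -> None:
    del state.keys[i0:i1]
    del state.chars[i0:i1]
    state.counts[region] -= i1 - i0


_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T
_TRANSVERSIONS = {65: (67, 84), 71: (67, 84), 67: (65, 71), 84: (65, 71)}


def _mutate_base(old: int, rng, ti_tv: float) -> int:
    if rng.random() < ti_tv / (1.0 + ti_tv):
        return _TRANSITION[old]
    pair = _TRANSVERSIONS[old]
    return pair[int(rng.integers(2))]


def _simulate_branch(state: _State, blen: float, branch: str,
                     model: EvolutionModel, rng, mirror: bool,
                     region_by_key: dict, at_by_region: dict,
                     counter: itertools.count, events: list) -> None:
    limit = state.non_ira_limit() if mirror else state.n
    if limit <= 2 * _MARGIN or blen <= 0:
        return

    # --- substitutions
    n_sub = rng.poisson(model.sub_rate * blen * limit)
    for p in np.sort(rng.integers(0, limit, n_sub)):
        p = int(p)
        old = state.chars[p]
        if old not in _TRANSITION:
            continue
        new = _mutate_base(old, rng, model.ti_tv_bias)
        state.chars[p] = new
        k = state.keys[p]
        events.append(Event(next(counter), branch, "substitution",
                            _region_of_key(k, region_by_key), 1,
                            f"{chr(old)}>{chr(new)}", site_key=k,
                            new_base=chr(new)))

    # --- indels
    sizes = np.array(sorted(model.indel_size_dist))
    probs = np.array([model.indel_size_dist[s] for s in sizes])
    n_indel = rng.poisson(model.indel_rate * blen * limit)
    hot: set = set()

    def touches_hot(ks: Iterable[tuple]) -> bool:
        return any(k in hot for k in ks)

    for _ in range(n_indel):
        size = int(rng.choice(sizes, p=probs))
        is_ins = rng.random() < model.ins_del_bias / (1.0 + model.ins_del_bias)
        # adjacent-motif duplication is modelled on the insertion side; a
        # targeted search for duplicate-adjacent deletion sites would skew
        # the realized size spectrum away from indel_size_dist
        tandem = is_ins and rng.random() < model.tandem_dup_fraction
        limit = state.non_ira_limit() if mirror else state.n
        for _retry in range(100):
            if is_ins:
                p = int(rng.integers(_MARGIN, limit - _MARGIN))
                flank, right = state.keys[p - 1], state.keys[p]
                region = _region_of_key(flank, region_by_key)
                if touches_hot((flank, right)):
                    continue
                if tandem and p >= size and \
                        _region_of_key(state.keys[p - size], region_by_key) == region:
                    payload = bytes(state.chars[p - size:p])
                else:
                    payload = bytes(_random_bases(
                        rng, size, at_by_region[region]))
                eid = next(counter)
                new_keys = tuple(flank + (-eid, m) for m in range(size))
                _insert(state, p - 1, new_keys, payload, region, region_by_key)
                hot.update(new_keys); hot.add(flank); hot.add(right)
                events.append(Event(eid, branch, "insertion", region, size,
                                    payload.decode(), site_key=flank,
                                    new_keys=new_keys))
                break
            else:
                p = int(rng.integers(_MARGIN, limit - _MARGIN - size))
                span = state.keys[p:p + size]
                region = _region_of_key(span[0], region_by_key)
                if _region_of_key(span[-1], region_by_key) != region:
                    continue
                if touches_hot(span) or touches_hot(
                        (state.keys[p - 1], state.keys[p + size])):
                    continue
                payload = bytes(state.chars[p:p + size]).decode()
                eid = next(counter)
                events.append(Event(eid, branch, "deletion", region, size,
                                    payload, del_keys=tuple(span)))
                hot.add(state.keys[p - 1]); hot.add(state.keys[p + size])
                hot.update(span)
                _delete(state, p, p + size, region)
                break

    # --- SSR slippage (+/- one repeat unit per event)
    if model.ssr_slippage_rate > 0:
        limit = state.non_ira_limit() if mirror else state.n
        seq = bytes(state.chars[:limit]).decode()
        loci = find_ssrs_in_seq(seq, THRESHOLDS_A)
        p_slip = min(1.0, model.ssr_slippage_rate * blen)
        chosen = []
        for loc in loci:
            if loc.start < _MARGIN or loc.end > limit - _MARGIN:
                continue
            if rng.random() >= p_slip:
                continue
            expand = bool(rng.integers(2))
            if not expand and loc.units < 2:
                expand = True
            chosen.append((loc, expand))
        for loc, expand in reversed(chosen):  # high coords first: indices stay valid
            u = loc.unit_len
            span_keys = state.keys[loc.start - 1:loc.end + 1]
            region = _region_of_key(state.keys[loc.start], region_by_key)
            if _region_of_key(state.keys[loc.end - 1], region_by_key) != region:
                continue
            if any(k in hot for k in span_keys):
                continue
            if expand:
                payload = bytes(state.chars[loc.end - u:loc.end])
                flank = state.keys[loc.end - 1]
                eid = next(counter)
                new_keys = tuple(flank + (-eid, m) for m in range(u))
                _insert(state, loc.end - 1, new_keys, payload, region,
                        region_by_key)
                hot.update(new_keys); hot.update(span_keys)
                events.append(Event(eid, branch, "ssr_expansion", region, u,
                                    payload.decode(), site_key=flank,
                                    new_keys=new_keys))
            else:
                span = state.keys[loc.end - u:loc.end]
                payload = bytes(state.chars[loc.end - u:loc.end]).decode()
                eid = next(counter)
                events.append(Event(eid, branch, "ssr_contraction", region, u,
                                    payload, del_keys=tuple(span)))
                hot.update(span_keys)
                _delete(state, loc.end - u, loc.end, region)

    if mirror:
        _rebuild_ira(state)


# ---------------------------------------------------------------------------
# Tree plumbing


def node_label(nd: dendropy.Node) -> str:
    return nd.taxon.label if nd.taxon is not None else (nd.label or "")


def label_internal_nodes(tree: dendropy.Tree) -> None:
    i = 0
    for nd in tree.preorder_node_iter():
        if nd.taxon is None and not nd.label:
            nd.label = f"nd{i}"
        i += 1


def _validate_tree(tree: dendropy.Tree) -> None:
    leaves = tree.leaf_nodes()
    if not leaves or all(lf is tree.seed_node for lf in leaves):
        raise ValueError("tree has no leaves to evolve to")
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        if nd.edge.length is None:
            raise ValueError(f"branch above {node_label(nd)!r} lacks a length")
        if nd.edge.length < 0:
            raise ValueError(f"negative branch length above {node_label(nd)!r}")


# ---------------------------------------------------------------------------
# Main entry points


@dataclass
class SimulationResult:
    genomes: dict                 # taxon -> GenomeRecord
    alignment: MultipleAlignment  # truth alignment over all tips
    log: TrueEventLog
    tree: dendropy.Tree
    ancestor: GenomeRecord


def evolve_along_tree(ancestor: GenomeRecord, tree: dendropy.Tree,
                      model: EvolutionModel,
                      mirror_ir: bool = True) -> SimulationResult:
    _validate_tree(tree)
    label_internal_nodes(tree)
    root_state, region_by_key = _ancestor_state(ancestor)
    rng = np.random.default_rng(model.rng_seed)
    counter = itertools.count(1)
    events: list[Event] = []
    tip_states: dict[str, _State] = {}

    at_by_region = {
        name: _at_fraction(ancestor.region_sequence(name))
        for name in ancestor.regions
    }
    at_by_region.setdefault("LSC", 0.5)

    def recurse(nd: dendropy.Node, state: _State) -> None:
        if nd.is_leaf():
            tip_states[node_label(nd)] = state
            return
        for child in nd.child_nodes():
            child_state = state.clone()
            _simulate_branch(child_state, child.edge.length, node_label(child),
                             model, rng, mirror_ir, region_by_key,
                             at_by_region, counter, events)
            recurse(child, child_state)

    recurse(tree.seed_node, root_state)
    return _assemble(ancestor, tree, tip_states, events, region_by_key,
                     mirror_ir)


def _at_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("A") + seq.count("T")) / acgt if acgt else 0.5


def _assemble(ancestor, tree, tip_states, events, region_by_key,
              mirror_ir) -> SimulationResult:
    tip_order = [node_label(lf) for lf in tree.leaf_node_iter()]
    all_keys: set = set()
    for st in tip_states.values():
        all_keys.update(st.keys)
    columns = sorted(all_keys)
    col_of = {k: i for i, k in enumerate(columns)}
    ncol = len(columns)

    rows = []
    for taxon in tip_order:
        st = tip_states[taxon]
        row = np.full(ncol, GAP, dtype=np.uint8)
        idx = np.fromiter((col_of[k] for k in st.keys), dtype=np.int64,
                          count=st.n)
        row[idx] = np.frombuffer(bytes(st.chars), dtype=np.uint8)
        rows.append(row.tobytes().decode())
    aln = MultipleAlignment(tip_order, rows)

    for ev in events:
        ks = ev.keys if ev.is_indel else (ev.site_key,)
        cols = [col_of[k] for k in ks if k in col_of]
        ev.column = min(cols) if cols else -1

    genomes = {
        taxon: _tip_genome(taxon, tip_states[taxon], ancestor)
        for taxon in tip_order
    }
    return SimulationResult(genomes, aln, TrueEventLog(events, mirror_ir),
                            tree, ancestor)


def _tip_genome(taxon: str, st: _State, ancestor: GenomeRecord) -> GenomeRecord:
    counts = st.counts
    bounds = {}
    pos = 0
    for name in ("LSC", "IRb", "SSC", "IRa"):
        bounds[name] = (pos, pos + counts.get(name, 0))
        pos += counts.get(name, 0)

    # map surviving ancestral coordinates to tip coordinates for gene lift-over
    b0, b1 = ancestor.regions["IRb"]
    a0, _ = ancestor.regions["IRa"]
    anc_idx, tip_idx = [], []
    for i, k in enumerate(st.keys):
        if len(k) == 1:
            anc_idx.append(k[0]); tip_idx.append(i)
        elif k[0] == _IRA_BASE and len(k) == 3:
            anc_idx.append(a0 + (b1 - 1 - (-k[1]))); tip_idx.append(i)
    order = np.argsort(anc_idx)
    anc_arr = np.asarray(anc_idx)[order]
    tip_arr = np.asarray(tip_idx)[order]

    genes = []
    for g in ancestor.genes:
        lo = int(np.searchsorted(anc_arr, g.start, side="left"))
        hi = int(np.searchsorted(anc_arr, g.end - 1, side="right")) - 1
        if lo > hi or lo >= anc_arr.shape[0]:
            continue
        genes.append(Gene(g.name, int(tip_arr[lo]), int(tip_arr[hi]) + 1,
                          g.strand, g.is_cds))
    return GenomeRecord(taxon, bytes(st.chars).decode(), bounds, genes)


def replay_event_log(ancestor: GenomeRecord, tree: dendropy.Tree,
                     log: TrueEventLog) -> dict[str, str]:
    """Re-apply the recorded events from the ancestor; returns tip sequences.

    Uses only the recorded event structure (no RNG); the result must be
    byte-identical to the simulated tip genomes.
    """
    label_internal_nodes(tree)
    root_state, region_by_key = _ancestor_state(ancestor)
    by_branch: dict[str, list[Event]] = {}
    for ev in log.events:
        by_branch.setdefault(ev.branch, []).append(ev)
    tips: dict[str, str] = {}

    def apply_branch(state: _State, branch: str) -> None:
        for ev in by_branch.get(branch, ()):
            if ev.kind == "substitution":
                i = bisect_left(state.keys, ev.site_key)
                state.chars[i] = ord(ev.new_base)
            elif ev.polarity == "insertion":
                i = bisect_right(state.keys, ev.site_key) - 1
                _insert(state, i, ev.new_keys, ev.payload.encode(),
                        ev.region, region_by_key)
            else:
                i = bisect_left(state.keys, ev.del_keys[0])
                _delete(state, i, i + len(ev.del_keys), ev.region)
        if log.mirror_ir:
            _rebuild_ira(state)

    def recurse(nd, state):
        if nd.is_leaf():
            tips[node_label(nd)] = bytes(state.chars).decode()
            return
        for child in nd.child_nodes():
            cs = state.clone()
            apply_branch(cs, node_label(child))
            recurse(child, cs)

    recurse(tree.seed_node, root_state)
    return tips


# ---------------------------------------------------------------------------
# Default study-condition tree and group labels


A_TAXA = ("A1", "A2")
D_TAXA = ("D5", "D6")
AD_TAXA = ("AD1", "AD1h", "AD1l", "AD2", "AD2k", "AD2y", "AD3", "AD4", "AD5")
OUTGROUP = "OUT"

_DEFAULT_NEWICK = (
    "(OUT:10.0,((D5:0.77,D6:0.77)D:3.12,((A1:0.13,A2:0.13)A:0.42,"
    "(((AD1:0.04,(AD1h:0.02,AD1l:0.02)AD1r:0.02)AD1c:0.26,AD3:0.30)AD13:0.08,"
    "(((AD2:0.04,(AD2k:0.02,AD2y:0.02)AD2r:0.02)AD2c:0.05,AD5:0.09)AD25:0.21,"
    "AD4:0.30)AD24:0.08)AD:0.17)AAD:3.34)ING:6.11)ROOT;"
)


def default_tree() -> dendropy.Tree:
    """Fixed rooted 14-taxon tree: one outgroup, 2+2 diploids, 9
    allotetraploids in four groups; branch lengths in millions of years with
    node heights matching the clock-dated splits (A/D 3.89 MY, tetraploid
    formation 0.55 MY, tetraploid crown 0.38 MY, ...)."""
    return tree_from_string(_DEFAULT_NEWICK)


def default_group_labels() -> dict[str, str]:
    labels = {t: "A_diploid" for t in A_TAXA}
    labels.update({t: "D_diploid" for t in D_TAXA})
    labels.update({t: "allotetraploid" for t in AD_TAXA})
    labels[OUTGROUP] = "outgroup"
    return labels


def simulate_dataset(spec: AncestralSpec | None = None,
                     model: EvolutionModel | None = None,
                     tree: dendropy.Tree | None = None,
                     mirror_ir: bool = True,
                     seed: int | None = None) -> SimulationResult:
    """One-call study-condition simulation; ``seed`` overrides both the
    ancestral and the evolution RNG streams."""
    spec = spec or AncestralSpec()
    model = model or EvolutionModel()
    if seed is not None:
        spec = replace(spec, rng_seed=seed)
        model = replace(model, rng_seed=seed + 1)
    tree = tree or default_tree()
    ancestor = build_ancestral_genome(spec)
    return evolve_along_tree(ancestor, tree, model, mirror_ir=mirror_ir)


# ---------------------------------------------------------------------------
# Dataset emission


def emit_dataset(result: SimulationResult, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": out / "genomes.fasta",
        "alignment": out / "alignment.fasta",
        "regions": out / "regions.tsv",
        "features": out / "features.gff3",
        "tree": out / "tree.nwk",
        "events": out / "events.tsv",
    }
    write_genomes(result.genomes.values(), paths["genomes"])
    write_alignment(result.alignment, paths["alignment"])
    write_regions({t: g.regions for t, g in result.genomes.items()},
                  paths["regions"])
    write_features({t: g.genes for t, g in result.genomes.items()},
                   paths["features"])
    write_tree(result.tree, paths["tree"])
    write_event_table(result.log.to_frame(), paths["events"])
    labels = default_group_labels()
    if set(result.genomes) <= set(labels):
        paths["groups"] = out / "groups.tsv"
        pd.DataFrame(
            [{"taxon": t, "group": labels[t]} for t in result.genomes],
            columns=["taxon", "group"]).to_csv(paths["groups"], sep="\t",
                                               index=False)
    return paths
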