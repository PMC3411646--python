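"""Readers/writers for every format the pipeline touches.

Internal coordinate convention is 0-based half-open everywhere; GFF3 is
converted to/from its native 1-based inclusive form at the file boundary.
The only gap character accepted is ``-``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

GAP = ord("-")
BASES = frozenset(b"ACGT")
REGION_ORDER = ("LSC", "IRb", "SSC", "IRa")

EVENT_TABLE_COLUMNS = [
    "event_id", "branch", "kind", "column", "length", "region", "payload",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised for inputs that parse but violate an invariant."""


@dataclass
class Gene:
    name: str
    start: int
    end: int
    strand: str = "+"
    is_cds: bool = True


@dataclass
class GenomeRecord:
    """One plastome: sequence plus its region map and gene features.

    ``regions`` maps region name -> (start, end), 0-based half-open on the
    linearized genome; a quadripartite genome partitions [0, len) in the
    order LSC, IRb, SSC, IRa.
    """

    taxon_id: str
    sequence: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValidationError(f"{self.taxon_id}: non-ACGTN characters {bad}")
        if self.regions:
            spans = sorted(self.regions.values())
            if spans[0][0] != 0 or spans[-1][1] != n:
                raise ValidationError(
                    f"{self.taxon_id}: regions do not partition [0, {n})")
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                if e0 != s1:
                    raise ValidationError(
                        f"{self.taxon_id}: regions overlap or leave a gap at {e0}")
        for g in self.genes:
            if g.start < 0 or g.end > n or g.start >= g.end:
                raise ValidationError(
                    f"{self.taxon_id}: gene {g.name} outside [0, {n})")

    def region_of(self, pos: int) -> str:
        for name, (s, e) in self.regions.items():
            if s <= pos < e:
                return name
        raise ValidationError(f"position {pos} not covered by a region")

    def region_sequence(self, name: str) -> str:
        s, e = self.regions[name]
        return self.sequence[s:e]


class MultipleAlignment:
    """Column-indexed aligned taxa with pairwise projection support.

    Rows are stored as a uint8 matrix of ASCII codes; all rows have equal
    length and the gap character is ``-``.
    """

    def __init__(self, taxa: Sequence[str], rows: Sequence[str]):
        taxa = list(taxa)
        if len(taxa) != len(set(taxa)):
            raise FormatError("duplicate taxon ids in alignment")
        if not taxa:
            raise FormatError("empty alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
        self.taxa = taxa
        joined = "".join(rows).encode("ascii")
        self.matrix = np.frombuffer(joined, dtype=np.uint8).reshape(
            len(taxa), lengths.pop()).copy()
        bad = set(np.unique(self.matrix).tobytes()) - set(b"ACGTN-")
        if bad:
            raise FormatError(
                f"illegal alignment characters: {sorted(chr(c) for c in bad)}")
        self._index = {t: i for i, t in enumerate(taxa)}

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.length

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.matrix[self._index[taxon]]
        except KeyError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def row_str(self, taxon: str) -> str:
        return self.row(taxon).tobytes().decode()

    def sequence(self, taxon: str) -> str:
        r = self.row(taxon)
        return r[r != GAP].tobytes().decode()

    def column_to_seq_pos(self, taxon: str) -> np.ndarray:
        """Per-column ungapped position for ``taxon``; -1 at gap columns."""
        r = self.row(taxon)
        nongap = r != GAP
        pos = np.cumsum(nongap) - 1
        pos[~nongap] = -1
        return pos

    def pos_to_column(self, taxon: str) -> np.ndarray:
        """Alignment column of each ungapped sequence position of ``taxon``."""
        r = self.row(taxon)
        return np.flatnonzero(r != GAP)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, MultipleAlignment)
                and self.taxa == other.taxa
                and np.array_equal(self.matrix, other.matrix))


@dataclass
class PairwiseView:
    """The columns of a master alignment where not both of two taxa are gaps."""

    taxon_a: str
    taxon_b: str
    row_a: np.ndarray           # uint8, len = n view columns
    row_b: np.ndarray
    master_columns: np.ndarray  # int, back-map into the master alignment

    @property
    def length(self) -> int:
        return self.row_a.shape[0]


def project_pairwise(aln: MultipleAlignment, a: str, b: str) -> PairwiseView:
    ra, rb = aln.row(a), aln.row(b)
    keep = ~((ra == GAP) & (rb == GAP))
    cols = np.flatnonzero(keep)
    return PairwiseView(a, b, ra[cols].copy(), rb[cols].copy(), cols)


# ---------------------------------------------------------------------------
# FASTA

def _read_fasta_records(path) -> list[tuple[str, str]]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    out = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate taxon id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if "." in seq:
            raise FormatError(f"{path}: '.' gap dialect rejected; use '-'")
        if any(c.islower() for c in seq):
            warnings.warn(f"{path}: lowercase bases in {rec.id} read as uppercase")
            seq = seq.upper()
        out.append((rec.id, seq))
    return out


def read_alignment(path) -> MultipleAlignment:
    recs = _read_fasta_records(path)
    lengths = {len(s) for _, s in recs}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged aligned FASTA, lengths {sorted(lengths)}")
    return MultipleAlignment([t for t, _ in recs], [s for _, s in recs])


def write_alignment(aln: MultipleAlignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in aln.taxa:
            fh.write(f">{t}\n")
            s = aln.row_str(t)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_genomes(path) -> dict[str, GenomeRecord]:
    """Unaligned FASTA -> bare GenomeRecords (no regions/genes)."""
    return {t: GenomeRecord(t, s) for t, s in _read_fasta_records(path)}


def write_genomes(genomes: Iterable[GenomeRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.taxon_id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Region tables (BED-like TSV: taxon, region, start, end; 0-based half-open)

def read_regions(path) -> dict[str, dict[str, tuple[int, int]]]:
    df = pd.read_csv(path, sep="\t", dtype={"taxon": str, "region": str})
    expected = ["taxon", "region", "start", "end"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: region table columns must be {expected}")
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        if row.region not in REGION_ORDER:
            raise FormatError(f"{path}: unknown region {row.region!r}")
        out.setdefault(row.taxon, {})[row.region] = (int(row.start), int(row.end))
    for taxon, regs in out.items():
        spans = sorted(regs.values())
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValidationError(f"{path}: overlapping regions for {taxon}")
    return out


def write_regions(regions: Mapping[str, Mapping[str, tuple[int, int]]], path) -> None:
    rows = [
        {"taxon": t, "region": r, "start": s, "end": e}
        for t, regs in regions.items()
        for r, (s, e) in sorted(regs.items(), key=lambda kv: kv[1])
    ]
    pd.DataFrame(rows, columns=["taxon", "region", "start", "end"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 subset (gene features; 1-based inclusive on disk, CDS phase 0 only)

def read_features(path) -> dict[str, list[Gene]]:
    out: dict[str, list[Gene]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in ("gene", "CDS"):
                continue
            name = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID=") or kv.startswith("Name="):
                    name = kv.split("=", 1)[1]
                    break
            if not name:
                raise FormatError(f"{path}:{lineno}: feature lacks ID/Name")
            out.setdefault(seqid, []).append(
                Gene(name, int(start) - 1, int(end), strand, ftype == "CDS"))
    return out


def write_features(features: Mapping[str, Sequence[Gene]], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for taxon, genes in features.items():
            for g in sorted(genes, key=lambda g: g.start):
                ftype = "CDS" if g.is_cds else "gene"
                phase = "0" if g.is_cds else "."
                fh.write("\t".join([
                    taxon, "plastdiverge", ftype, str(g.start + 1), str(g.end),
                    ".", g.strand, phase, f"ID={g.name}",
                ]) + "\n")


# ---------------------------------------------------------------------------
# Newick

def read_tree(path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"{path}: unparseable Newick ({exc})") from exc
    tree.is_rooted = True
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Event tables

def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"payload": str, "branch": str, "kind": str,
                            "region": str})
    if list(df.columns) != EVENT_TABLE_COLUMNS:
        raise FormatError(f"{path}: event table columns must be {EVENT_TABLE_COLUMNS}")
    return df


def write_event_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=EVENT_TABLE_COLUMNS)
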