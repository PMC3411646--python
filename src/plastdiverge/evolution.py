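"""Codon-level Ka/Ks (Nei–Gojobori 1986 with Jukes–Cantor correction),
synonymous-rate calibration, clock dating, and Tajima's relative rate test.

The NG86 estimator counts synonymous site fractions per codon (averaged
over both sequences), averages multi-hit codons over all substitution
orderings with stop-codon paths excluded, and applies
``d = -(3/4) ln(1 - 4p/3)``; ``p >= 3/4`` flags saturation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import isnan, log

import numpy as np
from scipy.stats import chi2

from .io import GAP, MultipleAlignment

_BASES = "TCAG"
_CODON_TABLE_11 = {}  # standard plastid/bacterial code
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(
        (a, b, c) for a in _BASES for b in _BASES for c in _BASES):
    _CODON_TABLE_11[_b1 + _b2 + _b3] = _AA[_i]
STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE_11.items() if aa == "*")


def translate_codon(codon: str) -> str:
    return _CODON_TABLE_11[codon]


@dataclass
class KaKsResult:
    ka: float
    ks: float
    n_sites: float
    s_sites: float
    n_diff_n: float
    n_diff_s: float
    n_codons: int
    saturated_s: bool = False
    saturated_n: bool = False

    @property
    def omega(self) -> float:
        if self.ks == 0 or isnan(self.ks) or isnan(self.ka):
            return float("nan")
        return self.ka / self.ks


@dataclass
class RateCalibration:
    rs: float                  # synonymous substitutions / site / year
    ra: float = float("nan")
    source: str = ""

    def __post_init__(self):
        if not self.rs > 0:
            raise ValueError("rs must be positive for dating")


@dataclass
class DatingResult:
    pair: tuple[str, str]
    t_my: float
    basis: str = "Ks"
    saturated: bool = False


@dataclass
class RelativeRateResult:
    n_a: int                   # columns where only lineage A is derived
    n_b: int
    chi_square: float
    p_value: float
    n_columns: int
    undefined: bool = False

    @property
    def significance(self) -> str:
        if self.undefined or self.p_value >= 0.05:
            return ""
        return "**" if self.p_value < 0.01 else "*"


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 possible changes at ``pos`` that are synonymous;
    changes to stop codons count as nonsynonymous."""
    aa = _CODON_TABLE_11[codon]
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if _CODON_TABLE_11[alt] == aa:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> float:
    return _SITES_CACHE[codon]


_SITES_CACHE: dict[str, float] = {}
for _c in _CODON_TABLE_11:
    _SITES_CACHE[_c] = sum(_syn_fraction(_c, p) for p in range(3))

_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all substitution orderings; paths through stops are dropped and
    the weights renormalized (all-blocked codons fall back to equal
    weighting)."""
    cached = _DIFF_CACHE.get((c1, c2))
    if cached is not None:
        return cached
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODON_TABLE_11[nxt] == "*" and nxt != c2:
                blocked = True
            if _CODON_TABLE_11[nxt] == _CODON_TABLE_11[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [(sd, nd) for sd, nd, blocked in paths if not blocked]
    if not usable:
        usable = [(sd, nd) for sd, nd, _ in paths]
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    _DIFF_CACHE[(c1, c2)] = (sd, nd)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); p >= 3/4 is saturated (returns nan)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_ka_ks(seq1: str, seq2: str,
               on_internal_stop: str = "raise") -> KaKsResult:
    """Nei–Gojobori Ka/Ks for a pair of in-frame aligned coding sequences.

    Codons containing a gap or N in either sequence are dropped pairwise.
    Internal stop codons are rejected by default; ``on_internal_stop="mask"``
    drops the offending codon instead (for bulk pipeline use where isolated
    frame damage should not abort a whole-genome summary).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    if len(seq1) % 3:
        raise ValueError("length must be a multiple of 3")
    seq1, seq2 = seq1.upper(), seq2.upper()
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    codons = [(seq1[i:i + 3], seq2[i:i + 3]) for i in range(0, len(seq1), 3)]
    last = len(codons) - 1
    for idx, (c1, c2) in enumerate(codons):
        if set(c1 + c2) - set("ACGT"):
            continue  # gap- or N-containing codon: dropped pairwise
        if (c1 in STOP_CODONS or c2 in STOP_CODONS):
            if idx != last and on_internal_stop == "raise":
                raise ValueError(f"internal stop codon at codon {idx}")
            continue  # terminal stop contributes no sites; masked if internal
        n_codons += 1
        s1, s2 = _codon_sites(c1), _codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += 3.0 - (s1 + s2) / 2.0
        d_s, d_n = _codon_differences(c1, c2)
        sd += d_s
        nd += d_n
    p_s = sd / s_sites if s_sites else 0.0
    p_n = nd / n_sites if n_sites else 0.0
    ks = jukes_cantor(p_s)
    ka = jukes_cantor(p_n)
    return KaKsResult(ka=ka, ks=ks, n_sites=n_sites, s_sites=s_sites,
                      n_diff_n=nd, n_diff_s=sd, n_codons=n_codons,
                      saturated_s=isnan(ks), saturated_n=isnan(ka))


# ---------------------------------------------------------------------------
# Calibration and dating: T = Ks / (2 rs)


def calibrate_rate(ks: float, t_cal_years: float,
                   ka: float = float("nan"), source: str = "") -> RateCalibration:
    if t_cal_years <= 0:
        raise ValueError("calibration time must be positive")
    ra = ka / (2.0 * t_cal_years) if not isnan(ka) else float("nan")
    return RateCalibration(rs=ks / (2.0 * t_cal_years), ra=ra, source=source)


def divergence_time(ks: float, calibration: RateCalibration,
                    pair: tuple[str, str] = ("", "")) -> DatingResult:
    if isnan(ks):
        return DatingResult(pair, float("nan"), saturated=True)
    t_years = ks / (2.0 * calibration.rs)
    return DatingResult(pair, t_years / 1e6)


# ---------------------------------------------------------------------------
# Tajima's relative rate test


def tajima_rrt_counts(n_a: int, n_b: int, n_columns: int = 0) -> RelativeRateResult:
    """chi^2 = (nA - nB)^2 / (nA + nB) on 1 df; nA + nB = 0 is undefined
    and reported as p = 1 with a flag."""
    if n_a + n_b == 0:
        return RelativeRateResult(n_a, n_b, 0.0, 1.0, n_columns, undefined=True)
    stat = (n_a - n_b) ** 2 / (n_a + n_b)
    return RelativeRateResult(n_a, n_b, stat, float(chi2.sf(stat, df=1)),
                              n_columns)


def tajima_rrt(aln: MultipleAlignment, taxon_a: str, taxon_b: str,
               outgroup: str) -> RelativeRateResult:
    """Relative-rate test on all gap-free, N-free columns of the three rows.

    nA counts columns where A differs while B matches the outgroup
    (lineage-A-unique differences); nB symmetrically.
    """
    ra, rb, ro = (aln.row(t) for t in (taxon_a, taxon_b, outgroup))
    clean = np.ones(ra.shape[0], dtype=bool)
    for r in (ra, rb, ro):
        clean &= (r != GAP) & (r != ord("N"))
    n_a = int(((ra != rb) & (rb == ro) & clean).sum())
    n_b = int(((rb != ra) & (ra == ro) & clean).sum())
    return tajima_rrt_counts(n_a, n_b, int(clean.sum()))
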