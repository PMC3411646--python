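import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastdiverge.io import GenomeRecord
from plastdiverge.ssr import (SSRGroup, SSRLocus, THRESHOLDS_A, THRESHOLDS_B,
                              ThresholdSet, attribute_short_indels,
                              canonical_motif, find_ssrs, find_ssrs_in_seq,
                              group_is_polymorphic, polymorphism_stats,
                              ssr_locus_homology)
from plastdiverge.synthetic import revcomp

from conftest import make_aln


class TestScanner:
    def test_mononucleotide_at_threshold(self):
        loci = find_ssrs_in_seq("CC" + "A" * 8 + "GG", THRESHOLDS_A)
        assert len(loci) == 1
        l = loci[0]
        assert (l.motif, l.unit_len, l.start, l.end) == ("A", 1, 2, 10)

    def test_below_threshold_ignored(self):
        assert find_ssrs_in_seq("CC" + "A" * 7 + "GG", THRESHOLDS_A) == []

    def test_dinucleotide_at_threshold(self):
        loci = find_ssrs_in_seq("ATATATAT", THRESHOLDS_A)
        assert len(loci) == 1
        assert (loci[0].motif, loci[0].unit_len) == ("AT", 2)

    def test_run_reported_at_smallest_generating_unit(self):
        loci = find_ssrs_in_seq("G" + "A" * 10 + "G", THRESHOLDS_A)
        assert [l.unit_len for l in loci] == [1]

    def test_trailing_partial_unit_truncated(self):
        loci = find_ssrs_in_seq("G" + "ATC" * 4 + "AT" + "GGG", THRESHOLDS_A)
        [l] = [l for l in loci if l.unit_len == 3]
        assert l.end - l.start == 12

    def test_shifted_repeat_found_maximally(self):
        # a period-2 chain whose first candidate start is a red herring
        loci = find_ssrs_in_seq("AXAGAGAGAGAG", ThresholdSet(
            {1: 8, 2: 8, 3: 9, 4: 12, 5: 15}))
        [l] = loci
        assert (l.start, l.end, l.motif) == (2, 12, "AG")

    def test_determinism_and_revcomp_consistency(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 3000,
                                 p=[0.32, 0.18, 0.18, 0.32]))
        loci = find_ssrs_in_seq(seq, THRESHOLDS_A)
        assert loci == find_ssrs_in_seq(seq, THRESHOLDS_A)
        rc = find_ssrs_in_seq(revcomp(seq), THRESHOLDS_A)
        mapped = sorted((len(seq) - l.end, l.length,
                         canonical_motif(revcomp(l.motif))) for l in rc)
        fwd = sorted((l.start, l.length, l.motif) for l in loci)
        assert len(mapped) == len(fwd)
        for (ms, ml, mm), (fs, fl, fm) in zip(mapped, fwd):
            # a trailing partial unit truncates on opposite ends of the two
            # strands, so starts may differ by up to unit_len - 1
            assert mm == fm and ml == fl and abs(ms - fs) < len(fm)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 2000,
                                     p=[0.35, 0.15, 0.15, 0.35]))
            a = {(l.start, l.end, l.motif)
                 for l in find_ssrs_in_seq(seq, THRESHOLDS_A)}
            b = {(l.start, l.end, l.motif)
                 for l in find_ssrs_in_seq(seq, THRESHOLDS_B)}
            assert b <= a

    def test_region_annotation(self):
        g = GenomeRecord("t", "C" * 10 + "A" * 9 + "C" * 5 + "T" * 8 + "C" * 8,
                         {"LSC": (0, 20), "IRb": (20, 30), "SSC": (30, 35),
                          "IRa": (35, 40)})
        loci = find_ssrs(g)
        assert [(l.motif, l.region) for l in loci] == \
            [("C", "LSC"), ("A", "LSC"), ("T", "IRb"), ("C", "SSC")]


class TestCanonicalMotifProperties:
    @given(st.text(alphabet="ACGT", min_size=1, max_size=5),
           st.integers(min_value=0, max_value=4))
    @settings(max_examples=200, derandomize=True)
    def test_rotation_invariant_and_idempotent(self, motif, k):
        k = k % len(motif)
        rotated = motif[k:] + motif[:k]
        canon = canonical_motif(motif)
        assert canonical_motif(rotated) == canon
        assert canonical_motif(canon) == canon
        assert len(canon) == len(motif)


class TestCanonicalMotif:
    @pytest.mark.parametrize("raw,expected", [
        ("TA", "AT"), ("GAA", "AAG"), ("A", "A"), ("CAG", "AGC")])
    def test_smallest_rotation(self, raw, expected):
        assert canonical_motif(raw) == expected

    def test_strand_not_collapsed(self):
        assert canonical_motif("AG") != canonical_motif("CT")


class TestHomology:
    def test_overlapping_same_motif_grouped(self):
        aln = make_aln({"t1": "CC" + "A" * 8 + "-GG",
                        "t2": "CC" + "A" * 9 + "GG"})
        loci = {t: find_ssrs_in_seq(aln.sequence(t), THRESHOLDS_A, t)
                for t in aln.taxa}
        groups = ssr_locus_homology(aln, loci)
        assert len(groups) == 1
        assert set(groups[0].members) == {"t1", "t2"}

    def test_different_motifs_not_grouped(self):
        aln = make_aln({"t1": "C" + "AT" * 5 + "C",
                        "t2": "C" + "AG" * 5 + "C"})
        loci = {t: find_ssrs_in_seq(aln.sequence(t), THRESHOLDS_A, t)
                for t in aln.taxa}
        groups = ssr_locus_homology(aln, loci)
        assert len(groups) == 2

    def test_locus_outside_sequence_rejected(self):
        aln = make_aln({"t1": "ACGT"})
        bad = {"t1": [SSRLocus("t1", "A", 1, 0, 10)]}
        with pytest.raises(ValueError):
            ssr_locus_homology(aln, bad)


class TestPolymorphism:
    def _group(self, lengths):
        members = {t: SSRLocus(t, "A", 1, 0, n) for t, n in lengths.items()
                   if n > 0}
        return SSRGroup("A", 1, members, 0, max(lengths.values()))

    def test_identical_lengths_conserved(self):
        g = self._group({"t1": 8, "t2": 8, "t3": 8})
        _, summary = polymorphism_stats([g], ["t1", "t2", "t3"])
        assert summary.loc[0, "n_conserved"] == 1

    def test_length_difference_is_polymorphic(self):
        g = self._group({"t1": 8, "t2": 9})
        assert group_is_polymorphic(g, "t1", "t2")
        matrix, _ = polymorphism_stats([g], ["t1", "t2"])
        assert matrix.loc["t1", "t2"] == 1

    def test_absence_counts_as_zero_length(self):
        g = self._group({"t1": 8, "t2": 0})
        assert group_is_polymorphic(g, "t1", "t2")

    def test_pair_matrix_symmetric_zero_diagonal(self, small_sim):
        aln = small_sim.alignment
        loci = {t: find_ssrs(g) for t, g in small_sim.genomes.items()}
        groups = ssr_locus_homology(aln, loci)
        matrix, _ = polymorphism_stats(groups, aln.taxa)
        assert (matrix.values == matrix.values.T).all()
        assert (np.diag(matrix.values) == 0).all()


class TestAttribution:
    def test_short_indel_in_polymorphic_group_attributed(self):
        class Ev:
            col_start, col_end, length = 3, 4, 1
        g = SSRGroup("A", 1, {"t1": SSRLocus("t1", "A", 1, 0, 9)}, 0, 9)
        att, unatt, frac = attribute_short_indels([Ev()], [g], ("t1", "t2"))
        assert (att, unatt, frac) == (1, 0, 1.0)

    def test_indel_outside_groups_not_attributed(self):
        class Ev:
            col_start, col_end, length = 50, 52, 2
        g = SSRGroup("A", 1, {"t1": SSRLocus("t1", "A", 1, 0, 9)}, 0, 9)
        att, unatt, frac = attribute_short_indels([Ev()], [g], ("t1", "t2"))
        assert (att, unatt) == (0, 1)

    def test_long_indels_ignored(self):
        class Ev:
            col_start, col_end, length = 2, 8, 6
        att, unatt, frac = attribute_short_indels([Ev()], [], ("t1", "t2"))
        assert att + unatt == 0 and np.isnan(frac)


def test_slippage_only_evolution_touches_only_ssr_loci(small_sim_subs_only):
    """With substitutions only there are no indels at all; with slippage only
    every event is an SSR expansion/contraction."""
    from plastdiverge.synthetic import AncestralSpec, EvolutionModel, simulate_dataset
    from conftest import SMALL_SPEC
    model = EvolutionModel(sub_rate=0.0, indel_rate=0.0)
    res = simulate_dataset(spec=AncestralSpec(**SMALL_SPEC), model=model, seed=9)
    kinds = {e.kind for e in res.log.events}
    assert kinds <= {"ssr_expansion", "ssr_contraction"}
    assert res.log.events  # slippage did occur at the seeded loci
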