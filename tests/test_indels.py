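import numpy as np
import pytest

from plastdiverge.divergence import extract_indels
from plastdiverge.indels import (GapLocus, GroupLabels,
                                 assign_events_to_branches, branch_for_event,
                                 classify_pattern, indel_ratio,
                                 indel_size_spectrum, multi_taxon_indel_loci,
                                 polarize_indels, spectrum_summary,
                                 tandem_dup_check)
from plastdiverge.io import project_pairwise
from plastdiverge.synthetic import (AD_TAXA, A_TAXA, D_TAXA, OUTGROUP,
                                    default_group_labels, default_tree)

from conftest import make_aln

GROUPS = GroupLabels(default_group_labels())
ALL_TAXA = frozenset(default_group_labels())


def locus(gapped) -> GapLocus:
    return GapLocus(0, 5, frozenset(gapped))


class TestLoci:
    def test_single_taxon_gap_run(self):
        aln = make_aln({"t1": "AAAAAAA", "t2": "AA-----", "t3": "AAAAAAA"})
        loci = multi_taxon_indel_loci(aln)
        assert len(loci) == 1
        assert (loci[0].col_start, loci[0].col_end) == (2, 7)
        assert loci[0].gapped_taxa == {"t2"}

    def test_nested_gaps_split_at_pattern_change(self):
        #            0123456789
        rows = {"t1": "AAAAAAAAAA",
                "t2": "AAA-----AA",
                "t3": "AAAAA---AA"}
        loci = multi_taxon_indel_loci(make_aln(rows))
        assert [(l.col_start, l.col_end, set(l.gapped_taxa)) for l in loci] == \
            [(3, 5, {"t2"}), (5, 8, {"t2", "t3"})]

    def test_simulated_single_branch_deletion_gaps_that_clade(self, small_sim):
        loci = multi_taxon_indel_loci(small_sim.alignment)
        clean = [e for e in small_sim.log.indel_events()
                 if e.kind == "deletion" and e.branch == "D" and e.column >= 0]
        starts = np.array([l.col_start for l in loci])
        hits = 0
        for ev in clean:
            i = int(np.searchsorted(starts, ev.column, side="right")) - 1
            if i >= 0 and loci[i].col_start <= ev.column < loci[i].col_end \
                    and loci[i].gapped_taxa == set(D_TAXA):
                hits += 1
        assert clean and hits >= 0.9 * len(clean)

    def test_pairwise_counts_consistent_with_loci(self, small_sim):
        """Pairwise indel events equal the loci at which exactly one of the
        two taxa is gapped (terminal loci aside)."""
        aln = small_sim.alignment
        a, b = "A1", "AD4"
        loci = multi_taxon_indel_loci(aln)
        one_gapped = [l for l in loci
                      if (a in l.gapped_taxa) != (b in l.gapped_taxa)]
        # merge adjacent loci that are identical from the pair's viewpoint
        merged = []
        for l in one_gapped:
            side = a in l.gapped_taxa
            if merged and merged[-1][1] == l.col_start and merged[-1][2] == side:
                merged[-1] = (merged[-1][0], l.col_end, side)
            else:
                merged.append((l.col_start, l.col_end, side))
        events = extract_indels(project_pairwise(aln, a, b))
        assert abs(len(events) - len(merged)) <= 2  # terminal-run exclusion


class TestClassification:
    def test_ad_stage1_deletion(self):
        verdict = classify_pattern(frozenset(AD_TAXA), GROUPS)
        assert verdict == ("deletion", "AD", 1, frozenset(AD_TAXA))

    def test_d_stage1_insertion_when_outgroup_gapped(self):
        gapped = frozenset({OUTGROUP}) | frozenset(A_TAXA) | frozenset(AD_TAXA)
        verdict = classify_pattern(gapped, GROUPS)
        assert verdict == ("insertion", "D", 1, frozenset(D_TAXA))

    def test_a_stage1_and_2_and_3(self):
        v = classify_pattern(frozenset(A_TAXA) | frozenset(AD_TAXA), GROUPS)
        assert v[:3] == ("deletion", "A", 1)
        v = classify_pattern(frozenset(A_TAXA), GROUPS)
        assert v[:3] == ("deletion", "A", 2)
        v = classify_pattern(frozenset({"A1"}), GROUPS)
        assert v[:3] == ("deletion", "A", 3)

    def test_ad_stage2_subset(self):
        v = classify_pattern(frozenset({"AD2", "AD2k", "AD2y"}), GROUPS)
        assert v[:3] == ("deletion", "AD", 2)

    def test_mixed_pattern_unmatched(self):
        gapped = frozenset({"A1", "AD1", "AD2", "AD3"})
        assert classify_pattern(gapped, GROUPS) is None

    def test_whole_ingroup_pattern_unmatched(self):
        assert classify_pattern(ALL_TAXA - {OUTGROUP}, GROUPS) is None


class TestPolarize:
    def test_partition_every_locus_classified_once(self, small_sim):
        loci = multi_taxon_indel_loci(small_sim.alignment)
        polarized = polarize_indels(loci, GROUPS)
        assert len(polarized) == len(loci)
        for p in polarized:
            assert p.polarity in ("insertion", "deletion", "unpolarized")

    def test_unpolarized_records_reason(self):
        out = polarize_indels([locus({"A1", "AD1", "AD2", "AD3"})], GROUPS)
        assert out[0].polarity == "unpolarized"
        assert out[0].reason == "no stage rule matches"

    def test_ssr_mask_flagging(self):
        out = polarize_indels([locus(AD_TAXA)], GROUPS, ssr_mask=[(0, 10)])
        assert out[0].ssr_associated and out[0].polarity == "deletion"

    def test_root_adjacent_flip_inverts_polarity(self):
        """Flipping the outgroup state at a D stage-1 locus yields the
        mirrored A stage-1 pattern with opposite polarity."""
        v1 = classify_pattern(frozenset(D_TAXA), GROUPS)
        v2 = classify_pattern(frozenset(D_TAXA) | {OUTGROUP}, GROUPS)
        assert v1[0] == "deletion" and v2[0] == "insertion"

    def test_tetraploid_crown_flip_is_unpolarizable(self):
        flipped = frozenset(AD_TAXA) | {OUTGROUP}
        assert classify_pattern(flipped, GROUPS) is None


class TestBranchAssignment:
    def test_stage1_ad_event_maps_to_crown_stem(self):
        tree = default_tree()
        [pol] = polarize_indels([locus(AD_TAXA)], GROUPS)
        assert branch_for_event(pol, tree) == "AD"

    def test_terminal_event_maps_to_pendant(self):
        tree = default_tree()
        [pol] = polarize_indels([locus({"AD5"})], GROUPS)
        assert branch_for_event(pol, tree) == "AD5"

    def test_non_clade_subset_flagged(self):
        tree = default_tree()
        [pol] = polarize_indels([locus({"AD3", "AD5"})], GROUPS)
        df = assign_events_to_branches([pol], tree)
        assert list(df["branch"]) == ["(non-clade)"]

    def test_tallies_split_by_polarity(self):
        tree = default_tree()
        # second locus: everything including the outgroup is gapped except
        # D5 — an insertion on the D5 pendant branch
        pols = polarize_indels(
            [GapLocus(0, 4, frozenset(AD_TAXA)),
             GapLocus(10, 11, frozenset(ALL_TAXA - {"D5"}))],
            GROUPS)
        df = assign_events_to_branches(pols, tree).set_index("branch")
        assert df.loc["AD", "n_deletions"] == 1
        assert df.loc["AD", "deletion_bp"] == 4
        assert df.loc["D5", "n_insertions"] == 1


class TestSpectrum:
    def test_fractions_and_mode(self):
        spec = indel_size_spectrum([1, 1, 5, 5, 5, 2])
        summary = spectrum_summary(spec)
        assert summary["frac_1bp"] == pytest.approx(1 / 3)
        assert spec.loc[spec["count"].idxmax(), "length"] == 5

    def test_empty(self):
        assert indel_size_spectrum([]).empty
        assert spectrum_summary(indel_size_spectrum([])) == {"n": 0}


class TestTandem:
    def test_adjacent_duplicate_detected(self):
        assert tandem_dup_check("ATGCA", upstream="TTATGCA", downstream="")
        assert tandem_dup_check("ATGCA", upstream="", downstream="ATGCATT")

    def test_non_duplicate(self):
        assert not tandem_dup_check("ATGCA", upstream="TTTTTTT",
                                    downstream="TTTTT")

    def test_simulator_tandem_insertions_all_match(self):
        from plastdiverge.synthetic import (AncestralSpec, EvolutionModel,
                                            simulate_dataset)
        from conftest import SMALL_SPEC
        model = EvolutionModel(tandem_dup_fraction=1.0, ins_del_bias=1e9,
                               ssr_slippage_rate=0, sub_rate=0)
        res = simulate_dataset(spec=AncestralSpec(**SMALL_SPEC), model=model,
                               seed=2)
        aln = res.alignment
        checked = matched = 0
        for ev in res.log.indel_events():
            # pendant-branch insertions: the tip row preserves the flank
            # unless a later insertion landed in between (rare)
            if ev.kind != "insertion" or ev.column < 1 or \
                    ev.branch not in aln.taxa:
                continue
            row = aln.row_str(ev.branch)
            up = row[:ev.column].replace("-", "")[-ev.length:]
            if len(up) == ev.length:
                checked += 1
                matched += tandem_dup_check(ev.payload, upstream=up,
                                            downstream="")
        assert checked >= 10 and matched >= 0.9 * checked

    def test_empty_indel_rejected(self):
        with pytest.raises(ValueError):
            tandem_dup_check("", "A", "A")


class TestIndelRatio:
    def test_arithmetic(self):
        assert indel_ratio(100, 0.5, 2) == pytest.approx(100.0)
        assert indel_ratio(0, 3.0) == 0.0

    def test_monotone_in_time(self):
        times = [0.5, 1.0, 2.0, 4.0]
        ratios = [indel_ratio(50, t) for t in times]
        assert ratios == sorted(ratios, reverse=True)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            indel_ratio(10, 0.0)


class TestGroupLabels:
    def test_requires_single_outgroup(self):
        labels = default_group_labels()
        labels["D6"] = "outgroup"
        with pytest.raises(ValueError, match="outgroup"):
            GroupLabels(labels)

    def test_empty_group_rejected(self):
        labels = {t: g for t, g in default_group_labels().items()
                  if g != "D_diploid"}
        with pytest.raises(ValueError, match="empty"):
            GroupLabels(labels)
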