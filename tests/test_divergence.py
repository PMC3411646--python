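import numpy as np
import pytest

from plastdiverge.divergence import (at_content, count_substitutions,
                                     divergence_percent, extract_indels,
                                     junction_distances, pairwise_divergence,
                                     pairwise_matrix, region_rate, s_i_ratio,
                                     sliding_at_vs_divergence)
from plastdiverge.io import Gene, GenomeRecord, project_pairwise

from conftest import make_aln


def pair_view(a: str, b: str):
    return project_pairwise(make_aln({"a": a, "b": b}), "a", "b")


class TestSubstitutions:
    def test_single_transversion(self):
        events, summary = count_substitutions(pair_view("ACGT", "ACGA"))
        assert summary.n_total == 1
        assert events[0].pair_type == "A/T"
        assert not events[0].is_transition

    def test_transition_classes(self):
        _, summary = count_substitutions(pair_view("AG", "GG"))
        assert summary.n_transitions == 1 and summary.n_transversions == 0

    def test_identical_sequences(self):
        events, summary = count_substitutions(pair_view("ACGT", "ACGT"))
        assert not events and summary.n_total == 0
        assert np.isnan(summary.si_sv)

    def test_n_columns_excluded(self):
        _, summary = count_substitutions(pair_view("ANGT", "AGGT"))
        assert summary.n_total == 0

    def test_conservation_si_plus_sv_and_pair_types(self, small_sim):
        aln = small_sim.alignment
        _, s = count_substitutions(project_pairwise(aln, "A1", "D6"))
        assert s.n_transitions + s.n_transversions == s.n_total
        assert sum(s.pair_type_counts.values()) == s.n_total

    def test_symmetry(self, small_sim):
        aln = small_sim.alignment
        _, ab = count_substitutions(project_pairwise(aln, "A2", "D5"))
        _, ba = count_substitutions(project_pairwise(aln, "D5", "A2"))
        assert ab.n_total == ba.n_total
        assert ab.n_transitions == ba.n_transitions


class TestIndels:
    def test_single_deletion_run(self):
        events = extract_indels(pair_view("ACGTA", "AC--A"))
        assert len(events) == 1
        ev = events[0]
        assert (ev.col_start, ev.col_end, ev.length) == (2, 4, 2)
        assert ev.gapped_taxon == "b"
        assert ev.bases == "GT"

    def test_gap_gap_removed_before_extraction(self):
        events = extract_indels(pair_view("A--C", "AGGC"))
        assert len(events) == 1 and events[0].length == 2

    def test_terminal_gap_runs_excluded(self):
        assert extract_indels(pair_view("--GTA", "ACGTA")) == []
        assert extract_indels(pair_view("ACG--", "ACGTA")) == []

    def test_planted_lengths_recovered(self, small_sim):
        """Deletions planted on the D5/D6 pendant branches reappear as
        pairwise D5-D6 gap runs at their planted column and length."""
        aln = small_sim.alignment
        pend = [e for e in small_sim.log.indel_events()
                if e.branch in ("D5", "D6") and e.kind == "deletion"
                and e.column >= 0]
        assert pend, "study-condition replicate should plant pendant deletions"
        events = extract_indels(project_pairwise(aln, "D5", "D6"))
        spans = {(e.col_start, e.length) for e in events}
        recovered = sum((ev.column, ev.length) in spans for ev in pend)
        assert recovered >= 0.9 * len(pend)


class TestRatios:
    def test_divergence_percent_values(self):
        assert divergence_percent(0, 1000) == 0.0
        assert divergence_percent(5, 1000) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            divergence_percent(1, 0)

    def test_region_rate(self):
        assert region_rate(0, 20_300) == 0.0
        assert region_rate(201, 20_300) == pytest.approx(9.9, abs=0.05)

    def test_s_i_ratio_nan_for_no_indels(self):
        assert np.isnan(s_i_ratio(10, 0))

    def test_region_counts_sum_to_totals(self, small_sim):
        regions = {t: g.regions for t, g in small_sim.genomes.items()}
        d = pairwise_divergence(small_sim.alignment, "A1", "D5", regions)
        stats = d.region_stats.set_index("region")
        total_subs = (stats.loc["LSC", "n_substitutions"]
                      + stats.loc["SSC", "n_substitutions"]
                      + 2 * stats.loc["IR", "n_substitutions"])
        assert total_subs == d.n_substitutions


class TestMatrix:
    def test_identical_taxa_all_zero(self):
        aln = make_aln({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        m = pairwise_matrix(aln)
        assert (m.loc["a", "b"], m.loc["b", "a"]) == (0, 0)
        assert m.loc["a", "a"] == ""

    def test_cells_match_single_pair_computation(self, small_sim):
        aln = small_sim.alignment
        taxa = ["A1", "D5", "AD3"]
        m = pairwise_matrix(aln, taxa)
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                view = project_pairwise(aln, a, b)
                _, s = count_substitutions(view)
                assert m.loc[b, a] == s.n_total
                assert m.loc[a, b] == len(extract_indels(view))

    def test_taxon_order_permutation(self, small_sim):
        """Per-pair indel and substitution counts do not depend on input
        order; only which triangle holds them does."""
        aln = small_sim.alignment
        m1 = pairwise_matrix(aln, ["A1", "A2", "D5"])   # A1 before D5
        m2 = pairwise_matrix(aln, ["D5", "A1", "A2"])   # D5 before A1
        assert m1.loc["A1", "D5"] == m2.loc["D5", "A1"]  # indels (upper)
        assert m1.loc["D5", "A1"] == m2.loc["A1", "D5"]  # substitutions


class TestProfiles:
    def test_constant_alignment(self):
        aln = make_aln({"a": "A" * 200, "b": "A" * 200})
        prof = sliding_at_vs_divergence(aln)
        assert (prof["at_fraction"] == 1.0).all()
        assert (prof["divergence"] == 0.0).all()

    def test_fully_divergent_alignment(self):
        aln = make_aln({"a": "A" * 150, "b": "T" * 150})
        prof = sliding_at_vs_divergence(aln)
        assert (prof["divergence"] == 1.0).all()

    def test_window_larger_than_alignment(self):
        aln = make_aln({"a": "ACGT"})
        with pytest.raises(ValueError):
            sliding_at_vs_divergence(aln, at_window=100)


class TestATContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATAT", 1.0), ("GCGC", 0.0), ("ATGCN", 0.5)])
    def test_values(self, seq, expected):
        assert at_content(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            at_content("")


class TestJunctions:
    def _genome(self, genes):
        # LSC [0,100) IRb [100,140) SSC [140,180) IRa [180,220)
        return GenomeRecord("t", "A" * 220,
                            {"LSC": (0, 100), "IRb": (100, 140),
                             "SSC": (140, 180), "IRa": (180, 220)},
                            genes)

    def test_gene_ending_exactly_at_junction(self):
        g = self._genome([Gene("rps19", 60, 100)])
        df = junction_distances(g, ["rps19"])
        assert df.iloc[0]["distance_bp"] == 0
        assert df.iloc[0]["junction"] == "LSC/IRb"

    def test_gene_ending_short_of_junction(self):
        g = self._genome([Gene("rps19", 50, 89)])
        assert junction_distances(g, ["rps19"]).iloc[0]["distance_bp"] == 11

    def test_gene_crossing_into_next_region(self):
        g = self._genome([Gene("rps19", 20, 155)])
        df = junction_distances(g, ["rps19"])
        assert df.iloc[0]["junction"] == "IRb/SSC"
        assert df.iloc[0]["distance_bp"] == -15

    def test_missing_gene(self):
        with pytest.raises(KeyError):
            junction_distances(self._genome([]), ["rps19"])


class TestBruteForceOracle:
    """Column-by-column reference implementation on small alignments."""

    @staticmethod
    def brute_force(a: str, b: str):
        keep = [i for i in range(len(a)) if not (a[i] == "-" and b[i] == "-")]
        pa = "".join(a[i] for i in keep)
        pb = "".join(b[i] for i in keep)
        subs = sum(1 for x, y in zip(pa, pb)
                   if x != y and x in "ACGT" and y in "ACGT")
        side = ["a" if x == "-" else "b" if y == "-" else None
                for x, y in zip(pa, pb)]
        runs = []
        i = 0
        while i < len(side):
            if side[i] is None:
                i += 1
                continue
            j = i
            while j < len(side) and side[j] == side[i]:
                j += 1
            if i > 0 and j < len(side):  # terminal runs excluded
                runs.append((side[i], j - i))
            i = j
        return subs, runs

    def test_random_small_alignments(self):
        rng = np.random.default_rng(7)
        alphabet = np.array(list("ACGT-N"))
        for _ in range(300):
            n = int(rng.integers(2, 50))
            a = "".join(rng.choice(alphabet, n))
            b = "".join(rng.choice(alphabet, n))
            if set(a) == {"-"} or set(b) == {"-"}:
                continue
            view = pair_view(a, b)
            _, summary = count_substitutions(view)
            indels = extract_indels(view)
            subs, runs = self.brute_force(a, b)
            assert summary.n_total == subs
            got = [("a" if ev.gapped_taxon == "a" else "b", ev.length)
                   for ev in indels]
            assert got == runs
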