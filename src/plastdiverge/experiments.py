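"""Study-condition experiments: parameter-recovery and calibration checks.

Each function runs the package end to end on synthetic data generated
under the default (study-condition) parameters — or on the printed worked
examples — and returns plain dicts of measured quantities. They are shared
by the analysis drivers, the test suite and the acceptance script so that
every reported number is recomputed the same way everywhere.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import chisquare

from .divergence import (divergence_percent, extract_indels,
                         pairwise_divergence, region_labels_for_columns,
                         region_rate, s_i_ratio)
from .evolution import (RateCalibration, calibrate_rate, divergence_time,
                        ng86_ka_ks, tajima_rrt)
from .indels import (GroupLabels, _clade_index, branch_for_event,
                     classify_pattern, multi_taxon_indel_loci,
                     polarize_indels)
from .io import MultipleAlignment, project_pairwise
from .ssr import (THRESHOLDS_A, THRESHOLDS_B, attribute_short_indels,
                  find_ssrs, find_ssrs_in_seq, ssr_locus_homology)
from .synthetic import (EvolutionModel, default_group_labels, node_label,
                        simulate_dataset)

# ---------------------------------------------------------------------------
# Worked examples from the printed pairwise tables


def worked_examples() -> dict:
    """Arithmetic the comparative tables print, recomputed from the printed
    counts (852 substitutions etc. over the 161.6-kb alignment)."""
    ssc_sub = region_rate(201, 20_300)
    ir_sub = region_rate(24, 25_600)
    return {
        "subst_divergence_pct_A2_D5": divergence_percent(852, 161_600),
        "subst_divergence_pct_AD5_A2": divergence_percent(147, 161_600),
        "indel_divergence_pct_AD2_AD5": divergence_percent(194, 161_600),
        "indel_divergence_pct_AD1_AD3": divergence_percent(559, 161_600),
        "indel_divergence_pct_AD1_A1": divergence_percent(711, 161_600),
        "indel_divergence_pct_max": divergence_percent(1_863, 161_600),
        "ssc_sub_rate_per_kb": ssc_sub,
        "ssc_indel_rate_per_kb": region_rate(29, 20_300),
        "lsc_sub_rate_per_kb": region_rate(605, 88_800),
        "ir_sub_rate_per_kb": ir_sub,
        "ssc_ir_sub_rate_ratio": round(ssc_sub, 1) / round(ir_sub, 1),
        "s_i_ratio_AD2_D5": s_i_ratio(873, 271),
    }


# ---------------------------------------------------------------------------
# Simulation-based recovery experiments


def _ssr_mask_columns(result) -> list[tuple[int, int]]:
    """Union of detected SSR spans across tips, in master columns."""
    spans = []
    for taxon, genome in result.genomes.items():
        p2c = result.alignment.pos_to_column(taxon)
        for loc in find_ssrs(genome, THRESHOLDS_A):
            spans.append((int(p2c[loc.start]), int(p2c[loc.end - 1]) + 1))
    spans.sort()
    merged = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlaps(mask, start, end) -> bool:
    starts = np.array([s for s, _ in mask])
    ends = np.array([e for _, e in mask])
    i = np.searchsorted(starts, end)
    return bool(np.any(ends[:i] > start))


def _ingroup_branches(tree, groups: GroupLabels) -> set[str]:
    """Labels of branches strictly inside the ingroup crown subtree (events
    on the root-to-crown and outgroup edges are unpolarizable with a single
    outgroup and stay out of recovery denominators)."""
    ingroup = frozenset(groups.labels) - groups.outgroup_all
    crown = None
    for nd in tree.postorder_node_iter():
        leaves = frozenset(node_label(lf) for lf in nd.leaf_iter())
        if leaves == ingroup:
            crown = nd
            break
    if crown is None:
        raise ValueError("ingroup is not a clade of the tree")
    labels = set()
    for nd in crown.preorder_iter():
        if nd is not crown:
            labels.add(node_label(nd))
    return labels


def polarization_and_spectrum_recovery(seed: int, n_replicates: int = 3) -> dict:
    """Plant indels at study-condition rates (slippage off, so every gap
    locus comes from the indel process), polarize against the outgroup and
    score per-event polarity/branch recovery; also collect the recovered
    size spectrum for a goodness-of-fit test against the planted law."""
    model = EvolutionModel(ssr_slippage_rate=0.0)
    groups = GroupLabels(default_group_labels())
    planted = recovered = 0
    flip_checked = flip_ok = 0
    unresolved = 0
    locus_lengths: list[int] = []

    for rep in range(n_replicates):
        result = simulate_dataset(model=model, seed=seed + rep)
        aln, tree, log = result.alignment, result.tree, result.log
        loci = multi_taxon_indel_loci(aln)
        mask = _ssr_mask_columns(result)
        polarized = polarize_indels(loci, groups, mask)
        if rep == 0:
            # spectrum goodness-of-fit at single-replicate scale: a handful
            # of cross-branch event collisions distort locus lengths, which
            # is negligible at this n but accumulates power when pooled.
            # Concerted IR evolution mirrors every IR event into both
            # copies; the IRa mirror is excluded so each event counts once
            # (the same both-copies-pooled-once convention used for rates).
            ref = next(t for t in aln.taxa
                       if result.genomes[t].regions)
            cols = np.array([l.col_start for l in loci])
            labels = region_labels_for_columns(
                aln, ref, result.genomes[ref].regions, cols)
            locus_lengths.extend(
                l.length for l, lab in zip(loci, labels) if lab != "IRa")
        clades = _clade_index(tree)
        ingroup = _ingroup_branches(tree, groups)
        starts = np.array([l.col_start for l in loci])
        out = groups.outgroup

        for ev in log.indel_events():
            if ev.kind not in ("insertion", "deletion"):
                continue
            if ev.branch not in ingroup or ev.column < 0:
                continue
            if _overlaps(mask, ev.column, ev.column + ev.length):
                continue
            planted += 1
            i = int(np.searchsorted(starts, ev.column, side="right")) - 1
            if i < 0 or not (loci[i].col_start <= ev.column < loci[i].col_end):
                unresolved += 1
                continue
            pol = polarized[i]
            if (pol.polarity == ev.polarity
                    and branch_for_event(pol, tree, clades) == ev.branch):
                recovered += 1

        # Outgroup flip: at root-adjacent (A/D lineage) stage-1 loci the
        # mirrored pattern polarizes with opposite polarity; at tetraploid
        # crown stage-1 loci the mirrored derived set (A+D) is not a clade
        # and must stay unpolarized — both behaviours are checked.
        for pol in polarized:
            if pol.polarity == "unpolarized" or pol.stage != 1:
                continue
            flip_checked += 1
            flipped_gapped = frozenset(pol.locus.gapped_taxa ^ {out})
            verdict = classify_pattern(flipped_gapped, groups)
            if pol.lineage in ("A", "D"):
                if verdict is not None and verdict[0] != pol.polarity:
                    flip_ok += 1
            else:  # AD crown
                if verdict is None:
                    flip_ok += 1

    model_probs = model.indel_size_dist
    sizes = sorted(model_probs)
    obs = np.array([sum(1 for L in locus_lengths if L == s) for s in sizes],
                   dtype=float)
    n_binned = obs.sum()
    exp = np.array([model_probs[s] for s in sizes]) * n_binned
    gof = chisquare(obs, exp)
    return {
        "n_planted": planted,
        "n_recovered": recovered,
        "recovery_fraction": recovered / planted if planted else float("nan"),
        "n_unresolved_loci": unresolved,
        "flip_checked": flip_checked,
        "flip_ok": flip_ok,
        "n_spectrum_events": int(n_binned),
        "spectrum_chi2": float(gof.statistic),
        "spectrum_gof_p": float(gof.pvalue),
        "frac_1bp": float(obs[sizes.index(1)] / n_binned) if n_binned else float("nan"),
        "frac_5bp": float(obs[sizes.index(5)] / n_binned) if n_binned else float("nan"),
    }


def study_divergence_summary(seed: int) -> dict:
    """Full default simulation; pairwise divergence metrics for the deepest
    diploid pair (A2 vs D5) the way the comparative tables report them."""
    result = simulate_dataset(seed=seed)
    aln = result.alignment
    regions = {t: g.regions for t, g in result.genomes.items()}
    d = pairwise_divergence(aln, "A2", "D5", regions)
    stats = d.region_stats.set_index("region")
    return {
        "alignment_length": aln.length,
        "n_substitutions_A2_D5": d.n_substitutions,
        "n_indel_events_A2_D5": d.total_indel_events,
        "subst_divergence_pct_A2_D5": d.subst_divergence_pct,
        "indel_divergence_pct_A2_D5": d.indel_divergence_pct,
        "si_sv_A2_D5": d.si_sv,
        "s_i_A2_D5": d.s_i,
        "ssc_sub_per_kb_A2_D5": float(stats.loc["SSC", "sub_per_kb"]),
        "ir_sub_per_kb_A2_D5": float(stats.loc["IR", "sub_per_kb"]),
        "lsc_indel_per_kb_A2_D5": float(stats.loc["LSC", "indel_per_kb"]),
    }


def ssr_attribution_experiment(seed: int) -> dict:
    """Slippage-only evolution: every indel arises at an SSR locus, so the
    1-3 bp indels attributed to polymorphic SSR groups should approach all
    of them."""
    model = EvolutionModel(sub_rate=0.0, indel_rate=0.0)
    result = simulate_dataset(model=model, seed=seed)
    aln = result.alignment
    loci_by_taxon = {t: find_ssrs(g, THRESHOLDS_A)
                     for t, g in result.genomes.items()}
    groups = ssr_locus_homology(aln, loci_by_taxon)
    attributed = total = 0
    taxa = aln.taxa
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            events = extract_indels(project_pairwise(aln, a, b))
            att, unatt, _ = attribute_short_indels(events, groups, (a, b))
            attributed += att
            total += att + unatt
    return {
        "n_short_indels": total,
        "n_attributed": attributed,
        "attributed_fraction": attributed / total if total else float("nan"),
        "n_slippage_events": len(result.log.indel_events()),
    }


def threshold_subset_experiment(seed: int, n_genomes: int = 100,
                                length: int = 50_000) -> dict:
    """Set-B loci must be a subset of set-A loci on random genomes."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ATCG", dtype=np.uint8)
    violations = 0
    n_a = n_b = 0
    for _ in range(n_genomes):
        seq = rng.choice(bases, size=length,
                         p=[0.315, 0.315, 0.185, 0.185]).tobytes().decode()
        loci_a = {(l.start, l.end, l.motif)
                  for l in find_ssrs_in_seq(seq, THRESHOLDS_A)}
        loci_b = {(l.start, l.end, l.motif)
                  for l in find_ssrs_in_seq(seq, THRESHOLDS_B)}
        if not loci_b <= loci_a:
            violations += 1
        n_a += len(loci_a)
        n_b += len(loci_b)
    return {"n_genomes": n_genomes, "violations": violations,
            "total_set_a": n_a, "total_set_b": n_b}


# ---------------------------------------------------------------------------
# Rate-test calibration


def tajima_type1_experiment(seed: int, n_reps: int = 800, n_sites: int = 2000,
                            d_ingroup: float = 0.04, d_out: float = 0.08,
                            alpha: float = 0.05) -> dict:
    """Empirical type-I error of the relative rate test under equal-rate
    lineages (Jukes–Cantor-style mutations, no indels)."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def mutate(anc: np.ndarray, d: float) -> np.ndarray:
        n = rng.binomial(anc.shape[0], d)
        pos = rng.choice(anc.shape[0], size=n, replace=False)
        out = anc.copy()
        shift = rng.integers(1, 4, size=n)
        out[pos] = bases[(np.searchsorted(bases, out[pos]) + shift) % 4]
        return out

    rejections = 0
    for _ in range(n_reps):
        anc = rng.choice(bases, size=n_sites)
        rows = [mutate(anc, d_ingroup), mutate(anc, d_ingroup),
                mutate(anc, d_out)]
        aln = MultipleAlignment(
            ["L1", "L2", "OG"], [r.tobytes().decode() for r in rows])
        res = tajima_rrt(aln, "L1", "L2", "OG")
        rejections += res.p_value < alpha
    rate = rejections / n_reps
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_reps)
    return {"n_reps": n_reps, "rejection_rate": rate,
            "ci_low": alpha - half, "ci_high": alpha + half}


def dating_identity_experiment(seed: int, n_pairs: int = 100) -> dict:
    """calibrate -> date must invert exactly; with the study's synonymous
    rate, the Ks implied by the A/D split time dates back to 3.89 MY."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_pairs):
        ks = float(rng.uniform(1e-4, 0.5))
        t_my = float(rng.uniform(0.01, 100.0))
        cal = calibrate_rate(ks, t_my * 1e6)
        back = divergence_time(ks, cal)
        max_err = max(max_err, abs(back.t_my - t_my))
    rs = 1.162e-9
    ks_ad = 2.0 * rs * 3.89e6
    t_ad = divergence_time(ks_ad, RateCalibration(rs=rs)).t_my
    return {"max_roundtrip_error_my": max_err, "rs_per_year": rs,
            "ks_a_vs_d": ks_ad, "t_a_vs_d_my": t_ad}


_NONSTOP = None


def _nonstop_codons():
    global _NONSTOP
    if _NONSTOP is None:
        from .evolution import _CODON_TABLE_11
        _NONSTOP = sorted(c for c, aa in _CODON_TABLE_11.items() if aa != "*")
    return _NONSTOP


def synonymous_process_experiment(seed: int, n_codons: int = 4000,
                                  p_change: float = 0.3) -> dict:
    """Evolve codons under a synonymous-only third-position process and
    re-estimate Ka/Ks; Ka must vanish and Ks must track the planted number
    of synonymous changes."""
    from .evolution import _CODON_TABLE_11
    rng = np.random.default_rng(seed)
    pool = _nonstop_codons()
    seq1 = [pool[i] for i in rng.integers(0, len(pool), n_codons)]
    seq2 = []
    n_changes = 0
    for codon in seq1:
        new = codon
        if rng.random() < p_change:
            aa = _CODON_TABLE_11[codon]
            alts = [codon[:2] + b for b in "ACGT"
                    if b != codon[2] and _CODON_TABLE_11[codon[:2] + b] == aa]
            if alts:
                new = alts[int(rng.integers(len(alts)))]
                n_changes += 1
        seq2.append(new)
    kk = ng86_ka_ks("".join(seq1), "".join(seq2))
    return {"n_codons": n_codons, "n_planted_syn_changes": n_changes,
            "ka": kk.ka, "ks": kk.ks, "s_sites": kk.s_sites,
            "n_diff_s": kk.n_diff_s, "n_diff_n": kk.n_diff_n}
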