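"""Orchestration: simulate -> divergence -> polarize -> ssr -> date -> rrt
as one reproducible run with a machine-readable manifest.

A config supplies either a simulation spec or real-input paths (never
both). All outputs are TSV with fixed headers plus ``manifest.json``;
re-running an identical config reproduces the tables byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .divergence import (pairwise_divergence, pairwise_matrix,
                         sliding_at_vs_divergence)
from .evolution import (RateCalibration, divergence_time, ng86_ka_ks,
                        tajima_rrt)
from .indels import (GroupLabels, assign_events_to_branches,
                     indel_size_spectrum, multi_taxon_indel_loci,
                     polarize_indels, polarized_table)
from .io import (GenomeRecord, read_alignment, read_features, read_regions,
                 read_tree)
from .ssr import (THRESHOLD_PRESETS, find_ssrs, loci_table, polymorphism_stats,
                  ssr_locus_homology)
from .synthetic import (AncestralSpec, EvolutionModel, default_group_labels,
                        emit_dataset, simulate_dataset)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # exactly one of: simulation ...
    simulate: bool = False
    spec: AncestralSpec | None = None
    model: EvolutionModel | None = None
    mirror_ir: bool = True
    # ... or real inputs
    alignment: str | None = None
    regions: str | None = None
    features: str | None = None
    tree: str | None = None
    groups: str | None = None   # TSV: taxon <tab> group
    # analysis options
    thresholds: str = "A"
    rate_rs: float | None = 1.162e-9   # synonymous subs/site/year for dating
    rrt_outgroup: str | None = None
    at_window: int = 100
    div_step: int = 10
    run_profile: bool = False   # the sliding AT/divergence table is large

    def validate(self) -> None:
        if self.simulate == bool(self.alignment):
            raise PipelineError(
                "config", "supply exactly one of simulation spec or input paths")
        if self.thresholds not in THRESHOLD_PRESETS:
            raise PipelineError("config", f"unknown threshold set {self.thresholds!r}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    spec = AncestralSpec(**raw.pop("spec")) if "spec" in raw else None
    model = EvolutionModel(**raw.pop("model")) if "model" in raw else None
    return PipelineConfig(spec=spec, model=model, **raw)


def _read_group_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["taxon", "group"]:
        raise PipelineError("config", "groups table columns must be taxon, group")
    return dict(zip(df["taxon"], df["group"]))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # ----- inputs ---------------------------------------------------------
    try:
        if config.simulate:
            result = simulate_dataset(config.spec, config.model,
                                      mirror_ir=config.mirror_ir,
                                      seed=config.seed)
            genomes, aln, tree = result.genomes, result.alignment, result.tree
            group_map = default_group_labels()
            paths.update(emit_dataset(result, out / "dataset"))
        else:
            aln = read_alignment(config.alignment)
            regions = read_regions(config.regions) if config.regions else {}
            features = read_features(config.features) if config.features else {}
            genomes = {
                t: GenomeRecord(t, aln.sequence(t), regions.get(t, {}),
                                features.get(t, []))
                for t in aln.taxa
            }
            tree = read_tree(config.tree) if config.tree else None
            group_map = (_read_group_labels(config.groups)
                         if config.groups else None)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    # ----- divergence -----------------------------------------------------
    try:
        matrix = pairwise_matrix(aln)
        paths["pairwise_matrix"] = out / "pairwise_matrix.tsv"
        matrix.to_csv(paths["pairwise_matrix"], sep="\t")

        region_tables = {t: g.regions for t, g in genomes.items()
                         if g.regions}
        rows, region_rows = [], []
        taxa = aln.taxa
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                d = pairwise_divergence(aln, a, b, region_tables)
                rows.append({
                    "taxon_a": a, "taxon_b": b,
                    "alignment_length": d.alignment_length,
                    "n_substitutions": d.n_substitutions,
                    "n_transitions": d.n_transitions,
                    "n_transversions": d.n_transversions,
                    "si_sv": d.si_sv,
                    "n_indel_events": d.total_indel_events,
                    "indel_bp": d.total_indel_length,
                    "s_i": d.s_i,
                    "subst_divergence_pct": round(d.subst_divergence_pct, 3),
                    "indel_divergence_pct": round(d.indel_divergence_pct, 3),
                })
                if d.region_stats is not None:
                    for rec in d.region_stats.to_dict("records"):
                        region_rows.append({"taxon_a": a, "taxon_b": b, **rec})
        paths["pairwise_divergence"] = out / "pairwise_divergence.tsv"
        pd.DataFrame(rows).to_csv(paths["pairwise_divergence"], sep="\t",
                                  index=False)
        paths["region_rates"] = out / "region_rates.tsv"
        pd.DataFrame(region_rows).to_csv(paths["region_rates"], sep="\t",
                                         index=False)
        if config.run_profile:
            profile = sliding_at_vs_divergence(aln, config.at_window,
                                               config.div_step)
            paths["at_divergence_profile"] = out / "at_divergence_profile.tsv"
            profile.to_csv(paths["at_divergence_profile"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("divergence", str(exc)) from exc

    # ----- SSR ------------------------------------------------------------
    try:
        thresholds = THRESHOLD_PRESETS[config.thresholds]
        loci_by_taxon = {t: find_ssrs(g, thresholds)
                         for t, g in genomes.items()}
        paths["ssrs"] = out / "ssrs.tsv"
        loci_table([l for ls in loci_by_taxon.values() for l in ls]).to_csv(
            paths["ssrs"], sep="\t", index=False)
        groups_ssr = ssr_locus_homology(aln, loci_by_taxon)
        poly_matrix, class_summary = polymorphism_stats(groups_ssr, aln.taxa)
        paths["ssr_polymorphism"] = out / "ssr_polymorphism.tsv"
        poly_matrix.to_csv(paths["ssr_polymorphism"], sep="\t")
        paths["ssr_classes"] = out / "ssr_classes.tsv"
        class_summary.to_csv(paths["ssr_classes"], sep="\t", index=False)
        ssr_mask = [(g.col_start, g.col_end) for g in groups_ssr]
    except Exception as exc:
        raise PipelineError("ssr", str(exc)) from exc

    # ----- indel polarization --------------------------------------------
    try:
        loci = multi_taxon_indel_loci(aln)
        spectrum = indel_size_spectrum([l.length for l in loci])
        paths["indel_spectrum"] = out / "indel_spectrum.tsv"
        spectrum.to_csv(paths["indel_spectrum"], sep="\t", index=False)
        if group_map is not None and tree is not None:
            labels = GroupLabels({t: g for t, g in group_map.items()
                                  if t in set(aln.taxa)})
            polarized = polarize_indels(loci, labels, ssr_mask)
            paths["polarized"] = out / "polarized_indels.tsv"
            polarized_table(polarized).to_csv(paths["polarized"], sep="\t",
                                              index=False)
            branch_counts = assign_events_to_branches(polarized, tree)
            paths["branch_counts"] = out / "branch_counts.tsv"
            branch_counts.to_csv(paths["branch_counts"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("polarize", str(exc)) from exc

    # ----- dating (Ks-based) ---------------------------------------------
    try:
        if config.rate_rs:
            calibration = RateCalibration(rs=config.rate_rs,
                                          source="configured rate")
            date_rows = []
            for i, a in enumerate(aln.taxa):
                if not genomes[a].genes:
                    continue
                for b in aln.taxa[i + 1:]:
                    s1, s2 = concatenated_cds_pair(aln, genomes[a], a, b)
                    if len(s1) < 300:
                        continue
                    kk = ng86_ka_ks(s1, s2, on_internal_stop="mask")
                    dating = divergence_time(kk.ks, calibration, (a, b))
                    date_rows.append({
                        "taxon_a": a, "taxon_b": b, "ks": kk.ks, "ka": kk.ka,
                        "t_my": dating.t_my, "saturated": dating.saturated})
            if date_rows:
                paths["dates"] = out / "dates.tsv"
                pd.DataFrame(date_rows).to_csv(paths["dates"], sep="\t",
                                               index=False)
    except Exception as exc:
        raise PipelineError("date", str(exc)) from exc

    # ----- relative rate tests -------------------------------------------
    try:
        rrt_rows = []
        outgroup_taxon = config.rrt_outgroup
        if outgroup_taxon is None and group_map is not None:
            d_taxa = sorted(t for t, g in group_map.items()
                            if g == "D_diploid" and t in set(aln.taxa))
            outgroup_taxon = d_taxa[0] if d_taxa else None
        if outgroup_taxon is not None and group_map is not None:
            ad = sorted(t for t, g in group_map.items()
                        if g == "allotetraploid" and t in set(aln.taxa))
            a_dip = sorted(t for t, g in group_map.items()
                           if g == "A_diploid" and t in set(aln.taxa))
            for t_ad in ad:
                for t_a in a_dip:
                    res = tajima_rrt(aln, t_ad, t_a, outgroup_taxon)
                    rrt_rows.append({
                        "taxon_a": t_ad, "taxon_b": t_a,
                        "outgroup": outgroup_taxon, "n_a": res.n_a,
                        "n_b": res.n_b, "chi_square": res.chi_square,
                        "p_value": res.p_value,
                        "significance": res.significance})
        if rrt_rows:
            paths["rrt"] = out / "rrt.tsv"
            pd.DataFrame(rrt_rows).to_csv(paths["rrt"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("rrt", str(exc)) from exc

    # ----- manifest -------------------------------------------------------
    manifest = {
        "plastdiverge_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "outputs": {k: str(v) for k, v in paths.items()},
        "conventions": {
            "coordinates": "0-based half-open internally; GFF3 1-based on disk",
            "gap_character": "-",
            "ir_reporting": "both copies pooled, reported once",
            "terminal_gaps": "excluded from indel events",
            "n_policy": "columns with N excluded from rates",
        },
    }
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths


def _jsonable(config: PipelineConfig) -> dict:
    raw = asdict(config)
    for key in ("spec", "model"):
        if raw.get(key) and "ssr_seed_loci" in (raw[key] or {}):
            raw[key]["ssr_seed_loci"] = [list(x) for x in raw[key]["ssr_seed_loci"]]
    return raw


def concatenated_cds_pair(aln, ref_genome: GenomeRecord, a: str, b: str,
                          ) -> tuple[str, str]:
    """In-frame aligned codon pair over the reference taxon's plus-strand
    CDS complement; codons whose three reference positions map to columns
    containing a gap in either taxon are dropped."""
    p2c = aln.pos_to_column(ref_genome.taxon_id)
    row_a, row_b = aln.row(a), aln.row(b)
    out1, out2 = [], []
    for g in ref_genome.genes:
        if not g.is_cds or g.strand != "+":
            continue
        span = g.end - g.start
        for i in range(g.start, g.start + span - span % 3, 3):
            cols = p2c[i:i + 3]
            ca = row_a[cols].tobytes().decode()
            cb = row_b[cols].tobytes().decode()
            if "-" in ca or "-" in cb:
                continue
            out1.append(ca)
            out2.append(cb)
    return "".join(out1), "".join(out2)
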