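"""End-to-end pipeline driver: scan -> triage -> re-annotate -> classify ->
phylogeny -> cluster -> density -> report.

Every stage is the corresponding library function; this module only wires
them together, tracks gene-model bookkeeping across merges and splits, and
writes the per-stage output tables.  All randomness is derived from the
single config seed, and outputs are formatted deterministically, so repeated
runs are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as C
from . import clusters as CL
from . import density as D
from . import phylogeny as P
from . import reannotation as R
from . import report as REP
from .genomeio import GeneModel, GenomeBundle, write_fasta, write_gff3_genes
from .maps import render_chromosome_map, render_density_figure
from .motifs import MONOCOT_MOTIFS, load_motifs
from .scan import build_scoring_model, calibrate, profile_sequence
from .triage import collapse_to_genes, triage


@dataclass
class PipelineConfig:
    """All pipeline thresholds (defaults are the published operating point)."""

    seed: int = 0
    initial_cap: float = 2.0  # E-value cap for any candidate
    p_cutoff: float = 1e-4  # per-window hit/report cutoff
    flank: int = 3000  # bp extension on both sides
    merge_max_gap: int = 10_000
    min_intron: int = 60
    cc_p_cutoff: float = 0.047
    cc_max_start: int = 98
    cluster_max_gap: int = 200_000
    cluster_max_intervening: int = 8
    density_window: int = 250_000
    density_bins: int = 200
    gmm_components: int = 2
    gmm_n_init: int = 10
    outlier_mass_level: float = 0.99
    bootstrap_replicates: int = 100
    min_support: int = 70
    max_diameter: float = 0.4
    identity_cutoff: float = 80.0
    nbarc_min_fraction: float = 0.5
    skip_extension: bool = False

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name not in ("seed", "skip_extension") and v is not None:
                if isinstance(v, (int, float)) and v <= 0:
                    raise ValueError(f"{f.name} must be positive, got {v}")


@dataclass
class FinalGene:
    gene_id: str
    model: GeneModel
    protein: str
    structure: R.StructureCall
    source_gene_ids: list[str]
    rebuilt: bool


@dataclass
class PipelineResult:
    config: PipelineConfig
    calibration: object
    statuses: list
    annotations: dict[str, C.NlrAnnotation]
    clusters: list[CL.Cluster]
    homogeneity: dict[str, str]
    tree: P.PhyloTree | None
    subgroups: P.SubgroupAssignment | None
    placements: list[CL.GenePlacement]
    density: pd.DataFrame
    gmm: D.GmmModel | None
    nlr_density: pd.DataFrame | None
    summary: dict
    subtype_table: pd.DataFrame
    removal_log: dict[str, str] = field(default_factory=dict)


def _own_hits(hits, gene: GeneModel, region: R.ExtendedRegion):
    lo = gene.start - region.region_start
    hi = gene.end - region.region_start
    return [h for h in hits if h.dna_start >= lo and h.dna_end <= hi]


def run_pipeline(
    bundle: GenomeBundle,
    training_positive: dict[str, str],
    training_negative: dict[str, str],
    config: PipelineConfig,
    panel: dict[str, str] | None = None,
    cc_overrides: dict[str, tuple[float, int]] | None = None,
    outdir=None,
) -> PipelineResult:
    models = {m: build_scoring_model(d) for m, d in load_motifs().items()}
    database_size = (len(bundle.proteins) + len(training_positive)
                     + len(training_negative))

    # 1. scan every annotated protein and the training sets
    profiles = {pid: profile_sequence(bundle.proteins[pid], models, pid,
                                      database_size, config.p_cutoff)
                for pid in sorted(bundle.proteins)}
    pos_profiles = [profile_sequence(seq, models, pid, database_size,
                                     config.p_cutoff)
                    for pid, seq in sorted(training_positive.items())]
    neg_profiles = [profile_sequence(seq, models, pid, database_size,
                                     config.p_cutoff)
                    for pid, seq in sorted(training_negative.items())]
    calibration = calibrate(pos_profiles, neg_profiles, database_size)

    # 2. triage transcripts, collapse to genes
    statuses = triage(list(profiles.values()), calibration,
                      config.initial_cap, config.p_cutoff)
    gene_support = collapse_to_genes(statuses, bundle.transcript_to_gene)
    candidate_ids = sorted(
        gene_support,
        key=lambda g: (bundle.genes[g].scaffold_id, bundle.genes[g].start))

    # 3. extend + six-frame re-scan every candidate gene
    flank = 0 if config.skip_extension else config.flank
    scans: dict[str, tuple[R.ExtendedRegion, list, dict]] = {}
    for gid in candidate_ids:
        gene = bundle.genes[gid]
        region = R.extend(gene, bundle.scaffolds[gene.scaffold_id], flank)
        hits, translations = R.rescan_six_frames(region, models,
                                                 config.p_cutoff)
        scans[gid] = (region, hits, translations)

    # 4. merge adjacent complementary models (using hits inside each model)
    consumed: set[str] = set()
    merged_entries: list[tuple[GeneModel, list[str]]] = []
    for a_id, b_id in zip(candidate_ids, candidate_ids[1:]):
        if a_id in consumed or b_id in consumed:
            continue
        ga, gb = bundle.genes[a_id], bundle.genes[b_id]
        ra, ha, _ = scans[a_id]
        rb, hb, _ = scans[b_id]
        own_a = R._collapse_series(_own_hits(ha, ga, ra), config.p_cutoff,
                                   scans[a_id][2])
        own_b = R._collapse_series(_own_hits(hb, gb, rb), config.p_cutoff,
                                   scans[b_id][2])
        merged = R.merge_adjacent((ga, own_a), (gb, own_b),
                                  config.merge_max_gap, config.p_cutoff)
        if merged is not None:
            consumed.update({a_id, b_id})
            merged_entries.append((merged, [a_id, b_id]))

    # 5. partition double models, build final gene entries
    final_genes: list[FinalGene] = []

    def finalise(gid: str, gene: GeneModel, region, hits, translations,
                 sources: list[str], force_rebuild: bool):
        groups = R.partition_signatures(hits, config.p_cutoff, translations)
        groups = [g for g in groups if g]
        if not groups:
            return
        split = len(groups) > 1
        for part, group in enumerate(groups, start=1):
            structure = R.call_structure(group, translations,
                                         config.min_intron, config.p_cutoff)
            aa_min = aa_max = None
            if split and part == 1:
                aa_max = min(h.start for h in groups[1])
            if split and part == 2:
                aa_min = max(h.end for h in groups[0])
            new_id = f"{gid}.{part}" if split else gid
            rescan_motifs = ({h.motif_id for h in group}
                             - MONOCOT_MOTIFS)
            original = None
            if not force_rebuild and not split and gene.protein_ids:
                tid = gene.protein_ids[0]
                if tid in bundle.proteins:
                    original_motifs = profiles[tid].motif_ids_at(config.p_cutoff)
                    if rescan_motifs <= original_motifs:
                        original = bundle.proteins[tid]
            if original is not None:
                final_genes.append(FinalGene(new_id, gene, original,
                                             structure, sources, False))
                continue
            protein = R.build_protein(structure, translations, aa_min, aa_max)
            dna_lo = min(h.dna_start for h in group)
            dna_hi = max(h.dna_end for h in group)
            strand = "-" if group[0].frame.startswith("-") else "+"
            model = GeneModel(
                new_id, gene.scaffold_id, strand,
                region.to_scaffold(dna_lo), region.to_scaffold(dna_hi),
                protein_ids=[f"{new_id}.p"])
            final_genes.append(FinalGene(new_id, model, protein, structure,
                                         sources, True))

    for gid in candidate_ids:
        if gid in consumed:
            continue
        region, hits, translations = scans[gid]
        finalise(gid, bundle.genes[gid], region, hits, translations, [gid],
                 force_rebuild=False)
    for merged_model, sources in merged_entries:
        region = R.extend(merged_model,
                          bundle.scaffolds[merged_model.scaffold_id], flank)
        hits, translations = R.rescan_six_frames(region, models,
                                                 config.p_cutoff)
        finalise(merged_model.gene_id, merged_model, region, hits,
                 translations, sources, force_rebuild=True)

    # 6. final scan of the (re-annotated) proteins; keep E < negative minimum
    annotations: dict[str, C.NlrAnnotation] = {}
    final_profiles = {}
    for fg in final_genes:
        if not fg.protein:
            continue
        prof = None
        if not fg.rebuilt and fg.model.protein_ids:
            prof = profiles.get(fg.model.protein_ids[0])
        if prof is None:
            prof = profile_sequence(fg.protein, models, fg.gene_id,
                                    database_size, config.p_cutoff)
        if prof.log10_e >= calibration.log10_t_main:
            continue
        final_profiles[fg.gene_id] = prof
        motif_ids = prof.motif_ids_at(config.p_cutoff)
        kin2 = None
        if 4 in motif_ids:  # presence gate is on the corrected scale
            kin2 = C.kin2_terminal_residue(fg.protein,
                                           prof.best_hit_per_motif.get(4),
                                           p_cutoff=1.0)
        nlr_class, conflict, evidence = C.classify_family(motif_ids, kin2)
        if cc_overrides and fg.gene_id in cc_overrides:
            p_sc, start = cc_overrides[fg.gene_id]
            cc = C.CcPrediction(
                p_score=p_sc, start_pos=start,
                present=bool(p_sc <= config.cc_p_cutoff
                             and 1 <= start <= config.cc_max_start))
        else:
            cc = C.predict_cc(fg.protein, config.cc_p_cutoff,
                              config.cc_max_start)
        comp = R.completeness(motif_ids, fg.structure, nlr_class)
        homolog = None
        if panel:
            match = C.rgene_homology(fg.protein, panel,
                                     config.identity_cutoff)
            if match and match["labelled"]:
                homolog = match["name"]
        annotations[fg.gene_id] = C.NlrAnnotation(
            gene_id=fg.gene_id, gene=fg.model, nlr_class=nlr_class,
            subtype=C.assign_subtype(nlr_class, cc.present, motif_ids),
            completeness=comp, kin2_terminal=kin2, cc=cc,
            motif_ids=motif_ids, structure=fg.structure,
            protein=fg.protein, log10_e=prof.log10_e,
            class_conflict=conflict, homolog_label=homolog,
            evidence=evidence, source_gene_ids=fg.source_gene_ids)

    # 7. phylogeny on the NB-ARC regions of accepted genes
    tree = None
    subgroups = None
    removal_log: dict[str, str] = {}
    entries = {gid: (annotations[gid].protein,
                     final_profiles[gid].best_hit_per_motif)
               for gid in sorted(annotations)}
    full_ids = {gid for gid, a in annotations.items()
                if a.completeness == "full_length"}
    regions, removal_log = P.extract_and_filter(
        entries, full_ids, config.nbarc_min_fraction, config.p_cutoff)
    if len(regions) >= 4:
        alignment = P.align(regions)
        tree = P.nj_bootstrap_tree(alignment, config.bootstrap_replicates,
                                   seed=config.seed)
        subgroups = P.detect_subgroups(tree, config.min_support,
                                       config.max_diameter)

    # 8. physical clustering on pseudomolecules
    scaffold_lengths = {k: len(v) for k, v in bundle.scaffolds.items()}
    final_ids = set(annotations)
    source_ids = {s for a in annotations.values() for s in a.source_gene_ids}
    placements: list[CL.GenePlacement] = []
    for gid in sorted(bundle.genes):
        if gid in source_ids or gid in final_ids:
            continue
        pl = CL.project(bundle.genes[gid], bundle.placements,
                        scaffold_lengths, is_nlr=False)
        if pl is not None:
            placements.append(pl)
    for gid in sorted(annotations):
        pl = CL.project(annotations[gid].gene, bundle.placements,
                        scaffold_lengths, is_nlr=True)
        if pl is not None:
            placements.append(pl)
    nlr_placements = [p for p in placements if p.is_nlr]
    clusters = CL.find_clusters(nlr_placements, placements,
                                config.cluster_max_gap,
                                config.cluster_max_intervening)
    homogeneity: dict[str, str] = {}
    labels = subgroups.labels if subgroups else {}
    patristic = subgroups.patristic if subgroups else None
    for cl in clusters:
        cl.homogeneity = CL.label_homogeneity(cl, labels, patristic,
                                              config.max_diameter)
        homogeneity[cl.cluster_id] = cl.homogeneity

    # 9. density landscape on the original annotation
    density = D.density_table(bundle.genes, bundle.repeats, scaffold_lengths,
                              config.density_window)
    ok = density[~density["omitted"]]
    gmm = None
    nlr_density = None
    if len(ok) >= config.gmm_components:
        hist = D.histogram2d(
            ok[["gene_density", "repeat_density"]].to_numpy(float),
            config.density_bins)
        gmm = D.fit_gmm(hist, config.gmm_components, config.seed,
                        config.gmm_n_init)
        rep_map = {gid: annotations[gid].source_gene_ids[0]
                   for gid in annotations}
        nlr_rows = ok[ok["gene_id"].isin(set(rep_map.values()))]
        if len(nlr_rows):
            nlr_density = D.flag_outliers(nlr_rows, gmm,
                                          config.outlier_mass_level,
                                          config.seed)

    classes = {gid: a.nlr_class for gid, a in annotations.items()}
    summary = REP.summary_counts(annotations, placements, clusters)
    summary["n_candidates"] = len(candidate_ids)
    summary["calibration_specific"] = bool(calibration.specific)
    subtype_table = REP.subtype_summary(annotations)

    result = PipelineResult(
        config=config, calibration=calibration, statuses=statuses,
        annotations=annotations, clusters=clusters, homogeneity=homogeneity,
        tree=tree, subgroups=subgroups, placements=placements,
        density=density, gmm=gmm, nlr_density=nlr_density, summary=summary,
        subtype_table=subtype_table, removal_log=removal_log)
    if outdir is not None:
        write_outputs(result, bundle, classes, outdir)
    return result


def _fmt(x: float) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return "nan"
        return f"{x:.6g}"
    return str(x)


def write_outputs(result: PipelineResult, bundle: GenomeBundle,
                  classes: dict[str, str], outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([{
        "sequence_id": s.sequence_id, "status": s.status,
        "log10_e": round(s.log10_e, 4), "reason": s.reason,
    } for s in result.statuses]).to_csv(out / "status.tsv", sep="\t",
                                        index=False)

    rows = []
    for gid in sorted(result.annotations):
        a = result.annotations[gid]
        rows.append({
            "gene_id": gid, "scaffold": a.gene.scaffold_id,
            "strand": a.gene.strand, "start": a.gene.start,
            "end": a.gene.end, "class": a.nlr_class, "subtype": a.subtype,
            "completeness": a.completeness, "kin2_terminal": a.kin2_terminal
            or "", "cc_present": a.cc.present,
            "cc_p_score": round(a.cc.p_score, 5),
            "introns": a.structure.intron_count,
            "frameshifts": a.structure.frameshift_count,
            "log10_e": round(a.log10_e, 2),
            "homolog": a.homolog_label or "",
            "motifs": ",".join(map(str, sorted(a.motif_ids))),
            "sources": ",".join(a.source_gene_ids),
        })
    pd.DataFrame(rows).to_csv(out / "annotations.tsv", sep="\t", index=False)

    models = {gid: result.annotations[gid].gene
              for gid in sorted(result.annotations)}
    write_gff3_genes(models, out / "reannotated.gff3")
    write_fasta({gid: result.annotations[gid].protein
                 for gid in sorted(result.annotations)},
                out / "reannotated_proteins.fa")

    pd.DataFrame([{
        "cluster_id": c.cluster_id, "pseudomolecule": c.pseudomolecule_id,
        "start": c.span[0], "end": c.span[1], "size": len(c.members),
        "homogeneity": c.homogeneity, "members": ",".join(c.members),
    } for c in result.clusters]).to_csv(out / "clusters.tsv", sep="\t",
                                        index=False)
    with open(out / "clusters.bed", "w") as fh:
        for c in result.clusters:
            fh.write(f"{c.pseudomolecule_id}\t{c.span[0]}\t{c.span[1]}"
                     f"\t{c.cluster_id}\n")

    CL.chromosome_summary(result.placements, result.clusters,
                          classes).to_csv(out / "chromosome_summary.tsv",
                                          sep="\t")
    result.density.to_csv(out / "density.tsv", sep="\t", index=False,
                          float_format="%.6g")
    if result.nlr_density is not None:
        result.nlr_density.to_csv(out / "nlr_density.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    if result.gmm is not None:
        with open(out / "gmm.txt", "w") as fh:
            for k in range(len(result.gmm.weights)):
                fh.write(f"component {k + 1}: weight="
                         f"{result.gmm.weights[k]:.6g} "
                         f"mean={np.array2string(result.gmm.means[k], precision=6)} "
                         f"cov={np.array2string(result.gmm.covariances[k], precision=6)}\n")

    if result.tree is not None:
        (out / "nbarc_tree.nwk").write_text(result.tree.to_newick() + "\n")
    if result.subgroups is not None:
        pd.DataFrame([
            {"gene_id": gid, "subgroup": lab or ""}
            for gid, lab in sorted(result.subgroups.labels.items())
        ]).to_csv(out / "subgroups.tsv", sep="\t", index=False)

    result.subtype_table.to_csv(out / "subtype_summary.tsv", sep="\t",
                                index=False)
    with open(out / "summary.tsv", "w") as fh:
        for k in sorted(result.summary):
            fh.write(f"{k}\t{_fmt(result.summary[k])}\n")

    pm_lengths: dict[str, int] = {}
    for _, row in bundle.placements.iterrows():
        pm = str(row["pseudomolecule_id"])
        end = int(row["offset"]) + len(bundle.scaffolds[row["scaffold_id"]])
        pm_lengths[pm] = max(pm_lengths.get(pm, 0), end)
    for pm in sorted(pm_lengths):
        svg = render_chromosome_map(pm, pm_lengths[pm], result.placements,
                                    result.clusters, classes)
        (out / f"map_{pm}.svg").write_text(svg)
    if result.gmm is not None and result.nlr_density is not None:
        flagged = list(result.nlr_density[result.nlr_density["outlier"]]
                       ["gene_id"])
        (out / "density_landscape.svg").write_text(
            render_density_figure(result.nlr_density, result.gmm, flagged))
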