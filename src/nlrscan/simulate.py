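"""Synthetic annotated genomes with known NB-LRR ground truth.

The generator emulates the structure of a draft plant genome annotation:
superscaffolds carrying background genes at gene-rich / gene-poor intensities
with contrasting repeat coverage, NB-LRR lineages laid out as tandem-
duplicated clusters with intervening decoy genes, a placement table joining
scaffolds into pseudomolecules with fixed 50 kb spacers, and the annotation
defects the re-annotation stage exists for: models trimmed so that motifs
fall outside them (recoverable only by flank extension), genuinely truncated
genes, one model containing two complete receptors, and one receptor split
across two adjacent models.

NB-LRR proteins are built by concatenating the packaged motif consensi in
the canonical domain-series order (TNL: TIR motifs + Kin-2 ending in D;
CNL: pre-NB motifs + Kin-2 ending in W, optionally preceded by an ideal
coiled coil), joined by per-lineage random linkers, then mutated — founder
mutations per lineage and lighter per-copy mutations, never touching two
anchor positions per motif so detection stays identifiable under the default
rates.  Training sets pair low-mutation templates (positives) with
kinase/PRR-like decoys carrying Walker-A/B-like islands (negatives); two
APAF-like negatives carry three exact NB-ARC-like islands and anchor the
negative E-value minimum well below any trimmed gene model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genomeio import (
    GeneModel,
    GenomeBundle,
    write_fasta,
    write_gff3_genes,
    write_placements,
    write_repeats_gff3,
)
from .motifs import AMINO_ACIDS, MotifDefinition, load_motifs

#: canonical motif series per class template (Kin-2 variant noted below)
TNL_SERIES = (18, 15, 13, 1, 4, 5, 10, 12, 3, 8, 9, 11, 19)
CNL_SERIES = (17, 16, 1, 6, 4, 5, 10, 2, 12, 3, 7, 9, 11, 19)
IDEAL_COIL = "LEALEGK" * 5

_CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class LineagePlan:
    lineage_id: str
    nlr_class: str  # TNL | CNL
    has_cc: bool
    copies: int
    scaffold: int
    slot: float  # fractional position of the array centre on the scaffold
    inter_copy_gap: int  # bp between consecutive copies
    intervening_decoys: int  # decoy genes inserted between copies
    placed: bool = True


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome (all rates per site)."""

    seed: int
    scaffold_lengths: tuple[int, ...] = (
        1_400_000, 1_200_000, 1_000_000, 1_000_000, 800_000, 600_000)
    genes_rich_per_mb: float = 100.0
    genes_poor_per_mb: float = 30.0
    repeat_cov_rich: float = 0.10
    repeat_cov_poor: float = 0.45
    decoy_len_range: tuple[int, int] = (150, 450)
    founder_rate: float = 0.20  # lineage founder vs class template
    copy_rate: float = 0.04  # tandem copy vs lineage founder
    positive_rate: float = 0.02  # training positives vs class template
    n_positive: int = 16
    n_negative: int = 40
    trimmed_genes: int = 3  # mis-annotated models (motifs outside the model)
    truncated_genes: int = 2  # genuinely partial receptors
    spacer: int = 50_000
    protect_anchors: bool = True  # keep 2 anchor positions per motif intact
    lineages: tuple[LineagePlan, ...] = (
        LineagePlan("L1", "CNL", True, 5, 0, 0.33, 25_000, 2),
        LineagePlan("L2", "CNL", False, 4, 1, 0.33, 30_000, 3),
        LineagePlan("L3", "TNL", False, 3, 2, 0.33, 20_000, 1),
        LineagePlan("L4", "CNL", True, 3, 3, 0.33, 40_000, 2),
        LineagePlan("L5", "TNL", False, 2, 4, 0.35, 25_000, 0),
        LineagePlan("L6", "CNL", False, 2, 0, 0.70, 30_000, 2),
        LineagePlan("L7", "TNL", False, 1, 5, 0.40, 0, 0, placed=False),
        LineagePlan("L8", "CNL", True, 1, 1, 0.70, 0, 0),
    )

    def __post_init__(self):
        for r in (self.founder_rate, self.copy_rate, self.positive_rate,
                  self.repeat_cov_rich, self.repeat_cov_poor):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")


@dataclass
class _PlannedGene:
    gene_id: str
    protein: str  # full protein actually encoded in the DNA
    annotated_protein: str  # protein implied by the annotated model
    kind: str  # decoy | nlr | trimmed | truncated | double | split_a | split_b
    strand: str
    truths: list[dict] = field(default_factory=list)
    annotated_codons: tuple[int, int] | None = None  # sub-span for trimmed/split


@dataclass
class SimulatedGenome:
    bundle: GenomeBundle
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scaffolds": outdir / "scaffolds.fa",
            "genes": outdir / "genes.gff3",
            "proteins": outdir / "proteins.fa",
            "repeats": outdir / "repeats.gff3",
            "placements": outdir / "placements.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.bundle.scaffolds, paths["scaffolds"])
        write_gff3_genes(self.bundle.genes, paths["genes"], source="simulated")
        write_fasta(self.bundle.proteins, paths["proteins"])
        write_repeats_gff3(self.bundle.repeats, paths["repeats"])
        write_placements(self.bundle.placements, paths["placements"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_protein(rng, length: int) -> str:
    from .scan import BACKGROUND
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=BACKGROUND))


def _mutate(protein: str, rate: float, rng,
            protected: frozenset[int] = frozenset()) -> str:
    out = list(protein)
    for i in range(len(out)):
        if i in protected or rng.random() >= rate:
            continue
        out[i] = AMINO_ACIDS[rng.integers(0, 20)]
    return "".join(out)


@dataclass
class _Template:
    protein: str
    motif_pieces: list[tuple[int, int, int]]  # (motif_id, start, end)
    protected: frozenset[int]


def build_template(nlr_class: str, has_cc: bool,
                   motifs: dict[int, MotifDefinition], rng) -> _Template:
    """Concatenate consensi in canonical order with random linkers.

    The Kin-2 motif (4) keeps its consensus-terminal aspartate for TNLs and
    gets the class-discriminating tryptophan for CNLs.
    """
    series = TNL_SERIES if nlr_class == "TNL" else CNL_SERIES
    parts = ["M"]
    if nlr_class == "CNL" and has_cc:
        parts.append(IDEAL_COIL)
    pos = sum(len(p) for p in parts)
    pieces, protected = [], set()
    for mid in series:
        cons = motifs[mid].consensus
        if mid == 4 and nlr_class == "CNL":
            cons = cons[:-1] + "W"
        parts.append(cons)
        pieces.append((mid, pos, pos + len(cons)))
        protected.update({pos, pos + len(cons) - 1})
        pos += len(cons)
        linker = _random_protein(rng, int(rng.integers(15, 41)))
        parts.append(linker)
        pos += len(linker)
    return _Template("".join(parts), pieces, frozenset(protected))


def _reverse_translate(protein: str) -> str:
    return "".join(_CODONS[aa] for aa in protein) + "TAA"


def _revcomp(dna: str) -> str:
    return dna.translate(_COMP)[::-1]


def _motif_end_codon(template: _Template, motif_id: int) -> int:
    for mid, _s, e in template.motif_pieces:
        if mid == motif_id:
            return e
    raise KeyError(motif_id)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate the full annotated genome plus ground truth (seeded)."""
    rng = np.random.default_rng(config.seed)
    motifs = load_motifs()
    templates = {
        ("TNL", False): build_template("TNL", False, motifs, rng),
        ("CNL", False): build_template("CNL", False, motifs, rng),
        ("CNL", True): build_template("CNL", True, motifs, rng),
    }

    # lineage founders: independent mutation of the class template,
    # each lineage with its own freshly drawn linkers
    founders: dict[str, _Template] = {}
    for plan in config.lineages:
        base = build_template(plan.nlr_class, plan.has_cc, motifs, rng)
        protected = base.protected if config.protect_anchors else frozenset()
        founders[plan.lineage_id] = replace(
            base, protein=_mutate(base.protein, config.founder_rate, rng,
                                  protected))

    gene_counter = [0]

    def next_id() -> str:
        gene_counter[0] += 1
        return f"G{gene_counter[0]:05d}"

    def make_decoy() -> _PlannedGene:
        length = int(rng.integers(*config.decoy_len_range))
        protein = "M" + _random_protein(rng, length - 1)
        return _PlannedGene(next_id(), protein, protein, "decoy",
                            "+" if rng.random() < 0.5 else "-")

    def make_copy(plan: LineagePlan) -> tuple[str, _Template]:
        tmpl = founders[plan.lineage_id]
        protected = tmpl.protected if config.protect_anchors else frozenset()
        return (_mutate(tmpl.protein, config.copy_rate, rng, protected), tmpl)

    # choose which NLR copies are trimmed / truncated, deterministically
    all_copies = [(plan, c) for plan in config.lineages
                  for c in range(plan.copies)]
    multi = [(p, c) for p, c in all_copies if p.copies >= 2 and c >= 1]
    multi.sort(key=lambda pc: (pc[1], pc[0].lineage_id))
    trimmed_set = set(map(tuple, [(p.lineage_id, c) for (p, c)
                                  in multi[:config.trimmed_genes]]))
    truncated_set = set(map(tuple, [(p.lineage_id, c) for (p, c)
                                    in multi[config.trimmed_genes:
                                             config.trimmed_genes
                                             + config.truncated_genes]]))

    def make_nlr(plan: LineagePlan, copy_index: int,
                 cluster_id: str | None) -> _PlannedGene:
        protein, tmpl = make_copy(plan)
        key = (plan.lineage_id, copy_index)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = next_id()
        truth = {
            "gene_id": gid, "original_model": gid, "is_nlr": True,
            "nlr_class": plan.nlr_class, "lineage": plan.lineage_id,
            "cluster_id": cluster_id or "", "has_cc": plan.has_cc,
            "completeness": "full_length", "flag": "normal",
        }
        if key in truncated_set:
            # the genome itself lacks linker+LRR: cut after GLPL (motif 3)
            cut = _motif_end_codon(tmpl, 3) + 2
            protein = protein[:cut]
            truth.update(completeness="partial", flag="truncated")
            return _PlannedGene(gid, protein, protein, "truncated", strand,
                                [truth])
        if key in trimmed_set:
            # annotation covers only the N-terminal motifs; the rest of the
            # receptor is in the DNA but outside the model (within 3 kb)
            anchor = 15 if plan.nlr_class == "TNL" else 16
            cut = _motif_end_codon(tmpl, anchor) + 2
            truth.update(flag="trimmed")
            return _PlannedGene(gid, protein, protein[:cut], "trimmed",
                                strand, [truth], annotated_codons=(0, cut))
        return _PlannedGene(gid, protein, protein, "nlr", strand, [truth])

    # special cases: one double model (two receptors in one ORF) and one
    # receptor split across two adjacent models
    def make_double(plan: LineagePlan, cluster_id: str) -> _PlannedGene:
        pa, _ = make_copy(plan)
        pb, _ = make_copy(plan)
        protein = pa + "GSGSGSGSGSGSGSGSGS" + pb
        gid = next_id()
        truths = [{
            "gene_id": f"{gid}.{part}", "original_model": gid, "is_nlr": True,
            "nlr_class": plan.nlr_class, "lineage": plan.lineage_id,
            "cluster_id": cluster_id, "has_cc": plan.has_cc,
            "completeness": "full_length", "flag": "double",
        } for part in (1, 2)]
        return _PlannedGene(gid, protein, protein, "double",
                            "+" if rng.random() < 0.5 else "-", truths)

    def make_split(plan: LineagePlan) -> list[_PlannedGene]:
        protein, tmpl = make_copy(plan)
        cut = _motif_end_codon(tmpl, 10) + 4  # split after RNBS-C
        gid_a, gid_b = next_id(), next_id()
        strand = "+" if rng.random() < 0.5 else "-"
        first, second = (gid_a, gid_b)
        merged = f"{first}_{second}"
        truth = {
            "gene_id": merged, "original_model": f"{gid_a}+{gid_b}",
            "is_nlr": True, "nlr_class": plan.nlr_class,
            "lineage": plan.lineage_id, "cluster_id": "",
            "has_cc": plan.has_cc, "completeness": "full_length",
            "flag": "split",
        }
        a = _PlannedGene(gid_a, protein, protein[:cut], "split_a", strand,
                         [truth], annotated_codons=(0, cut))
        b = _PlannedGene(gid_b, protein, protein[cut:], "split_b", strand,
                         [], annotated_codons=(cut, len(protein)))
        return [a, b]

    # assemble per-scaffold gene streams ------------------------------------
    slot_events: dict[int, list[tuple[float, list[_PlannedGene], int, int]]] = {
        i: [] for i in range(len(config.scaffold_lengths))}
    cluster_counter = [0]

    def new_cluster_id(n_members: int) -> str | None:
        if n_members < 2:
            return None
        cluster_counter[0] += 1
        return f"T{cluster_counter[0]}"

    for plan in config.lineages:
        cid = new_cluster_id(plan.copies)
        array = [make_nlr(plan, c, cid) for c in range(plan.copies)]
        slot_events[plan.scaffold].append(
            (plan.slot, array, plan.inter_copy_gap, plan.intervening_decoys))

    # heterogeneous pair: one copy each from two different-class lineages
    hcid = new_cluster_id(2)
    hetero = [make_nlr(config.lineages[0], 90, hcid),
              make_nlr(config.lineages[2], 90, hcid)]
    for g in hetero:
        g.truths[0]["cluster_id"] = hcid
    slot_events[2].append((0.70, hetero, 60_000, 2))

    dcid = new_cluster_id(2)
    double = make_double(config.lineages[3], dcid)
    slot_events[3].append((0.70, [double], 0, 0))

    split_pair = make_split(config.lineages[4])
    slot_events[4].append((0.70, split_pair, 0, 0))

    scaffolds: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    proteins: dict[str, str] = {}
    repeats: dict[str, list[tuple[int, int]]] = {}
    truth_rows: list[dict] = []

    for si, target_len in enumerate(config.scaffold_lengths):
        sid = f"scaffold{si + 1:02d}"
        events = sorted(slot_events[si], key=lambda e: e[0])
        stream: list[tuple[_PlannedGene, int]] = []  # (gene, preceding gap)
        cursor = 0
        ev_idx = 0
        rich_first = si % 2 == 0
        while cursor < target_len:
            frac = cursor / target_len
            rich = (frac < 0.5) == rich_first
            mean_gap = 1e6 / (config.genes_rich_per_mb if rich
                              else config.genes_poor_per_mb)
            while ev_idx < len(events) and frac >= events[ev_idx][0]:
                _slot, array, gap_bp, n_decoys = events[ev_idx]
                for k, gene in enumerate(array):
                    if k == 0:
                        stream.append((gene, 2000))
                        cursor += 2000 + 3 * len(gene.protein) + 3
                        continue
                    if gene.kind == "split_b":
                        stream.append((gene, 0))
                        cursor += 3 * len(gene.protein) + 3
                        continue
                    sub_gap = max(500, gap_bp // (n_decoys + 1))
                    for _ in range(n_decoys):
                        decoy = make_decoy()
                        stream.append((decoy, sub_gap))
                        cursor += sub_gap + 3 * len(decoy.protein) + 3
                    stream.append((gene, sub_gap))
                    cursor += sub_gap + 3 * len(gene.protein) + 3
                ev_idx += 1
            gap = int(rng.exponential(mean_gap)) + 200
            decoy = make_decoy()
            stream.append((decoy, gap))
            cursor += gap + 3 * len(decoy.protein) + 3
        length = cursor + 1000

        # lay the stream onto DNA
        bases = rng.integers(0, 4, size=length)
        dna = np.array(list("ACGT"))[bases]
        pos = 0
        prev_cds = (0, 0)
        for gene, gap in stream:
            if gene.kind == "split_b":
                # second half of a receptor split across two models: the DNA
                # was already written by the first half; both models point
                # into one contiguous CDS
                start, end = prev_cds
            else:
                pos += gap
                cds = _reverse_translate(gene.protein)
                start, end = pos, pos + len(cds)
                dna[start:end] = list(cds if gene.strand == "+"
                                      else _revcomp(cds))
                pos = end
            prev_cds = (start, end)
            # annotated model may cover only part of the encoded protein
            if gene.annotated_codons is None:
                m_start, m_end = start, end
            else:
                c0, c1 = gene.annotated_codons
                if gene.strand == "+":
                    m_start, m_end = start + 3 * c0, start + 3 * c1
                else:
                    m_start, m_end = end - 3 * c1, end - 3 * c0
            tid = f"{gene.gene_id}.1"
            genes[gene.gene_id] = GeneModel(
                gene.gene_id, sid, gene.strand, m_start, m_end,
                exons=[(m_start, m_end)], protein_ids=[tid])
            proteins[tid] = gene.annotated_protein
            for t in gene.truths:
                row = dict(t)
                row.update(scaffold=sid, start=m_start, end=m_end,
                           strand=gene.strand)
                truth_rows.append(row)
        scaffolds[sid] = "".join(dna)

        # repeats per regime block
        ivs: list[tuple[int, int]] = []
        for blo, bhi, rich in ((0, length // 2, rich_first),
                               (length // 2, length, not rich_first)):
            cov_target = (config.repeat_cov_rich if rich
                          else config.repeat_cov_poor)
            covered = 0
            while covered < cov_target * (bhi - blo):
                ln = int(rng.integers(500, 5000))
                s = int(rng.integers(blo, max(blo + 1, bhi - ln)))
                ivs.append((s, s + ln))
                covered += ln
        repeats[sid] = sorted(ivs)

    # placements: scaffolds onto pseudomolecules with spacers; the scaffold
    # of any lineage flagged placed=False stays unplaced
    unplaced = {p.scaffold for p in config.lineages if not p.placed}
    rows = []
    pm_assign = [0, 0, 1, 1, 2, 2]
    offsets = dict.fromkeys(range(3), 0)
    for si in range(len(config.scaffold_lengths)):
        if si in unplaced:
            continue
        pm = pm_assign[si % len(pm_assign)]
        sid = f"scaffold{si + 1:02d}"
        rows.append({
            "scaffold_id": sid, "pseudomolecule_id": f"chr{pm + 1:02d}",
            "offset": offsets[pm],
            "orientation": "+" if si % 3 != 1 else "-",
        })
        offsets[pm] += len(scaffolds[sid]) + config.spacer
    placements = pd.DataFrame(rows)

    truth = pd.DataFrame(truth_rows)
    mapped = {r["scaffold_id"] for r in rows}
    truth["mapped"] = truth["scaffold"].isin(mapped)
    # receptors on unplaced scaffolds cannot belong to a physical cluster
    truth.loc[~truth["mapped"], "cluster_id"] = ""

    bundle = GenomeBundle(scaffolds=scaffolds, genes=genes, proteins=proteins,
                          repeats=repeats, placements=placements)
    return SimulatedGenome(bundle=bundle, truth=truth, config=config)


def simulate_training_sets(config: SimulationConfig
                           ) -> tuple[dict[str, str], dict[str, str]]:
    """Positive (low-mutation NLR templates) and negative (decoy) proteins.

    Negatives are kinase/PRR-like: random background proteins carrying a
    Walker-A-like island (a mutated copy of the P-loop consensus), half of
    them also a Walker-B-like island (mutated Kin-2 consensus); the first two
    are APAF-like with three exact NB-ARC-like islands (P-loop, Kin-2,
    RNBS-B) and pin the negative E-value minimum.
    """
    if config.n_negative <= 0:
        raise ValueError("need at least one negative training sequence")
    if config.n_positive <= 0:
        raise ValueError("need at least one positive training sequence")
    rng = np.random.default_rng(config.seed + 101)
    motifs = load_motifs()
    positives: dict[str, str] = {}
    for i in range(config.n_positive):
        cls = "TNL" if i % 2 else "CNL"
        tmpl = build_template(cls, cls == "CNL" and i % 4 == 0, motifs, rng)
        protected = tmpl.protected if config.protect_anchors else frozenset()
        positives[f"POS{i + 1:03d}_{cls}"] = _mutate(
            tmpl.protein, config.positive_rate, rng, protected)
    negatives: dict[str, str] = {}
    p_loop = motifs[1].consensus
    kin2 = motifs[4].consensus
    rnbs_b = motifs[5].consensus
    for i in range(config.n_negative):
        backbone = "M" + _random_protein(rng, int(rng.integers(320, 420)))
        if i < 2:  # APAF-like: three exact NB-ARC-like islands
            islands = [(50, p_loop), (150, kin2), (250, rnbs_b)]
        else:
            u = float(rng.uniform(0.10, 0.40))
            islands = [(50, _mutate(p_loop, u, rng))]
            if i % 2 == 0:
                islands.append((160, _mutate(kin2, u, rng)))
        out = backbone
        for pos, island in islands:
            out = out[:pos] + island + out[pos + len(island):]
        negatives[f"NEG{i + 1:03d}"] = out
    return positives, negatives


def write_training_sets(config: SimulationConfig, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pos, neg = simulate_training_sets(config)
    paths = {"positive": outdir / "training_positive.fa",
             "negative": outdir / "training_negative.fa"}
    write_fasta(pos, paths["positive"])
    write_fasta(neg, paths["negative"])
    return paths


def evaluate(predicted: dict, truth: pd.DataFrame) -> dict:
    """Score pipeline output against the planted ground truth.

    ``predicted`` needs keys: ``annotations`` (gene id -> NlrAnnotation),
    ``clusters`` (list of Cluster), ``homogeneity`` (cluster id -> label).
    Reports identification precision/recall, class and completeness accuracy,
    exact and pairwise (Rand) cluster recovery, and homogeneity accuracy.
    """
    truth_nlr = truth[truth["is_nlr"]]
    truth_ids = set(truth_nlr["gene_id"])
    pred_ids = set(predicted["annotations"])
    tp = truth_ids & pred_ids
    recall = len(tp) / len(truth_ids) if truth_ids else float("nan")
    precision = len(tp) / len(pred_ids) if pred_ids else float("nan")

    by_id = truth_nlr.set_index("gene_id")
    class_ok = completeness_ok = 0
    confusion: dict[tuple[str, str], int] = {}
    for gid in sorted(tp):
        ann = predicted["annotations"][gid]
        if ann.nlr_class == by_id.loc[gid, "nlr_class"]:
            class_ok += 1
        key = (by_id.loc[gid, "completeness"], ann.completeness)
        confusion[key] = confusion.get(key, 0) + 1
        if key[0] == key[1]:
            completeness_ok += 1

    # cluster recovery among correctly identified, mapped genes
    truth_clusters: dict[str, set[str]] = {}
    for _, row in truth_nlr.iterrows():
        if row["cluster_id"]:
            truth_clusters.setdefault(row["cluster_id"], set()).add(
                row["gene_id"])
    pred_clusters = {c.cluster_id: set(c.members) for c in
                     predicted["clusters"]}
    exact = sum(1 for members in truth_clusters.values()
                if members in pred_clusters.values())
    exact_rate = exact / len(truth_clusters) if truth_clusters else float("nan")

    mapped_ids = sorted(truth_nlr[truth_nlr["mapped"]]["gene_id"])
    t_label = {g: next((cid for cid, m in truth_clusters.items() if g in m),
                       f"_s{g}") for g in mapped_ids}
    p_label = {g: next((cid for cid, m in pred_clusters.items() if g in m),
                       f"_s{g}") for g in mapped_ids}
    agree = total = 0
    for i, a in enumerate(mapped_ids):
        for b in mapped_ids[i + 1:]:
            total += 1
            same_t = t_label[a] == t_label[b]
            same_p = p_label[a] == p_label[b]
            agree += same_t == same_p
    rand_index = agree / total if total else float("nan")

    homo_ok = homo_n = 0
    truth_homo = {}
    for cid, members in truth_clusters.items():
        lineages = set(by_id.loc[sorted(members), "lineage"])
        truth_homo[frozenset(members)] = (
            "homogeneous" if len(lineages) == 1 else "heterogeneous")
    for cid, members in pred_clusters.items():
        key = frozenset(members)
        if key in truth_homo:
            homo_n += 1
            if predicted["homogeneity"].get(cid) == truth_homo[key]:
                homo_ok += 1

    n_id = len(tp)
    return {
        "recall": recall,
        "precision": precision,
        "class_accuracy": class_ok / n_id if n_id else float("nan"),
        "completeness_accuracy": completeness_ok / n_id if n_id else float("nan"),
        "completeness_confusion": confusion,
        "cluster_exact_recovery": exact_rate,
        "cluster_rand_index": rand_index,
        "homogeneity_accuracy": homo_ok / homo_n if homo_n else float("nan"),
        "n_truth_nlr": len(truth_ids),
        "n_predicted": len(pred_ids),
    }
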