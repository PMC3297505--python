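"""Genome bundle I/O: FASTA, GFF3 gene models, repeat intervals, placements.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the format's 1-based inclusive convention.  The GFF3 reader/writer covers the
flat gene -> mRNA -> CDS models this pipeline produces and consumes, and
reports malformed lines and out-of-bounds features by line number / feature
id, as required of a validating loader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GeneModel:
    gene_id: str
    scaffold_id: str
    strand: str  # '+' or '-'
    start: int  # 0-based half-open on the scaffold
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    protein_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid interval "
                             f"[{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev = self.start - 1
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e or s <= prev:
                raise ValueError(f"{self.gene_id}: bad exon [{s},{e})")
            prev = e


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
    del width  # Biopython wraps at 60 columns


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"attribute {item!r} lacks '='")
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path, scaffold_lengths: dict[str, int] | None = None
                    ) -> dict[str, GeneModel]:
    """Read gene/mRNA/CDS features into GeneModel records.

    Raises on malformed lines (with line number) and on features outside
    their scaffold (with feature id) when scaffold lengths are supplied.
    """
    genes: dict[str, GeneModel] = {}
    mrna_gene: dict[str, str] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, "
                                 f"got {len(fields)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start) - 1, int(end)  # to 0-based half-open
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 0 or start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}..{end}")
            attr = _parse_attributes(attrs)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID")
                if scaffold_lengths is not None:
                    if seqid not in scaffold_lengths:
                        raise ValueError(f"gene {gid}: unknown scaffold {seqid}")
                    if end_i > scaffold_lengths[seqid]:
                        raise ValueError(f"gene {gid}: end {end_i} beyond "
                                         f"scaffold {seqid}")
                genes[gid] = GeneModel(gid, seqid, strand, start_i, end_i)
            elif ftype == "mRNA":
                tid, parent = attr.get("ID"), attr.get("Parent")
                if tid is None or parent is None:
                    raise ValueError(f"{path}:{lineno}: mRNA needs ID and Parent")
                mrna_gene[tid] = parent
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: CDS needs Parent")
                cds.setdefault(parent, []).append((start_i, end_i))
    for tid, gid in mrna_gene.items():
        if gid not in genes:
            raise ValueError(f"mRNA {tid}: unknown gene {gid}")
        genes[gid].protein_ids.append(tid)
        for iv in sorted(cds.get(tid, [])):
            if iv not in genes[gid].exons:
                genes[gid].exons.append(iv)
    for g in genes.values():
        g.protein_ids.sort()
        g.__post_init__()
    return genes


def write_gff3_genes(genes: dict[str, GeneModel], path, source: str = "nlrscan"
                     ) -> None:
    lines = ["##gff-version 3"]
    for gid in sorted(genes, key=lambda g: (genes[g].scaffold_id, genes[g].start, g)):
        g = genes[gid]
        lines.append("\t".join([
            g.scaffold_id, source, "gene", str(g.start + 1), str(g.end), ".",
            g.strand, ".", f"ID={gid}"]))
        for tid in g.protein_ids or [gid + ".1"]:
            lines.append("\t".join([
                g.scaffold_id, source, "mRNA", str(g.start + 1), str(g.end),
                ".", g.strand, ".", f"ID={tid};Parent={gid}"]))
            for s, e in g.exons or [(g.start, g.end)]:
                lines.append("\t".join([
                    g.scaffold_id, source, "CDS", str(s + 1), str(e), ".",
                    g.strand, "0", f"ID={tid}.cds;Parent={tid}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_repeats_gff3(path) -> dict[str, list[tuple[int, int]]]:
    """Repeat intervals per scaffold, 0-based half-open, sorted."""
    repeats: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            seqid, start, end = fields[0], fields[3], fields[4]
            repeats.setdefault(seqid, []).append((int(start) - 1, int(end)))
    return {k: sorted(v) for k, v in repeats.items()}


def write_repeats_gff3(repeats: dict[str, list[tuple[int, int]]], path) -> None:
    lines = ["##gff-version 3"]
    for seqid in sorted(repeats):
        for i, (s, e) in enumerate(sorted(repeats[seqid])):
            lines.append("\t".join([
                seqid, "simulated", "repeat_region", str(s + 1), str(e), ".",
                "+", ".", f"ID={seqid}.rep{i}"]))
    Path(path).write_text("\n".join(lines) + "\n")


PLACEMENT_COLUMNS = ["scaffold_id", "pseudomolecule_id", "offset", "orientation"]


def read_placements(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str,
                                            "pseudomolecule_id": str})
    missing = set(PLACEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"placement table missing columns {sorted(missing)}")
    dup = df["scaffold_id"][df["scaffold_id"].duplicated()]
    if len(dup):
        raise ValueError(f"scaffold placed twice: {sorted(set(dup))}")
    return df


def write_placements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PLACEMENT_COLUMNS)


@dataclass
class GenomeBundle:
    """A validated annotated-genome input set."""

    scaffolds: dict[str, str]
    genes: dict[str, GeneModel]
    proteins: dict[str, str]
    repeats: dict[str, list[tuple[int, int]]]
    placements: pd.DataFrame
    transcript_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for gid, g in self.genes.items():
            if g.scaffold_id not in self.scaffolds:
                raise ValueError(f"gene {gid}: unknown scaffold {g.scaffold_id}")
            if g.end > len(self.scaffolds[g.scaffold_id]):
                raise ValueError(f"gene {gid}: beyond scaffold end")
            for tid in g.protein_ids:
                self.transcript_to_gene.setdefault(tid, gid)
        for pid in self.proteins:
            if pid not in self.transcript_to_gene:
                # single-transcript convention: a protein named like a gene
                if pid in self.genes:
                    self.transcript_to_gene[pid] = pid
                else:
                    raise ValueError(f"protein {pid}: no matching gene model")


def read_genome_bundle(scaffold_fasta, gene_gff3, protein_fasta, repeat_gff3,
                       placement_tsv) -> GenomeBundle:
    scaffolds = read_fasta(scaffold_fasta)
    lengths = {k: len(v) for k, v in scaffolds.items()}
    return GenomeBundle(
        scaffolds=scaffolds,
        genes=read_gff3_genes(gene_gff3, lengths),
        proteins=read_fasta(protein_fasta),
        repeats=read_repeats_gff3(repeat_gff3),
        placements=read_placements(placement_tsv),
    )
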