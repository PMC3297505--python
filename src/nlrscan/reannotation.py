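"""Gene-model re-annotation: flank extension, six-frame re-scan, split/merge,
intron/frameshift and completeness calling.

Candidate gene models whose predicted proteins lack expected NB-LRR domains
are extended by a fixed flank (default 3 kb) on both sides, the extended DNA
is conceptually translated in all six frames, and each frame is scanned with
the motif models.  The framed hits drive four deterministic calls:

* a model carrying two complete, non-interleaved motif series is split in two;
* two adjacent models carrying complementary prefix/suffix portions of one
  canonical series are merged;
* frame changes between consecutive hits are called introns (gap >= a minimum
  intron length) or frameshifts (shorter gaps, or an in-frame stop codon);
* the resolved motif complement plus the structure call yields the
  full length / potentially full length / partial completeness class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genomeio import GeneModel
from .motifs import CANONICAL_STAGE, LRR_MOTIFS, TIR_MOTIFS
from .scan import DEFAULT_P_CUTOFF, MotifHit, MotifScoringModel, scan

FRAMES = ("+0", "+1", "+2", "-0", "-1", "-2")
NB_ARC_CORE = frozenset({1, 4, 5, 10, 3})


@dataclass
class ExtendedRegion:
    gene_id: str
    scaffold_id: str
    region_start: int  # clipped, 0-based half-open on the scaffold
    region_end: int
    sequence: str
    offset: int  # region_start relative to the original gene start

    def to_scaffold(self, region_pos: int) -> int:
        return self.region_start + region_pos


@dataclass
class StructureCall:
    intron_count: int
    frameshift_count: int
    # (frame, aa_start, aa_end, dna_start, dna_end) per joined segment,
    # aa coordinates in the frame's conceptual translation, dna in the region
    cds_segments: list[tuple[str, int, int, int, int]]
    coding_length: int  # bp


def extend(gene: GeneModel, scaffold_seq: str, flank: int = 3000) -> ExtendedRegion:
    """Clip-extend a gene interval by ``flank`` bp on both sides."""
    if gene.end > len(scaffold_seq):
        raise ValueError(f"gene {gene.gene_id} lies outside its scaffold")
    start = max(0, gene.start - flank)
    end = min(len(scaffold_seq), gene.end + flank)
    return ExtendedRegion(
        gene_id=gene.gene_id, scaffold_id=gene.scaffold_id,
        region_start=start, region_end=end,
        sequence=scaffold_seq[start:end], offset=start - gene.start,
    )


def translate_frames(dna: str) -> dict[str, str]:
    """Conceptual translation in all six frames (X for ambiguity, * for stops)."""
    seq = Seq(dna.upper())
    rc = seq.reverse_complement()
    out = {}
    for k in range(3):
        for sign, s in (("+", seq), ("-", rc)):
            sub = s[k:]
            sub = sub[: len(sub) - len(sub) % 3]
            out[f"{sign}{k}"] = str(sub.translate())
    return out


def hit_dna_span(hit_aa_start: int, hit_aa_end: int, frame: str, region_len: int
                 ) -> tuple[int, int]:
    """Map an amino-acid window in a frame translation to region DNA coords."""
    k = int(frame[1])
    if frame[0] == "+":
        return k + 3 * hit_aa_start, k + 3 * hit_aa_end
    return region_len - (k + 3 * hit_aa_end), region_len - (k + 3 * hit_aa_start)


def rescan_six_frames(
    region: ExtendedRegion,
    models: dict[int, MotifScoringModel],
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> tuple[list[MotifHit], dict[str, str]]:
    """Scan all six conceptual translations; hits carry frames and DNA coords."""
    translations = translate_frames(region.sequence)
    hits: list[MotifHit] = []
    for frame in FRAMES:
        protein = translations[frame]
        if not protein:
            continue
        for mid, model in sorted(models.items()):
            for h in scan(protein, model, region.gene_id, p_cutoff, frame=frame):
                h.dna_start, h.dna_end = hit_dna_span(
                    h.start, h.end, frame, len(region.sequence))
                hits.append(h)
    hits.sort(key=lambda h: (h.dna_start, h.motif_id))
    return hits, translations


def _coding_sorted(hits: list[MotifHit]) -> list[MotifHit]:
    """Order hits 5'->3' along the coding strand (majority vote over hits)."""
    if not hits:
        return []
    minus = sum(h.frame.startswith("-") for h in hits)
    strand = "-" if minus > len(hits) - minus else "+"
    same = [h for h in hits if h.frame.startswith(strand)]
    return sorted(same, key=lambda h: h.dna_start, reverse=(strand == "-"))


#: a hit this strong stands on its own even without an ORF co-occurrence
P_STRONG = 1e-8


def _orf_filter(hits: list[MotifHit], translations: dict[str, str]
                ) -> list[MotifHit]:
    """Keep hits that share an open reading frame with another motif.

    A six-frame scan of a multi-kb region produces scattered chance hits;
    genuine domain hits of one gene co-occur inside a single stop-free
    stretch of one frame.  Hits whose ORF carries no second distinct motif
    are dropped unless individually overwhelming (p <= P_STRONG).
    """
    import bisect

    stops = {f: [i for i, c in enumerate(t) if c == "*"]
             for f, t in translations.items()}
    groups: dict[tuple[str, int], list[MotifHit]] = {}
    for h in hits:
        orf = bisect.bisect_right(stops[h.frame], h.start)
        groups.setdefault((h.frame, orf), []).append(h)
    kept = []
    for group in groups.values():
        if len({h.motif_id for h in group}) >= 2:
            kept.extend(group)
        else:
            kept.extend(h for h in group if h.p_value <= P_STRONG)
    return kept


def _collapse_series(hits: list[MotifHit], p_cutoff: float,
                     translations: dict[str, str] | None = None
                     ) -> list[MotifHit]:
    """Significant non-monocot hits in coding order, one per motif occurrence."""
    sig = [h for h in hits
           if h.p_value <= p_cutoff and h.motif_id in CANONICAL_STAGE]
    if translations is not None:
        sig = _orf_filter(sig, translations)
    ordered = _coding_sorted(sig)
    collapsed: list[MotifHit] = []
    for h in ordered:
        prev = collapsed[-1] if collapsed else None
        if (prev is not None and prev.motif_id == h.motif_id
                and abs(h.dna_start - prev.dna_start) < 3 * (h.end - h.start)):
            if h.score > prev.score:
                collapsed[-1] = h
            continue
        collapsed.append(h)
    return collapsed


def partition_signatures(
    hits: list[MotifHit], p_cutoff: float = DEFAULT_P_CUTOFF,
    translations: dict[str, str] | None = None,
) -> list[list[MotifHit]]:
    """Split a hit series in two when the canonical series occurs twice.

    Walking the collapsed hits in coding order, a split happens before the
    first hit that restarts the series at an N-terminal/P-loop anchor after a
    complete tail (linker/LRR) has been seen, provided the remainder also
    reaches a tail.  Otherwise one group is returned.
    """
    series = _collapse_series(hits, p_cutoff, translations)
    strong = [h for h in series if h.p_value <= P_STRONG] or series
    stages = [CANONICAL_STAGE[h.motif_id] for h in strong]
    for i in range(1, len(strong)):
        if (stages[i] <= 1 and max(stages[:i]) >= 8 and max(stages[i:]) >= 8):
            boundary = strong[i]
            first = [h for h in series if _before(h, boundary)]
            second = [h for h in series if not _before(h, boundary)]
            return [first, second]
    return [series]


def _before(hit: MotifHit, boundary: MotifHit) -> bool:
    """True when ``hit`` precedes ``boundary`` in coding order."""
    if boundary.frame.startswith("-"):
        return hit.dna_start > boundary.dna_start
    return hit.dna_start < boundary.dna_start


def merge_adjacent(
    a: tuple[GeneModel, list[MotifHit]],
    b: tuple[GeneModel, list[MotifHit]],
    max_gap: int = 10_000,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> GeneModel | None:
    """Merge two adjacent models holding complementary parts of one series.

    The models must sit on one scaffold and strand within ``max_gap`` bp;
    taking them in coding order, each hit series must be canonically
    non-decreasing, the upstream series must end no later in the series than
    the downstream one begins, and the union must be motif-rich enough to
    look like one receptor.  Returns the merged model or None.
    """
    (gene_a, hits_a), (gene_b, hits_b) = a, b
    if gene_a.scaffold_id != gene_b.scaffold_id or gene_a.strand != gene_b.strand:
        return None
    lo, hi = sorted([gene_a, gene_b], key=lambda g: g.start)
    if hi.start - lo.end > max_gap or hi.start < lo.end:
        return None
    first, second = (lo, hi) if gene_a.strand == "+" else (hi, lo)
    def decisive(hits):
        collapsed = _collapse_series(hits, p_cutoff)
        return [h for h in collapsed if h.p_value <= P_STRONG] or collapsed

    series = {id(gene_a): decisive(hits_a), id(gene_b): decisive(hits_b)}
    sa = [CANONICAL_STAGE[h.motif_id] for h in series[id(first)]]
    sb = [CANONICAL_STAGE[h.motif_id] for h in series[id(second)]]
    if not sa or not sb:
        return None
    if sa != sorted(sa) or sb != sorted(sb) or sa[-1] > sb[0]:
        return None
    union = {h.motif_id for h in series[id(gene_a)] + series[id(gene_b)]}
    if len(union) < 4:
        return None
    return GeneModel(
        gene_id=f"{first.gene_id}_{second.gene_id}",
        scaffold_id=gene_a.scaffold_id, strand=gene_a.strand,
        start=lo.start, end=hi.end,
        protein_ids=[f"{first.gene_id}_{second.gene_id}.1"],
    )


def call_structure(
    hits: list[MotifHit],
    translations: dict[str, str],
    min_intron: int = 60,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    orf_filter: bool = True,
) -> StructureCall:
    """Call introns and frameshifts from framed hits.

    Consecutive hits in one frame with no in-frame stop between them join one
    CDS segment.  A frame change across a gap of at least ``min_intron`` bp
    counts as an intron; a frame change across a shorter gap, or an in-frame
    stop codon between same-frame hits, counts as a frameshift.
    """
    series = _collapse_series(hits, p_cutoff,
                               translations if orf_filter else None)
    if not series:
        raise ValueError("structure call requires at least one hit")
    strong = [h for h in series if h.p_value <= P_STRONG]
    if strong:
        series = strong
    introns = frameshifts = 0
    segments: list[list[MotifHit]] = [[series[0]]]
    for prev, cur in zip(series, series[1:]):
        gap = _coding_gap(prev, cur)
        if cur.frame == prev.frame:
            trans = translations[cur.frame]
            lo, hi = sorted([prev.end, cur.start]) if gap >= 0 else (0, 0)
            if gap >= 0 and "*" in trans[lo:hi]:
                frameshifts += 1
                segments.append([cur])
            else:
                segments[-1].append(cur)
        elif gap >= min_intron:
            introns += 1
            segments.append([cur])
        else:
            frameshifts += 1
            segments.append([cur])
    out_segments = []
    coding = 0
    for seg in segments:
        aa_start = min(h.start for h in seg)
        aa_end = max(h.end for h in seg)
        dna_start = min(h.dna_start for h in seg)
        dna_end = max(h.dna_end for h in seg)
        out_segments.append((seg[0].frame, aa_start, aa_end, dna_start, dna_end))
        coding += dna_end - dna_start
    return StructureCall(introns, frameshifts, out_segments, coding)


def _coding_gap(prev: MotifHit, cur: MotifHit) -> int:
    if prev.frame.startswith("-"):
        return prev.dna_start - cur.dna_end
    return cur.dna_start - prev.dna_end


def build_protein(structure: StructureCall, translations: dict[str, str],
                  aa_min: int | None = None, aa_max: int | None = None) -> str:
    """Reconstruct the re-annotated protein from the structure call.

    Each CDS segment contributes its frame translation between the bounding
    hits; the first segment is extended upstream and the last downstream to
    the enclosing stop codons (open-reading-frame completion), so N-terminal
    domains upstream of the first motif hit (e.g. a coiled coil) are
    recovered.  ``aa_min``/``aa_max`` bound that extension (used when one
    open reading frame holds two receptors that were partitioned apart).
    """
    parts = []
    for i, (frame, aa_start, aa_end, _ds, _de) in enumerate(structure.cds_segments):
        trans = translations[frame]
        lo, hi = aa_start, aa_end
        if i == 0:
            stop = trans.rfind("*", 0, lo)
            lo = stop + 1
            if aa_min is not None:
                lo = max(lo, aa_min)
        if i == len(structure.cds_segments) - 1:
            stop = trans.find("*", hi)
            hi = stop if stop != -1 else len(trans)
            if aa_max is not None:
                hi = min(hi, aa_max)
        parts.append(trans[lo:hi])
    return "".join(parts).replace("*", "")


def completeness(
    motif_ids: set[int],
    structure: StructureCall,
    nlr_class: str,
) -> str:
    """Completeness class from the motif complement and structure call.

    Required domains: NB-ARC core (P-loop, Kin-2, RNBS-B, RNBS-C, GLPL) and
    at least one LRR motif for every class, plus at least one TIR motif for
    TNLs (an N-terminal CC motif is optional for CNLs).  With all domains
    present, the gene is full length when intron-free, or with at most two
    introns and no frameshift; otherwise potentially full length.  Missing
    required domains make it partial.
    """
    required = NB_ARC_CORE <= motif_ids and bool(motif_ids & LRR_MOTIFS)
    if nlr_class == "TNL":
        required = required and bool(motif_ids & TIR_MOTIFS)
    if not required:
        return "partial"
    if structure.intron_count == 0 or (
            structure.intron_count <= 2 and structure.frameshift_count == 0):
        return "full_length"
    return "potentially_full_length"
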