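"""NB-ARC phylogeny: extraction, filtering, alignment, NJ bootstrap, subgroups.

The NB-ARC nucleotide-binding module is the only region conserved enough to
align across the whole NB-LRR complement, so trees are built from it alone.
Regions carrying ambiguity characters are removed, as are regions shorter
than half the reference (median full-length) NB-ARC.  The alignment anchors
the NB-ARC motif hits into fixed column blocks and aligns the inter-anchor
segments with a progressive guide-tree aligner (mafft); distances are
Poisson-corrected mismatch proportions with pairwise gap deletion, the
topology is neighbour-joining, and supports come from column-bootstrap
replicates.  Bootstrap-supported compact clades become the subgroups used
for cluster-homogeneity calls.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .motifs import NB_ARC_MOTIFS
from .scan import DEFAULT_P_CUTOFF, MotifHit

#: canonical order of NB-ARC motifs along the domain
NB_ARC_ORDER = (1, 6, 4, 5, 10, 2, 12, 3)
AMBIGUOUS = set("XBZJUO*")


@dataclass
class NbArcRegion:
    gene_id: str
    sequence: str
    span: tuple[int, int]  # on the source protein
    fraction_of_full: float
    motif_spans: dict[int, tuple[int, int]] = field(default_factory=dict)


def extract_nbarc(
    protein: str,
    best_hits: dict[int, MotifHit],
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> NbArcRegion | None:
    """Cut the NB-ARC region: first to last significant NB-ARC motif hit."""
    hits = {m: h for m, h in best_hits.items()
            if m in NB_ARC_MOTIFS and h.p_value <= p_cutoff}
    if not hits:
        return None
    start = min(h.start for h in hits.values())
    end = max(h.end for h in hits.values())
    return NbArcRegion(
        gene_id=next(iter(hits.values())).sequence_id,
        sequence=protein[start:end],
        span=(start, end),
        fraction_of_full=1.0,  # set by extract_and_filter
        motif_spans={m: (h.start - start, h.end - start)
                     for m, h in hits.items()},
    )


def extract_and_filter(
    entries: dict[str, tuple[str, dict[int, MotifHit]]],
    full_length_ids: set[str] | None = None,
    min_fraction: float = 0.5,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> tuple[list[NbArcRegion], dict[str, str]]:
    """Extract NB-ARC regions and apply the ambiguity and length filters.

    ``entries`` maps gene id -> (protein, best hit per motif).  The reference
    NB-ARC length is the median over regions of full-length genes (all
    regions when none are flagged); regions shorter than ``min_fraction`` of
    it are excluded (boundary inclusive: exactly the threshold is retained).
    Returns the retained regions and a removal log (gene id -> reason).
    """
    removed: dict[str, str] = {}
    regions: dict[str, NbArcRegion] = {}
    for gid, (protein, best_hits) in entries.items():
        region = extract_nbarc(protein, best_hits, p_cutoff)
        if region is None:
            removed[gid] = "no NB-ARC motif hits"
            continue
        region.gene_id = gid
        if AMBIGUOUS & set(region.sequence):
            removed[gid] = "ambiguous residues in NB-ARC region"
            continue
        regions[gid] = region
    if not regions:
        return [], removed
    pool = [r for r in regions.values()
            if full_length_ids and r.gene_id in full_length_ids]
    if not pool:
        pool = list(regions.values())
    reference = float(np.median([len(r.sequence) for r in pool]))
    kept = []
    for gid, region in regions.items():
        region.fraction_of_full = len(region.sequence) / reference
        if region.fraction_of_full < min_fraction:
            removed[gid] = (f"NB-ARC fraction {region.fraction_of_full:.2f} "
                            f"< {min_fraction}")
        else:
            kept.append(region)
    return kept, removed


def _mafft(sequences: dict[str, str]) -> dict[str, str]:
    """Align a segment set with mafft (progressive, guide-tree based)."""
    nonempty = {k: v for k, v in sequences.items() if v}
    if len(nonempty) <= 1:
        width = max((len(v) for v in sequences.values()), default=0)
        return {k: v + "-" * (width - len(v)) for k, v in sequences.items()}
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "seg.fa"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in nonempty.items()))
        proc = subprocess.run(
            ["mafft", "--quiet", "--amino", "--inputorder", str(fasta)],
            capture_output=True, text=True, check=True,
        )
    aligned: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            aligned[name] = ""
        elif name is not None:
            aligned[name] += line.strip()
    width = max(len(v) for v in aligned.values())
    return {k: aligned.get(k, "").upper() + "-" * (width - len(aligned.get(k, "")))
            if k in aligned else "-" * width
            for k in sequences}


def align(regions: list[NbArcRegion]) -> dict[str, str]:
    """Motif-anchored multiple alignment of NB-ARC regions.

    NB-ARC motifs hit in every region (in canonical, strictly increasing
    positions) become fixed anchor blocks occupying identical column ranges;
    the inter-anchor segments are aligned progressively.  Without common
    anchors the whole regions are aligned progressively in one block.
    """
    if not regions:
        return {}
    if len(regions) == 1:
        return {regions[0].gene_id: regions[0].sequence}
    anchors = []
    for mid in NB_ARC_ORDER:
        if all(mid in r.motif_spans for r in regions):
            anchors.append(mid)
    for r in regions:  # anchors must be ordered and disjoint in every region
        spans = [r.motif_spans[m] for m in anchors]
        if any(b[0] < a[1] for a, b in zip(spans, spans[1:])):
            anchors = []
            break
    ids = [r.gene_id for r in regions]
    pieces: list[dict[str, str]] = []
    prev_end = {r.gene_id: 0 for r in regions}
    for mid in anchors:
        seg = {r.gene_id: r.sequence[prev_end[r.gene_id]:r.motif_spans[mid][0]]
               for r in regions}
        pieces.append(_mafft(seg))
        pieces.append({r.gene_id:
                       r.sequence[r.motif_spans[mid][0]:r.motif_spans[mid][1]]
                       for r in regions})
        prev_end = {r.gene_id: r.motif_spans[mid][1] for r in regions}
    tail = {r.gene_id: r.sequence[prev_end[r.gene_id]:] for r in regions}
    pieces.append(_mafft(tail))
    return {gid: "".join(p[gid] for p in pieces) for gid in ids}


def _alignment_matrix(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(alignment)
    width = {len(s) for s in alignment.values()}
    if len(width) != 1:
        raise ValueError("ragged alignment")
    arr = np.array([[(-1 if c in "-." or c in AMBIGUOUS else ord(c))
                     for c in alignment[i]] for i in ids], dtype=np.int16)
    return ids, arr


def distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Poisson-corrected pairwise distances with pairwise gap deletion."""
    ids, arr = _alignment_matrix(alignment)
    return DistanceMatrix(_distances_from_matrix(arr, ids), ids)


def _distances_from_matrix(arr: np.ndarray, ids: list[str]) -> np.ndarray:
    n = len(arr)
    valid = arr >= 0
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(f"no shared columns between {ids[i]!r} "
                                 f"and {ids[j]!r}")
            p = float((arr[i][shared] != arr[j][shared]).mean())
            dm[i, j] = dm[j, i] = -np.log(max(1.0 - p, 1e-6))
    return dm


@dataclass
class PhyloTree:
    tree: TreeNode  # branch lengths; internal node names hold supports
    supports: dict[frozenset, int]  # tip-name set under an internal edge -> %
    leaf_ids: list[str]

    def to_newick(self) -> str:
        import io
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def _bipartitions(tree: TreeNode, all_tips: frozenset) -> dict[frozenset, TreeNode]:
    """Canonical non-trivial bipartitions: the side excluding a fixed taxon."""
    ref = min(all_tips)
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        canonical = side if ref not in side else all_tips - side
        out[canonical] = node
    return out


def nj_bootstrap_tree(
    alignment: dict[str, str],
    replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """Neighbour-joining tree with column-bootstrap supports.

    Distances are Poisson-corrected mismatch proportions under pairwise gap
    deletion; supports are the percentage of ``replicates`` column-resampled
    trees containing each internal bipartition.  Deterministic given seed.
    """
    if len(alignment) < 4:
        raise ValueError("need >= 4 sequences for a meaningful unrooted tree")
    ids, arr = _alignment_matrix(alignment)
    tree = nj(DistanceMatrix(_distances_from_matrix(arr, ids), ids))
    # midpoint rooting: NJ's arbitrary root can fall inside a clade of
    # interest, which would hide it from rooted clade traversal
    tree = tree.root_at_midpoint()
    all_tips = frozenset(ids)
    biparts = _bipartitions(tree, all_tips)
    counts = dict.fromkeys(biparts, 0)
    rng = np.random.default_rng(seed)
    ncols = arr.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        try:
            rep = nj(DistanceMatrix(_distances_from_matrix(arr[:, cols], ids),
                                    ids))
        except ValueError:
            continue
        for bp in _bipartitions(rep, all_tips):
            if bp in counts:
                counts[bp] += 1
    supports = {}
    for bp, node in biparts.items():
        sup = round(100 * counts[bp] / replicates)
        supports[bp] = sup
        node.name = str(sup)
    return PhyloTree(tree=tree, supports=supports, leaf_ids=ids)


@dataclass
class SubgroupAssignment:
    labels: dict[str, str | None]  # gene id -> subgroup label or None
    subgroups: dict[str, dict]  # label -> {support, diameter, members}
    patristic: DistanceMatrix


def detect_subgroups(
    phylo: PhyloTree,
    min_support: int = 70,
    max_diameter: float = 0.4,
) -> SubgroupAssignment:
    """Greedy root-down detection of supported, compact clades.

    A clade qualifies when its bipartition support is at least ``min_support``
    and its maximum within-clade patristic distance (diameter) is at most
    ``max_diameter``; descent stops at the first qualifying (maximal) clade.
    Leaves outside every qualifying clade get None.
    """
    patristic = phylo.tree.tip_tip_distances()
    all_tips = frozenset(phylo.leaf_ids)
    ref = min(all_tips)
    labels: dict[str, str | None] = dict.fromkeys(phylo.leaf_ids)
    subgroups: dict[str, dict] = {}

    def diameter(tips: list[str]) -> float:
        if len(tips) < 2:
            return 0.0
        idx = [patristic.index(t) for t in tips]
        sub = patristic.data[np.ix_(idx, idx)]
        return float(sub.max())

    def walk(node):
        if node.is_tip():
            return
        tips = [t.name for t in node.tips()]
        side = frozenset(tips)
        canonical = side if ref not in side else all_tips - side
        sup = phylo.supports.get(canonical)
        if (sup is not None and len(tips) >= 2
                and sup >= min_support and diameter(tips) <= max_diameter):
            label = f"SG{len(subgroups) + 1}"
            subgroups[label] = {"support": sup, "diameter": diameter(tips),
                                "members": sorted(tips)}
            for t in tips:
                labels[t] = label
            return
        for child in node.children:
            walk(child)

    for child in phylo.tree.children:
        walk(child)
    return SubgroupAssignment(labels=labels, subgroups=subgroups,
                              patristic=patristic)
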