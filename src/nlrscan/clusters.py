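"""Physical clustering of NB-LRR genes on pseudomolecules.

Genes are projected from superscaffolds to pseudomolecule coordinates through
a placement table (offset + orientation; minus-oriented scaffolds reverse
intra-scaffold coordinates).  Two neighbouring NB-LRRs chain into one cluster
when their nearest-end distance is under 200 kb AND fewer than eight
annotated non-NB-LRR genes lie strictly between them; singletons are not
clusters.  A cluster is homogeneous when all members share one phylogenetic
subgroup (with a patristic-distance fallback for members absent from the
tree), heterogeneous otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genomeio import GeneModel


@dataclass
class GenePlacement:
    gene_id: str
    pseudomolecule_id: str
    start: int  # bp on the pseudomolecule, 0-based half-open
    end: int
    strand: str
    is_nlr: bool = False


def project(
    gene: GeneModel,
    placements: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    is_nlr: bool = False,
) -> GenePlacement | None:
    """Project a gene to pseudomolecule coordinates; None when unplaced."""
    rows = placements[placements["scaffold_id"] == gene.scaffold_id]
    if len(rows) > 1:
        raise ValueError(f"scaffold {gene.scaffold_id} placed twice")
    if len(rows) == 0:
        return None
    row = rows.iloc[0]
    offset = int(row["offset"])
    if row["orientation"] == "+":
        start, end = offset + gene.start, offset + gene.end
        strand = gene.strand
    else:
        length = scaffold_lengths[gene.scaffold_id]
        start = offset + length - gene.end
        end = offset + length - gene.start
        strand = "-" if gene.strand == "+" else "+"
    return GenePlacement(gene.gene_id, str(row["pseudomolecule_id"]),
                         start, end, strand, is_nlr)


@dataclass
class Cluster:
    cluster_id: str
    pseudomolecule_id: str
    members: list[str]  # gene ids ordered by position
    span: tuple[int, int]
    homogeneity: str | None = None  # homogeneous | heterogeneous


def _intervening(a: GenePlacement, b: GenePlacement,
                 others: list[GenePlacement]) -> int:
    lo, hi = a.end, b.start
    return sum(1 for g in others if g.start >= lo and g.end <= hi)


def chainable(a: GenePlacement, b: GenePlacement,
              non_nlr: list[GenePlacement],
              max_gap: int = 200_000, max_intervening: int = 8) -> bool:
    """Dual adjacency rule for two consecutive NB-LRRs (a upstream of b)."""
    if a.pseudomolecule_id != b.pseudomolecule_id:
        return False
    gap = b.start - a.end  # nearest-end distance
    if gap >= max_gap:
        return False
    return _intervening(a, b, non_nlr) < max_intervening


def find_clusters(
    nlr: list[GenePlacement],
    all_genes: list[GenePlacement],
    max_gap: int = 200_000,
    max_intervening: int = 8,
) -> list[Cluster]:
    """Chain consecutive NB-LRRs into clusters, ids in genome order (C1...)."""
    non_nlr_by_pm: dict[str, list[GenePlacement]] = {}
    nlr_ids = {g.gene_id for g in nlr}
    for g in all_genes:
        if g.gene_id not in nlr_ids:
            non_nlr_by_pm.setdefault(g.pseudomolecule_id, []).append(g)
    clusters: list[Cluster] = []
    by_pm: dict[str, list[GenePlacement]] = {}
    for g in nlr:
        by_pm.setdefault(g.pseudomolecule_id, []).append(g)
    for pm in sorted(by_pm):
        genes = sorted(by_pm[pm], key=lambda g: (g.start, g.gene_id))
        others = non_nlr_by_pm.get(pm, [])
        chain = [genes[0]] if genes else []
        for prev, cur in zip(genes, genes[1:]):
            if chainable(prev, cur, others, max_gap, max_intervening):
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    clusters.append(_close(chain, pm, len(clusters) + 1))
                chain = [cur]
        if len(chain) >= 2:
            clusters.append(_close(chain, pm, len(clusters) + 1))
    return clusters


def _close(chain: list[GenePlacement], pm: str, number: int) -> Cluster:
    return Cluster(
        cluster_id=f"C{number}",
        pseudomolecule_id=pm,
        members=[g.gene_id for g in chain],
        span=(chain[0].start, chain[-1].end),
    )


def label_homogeneity(
    cluster: Cluster,
    subgroup_labels: dict[str, str | None],
    patristic=None,
    fallback_max_dist: float = 0.8,
) -> str:
    """Homogeneous iff all members share one subgroup label.

    Members without a label (absent from the tree or unassigned) fall back to
    pairwise patristic distances: homogeneous iff every available pairwise
    distance is at most ``fallback_max_dist``.
    """
    labels = [subgroup_labels.get(m) for m in cluster.members]
    if all(lb is not None for lb in labels):
        return "homogeneous" if len(set(labels)) == 1 else "heterogeneous"
    if patristic is None:
        return "heterogeneous"
    in_tree = [m for m in cluster.members if m in patristic.ids]
    for i, a in enumerate(in_tree):
        for b in in_tree[i + 1:]:
            if patristic[a, b] > fallback_max_dist:
                return "heterogeneous"
    return "homogeneous"


def chromosome_summary(
    placements: list[GenePlacement],
    clusters: list[Cluster],
    classes: dict[str, str],
) -> pd.DataFrame:
    """Per-pseudomolecule TNL/CNL x clustered/unclustered counts.

    Counts partition the mapped NB-LRR set; row sums equal the mapped count
    per pseudomolecule.
    """
    clustered = {m for c in clusters for m in c.members}
    rows = {}
    for g in placements:
        if not g.is_nlr:
            continue
        row = rows.setdefault(g.pseudomolecule_id, {
            "TNL_clustered": 0, "TNL_unclustered": 0,
            "CNL_clustered": 0, "CNL_unclustered": 0,
            "other_clustered": 0, "other_unclustered": 0,
        })
        cls = classes.get(g.gene_id, "other")
        key = cls if cls in ("TNL", "CNL") else "other"
        key += "_clustered" if g.gene_id in clustered else "_unclustered"
        row[key] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "pseudomolecule_id"
    if len(df):
        df["total"] = df.sum(axis=1)
    return df
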