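"""Pseudomolecule projection, cluster chaining, homogeneity, summaries."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from nlrscan.clusters import (
    Cluster,
    GenePlacement,
    chromosome_summary,
    find_clusters,
    label_homogeneity,
    project,
)
from nlrscan.genomeio import GeneModel

PLACEMENTS = pd.DataFrame({
    "scaffold_id": ["s1", "s2"],
    "pseudomolecule_id": ["chr1", "chr1"],
    "offset": [1_000_000, 2_000_000],
    "orientation": ["+", "-"],
})
LENGTHS = {"s1": 10_000, "s2": 10_000}


class TestProject:
    def test_plus_orientation_adds_offset(self):
        g = GeneModel("g", "s1", "+", 100, 400)
        pl = project(g, PLACEMENTS, LENGTHS)
        assert (pl.start, pl.end, pl.strand) == (1_000_100, 1_000_400, "+")
        assert pl.pseudomolecule_id == "chr1"

    def test_minus_orientation_reverses_coordinates(self):
        g = GeneModel("g", "s2", "+", 100, 400)
        pl = project(g, PLACEMENTS, LENGTHS)
        assert (pl.start, pl.end) == (2_009_600, 2_009_900)
        assert pl.strand == "-"

    def test_unplaced_scaffold_is_unmapped(self):
        g = GeneModel("g", "s3", "+", 100, 400)
        assert project(g, PLACEMENTS, LENGTHS) is None

    def test_duplicate_placement_rejected(self):
        dup = pd.concat([PLACEMENTS, PLACEMENTS.iloc[[0]]])
        g = GeneModel("g", "s1", "+", 100, 400)
        with pytest.raises(ValueError, match="twice"):
            project(g, dup, LENGTHS)


def nlr(gid, start, end, pm="chr1"):
    return GenePlacement(gid, pm, start, end, "+", is_nlr=True)


def bg(gid, start, end, pm="chr1"):
    return GenePlacement(gid, pm, start, end, "+", is_nlr=False)


class TestFindClusters:
    def test_close_pair_with_few_intervening_forms_a_cluster(self):
        nlrs = [nlr("n1", 0, 1000), nlr("n2", 151_000, 152_000)]
        others = [bg(f"b{i}", 20_000 + 10_000 * i, 21_000 + 10_000 * i)
                  for i in range(3)]
        clusters = find_clusters(nlrs, nlrs + others)
        assert len(clusters) == 1
        assert clusters[0].members == ["n1", "n2"]

    def test_exactly_200kb_apart_stays_separate(self):
        nlrs = [nlr("n1", 0, 1000), nlr("n2", 201_000, 202_000)]
        assert find_clusters(nlrs, nlrs) == []
        nlrs2 = [nlr("n1", 0, 1000), nlr("n2", 200_999, 202_000)]
        assert len(find_clusters(nlrs2, nlrs2)) == 1

    def test_eight_intervening_genes_stay_separate(self):
        nlrs = [nlr("n1", 0, 1000), nlr("n2", 51_000, 52_000)]
        others = [bg(f"b{i}", 2_000 + 5_000 * i, 3_000 + 5_000 * i)
                  for i in range(8)]
        assert find_clusters(nlrs, nlrs + others) == []
        assert len(find_clusters(nlrs, nlrs + others[:7])) == 1

    def test_singletons_are_not_clusters(self):
        nlrs = [nlr("n1", 0, 1000), nlr("n2", 500_000, 501_000)]
        assert find_clusters(nlrs, nlrs) == []

    def test_cluster_ids_in_genome_order(self):
        nlrs = [nlr("a1", 0, 1000), nlr("a2", 10_000, 11_000),
                nlr("b1", 900_000, 901_000), nlr("b2", 910_000, 911_000)]
        clusters = find_clusters(nlrs, nlrs)
        assert [c.cluster_id for c in clusters] == ["C1", "C2"]
        assert clusters[0].members == ["a1", "a2"]

    def _brute_force(self, nlrs, all_genes, max_gap=200_000,
                     max_intervening=8):
        """O(n^2) oracle: chain consecutive NB-LRRs by both rules."""
        by_pm = {}
        for g in sorted(nlrs, key=lambda g: (g.pseudomolecule_id, g.start)):
            by_pm.setdefault(g.pseudomolecule_id, []).append(g)
        nlr_ids = {g.gene_id for g in nlrs}
        clusters = []
        for pm, genes in sorted(by_pm.items()):
            others = [g for g in all_genes
                      if g.pseudomolecule_id == pm and g.gene_id not in nlr_ids]
            current = [genes[0]]
            for prev, cur in zip(genes, genes[1:]):
                between = sum(1 for o in others
                              if o.start >= prev.end and o.end <= cur.start)
                if (cur.start - prev.end < max_gap
                        and between < max_intervening):
                    current.append(cur)
                else:
                    if len(current) > 1:
                        clusters.append([g.gene_id for g in current])
                    current = [cur]
            if len(current) > 1:
                clusters.append([g.gene_id for g in current])
        return clusters

    @pytest.mark.parametrize("seed", range(4))
    def test_chaining_matches_brute_force_on_random_pseudomolecules(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for pm in ("chr1", "chr2"):
            starts = np.sort(rng.choice(5_000_000, size=100, replace=False))
            for i, s in enumerate(starts):
                gid = f"{pm}g{i}"
                is_nlr = rng.random() < 0.25
                genes.append(GenePlacement(gid, pm, int(s), int(s) + 1000,
                                           "+", is_nlr))
        nlrs = [g for g in genes if g.is_nlr]
        got = [c.members for c in find_clusters(nlrs, genes)]
        assert got == self._brute_force(nlrs, genes)

    def test_member_conservation(self):
        rng = np.random.default_rng(9)
        starts = np.sort(rng.choice(3_000_000, size=60, replace=False))
        nlrs = [nlr(f"n{i}", int(s), int(s) + 500)
                for i, s in enumerate(starts)]
        clusters = find_clusters(nlrs, nlrs)
        clustered = [m for c in clusters for m in c.members]
        assert len(clustered) == len(set(clustered))
        assert set(clustered) <= {g.gene_id for g in nlrs}


class TestHomogeneity:
    def _cluster(self, members):
        return Cluster("C1", "chr1", members, (0, 1000))

    def test_single_subgroup_is_homogeneous(self):
        labels = {"a": "SG1", "b": "SG1", "c": "SG1"}
        assert label_homogeneity(self._cluster(["a", "b", "c"]),
                                 labels) == "homogeneous"

    def test_two_subgroups_are_heterogeneous(self):
        labels = {"a": "SG1", "b": "SG2"}
        assert label_homogeneity(self._cluster(["a", "b"]),
                                 labels) == "heterogeneous"

    def test_unassigned_member_falls_back_to_patristic_distance(self):
        labels = {"a": "SG1", "b": "SG1", "c": None}
        close = DistanceMatrix(np.array([[0, .1, .2], [.1, 0, .15],
                                         [.2, .15, 0]]), ["a", "b", "c"])
        assert label_homogeneity(self._cluster(["a", "b", "c"]), labels,
                                 close, 0.4) == "homogeneous"
        far = DistanceMatrix(np.array([[0, .1, 2.], [.1, 0, 2.],
                                       [2., 2., 0]]), ["a", "b", "c"])
        assert label_homogeneity(self._cluster(["a", "b", "c"]), labels,
                                 far, 0.4) == "heterogeneous"


class TestChromosomeSummary:
    def _placements(self):
        out = []
        for i in range(6):
            out.append(GenePlacement(f"n{i}", "chr1" if i < 4 else "chr2",
                                     i * 10_000, i * 10_000 + 500, "+", True))
        return out

    def test_counts_partition_the_mapped_set(self):
        placements = self._placements()
        clusters = [Cluster("C1", "chr1", ["n0", "n1"], (0, 10_500))]
        classes = {f"n{i}": ("TNL" if i % 2 else "CNL") for i in range(6)}
        df = chromosome_summary(placements, clusters, classes)
        assert int(df["total"].sum()) == 6
        clustered_cols = [c for c in df.columns if c.endswith("_clustered")]
        assert int(df.loc["chr1", clustered_cols].sum()) == 2

    def test_summary_matches_brute_force_recount(self):
        placements = self._placements()
        clusters = [Cluster("C1", "chr1", ["n0", "n1"], (0, 10_500))]
        classes = dict.fromkeys([p.gene_id for p in placements], "CNL")
        df = chromosome_summary(placements, clusters, classes)
        clustered = {m for c in clusters for m in c.members}
        for pm in ("chr1", "chr2"):
            expect = sum(1 for p in placements
                         if p.pseudomolecule_id == pm
                         and p.gene_id in clustered)
            assert int(df.loc[pm, "CNL_clustered"]) == expect
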