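"""NB-ARC extraction/filtering, anchored alignment, NJ bootstrap, subgroups."""

import io
import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from nlrscan.phylogeny import (
    NbArcRegion,
    PhyloTree,
    align,
    detect_subgroups,
    distance_matrix,
    extract_and_filter,
    nj_bootstrap_tree,
)
from nlrscan.scan import MotifHit


def entry(protein, spans):
    """(protein, best hits) with NB-ARC motif spans given as {mid: (s, e)}."""
    hits = {mid: MotifHit(mid, "g", s, e, "none", 50.0, 1e-12)
            for mid, (s, e) in spans.items()}
    return protein, hits


class TestExtractAndFilter:
    def _entries(self):
        # three full-length regions (100 aa) plus two short ones
        out = {}
        for i, gid in enumerate(("f1", "f2", "f3")):
            out[gid] = entry("K" * 120, {1: (0, 10), 3: (90, 100)})
        out["half"] = entry("K" * 60, {1: (0, 10), 3: (40, 50)})
        out["short"] = entry("K" * 60, {1: (0, 10), 3: (39, 49)})
        return out

    def test_fraction_boundary_is_inclusive(self):
        regions, removed = extract_and_filter(
            self._entries(), full_length_ids={"f1", "f2", "f3"})
        kept = {r.gene_id for r in regions}
        assert "half" in kept  # exactly 50% of the 100-aa reference
        assert removed["short"].startswith("NB-ARC fraction 0.49")

    def test_ambiguous_region_removed(self):
        entries = {"amb": entry("K" * 40 + "X" + "K" * 80,
                                {1: (0, 10), 3: (90, 100)}),
                   "ok": entry("K" * 120, {1: (0, 10), 3: (90, 100)})}
        regions, removed = extract_and_filter(entries)
        assert [r.gene_id for r in regions] == ["ok"]
        assert "ambiguous" in removed["amb"]

    def test_gene_without_nbarc_hits_excluded_with_reason(self):
        entries = {"none": entry("K" * 100, {9: (0, 10)}),
                   "ok": entry("K" * 120, {1: (0, 10), 3: (90, 100)})}
        regions, removed = extract_and_filter(entries)
        assert [r.gene_id for r in regions] == ["ok"]
        assert removed["none"] == "no NB-ARC motif hits"

    def test_full_length_region_has_fraction_one(self):
        regions, _ = extract_and_filter(
            {"f": entry("K" * 120, {1: (0, 10), 3: (90, 100)})})
        assert regions[0].fraction_of_full == pytest.approx(1.0)
        assert regions[0].span == (0, 100)


def region(gid, sequence, spans):
    return NbArcRegion(gene_id=gid, sequence=sequence, span=(0, len(sequence)),
                       fraction_of_full=1.0, motif_spans=spans)


class TestAlign:
    ANCHOR1 = "PIWGMGGVGK"
    ANCHOR2 = "CGGLPLAIKV"

    def _region(self, gid, middle):
        seq = self.ANCHOR1 + middle + self.ANCHOR2
        return region(gid, seq, {1: (0, 10),
                                 3: (10 + len(middle), 20 + len(middle))})

    def test_identical_sequences_align_without_gaps(self):
        aligned = align([self._region("a", "KLMNP"),
                         self._region("b", "KLMNP")])
        assert aligned["a"] == aligned["b"]
        assert "-" not in aligned["a"]

    def test_three_residue_insertion_gives_one_gap_block(self):
        aligned = align([self._region("a", "KLMNPQRST"),
                         self._region("b", "KLMNEEEPQRST")])
        assert aligned["a"].count("-") == 3
        assert "---" in aligned["a"]
        assert "-" not in aligned["b"]

    def test_anchor_motifs_occupy_identical_columns(self):
        regions = [self._region(g, m) for g, m in
                   [("a", "KLMNP"), ("b", "KLMNP"), ("c", "QRSTV")]]
        aligned = align(regions)
        for gid in ("a", "b", "c"):
            assert aligned[gid][:10] == self.ANCHOR1
            assert aligned[gid][-10:] == self.ANCHOR2

    def test_single_region_aligns_trivially(self):
        r = self._region("only", "KLMNP")
        assert align([r]) == {"only": r.sequence}


def _evolved_quartet(rng, n=240):
    """Four sequences with block-disjoint mutations: ((A,B),(C,D))."""
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    root = rng.choice(alphabet, size=n)
    blocks = np.array_split(np.arange(n), 5)  # edges: A, B, C, D, internal
    counts = rng.integers(6, 18, size=5)
    seqs = {}
    left = root.copy()
    right = root.copy()
    for i in blocks[4][:counts[4]]:
        right[i] = "W" if right[i] != "W" else "Y"
    for name, base, block, cnt in (("A", left, blocks[0], counts[0]),
                                   ("B", left, blocks[1], counts[1]),
                                   ("C", right, blocks[2], counts[2]),
                                   ("D", right, blocks[3], counts[3])):
        s = base.copy()
        for i in block[:cnt]:
            s[i] = "F" if s[i] != "F" else "H"
        seqs[name] = "".join(s)
    return seqs


def _least_squares_topology(dm):
    """Oracle: exhaustive least-squares fit of the three 4-taxon topologies."""
    ids = list(dm.ids)
    pairs = list(itertools.combinations(range(4), 2))
    best = None
    for split in ([(0, 1), (2, 3)], [(0, 2), (1, 3)], [(0, 3), (1, 2)]):
        # edges: 4 terminal + 1 internal; path indicator design matrix
        design = []
        for i, j in pairs:
            row = [0.0] * 5
            row[i] = row[j] = 1.0
            same = any(set((i, j)) == set(s) for s in split)
            row[4] = 0.0 if same else 1.0
            design.append(row)
        y = np.array([dm[ids[i], ids[j]] for i, j in pairs])
        coef, *_ = np.linalg.lstsq(np.array(design), y, rcond=None)
        sse = float(((np.array(design) @ coef - y) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, split)
    (i, j), _ = best[1]
    return frozenset({ids[i], ids[j]})


class TestNjBootstrap:
    @pytest.mark.parametrize("seed", range(8))
    def test_nj_matches_least_squares_oracle_on_quartets(self, seed):
        rng = np.random.default_rng(seed)
        seqs = _evolved_quartet(rng)
        dm = distance_matrix(seqs)
        oracle_pair = _least_squares_topology(dm)
        phylo = nj_bootstrap_tree(seqs, replicates=10, seed=0)
        ref = min(phylo.leaf_ids)
        tips = frozenset(phylo.leaf_ids)
        splits = set(phylo.supports)
        canonical = oracle_pair if ref not in oracle_pair else tips - oracle_pair
        assert canonical in splits

    def test_identical_sequences_group_with_zero_distance(self):
        seqs = {"a": "KLMNPKLMNP", "b": "KLMNPKLMNP",
                "c": "WWWNPKLYYP", "d": "WWFNPKLYYF"}
        phylo = nj_bootstrap_tree(seqs, replicates=10, seed=0)
        pat = phylo.tree.tip_tip_distances()
        assert pat["a", "b"] == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_gives_identical_supports(self):
        rng = np.random.default_rng(3)
        seqs = _evolved_quartet(rng)
        t1 = nj_bootstrap_tree(seqs, replicates=25, seed=7)
        t2 = nj_bootstrap_tree(seqs, replicates=25, seed=7)
        assert t1.supports == t2.supports
        assert t1.to_newick() == t2.to_newick()

    def test_disjoint_columns_raise_naming_the_pair(self):
        with pytest.raises(ValueError, match="'a'.*'b'"):
            distance_matrix({"a": "KL--", "b": "--MN",
                             "c": "KLMN", "d": "KLMN"})

    def test_fewer_than_four_sequences_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            nj_bootstrap_tree({"a": "KL", "b": "KL", "c": "KM"})


def _hand_tree(newick, supports):
    tree = TreeNode.read(io.StringIO(newick))
    leaf_ids = [t.name for t in tree.tips()]
    return PhyloTree(tree=tree, supports=supports, leaf_ids=leaf_ids)


class TestDetectSubgroups:
    NEWICK = ("(((a:0.01,b:0.01):0.01,c:0.02):0.5,"
              "((d:0.01,e:0.01):0.5,f:0.6):0.1);")

    def _supports(self, abc=95, ab=99, de=95):
        tips = frozenset("abcdef")
        def canon(side):
            side = frozenset(side)
            return side if "a" not in side else tips - side
        return {canon("ab"): ab, canon("abc"): abc, canon("de"): de}

    def test_supported_compact_clade_is_a_subgroup(self):
        phylo = _hand_tree(self.NEWICK, self._supports())
        sg = detect_subgroups(phylo, min_support=70, max_diameter=0.4)
        assert sg.labels["d"] == sg.labels["e"] is not None

    def test_low_support_clade_is_not_a_subgroup_even_if_compact(self):
        phylo = _hand_tree(self.NEWICK, self._supports(de=60))
        sg = detect_subgroups(phylo, min_support=70, max_diameter=0.4)
        assert sg.labels["d"] is None and sg.labels["e"] is None

    def test_nested_qualifying_clades_report_only_the_maximal(self):
        phylo = _hand_tree(self.NEWICK, self._supports())
        sg = detect_subgroups(phylo, min_support=70, max_diameter=0.4)
        label = sg.labels["a"]
        assert label is not None
        assert sg.labels["b"] == sg.labels["c"] == label
        assert sorted(sg.subgroups[label]["members"]) == ["a", "b", "c"]

    def test_diameter_bound_forces_descent_to_inner_clade(self):
        wide = ("(((a:0.01,b:0.01):0.01,c:0.30):0.5,"
                "((d:0.01,e:0.01):0.5,f:0.6):0.1);")
        phylo = _hand_tree(wide, self._supports())
        sg = detect_subgroups(phylo, min_support=70, max_diameter=0.1)
        assert sg.labels["a"] == sg.labels["b"] is not None
        assert sg.labels["c"] is None

    def test_subgroups_are_disjoint(self):
        phylo = _hand_tree(self.NEWICK, self._supports())
        sg = detect_subgroups(phylo, min_support=70, max_diameter=0.4)
        seen = {}
        for label, info in sg.subgroups.items():
            for m in info["members"]:
                assert m not in seen
                seen[m] = label
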