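"""Flank extension, six-frame re-scan, split/merge, structure, completeness."""

import numpy as np
import pytest
from Bio.Seq import Seq

from nlrscan.genomeio import GeneModel
from nlrscan.reannotation import (
    ExtendedRegion,
    StructureCall,
    build_protein,
    call_structure,
    completeness,
    extend,
    merge_adjacent,
    partition_signatures,
    rescan_six_frames,
    translate_frames,
)
from nlrscan.scan import MotifHit, scan
from nlrscan.simulate import _CODONS


def mk_hit(motif_id, dna_start, length_aa=20, frame="+0", p=1e-12):
    k = int(frame[1])
    aa_start = (dna_start - k) // 3
    return MotifHit(motif_id=motif_id, sequence_id="g", start=aa_start,
                    end=aa_start + length_aa, frame=frame, score=100.0,
                    p_value=p, dna_start=dna_start,
                    dna_end=dna_start + 3 * length_aa)


def mk_series(motif_ids, frame="+0", start=0, step=120):
    return [mk_hit(m, start + i * step, frame=frame)
            for i, m in enumerate(motif_ids)]


class TestExtend:
    def test_basic_extension_arithmetic(self):
        gene = GeneModel("g", "s", "+", 5000, 8000)
        region = extend(gene, "A" * 100_000, flank=3000)
        assert (region.region_start, region.region_end) == (2000, 11000)
        assert region.offset == -3000

    def test_left_clipping(self):
        gene = GeneModel("g", "s", "+", 1000, 4000)
        region = extend(gene, "A" * 100_000, flank=3000)
        assert (region.region_start, region.region_end) == (0, 7000)

    def test_back_projection_of_region_hit(self):
        gene = GeneModel("g", "s", "+", 5000, 8000)
        region = extend(gene, "A" * 100_000, flank=3000)
        assert region.to_scaffold(3120) == 5120

    def test_gene_outside_scaffold_rejected(self):
        gene = GeneModel("g", "s", "+", 50, 200)
        with pytest.raises(ValueError, match="outside"):
            extend(gene, "A" * 100)

    def test_extension_is_clipped_idempotently(self):
        gene = GeneModel("g", "s", "+", 100, 900)
        scaffold = "A" * 1000
        region = extend(gene, scaffold, flank=3000)
        assert (region.region_start, region.region_end) == (0, 1000)
        again = extend(GeneModel("g", "s", "+", region.region_start + 1,
                                 region.region_end), scaffold, flank=3000)
        assert (again.region_start, again.region_end) == (0, 1000)


class TestSixFrameRescan:
    def test_planted_reverse_complement_motif_found_on_minus_frame(
            self, motifs, models):
        rng = np.random.default_rng(0)
        cds = "".join(_CODONS[aa] for aa in motifs[3].consensus)
        bases = "".join(rng.choice(list("ACGT"), size=2000))
        planted_at = 601  # frame offset 1 relative to the region
        dna = (bases[:planted_at]
               + str(Seq(cds).reverse_complement())
               + bases[planted_at + len(cds):])
        region = ExtendedRegion("g", "s", 0, len(dna), dna, 0)
        hits, _ = rescan_six_frames(region, {3: models[3]})
        best = [h for h in hits if h.best and h.score == models[3].max_score]
        assert len(best) == 1
        assert best[0].frame.startswith("-")
        assert (best[0].dna_start, best[0].dna_end) == (
            planted_at, planted_at + len(cds))

    def test_rescan_is_deterministic(self, models):
        rng = np.random.default_rng(1)
        dna = "".join(rng.choice(list("ACGT"), size=1500))
        region = ExtendedRegion("g", "s", 0, len(dna), dna, 0)
        h1, _ = rescan_six_frames(region, models, p_cutoff=1e-3)
        h2, _ = rescan_six_frames(region, models, p_cutoff=1e-3)
        assert [(h.motif_id, h.frame, h.dna_start, h.score) for h in h1] == \
            [(h.motif_id, h.frame, h.dna_start, h.score) for h in h2]

    def test_frame_hits_agree_with_protein_space_oracle(self, models):
        rng = np.random.default_rng(2)
        dna = "".join(rng.choice(list("ACGT"), size=1200))
        region = ExtendedRegion("g", "s", 0, len(dna), dna, 0)
        hits, translations = rescan_six_frames(region, models, p_cutoff=1e-3)
        by_frame = {}
        for frame, protein in translations.items():
            for mid, model in models.items():
                for h in scan(protein, model, "g", 1e-3, frame=frame):
                    by_frame.setdefault(frame, []).append(
                        (mid, h.start, h.end, h.score))
        got = {}
        for h in hits:
            got.setdefault(h.frame, []).append(
                (h.motif_id, h.start, h.end, h.score))
        for frame in translations:
            assert sorted(got.get(frame, [])) == \
                sorted(by_frame.get(frame, []))

    def test_n_runs_translate_to_x(self):
        frames = translate_frames("ATGNNNAAA")
        assert frames["+0"] == "MXK"


class TestPartitionSignatures:
    def test_double_series_splits_into_two_groups(self):
        series = mk_series([18, 1, 4, 3, 9]) + mk_series([18, 1, 4, 3, 9],
                                                         start=1200)
        groups = partition_signatures(series)
        assert len(groups) == 2
        assert [h.motif_id for h in groups[0]] == [18, 1, 4, 3, 9]
        assert [h.motif_id for h in groups[1]] == [18, 1, 4, 3, 9]

    def test_single_series_stays_whole(self):
        groups = partition_signatures(mk_series([18, 1, 4, 3, 9]))
        assert len(groups) == 1

    def test_two_ploops_with_single_tail_do_not_split(self):
        groups = partition_signatures(mk_series([1, 4, 5, 1, 3, 7, 9]))
        assert len(groups) == 1

    def test_split_works_on_minus_strand(self):
        series = (mk_series([18, 1, 4, 3, 9], frame="-0", start=1800,
                            step=-120)
                  + mk_series([18, 1, 4, 3, 9], frame="-0", start=700,
                              step=-120))
        groups = partition_signatures(series)
        assert len(groups) == 2


class TestMergeAdjacent:
    def _genes(self, gap=500, scaffold_b="s1", strand_b="+"):
        a = GeneModel("ga", "s1", "+", 0, 1000)
        b = GeneModel("gb", scaffold_b, strand_b, 1000 + gap, 2400 + gap)
        return a, b

    def test_complementary_prefix_suffix_merges(self):
        a, b = self._genes()
        merged = merge_adjacent((a, mk_series([17, 1, 4, 5])),
                                (b, mk_series([3, 7, 9, 11])))
        assert merged is not None
        assert merged.gene_id == "ga_gb"
        assert (merged.start, merged.end) == (0, 2900)

    def test_duplicated_series_start_does_not_merge(self):
        a, b = self._genes()
        assert merge_adjacent(
            (a, mk_series([17, 1, 4, 5, 3, 7, 9])),
            (b, mk_series([17, 1, 4, 5]))) is None

    def test_order_violation_does_not_merge(self):
        a, b = self._genes()
        assert merge_adjacent((a, mk_series([9, 11])),
                              (b, mk_series([17, 1, 4, 5]))) is None

    def test_different_scaffold_or_strand_does_not_merge(self):
        a, b = self._genes(scaffold_b="s2")
        assert merge_adjacent((a, mk_series([17, 1, 4, 5])),
                              (b, mk_series([3, 7, 9]))) is None
        a, b = self._genes(strand_b="-")
        assert merge_adjacent((a, mk_series([17, 1, 4, 5])),
                              (b, mk_series([3, 7, 9]))) is None

    def test_gap_beyond_limit_does_not_merge(self):
        a, b = self._genes(gap=20_000)
        assert merge_adjacent((a, mk_series([17, 1, 4, 5])),
                              (b, mk_series([3, 7, 9]))) is None


class TestCallStructure:
    def test_single_frame_without_stops_is_intact(self):
        translations = {"+0": "A" * 2000}
        structure = call_structure(mk_series([17, 1, 4, 5, 3, 9]),
                                   translations, orf_filter=False)
        assert (structure.intron_count, structure.frameshift_count) == (0, 0)
        assert len(structure.cds_segments) == 1

    def test_frame_change_with_long_gap_is_an_intron(self):
        h1 = mk_hit(1, 30, frame="+0")
        h2 = mk_hit(4, h1.dna_end + 300, frame="+2")
        structure = call_structure([h1, h2], {"+0": "A" * 500, "+2": "A" * 500},
                                   orf_filter=False)
        assert (structure.intron_count, structure.frameshift_count) == (1, 0)

    def test_frame_change_with_short_gap_is_a_frameshift(self):
        h1 = mk_hit(1, 30, frame="+0")
        h2 = mk_hit(4, h1.dna_end + 6, frame="+1")
        structure = call_structure([h1, h2], {"+0": "A" * 500, "+1": "A" * 500},
                                   orf_filter=False)
        assert (structure.intron_count, structure.frameshift_count) == (0, 1)

    def test_in_frame_stop_between_hits_is_a_frameshift(self):
        h1 = mk_hit(1, 0, length_aa=10, frame="+0")
        h2 = mk_hit(4, 60, length_aa=10, frame="+0")
        trans = "A" * 12 + "*" + "A" * 500
        structure = call_structure([h1, h2], {"+0": trans}, orf_filter=False)
        assert structure.frameshift_count == 1

    def test_coding_length_sums_segments(self):
        structure = call_structure(mk_series([1, 4, 5]), {"+0": "A" * 500},
                                   orf_filter=False)
        assert structure.coding_length == sum(
            e - s for _f, _a, _b, s, e in structure.cds_segments)


class TestBuildProtein:
    def test_orf_extension_to_bounding_stops(self):
        # hits cover aa 20..40; stops at aa 5 and 60
        trans = "L" * 5 + "*" + "M" + "K" * 54 + "*" + "Y" * 20
        structure = StructureCall(0, 0, [("+0", 20, 40, 60, 120)], 60)
        protein = build_protein(structure, {"+0": trans})
        assert protein == trans[6:61].replace("*", "")
        assert len(protein) == 55

    def test_aa_bounds_limit_extension(self):
        trans = "K" * 200
        structure = StructureCall(0, 0, [("+0", 50, 80, 150, 240)], 90)
        protein = build_protein(structure, {"+0": trans}, aa_min=40, aa_max=100)
        assert protein == "K" * 60


class TestCompleteness:
    FULL = {17, 16, 1, 4, 5, 10, 3, 9}

    def _structure(self, introns, frameshifts):
        return StructureCall(introns, frameshifts, [("+0", 0, 10, 0, 30)], 30)

    def test_all_domains_intact_is_full_length(self):
        assert completeness(self.FULL, self._structure(0, 0), "CNL") == \
            "full_length"

    def test_two_introns_without_frameshift_is_full_length(self):
        assert completeness(self.FULL, self._structure(2, 0), "CNL") == \
            "full_length"

    def test_three_introns_is_potentially_full_length(self):
        assert completeness(self.FULL, self._structure(3, 0), "CNL") == \
            "potentially_full_length"

    def test_intron_with_frameshift_is_potentially_full_length(self):
        assert completeness(self.FULL, self._structure(1, 1), "CNL") == \
            "potentially_full_length"

    def test_missing_lrr_is_partial(self):
        assert completeness(self.FULL - {9}, self._structure(0, 0), "CNL") == \
            "partial"

    def test_tnl_requires_a_tir_motif(self):
        motifs = {18, 1, 4, 5, 10, 3, 9}
        assert completeness(motifs, self._structure(0, 0), "TNL") == \
            "full_length"
        assert completeness(motifs - {18}, self._structure(0, 0), "TNL") == \
            "partial"

    def test_cnl_does_not_require_n_terminal_motifs(self):
        motifs = {1, 4, 5, 10, 3, 9}  # the CC-less NB-LRR subtype
        assert completeness(motifs, self._structure(0, 0), "CNL") == \
            "full_length"
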