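"""Novel-miRNA discovery: clustering, precursor excision, hairpin criteria, star."""

import random

import pandas as pd
import pytest

from nutrimir import discover
from nutrimir._util import revcomp
from nutrimir.discover import (
    HairpinCandidate,
    cluster_loci,
    discover_candidates,
    evaluate_hairpin,
    extract_precursors,
    find_star,
    star_interval_from_mature,
)
from nutrimir.fold import fold_rna
from nutrimir.io import GenomeLocus
from nutrimir.mapper import MappedTag
from nutrimir.preprocess import ReadTagTable
from nutrimir.synthio import HAIRPIN_LOOP


def tag(seq, *loci):
    return MappedTag(seq, [GenomeLocus(*l) for l in loci])


def table_of(rows):
    return ReadTagTable(
        pd.DataFrame(
            {
                "sequence": [r[0] for r in rows],
                "count_A": [r[1] for r in rows],
                "count_B": [r[2] for r in rows],
            }
        )
    )


def perfect_hairpin(mature: str, pad: int = 12) -> tuple[str, int]:
    """Precursor hosting mature + 8-nt loop + reverse complement, plus inert pads."""
    pre = "C" * pad + mature + HAIRPIN_LOOP + revcomp(mature) + "C" * pad
    return pre, pad


MATURE = "TGACATCCAGATAGAAGCTTT"  # 21 nt


class TestClusterLoci:
    def test_single_qualifying_tag(self):
        t = tag("A" * 21, ("chr1", 100, 121, "+"))
        cl = cluster_loci([t], {"A" * 21: "other"}, table=table_of([("A" * 21, 5, 5)]))
        assert len(cl) == 1 and cl[0].locus == GenomeLocus("chr1", 100, 121, "+")

    def test_structural_class_excluded(self):
        t = tag("A" * 21, ("chr1", 100, 121, "+"))
        assert cluster_loci([t], {"A" * 21: "tRNA"}, table=table_of([("A" * 21, 9, 9)])) == []

    def test_known_mature_excluded(self):
        t = tag(MATURE, ("chr1", 100, 121, "+"))
        cl = cluster_loci([t], {MATURE: "other"}, known_matures={MATURE},
                          table=table_of([(MATURE, 9, 9)]))
        assert cl == []

    def test_min_count_and_nloci_filters(self):
        low = tag("C" * 21, ("chr1", 100, 121, "+"))
        multi = tag("G" * 21, *[("chr1", i * 1000, i * 1000 + 21, "+") for i in range(7)])
        classes = {"C" * 21: "other", "G" * 21: "other"}
        tab = table_of([("C" * 21, 2, 2), ("G" * 21, 50, 50)])
        assert cluster_loci([low, multi], classes, table=tab, min_count=5, max_nloci=5) == []

    def test_single_linkage_matches_union_find_oracle(self):
        rng = random.Random(9)
        entries = []
        for i in range(20):
            start = rng.randrange(0, 2000)
            entries.append(("chr1", start, start + 21, "+", f"T{i:02d}" + "A" * 18))
        tags = [tag(seq, (c, s, e, st)) for c, s, e, st, seq in entries]
        classes = {e[4]: "other" for e in entries}
        tab = table_of([(e[4], 10, 10) for e in entries])
        clusters = cluster_loci(tags, classes, table=tab, merge_distance=30,
                                mature_lengths=(20, 24))
        # union-find oracle over interval gaps
        parent = list(range(len(entries)))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                gap = max(entries[i][1], entries[j][1]) - min(entries[i][2], entries[j][2])
                if gap <= 30:
                    parent[find(i)] = find(j)
        n_groups = len({find(i) for i in range(len(entries))})
        assert len(clusters) == n_groups
        assert sum(len(c.members) for c in clusters) == len(entries)

    def test_representative_highest_count_then_lexicographic(self):
        t1 = tag("C" * 21, ("chr1", 100, 121, "+"))
        t2 = tag("A" * 21, ("chr1", 110, 131, "+"))
        classes = {"C" * 21: "other", "A" * 21: "other"}
        tab = table_of([("C" * 21, 10, 10), ("A" * 21, 10, 10)])
        (cl,) = cluster_loci([t1, t2], classes, table=tab)
        assert cl.representative == "A" * 21  # tie -> lexicographic


class TestExtractPrecursors:
    def _cluster(self, chrom, s, e, strand, rep):
        from nutrimir.discover import LocusCluster

        loc = GenomeLocus(chrom, s, e, strand)
        return LocusCluster(loc, rep, loc, [rep], 10, 10)

    def test_window_arithmetic(self):
        genome = {"chr1": "A" * 1000}
        cl = self._cluster("chr1", 500, 521, "+", "G" * 21)
        wins = extract_precursors(cl, genome, long_flank=150, short_flank=20)
        assert [len(w) for w, _ in wins] == [541 - 350, 671 - 480]
        assert [off for _, off in wins] == [150, 20]

    def test_minus_strand_contains_mature_verbatim(self):
        mature = MATURE
        genome_seq = "C" * 300 + revcomp(mature) + "G" * 300
        cl = self._cluster("chr1", 300, 321, "-", mature)
        for window, off in extract_precursors(cl, {"chr1": genome_seq}):
            assert window[off : off + len(mature)] == mature

    def test_edge_clipping_and_full_clip_error(self):
        genome = {"chr1": "A" * 200}
        cl = self._cluster("chr1", 10, 31, "+", "G" * 21)
        wins = extract_precursors(cl, genome, long_flank=150, short_flank=20)
        assert len(wins) == 2  # clipped but usable
        with pytest.raises(ValueError):
            extract_precursors(
                self._cluster("chr1", 0, 200, "+", "G" * 21), genome, 150, 20
            )


class TestEvaluateHairpin:
    def test_planted_hairpin_passes_all_flags(self):
        pre, off = perfect_hairpin(MATURE)
        structure, score = fold_rna(pre)
        cand = evaluate_hairpin(pre, structure, off, len(MATURE), score=score)
        assert cand.passes, cand.flags

    def test_mature_across_terminal_loop_fails(self):
        pre, off = perfect_hairpin(MATURE)
        structure, _ = fold_rna(pre)
        # place the "mature" across the loop: it spans both arms
        across = off + len(MATURE) - 6
        cand = evaluate_hairpin(pre, structure, across, 21)
        assert not cand.passes

    def test_unpaired_budget_enforced(self):
        # 5 unpaired mature bases under a limit of 4 must fail
        pre = "G" * 3 + MATURE + HAIRPIN_LOOP + revcomp(MATURE)[:-5] + "C" * 3
        structure, _ = fold_rna(pre)
        cand = evaluate_hairpin(pre, structure, 3, len(MATURE), max_unpaired_mature=4)
        if cand.unpaired_mature >= 5:
            assert not cand.flags["unpaired_mature_ok"]

    def test_offset_outside_precursor_errors(self):
        pre, _ = perfect_hairpin(MATURE)
        with pytest.raises(ValueError):
            evaluate_hairpin(pre, "." * len(pre), len(pre) - 3, 21)


class TestFindStar:
    def _candidate(self, table=None):
        pre, off = perfect_hairpin(MATURE)
        structure, score = fold_rna(pre)
        cand = evaluate_hairpin(pre, structure, off, len(MATURE), score=score)
        assert cand.passes
        return find_star(cand, table), pre, off

    def test_two_nt_three_prime_overhang_geometry(self):
        cand, pre, off = self._candidate()
        L = len(MATURE)
        # star spans the 3' arm shifted by the canonical 2-nt 3' overhang
        assert cand.star_interval == (off + L + 10, off + 2 * L + 10)

    def test_star_rederives_mature_interval(self):
        """Applying the overhang geometry to the star returns the mature."""
        cand, pre, off = self._candidate()
        s0, s1 = cand.star_interval
        back = star_interval_from_mature(cand.structure, s0, s1 - s0)
        assert back == (off, off + len(MATURE))

    def test_star_support_found_in_table(self):
        cand, pre, off = self._candidate()
        star = cand.star_sequence
        supported, _, _ = None, None, None
        cand2, _, _ = self._candidate(table_of([(star, 4, 3)]))
        assert cand2.star_supported and cand2.star_read_count == 7

    def test_one_nt_end_variants_also_count(self):
        cand, pre, off = self._candidate()
        s0, s1 = cand.star_interval
        variant = pre[s0 + 1 : s1]  # star trimmed by 1 nt at the 5' end
        cand2, _, _ = self._candidate(table_of([(variant, 2, 0)]))
        assert cand2.star_supported

    def test_unrelated_tags_do_not_support(self):
        cand2, _, _ = self._candidate(table_of([("T" * 21, 50, 50)]))
        assert not cand2.star_supported

    def test_fully_unpaired_mature_undefined(self):
        cand = HairpinCandidate(
            precursor="A" * 60, structure="." * 60, score=0,
            mature_offset=10, mature_len=21,
        )
        with pytest.raises(ValueError):
            find_star(cand)


class TestPipelineRecovery:
    def test_all_planted_hairpins_recovered_and_no_background(self, study):
        """Every planted novel miRNA yields a passing candidate; structural
        and decoy loci yield none; star support mirrors planting."""
        found = discover_candidates(
            study.mapped, study.classes, study.mapped_table,
            study.chroms, study.known_matures,
        )
        reps = {cl.representative for cl, _ in found}
        planted = {m.mature for m in study.truth.novel}
        assert planted <= reps
        assert reps == planted  # nothing but planted hairpins
        for m in study.truth.novel:
            cand = next(c for cl, c in found if cl.representative == m.mature)
            assert cand.star_supported == m.star_planted

    def test_candidate_flags_reevaluate_consistently(self, study):
        found = discover_candidates(
            study.mapped, study.classes, study.mapped_table,
            study.chroms, study.known_matures,
        )
        for _, cand in found:
            again = evaluate_hairpin(
                cand.precursor, cand.structure, cand.mature_offset, cand.mature_len
            )
            assert again.flags == cand.flags
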