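"""Adapter trimming, filters, dedup, the 1-deletion aligner and clusters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cracsplice import (
    AlignedRead,
    align_reads,
    assemble_clusters,
    call_crosslink_sites,
    collapse_aligned_duplicates,
    collapse_fastq_duplicates,
    filter_low_complexity,
    import_sam,
    preprocess_reads,
    trim_adapter,
)
from cracsplice.preprocess import CollapsedRead, GenomeIndex
from cracsplice.simulate import substream

from conftest import random_seq

ADAPTER = "AGATCGGAAGAGC"


class TestTrimAdapter:
    def test_full_adapter_suffix_removed(self):
        seq, found = trim_adapter("ACGTACGT" + "AGATCGGA", "AGATCGGAAGAG")
        assert (seq, found) == ("ACGTACGT", True)

    def test_read_without_adapter_unchanged(self):
        seq, found = trim_adapter("ACGTACGTACGTACC", ADAPTER)
        assert (seq, found) == ("ACGTACGTACGTACC", False)

    def test_minimum_overlap_of_four(self):
        seq, found = trim_adapter("CCCCCCAGAT", ADAPTER)
        assert (seq, found) == ("CCCCCC", True)
        # three bases of adapter are below the minimum overlap
        seq, found = trim_adapter("CCCCCCCAGA", ADAPTER)
        assert not found

    def test_one_mismatch_tolerated_two_rejected(self):
        seq, found = trim_adapter("CCCCCC" + "AGCTCGGA", ADAPTER)  # 1 mismatch
        assert (seq, found) == ("CCCCCC", True)
        seq, found = trim_adapter("CCCCCC" + "TTCTCGGA", ADAPTER)  # early mismatches
        assert not found

    def test_brute_force_oracle_on_planted_adapters(self):
        """Reads built as insert + adapter prefix trim back to the insert.

        Oracle: construction; the adapter content is known by design and the
        insert is adapter-free at its 3' end.
        """
        rng = substream(99, "trim_oracle")
        for i in range(200):
            n = int(rng.integers(15, 30))
            insert = "".join("ACGT"[j] for j in rng.integers(0, 4, n))
            # avoid a chance adapter-prefix suffix extending the match
            while insert.endswith(ADAPTER[0]):
                insert = insert[:-1]
            m = int(rng.integers(4, len(ADAPTER) + 1))
            trimmed, found = trim_adapter(insert + ADAPTER[:m], ADAPTER)
            assert found and trimmed == insert

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_trimmed_is_prefix_of_read(self, seq):
        trimmed, found = trim_adapter(seq, ADAPTER)
        assert seq.startswith(trimmed)
        assert found == (len(trimmed) < len(seq)) or not found


class TestLowComplexity:
    @pytest.mark.parametrize(
        "seq,keep",
        [
            ("AAAAAAAAAA", False),       # 100% > 80%
            ("AAAAAAAAGC", True),        # exactly 80% is kept ("more than")
            ("ACGTACGTAC", True),
            ("AAAAAAAAAG", False),       # 90%
        ],
    )
    def test_mono_fraction_boundary(self, seq, keep):
        assert filter_low_complexity(seq) is keep

    def test_empty_sequence_dropped(self):
        assert filter_low_complexity("") is False


class TestFastqDedup:
    def test_identical_reads_collapse_with_multiplicity(self):
        reads = [("r1", "ACGT", "AAA"), ("r2", "ACGT", "AAA"), ("r3", "ACGT", "AAA")]
        out = collapse_fastq_duplicates(reads)
        assert len(out) == 1 and out[0].multiplicity == 3

    def test_distinct_barcodes_stay_separate(self):
        reads = [("r1", "ACGT", "AAA"), ("r2", "ACGT", "TTT")]
        assert len(collapse_fastq_duplicates(reads)) == 2

    def test_simulated_lineage_count_recovered(self, small_cfg, small_crac, small_sim):
        ann, _ = small_sim
        reads, truth = small_crac
        aligned, report = preprocess_reads(
            reads, ann, small_cfg.adapter_sequence,
            barcode_length=small_cfg.barcode_length, collapse_aligned=False,
        )
        assert report["molecules_after_dedup"] == truth[~truth.is_junk].lineage.nunique()


class TestAligner:
    @pytest.fixture(scope="class")
    @staticmethod
    def genome():
        return {"chr1": random_seq(2000, seed=123)}

    def test_exact_match_single_block(self, genome):
        q = genome["chr1"][100:140]
        reads = [CollapsedRead("r", q, "AAAAAA", 1)]
        aligned, _ = align_reads(reads, genome)
        assert aligned[0].blocks == ((100, 140),)
        assert aligned[0].deletion_positions == ()
        assert aligned[0].strand == "+"

    def test_single_deletion_split_blocks(self, genome):
        s = genome["chr1"]
        q = s[100:120] + s[121:141]
        aligned, _ = align_reads([CollapsedRead("r", q, "A", 1)], genome)
        (r,) = aligned
        assert r.deletion_positions == (120,) or (
            # canonicalised to the leftmost base of a homopolymer run
            s[r.deletion_positions[0]] == s[120]
        )
        assert r.aligned_length == 40

    def test_reverse_strand_placement(self, genome):
        from cracsplice.annotation import revcomp

        q = revcomp(genome["chr1"][200:240])
        aligned, _ = align_reads([CollapsedRead("r", q, "A", 1)], genome)
        (r,) = aligned
        assert (r.strand, r.blocks) == ("-", ((200, 240),))
        assert r.five_prime_end == 239

    def test_repeated_sequence_dropped_as_ambiguous(self):
        core = random_seq(60, seed=7)
        genome = {"chr1": core + random_seq(100, seed=8) + core}
        q = core[10:40]
        aligned, stats = align_reads([CollapsedRead("r", q, "A", 1)], genome)
        assert not aligned and stats["n_ambiguous"] == 1

    def test_exhaustive_oracle_on_toy_genome(self, genome):
        """Aligner vs brute-force enumeration of every placement.

        Oracle: O(genome x read) scan testing the exact match and every
        single-deletion placement on both strands, with run-canonical
        deletion positions; the aligner must agree on keep/drop and
        coordinates.
        """
        from cracsplice.annotation import revcomp
        from cracsplice.simulate import canonical_deletion_position

        s = genome["chr1"]
        rng = substream(5, "align_oracle")

        def brute(q):
            hits = []
            for strand, query in (("+", q), ("-", revcomp(q))):
                L = len(query)
                for pos in range(len(s) - L + 1):
                    if s[pos : pos + L] == query:
                        hits.append((strand, pos, None))
                for pos in range(len(s) - L):
                    window = s[pos : pos + L + 1]
                    for d in range(L + 1):
                        if window[:d] + window[d + 1 :] == query:
                            gd = canonical_deletion_position(s, pos + d)
                            if gd > pos:
                                hits.append((strand, pos, gd))
                            break  # first (leftmost) deletion placement
            exact = [h for h in hits if h[2] is None]
            return sorted(set(exact if exact else hits))

        for trial in range(60):
            pos = int(rng.integers(0, 1950))
            L = int(rng.integers(24, 41))
            q = s[pos : pos + L]
            mode = trial % 3
            if mode == 1:  # plant a deletion
                d = int(rng.integers(8, L - 8))
                q = s[pos : pos + d] + s[pos + d + 1 : pos + L + 1]
            elif mode == 2:  # random read, usually unalignable
                q = "".join("ACGT"[j] for j in rng.integers(0, 4, L))
            expected = brute(q)
            aligned, _ = align_reads([CollapsedRead("r", q, "A", 1)], genome)
            if len(expected) == 1:
                (strand, p, gd) = expected[0]
                assert len(aligned) == 1
                r = aligned[0]
                assert (r.strand, r.start) == (strand, p)
                assert r.deletion_positions == (() if gd is None else (gd,))
            else:
                assert not aligned


class TestAlignedCollapse:
    def _read(self, rid, start, end, strand="+", barcode="AA", mult=1, dels=()):
        return AlignedRead(rid, "chr1", strand, ((start, end),), tuple(dels), barcode, mult)

    def test_same_five_prime_and_barcode_keep_longest(self):
        reads = [self._read("a", 100, 130), self._read("b", 100, 135, mult=2)]
        out = collapse_aligned_duplicates(reads)
        assert len(out) == 1
        assert out[0].read_id == "b" and out[0].multiplicity == 3

    def test_different_barcodes_kept_separate(self):
        reads = [self._read("a", 100, 130, barcode="AA"),
                 self._read("b", 100, 135, barcode="CC")]
        assert len(collapse_aligned_duplicates(reads)) == 2

    def test_minus_strand_key_uses_rightmost_terminus(self):
        # same right edge = same 5' end on the minus strand
        reads = [self._read("a", 100, 140, strand="-"),
                 self._read("b", 110, 140, strand="-")]
        assert len(collapse_aligned_duplicates(reads)) == 1

    def test_idempotent(self):
        reads = [self._read("a", 100, 130), self._read("b", 100, 135),
                 self._read("c", 200, 230)]
        once = collapse_aligned_duplicates(reads)
        assert collapse_aligned_duplicates(once) == once


class TestCrosslinkSites:
    def test_reads_without_deletion_contribute_nothing(self):
        r = AlignedRead("a", "chr1", "+", ((10, 40),))
        assert len(call_crosslink_sites([r])) == 0

    def test_multi_deletion_reads_excluded(self):
        r = AlignedRead("a", "chr1", "+", ((10, 20), (21, 30), (31, 40)), (20, 30))
        assert len(call_crosslink_sites([r])) == 0

    def test_site_counts_accumulate(self):
        reads = [
            AlignedRead(f"r{i}", "chr1", "+", ((100, 120), (121, 140)), (120,))
            for i in range(5)
        ]
        sites = call_crosslink_sites(reads)
        assert sites.sites == {("chr1", "+", 120): 5}

    def test_restriction_to_gene_set(self, toy_ann):
        inside = AlignedRead("a", "chr2", "+", ((10, 30), (31, 50)), (30,))
        outside = AlignedRead("b", "chr2", "+", ((340, 360), (361, 380)), (360,))
        wrong_strand = AlignedRead("c", "chr2", "-", ((10, 30), (31, 50)), (30,))
        sites = call_crosslink_sites(
            [inside, outside, wrong_strand], toy_ann, restrict_to=["geneB"]
        )
        assert sites.sites == {("chr2", "+", 30): 1}


class TestClusters:
    def _read(self, rid, start, end, strand="+"):
        return AlignedRead(rid, "chr1", strand, ((start, end),))

    def test_overlapping_reads_merge(self, toy_ann):
        genome = {"chr1": toy_ann.chromosomes["chr1"]}
        cs = assemble_clusters([self._read("a", 1, 10), self._read("b", 5, 15)], genome)
        assert len(cs) == 1
        assert (cs.clusters[0].start, cs.clusters[0].end) == (1, 15)
        assert cs.clusters[0].seq == genome["chr1"][1:15]

    def test_disjoint_reads_stay_separate(self, toy_ann):
        genome = {"chr1": toy_ann.chromosomes["chr1"]}
        cs = assemble_clusters([self._read("a", 1, 10), self._read("b", 20, 30)], genome)
        assert len(cs) == 2

    def test_opposite_strands_never_merge(self, toy_ann):
        genome = {"chr1": toy_ann.chromosomes["chr1"]}
        cs = assemble_clusters(
            [self._read("a", 1, 10), self._read("b", 5, 15, strand="-")], genome
        )
        assert len(cs) == 2
        minus = [c for c in cs.clusters if c.strand == "-"][0]
        from cracsplice.annotation import revcomp

        assert minus.seq == revcomp(genome["chr1"][5:15])

    def test_merge_is_order_independent(self, small_sim, small_cfg, small_crac):
        ann, _ = small_sim
        reads, _ = small_crac
        aligned, _ = preprocess_reads(
            reads, ann, small_cfg.adapter_sequence,
            barcode_length=small_cfg.barcode_length,
        )
        rng = substream(3, "shuffle")
        shuffled = [aligned[i] for i in rng.permutation(len(aligned))]
        assert assemble_clusters(aligned, ann) == assemble_clusters(shuffled, ann)


class TestPipeline:
    def test_read_conservation_through_all_filters(self, small_cfg, small_crac, small_sim):
        ann, _ = small_sim
        reads, _ = small_crac
        _, report = preprocess_reads(
            reads, ann, small_cfg.adapter_sequence,
            barcode_length=small_cfg.barcode_length,
        )
        assert report["conserved"]
        assert report["reads_in"] == len(reads)

    def test_junk_reads_are_filtered_out(self, small_cfg, small_crac, small_sim):
        ann, _ = small_sim
        reads, truth = small_crac
        aligned, report = preprocess_reads(
            reads, ann, small_cfg.adapter_sequence,
            barcode_length=small_cfg.barcode_length,
        )
        n_junk = int(truth.is_junk.sum())
        assert n_junk > 0
        dropped = report["no_adapter"] + report["low_complexity"] + report["unaligned"]
        assert dropped >= n_junk

    def test_sam_import_blocks_and_deletions(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:2000\n"
            "r1\t0\tchr1\t101\t60\t20M1D20M\t*\t0\t0\t" + "A" * 40 + "\t*\tBC:Z:ACGTAC\n"
            "r2\t16\tchr1\t201\t60\t40M\t*\t0\t0\t" + "C" * 40 + "\t*\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"
        )
        reads = import_sam(str(sam))
        assert len(reads) == 2
        r1, r2 = reads
        assert r1.blocks == ((100, 120), (121, 141))
        assert r1.deletion_positions == (120,)
        assert r1.barcode == "ACGTAC"
        assert r2.strand == "-" and r2.blocks == ((200, 240),)
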