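"""Targets, built-in aligner, SAM ingestion and variant extraction."""

import numpy as np
import pytest

from uidcall.align import (
    AlignedRead,
    BuiltinAligner,
    IngestStats,
    PerReadVariant,
    Reference,
    TargetLookup,
    TargetRegion,
    extract_variants,
    ingest_sam,
    load_targets,
    parse_uid_from_name,
    reverse_complement,
)


class TestLoadTargets:
    def test_region_length_from_bed_coordinates(self):
        regions = load_targets(["chr3\t38172600\t38172716\n"])
        assert len(regions) == 1
        assert len(regions[0]) == 116

    def test_abutting_half_open_regions_merge(self):
        regions = load_targets(["chr1\t0\t10", "chr1\t10\t20"])
        assert regions == [TargetRegion("chr1", 0, 20)]

    def test_overlapping_regions_merge_but_chroms_stay_apart(self):
        regions = load_targets(
            ["chr2\t5\t15", "chr1\t0\t10", "chr1\t8\t12"]
        )
        assert [(r.chrom, r.start, r.end) for r in regions] == [
            ("chr1", 0, 12), ("chr2", 5, 15),
        ]

    def test_empty_bed_gives_empty_targets(self):
        assert load_targets([]) == []

    @pytest.mark.parametrize(
        "line,msg",
        [
            ("chr1\t10\t10", "line 1"),
            ("chr1\t20\t10", "line 1"),
            ("chr1\t5", "line 1"),
            ("chr1\tx\ty", "line 1"),
        ],
    )
    def test_malformed_lines_report_line_number(self, line, msg):
        with pytest.raises(ValueError, match=msg):
            load_targets([line])


class TestTargetLookup:
    def test_point_membership_is_one_based(self):
        lut = TargetLookup([TargetRegion("c", 10, 20)])
        assert not lut.contains("c", 10)  # base 10 is 0-based position 9
        assert lut.contains("c", 11)
        assert lut.contains("c", 20)
        assert not lut.contains("c", 21)
        assert not lut.contains("other", 15)

    def test_interval_overlap(self):
        lut = TargetLookup([TargetRegion("c", 10, 20)])
        assert lut.overlaps("c", 0, 11)
        assert not lut.overlaps("c", 0, 10)
        assert lut.overlaps("c", 19, 30)
        assert not lut.overlaps("c", 20, 30)


def oracle_best_placement(seq, reference):
    """Exhaustive ungapped scoring over all offsets and both strands,
    ties broken by (chrom, leftmost, + strand)."""
    best = None
    for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
        for chrom in reference.chroms():
            ref = reference.seq(chrom)
            for start in range(len(ref) - len(seq) + 1):
                mism = sum(
                    a != b
                    for a, b in zip(oriented, ref[start : start + len(seq)])
                )
                score = len(seq) - 2 * mism
                key = (-score, chrom, start, strand != "+")
                if best is None or key < best[0]:
                    best = (key, score, chrom, start, strand)
    return best[1:]


class TestBuiltinAligner:
    def test_exact_substring_maps_at_offset(self, small_ref):
        chrom = small_ref.chroms()[0]
        read = small_ref.fetch(chrom, 500, 560)
        hit = BuiltinAligner(small_ref).align(read)
        assert (hit.mapped, hit.pos, hit.strand) == (True, 501, "+")
        assert hit.n_mismatches == 0

    def test_reverse_complement_maps_same_locus_minus_strand(self, small_ref):
        chrom = small_ref.chroms()[0]
        read = small_ref.fetch(chrom, 500, 560)
        hit = BuiltinAligner(small_ref).align(reverse_complement(read))
        assert (hit.mapped, hit.pos, hit.strand) == (True, 501, "-")
        assert hit.seq == read  # stored in reference orientation

    def test_two_mismatch_read_matches_exhaustive_oracle(self, small_ref):
        chrom = small_ref.chroms()[0]
        read = list(small_ref.fetch(chrom, 300, 340))
        read[5] = "A" if read[5] != "A" else "C"
        read[20] = "G" if read[20] != "G" else "T"
        read = "".join(read)
        score, o_chrom, o_start, o_strand = oracle_best_placement(
            read, small_ref
        )
        hit = BuiltinAligner(small_ref, seed_len=8).align(read)
        assert hit.mapped
        assert (hit.chrom, hit.pos - 1, hit.strand) == (
            o_chrom, o_start, o_strand,
        )
        assert len(read) - 2 * hit.n_mismatches == score

    def test_exhaustive_mode_agrees_with_oracle_on_random_reads(
        self, small_ref, rng
    ):
        aligner = BuiltinAligner(small_ref, min_score_fraction=0.0)
        chrom = small_ref.chroms()[0]
        for _ in range(10):
            start = int(rng.integers(0, 1960))
            read = list(small_ref.fetch(chrom, start, start + 30))
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(0, 30))
                read[i] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            if rng.random() < 0.5:
                read = reverse_complement(read)
            score, o_chrom, o_start, o_strand = oracle_best_placement(
                read, small_ref
            )
            hit = aligner.align(read, exhaustive=True)
            assert (hit.chrom, hit.pos - 1, hit.strand) == (
                o_chrom, o_start, o_strand,
            ), read

    def test_palindromic_tie_prefers_plus_strand(self):
        # GAATTC is its own reverse complement: both strands score equally
        ref = Reference({"r": "TTTTGAATTCTTTT"})
        hit = BuiltinAligner(ref, seed_len=6, min_score_fraction=0.0).align(
            "GAATTC"
        )
        assert (hit.pos, hit.strand) == (5, "+")

    def test_unmappable_read_reported_unmapped(self, small_ref):
        hit = BuiltinAligner(small_ref, min_score_fraction=0.9).align(
            "A" * 40
        )
        assert not hit.mapped

    def test_empty_read_raises(self, small_ref):
        with pytest.raises(ValueError):
            BuiltinAligner(small_ref).align("", read_id="r0")


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:ref\tLN:60\n"


def sam_line(name, flag, pos, cigar, seq):
    return (
        f"{name}\t{flag}\tref\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t"
        f"{'I' * len(seq)}\n"
    )


class TestIngestSam:
    def test_uid_parsed_from_final_name_token(self, tmp_path, tiny_ref):
        sam = tmp_path / "a.sam"
        seq = tiny_ref.fetch("ref", 10, 30)
        sam.write_text(
            SAM_HEADER + sam_line("r1:AAAAACCCCC", 0, 11, "20M", seq)
        )
        stats = IngestStats()
        reads = list(ingest_sam(sam, stats=stats))
        assert len(reads) == 1
        assert reads[0].uid == "AAAAACCCCC"
        assert reads[0].pos == 11
        assert stats.mapped == 1

    def test_unmapped_records_skipped_and_counted(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            SAM_HEADER + sam_line("r1:ACGTACGTAC", 4, 0, "*", "ACGT")
        )
        stats = IngestStats()
        assert list(ingest_sam(sam, stats=stats)) == []
        assert stats.unmapped == 1

    def test_name_without_uid_skipped_with_reason(self, tmp_path, tiny_ref):
        sam = tmp_path / "a.sam"
        seq = tiny_ref.fetch("ref", 0, 20)
        sam.write_text(SAM_HEADER + sam_line("bare_name", 0, 1, "20M", seq))
        stats = IngestStats()
        assert list(ingest_sam(sam, stats=stats)) == []
        assert stats.uid_missing == 1

    def test_header_only_sam_is_empty_stream(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_HEADER)
        stats = IngestStats()
        assert list(ingest_sam(sam, stats=stats)) == []
        assert stats.records == 0

    @pytest.mark.parametrize(
        "name,expected",
        [("r1:AAAA", "AAAA"), ("r1", None), ("r1:", None), ("r1:AAXN", None)],
    )
    def test_parse_uid_from_name(self, name, expected):
        assert parse_uid_from_name(name) == expected


def make_read(seq, pos, cigar=None, uid="AAAAACCCCC", read_id="r1",
              strand="+", chrom="ref"):
    return AlignedRead(
        read_id=read_id, uid=uid, chrom=chrom, pos=pos, strand=strand,
        cigar=cigar or f"{len(seq)}M", seq=seq, mapped=True,
    )


def oracle_gapless_variants(read, reference, lut):
    """Independent position-by-position comparison for a gapless read."""
    ref = reference.seq(read.chrom)
    out = []
    for i, base in enumerate(read.seq):
        pos1 = read.pos + i
        ref_base = ref[pos1 - 1]
        if base != ref_base and base != "N" and lut.contains(read.chrom, pos1):
            out.append((read.chrom, pos1, ref_base, base))
    return out


class TestExtractVariants:
    LUT = TargetLookup([TargetRegion("ref", 0, 60)])

    def test_identical_read_yields_nothing(self, tiny_ref):
        read = make_read(tiny_ref.fetch("ref", 10, 40), pos=11)
        assert extract_variants(read, tiny_ref, self.LUT) == []

    def test_single_substitution_reported_with_alleles(self, tiny_ref):
        seq = list(tiny_ref.fetch("ref", 10, 40))
        ref_base = seq[7]
        alt = "A" if ref_base != "A" else "G"
        seq[7] = alt
        read = make_read("".join(seq), pos=11)
        variants = extract_variants(read, tiny_ref, self.LUT)
        assert [(v.pos, v.ref_allele, v.alt_allele, v.var_type)
                for v in variants] == [(18, ref_base, alt, "SNV")]

    def test_n_bases_never_yield_observations(self, tiny_ref):
        seq = "N" * 30
        read = make_read(seq, pos=11)
        assert extract_variants(read, tiny_ref, self.LUT) == []

    def test_target_boundary_keeps_inside_discards_outside(self, tiny_ref):
        lut = TargetLookup([TargetRegion("ref", 0, 25)])
        seq = list(tiny_ref.fetch("ref", 10, 40))
        # one mismatch inside the target (1-based pos 20 <= 25), one outside
        seq[9] = "A" if seq[9] != "A" else "C"    # pos 20, inside
        seq[25] = "A" if seq[25] != "A" else "C"  # pos 36, outside
        read = make_read("".join(seq), pos=11)
        variants = extract_variants(read, tiny_ref, lut)
        assert [v.pos for v in variants] == [20]

    def test_two_base_deletion_left_anchored(self):
        # 30 bp reference crafted by hand; read deletes ref bases 11-12
        ref = Reference({"ref": "AAACCCGGGTTTAAACCCGGGTTTAAACCC"})
        lut = TargetLookup([TargetRegion("ref", 0, 30)])
        read_seq = ref.fetch("ref", 4, 10) + ref.fetch("ref", 12, 22)
        read = make_read(read_seq, pos=5, cigar="6M2D10M")
        variants = extract_variants(read, ref, lut)
        assert len(variants) == 1
        v = variants[0]
        assert v.var_type == "DEL"
        assert v.pos == 10  # anchor base before the deleted pair
        assert v.ref_allele == ref.fetch("ref", 9, 12)
        assert v.alt_allele == ref.fetch("ref", 9, 10)
        assert len(v.ref_allele) == 3

    def test_insertion_left_anchored_with_context(self, tiny_ref):
        seq = tiny_ref.fetch("ref", 10, 20) + "TAG" + tiny_ref.fetch(
            "ref", 20, 30
        )
        read = make_read(seq, pos=11, cigar="10M3I10M")
        variants = extract_variants(read, tiny_ref, self.LUT)
        assert len(variants) == 1
        v = variants[0]
        assert (v.var_type, v.pos) == ("INS", 20)
        assert v.ref_allele == tiny_ref.fetch("ref", 19, 20)
        assert v.alt_allele == v.ref_allele + "TAG"

    def test_soft_clipped_bases_ignored(self, tiny_ref):
        clipped = "TTTTT"
        seq = clipped + tiny_ref.fetch("ref", 10, 30)
        read = make_read(seq, pos=11, cigar="5S20M")
        assert extract_variants(read, tiny_ref, self.LUT) == []

    def test_alignment_past_reference_end_raises(self, tiny_ref):
        read = make_read("A" * 30, pos=41, read_id="runaway")
        with pytest.raises(ValueError, match="runaway"):
            extract_variants(read, tiny_ref, self.LUT)

    def test_gapless_reads_match_brute_force_oracle(self, small_ref, rng):
        chrom = small_ref.chroms()[0]
        lut = TargetLookup([TargetRegion(chrom, 100, 1500)])
        for _ in range(20):
            start = int(rng.integers(0, 1950))
            seq = list(small_ref.fetch(chrom, start, start + 50))
            for _ in range(int(rng.integers(0, 5))):
                i = int(rng.integers(0, 50))
                seq[i] = "ACGTN"[int(rng.integers(0, 5))]
            read = make_read("".join(seq), pos=start + 1, chrom=chrom)
            got = [
                (v.chrom, v.pos, v.ref_allele, v.alt_allele)
                for v in extract_variants(read, small_ref, lut)
            ]
            assert got == oracle_gapless_variants(read, small_ref, lut)

    def test_strand_invariance_through_alignment(self, small_ref):
        # a read and its reverse complement align to the same locus and
        # yield identical observations on the reference strand
        chrom = small_ref.chroms()[0]
        lut = TargetLookup([TargetRegion(chrom, 0, 2000)])
        seq = list(small_ref.fetch(chrom, 700, 760))
        seq[30] = "A" if seq[30] != "A" else "T"
        fwd = "".join(seq)
        aligner = BuiltinAligner(small_ref, seed_len=10)
        obs = []
        for oriented in (fwd, reverse_complement(fwd)):
            hit = aligner.align(oriented, uid="ACGTACGTAC")
            obs.append(
                {
                    (v.chrom, v.pos, v.ref_allele, v.alt_allele)
                    for v in extract_variants(hit, small_ref, lut)
                }
            )
        assert obs[0] == obs[1] and len(obs[0]) == 1

    def test_target_monotonicity(self, small_ref, rng):
        # enlarging the target never removes observations
        chrom = small_ref.chroms()[0]
        seq = list(small_ref.fetch(chrom, 200, 260))
        for i in (5, 25, 45):
            seq[i] = "A" if seq[i] != "A" else "G"
        read = make_read("".join(seq), pos=201, chrom=chrom)
        sizes = []
        for end in (220, 240, 2000):
            lut = TargetLookup([TargetRegion(chrom, 200, end)])
            sizes.append(len(extract_variants(read, small_ref, lut)))
        assert sizes == sorted(sizes)
        assert len(read.seq) >= sizes[-1]
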