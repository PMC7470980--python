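"""Annotation reading, read/ORF filters, and 3'-end density."""

import collections

import numpy as np
import pytest
from Bio.Seq import Seq

from ribopause.genome import (
    AnnotationError, DensityTrack, FootprintAlignment, FilterReport,
    compute_density, filter_orfs, filter_reads_by_length,
    intersect_conditions, read_annotations,
)
from conftest import make_orf, make_track


class TestReadAnnotations:
    def test_toy_two_orf_extraction(self, toy_genome_files):
        t = toy_genome_files
        orfs = read_annotations(t["ann"], t["fasta"])
        assert [o.orf_id for o in orfs] == ["orfA", "orfB"]
        assert orfs[0].sequence == t["plus_seq"]

    def test_minus_strand_is_reverse_complement_of_slice(self, toy_genome_files):
        t = toy_genome_files
        orfB = read_annotations(t["ann"], t["fasta"])[1]
        genomic_slice = t["contig"][24:36]
        assert orfB.sequence == str(Seq(genomic_slice).reverse_complement())
        assert orfB.sequence == t["minus_seq"]
        assert orfB.sequence.startswith("ATG")

    def test_length_not_divisible_by_three_rejected(self, toy_genome_files, tmp_path):
        ann = tmp_path / "bad.tsv"
        ann.write_text("chr1\t10\t20\t+\tbad\n")  # 10 nt
        with pytest.raises(AnnotationError, match="divisible by 3"):
            read_annotations(ann, toy_genome_files["fasta"])

    def test_interval_outside_contig_rejected(self, toy_genome_files, tmp_path):
        ann = tmp_path / "oob.tsv"
        ann.write_text("chr1\t10\t100000\t+\toob\n")
        with pytest.raises(AnnotationError, match="outside contig"):
            read_annotations(ann, toy_genome_files["fasta"])

    def test_duplicate_orf_id_rejected(self, toy_genome_files, tmp_path):
        ann = tmp_path / "dup.tsv"
        ann.write_text("chr1\t10\t19\t+\tx\nchr1\t24\t36\t-\tx\n")
        with pytest.raises(AnnotationError, match="duplicate"):
            read_annotations(ann, toy_genome_files["fasta"])


def _aln(length, read_id, pos=100, strand="+", contig="chr1"):
    return FootprintAlignment(read_id, contig, pos, strand, length)


class TestReadLengthFilter:
    def test_boundaries_inclusive(self):
        alns = [_aln(length, f"r{length}") for length in (14, 15, 40, 41)]
        kept, report = filter_reads_by_length(alns, 15, 40)
        assert sorted(a.length for a in kept) == [15, 40]
        assert report.rejections == {"too_short": 1, "too_long": 1}

    def test_empty_input(self):
        kept, report = filter_reads_by_length([])
        assert kept == [] and report.n_reads_in == 0 and report.n_reads_kept == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        lengths = rng.integers(10, 51, size=1000)
        alns = [_aln(int(n), f"r{i}") for i, n in enumerate(lengths)]
        kept, _ = filter_reads_by_length(alns, 15, 40)
        assert len(kept) == sum(1 for n in lengths if 15 <= n <= 40)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        alns = [_aln(int(n), f"r{i}") for i, n in enumerate(rng.integers(10, 51, 200))]
        once, _ = filter_reads_by_length(alns)
        twice, rep = filter_reads_by_length(once)
        assert twice == once and rep.n_reads_kept == rep.n_reads_in

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="min_len"):
            filter_reads_by_length([], 40, 15)


class TestComputeDensity:
    def test_single_read_single_position(self):
        orf = make_orf("o1", "ATG" + "AAA" * 20 + "TAA", start=1000)
        aln = [_aln(30, "r0", pos=1030)]
        tracks = compute_density(aln, [orf])
        v = tracks["o1"].values
        assert v[30] == pytest.approx(1e6)
        assert v.sum() == pytest.approx(1e6)

    def test_matches_dictionary_tally_oracle(self):
        rng = np.random.default_rng(3)
        orfs = [
            make_orf("o1", "ATG" + "ACT" * 30 + "TAA", start=100),
            make_orf("o2", "ATG" + "GCA" * 40 + "TAA", start=500),
        ]
        positions = rng.integers(100, 650, size=10)
        alns = [_aln(25, f"r{i}", pos=int(p)) for i, p in enumerate(positions)]
        tracks = compute_density(alns, orfs)
        oracle = collections.Counter(int(p) for p in positions)
        for orf in orfs:
            counts = tracks[orf.orf_id].counts
            for local in range(orf.length):
                assert counts[local] == pytest.approx(
                    oracle.get(orf.start + local, 0), abs=1e-9
                )

    def test_opposite_strand_contributes_zero(self):
        orf = make_orf("o1", "ATG" + "AAA" * 20 + "TAA", start=0)
        alns = [_aln(25, "r0", pos=10, strand="-"), _aln(25, "r1", pos=10, strand="+")]
        tracks = compute_density(alns, [orf])
        assert tracks["o1"].counts.sum() == pytest.approx(1)
        assert tracks["o1"].counts[10] == pytest.approx(1)

    def test_minus_strand_orf_uses_coding_local_coordinates(self):
        seq = "ATG" + "CCG" * 20 + "TAA"
        orf = make_orf("o1", seq, start=200, strand="-")
        # coding-local position 5 on a - ORF sits at genome end-1-5
        alns = [_aln(25, "r0", pos=orf.end - 1 - 5, strand="-")]
        tracks = compute_density(alns, [orf])
        assert tracks["o1"].counts[5] == pytest.approx(1)

    def test_conservation_of_counts(self, default_sim):
        """Total raw counts across tracks equal the reads landing in ORFs."""
        d = default_sim
        total = sum(t.counts.sum() for t in d["tracks"].values())
        spans = {(o.contig, o.strand): [] for o in d["orfs"]}
        for o in d["orfs"]:
            spans[(o.contig, o.strand)].append((o.start, o.end))
        kept, _ = filter_reads_by_length(d["alignments"])
        inside = sum(
            1 for a in kept
            if any(s <= a.three_prime_pos < e for s, e in spans.get((a.contig, a.strand), []))
        )
        assert round(total) == inside

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            compute_density([], [])

    def test_duplicate_read_ids_rejected(self):
        orf = make_orf("o1", "ATG" + "AAA" * 20 + "TAA")
        alns = [_aln(25, "dup", pos=5), _aln(25, "dup", pos=6)]
        with pytest.raises(ValueError, match="uniquely mapped"):
            compute_density(alns, [orf])


class TestOrfFilter:
    def _track(self, length, counts_per_nt):
        return make_track(np.full(length, counts_per_nt))

    def test_length_boundary_169_vs_170(self):
        short = make_orf("short", "N" * 169)
        ok = make_orf("ok", "N" * 170)
        tracks = {"short": self._track(169, 10), "ok": self._track(170, 10)}
        included, windows, report = filter_orfs(tracks, [short, ok])
        assert included == ["ok"]
        assert report.rejections["too_short"] == 1

    def test_density_boundary_one_per_codon(self):
        """300-nt ORF: 100 footprints (1/codon) kept, 99 excluded."""
        orf = make_orf("o", "A" * 300)
        for total, expect in ((100, True), (99, False)):
            values = np.zeros(300)
            values[:total] = 1.0
            inc, _, _ = filter_orfs({"o": make_track(values)}, [orf])
            assert (inc == ["o"]) is expect

    def test_window_arithmetic(self):
        orf = make_orf("o", "N" * 170)
        _, windows, _ = filter_orfs({"o": self._track(170, 5)}, [orf])
        assert windows["o"] == (50, 150)

    def test_threshold_invariant_to_library_rescaling(self):
        """The 1-per-codon cut is on raw counts, not RPM."""
        orf = make_orf("o", "A" * 300)
        values = np.zeros(300)
        values[:100] = 1.0
        for total_mapped in (10**4, 10**6, 10**8):
            rpm = values / (total_mapped / 1e6)
            track = DensityTrack("o", rpm, total_mapped)
            inc, _, _ = filter_orfs({"o": track}, [orf])
            assert inc == ["o"]

    def test_excessive_trims_rejected(self):
        with pytest.raises(ValueError, match="trim"):
            filter_orfs({}, [], min_len=60, trim5=50, trim3=20)


class TestIntersect:
    @pytest.mark.parametrize("a, b, expected", [
        ({"a", "b", "c"}, {"b", "c", "d"}, ["b", "c"]),
        ({"a"}, {"b"}, []),
        ({"x", "y"}, {"x", "y"}, ["x", "y"]),
    ])
    def test_intersection(self, a, b, expected):
        assert intersect_conditions(a, b) == expected


def test_filter_report_rejects_impossible_counters():
    with pytest.raises(ValueError):
        FilterReport(n_reads_in=5, n_reads_kept=6)
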