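"""Genomic data model, readers, and read/ORF-level filters.

Coordinates are 0-based half-open internally; human-readable reports are
1-based inclusive.  Footprints are identified by the genome coordinate of
their 3'-most aligned base, because ribosome position is inferred from a
fixed offset upstream of the footprint 3' end.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq


class AnnotationError(ValueError):
    """Malformed or out-of-bounds ORF annotation."""


@dataclass(frozen=True)
class OrfAnnotation:
    """A protein-coding interval with its coding-strand sequence.

    ``start``/``end`` are 0-based half-open genome coordinates; ``sequence``
    is the coding strand (reverse-complemented for '-' ORFs), so
    ``sequence[0:3]`` is always the start codon.
    """

    orf_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.orf_id}: strand must be + or -")
        if self.end <= self.start:
            raise AnnotationError(f"{self.orf_id}: empty interval")
        if len(self.sequence) != self.length:
            raise AnnotationError(
                f"{self.orf_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def local_position(self, genome_pos: int) -> int:
        """Map a genome coordinate to ORF-local coding-strand coordinates
        (0 = first nt of the start codon)."""
        if self.strand == "+":
            return genome_pos - self.start
        return self.end - 1 - genome_pos


@dataclass(frozen=True)
class FootprintAlignment:
    """One uniquely mapped ribosome footprint, keyed by its 3'-end."""

    read_id: str
    contig: str
    three_prime_pos: int
    strand: str
    length: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.read_id}: non-positive length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.read_id}: strand must be + or -")


@dataclass
class DensityTrack:
    """Per-nucleotide RPM-normalized 3'-end density over one ORF.

    ``values[i] * total_mapped / 1e6`` recovers the integer count of
    footprint 3' ends at ORF-local position ``i``.
    """

    orf_id: str
    values: np.ndarray
    total_mapped: int

    @property
    def counts(self) -> np.ndarray:
        """Raw 3'-end counts (un-normalized)."""
        return self.values * self.total_mapped / 1e6


@dataclass
class FilterReport:
    """Bookkeeping for any filtering stage: kept <= in for every counter."""

    n_reads_in: int = 0
    n_reads_kept: int = 0
    n_orfs_in: int = 0
    n_orfs_kept: int = 0
    rejections: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_reads_kept > self.n_reads_in or self.n_orfs_kept > self.n_orfs_in:
            raise ValueError("kept exceeds input count")


# ---------------------------------------------------------------------------
# Readers / writers

_ANN_COLUMNS = ["contig", "start", "end", "strand", "orf_id"]
_ALN_COLUMNS = ["contig", "three_prime_pos", "strand", "length", "read_id"]


def read_annotations(ann_path, genome_path) -> list[OrfAnnotation]:
    """Read a GFF-like tab-separated ORF table plus genome FASTA.

    The table columns are (contig, start, end, strand, orf_id) with 0-based
    half-open coordinates; lines starting with '#' are comments.  Sequences
    are extracted from the coding strand and must be a multiple of 3 long.
    Returns ORFs ordered by (contig, start).
    """
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_path), "fasta")}
    orfs: list[OrfAnnotation] = []
    seen: set[str] = set()
    with open(ann_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields == _ANN_COLUMNS:  # header row
                continue
            if len(fields) != 5:
                raise AnnotationError(f"line {lineno}: expected 5 columns, got {len(fields)}")
            contig, start_s, end_s, strand, orf_id = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: non-integer coordinate") from exc
            if contig not in genome:
                raise AnnotationError(f"line {lineno}: unknown contig {contig!r}")
            if not (0 <= start < end <= len(genome[contig])):
                raise AnnotationError(
                    f"line {lineno}: interval [{start},{end}) outside contig "
                    f"{contig} (length {len(genome[contig])})"
                )
            if (end - start) % 3 != 0:
                raise AnnotationError(
                    f"line {lineno}: ORF {orf_id} length {end - start} not divisible by 3"
                )
            if orf_id in seen:
                raise AnnotationError(f"line {lineno}: duplicate orf_id {orf_id!r}")
            seen.add(orf_id)
            seq = genome[contig][start:end]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            orfs.append(OrfAnnotation(orf_id, contig, start, end, strand, seq))
    orfs.sort(key=lambda o: (o.contig, o.start))
    return orfs


def read_alignments(path) -> list[FootprintAlignment]:
    """Read a BED-like alignment table: contig, 3'-end pos, strand, length, read_id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_ALN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    return [
        FootprintAlignment(
            read_id=str(r.read_id), contig=str(r.contig),
            three_prime_pos=int(r.three_prime_pos), strand=str(r.strand),
            length=int(r.length),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignments(alignments, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(_ALN_COLUMNS) + "\n")
        for a in alignments:
            fh.write(f"{a.contig}\t{a.three_prime_pos}\t{a.strand}\t{a.length}\t{a.read_id}\n")


def write_filter_report(report: FilterReport, path, comment: str = "") -> None:
    """TSV dump of a FilterReport: counter name, value."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("counter\tvalue\n")
        for name in ("n_reads_in", "n_reads_kept", "n_orfs_in", "n_orfs_kept"):
            fh.write(f"{name}\t{getattr(report, name)}\n")
        for rule, n in sorted(report.rejections.items()):
            fh.write(f"rejected_{rule}\t{n}\n")


def write_annotations(orfs, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(_ANN_COLUMNS) + "\n")
        for o in orfs:
            fh.write(f"{o.contig}\t{o.start}\t{o.end}\t{o.strand}\t{o.orf_id}\n")


# ---------------------------------------------------------------------------
# Filters and density

def filter_reads_by_length(alignments, min_len: int = 15, max_len: int = 40):
    """Keep footprints with min_len <= length <= max_len (bounds inclusive).

    Returns (kept alignments, FilterReport).  Idempotent.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [a for a in alignments if min_len <= a.length <= max_len]
    n_short = sum(1 for a in alignments if a.length < min_len)
    n_long = sum(1 for a in alignments if a.length > max_len)
    report = FilterReport(
        n_reads_in=len(alignments), n_reads_kept=len(kept),
        rejections={"too_short": n_short, "too_long": n_long},
    )
    return kept, report


def compute_density(alignments, orfs) -> dict[str, DensityTrack]:
    """RPM-normalized 3'-end density per ORF nucleotide.

    ``value[i] = count of same-strand footprint 3' ends at ORF-local i /
    (total_mapped / 1e6)`` with total_mapped = number of input alignments.
    A 3' end inside two overlapping same-strand ORFs is counted for both
    (transparent double-counting; the overlap count is auditable via
    :func:`filter_orfs` reports).
    """
    total_mapped = len(alignments)
    if total_mapped == 0:
        raise ValueError("no alignments: nothing to normalize by")
    ids = [a.read_id for a in alignments]
    if len(set(ids)) != total_mapped:
        dup = collections.Counter(ids).most_common(1)[0][0]
        raise ValueError(f"duplicate read_id {dup!r}: input must be uniquely mapped")

    tallies: dict[tuple[str, str], collections.Counter] = collections.defaultdict(collections.Counter)
    for a in alignments:
        tallies[(a.contig, a.strand)][a.three_prime_pos] += 1

    scale = total_mapped / 1e6
    tracks: dict[str, DensityTrack] = {}
    for orf in orfs:
        counts = np.zeros(orf.length)
        tally = tallies.get((orf.contig, orf.strand))
        if tally:
            for pos, n in tally.items():
                if orf.start <= pos < orf.end:
                    counts[orf.local_position(pos)] = n
        tracks[orf.orf_id] = DensityTrack(orf.orf_id, counts / scale, total_mapped)
    return tracks


def filter_orfs(
    tracks: dict[str, DensityTrack],
    orfs,
    min_len: int = 170,
    min_density_per_codon: float = 1.0,
    trim5: int = 50,
    trim3: int = 20,
):
    """Apply ORF-level inclusion filters and derive trimmed analysis windows.

    An ORF is kept iff its length is >= min_len nt AND its mean raw footprint
    count per codon is >= min_density_per_codon (equivalently 0.33 per nt);
    the count threshold is applied to raw counts, not RPM, and is computed
    over the full ORF before trimming.  The analysis window excludes the
    first ``trim5`` and last ``trim3`` nt: ``[trim5, length - trim3)`` in
    ORF-local coordinates.

    Returns (included ids, windows dict orf_id -> (lo, hi), FilterReport).
    """
    if trim5 + trim3 >= min_len:
        raise ValueError(f"trim5 + trim3 = {trim5 + trim3} >= min ORF length {min_len}")
    included: list[str] = []
    windows: dict[str, tuple[int, int]] = {}
    n_short = n_sparse = 0
    orf_by_id = {o.orf_id: o for o in orfs}
    for orf_id in sorted(tracks):
        orf = orf_by_id[orf_id]
        track = tracks[orf_id]
        if orf.length < min_len:
            n_short += 1
            continue
        mean_per_codon = track.counts.sum() / (orf.length / 3)
        if mean_per_codon < min_density_per_codon:
            n_sparse += 1
            continue
        included.append(orf_id)
        windows[orf_id] = (trim5, orf.length - trim3)
    report = FilterReport(
        n_orfs_in=len(tracks), n_orfs_kept=len(included),
        rejections={"too_short": n_short, "low_density": n_sparse},
    )
    return included, windows, report


def intersect_conditions(included_a, included_b) -> list[str]:
    """ORFs passing the inclusion filters in both conditions, sorted."""
    return sorted(set(included_a) & set(included_b))
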