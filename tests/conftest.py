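"""Shared fixtures: tiny hand-written genomes and simulated datasets.

All datasets are generated at test time with fixed seeds; nothing is
stored on disk in the repository.
"""

import numpy as np
import pytest

from ribopause import simulate as sim
from ribopause.genome import (
    OrfAnnotation, compute_density, filter_orfs, filter_reads_by_length,
)


@pytest.fixture(scope="session")
def toy_genome_files(tmp_path_factory):
    """Two-ORF toy genome: one + strand, one - strand."""
    d = tmp_path_factory.mktemp("toy_genome")
    # contig: 10 nt pad, 9-nt + ORF, 5 nt pad, 12-nt - ORF, 6 nt pad
    plus_orf = "ATGAAATAA"
    minus_orf_coding = "ATGCCCGGGTAA"
    from Bio.Seq import Seq

    contig = "GGGGGCCCCC" + plus_orf + "TTTTT" + str(Seq(minus_orf_coding).reverse_complement()) + "ACACAC"
    fasta = d / "genome.fa"
    fasta.write_text(f">chr1\n{contig}\n")
    ann = d / "orfs.tsv"
    ann.write_text(
        "contig\tstart\tend\tstrand\torf_id\n"
        "chr1\t10\t19\t+\torfA\n"
        "chr1\t24\t36\t-\torfB\n"
    )
    return {"fasta": fasta, "ann": ann, "contig": contig,
            "plus_seq": plus_orf, "minus_seq": minus_orf_coding}


@pytest.fixture(scope="session")
def default_sim():
    """A moderately deep simulated dataset with default (uniform) dwell."""
    cfg = sim.SimulationConfig(seed=101, n_orfs=25, depth=150_000)
    rng = np.random.default_rng(cfg.seed)
    orfs, genome = sim.generate_orfs(cfg, rng)
    alignments, truth = sim.simulate_footprints(orfs, cfg, rng)
    kept, _ = filter_reads_by_length(alignments)
    tracks = compute_density(kept, orfs)
    included, windows, _ = filter_orfs(tracks, orfs)
    return {
        "config": cfg, "orfs": orfs, "genome": genome,
        "alignments": alignments, "truth": truth,
        "tracks": tracks, "included": included, "windows": windows,
    }


@pytest.fixture(scope="session")
def fixture_pair(tmp_path_factory):
    """The paired toxin/control fixture datasets written to a temp dir."""
    from ribopause.pipeline import make_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(out, seed=0)


def make_track(values, total_mapped=1_000_000):
    """DensityTrack whose RPM values equal raw counts (library of 1e6)."""
    from ribopause.genome import DensityTrack

    return DensityTrack("toy", np.asarray(values, dtype=float), total_mapped)


def make_orf(orf_id, seq, start=0, contig="chr1", strand="+"):
    return OrfAnnotation(orf_id, contig, start, start + len(seq), strand, seq)
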