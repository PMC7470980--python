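"""Synthetic aligned-footprint generator.

Emulates the statistical structure the downstream analysis assumes:
codon-specific ribosome dwell times (elevated Gly dwell in a "toxin"
condition, elevated Ser dwell in a "control" condition), memoryless
per-codon premature drop-off producing a 3'-ward density decline, footprint
lengths in 15-40 nt, and a configurable A-site-to-3'-end offset.

The generative model: the expected footprint count with its A site at
sense codon k of an ORF is proportional to

    dwell(codon_k) * (1 - q)**k

where q is the per-codon drop-off probability; counts are Poisson.  Each
emitted footprint's 3'-end sits ``offset_3prime`` nt downstream of the
first nucleotide of its A-site codon (optionally with +/-1 nt jitter).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import OrfAnnotation, FootprintAlignment, write_alignments, write_annotations

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "TCAG"
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)
assert len(SENSE_CODONS) == 61

# standard genetic code, coding-strand DNA codons
_CODE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
GENETIC_CODE = {
    a + b + c: _CODE[16 * i + 4 * j + k]
    for i, a in enumerate(BASES)
    for j, b in enumerate(BASES)
    for k, c in enumerate(BASES)
}
CODONS_FOR_AA = {
    aa: tuple(c for c in SENSE_CODONS if GENETIC_CODE[c] == aa)
    for aa in sorted(set(GENETIC_CODE.values()) - {"*"})
}


def uniform_codon_usage() -> dict[str, float]:
    return {c: 1.0 / 61 for c in SENSE_CODONS}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic Ribo-seq condition.

    depth is the expected total footprint count across the dataset;
    orf_length_range is in codons (start and stop included);
    dwell_multipliers maps codon -> relative dwell (default 1.0 everywhere);
    dropoff_per_codon is the memoryless per-codon drop-off probability q;
    offset_3prime is the A-site-first-nt to footprint-3'-end distance in nt.
    """

    seed: int = 0
    n_orfs: int = 50
    orf_length_range: tuple[int, int] = (120, 320)
    codon_usage: dict[str, float] = field(default_factory=uniform_codon_usage)
    dwell_multipliers: dict[str, float] = field(default_factory=dict)
    dropoff_per_codon: float = 0.0
    offset_3prime: int = 11
    length_mean: float = 25.0
    length_sd: float = 3.0
    length_range: tuple[int, int] = (15, 40)
    depth: int = 100_000
    jitter: int = 0
    both_strands: bool = False
    contig: str = "sim_chr"
    spacer: int = 100

    def __post_init__(self):
        bad = set(self.codon_usage) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"codon_usage contains non-sense codons: {sorted(bad)}")
        total = sum(self.codon_usage.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"codon_usage sums to {total}, expected 1")
        if any(m <= 0 for m in self.dwell_multipliers.values()):
            raise ValueError("dwell multipliers must be positive")
        if not 0.0 <= self.dropoff_per_codon < 1.0:
            raise ValueError("dropoff_per_codon must lie in [0, 1)")
        if not 0 <= self.offset_3prime < self.length_range[0]:
            raise ValueError(
                f"offset_3prime {self.offset_3prime} must lie in "
                f"[0, min footprint length {self.length_range[0]})"
            )
        lo, hi = self.orf_length_range
        if lo < 3 or hi < lo:
            raise ValueError(f"invalid orf_length_range {self.orf_length_range}")
        if self.n_orfs < 1 or self.depth < 1:
            raise ValueError("n_orfs and depth must be positive")

    def dwell(self, codon: str) -> float:
        return self.dwell_multipliers.get(codon, 1.0)


def _dwell_for_amino_acid(aa: str, multiplier: float) -> dict[str, float]:
    """Multiplier applied uniformly to every codon of one amino acid."""
    return {c: multiplier for c in CODONS_FOR_AA[aa]}


def gly_stall_config(multiplier: float = 5.0, **kw) -> SimulationConfig:
    """Toxin-like condition: elevated dwell at all four Gly codons."""
    return SimulationConfig(dwell_multipliers=_dwell_for_amino_acid("G", multiplier), **kw)


def ser_stall_config(multiplier: float = 2.0, **kw) -> SimulationConfig:
    """Control-like condition: mild 'hungry codon' pausing at Ser codons."""
    return SimulationConfig(dwell_multipliers=_dwell_for_amino_acid("S", multiplier), **kw)


# ---------------------------------------------------------------------------

def generate_orfs(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Generate ORF annotations and the genome that carries them.

    Every ORF starts with ATG, ends with a stop codon, contains no internal
    stops (codon usage covers sense codons only) and has length divisible
    by 3.  ORFs are laid head-to-tail on one contig separated by random
    spacers; all on the + strand unless both_strands is set, in which case
    strands alternate.  Returns (orfs, {contig: sequence}).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    codons = np.array(SENSE_CODONS)
    probs = np.array([config.codon_usage.get(c, 0.0) for c in SENSE_CODONS])
    lo, hi = config.orf_length_range

    from Bio.Seq import Seq

    pieces: list[str] = []
    orfs: list[OrfAnnotation] = []
    cursor = 0
    for i in range(config.n_orfs):
        spacer = "".join(rng.choice(list("ACGT"), size=config.spacer))
        pieces.append(spacer)
        cursor += config.spacer
        n_codons = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(codons, size=n_codons - 2, p=probs))
        coding = "ATG" + body + "TAA"
        strand = "-" if (config.both_strands and i % 2 == 1) else "+"
        genomic = coding if strand == "+" else str(Seq(coding).reverse_complement())
        start, end = cursor, cursor + len(coding)
        orfs.append(OrfAnnotation(f"orf{i:04d}", config.contig, start, end, strand, coding))
        pieces.append(genomic)
        cursor = end
    pieces.append("".join(rng.choice(list("ACGT"), size=config.spacer)))
    return orfs, {config.contig: "".join(pieces)}


def generate_orfs_aa_fraction(
    aa: str,
    fraction: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Generate ORFs in which exactly ``fraction`` of sense codons encode
    amino acid ``aa``.

    Used for closed-form pause-score oracles, where the expected mean
    pause score at the target codons, m / (f*m + 1 - f), holds at a fixed
    per-gene codon fraction f; multinomial codon sampling would leave f
    fluctuating between genes.  ORF lengths are rounded so that
    fraction * n_sense_codons is an integer; target-amino-acid codons are
    drawn uniformly among that amino acid's codons, the rest uniformly
    among the other sense codons.  Returns (orfs, genome) like
    :func:`generate_orfs`.
    """
    from fractions import Fraction

    from Bio.Seq import Seq

    if rng is None:
        rng = np.random.default_rng(config.seed)
    den = Fraction(fraction).limit_denominator(1000).denominator
    target = np.array(CODONS_FOR_AA[aa])
    others = np.array([c for c in SENSE_CODONS if GENETIC_CODE[c] != aa])
    lo, hi = config.orf_length_range

    pieces: list[str] = []
    orfs: list[OrfAnnotation] = []
    cursor = 0
    for i in range(config.n_orfs):
        pieces.append("".join(rng.choice(list("ACGT"), size=config.spacer)))
        cursor += config.spacer
        n_codons = int(rng.integers(lo, hi + 1))
        n_sense = max(den, round((n_codons - 1) / den) * den)
        n_target = round(fraction * n_sense)
        body = list(rng.choice(target, size=n_target)) + list(
            rng.choice(others, size=n_sense - 1 - n_target)
        )
        body = list(rng.permutation(body))
        coding = "ATG" + "".join(body) + "TAA"
        start, end = cursor, cursor + len(coding)
        orfs.append(OrfAnnotation(f"orf{i:04d}", config.contig, start, end, "+", coding))
        pieces.append(coding)
        cursor = end
    pieces.append("".join(rng.choice(list("ACGT"), size=config.spacer)))
    return orfs, {config.contig: "".join(pieces)}


def simulate_codon_counts(
    orfs, config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Poisson footprint counts per sense codon for each ORF.

    This is the generative core shared by read-level simulation and by the
    fast statistical-replicate path: count_k ~ Poisson(lambda * w_k) with
    w_k = dwell(codon_k) * (1 - q)**k and lambda set so the expected total
    over the dataset equals ``config.depth``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    q = config.dropoff_per_codon
    weights: dict[str, np.ndarray] = {}
    total_w = 0.0
    for orf in orfs:
        n_sense = orf.n_codons - 1  # exclude the stop codon
        w = np.array(
            [config.dwell(orf.sequence[3 * k : 3 * k + 3]) for k in range(n_sense)]
        )
        w *= (1.0 - q) ** np.arange(n_sense)
        weights[orf.orf_id] = w
        total_w += w.sum()
    lam = config.depth / total_w
    return {oid: rng.poisson(lam * w) for oid, w in weights.items()}


def counts_to_density_values(counts: np.ndarray, orf_length: int, offset: int) -> np.ndarray:
    """Deterministic 3'-end per-nt count vector implied by per-codon counts.

    Codon k's footprints place their 3' ends at ORF-local 3*k + offset;
    ends falling past the ORF's last nucleotide are dropped (they land in
    the downstream intergenic region and are invisible to an ORF-local
    track), mirroring what read-level simulation plus density computation
    produce with zero jitter.
    """
    values = np.zeros(orf_length)
    pos = 3 * np.arange(len(counts)) + offset
    inside = pos < orf_length
    values[pos[inside]] = counts[inside]
    return values


def simulate_footprints(orfs, config: SimulationConfig, rng: np.random.Generator | None = None):
    """Emit individual footprint alignments plus a per-read truth table.

    Returns (alignments, truth DataFrame with columns read_id, orf_id,
    a_site_codon_index).  Footprint lengths follow a rounded Gaussian
    truncated to ``length_range``; lengths not exceeding the 3' offset are
    resampled so the A site always lies within the footprint.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = simulate_codon_counts(orfs, config, rng)
    lo, hi = config.length_range
    min_len = max(lo, config.offset_3prime + 1)

    alignments: list[FootprintAlignment] = []
    truth_rows: list[tuple[str, str, int]] = []
    serial = 0
    for orf in orfs:
        for k, n in enumerate(counts[orf.orf_id]):
            if n == 0:
                continue
            local = 3 * k + config.offset_3prime
            for _ in range(int(n)):
                jit = int(rng.integers(-config.jitter, config.jitter + 1)) if config.jitter else 0
                pos_local = local + jit
                if orf.strand == "+":
                    gpos = orf.start + pos_local
                else:
                    gpos = orf.end - 1 - pos_local
                length = 0
                while not (min_len <= length <= hi):
                    length = int(round(rng.normal(config.length_mean, config.length_sd)))
                read_id = f"r{serial:07d}"
                serial += 1
                alignments.append(
                    FootprintAlignment(read_id, orf.contig, gpos, orf.strand, length)
                )
                truth_rows.append((read_id, orf.orf_id, k))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "orf_id", "a_site_codon_index"])
    return alignments, truth


def write_dataset(out_dir, orfs, genome: dict[str, str], alignments, truth, config) -> None:
    """Write FASTA + annotation + alignment + truth tables and the config."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    stamp = f"ribopause simulate seed={config.seed}"
    write_annotations(orfs, out / "orfs.tsv", comment=stamp)
    write_alignments(alignments, out / "alignments.tsv", comment=stamp)
    with open(out / "truth.tsv", "w") as fh:
        fh.write(f"# {stamp}\n")
        truth.to_csv(fh, sep="\t", index=False)
    cfg = dataclasses.asdict(config)
    cfg["orf_length_range"] = list(cfg["orf_length_range"])
    cfg["length_range"] = list(cfg["length_range"])
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
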