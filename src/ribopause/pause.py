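"""A-site offset calibration and pause-score computation.

The ribosome's A site is inferred from the footprint 3' end by a single
global upstream shift (11 nt in the default configuration).  The shift is
calibrated from start- and stop-anchored metagene profiles: because no
elongating ribosome can place its A site upstream of the start codon,
3'-end density rises abruptly at ORF-local position Delta, and the
stop-anchored profile constrains the reading frame of the shift.

Pause scores follow the standard definition: per-nucleotide density
divided by the mean density over the gene's trimmed analysis window, so
the window mean of every pause profile is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GENETIC_CODE, STOP_CODONS


class CalibrationError(RuntimeError):
    """Metagene profile has no discernible initiation edge."""


@dataclass
class MetageneProfile:
    """Average (per-ORF mean-normalized) density aligned at a common anchor."""

    anchor: str  # "start" or "stop"
    offsets: np.ndarray  # nt relative to the anchor nucleotide
    mean_density: np.ndarray

    def __post_init__(self):
        if len(self.offsets) != len(self.mean_density):
            raise ValueError("offsets and mean_density lengths differ")


@dataclass
class PauseProfile:
    """Per-nucleotide pause scores over one ORF's trimmed window."""

    orf_id: str
    per_nt_scores: np.ndarray
    window: tuple[int, int]


@dataclass
class CalibrationResult:
    offset: int
    start_profile: MetageneProfile
    stop_profile: MetageneProfile
    edge_scores: dict[int, float]
    frame_consistent: bool


def start_stop_metagene(tracks, orfs, span: int):
    """Start- and stop-anchored metagene profiles over ``span`` nt.

    Each ORF's density is divided by its own mean before averaging, so
    deeply covered genes do not dominate the profile.  The stop anchor is
    the first nucleotide of the stop codon; stop-profile offsets run from
    -(span - 3) to +2 (the last ORF nucleotide).
    """
    orf_by_id = {o.orf_id: o for o in orfs}
    start_rows, stop_rows = [], []
    for orf_id, track in tracks.items():
        L = orf_by_id[orf_id].length
        if L < span + 3:
            continue
        v = track.values / track.values.mean() if track.values.mean() > 0 else None
        if v is None:
            continue
        start_rows.append(v[:span])
        stop_rows.append(v[L - span :])
    if not start_rows:
        raise ValueError("no ORF long enough for the requested metagene span")
    start = MetageneProfile("start", np.arange(span), np.mean(start_rows, axis=0))
    stop_offsets = np.arange(-(span - 3), 3)  # anchor = first nt of stop codon
    stop = MetageneProfile("stop", stop_offsets, np.mean(stop_rows, axis=0))
    return start, stop


def calibrate_offset(tracks, orfs, candidate_range=range(5, 21)) -> CalibrationResult:
    """Recover the 3'-end -> A-site shift from metagene edge alignment.

    For each candidate shift Delta, the edge score is the start-anchored
    metagene density at position Delta minus the mean density over the
    3 nt immediately upstream: the true shift has zero density upstream
    (no A site before the start codon) and the codon-0 spike at Delta.
    Ties prefer the smaller Delta.  The stop-anchored profile's last
    occupied position must agree with Delta modulo 3 (frame consistency).

    Raises :class:`CalibrationError` when the profile is flat (no
    initiation edge), advising a manually supplied offset.
    """
    candidates = list(candidate_range)
    if not candidates:
        raise ValueError("empty candidate range")
    if len(tracks) < 10:
        raise ValueError(f"calibration needs >= 10 included ORFs, got {len(tracks)}")
    span = max(candidates) + 7
    start, stop = start_stop_metagene(tracks, orfs, span)
    m = start.mean_density
    scores = {}
    for d in candidates:
        upstream = m[max(0, d - 3) : d]
        scores[d] = float(m[d] - (upstream.mean() if len(upstream) else 0.0))
    best = max(candidates, key=lambda d: (scores[d], -d))
    overall = m.mean()
    if overall <= 0 or scores[best] <= 0.05 * overall:
        raise CalibrationError(
            "no discernible initiation edge in the start-anchored metagene; "
            "supply the A-site offset manually"
        )
    ms = stop.mean_density
    occupied = np.nonzero(ms > 0.1 * ms.max())[0]
    frame_consistent = bool(
        len(occupied) and (best - int(stop.offsets[occupied[-1]])) % 3 == 0
    )
    return CalibrationResult(best, start, stop, scores, frame_consistent)


def pause_scores(track, window: tuple[int, int]) -> PauseProfile:
    """Per-nt pause scores: density / mean density over the trimmed window."""
    lo, hi = window
    v = track.values[lo:hi]
    mean = v.mean()
    if not mean > 0:
        raise ValueError(
            f"{track.orf_id}: zero density in window [{lo},{hi}) "
            "(ORF should have been excluded by the density filter)"
        )
    return PauseProfile(track.orf_id, v / mean, (lo, hi))


def codon_pause_table(profiles, orfs, offset: int, top_n: int | None = None) -> pd.DataFrame:
    """Mean A-site pause score per codon and per amino acid.

    A footprint 3' end at ORF-local p reports an A site starting at
    p - offset; equivalently the codon at nt [c, c+3) collects the pause
    scores at positions [c + offset, c + offset + 3), averaged over the
    three nucleotides.  Occurrences whose shifted positions fall outside
    the trimmed window are skipped.  Returns a tidy table with rows for
    each of the 61 sense codons and, below them, per-amino-acid
    aggregates (occurrence-weighted means), columns:
    level, key, amino_acid, n, mean_pause_score, n_skipped.
    """
    orf_by_id = {o.orf_id: o for o in orfs}
    sums: dict[str, float] = {}
    sq_sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_skipped = 0
    prof_list = profiles.values() if isinstance(profiles, dict) else profiles
    if top_n is not None:
        prof_list = sorted(prof_list, key=lambda p: p.orf_id)[:top_n]
    for prof in prof_list:
        seq = orf_by_id[prof.orf_id].sequence
        lo, hi = prof.window
        for k in range(len(seq) // 3):
            codon = seq[3 * k : 3 * k + 3]
            if codon in STOP_CODONS:
                continue
            s = 3 * k + offset
            if s < lo or s + 3 > hi:
                n_skipped += 1
                continue
            occ = prof.per_nt_scores[s - lo : s - lo + 3].mean()
            sums[codon] = sums.get(codon, 0.0) + occ
            sq_sums[codon] = sq_sums.get(codon, 0.0) + occ * occ
            counts[codon] = counts.get(codon, 0) + 1

    def _stats(total, total_sq, n):
        if n == 0:
            return np.nan, np.nan
        mean = total / n
        if n == 1:
            return mean, np.nan
        var = max(0.0, (total_sq - n * mean * mean) / (n - 1))
        return mean, np.sqrt(var)

    rows = []
    from .simulate import SENSE_CODONS

    for codon in SENSE_CODONS:
        n = counts.get(codon, 0)
        mean, sd = _stats(sums.get(codon, 0.0), sq_sums.get(codon, 0.0), n)
        rows.append({
            "level": "codon", "key": codon, "amino_acid": GENETIC_CODE[codon],
            "n": n, "mean_pause_score": mean, "sd_pause_score": sd,
        })
    aa_sums: dict[str, float] = {}
    aa_sq: dict[str, float] = {}
    aa_counts: dict[str, int] = {}
    for codon in SENSE_CODONS:
        aa = GENETIC_CODE[codon]
        aa_sums[aa] = aa_sums.get(aa, 0.0) + sums.get(codon, 0.0)
        aa_sq[aa] = aa_sq.get(aa, 0.0) + sq_sums.get(codon, 0.0)
        aa_counts[aa] = aa_counts.get(aa, 0) + counts.get(codon, 0)
    for aa in sorted(aa_sums):
        n = aa_counts[aa]
        mean, sd = _stats(aa_sums[aa], aa_sq[aa], n)
        rows.append({
            "level": "amino_acid", "key": aa, "amino_acid": aa,
            "n": n, "mean_pause_score": mean, "sd_pause_score": sd,
        })
    table = pd.DataFrame(rows)
    table.attrs["n_skipped"] = n_skipped
    return table


def write_metagene_profiles(profiles, path, comment: str = "") -> None:
    """TSV of one or more metagene profiles: anchor, offset, mean_density."""
    rows = []
    for prof in profiles:
        for off, dens in zip(prof.offsets, prof.mean_density):
            rows.append((prof.anchor, int(off), dens))
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("anchor\toffset\tmean_density\n")
        for anchor, off, dens in rows:
            fh.write(f"{anchor}\t{off}\t{dens:.6g}\n")


def write_pause_profile(profile: PauseProfile, path, comment: str = "") -> None:
    """Per-gene profile TSV (position, score); positions are 1-based."""
    lo, _ = profile.window
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("position\tpause_score\n")
        for i, s in enumerate(profile.per_nt_scores):
            fh.write(f"{lo + i + 1}\t{s:.6g}\n")


def toeprint_asite(stall_position: int, offset: int = 13) -> int:
    """First nucleotide of the A-site codon from a toeprint stall position.

    Reverse transcriptase stalls a fixed distance downstream of a stalled
    ribosome's A site; the A-site codon's first nucleotide lies ``offset``
    nt upstream of the stall.  Positions share whatever 1-based coordinate
    system the input uses.
    """
    result = stall_position - offset
    if result <= 0:
        raise ValueError(
            f"stall position {stall_position} yields non-positive A-site position"
        )
    return result
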