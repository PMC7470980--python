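"""In-silico RNase T1 digestion and average-mass MH+ computation.

RNase T1 cleaves single-stranded RNA 3' of unmodified guanosine, leaving a
3'-phosphorylated upstream fragment and a 5'-OH downstream fragment.  The
diagnostic 3'-terminal fragment of a tRNA retains the molecule's native
3' terminus, where an aminoacyl group (and, for GNAT-toxin-modified tRNA,
an additional N-acetyl group on the amino acid's alpha-amino group) may be
esterified.  Masses are average (linear-mode MALDI-TOF) by default, built
from elemental composition; monoisotopic masses are available through
``monoisotopic=True``.

A printed "T" in an RNA sequence is read as unmodified uridine unless a
modified-base mass offset is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AVERAGE = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}
MONO = {"H": 1.0078250319, "C": 12.0, "N": 14.0030740052,
        "O": 15.9949146221, "P": 30.97376151}

# ribonucleoside elemental formulas
_NUCLEOSIDES = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 4},  # adenosine
    "C": {"C": 9, "H": 13, "N": 3, "O": 5},   # cytidine
    "G": {"C": 10, "H": 13, "N": 5, "O": 5},  # guanosine
    "U": {"C": 9, "H": 12, "N": 2, "O": 6},   # uridine
}
_HPO3 = {"H": 1, "P": 1, "O": 3}
_H2O = {"H": 2, "O": 1}

# amino acid residue formulas (residue = amino acid - H2O)
_RESIDUES = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}
_ACETYL = {"C": 2, "H": 2, "O": 1}

_AVG_S = 32.06
_MONO_S = 31.97207069


def _formula_mass(formula: dict, monoisotopic: bool = False) -> float:
    table = MONO if monoisotopic else AVERAGE
    total = 0.0
    for elem, count in formula.items():
        if elem == "S":
            total += (_MONO_S if monoisotopic else _AVG_S) * count
        else:
            total += table[elem] * count
    return total


@dataclass(frozen=True)
class RnaFragment:
    """An RNA oligonucleotide with terminal chemistry and 3' adducts.

    ``five_prime`` is "OH" or "phosphate"; ``three_prime`` is "OH",
    "linear_phosphate" or "cyclic_phosphate".  ``adducts`` is an ordered
    tuple drawn from {"glycyl", "acetyl", "aminoacyl:X"} — an acetyl is
    only valid on top of an aminoacyl (it blocks the amino acid's
    alpha-amino group, not the RNA).
    """

    sequence: str
    five_prime: str = "OH"
    three_prime: str = "OH"
    adducts: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty fragment sequence")
        bad = set(self.sequence.upper()) - set("ACGU")
        if bad:
            raise ValueError(f"non-RNA characters in fragment: {sorted(bad)}")
        if self.five_prime not in ("OH", "phosphate"):
            raise ValueError(f"bad 5' terminus {self.five_prime!r}")
        if self.three_prime not in ("OH", "linear_phosphate", "cyclic_phosphate"):
            raise ValueError(f"bad 3' terminus {self.three_prime!r}")
        has_aa = any(a == "glycyl" or a.startswith("aminoacyl:") for a in self.adducts)
        if "acetyl" in self.adducts and not has_aa:
            raise ValueError("acetyl adduct requires an aminoacyl adduct "
                             "(acetylation is of the amino acid's alpha-amino group)")

    def with_adducts(self, *adducts: str) -> "RnaFragment":
        return RnaFragment(self.sequence, self.five_prime, self.three_prime,
                           self.adducts + tuple(adducts))


def _adduct_mass(adduct: str, monoisotopic: bool) -> float:
    if adduct == "glycyl":
        return _formula_mass(_RESIDUES["G"], monoisotopic)
    if adduct == "acetyl":
        return _formula_mass(_ACETYL, monoisotopic)
    if adduct.startswith("aminoacyl:"):
        aa = adduct.split(":", 1)[1]
        if aa not in _RESIDUES:
            raise ValueError(f"unknown amino acid {aa!r}")
        return _formula_mass(_RESIDUES[aa], monoisotopic)
    raise ValueError(f"unknown adduct {adduct!r}")


def neutral_mass(fragment: RnaFragment, monoisotopic: bool = False) -> float:
    """Neutral average (or monoisotopic) mass of the fragment in Da."""
    seq = fragment.sequence.upper()
    mass = sum(_formula_mass(_NUCLEOSIDES[b], monoisotopic) for b in seq)
    link = _formula_mass(_HPO3, monoisotopic) - _formula_mass(_H2O, monoisotopic)
    mass += (len(seq) - 1) * link
    phos = _formula_mass(_HPO3, monoisotopic)
    if fragment.five_prime == "phosphate":
        mass += phos
    if fragment.three_prime == "linear_phosphate":
        mass += phos
    elif fragment.three_prime == "cyclic_phosphate":
        mass += phos - _formula_mass(_H2O, monoisotopic)
    for adduct in fragment.adducts:
        mass += _adduct_mass(adduct, monoisotopic)
    return mass


def average_mass(fragment: RnaFragment, monoisotopic: bool = False) -> float:
    """MH+ m/z of the fragment (neutral mass plus one hydrogen)."""
    return neutral_mass(fragment, monoisotopic) + (MONO if monoisotopic else AVERAGE)["H"]


def clean_rna(sequence: str) -> str:
    """Normalize a printed RNA sequence: uppercase, strip 5'-/p/-3'
    decoration, read T as unmodified U."""
    seq = sequence.upper().replace("5'-", "").replace("-3'", "").replace("P", "")
    seq = seq.replace("T", "U").replace("’", "")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters after cleanup: {sorted(bad)}")
    return seq


def t1_digest(rna: str, protected_positions=frozenset(),
              native_three_prime: str = "OH") -> list[RnaFragment]:
    """Cleave 3' of every unprotected G, as RNase T1 does.

    ``protected_positions`` are 0-based indices of G residues exempt from
    cleavage (modeling modified or inaccessible guanosines — e.g. the
    internal G of a tRNA's T1-resistant 3'-terminal fragment).  Upstream
    fragments carry a 3' linear phosphate and 5'-OH; the 3'-terminal
    fragment keeps the molecule's native 3' terminus.
    """
    seq = clean_rna(rna)
    for pos in protected_positions:
        if not (0 <= pos < len(seq)) or seq[pos] != "G":
            raise ValueError(f"protected position {pos} is not a G")
    cuts = [i + 1 for i, b in enumerate(seq) if b == "G" and i not in protected_positions]
    starts = [0] + [c for c in cuts if c < len(seq)]
    ends = starts[1:] + [len(seq)]
    fragments = []
    for s, e in zip(starts, ends):
        is_last = e == len(seq)
        fragments.append(RnaFragment(
            seq[s:e], five_prime="OH",
            three_prime=native_three_prime if is_last else "linear_phosphate",
        ))
    return fragments


@dataclass
class MassSpectrumMatch:
    observed_mz: float
    theoretical_mz: float
    delta: float
    fragment: RnaFragment | None
    matched: bool


def match_peaks(observed, candidates, tolerance: float = 1.0) -> list[MassSpectrumMatch]:
    """Match observed MH+ peaks to candidate fragments within tolerance.

    Each observed peak is paired with the candidate of smallest |delta|;
    exact ties resolve to the lower theoretical mass.  Peaks with no
    candidate within tolerance are reported with matched=False.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    cand = list(candidates)
    if not cand:
        raise ValueError("empty candidate list")
    theo = [(average_mass(f), f) for f in cand]
    results = []
    for mz in observed:
        best_mass, best_frag = min(theo, key=lambda t: (abs(mz - t[0]), t[0]))
        delta = mz - best_mass
        results.append(MassSpectrumMatch(
            observed_mz=float(mz), theoretical_mz=best_mass, delta=delta,
            fragment=best_frag, matched=abs(delta) <= tolerance,
        ))
    return results


def modification_series(fragment: RnaFragment) -> pd.DataFrame:
    """MH+ series across the charging/acetylation/hydrolysis cycle.

    Rows: the bare fragment (uncharged tRNA 3' end), + glycyl (after
    glycyl-tRNA synthetase), + glycyl + acetyl (after the GNAT toxin), and
    after peptidyl-tRNA hydrolase (Pth), which removes the blocked
    aminoacyl group and restores the unmodified mass exactly.
    """
    bare = RnaFragment(fragment.sequence, fragment.five_prime, fragment.three_prime, ())
    species = [
        ("unmodified", bare),
        ("glycyl", bare.with_adducts("glycyl")),
        ("acetyl-glycyl", bare.with_adducts("glycyl", "acetyl")),
        ("after_pth", bare),
    ]
    return pd.DataFrame(
        [{"species": name, "mh_plus": average_mass(frag)} for name, frag in species]
    )
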