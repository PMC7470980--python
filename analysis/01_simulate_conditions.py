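#!/usr/bin/env python
"""Generate the paired synthetic Ribo-seq conditions.

Writes a "toxin" dataset (Gly dwell x5, per-codon drop-off q = 0.004) and
a "control" dataset (Ser dwell x2, no drop-off) over a shared set of 40
ORFs at 200k expected footprints each.  Raw footprint tables are large,
so they go under scratch/; downstream steps read them from there.
"""

import pathlib
import sys

from ribopause.pipeline import make_fixtures

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    out = ROOT / "scratch" / "fixtures"
    info = make_fixtures(out, seed=seed)
    for label, path in info["datasets"].items():
        n = sum(1 for _ in open(path / "alignments.tsv")) - 2
        print(f"{label}: {n} footprints -> {path}")
    print("shared annotations:", info["annotations"])


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
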