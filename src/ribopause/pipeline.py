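"""End-to-end orchestration: paired-condition Ribo-seq analysis from
aligned footprints to pause tables and the compositional metagene test.

Stages: read inputs -> length-filter reads -> 3'-end densities -> ORF
filters -> paired ORF intersection -> A-site offset calibration -> pause
scores and codon/amino-acid tables -> 10-bin compositions, geometric-mean
profiles, ilr, paired Hotelling T^2, Mardia normality check.  All outputs
are TSV with a provenance comment line; a manifest records the config
hash, package version, ilr basis and calibrated offset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import (
    read_annotations, read_alignments, filter_reads_by_length,
    compute_density, filter_orfs, intersect_conditions,
)
from .genome import write_filter_report
from .pause import (
    calibrate_offset, codon_pause_table, pause_scores, write_metagene_profiles,
)
from .composition import (
    bin_composition, replace_zeros, geometric_mean_profile,
    ilr_basis, ilr_transform, paired_hotelling, normality_check,
)
from . import simulate


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    annotations: str = ""
    genome: str = ""
    alignments_a: str = ""   # condition A, e.g. toxin
    alignments_b: str = ""   # condition B, e.g. control
    label_a: str = "toxin"
    label_b: str = "control"
    min_read_len: int = 15
    max_read_len: int = 40
    min_orf_len: int = 170
    min_density_per_codon: float = 1.0
    trim5: int = 50
    trim3: int = 20
    n_bins: int = 10
    alpha: float = 0.01
    offset: int | str = "auto"   # nt, or "auto" to calibrate
    candidate_range: tuple[int, int] = (5, 20)
    basis: str = "pivot-1"
    mass_tolerance: float = 1.0
    top_n: int | None = None
    seed: int = 0
    out_dir: str = "results/pipeline"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("min_read_len", "max_read_len", "min_orf_len", "n_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _analyze_condition(label, aln_path, orfs, cfg):
    alignments = read_alignments(aln_path)
    kept, read_report = filter_reads_by_length(alignments, cfg.min_read_len, cfg.max_read_len)
    tracks = compute_density(kept, orfs)
    included, windows, orf_report = filter_orfs(
        tracks, orfs, cfg.min_orf_len, cfg.min_density_per_codon, cfg.trim5, cfg.trim3
    )
    return {
        "label": label, "tracks": tracks, "included": included,
        "windows": windows, "read_report": read_report, "orf_report": orf_report,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the paired analysis; returns the result bundle and writes TSVs."""
    if not cfg.alignments_a or not cfg.alignments_b:
        raise StageError(
            "inputs: both condition alignment tables are required — the "
            "compositional comparison is a paired test"
        )
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"ribopause {__version__} config={cfg.config_hash()}"

    def _write(df: pd.DataFrame, name: str):
        with open(out / name, "w") as fh:
            fh.write(f"# {stamp}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    try:
        orfs = read_annotations(cfg.annotations, cfg.genome)
    except Exception as exc:
        raise StageError(f"annotations: {exc}") from exc

    conds = {}
    for label, path in ((cfg.label_a, cfg.alignments_a), (cfg.label_b, cfg.alignments_b)):
        try:
            conds[label] = _analyze_condition(label, path, orfs, cfg)
        except Exception as exc:
            raise StageError(f"density[{label}]: {exc}") from exc

    paired = intersect_conditions(
        conds[cfg.label_a]["included"], conds[cfg.label_b]["included"]
    )
    if not paired:
        raise StageError("intersect: no ORF passes the filters in both conditions")

    # A-site offset: calibrate on condition B (the control-like condition)
    # unless a fixed offset was configured
    if cfg.offset == "auto":
        try:
            ref = conds[cfg.label_b]
            cal_tracks = {oid: ref["tracks"][oid] for oid in ref["included"]}
            lo, hi = cfg.candidate_range
            cal = calibrate_offset(cal_tracks, orfs, range(lo, hi + 1))
            offset = cal.offset
        except Exception as exc:
            raise StageError(f"calibration: {exc}") from exc
    else:
        offset = int(cfg.offset)
        cal = None
    if cal is not None:
        write_metagene_profiles(
            [cal.start_profile, cal.stop_profile],
            out / "metagene_profiles.tsv", comment=stamp,
        )
    for label, cond in conds.items():
        write_filter_report(cond["read_report"], out / f"filter_reads_{label}.tsv", stamp)
        write_filter_report(cond["orf_report"], out / f"filter_orfs_{label}.tsv", stamp)

    results = {"orfs": orfs, "paired_ids": paired, "offset": offset,
               "calibration": cal, "conditions": conds}

    # pause scores and codon tables
    for label, cond in conds.items():
        profiles = {}
        for oid in cond["included"]:
            profiles[oid] = pause_scores(cond["tracks"][oid], cond["windows"][oid])
        cond["profiles"] = profiles
        table = codon_pause_table(profiles, orfs, offset, top_n=cfg.top_n)
        cond["codon_table"] = table
        _write(table, f"codon_pause_{label}.tsv")

    # compositional comparison on paired ORFs
    basis = ilr_basis(cfg.n_bins, cfg.basis)
    comp_rows, ilr_by_label = [], {}
    for label in (cfg.label_a, cfg.label_b):
        cond = conds[label]
        comps = np.array([
            replace_zeros(bin_composition(cond["tracks"][oid], cond["windows"][oid], cfg.n_bins))
            for oid in paired
        ])
        ilr_by_label[label] = ilr_transform(comps, basis)
        cond["compositions"] = comps
        for oid, parts in zip(paired, comps):
            comp_rows.append({"orf_id": oid, "condition": label,
                              **{f"bin{j+1}": v for j, v in enumerate(parts)}})
        gm = geometric_mean_profile(comps)
        cond["gmean_profile"] = gm
    _write(pd.DataFrame(comp_rows), "compositions.tsv")
    _write(pd.DataFrame({
        "bin": np.arange(1, cfg.n_bins + 1),
        cfg.label_a: conds[cfg.label_a]["gmean_profile"],
        cfg.label_b: conds[cfg.label_b]["gmean_profile"],
    }), "gmean_profiles.tsv")

    try:
        hot = paired_hotelling(ilr_by_label[cfg.label_a], ilr_by_label[cfg.label_b])
    except Exception as exc:
        raise StageError(f"hotelling: {exc}") from exc
    normality = {
        label: normality_check(coords) for label, coords in ilr_by_label.items()
    }
    results.update(hotelling=hot, normality=normality)
    _write(pd.DataFrame([{
        "T2": hot.T2, "F": hot.F, "df1": hot.df1, "df2": hot.df2,
        "p_value": hot.p_value, "n_pairs": hot.n_pairs,
        "reject_at_alpha": hot.p_value < cfg.alpha, "alpha": cfg.alpha,
        "basis_id": cfg.basis,
    }]), "hotelling.tsv")

    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "basis_id": cfg.basis,
        "offset": offset,
        "offset_source": "calibrated" if cfg.offset == "auto" else "configured",
        "n_paired_orfs": len(paired),
        "hotelling_p": hot.p_value,
        "filters": {
            label: {
                "reads_in": cond["read_report"].n_reads_in,
                "reads_kept": cond["read_report"].n_reads_kept,
                "orfs_in": cond["orf_report"].n_orfs_in,
                "orfs_kept": cond["orf_report"].n_orfs_kept,
            }
            for label, cond in conds.items()
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    results["manifest"] = manifest
    return results


def make_fixtures(out_dir, seed: int = 0, n_orfs: int = 40, depth: int = 200_000) -> dict:
    """Generate the paired toxin/control fixture datasets used by tests.

    Toxin: Gly dwell x5 with per-codon drop-off q = 0.004 (elongation
    arrest at Gly plus 3'-ward density decline).  Control: Ser dwell x2
    ('hungry' Ser codons during harvest), no drop-off.  Both share the
    same ORF set.  Idempotent for a fixed seed.
    """
    out = pathlib.Path(out_dir)
    base = simulate.SimulationConfig(seed=seed, n_orfs=n_orfs, depth=depth)
    orfs, genome = simulate.generate_orfs(base)
    datasets = {}
    scenarios = {
        "toxin": simulate.gly_stall_config(
            5.0, seed=seed + 1, n_orfs=n_orfs, depth=depth, dropoff_per_codon=0.004),
        "control": simulate.ser_stall_config(
            2.0, seed=seed + 2, n_orfs=n_orfs, depth=depth),
    }
    for label, cfg in scenarios.items():
        rng = np.random.default_rng(cfg.seed)
        alignments, truth = simulate.simulate_footprints(orfs, cfg, rng)
        d = out / label
        simulate.write_dataset(d, orfs, genome, alignments, truth, cfg)
        datasets[label] = d
    return {"orf_dir": out, "datasets": datasets,
            "annotations": out / "toxin" / "orfs.tsv",
            "genome": out / "toxin" / "genome.fa"}
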