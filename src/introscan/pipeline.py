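"""Config-driven orchestration: filter -> windows -> introgression -> classify.

A single YAML config is the only entry point; rerunning the same config
reproduces byte-identical TSV/BED outputs (floats are formatted with a
fixed ``%.6g`` representation and stage order is fixed).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import classify_windows, decile_summary, associate_genes, intersect_candidates, read_genes
from .intervals import IntervalSet
from .introgression import genome_d, strong_regions, window_d_fd
from .vcfio import filter_variants, population_frequencies, read_vcf
from .windows import WindowSpec, combine_window_stats, window_fst, window_pi

log = logging.getLogger("introscan")

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Everything one scan needs; serializes losslessly to/from YAML."""

    vcf: str
    pop_table: str
    roles: dict  # role P1/P2/P3/O -> population label
    out_dir: str
    genes: str | None = None
    loci: str | None = None
    candidate_sets: dict = field(default_factory=dict)  # name -> path (one id/line)
    window_size_bp: int = 50_000
    window_step_bp: int = 5_000
    maf_min: float = 0.05
    max_missing: float = 0.10
    qual_min: float = 30.0
    depth_min: float = 4.0
    depth_max: float = 100.0
    min_informative: int = 5
    top_fst_fraction: float = 0.05
    tail_ratio_fraction: float = 0.05
    top_fd_fraction: float = 0.01
    flank_bp: int = 2_000
    chrom_lengths: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("top_fst_fraction", "tail_ratio_fraction", "top_fd_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 0.5:
                raise ValueError(f"{name} must be in (0, 0.5], got {v}")

    def validate_paths(self) -> None:
        for p in [self.vcf, self.pop_table, self.genes, self.loci, *self.candidate_sets.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full scan; returns (and writes) the run manifest.

    Stage order: read -> filter -> window pi/FST -> introgression ->
    classification -> deciles -> strong regions -> gene association ->
    candidate intersection.  Any stage error aborts with the stage name
    recorded in a partial manifest.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "warnings": [],
    }
    spec = WindowSpec(config.window_size_bp, config.window_step_bp)
    lengths = {str(k): int(v) for k, v in config.chrom_lengths.items()} or None
    stage = "read"
    try:
        panel = read_vcf(config.vcf, config.pop_table)
        manifest["stages"]["read"] = {
            "n_sites": panel.n_sites,
            "n_samples": panel.n_samples,
            "dropped": getattr(panel, "dropped_records", {}),
        }
        log.info("read: %d sites x %d samples", panel.n_sites, panel.n_samples)

        stage = "filter"
        panel, report = filter_variants(
            panel, config.maf_min, config.max_missing,
            config.qual_min, config.depth_min, config.depth_max,
        )
        _write_tsv(report.to_frame(), out / "filter_report.tsv")
        manifest["stages"]["filter"] = {
            "kept": report.n_kept, "dropped": report.dropped, "skipped": report.skipped,
        }
        manifest["warnings"] += [f"{s} filter skipped (field absent)" for s in report.skipped]
        log.info("filter: kept %d/%d sites", report.n_kept, report.n_input)

        stage = "windows"
        pop1, pop2 = config.roles["P1"], config.roles["P2"]
        pi1 = window_pi(panel, pop1, spec, lengths)
        pi2 = window_pi(panel, pop2, spec, lengths)
        fst = window_fst(panel, pop1, pop2, spec, lengths)
        wstats = combine_window_stats(pi1, pi2, fst, pop1, pop2)
        n = _write_tsv(wstats, out / "window_stats.tsv")
        manifest["stages"]["windows"] = {"n_windows": n}
        log.info("windows: %d windows", n)

        stage = "introgression"
        freqs = population_frequencies(panel, config.roles)
        fd_win = window_d_fd(freqs, spec, config.min_informative, lengths)
        _write_tsv(fd_win, out / "introgression_windows.tsv")
        summary = genome_d(freqs)
        (out / "genome_d.json").write_text(json.dumps(summary, sort_keys=True))
        manifest["stages"]["introgression"] = {
            "n_windows": len(fd_win),
            "n_ok": int((fd_win["status"] == "OK").sum()),
            "genome_D": summary["D"],
        }
        log.info("introgression: %d windows, D=%.4f", len(fd_win), summary["D"])

        stage = "classify"
        type1, type2, creport = classify_windows(
            wstats.rename(columns={f"pi_{pop1}": "pi_P1", f"pi_{pop1}_valid": "pi_P1_valid",
                                   f"pi_{pop2}": "pi_P2", f"pi_{pop2}_valid": "pi_P2_valid"}),
            "P1", "P2", config.top_fst_fraction, config.tail_ratio_fraction,
        )
        type1.to_bed(out / "type1.bed")
        type2.to_bed(out / "type2.bed")
        (out / "classify_report.json").write_text(json.dumps(creport, sort_keys=True))
        manifest["stages"]["classify"] = creport

        stage = "deciles"
        deciles, rho = decile_summary(wstats, fd_win)
        _write_tsv(deciles, out / "decile_summary.tsv")
        manifest["stages"]["deciles"] = {"spearman_rho": rho}

        stage = "strong_regions"
        strong = strong_regions(fd_win, config.top_fd_fraction)
        strong.to_bed(out / "strong_introgression.bed")
        manifest["stages"]["strong_regions"] = {
            "n_intervals": len(strong), "total_bp": strong.total_span(),
        }

        stage = "associate"
        if config.genes:
            genes = read_genes(config.genes)
            assoc = {
                "type1": sorted(associate_genes(type1, genes, config.flank_bp)),
                "type2": sorted(associate_genes(type2, genes, config.flank_bp)),
                "strong_introgression": sorted(
                    associate_genes(strong, genes, config.flank_bp)
                ),
            }
            (out / "gene_association.json").write_text(json.dumps(assoc, sort_keys=True))
            manifest["stages"]["associate"] = {k: len(v) for k, v in assoc.items()}

            named_sets = {
                "differentiated": set(assoc["type1"]) | set(assoc["type2"]),
                "introgressed": set(assoc["strong_introgression"]),
            }
            for name, path in config.candidate_sets.items():
                named_sets[name] = {
                    ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
                }
            if len(named_sets) >= 2:
                venn = intersect_candidates(named_sets)
                (out / "venn_report.json").write_text(json.dumps(venn, sort_keys=True))
                manifest["stages"]["intersect"] = {
                    "full_count": venn["full"]["count"],
                }
    except Exception as exc:  # record the failing stage, then re-raise
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (Path(config.out_dir) / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, default=str)
        )
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, default=str))
    return manifest
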