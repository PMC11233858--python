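"""Four-population genotype simulator with known drift and introgression.

The generator emulates the statistical structure assumed by the four-taxon
scan (((P1, P2), P3), O): per-site ancestral allele frequencies shared by
all populations, per-population drift under the Balding-Nichols model, and
windowed donor->P2 introgression at a known admixture fraction.  Because
Balding-Nichols drift has a closed-form variance decomposition, every
downstream statistic (pi, Weir-Cockerham FST, Patterson's D, f_d) has a
known expectation, which is what makes quantitative recovery tests possible
without an external coalescent simulator.

Default conditions mirror the blueberry resequencing panel the scan was
designed around: P1 = northern highbush (81 accessions), P2 = southern
highbush (82, after excluding one admixed accession), P3 = a donor species
panel (15), O = cranberry outgroup (12); ~6.62 SNPs/kb; weak P1/P2
differentiation (drift_F = 0.04 each, giving a pairwise Weir-Cockerham
expectation of ~0.04) and a strongly drifted donor (drift_F = 0.3).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .panel import GenotypePanel

POPS = ("P1", "P2", "P3", "O")


@dataclass
class SimConfig:
    """Parameters of one simulated panel; identical config => identical output."""

    n_chromosomes: int = 4
    chrom_length_bp: int = 2_000_000
    snp_density: float = 6.62  # SNPs per kb
    n_samples: dict = field(
        default_factory=lambda: {"P1": 81, "P2": 82, "P3": 15, "O": 12}
    )
    drift_F: dict = field(
        default_factory=lambda: {"P1": 0.04, "P2": 0.04, "P3": 0.3, "O": 0.0}
    )
    #: half-open bp intervals (chrom, start, end) with donor->P2 admixture
    introgressed_windows: list = field(default_factory=list)
    admixture_f: float = 0.0
    missing_rate: float = 0.03
    seed: int = 0
    #: "fixed_ancestral": O monomorphic for the ancestral allele (pO = 0);
    #: "drifted": O drawn from Balding-Nichols with drift_F["O"].
    outgroup_mode: str = "fixed_ancestral"
    #: windows where one population's drift is locally elevated, emulating
    #: localized differentiation (e.g. a selective sweep in the recipient's
    #: sister group); same (chrom, start, end) convention.
    elevated_drift_windows: list = field(default_factory=list)
    elevated_drift_F: float = 0.3
    elevated_drift_pop: str = "P1"
    #: False: mixture at the frequency level (p2' = (1-f) p2 + f p3);
    #: True: each P2 allele draw comes from p3 with probability f.
    haplotype_mode: bool = False

    def __post_init__(self) -> None:
        for name, v in (("admixture_f", self.admixture_f), ("missing_rate", self.missing_rate)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for pop in POPS:
            if self.n_samples.get(pop, 0) < 2:
                raise ValueError(f"population {pop} needs >= 2 samples")
            F = self.drift_F.get(pop, 0.0)
            if not 0.0 <= F < 1.0:
                raise ValueError(f"drift_F[{pop}] must be in [0, 1), got {F}")
        if not 0.0 <= self.elevated_drift_F < 1.0:
            raise ValueError("elevated_drift_F must be in [0, 1)")
        if self.outgroup_mode not in ("fixed_ancestral", "drifted"):
            raise ValueError(f"unknown outgroup_mode {self.outgroup_mode!r}")
        for windows in (self.introgressed_windows, self.elevated_drift_windows):
            for c, s, e in windows:
                if not (0 <= s < e <= self.chrom_length_bp):
                    raise ValueError(f"window {c}:{s}-{e} outside chromosome bounds")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("introgressed_windows", "elevated_drift_windows"):
            d[key] = [tuple(w) for w in d.get(key, [])]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulation: the frequencies every statistic sees.

    ``pop_freqs[pop][chrom]`` is the per-site post-drift (and, for P2,
    post-introgression) allele frequency; ``positions[chrom]`` the 1-based
    site positions.
    """

    config: SimConfig
    positions: dict
    ancestral: dict
    pop_freqs: dict

    def sites_in_window(self, chrom: str, start: int, end: int) -> np.ndarray:
        pos = self.positions[chrom]
        return (pos > start) & (pos <= end)  # 1-based pos vs half-open bp window

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "positions": {c: p.tolist() for c, p in self.positions.items()},
            "ancestral": {c: a.tolist() for c, a in self.ancestral.items()},
            "pop_freqs": {
                pop: {c: f.tolist() for c, f in by_chrom.items()}
                for pop, by_chrom in self.pop_freqs.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            config=SimConfig.from_dict(d["config"]),
            positions={c: np.asarray(p, dtype=np.int64) for c, p in d["positions"].items()},
            ancestral={c: np.asarray(a) for c, a in d["ancestral"].items()},
            pop_freqs={
                pop: {c: np.asarray(f) for c, f in by_chrom.items()}
                for pop, by_chrom in d["pop_freqs"].items()
            },
        )


def _balding_nichols(rng: np.random.Generator, x: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Beta(x(1-F)/F, (1-x)(1-F)/F) draws; F = 0 means no drift (freq = x)."""
    F = np.broadcast_to(np.asarray(F, dtype=float), x.shape)
    out = x.copy()
    drift = F > 0.0
    if np.any(drift):
        ratio = (1.0 - F[drift]) / F[drift]
        out[drift] = rng.beta(x[drift] * ratio, (1.0 - x[drift]) * ratio)
    return out


def simulate_frequencies(config: SimConfig) -> SimTruth:
    """Draw ancestral and per-population site frequencies for every chromosome.

    Ancestral frequencies are Uniform(0.05, 0.95) (segregating in the
    ancestor, the regime where the four-taxon statistics are informative);
    site positions are uniform along each chromosome at the configured
    density.  Within introgressed windows the P2 frequency is replaced by
    the mixture (1-f) p2 + f p3.
    """
    rng = np.random.default_rng(config.seed)
    n_sites = int(round(config.chrom_length_bp / 1000.0 * config.snp_density))
    positions: dict = {}
    ancestral: dict = {}
    pop_freqs: dict = {pop: {} for pop in POPS}

    intro_by_chrom: dict[str, list] = {}
    for c, s, e in config.introgressed_windows:
        intro_by_chrom.setdefault(c, []).append((s, e))
    elev_by_chrom: dict[str, list] = {}
    for c, s, e in config.elevated_drift_windows:
        elev_by_chrom.setdefault(c, []).append((s, e))

    for chrom in config.chrom_names():
        pos = np.sort(rng.choice(config.chrom_length_bp, size=n_sites, replace=False)) + 1
        x = rng.uniform(0.05, 0.95, size=pos.size)
        positions[chrom] = pos
        ancestral[chrom] = x

        elevated = np.zeros(pos.size, dtype=bool)
        for s, e in elev_by_chrom.get(chrom, []):
            elevated |= (pos > s) & (pos <= e)

        for pop in POPS:
            if pop == "O" and config.outgroup_mode == "fixed_ancestral":
                pop_freqs[pop][chrom] = np.zeros(pos.size)
                continue
            F = np.full(pos.size, config.drift_F.get(pop, 0.0))
            if pop == config.elevated_drift_pop:
                F[elevated] = config.elevated_drift_F
            pop_freqs[pop][chrom] = _balding_nichols(rng, x, F)

        if config.admixture_f > 0.0 and not config.haplotype_mode:
            mixed = np.zeros(pos.size, dtype=bool)
            for s, e in intro_by_chrom.get(chrom, []):
                mixed |= (pos > s) & (pos <= e)
            f = config.admixture_f
            p2, p3 = pop_freqs["P2"][chrom], pop_freqs["P3"][chrom]
            pop_freqs["P2"][chrom] = np.where(mixed, (1.0 - f) * p2 + f * p3, p2)

    return SimTruth(config=config, positions=positions, ancestral=ancestral, pop_freqs=pop_freqs)


def simulate_genotypes(truth: SimTruth) -> GenotypePanel:
    """Draw diploid genotypes: two Bernoulli allele draws per sample per site.

    A fresh generator seeded from the config seed keeps genotype draws
    reproducible given the truth.  In haplotype mode each P2 allele copy
    inside an introgressed window is drawn from the donor frequency with
    probability f, which preserves the marginal mixture frequency while
    adding within-window LD.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples: list[str] = []
    sample_pops: dict[str, str] = {}
    for pop in POPS:
        for i in range(config.n_samples[pop]):
            name = f"{pop}_{i:03d}"
            samples.append(name)
            sample_pops[name] = pop

    intro_by_chrom: dict[str, list] = {}
    for c, s, e in config.introgressed_windows:
        intro_by_chrom.setdefault(c, []).append((s, e))

    chrom_arrs, pos_arrs, geno_arrs = [], [], []
    for chrom in config.chrom_names():
        pos = truth.positions[chrom]
        cols = []
        for pop in POPS:
            n = config.n_samples[pop]
            p = truth.pop_freqs[pop][chrom]
            if config.haplotype_mode and pop == "P2" and config.admixture_f > 0.0:
                mixed = np.zeros(pos.size, dtype=bool)
                for s, e in intro_by_chrom.get(chrom, []):
                    mixed |= (pos > s) & (pos <= e)
                p3 = truth.pop_freqs["P3"][chrom]
                g = np.zeros((pos.size, n), dtype=np.int8)
                for _copy in range(2):
                    donor = rng.random((pos.size, n)) < config.admixture_f
                    donor &= mixed[:, None]
                    src = np.where(donor, p3[:, None], p[:, None])
                    g += (rng.random((pos.size, n)) < src).astype(np.int8)
            else:
                g = rng.binomial(2, p[:, None], size=(pos.size, n)).astype(np.int8)
            cols.append(g)
        geno = np.concatenate(cols, axis=1)
        if config.missing_rate > 0.0:
            geno[rng.random(geno.shape) < config.missing_rate] = -1
        chrom_arrs.append(np.full(pos.size, chrom, dtype=object))
        pos_arrs.append(pos)
        geno_arrs.append(geno)

    return GenotypePanel(
        chrom=np.concatenate(chrom_arrs),
        pos=np.concatenate(pos_arrs),
        geno=np.concatenate(geno_arrs, axis=0),
        qual=np.full(sum(p.size for p in pos_arrs), 100.0),
        samples=samples,
        sample_pops=sample_pops,
    )


def write_vcf_fixture(panel: GenotypePanel, path) -> Path:
    """Write the panel as a minimal VCF 4.2 (GT-only FORMAT unless depth set).

    The writer is deterministic byte-for-byte for a given panel, so a fixed
    SimConfig reproduces an identical file.
    """
    if panel.n_sites == 0:
        raise ValueError("refusing to write an empty panel")
    path = Path(path)
    gt_map = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    has_depth = panel.depth is not None
    fmt = "GT:DP" if has_depth else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        lengths: dict[str, int] = {}
        for c, p in zip(panel.chrom, panel.pos):
            lengths[c] = max(lengths.get(c, 0), int(p))
        for c, ln in lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for i in range(panel.n_sites):
            q = panel.qual[i]
            qual = "." if np.isnan(q) else f"{q:g}"
            calls = []
            for j in range(panel.n_samples):
                gt = gt_map[int(panel.geno[i, j])]
                if has_depth:
                    d = panel.depth[i, j]
                    gt += ":." if np.isnan(d) else f":{int(d)}"
                calls.append(gt)
            fh.write(
                f"{panel.chrom[i]}\t{panel.pos[i]}\t.\tA\tT\t{qual}\tPASS\t.\t{fmt}\t"
                + "\t".join(calls)
                + "\n"
            )
    return path


def write_population_table(panel: GenotypePanel, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s in panel.samples:
            fh.write(f"{s}\t{panel.sample_pops[s]}\n")
    return path


def emit_fixture(config: SimConfig, outdir) -> dict:
    """simulate -> write VCF + population TSV + truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_frequencies(config)
    panel = simulate_genotypes(truth)
    paths = {
        "vcf": str(write_vcf_fixture(panel, outdir / "panel.vcf")),
        "pop_table": str(write_population_table(panel, outdir / "populations.tsv")),
        "truth": str(outdir / "truth.json"),
    }
    truth.to_json(outdir / "truth.json")
    return paths
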