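"""Read multi-sample VCFs into genotype panels; SNP filters; role frequencies."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import GenotypePanel, SiteFrequencies

# cyvcf2 gt_types coding: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_TO_DOSAGE = np.array([0, 1, -1, 2], dtype=np.int8)


def read_population_table(path) -> dict[str, str]:
    """Two-column TSV (sample_id, population); header row optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"population table {path} needs two tab-separated columns")
    if df.iloc[0, 0] == "sample_id":
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_vcf(path, pop_table) -> GenotypePanel:
    """Load biallelic SNP records; multiallelic sites and indels are dropped.

    ``pop_table`` may be a path to a sample->population TSV or a mapping.
    Every VCF sample must have a population label; extra table rows only
    trigger a warning.  Genotypes are coded as alternate-allele dosage with
    phase ignored.
    """
    pops = pop_table if isinstance(pop_table, dict) else read_population_table(pop_table)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unlabeled = [s for s in samples if s not in pops]
    if unlabeled:
        raise ValueError(f"VCF samples absent from population table: {unlabeled[:5]}")
    extra = set(pops) - set(samples)
    if extra:
        warnings.warn(f"{len(extra)} population-table rows not present in VCF")

    chrom, pos, qual, geno, depth = [], [], [], [], []
    dropped = {"multiallelic": 0, "indel": 0}
    any_depth = False
    for v in vcf:
        if len(v.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.ALT[0] not in "ACGT":
            dropped["indel"] += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        qual.append(np.nan if v.QUAL is None else float(v.QUAL))
        geno.append(_GT_TO_DOSAGE[np.asarray(v.gt_types)])
        try:
            dp = v.format("DP")
        except KeyError:  # DP not declared in the header
            dp = None
        if dp is not None:
            any_depth = True
            dp = dp.astype(float).reshape(-1)
            dp[dp < 0] = np.nan  # cyvcf2 encodes missing DP as negative
            depth.append(dp)
        else:
            depth.append(np.full(len(samples), np.nan))
    if not chrom:
        raise ValueError(f"no biallelic SNP records in {path}")

    panel = GenotypePanel(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        geno=np.vstack(geno),
        qual=np.array(qual, dtype=float),
        samples=samples,
        sample_pops={s: pops[s] for s in samples},
        depth=np.vstack(depth) if any_depth else None,
    )
    panel.dropped_records = dropped  # type: ignore[attr-defined]
    return panel


@dataclass
class FilterReport:
    """Per-criterion drop counts from one filtering pass."""

    n_input: int
    n_kept: int
    dropped: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input), ("kept", self.n_kept)]
        rows += [(f"dropped_{k}", v) for k, v in self.dropped.items()]
        return pd.DataFrame(rows, columns=["metric", "count"])


def filter_variants(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    qual_min: float = 30.0,
    depth_min: float = 4.0,
    depth_max: float = 100.0,
) -> tuple[GenotypePanel, FilterReport]:
    """Apply the standard SNP quality filters, pooled over all samples.

    Retains sites with minor allele frequency > ``maf_min`` (over all called
    alleles, samples pooled), missing-genotype fraction < ``max_missing``,
    QUAL > ``qual_min``, and mean site depth strictly inside
    (``depth_min``, ``depth_max``).  Each criterion is evaluated on the
    input panel independently, so the surviving set does not depend on the
    order of application.  A criterion whose source field is absent (no
    depth, no QUAL) is skipped with a warning and recorded in the report.
    """
    n = panel.n_sites
    masks: dict[str, np.ndarray] = {}
    skipped: list[str] = []

    alt, called = panel.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    masks["maf"] = (called > 0) & (maf > maf_min)

    missing_frac = (panel.geno < 0).mean(axis=1)
    masks["missing"] = missing_frac < max_missing

    if np.isnan(panel.qual).all():
        skipped.append("qual")
    else:
        masks["qual"] = panel.qual > qual_min

    if panel.depth is None or np.isnan(panel.depth).all():
        skipped.append("depth")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_depth = np.nanmean(panel.depth, axis=1)
        masks["depth"] = (mean_depth > depth_min) & (mean_depth < depth_max)
    for name in skipped:
        warnings.warn(f"{name} field absent; {name} filter skipped")

    keep = np.ones(n, dtype=bool)
    for m in masks.values():
        keep &= m
    report = FilterReport(
        n_input=n,
        n_kept=int(keep.sum()),
        dropped={k: int((~m).sum()) for k, m in masks.items()},
        skipped=skipped,
    )
    return panel.take_sites(keep), report


def population_frequencies(panel: GenotypePanel, roles: dict[str, str]) -> SiteFrequencies:
    """Per-site alternate-allele frequencies for the P1/P2/P3/O roles.

    ``roles`` maps each role name to a population label of the panel.
    Frequencies are computed over called alleles only; sites where any role
    has fewer than two called alleles are flagged unusable for D/f_d.
    """
    for role in ("P1", "P2", "P3", "O"):
        if role not in roles:
            raise ValueError(f"role {role} not assigned")
    freqs, counts = {}, {}
    for role, pop in roles.items():
        idx = panel.sample_indices(pop)
        alt, called = panel.allele_counts(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[role] = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
        counts[role] = called
    return SiteFrequencies(
        chrom=panel.chrom,
        pos=panel.pos,
        p1=freqs["P1"],
        p2=freqs["P2"],
        p3=freqs["P3"],
        pO=freqs["O"],
        n1=counts["P1"],
        n2=counts["P2"],
        n3=counts["P3"],
        nO=counts["O"],
    )
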