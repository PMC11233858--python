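"""Outlier-interval classification and downstream association logic.

Type 1 intervals are windows in the top tail of FST that also sit in the
top tail of the P2/P1 nucleotide-diversity ratio (differentiation with a
diversity gain in P2, the signature expected under donor introgression);
Type 2 intervals combine the same FST tail with the bottom ratio tail
(differentiation with diversity loss, the classic sweep signature).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, span_of_windows
from .panel import GenotypePanel


@dataclass
class GeneModel:
    """A gene body; strand is carried but association is strand-agnostic."""

    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")


def _nearest_rank_upper(values: np.ndarray, fraction: float) -> float:
    """Value of the k-th largest element, k = ceil(fraction * n)."""
    k = max(1, int(np.ceil(fraction * values.size)))
    return float(np.sort(values)[::-1][k - 1])


def _nearest_rank_lower(values: np.ndarray, fraction: float) -> float:
    k = max(1, int(np.ceil(fraction * values.size)))
    return float(np.sort(values)[k - 1])


def classify_windows(
    windows: pd.DataFrame,
    pop_a: str = "P1",
    pop_b: str = "P2",
    top_fst_fraction: float = 0.05,
    tail_ratio_fraction: float = 0.05,
) -> tuple[IntervalSet, IntervalSet, dict]:
    """Split differentiated windows into Type 1 / Type 2 interval sets.

    ``windows`` is the combined per-window table (see
    :func:`introscan.windows.combine_window_stats`) with columns ``fst``,
    ``pi_<pop_a>``, ``pi_<pop_b>`` and their validity flags.  FST is
    z-scored across valid windows; tails are nearest-rank percentiles of
    the analyzed window set itself, with ties at the cutoff included.  When
    a statistic is constant across windows its tails are empty (no window
    exceeds a degenerate threshold).  Windows where either pi is zero are
    excluded from the ratio tails (log2 undefined) and counted separately;
    they remain eligible for the FST tail.

    Returns (Type1 IntervalSet, Type2 IntervalSet, report).  The report
    carries both merged-interval spans and summed-window spans, plus the
    z-score and log2-ratio thresholds actually used.
    """
    ca, cb = f"pi_{pop_a}", f"pi_{pop_b}"
    valid = (
        windows["fst_valid"].fillna(False).astype(bool)
        & windows[f"{ca}_valid"].fillna(False).astype(bool)
        & windows[f"{cb}_valid"].fillna(False).astype(bool)
        & np.isfinite(windows["fst"])
    )
    w = windows[valid].reset_index(drop=True)
    if len(w) < 20:
        raise ValueError(f"only {len(w)} valid windows; percentiles are meaningless")

    fst = w["fst"].to_numpy(dtype=float)
    mu, sd = fst.mean(), fst.std(ddof=0)
    z = (fst - mu) / sd if sd > 0 else np.zeros_like(fst)
    if sd > 0:
        fst_cut = _nearest_rank_upper(fst, top_fst_fraction)
        top_fst = fst >= fst_cut
        z_cut = (fst_cut - mu) / sd
    else:  # constant FST: degenerate threshold, empty tail
        top_fst = np.zeros(len(w), dtype=bool)
        z_cut = float("nan")

    ratio_ok = (w[ca].to_numpy() > 0) & (w[cb].to_numpy() > 0)
    n_ratio_excluded = int((~ratio_ok).sum())
    log2r = np.full(len(w), np.nan)
    log2r[ratio_ok] = np.log2(w[cb].to_numpy()[ratio_ok] / w[ca].to_numpy()[ratio_ok])
    rvals = log2r[ratio_ok]
    if rvals.size and rvals.max() > rvals.min():
        up_cut = _nearest_rank_upper(rvals, tail_ratio_fraction)
        lo_cut = _nearest_rank_lower(rvals, tail_ratio_fraction)
        high_ratio = ratio_ok & (log2r >= up_cut)
        low_ratio = ratio_ok & (log2r <= lo_cut) & ~(log2r >= up_cut)
    else:
        up_cut = lo_cut = float("nan")
        high_ratio = low_ratio = np.zeros(len(w), dtype=bool)

    type1_mask = top_fst & high_ratio
    type2_mask = top_fst & low_ratio
    to_raw = lambda m: list(
        zip(w["chrom"][m], w["start"][m].astype(int), w["end"][m].astype(int))
    )
    type1 = IntervalSet.from_raw(to_raw(type1_mask), "Type1")
    type2 = IntervalSet.from_raw(to_raw(type2_mask), "Type2")
    report = {
        "n_valid_windows": int(len(w)),
        "n_ratio_excluded_zero_pi": n_ratio_excluded,
        "fst_z_threshold": float(z_cut),
        "log2_ratio_upper": float(up_cut),
        "log2_ratio_lower": float(lo_cut),
        "n_type1_windows": int(type1_mask.sum()),
        "n_type2_windows": int(type2_mask.sum()),
        "type1_merged_bp": type1.total_span(),
        "type2_merged_bp": type2.total_span(),
        "type1_summed_window_bp": span_of_windows(to_raw(type1_mask)),
        "type2_summed_window_bp": span_of_windows(to_raw(type2_mask)),
    }
    return type1, type2, report


def decile_summary(windows: pd.DataFrame, fd_windows: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Bin windows into 10 FST deciles (high to low) and summarize f_d per bin.

    Windows are matched to the introgression table by identical
    (chrom, start, end) coordinates, ranked by FST descending, and split
    into 10 equal-count bins (any remainder goes to the first bins).  Each
    bin reports an FST summary and the quartiles of OK-window f_d values.
    The second return value is the Spearman correlation between decile
    index (1 = highest FST) and the bin's median f_d.
    """
    key = ["chrom", "start", "end"]
    merged = windows.merge(fd_windows[key + ["fd", "status"]], on=key, how="left")
    merged = merged[merged["fst_valid"].fillna(False).astype(bool) & np.isfinite(merged["fst"])]
    merged = merged.sort_values(
        ["fst"] + key, ascending=[False, True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(merged)
    q, r = divmod(n, 10)
    sizes = [q + 1] * r + [q] * (10 - r)
    rows, start = [], 0
    for i, size in enumerate(sizes, start=1):
        chunk = merged.iloc[start : start + size]
        start += size
        fd_ok = chunk.loc[chunk["status"] == "OK", "fd"].to_numpy(dtype=float)
        rows.append(
            {
                "decile": i,
                "n_windows": size,
                "fst_mean": chunk["fst"].mean(),
                "fst_median": chunk["fst"].median(),
                "n_fd_ok": fd_ok.size,
                "fd_median": np.median(fd_ok) if fd_ok.size else np.nan,
                "fd_q1": np.percentile(fd_ok, 25) if fd_ok.size else np.nan,
                "fd_q3": np.percentile(fd_ok, 75) if fd_ok.size else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    defined = table["fd_median"].notna()
    if defined.sum() >= 3:
        rho = float(
            stats.spearmanr(table.loc[defined, "decile"], table.loc[defined, "fd_median"]).statistic
        )
    else:
        rho = float("nan")
    return table, rho


def read_genes(path) -> list[GeneModel]:
    """Gene models from BED6 (name in column 4) or GFF3 gene features."""
    genes: list[GeneModel] = []
    with open(str(path)) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 9 and f[3].isdigit():  # GFF3: 1-based inclusive
                if f[2].lower() != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}-{f[4]}"))
                genes.append(GeneModel(gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
            else:  # BED
                gid = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                strand = f[5] if len(f) > 5 else "."
                genes.append(GeneModel(gid, f[0], int(f[1]), int(f[2]), strand))
    return genes


def associate_genes(
    intervals: IntervalSet, genes: list[GeneModel], flank_bp: int = 0
) -> set[str]:
    """Genes whose flank-extended body overlaps >= 1 interval by >= 1 bp."""
    if genes and len(intervals):
        gene_chroms = {g.chrom for g in genes}
        iv_chroms = {c for c, _, _ in intervals}
        if not gene_chroms & iv_chroms:
            raise ValueError(
                "no chromosome name shared between genes and intervals "
                f"(genes: {sorted(gene_chroms)[:3]}..., intervals: {sorted(iv_chroms)[:3]}...)"
            )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    hits = set()
    for g in genes:
        gs, ge = max(0, g.start - flank_bp), g.end + flank_bp
        for s, e in by_chrom.get(g.chrom, []):
            if gs < e and s < ge:
                hits.add(g.gene_id)
                break
    return hits


def intersect_candidates(sets: dict[str, set]) -> dict:
    """Venn-style report over >= 2 named gene-id sets, deterministic order."""
    if len(sets) < 2:
        raise ValueError("need at least two named sets")
    names = sorted(sets)
    report: dict = {"set_sizes": {n: len(sets[n]) for n in names}, "pairwise": {}, "full": {}}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = sorted(sets[a] & sets[b])
            report["pairwise"][f"{a}&{b}"] = {"count": len(inter), "members": inter}
    full = set(sets[names[0]])
    for n in names[1:]:
        full &= sets[n]
    report["full"] = {"count": len(full), "members": sorted(full)}
    return report


def locus_summary(
    panel: GenotypePanel, loci: list[tuple[str, int]], groups: list[str]
) -> pd.DataFrame:
    """Per-locus, per-group genotype-class fractions and allele frequencies.

    Loci absent from the panel are reported with ``found = False`` rather
    than silently skipped; a group with no called genotype at a locus has
    NaN fractions (flagged undefined).
    """
    rows = []
    for chrom, pos in loci:
        idx = np.flatnonzero((panel.chrom == chrom) & (panel.pos == pos))
        for group in groups:
            row = {"chrom": chrom, "pos": pos, "group": group, "found": idx.size > 0}
            if idx.size > 0:
                g = panel.geno[idx[0], panel.sample_indices(group)]
                called = g[g >= 0]
                n = called.size
                if n > 0:
                    row.update(
                        n_called=n,
                        frac_hom_ref=float((called == 0).sum() / n),
                        frac_het=float((called == 1).sum() / n),
                        frac_hom_alt=float((called == 2).sum() / n),
                        alt_freq=float(called.sum() / (2 * n)),
                    )
                else:
                    row.update(
                        n_called=0,
                        frac_hom_ref=np.nan,
                        frac_het=np.nan,
                        frac_hom_alt=np.nan,
                        alt_freq=np.nan,
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def genotype_concordance(
    panel: GenotypePanel, locus_a: tuple[str, int], locus_b: tuple[str, int]
) -> float:
    """Fraction of samples with the same genotype class at two loci.

    Computed over samples called at both loci; supports checking whether
    two nearby variants travel together across the panel.
    """
    ia = np.flatnonzero((panel.chrom == locus_a[0]) & (panel.pos == locus_a[1]))
    ib = np.flatnonzero((panel.chrom == locus_b[0]) & (panel.pos == locus_b[1]))
    if ia.size == 0 or ib.size == 0:
        raise ValueError("locus not found in panel")
    ga, gb = panel.geno[ia[0]], panel.geno[ib[0]]
    both = (ga >= 0) & (gb >= 0)
    if both.sum() == 0:
        return float("nan")
    return float((ga[both] == gb[both]).mean())
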