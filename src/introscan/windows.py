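"""Sliding-window nucleotide diversity, Weir-Cockerham FST, and LD pruning.

Window coordinates are 0-based half-open ``[start, end)`` in bp; a 1-based
variant position ``p`` falls in the window iff ``start < p <= end``.  The
grid starts at the configured anchor and advances by ``step_bp``; a window
is emitted only while its start lies before the chromosome's last variant
position, and terminal windows are truncated at the chromosome end (the
per-bp pi denominator uses the truncated length).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class WindowSpec:
    """50-kb windows sliding in 5-kb steps by default."""

    size_bp: int = 50_000
    step_bp: int = 5_000
    anchor: int = 1  # 1-based position of the first window's first bp

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError("size_bp must be positive")
        if self.step_bp <= 0 or self.step_bp > self.size_bp:
            raise ValueError("need 0 < step_bp <= size_bp")


def window_grid(last_pos: int, spec: WindowSpec, chrom_length: int | None = None) -> np.ndarray:
    """(n_windows, 2) array of [start, end) bounds for one chromosome."""
    chrom_length = int(chrom_length) if chrom_length is not None else int(last_pos)
    first = spec.anchor - 1  # 0-based
    if last_pos <= first:
        return np.empty((0, 2), dtype=np.int64)
    starts = np.arange(first, last_pos, spec.step_bp, dtype=np.int64)
    ends = np.minimum(starts + spec.size_bp, chrom_length)
    keep = ends > starts
    return np.column_stack([starts[keep], ends[keep]])


def _window_sums(pos: np.ndarray, values: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Sum per-site values over each [start, end) window via prefix sums."""
    csum = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    lo = np.searchsorted(pos, bounds[:, 0], side="right")
    hi = np.searchsorted(pos, bounds[:, 1], side="right")
    return csum[hi] - csum[lo]


def _per_chrom(panel: GenotypePanel):
    for chrom in panel.chromosomes:
        mask = panel.chrom == chrom
        yield chrom, np.flatnonzero(mask)


def site_pi(alt: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Per-site pi = 1 - [C(a,2) + C(n-a,2)] / C(n,2) over called alleles.

    Sites with fewer than two called alleles contribute 0.
    """
    n = called.astype(float)
    a = alt.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        same = (a * (a - 1) + (n - a) * (n - a - 1)) / (n * (n - 1))
    pi = 1.0 - same
    pi[called < 2] = 0.0
    return pi


def window_pi(
    panel: GenotypePanel,
    population: str,
    spec: WindowSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed nucleotide diversity for one population.

    The window value is the sum of per-site pi divided by the window length
    in bp (monomorphic and unobserved positions contribute zero), matching
    the per-bp convention of the standard windowed-scan tools.  Windows with
    no called site are flagged invalid.
    """
    spec = spec or WindowSpec()
    idx = panel.sample_indices(population)
    if idx.size < 2:
        raise ValueError(f"population {population!r} needs >= 2 samples for pi")
    alt, called = panel.allele_counts(idx)
    pi = site_pi(alt, called)
    rows = []
    for chrom, sites in _per_chrom(panel):
        pos = panel.pos[sites]
        bounds = window_grid(
            int(pos[-1]), spec, (chrom_lengths or {}).get(chrom)
        )
        if bounds.size == 0:
            continue
        pi_sum = _window_sums(pos, pi[sites], bounds)
        n_snps = _window_sums(pos, np.ones(sites.size), bounds).astype(int)
        n_called = _window_sums(pos, (called[sites] >= 2).astype(float), bounds).astype(int)
        length = (bounds[:, 1] - bounds[:, 0]).astype(float)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": bounds[:, 0],
                    "end": bounds[:, 1],
                    "n_snps": n_snps,
                    "pi": pi_sum / length,
                    "valid": n_called > 0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else _empty_pi_frame()


def _empty_pi_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": [], "start": [], "end": [], "n_snps": [], "pi": [], "valid": []}
    )


def wc_site_components(
    n1, p1, h1, n2, p2, h2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-site variance components for two populations.

    Inputs are per-population called-individual counts ``n``, alternate
    allele frequencies ``p`` and observed heterozygote fractions ``h``.
    Returns (a, b, c, defined): among-population, among-individual-within,
    and within-individual components, and a mask of sites where the
    components are defined (>= 2 called individuals per population and the
    site polymorphic across the pooled sample).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0
    defined = (n1 >= 2) & (n2 >= 2) & (pbar > 0.0) & (pbar < 1.0)
    return a, b, c, defined


def _pop_site_summaries(panel: GenotypePanel, population: str):
    idx = panel.sample_indices(population)
    g = panel.geno[:, idx]
    called = g >= 0
    n = called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, (g == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
    return n, p, h


def window_fst(
    panel: GenotypePanel,
    pop_a: str,
    pop_b: str,
    spec: WindowSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham weighted FST between two populations.

    Per window the estimate is the ratio of sums sum(a) / sum(a + b + c)
    over sites with defined components (the "weighted" estimator); negative
    estimates are retained.  Windows with no informative site are invalid.
    """
    spec = spec or WindowSpec()
    for pop in (pop_a, pop_b):
        if panel.sample_indices(pop).size < 2:
            raise ValueError(f"population {pop!r} needs >= 2 samples for FST")
    n1, p1, h1 = _pop_site_summaries(panel, pop_a)
    n2, p2, h2 = _pop_site_summaries(panel, pop_b)
    a, b, c, defined = wc_site_components(n1, p1, h1, n2, p2, h2)
    a = np.where(defined, a, 0.0)
    abc = a + np.where(defined, b, 0.0) + np.where(defined, c, 0.0)
    rows = []
    for chrom, sites in _per_chrom(panel):
        pos = panel.pos[sites]
        bounds = window_grid(int(pos[-1]), spec, (chrom_lengths or {}).get(chrom))
        if bounds.size == 0:
            continue
        a_sum = _window_sums(pos, a[sites], bounds)
        abc_sum = _window_sums(pos, abc[sites], bounds)
        n_inf = _window_sums(pos, defined[sites].astype(float), bounds).astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(abc_sum != 0.0, a_sum / abc_sum, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": bounds[:, 0],
                    "end": bounds[:, 1],
                    "n_snps": n_inf,
                    "fst": fst,
                    "valid": (n_inf > 0) & np.isfinite(fst),
                }
            )
        )
    cols = ["chrom", "start", "end", "n_snps", "fst", "valid"]
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)


def genome_fst(panel: GenotypePanel, pop_a: str, pop_b: str) -> float:
    """Genome-wide weighted Weir-Cockerham FST (ratio of summed components)."""
    n1, p1, h1 = _pop_site_summaries(panel, pop_a)
    n2, p2, h2 = _pop_site_summaries(panel, pop_b)
    a, b, c, defined = wc_site_components(n1, p1, h1, n2, p2, h2)
    num = a[defined].sum()
    den = (a + b + c)[defined].sum()
    return float(num / den)


def combine_window_stats(
    pi_a: pd.DataFrame, pi_b: pd.DataFrame, fst: pd.DataFrame, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Join per-window pi (both populations) and FST on identical coordinates."""
    key = ["chrom", "start", "end"]
    out = fst.rename(columns={"n_snps": "n_snps_fst", "valid": "fst_valid"})
    for pi, pop in ((pi_a, pop_a), (pi_b, pop_b)):
        sub = pi[key + ["pi", "valid"]].rename(
            columns={"pi": f"pi_{pop}", "valid": f"pi_{pop}_valid"}
        )
        out = out.merge(sub, on=key, how="left")
    return out


def dosage_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages at two sites.

    Computed over samples called at both sites; 0.0 when either site is
    monomorphic among those samples (nothing to prune on).
    """
    gi, gj = panel.geno[i], panel.geno[j]
    both = (gi >= 0) & (gj >= 0)
    if both.sum() < 2:
        return 0.0
    x = gi[both].astype(float)
    y = gj[both].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    panel: GenotypePanel,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> GenotypePanel:
    """Greedy LD pruning with composite (dosage-correlation) r-squared.

    Within each window of ``window_snps`` consecutive sites, while any
    retained pair has r^2 > ``r2_max``, the later-positioned SNP of the
    worst (highest-r^2) pair is removed; the window then advances by
    ``step_snps`` sites.  Deterministic: ties on r^2 resolve to the pair
    with the smallest site indices, and the removed SNP is always the
    later-positioned one.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    keep = np.ones(panel.n_sites, dtype=bool)
    for _chrom, sites in _per_chrom(panel):
        for w0 in range(0, sites.size, step_snps):
            window = sites[w0 : w0 + window_snps]
            if window.size < 2:
                continue
            while True:
                active = [int(s) for s in window if keep[s]]
                worst, worst_pair = r2_max, None
                for ii in range(len(active)):
                    for jj in range(ii + 1, len(active)):
                        r2 = dosage_r2(panel, active[ii], active[jj])
                        if r2 > worst:
                            worst, worst_pair = r2, (active[ii], active[jj])
                if worst_pair is None:
                    break
                keep[worst_pair[1]] = False  # later-positioned SNP goes
            if w0 + window_snps >= sites.size:
                break
    return panel.take_sites(keep)
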