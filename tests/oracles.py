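"""Independent brute-force oracles the tests check the implementation against.

Everything here is deliberately written from first principles (per-site
loops, exhaustive pair enumeration) and shares no code with the package.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def pairwise_pi_per_site(dosages: list[int]) -> float:
    """pi at one site by exhaustive comparison of all allele pairs.

    ``dosages`` are 0/1/2 with -1 missing; each called genotype contributes
    two alleles.
    """
    alleles: list[int] = []
    for d in dosages:
        if d >= 0:
            alleles += [1] * d + [0] * (2 - d)
    n = len(alleles)
    if n < 2:
        return 0.0
    diff = sum(a != b for a, b in itertools.combinations(alleles, 2))
    return diff / math.comb(n, 2)


def window_pi_oracle(positions, dosage_matrix, start: int, end: int) -> float:
    """Mean pairwise difference per bp over a [start, end) window."""
    total = 0.0
    for p, row in zip(positions, dosage_matrix):
        if start < p <= end:
            total += pairwise_pi_per_site(list(row))
    return total / (end - start)


def wc_components_site(geno_a: list[int], geno_b: list[int]):
    """Weir & Cockerham (1984) a, b, c for one site, two populations.

    Scalar transcription of the published two-level formulas; returns None
    when undefined (< 2 called individuals in either population, or the
    pooled sample monomorphic).
    """
    def summarize(geno):
        called = [g for g in geno if g >= 0]
        n = len(called)
        if n == 0:
            return 0, 0.0, 0.0
        p = sum(called) / (2 * n)
        h = sum(1 for g in called if g == 1) / n
        return n, p, h

    n1, p1, h1 = summarize(geno_a)
    n2, p2, h2 = summarize(geno_b)
    if n1 < 2 or n2 < 2:
        return None
    r = 2
    nbar = (n1 + n2) / r
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar <= 0.0 or pbar >= 1.0:
        return None
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def weighted_fst_oracle(geno_a_rows, geno_b_rows) -> float:
    """Ratio-of-sums FST over a list of sites (rows of per-sample dosages)."""
    num = den = 0.0
    for ga, gb in zip(geno_a_rows, geno_b_rows):
        comp = wc_components_site(list(ga), list(gb))
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def d_fd_site_loop(p1, p2, p3, pO):
    """Pattern sums by an explicit per-site loop with scalar arithmetic.

    Applies the same polarization rule (flip when pO > 0.5, drop pO == 0.5)
    and returns (abba, baba, abba_d, baba_d, n_informative).
    """
    A = B = AD = BD = 0.0
    n_inf = 0
    for q1, q2, q3, qO in zip(p1, p2, p3, pO):
        if any(not np.isfinite(q) for q in (q1, q2, q3, qO)) or qO == 0.5:
            continue
        if qO > 0.5:
            q1, q2, q3, qO = 1 - q1, 1 - q2, 1 - q3, 1 - qO
        abba = (1 - q1) * q2 * q3 * (1 - qO)
        baba = q1 * (1 - q2) * q3 * (1 - qO)
        pd = max(q2, q3)
        A += abba
        B += baba
        AD += (1 - q1) * pd * pd * (1 - qO)
        BD += q1 * (1 - pd) * pd * (1 - qO)
        if abba + baba > 0:
            n_inf += 1
    return A, B, AD, BD, n_inf


def merge_oracle(intervals):
    """Interval merge by membership scan over every covered bp-run boundary."""
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def r2_oracle(gi, gj) -> float:
    """Dosage r^2 at two sites over samples called at both."""
    pairs = [(a, b) for a, b in zip(gi, gj) if a >= 0 and b >= 0]
    if len(pairs) < 2:
        return 0.0
    x = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([b for _, b in pairs], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_prune_oracle(positions_by_chrom, geno, window_snps, step_snps, r2_max):
    """Greedy pruning re-implemented with explicit loops.

    ``positions_by_chrom`` is a list of (chrom, site_index) in panel order;
    ``geno`` the full dosage matrix.  Returns the set of retained site
    indices under the same rule: per window, repeatedly drop the
    later-positioned SNP of the highest-r^2 pair above threshold.
    """
    keep = set(idx for _, idx in positions_by_chrom)
    chroms: dict[str, list[int]] = {}
    for chrom, idx in positions_by_chrom:
        chroms.setdefault(chrom, []).append(idx)
    for sites in chroms.values():
        w0 = 0
        while True:
            window = sites[w0 : w0 + window_snps]
            while True:
                active = [s for s in window if s in keep]
                best = None
                best_r2 = r2_max
                for i in range(len(active)):
                    for j in range(i + 1, len(active)):
                        r2 = r2_oracle(list(geno[active[i]]), list(geno[active[j]]))
                        if r2 > best_r2:
                            best_r2 = r2
                            best = (active[i], active[j])
                if best is None:
                    break
                keep.discard(best[1])
            if w0 + window_snps >= len(sites):
                break
            w0 += step_snps
    return keep


def associate_genes_oracle(intervals, genes, flank):
    """All-pairs overlap scan."""
    hits = set()
    for g in genes:
        gs, ge = max(0, g.start - flank), g.end + flank
        for c, s, e in intervals:
            if c == g.chrom and gs < e and s < ge:
                hits.add(g.gene_id)
    return hits


def classify_oracle(fst, log2_ratio, ratio_defined, top_frac=0.05):
    """Percentile-then-filter reclassification (nearest-rank, ties included)."""
    n = len(fst)
    k = max(1, math.ceil(top_frac * n))
    fst_cut = sorted(fst, reverse=True)[k - 1]
    rvals = sorted(v for v, d in zip(log2_ratio, ratio_defined) if d)
    kr = max(1, math.ceil(top_frac * len(rvals)))
    up = sorted(rvals, reverse=True)[kr - 1]
    lo = rvals[kr - 1]
    type1 = [
        i
        for i in range(n)
        if fst[i] >= fst_cut and ratio_defined[i] and log2_ratio[i] >= up
    ]
    type2 = [
        i
        for i in range(n)
        if fst[i] >= fst_cut
        and ratio_defined[i]
        and log2_ratio[i] <= lo
        and not log2_ratio[i] >= up
    ]
    return type1, type2
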