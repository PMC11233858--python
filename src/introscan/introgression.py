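"""Frequency-based Patterson's D and f_d in sliding windows.

The four-taxon configuration is (((P1, P2), P3), O): an excess of ABBA over
BABA site patterns indicates gene flow between the donor P3 and P2.  All
statistics are computed from population allele frequencies (not single
genomes), so a polymorphic outgroup down-weights sites smoothly instead of
discarding them.

Polarization: the outgroup is taken to carry the ancestral allele.  The
alternate allele is treated as derived when pO < 0.5; when pO > 0.5 all
four frequencies are flipped (p -> 1 - p); sites with pO exactly 0.5 carry
no ancestral information and are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .panel import SiteFrequencies
from .windows import WindowSpec, window_grid, _window_sums

STATUS_OK = "OK"
STATUS_TOO_FEW = "TOO_FEW_SNPS"
STATUS_NEG_D = "NEGATIVE_D"
STATUS_FD_GT_1 = "FD_GT_1"
STATUS_UNDEFINED = "UNDEFINED"


@dataclass
class SitePatterns:
    """Per-site ABBA/BABA weights after polarization.

    ``abba_d`` / ``baba_d`` are the complete-introgression analogues used in
    the f_d denominator, built with the dynamic donor frequency
    pD = max(p2, p3) per site.  ``usable`` marks the sites that entered the
    computation (all four role frequencies defined, pO != 0.5).
    """

    chrom: np.ndarray
    pos: np.ndarray
    abba: np.ndarray
    baba: np.ndarray
    abba_d: np.ndarray
    baba_d: np.ndarray
    usable: np.ndarray


def site_patterns(freqs: SiteFrequencies) -> SitePatterns:
    """ABBA/BABA pattern weights from derived-allele frequencies.

    ABBA = (1-p1) p2 p3 (1-pO), BABA = p1 (1-p2) p3 (1-pO); the dynamic
    denominator substitutes pD = max(p2, p3) for both P2 and P3.
    """
    usable = freqs.usable.copy()
    for arr in (freqs.p1, freqs.p2, freqs.p3, freqs.pO):
        usable &= np.isfinite(arr)
    p1, p2, p3, pO = (
        np.where(usable, arr, 0.0) for arr in (freqs.p1, freqs.p2, freqs.p3, freqs.pO)
    )
    flip = pO > 0.5
    usable = usable & (pO != 0.5)
    p1 = np.where(flip, 1.0 - p1, p1)
    p2 = np.where(flip, 1.0 - p2, p2)
    p3 = np.where(flip, 1.0 - p3, p3)
    pO = np.where(flip, 1.0 - pO, pO)

    abba = (1.0 - p1) * p2 * p3 * (1.0 - pO)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - pO)
    pd_dyn = np.maximum(p2, p3)
    abba_d = (1.0 - p1) * pd_dyn * pd_dyn * (1.0 - pO)
    baba_d = p1 * (1.0 - pd_dyn) * pd_dyn * (1.0 - pO)
    z = ~usable
    for arr in (abba, baba, abba_d, baba_d):
        arr[z] = 0.0
    return SitePatterns(
        chrom=freqs.chrom,
        pos=freqs.pos,
        abba=abba,
        baba=baba,
        abba_d=abba_d,
        baba_d=baba_d,
        usable=usable,
    )


def _status_and_fd(n_inf, d, fd_raw, denom_d, min_informative):
    status = np.full(n_inf.shape, STATUS_OK, dtype=object)
    fd = fd_raw.copy()
    undefined = (denom_d == 0.0) | ~np.isfinite(fd_raw) | ~np.isfinite(d)
    status[undefined] = STATUS_UNDEFINED
    status[(~undefined) & (fd_raw > 1.0)] = STATUS_FD_GT_1
    status[np.isfinite(d) & (d < 0.0)] = STATUS_NEG_D
    status[n_inf < min_informative] = STATUS_TOO_FEW
    fd[status != STATUS_OK] = np.nan
    return status, fd


def window_d_fd(
    freqs: SiteFrequencies,
    spec: WindowSpec | None = None,
    min_informative: int = 5,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed Patterson's D and f_d with the standard validity filters.

    D = sum(ABBA - BABA) / sum(ABBA + BABA) and
    f_d = sum(ABBA - BABA) / sum(ABBA_D - BABA_D) over the window's usable
    sites.  An informative site is one with ABBA + BABA > 0.  Windows with
    fewer than ``min_informative`` informative sites are flagged
    TOO_FEW_SNPS; windows with D < 0 NEGATIVE_D; windows with f_d > 1
    FD_GT_1; a zero f_d denominator is flagged UNDEFINED (never infinity).
    Only OK windows carry an f_d value.
    """
    spec = spec or WindowSpec()
    pat = site_patterns(freqs)
    rows = []
    for chrom in pd.unique(pat.chrom):
        sites = np.flatnonzero(pat.chrom == chrom)
        pos = pat.pos[sites]
        bounds = window_grid(int(pos[-1]), spec, (chrom_lengths or {}).get(chrom))
        if bounds.size == 0:
            continue
        abba = _window_sums(pos, pat.abba[sites], bounds)
        baba = _window_sums(pos, pat.baba[sites], bounds)
        abba_d = _window_sums(pos, pat.abba_d[sites], bounds)
        baba_d = _window_sums(pos, pat.baba_d[sites], bounds)
        informative = (pat.abba[sites] + pat.baba[sites]) > 0.0
        n_inf = _window_sums(pos, informative.astype(float), bounds).astype(int)
        num = abba - baba
        denom = abba + baba
        denom_d = abba_d - baba_d
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0.0, num / denom, np.nan)
            fd_raw = np.where(denom_d != 0.0, num / denom_d, np.nan)
        status, fd = _status_and_fd(n_inf, d, fd_raw, denom_d, min_informative)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": bounds[:, 0],
                    "end": bounds[:, 1],
                    "n_informative": n_inf,
                    "abba_sum": abba,
                    "baba_sum": baba,
                    "D": d,
                    "fd": fd,
                    "status": status,
                }
            )
        )
    cols = [
        "chrom", "start", "end", "n_informative",
        "abba_sum", "baba_sum", "D", "fd", "status",
    ]
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)


def genome_d(freqs: SiteFrequencies) -> dict:
    """Genome-wide D with a block-jackknife standard error over chromosomes.

    Delete-one jackknife: D is recomputed leaving each chromosome out in
    turn; SE^2 = (g - 1)/g * sum((D_-j - mean)^2).  With g < 2 blocks the
    SE is reported as NaN.
    """
    pat = site_patterns(freqs)
    chroms = list(pd.unique(pat.chrom))
    num_by = np.array(
        [(pat.abba - pat.baba)[pat.chrom == c].sum() for c in chroms]
    )
    den_by = np.array(
        [(pat.abba + pat.baba)[pat.chrom == c].sum() for c in chroms]
    )
    total_num, total_den = num_by.sum(), den_by.sum()
    d_global = float(total_num / total_den) if total_den > 0 else float("nan")
    g = len(chroms)
    if g >= 2 and total_den > 0:
        loo = (total_num - num_by) / (total_den - den_by)
        se = float(np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum()))
    else:
        se = float("nan")
    return {"D": d_global, "D_se": se, "n_blocks": g, "Z": d_global / se if se else float("nan")}


def fd_permutation_test(
    windows: pd.DataFrame,
    truth: IntervalSet,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Permutation test of mean f_d inside vs outside designated intervals.

    The observed statistic is mean(fd in windows overlapping ``truth``) -
    mean(fd elsewhere) over OK windows; the null distribution permutes the
    fd values across window positions.  Returns the observed difference and
    a two-sided p-value ((#draws at least as extreme + 1) / (n + 1)).

    Permutation assumes the windows are exchangeable: pass NON-overlapping
    windows (step == size).  Overlapping sliding windows share sites, which
    makes the test anti-conservative.
    """
    rng = rng or np.random.default_rng()
    ok = windows[windows["status"] == STATUS_OK]
    in_truth = np.array(
        [truth.overlaps(c, int(s), int(e)) for c, s, e in zip(ok["chrom"], ok["start"], ok["end"])]
    )
    fd = ok["fd"].to_numpy(dtype=float)
    if in_truth.sum() == 0 or in_truth.all():
        return {"observed": float("nan"), "p_value": 1.0, "n_in": int(in_truth.sum())}
    obs = fd[in_truth].mean() - fd[~in_truth].mean()
    null = np.empty(n_draws)
    for i in range(n_draws):
        perm = rng.permutation(fd)
        null[i] = perm[in_truth].mean() - perm[~in_truth].mean()
    p = (np.sum(np.abs(null) >= abs(obs)) + 1) / (n_draws + 1)
    return {"observed": float(obs), "p_value": float(p), "n_in": int(in_truth.sum())}


def strong_regions(windows: pd.DataFrame, top_fraction: float = 0.01) -> IntervalSet:
    """Merge the top-``top_fraction`` f_d windows into strong-introgression regions.

    The cutoff is the nearest-rank upper quantile of f_d over OK windows
    only; windows tied at the cutoff are all included.  Selected windows
    are merged with bookended-interval semantics.
    """
    ok = windows[windows["status"] == STATUS_OK]
    if len(ok) == 0:
        import warnings

        warnings.warn("no OK windows; strong-introgression set is empty")
        return IntervalSet([], "strong-introgression")
    k = max(1, int(np.ceil(top_fraction * len(ok))))
    cutoff = np.sort(ok["fd"].to_numpy())[::-1][k - 1]
    sel = ok[ok["fd"] >= cutoff]
    raw = list(zip(sel["chrom"], sel["start"].astype(int), sel["end"].astype(int)))
    return IntervalSet.from_raw(raw, "strong-introgression")
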