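import numpy as np
import pandas as pd
import pytest

from introscan.intervals import IntervalSet, merge_intervals
from introscan.introgression import (
    STATUS_FD_GT_1,
    STATUS_NEG_D,
    STATUS_OK,
    STATUS_TOO_FEW,
    STATUS_UNDEFINED,
    fd_permutation_test,
    genome_d,
    site_patterns,
    strong_regions,
    window_d_fd,
)
from introscan.panel import SiteFrequencies
from introscan.sim import SimConfig, simulate_frequencies, simulate_genotypes
from introscan.vcfio import population_frequencies
from introscan.windows import WindowSpec

import oracles
from conftest import ROLES


def freqs_from_arrays(p1, p2, p3, pO, pos=None, chrom=None, n=20):
    m = len(p1)
    counts = np.full(m, n)
    return SiteFrequencies(
        chrom=np.array(chrom if chrom is not None else ["chr1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 10),
        p1=np.asarray(p1, dtype=float),
        p2=np.asarray(p2, dtype=float),
        p3=np.asarray(p3, dtype=float),
        pO=np.asarray(pO, dtype=float),
        n1=counts, n2=counts, n3=counts, nO=counts,
    )


class TestSitePatterns:
    def test_canonical_abba_site(self):
        pat = site_patterns(freqs_from_arrays([0], [1], [1], [0]))
        assert pat.abba[0] == 1.0 and pat.baba[0] == 0.0
        assert pat.abba_d[0] == 1.0 and pat.baba_d[0] == 0.0

    def test_p1_equals_p2_contributes_zero_net(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        p3 = rng.uniform(0, 1, 50)
        pat = site_patterns(freqs_from_arrays(p, p, p3, np.zeros(50)))
        np.testing.assert_allclose(pat.abba, pat.baba, atol=1e-15)

    def test_swapping_p1_p2_negates_site_contributions(self):
        rng = np.random.default_rng(2)
        p1, p2, p3 = (rng.uniform(0, 1, 40) for _ in range(3))
        pO = np.zeros(40)
        fwd = site_patterns(freqs_from_arrays(p1, p2, p3, pO))
        rev = site_patterns(freqs_from_arrays(p2, p1, p3, pO))
        np.testing.assert_allclose(fwd.abba - fwd.baba, -(rev.abba - rev.baba), atol=1e-15)

    def test_polarization_flips_high_outgroup_frequency(self):
        # pO = 0.9: derived allele is the REF allele; flipping must recover
        # the canonical ABBA weight of the mirrored site
        pat = site_patterns(freqs_from_arrays([1.0], [0.0], [0.0], [0.9]))
        mirrored = site_patterns(freqs_from_arrays([0.0], [1.0], [1.0], [0.1]))
        assert pat.abba[0] == pytest.approx(mirrored.abba[0])
        assert pat.usable[0]

    def test_po_half_excluded(self):
        pat = site_patterns(freqs_from_arrays([0.2], [0.8], [0.9], [0.5]))
        assert not pat.usable[0]
        assert pat.abba[0] == 0.0

    def test_pattern_sums_match_site_loop_oracle(self):
        rng = np.random.default_rng(3)
        p1, p2, p3, pO = (rng.uniform(0, 1, 200) for _ in range(4))
        pat = site_patterns(freqs_from_arrays(p1, p2, p3, pO))
        A, B, AD, BD, n_inf = oracles.d_fd_site_loop(p1, p2, p3, pO)
        assert pat.abba.sum() == pytest.approx(A, abs=1e-12)
        assert pat.baba.sum() == pytest.approx(B, abs=1e-12)
        assert pat.abba_d.sum() == pytest.approx(AD, abs=1e-12)
        assert pat.baba_d.sum() == pytest.approx(BD, abs=1e-12)


class TestWindowDfd:
    def test_perfect_introgression_window(self):
        freqs = freqs_from_arrays([0.0] * 10, [1.0] * 10, [1.0] * 10, [0.0] * 10)
        out = window_d_fd(freqs, WindowSpec(100, 100))
        assert out["status"][0] == STATUS_OK
        assert out["D"][0] == pytest.approx(1.0)
        assert out["fd"][0] == pytest.approx(1.0)

    def test_too_few_informative_snps(self):
        # 3 informative sites: disregarded regardless of values
        freqs = freqs_from_arrays([0.0] * 3, [1.0] * 3, [1.0] * 3, [0.0] * 3)
        out = window_d_fd(freqs, WindowSpec(100, 100), min_informative=5)
        assert out["status"][0] == STATUS_TOO_FEW
        assert np.isnan(out["fd"][0])

    def test_negative_d_window_excluded(self):
        # BABA-dominant window: D < 0
        freqs = freqs_from_arrays([1.0] * 6, [0.0] * 6, [1.0] * 6, [0.0] * 6)
        out = window_d_fd(freqs, WindowSpec(100, 100))
        assert out["status"][0] == STATUS_NEG_D
        assert np.isnan(out["fd"][0])

    def test_fd_above_one_flagged(self):
        # five clean ABBA sites (num = den = 1 each) plus one site where
        # p1 > p2 > p3 makes the dynamic-denominator contribution more
        # negative than the numerator one: sums give fd = 4.99/4.91 > 1
        p1 = [0.0] * 5 + [1.0]
        p2 = [1.0] * 5 + [0.9]
        p3 = [1.0] * 5 + [0.1]
        freqs = freqs_from_arrays(p1, p2, p3, [0.0] * 6)
        out = window_d_fd(freqs, WindowSpec(100, 100))
        num = 5 * 1.0 + 0.1 * (0.9 - 1.0)
        den = 5 * 1.0 + 0.9 * (0.9 - 1.0)
        assert num / den > 1.0  # construction check
        assert out["status"][0] == STATUS_FD_GT_1
        assert np.isnan(out["fd"][0])

    def test_zero_denominator_marked_undefined_not_infinite(self):
        # one site with den contribution +0.5 cancelled by two sites at
        # -0.25 each, while the ABBA-BABA numerator stays positive
        p1 = [0.5, 1.0, 1.0]
        p2 = [1.0, 0.5, 0.5]
        p3 = [0.5, 0.1, 0.1]
        freqs = freqs_from_arrays(p1, p2, p3, [0.0] * 3)
        out = window_d_fd(freqs, WindowSpec(100, 100), min_informative=1)
        assert out["D"][0] > 0.0
        assert out["status"][0] == STATUS_UNDEFINED
        assert np.isnan(out["fd"][0])
        assert not np.isinf(out.select_dtypes(float).to_numpy()).any()

    def test_window_sums_match_oracle_on_random_table(self):
        rng = np.random.default_rng(4)
        m = 200
        pos = np.sort(rng.choice(np.arange(1, 2000), size=m, replace=False))
        p = [rng.uniform(0, 1, m) for _ in range(4)]
        freqs = freqs_from_arrays(*p, pos=pos)
        out = window_d_fd(freqs, WindowSpec(500, 250), min_informative=1)
        for _, row in out.iterrows():
            sel = (pos > row["start"]) & (pos <= row["end"])
            A, B, AD, BD, n_inf = oracles.d_fd_site_loop(*(q[sel] for q in p))
            assert row["abba_sum"] == pytest.approx(A, abs=1e-12)
            assert row["baba_sum"] == pytest.approx(B, abs=1e-12)
            assert row["n_informative"] == n_inf
            if row["status"] == STATUS_OK:
                assert row["fd"] == pytest.approx((A - B) / (AD - BD), abs=1e-12)

    def test_fd_bounded_by_one_when_donor_dominates(self):
        """If p2 <= p3 at every site, the dynamic denominator caps fd at 1."""
        rng = np.random.default_rng(5)
        p2 = rng.uniform(0, 0.5, 100)
        p3 = p2 + rng.uniform(0, 0.5, 100)
        freqs = freqs_from_arrays(rng.uniform(0, 1, 100), p2, p3, np.zeros(100))
        out = window_d_fd(freqs, WindowSpec(300, 300), min_informative=1)
        ok = out[out["status"] == STATUS_OK]
        assert (ok["fd"] <= 1.0 + 1e-12).all()


class TestGenomeD:
    def test_d_swaps_sign_under_p1_p2_exchange(self):
        rng = np.random.default_rng(6)
        p1, p2, p3 = (rng.uniform(0, 1, 300) for _ in range(3))
        chrom = np.array(["chr1"] * 150 + ["chr2"] * 150, dtype=object)
        pos = np.concatenate([np.arange(1, 151) * 10] * 2)
        fwd = genome_d(freqs_from_arrays(p1, p2, p3, np.zeros(300), pos=pos, chrom=chrom))
        rev = genome_d(freqs_from_arrays(p2, p1, p3, np.zeros(300), pos=pos, chrom=chrom))
        assert fwd["D"] == pytest.approx(-rev["D"])

    def test_null_simulation_d_within_three_jackknife_se(self):
        cfg = SimConfig(
            n_chromosomes=4,
            chrom_length_bp=500_000,
            n_samples={"P1": 25, "P2": 25, "P3": 10, "O": 8},
            drift_F={"P1": 0.05, "P2": 0.05, "P3": 0.3, "O": 0.0},
            seed=7,
        )
        panel = simulate_genotypes(simulate_frequencies(cfg))
        res = genome_d(population_frequencies(panel, ROLES))
        assert res["n_blocks"] == 4
        assert abs(res["D"]) < 3 * res["D_se"]


class TestStrongRegions:
    def make_windows(self, n, fds, starts=None):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": starts if starts is not None else np.arange(n) * 100_000,
                "end": (starts if starts is not None else np.arange(n) * 100_000) + np.full(n, 50_000),
                "fd": fds,
                "status": [STATUS_OK] * n,
            }
        )

    def test_nearest_rank_selects_exactly_one_of_hundred(self):
        rng = np.random.default_rng(8)
        fds = rng.permutation(np.linspace(0.01, 0.99, 100))
        win = self.make_windows(100, fds)
        out = strong_regions(win, top_fraction=0.01)
        top = win.loc[np.argmax(fds)]
        assert out.intervals == [("chr1", int(top["start"]), int(top["end"]))]

    def test_overlapping_selection_merges(self):
        win = self.make_windows(2, [0.9, 0.8], starts=np.array([0, 5_000]))
        out = strong_regions(win, top_fraction=1.0)
        assert out.intervals == [("chr1", 0, 55_000)]

    def test_no_ok_windows_warns_and_returns_empty(self):
        win = self.make_windows(3, [0.1, 0.2, 0.3])
        win["status"] = STATUS_NEG_D
        with pytest.warns(UserWarning):
            out = strong_regions(win)
        assert len(out) == 0

    def test_merge_matches_sweep_oracle(self):
        rng = np.random.default_rng(9)
        raw = [
            (f"chr{rng.integers(1, 4)}", int(s), int(s + rng.integers(1, 60_000)))
            for s in rng.integers(0, 500_000, size=60)
        ]
        assert merge_intervals(raw) == oracles.merge_oracle(raw)


class TestPermutationCalibration:
    def test_null_fd_not_enriched_in_designated_windows(self):
        cfg = SimConfig(
            n_chromosomes=2,
            chrom_length_bp=500_000,
            n_samples={"P1": 20, "P2": 20, "P3": 10, "O": 8},
            drift_F={"P1": 0.05, "P2": 0.05, "P3": 0.3, "O": 0.0},
            seed=17,
        )
        panel = simulate_genotypes(simulate_frequencies(cfg))
        fd = window_d_fd(population_frequencies(panel, ROLES), WindowSpec())
        truth = IntervalSet.from_raw(
            [("chr1", 100_000, 150_000), ("chr2", 300_000, 350_000)], "truth"
        )
        res = fd_permutation_test(fd, truth, 1000, np.random.default_rng(17))
        assert res["p_value"] > 0.05
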