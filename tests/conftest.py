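import json
from pathlib import Path

import numpy as np
import pytest

from introscan.panel import GenotypePanel
from introscan.sim import SimConfig, simulate_frequencies, simulate_genotypes

FIXTURES = Path(__file__).parent / "fixtures"

ROLES = {"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"}


def make_panel(geno, pops, chrom=None, pos=None, qual=None, depth=None):
    """Build a panel from a (sites x samples) dosage list and per-sample pops."""
    geno = np.asarray(geno, dtype=np.int8)
    n_sites, n_samples = geno.shape
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypePanel(
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_sites, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, n_sites + 1) * 10),
        geno=geno,
        qual=np.array(qual if qual is not None else [100.0] * n_sites),
        samples=samples,
        sample_pops={s: p for s, p in zip(samples, pops)},
        depth=None if depth is None else np.asarray(depth, dtype=float),
    )


@pytest.fixture(scope="session")
def pilot_bands():
    return json.loads((FIXTURES / "pilot_bands.json").read_text())


@pytest.fixture(scope="session")
def small_sim():
    """A small two-chromosome panel with default (weak) drift, no introgression."""
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_length_bp=300_000,
        n_samples={"P1": 12, "P2": 12, "P3": 8, "O": 6},
        seed=5,
    )
    truth = simulate_frequencies(cfg)
    return truth, simulate_genotypes(truth)


def scan_fixture_config(admixture_f, seed, elevated_F=0.35):
    """The differentiation-scan study design used across recovery tests.

    Eight 50-kb truth windows (two per chromosome) carry locally elevated
    P1 drift and donor introgression into P2; background drift is weak and
    symmetric and the donor is strongly drifted, emulating introgression
    from a divergent species into one of two weakly differentiated sister
    subgroups.
    """
    truth_windows = [
        (f"chr{c}", s, s + 50_000) for c in (1, 2, 3, 4) for s in (200_000, 600_000)
    ]
    return SimConfig(
        n_chromosomes=4,
        chrom_length_bp=1_000_000,
        n_samples={"P1": 40, "P2": 40, "P3": 15, "O": 10},
        drift_F={"P1": 0.04, "P2": 0.04, "P3": 0.3, "O": 0.0},
        introgressed_windows=truth_windows,
        admixture_f=admixture_f,
        elevated_drift_windows=truth_windows if elevated_F is not None else [],
        elevated_drift_F=elevated_F if elevated_F is not None else 0.0,
        elevated_drift_pop="P1",
        missing_rate=0.03,
        seed=seed,
    )
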