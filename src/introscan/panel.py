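"""The in-memory genotype container shared by every stage of the scan."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MISSING = -1  # sentinel dosage for an uncalled genotype


@dataclass
class GenotypePanel:
    """Diploid genotypes at biallelic SNP sites, as alternate-allele dosage.

    Attributes
    ----------
    chrom : array of str, one per site
    pos : array of int, 1-based positions, strictly increasing per chromosome
    geno : int8 array (n_sites, n_samples); 0/1/2 dosage, -1 missing
    qual : float array per site (NaN when absent)
    depth : optional float array (n_sites, n_samples) of per-genotype depth
    samples : sample names, column order of ``geno``
    sample_pops : sample name -> population label
    """

    chrom: np.ndarray
    pos: np.ndarray
    geno: np.ndarray
    qual: np.ndarray
    samples: list[str]
    sample_pops: dict[str, str]
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.qual = np.asarray(self.qual, dtype=float)
        if self.geno.shape != (self.pos.size, len(self.samples)):
            raise ValueError("geno shape does not match (n_sites, n_samples)")
        missing = [s for s in self.samples if s not in self.sample_pops]
        if missing:
            raise ValueError(f"samples without a population label: {missing[:5]}")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic views ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.sample_pops[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.sample_pops[s] == population],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise ValueError(f"population {population!r} has no samples")
        return idx

    # -- subsetting ----------------------------------------------------------

    def take_sites(self, index: np.ndarray) -> "GenotypePanel":
        """Panel restricted to the given site indices / boolean mask."""
        index = np.asarray(index)
        return GenotypePanel(
            chrom=self.chrom[index],
            pos=self.pos[index],
            geno=self.geno[index],
            qual=self.qual[index],
            samples=list(self.samples),
            sample_pops=dict(self.sample_pops),
            depth=None if self.depth is None else self.depth[index],
        )

    # -- allele bookkeeping --------------------------------------------------

    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, called allele count) per site over the samples."""
        g = self.geno if sample_idx is None else self.geno[:, sample_idx]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)

    def equal(self, other: "GenotypePanel") -> bool:
        """Element-wise content equality (sites, samples, genotypes)."""
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.geno, other.geno)
            and all(self.sample_pops[s] == other.sample_pops[s] for s in self.samples)
        )


@dataclass
class SiteFrequencies:
    """Per-site alternate-allele frequencies for the four scan roles.

    ``p1/p2/p3/pO`` are frequencies among called alleles of the samples
    assigned to roles P1, P2, P3 and O; ``n1..nO`` the called-allele counts.
    A site is ``usable`` for the four-taxon statistics only when every role
    has at least two called alleles.
    """

    chrom: np.ndarray
    pos: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    pO: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    n3: np.ndarray
    nO: np.ndarray
    usable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.usable is None:
            counts = np.vstack([self.n1, self.n2, self.n3, self.nO])
            self.usable = (counts >= 2).all(axis=0)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)
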