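# Methods

## Setting

Two closely related, weakly differentiated subgroups (P1, P2) are scanned
for localized differentiation and for gene flow from a divergent donor
species (P3), with an outgroup (O) carrying the putative ancestral allele.
All statistics operate on biallelic diploid SNP genotypes coded as
alternate-allele dosage; missing calls are excluded from every allele
count (no imputation).

## Estimators

**Nucleotide diversity.** Per site, `pi = 1 - [C(a,2) + C(n-a,2)] / C(n,2)`
over the `n` called alleles with `a` alternate copies. The windowed value
divides the sum of site pi by the window length in bp — the convention of
the standard windowed-scan tools — so unobserved and monomorphic positions
contribute zero diversity rather than being dropped from the denominator.
Terminal windows are truncated at the chromosome end (or, when no
chromosome length is supplied, at the last variant) and use their actual
length.

**F_ST.** Weir & Cockerham's (1984) two-level variance components are
computed per site from genotype counts (sample sizes, allele frequencies
and observed heterozygosity per population); the windowed estimate is the
weighted "ratio of sums" `sum(a)/sum(a+b+c)`, not a mean of per-site
ratios. Sites need at least two called individuals per population and
pooled polymorphism to enter the sums. Negative estimates are kept: the
classification step z-scores windows, and clamping would bias the tails.
Under the Balding–Nichols generator with both populations at drift F, the
estimator's expectation is F itself, which the recovery tests exploit.

**Patterson's D and f_d.** Frequency-based (population) forms:
`ABBA = (1-p1) p2 p3 (1-pO)` and `BABA = p1 (1-p2) p3 (1-pO)` per site,
`D = sum(ABBA-BABA)/sum(ABBA+BABA)` per window; f_d rescales the
numerator by a hypothetical complete-introgression denominator built with
the per-site dynamic donor frequency `pD = max(p2, p3)`. A site is
informative when `ABBA + BABA > 0` (a definition this package fixes, since
common usage varies). Window validity follows the standard scan filters:
fewer than 5 informative sites, D < 0, or f_d > 1 invalidate a window; a
zero f_d denominator with a nonzero numerator is flagged UNDEFINED, never
reported as infinity. Exclusion happens before the top-1% quantile, so
invalid windows never enter the strong-introgression cutoff.

**Polarization.** The alternate allele is treated as derived when
pO < 0.5; when pO > 0.5 all four frequencies are flipped; pO = 0.5 sites
carry no ancestral information and are excluded. With the default
monomorphic-ancestral outgroup this is exact; a polymorphic outgroup
down-weights sites smoothly through the (1 - pO) factor.

**Genome-wide D uncertainty.** Delete-one block jackknife over
chromosomes: SE² = (g-1)/g · Σ(D₋ⱼ − mean)². Chromosomes are the blocks
because within-chromosome windows share LD; with the simulator's
independent sites this is conservative.

**Permutation calibration.** The f_d-enrichment permutation test shuffles
window f_d values between designated and background windows. It must be
run on non-overlapping windows (step = size): 50-kb/5-kb sliding windows
share ~90% of their sites with neighbours, are not exchangeable, and make
the naive test anti-conservative (observed during development: null
p-values down to ~0.001 on sliding windows vs 0.29–0.86 on
non-overlapping ones across null seeds).

**Classification.** F_ST is z-scored across valid windows; tail cutoffs
are nearest-rank percentiles of the analyzed window set itself (the
thresholds are data-derived, as in the source analyses), with ties at the
cutoff included. Two guards: (i) a constant statistic yields empty tails
(every window "tied at the cutoff" is not an outlier set); (ii) a window
satisfying both ratio tails (possible only in degenerate near-constant
data) is assigned to Type 1 only, keeping the sets disjoint. Windows with
zero pi in either population are excluded from the ratio tails (log2
undefined) but stay eligible for the F_ST tail, and are counted in the
report. The interval report gives both the merged span and the summed
(overlap-double-counting) window span, since either convention is used
when interval totals are quoted.

**Deciles.** Valid windows are ranked by F_ST descending and split into 10
equal-count bins, remainder to the first bins; each bin reports F_ST
summaries and the quartiles of its OK-window f_d values, plus the Spearman
correlation between decile index and median f_d.

**LD pruning.** Greedy, PLINK-style composite r² (squared Pearson
correlation of dosages over samples called at both sites — genotypes are
unphased, so haplotype-EM r² is not attempted). Within each 50-SNP window
the worst pair above threshold loses its later-positioned member, ties on
r² resolving to the smallest site indices; the window then slides by 10
SNPs. Fully deterministic.

**Coordinates.** VCF positions stay 1-based internally; every emitted
interval (windows, BED outputs) is 0-based half-open. A 1-based position p
is inside [start, end) iff start < p <= end.

## The simulator

`introscan.sim` draws, per site: an ancestral frequency
x ~ Uniform(0.05, 0.95) (segregating ancestor — the informative regime for
the four-taxon statistics), then each population's frequency from the
Balding–Nichols law Beta(x(1−F)/F, (1−x)(1−F)/F) with its drift parameter
F (F = 0 means the frequency equals x exactly). The outgroup is
monomorphic ancestral by default, making derived = alternate exact and
isolating estimator behaviour from polarization error; a drifted-outgroup
mode exercises the polymorphic-outgroup path. Genotypes are two Bernoulli
allele draws per sample per site (Hardy–Weinberg within populations),
with uniform random site placement at the configured density and uniform
missingness. Introgression replaces the P2 frequency inside designated
windows with the mixture (1−f)·p2 + f·p3; an optional haplotype mode draws
each P2 allele copy from the donor with probability f instead, preserving
the marginal frequency while adding within-window LD.

Default conditions mirror the blueberry-style study panel the scan was
designed around: sample sizes 81/82/15/12 for P1/P2/P3/O, 6.62 SNPs/kb,
background drift F = 0.04 for P1 and P2 (pairwise Weir–Cockerham
expectation ≈ 0.04, matching the weak subgroup differentiation such panels
show), a strongly drifted donor (F = 0.3), 3% missingness.

**What the generator does not emulate:** linkage disequilibrium between
sites (sites are exchangeable given position), recombination maps,
selection, mutation-rate variation, polyploid dosage (the analyses it
supports treat tetraploid genotypes under a diploid model, which is known
to understate donor introgression), and sequencing-error structure in
depth/quality fields. Passing recovery tests therefore demonstrate
estimator correctness and calibration under the assumed frequency model,
not robustness to real-data LD or mapping artifacts.

**A structural consequence of the symmetric model** worth knowing when
designing experiments: with all populations sharing the ancestral
frequency, frequency-level introgression changes Var(p2') =
[(1−f)² F2 + f² F3]·x(1−x), and both F_ST(P1,P2) and pi_P2 are driven by
that same variance — so introgression alone cannot simultaneously raise
F_ST and the pi_P2/pi_P1 ratio. The "differentiated + diverse" (Type 1)
signature is instead produced by elevating P1's drift locally
(`elevated_drift_windows`, emulating differentiation on the sister-group
side, e.g. local selection) in the same windows that receive donor
introgression into P2. That construction yields high F_ST, high pi ratio
and high f_d together and is what the scan-logic recovery fixture uses.

## Test and reproduction problem sizes

Chosen as the smallest sizes at which the quantities of interest are
stable: F_ST recovery at 20k SNPs and 50 samples/population (matching the
registered ±0.015 check); f_d recovery on two 1.5-Mb chromosomes with
twelve 50-kb truth windows at f ∈ {0.1, 0.3, 0.5}, whose tolerance bands
were registered from a pre-build pilot (5 replicate seeds) and committed
to `tests/fixtures/pilot_bands.json`; the scan-logic fixture on four 1-Mb
chromosomes with eight truth windows. f_d underestimates f in this
weak-divergence regime (the dynamic-donor denominator exceeds the true
introgressed fraction's contribution when P2 and P3 are weakly
differentiated); the registered bands reflect the estimator's actual
operating characteristics, and the strict-increase check carries the
parameter-recovery content. Seed-to-seed spread of small-n window means is
substantial; the committed recovery tests run at fixed seeds.

## Known limitations

* Per-genotype depth is simulated only as absent; the depth filter is
  exercised through hand-built fixtures.
* The jackknife SE uses chromosomes as blocks; with few chromosomes the
  SE itself is noisy (g = 4 in the fixtures).
* `ld_prune` is quadratic per window and intended for panel-scale marker
  sets, not tens of millions of sites.
* Interval algebra assumes merged, sorted inputs beyond `IntervalSet`'s
  own constructors; external BED files are merged on load.
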