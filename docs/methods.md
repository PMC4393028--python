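# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
conventions a maintainer needs.

## Coordinates and data model

All positions are 1-based physical bp; intervals are closed
`[start_bp, end_bp]` with length `end_bp − start_bp`, so reported Mb lengths
are position differences (PLINK's convention). BED exports convert to
0-based half-open. Genotypes are counts of the dataset-minor allele
(0/1/2, −1 missing); the minor orientation is recomputed after every filter,
with ties at p = 0.5 keeping the current allele order (first read breaks
ties toward the lexicographically later label so parsing is deterministic).
Phased haplotypes are two 0/1 rows per sample whose sums reproduce the
genotype codes.

## LD decay and the Ne trajectory

r² between SNP pairs on the same chromosome is computed from phased
haplotype frequencies (`r² = D²/(p₁q₁p₂q₂)`) when haplotypes are available,
otherwise as the squared Pearson correlation of genotype codes over
complete cases (composite LD). Monomorphic SNPs never pair. Pairs are
grouped into half-open distance bins (default 0.1 Mb; a pair exactly on a
boundary joins the upper bin) and the unweighted bin mean r̄² is inverted
through Sved's equilibrium relation `Ne = (1 − r̄²)/(4 c r̄²)`, with
`c` = bin-midpoint distance × recombination scale. The default scale is
1e-8 Morgan/bp (100 Mb = 1 Morgan), a standard genome-wide average for
dogs. The generation a bin probes is `g = round(1/(2c))` — the same
relation that gives IBD segments from an ancestor g generations back a mean
length of `1/(2g)` Morgan — and `ΔF = 1/(2 Ne)`. Several bins can round to
one g; the trajectory reports the pair-count-weighted mean Ne per g.
Bins with r̄² of exactly 0 or 1 cannot be inverted and are flagged rather
than estimated. Distances that round to g < 1 clamp to 1 with a warning.

Two practical notes, both visible in the validation experiments. First,
Sved's expectation refers to common variants; in a simulated
mutation–drift equilibrium the site-frequency spectrum is dominated by
young rare alleles whose r² is far below the equilibrium value, which
inflates Ne severalfold. Restricting to MAF ≥ 0.15 — the composition a SNP
array effectively has — recovers simulated constant-N truth within ±25%
(median over 20 seeds, N = 25 and 50). Second, per-seed r̄² has large
genealogical variance in tiny populations; medians over seeds, not single
runs, are the meaningful quantity at this scale.

## Runs of homozygosity and inbreeding coefficients

A ROH is a maximal window of consecutive SNPs on one chromosome with zero
heterozygous calls, at most `max_missing` (default 5) missing calls, and
homozygous non-missing SNPs at both ends — endpoints must be evidence-backed,
so missing calls never start or end a run. A window is reported when it has
at least `min_snps` SNPs (all spanned SNPs counted, missing included) and
spans at least `min_length_bp` (default 1 Mb). Calling is an exact maximal-
window scan, not a sliding-window heuristic, and is verified against an
exhaustive all-substring oracle; when more than `max_missing` missing calls
fall between two heterozygotes the maximal windows overlap, which is why
`F_ROH` sums the merged union of an individual's segments (guaranteeing
`F_ROH ≤ 1`).

The SNP-count floor can be derived from the data as
`l = round(log(α/(n_SNP·n_ind)) / log(hom))`: the chance that a run of `l`
homozygous SNPs arises without autozygosity in `n_SNP·n_ind` opportunities,
at mean per-SNP homozygosity `hom`, is held below `α` (default 0.05). The
floor grows steeply as `hom → 1` — extremely homozygous datasets need very
long runs before a run means anything.

`F_ROH` divides by the SNP-covered autosome length (sum over chromosomes of
last − first SNP position) by default; a fixed genome-size constant (e.g.
2.29 Gb for the dog autosomes) can be supplied instead, and the two
denominators differ by the uncovered chromosome ends. A ROH length floor of
L Morgan restricts `F_ROH` to inbreeding from roughly the last `1/(2L)`
generations.

Consensus ROHs are computed on SNP support: a SNP is covered for a sample
when it lies in any of that sample's segments, the boolean AND across
samples is taken per SNP, and maximal covered runs become consensus
intervals (endpoints are SNP positions; no length floor).

`F_IS` for individual i is `(O_i − E_i)/(n_i − E_i)` with `O_i` the
observed homozygous-SNP count, `n_i` the SNPs genotyped in i, and `E_i` the
sum over those SNPs of `1 − 2pq·(2N/(2N−1))` — sample allele frequencies
with the small-sample correction (toggleable). SNPs with fewer than two
genotyped samples are excluded from both counts.

## Pedigree inbreeding

`F` of an individual is the kinship of its parents, computed by the
recursive tabular method (memoised kinship with recursion on the
generationally younger argument). "Last k generations" keeps ancestors
within k meioses of the focal animal; deeper ancestors become unknown
founders, assumed non-inbred and unrelated — so truncated F is a lower
bound and is monotone non-decreasing in depth. The implementation is tested
against an independent Wright path-counting oracle. Completeness is the
MacCluer-style index: the fraction of filled ancestor slots per generation,
averaged over generations 1..k. `ΔF` from pedigree data is the plain
average `mean F / generations`; the divisor is an explicit argument because
conventions differ.

## Long-range haplotype test

Chromosomes are tiled with fixed-size cores (default 10 SNPs,
non-overlapping; both knobs exposed — overlapping cores refine localisation
at proportional cost). For each distinct core haplotype, EHH at test
distance d (default 1 Mb in the CLI) is the fraction of carrier pairs
identical at every SNP from the core edge to the last SNP within d, per
direction; a single carrier scores 0, an empty window 1. REHH divides by
the pair-count-weighted mean EHH of the other haplotypes at the same core,
cancelling shared recombination-rate variation; it is undefined (and the
haplotype unscored) when no other haplotype contributes pairs. The reported
REHH is the larger of the two directions, both are written out. ln REHH is
standardised within 20 equal-width core-frequency bins and the z-score
mapped to a one-sided upper-tail normal P (selection inflates REHH;
reported as −log10 P). Bins with fewer than two defined values or zero
spread leave members unscored. Haplotypes below frequency 0.1 are scored
but flagged unreliable — their EHH rests on a handful of pairs.
Significant regions (default: frequency ≥ 0.5 and −log10 P > 3) are
exported as BED intervals extended ±0.5 Mb, deliberately not merged.

Power at realistic sample sizes deserves honesty: with ~56 diploids, the
within-bin z-score of a genuine 10–15-generation sweep typically reaches
only 1–2, because neutral ln-REHH dispersion within a frequency bin is
large (small-carrier EHH noise) and a sweep both erodes its own local
polymorphism and, in a small genome, populates its own frequency bin.
Validation experiments across many simulated backgrounds place the swept
core around the 85th–93rd genome-wide percentile of −log10 P, not reliably
in the top 5%. The scan localises strong recent sweeps as runs of
elevated-REHH cores, but single-core significance at this sample size
should be read as ranking, not calibrated error control.

## The Wright–Fisher simulator

Discrete generations; sexed random mating (alternating sexes at birth, one
sire and one dam per offspring, selfing impossible — this also keeps
recorded pedigrees role-consistent); per-meiosis recombination as Poisson
crossovers at the genome's Morgan length with uniform breakpoints;
infinite-sites mutation (each hit a new site with one carrier). Founders
carry standing variation at uniformly placed sites with ancestral
frequencies drawn U(0.05, 0.95) — the common-variant pool a SNP chip would
have been designed on. A single seeded RNG stream drives everything; equal
seeds give byte-identical results.

Chip-like ascertainment selects sites on a near-uniform bp grid subject to
a MAF floor in the *ancestral* pool (breed-private mutations are never
"on the chip"), and therefore keeps sites monomorphic in the sample — the
fixed SNPs are what make a bottlenecked population's chip homozygosity
extreme. Without ascertainment, output is restricted to sample-polymorphic
sites.

Admixture replaces each gamete of the pulse generation independently with a
migrant gamete (probability = pulse fraction) drawn from an N = 1000
outside population simulated for a 20-generation burn-in on the same
founder site grid with independent frequencies; migrant parents are
recorded as unknown in the pedigree. Selection is additive (fitness
1 : 1+s/2 : 1+s) through weighted parent sampling, acting on a standing
variant chosen at onset: within a starting-frequency band backward-computed
from the deterministic selection recursion to land near frequency 0.6 at
sampling (detectable but not fixed), the candidate whose carriers share the
most homogeneous ±60-SNP background is taken — a young variant, so the
sweep drags one long haplotype, the signature the long-range test is built
for. An old variant at the same frequency would give a soft sweep with
little EHH signal.

What the simulator does not emulate: genotyping error and missingness
structure (calls are perfect; missingness enters only via user-made
fixtures), varying recombination/mutation landscapes, overlapping
generations and litters, real chip ascertainment bias beyond the uniform
grid + panel-MAF approximation, and phasing error (haplotypes are true).
Passing tests therefore validate estimator logic under known truth, not
robustness to array artefacts.

Bundled fixtures: `tiny_toy` (3 samples × 8 SNPs, hand-checkable),
`bottleneck28` (28 diploids, 3 × 25 Mb chromosomes, 2400 chip-like SNPs;
~30 generations near Ne 25 then ~60 near Ne 13, a small recent recovery and
a 1/16 admixture pulse five generations back — chosen so founder
heterozygosity ~0.30 drifts to mean chip homozygosity ~0.95 with extreme
LD, long ROHs and hundreds of consensus ROHs), and `sweep_demo`
(56 diploids, 16 × 15 Mb chromosomes, constant Ne 150 for 80 generations,
one s = 0.8 sweep over the last 12 generations). Fixture sizes are scaled
a factor ~50 below a 170k-SNP, 38-autosome array study so the whole suite
runs in minutes; the scaling is in SNP count and genome size, not in the
per-SNP or per-window rules.

## Pipeline

`PipelineConfig` (YAML, unknown keys rejected) drives: PLINK text input →
call-rate filter (strict `> 0.90` by default) → sex-chromosome exclusion →
optional MAF filter (own frequencies or an external panel table) → LD/Ne →
ROH at each configured threshold (integers or `auto` = the derived `l`) →
consensus, `F_ROH`, `F_IS`, pedigree `F` → correlation matrix → scan →
TSV/BED reports, with per-stage in/kept/filtered accounting in the log and
byte-identical reruns for a fixed config. Plots (LD decay, Ne trajectory)
are optional and headless-safe; TSVs are the contract.
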