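"""Forward-in-time Wright-Fisher diploid simulator with pedigree recording.

Generates phased genotypes under a user-specified trajectory of small
population sizes (discrete generations, sexed random mating, per-meiosis
Poisson recombination, infinite-sites mutation on top of founder standing
variation), with optional features matching a strongly bottlenecked breed
history: a recent admixture pulse from a large outside population and a
positively selected locus. The full parentage of every simulated individual
is recorded, so pedigree- and genotype-based inbreeding measures can be
compared against the same truth.

Founders carry standing variation at uniformly scattered sites with
frequencies drawn uniformly from (0.05, 0.95) — a stand-in for the common
variation a SNP chip would have been ascertained on. Selection acts on a
standing variant: at the onset generation the segregating site nearest the
requested position with minor-allele frequency in [0.05, 0.30] is picked and
parents are sampled with additive fitness 1 : 1+s/2 : 1+s thereafter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    GenotypeDataset,
    HaplotypeSet,
    write_haplotypes_tsv,
    write_plink_text,
)

FIXTURE_NAMES = ("tiny_toy", "bottleneck28", "sweep_demo")


@dataclass
class SelectedLocus:
    chrom: int  # 1-based chromosome number
    bp: int
    s: float
    onset_generation: int  # generations before the end of the simulation

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.onset_generation < 1:
            raise ValueError("onset_generation must be >= 1")


@dataclass
class WFScenario:
    """Study conditions for one simulation run.

    ``ne_history`` lists diploid population sizes oldest to newest; the last
    entry is the generation sampled. ``admixture`` is (generations before the
    end, fraction of gametes replaced by migrants from an independently
    simulated N=1000 population). A fixed seed yields byte-identical output.
    """

    ne_history: list
    n_chrom: int = 3
    chrom_length_bp: int = 25_000_000
    recomb_morgan_per_bp: float = 1e-8
    mutation_rate: float = 1e-9  # per bp per gamete per generation
    founder_sites_per_chrom: int = 800
    n_segsites_target: int | None = None
    ascertainment_maf_floor: float = 0.05
    admixture: tuple | None = None  # (generations_before_end, fraction)
    selected_locus: SelectedLocus | None = None
    sample_size: int = 28
    seed: int = 0
    track_heterozygosity: bool = False

    def __post_init__(self) -> None:
        if len(self.ne_history) < 2:
            raise ValueError("ne_history needs at least two generations")
        if any(n < 2 for n in self.ne_history):
            raise ValueError("all population sizes must be >= 2")
        if self.sample_size > self.ne_history[-1]:
            raise ValueError("sample_size exceeds the final population size")
        if self.admixture is not None:
            gens, frac = self.admixture
            if not 0 <= frac <= 1:
                raise ValueError("admixture fraction must be in [0, 1]")
            if not 1 <= gens < len(self.ne_history):
                raise ValueError("admixture generation outside the simulated span")
        if self.selected_locus is not None:
            if not 1 <= self.selected_locus.chrom <= self.n_chrom:
                raise ValueError("selected locus chromosome out of range")


@dataclass
class SimulationResult:
    haplotypes: HaplotypeSet
    genotypes: GenotypeDataset
    pedigree: pd.DataFrame  # id, sire, dam, generation ("0" = unknown parent)
    true_ne: list
    selected_site: dict | None  # {"chrom", "bp", "snp_index"} or None
    het_history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# gamete machinery
# ---------------------------------------------------------------------------

def _make_gametes(
    H: np.ndarray,
    pos: np.ndarray,
    parents: np.ndarray,
    rng: np.random.Generator,
    morgan_len: float,
    length_bp: int,
) -> np.ndarray:
    """One recombinant gamete per entry of ``parents`` from diploid matrix H.

    Crossover counts are Poisson(morgan_len) per meiosis with breakpoints
    uniform on the chromosome; the zero-crossover majority is a bulk row copy.
    """
    n_g = len(parents)
    starts = rng.integers(0, 2, size=n_g)
    n_cross = rng.poisson(morgan_len, size=n_g)
    out = np.empty((n_g, H.shape[1]), dtype=np.int8)
    zero = n_cross == 0
    if zero.any():
        out[zero] = H[2 * parents[zero] + starts[zero]]
    for g in np.flatnonzero(~zero):
        breaks = np.sort(rng.uniform(0, length_bp, n_cross[g]))
        seg = np.searchsorted(breaks, pos)
        which = (starts[g] + seg) % 2
        p = parents[g]
        out[g] = np.where(which == 0, H[2 * p], H[2 * p + 1])
    return out


def _add_mutations(
    H_list: list,
    pos_list: list,
    rng: np.random.Generator,
    mu: float,
    length_bp: int,
) -> None:
    """Infinite-sites mutation: each hit creates a new site with one carrier."""
    for c in range(len(H_list)):
        n_hap = H_list[c].shape[0]
        n_new = rng.poisson(mu * length_bp * n_hap)
        if n_new == 0:
            continue
        new_pos = rng.integers(1, length_bp + 1, size=n_new)
        new_pos = np.setdiff1d(np.unique(new_pos), pos_list[c])
        if new_pos.size == 0:
            continue
        carriers = rng.integers(0, n_hap, size=new_pos.size)
        ins = np.searchsorted(pos_list[c], new_pos)
        pos_list[c] = np.insert(pos_list[c], ins, new_pos)
        cols = np.zeros((n_hap, new_pos.size), dtype=np.int8)
        cols[carriers, np.arange(new_pos.size)] = 1
        H_list[c] = np.insert(H_list[c], ins, cols, axis=1)


def _prune_monomorphic(H_list, pos_list, protect_pos) -> None:
    for c in range(len(H_list)):
        counts = H_list[c].sum(axis=0)
        poly = (counts > 0) & (counts < H_list[c].shape[0])
        keep = poly | np.isin(pos_list[c], protect_pos[c])
        H_list[c] = H_list[c][:, keep]
        pos_list[c] = pos_list[c][keep]


def _founder_population(
    rng: np.random.Generator, n_dip: int, n_chrom: int, length_bp: int, sites: int
) -> tuple[list, list, list]:
    """Founder haplotypes plus the ancestral-pool frequency of each site.

    The ancestral frequencies double as the chip discovery panel during
    ascertainment: array SNPs were chosen for being common in an outside
    pool, not in the (possibly fixed) study population.
    """
    H_list, pos_list, freq_list = [], [], []
    for _c in range(n_chrom):
        pos = np.sort(rng.choice(np.arange(1, length_bp + 1), size=sites, replace=False))
        freq = rng.uniform(0.05, 0.95, size=sites)
        H = (rng.random((2 * n_dip, sites)) < freq).astype(np.int8)
        H_list.append(H)
        pos_list.append(pos)
        freq_list.append(freq)
    return H_list, pos_list, freq_list


def _mean_het(H_list, n_sites_total: int) -> float:
    acc = 0.0
    for H in H_list:
        p = H.mean(axis=0)
        acc += float((2 * p * (1 - p)).sum())
    return acc / n_sites_total


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def simulate(scenario: WFScenario) -> SimulationResult:
    """Run the scenario and return phased haplotypes, genotypes and pedigree."""
    rng = np.random.default_rng(scenario.seed)
    hist = [int(n) for n in scenario.ne_history]
    T = len(hist)
    L = scenario.chrom_length_bp
    morgan_len = L * scenario.recomb_morgan_per_bp

    H_list, pos_list, founder_freq = _founder_population(
        rng, hist[0], scenario.n_chrom, L, scenario.founder_sites_per_chrom
    )
    founder_pos = [p.copy() for p in pos_list]
    n_founder_sites = scenario.founder_sites_per_chrom * scenario.n_chrom

    ped_rows = [(f"G0I{i}", "0", "0", 0) for i in range(hist[0])]
    het_history = []
    if scenario.track_heterozygosity:
        het_history.append(_mean_het(H_list, n_founder_sites))

    t_pulse = T - scenario.admixture[0] if scenario.admixture else None
    t_sel = T - scenario.selected_locus.onset_generation if scenario.selected_locus else None
    sel_site = None  # (chrom_index, position)
    donor = None

    for t in range(1, T):
        n_prev, n_now = hist[t - 1], hist[t]
        # sexes alternate deterministically: even index = sire pool
        males = np.arange(0, n_prev, 2)
        females = np.arange(1, n_prev, 2)

        weights = np.ones(n_prev)
        if t_sel is not None and t >= t_sel:
            if sel_site is None:
                sel_site = _pick_selected_site(
                    H_list, pos_list, scenario.selected_locus
                )
            c, site_pos = sel_site
            j = int(np.searchsorted(pos_list[c], site_pos))
            geno = H_list[c][0::2, j] + H_list[c][1::2, j]
            weights = 1.0 + scenario.selected_locus.s * geno / 2.0

        wm = weights[males] / weights[males].sum()
        wf = weights[females] / weights[females].sum()
        sires = males[rng.choice(len(males), size=n_now, p=wm)]
        dams = females[rng.choice(len(females), size=n_now, p=wf)]

        migrant_sire = np.zeros(n_now, dtype=bool)
        migrant_dam = np.zeros(n_now, dtype=bool)
        if t_pulse is not None and t == t_pulse:
            frac = scenario.admixture[1]
            migrant_sire = rng.random(n_now) < frac
            migrant_dam = rng.random(n_now) < frac
            donor = _simulate_donor(rng, founder_pos, pos_list, L, morgan_len)

        new_H = []
        for c in range(scenario.n_chrom):
            g_sire = _make_gametes(H_list[c], pos_list[c], sires, rng, morgan_len, L)
            g_dam = _make_gametes(H_list[c], pos_list[c], dams, rng, morgan_len, L)
            if migrant_sire.any():
                g_sire[migrant_sire] = _donor_gametes(
                    donor[c], pos_list[c], int(migrant_sire.sum()), rng, morgan_len, L
                )
            if migrant_dam.any():
                g_dam[migrant_dam] = _donor_gametes(
                    donor[c], pos_list[c], int(migrant_dam.sum()), rng, morgan_len, L
                )
            H = np.empty((2 * n_now, H_list[c].shape[1]), dtype=np.int8)
            H[0::2] = g_sire
            H[1::2] = g_dam
            new_H.append(H)
        H_list = new_H

        for i in range(n_now):
            sire_id = "0" if migrant_sire[i] else f"G{t-1}I{sires[i]}"
            dam_id = "0" if migrant_dam[i] else f"G{t-1}I{dams[i]}"
            ped_rows.append((f"G{t}I{i}", sire_id, dam_id, t))

        if scenario.mutation_rate > 0:
            _add_mutations(H_list, pos_list, rng, scenario.mutation_rate, L)
        if scenario.track_heterozygosity:
            het_history.append(_mean_het(H_list, n_founder_sites))
        if t % 32 == 0 and (t_pulse is None or t > t_pulse):
            protect = [p.copy() for p in founder_pos]
            if sel_site is not None:
                protect[sel_site[0]] = np.append(protect[sel_site[0]], sel_site[1])
            _prune_monomorphic(H_list, pos_list, protect)

    # sample diploids from the final generation
    n_final = hist[-1]
    chosen = np.sort(rng.choice(n_final, size=scenario.sample_size, replace=False))
    sample_ids = [f"G{T-1}I{i}" for i in chosen]
    hap_rows = np.empty(2 * scenario.sample_size, dtype=np.int64)
    hap_rows[0::2] = 2 * chosen
    hap_rows[1::2] = 2 * chosen + 1

    # with chip-like ascertainment enabled, keep sample-monomorphic sites
    # too: array content is decided by the discovery panel, not the study
    # population, and fixed SNPs are what make its homozygosity extreme
    keep_mono = scenario.n_segsites_target is not None
    variants, hap_mat, sel_index, panel = _build_variant_table(
        H_list, pos_list, hap_rows, sel_site, founder_pos, founder_freq, keep_mono
    )
    haps = HaplotypeSet(sample_ids, variants, hap_mat)

    if scenario.n_segsites_target is not None:
        must = None
        if sel_index is not None:
            must = np.array([sel_index])
        haps = ascertain_snps(
            haps,
            scenario.n_segsites_target,
            maf_floor=scenario.ascertainment_maf_floor,
            rng=rng,
            panel_freqs=panel,
            must_include=must,
        )
        sel_index = _relocate_selected(haps, sel_site)

    p_sample = haps.haplotypes.mean(axis=0) if haps.n_snps else np.empty(0)
    if not ((p_sample > 0) & (p_sample < 1)).any():
        raise RuntimeError(
            "no polymorphic sites in the sample; increase mutation_rate or "
            "founder_sites_per_chrom"
        )
    # favoured-allele sample frequency, recorded before minor-allele
    # orientation folds frequencies to <= 0.5
    swept_freq = float(haps.haplotypes[:, sel_index].mean()) if sel_index is not None else None
    haps = _orient_to_minor(haps)
    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "generation"])
    selected = None
    if sel_site is not None:
        selected = {
            "chrom": str(sel_site[0] + 1),
            "bp": int(sel_site[1]),
            "snp_index": sel_index,
            "swept_freq": swept_freq,
        }
    return SimulationResult(
        haplotypes=haps,
        genotypes=haps.to_genotypes(),
        pedigree=pedigree,
        true_ne=list(scenario.ne_history),
        selected_site=selected,
        het_history=het_history,
    )


def _carrier_homogeneity(H: np.ndarray, j: int, carriers: np.ndarray, window: int = 60) -> float:
    """Fraction of carrier pairs identical over +-window SNPs around site j."""
    if carriers.size < 2:
        return 0.0
    lo, hi = max(0, j - window), min(H.shape[1], j + window + 1)
    sub = H[np.ix_(carriers, np.arange(lo, hi))]
    _, counts = np.unique(sub, axis=0, return_counts=True)
    same = int((counts * (counts - 1) // 2).sum())
    return same / (carriers.size * (carriers.size - 1) // 2)


def _pick_selected_site(H_list, pos_list, locus: SelectedLocus):
    """Choose the standing variant selection will act on.

    The starting frequency band is chosen so that deterministic additive
    growth over the sweep's duration lands near 0.7: past 0.5 (detectable,
    satisfying the frequency target) but short of fixation, where the
    haplotype contrast the long-range test needs would disappear. Within the
    band, prefer the variant whose carriers share a single haplotype
    background (a young variant): sweeping a young variant drags one long
    haplotype to high frequency — the classic hard-sweep signature — whereas
    an old variant scattered over many backgrounds gives only a soft sweep.
    """
    c = locus.chrom - 1
    p = H_list[c].mean(axis=0)
    maf = np.minimum(p, 1 - p)
    # backward-iterate the deterministic additive recursion
    # p' = p (1 + s(1+p)/2) / (1 + s p) from a target endpoint of 0.6, so
    # drift scatters final frequencies around 0.45-0.8 rather than fixation
    p_star = 0.6
    for _ in range(locus.onset_generation):
        lo_b, hi_b = 1e-6, p_star
        for _bisect in range(50):
            mid = 0.5 * (lo_b + hi_b)
            nxt = mid * (1 + locus.s * (1 + mid) / 2) / (1 + locus.s * mid)
            if nxt < p_star:
                lo_b = mid
            else:
                hi_b = mid
        p_star = 0.5 * (lo_b + hi_b)
    lo, hi = max(0.01, 0.7 * p_star), min(0.45, 1.5 * p_star)
    eligible = np.flatnonzero((maf >= lo) & (maf <= hi))
    if eligible.size == 0:
        eligible = np.flatnonzero((maf >= 0.02) & (maf <= 0.5))
    if eligible.size == 0:
        eligible = np.flatnonzero((p > 0) & (p < 1))
    if eligible.size == 0:
        raise RuntimeError("no segregating site available for the selected locus")
    # rank candidates: carrier-background homogeneity first, proximity second;
    # keep the search local so the sweep lands near the requested position
    # (and away from chromosome ends, where EHH windows truncate)
    radius = 3_000_000
    local = eligible[np.abs(pos_list[c][eligible] - locus.bp) <= radius]
    while local.size == 0 and radius < pos_list[c][-1]:
        radius *= 2
        local = eligible[np.abs(pos_list[c][eligible] - locus.bp) <= radius]
    order = local[np.argsort(np.abs(pos_list[c][local] - locus.bp))][:60]
    best_j, best_score = None, -1.0
    for j in order:
        minor_is_one = p[j] <= 0.5
        carriers = np.flatnonzero(H_list[c][:, j] == (1 if minor_is_one else 0))
        score = _carrier_homogeneity(H_list[c], int(j), carriers)
        if score > best_score:
            best_j, best_score = int(j), score
    j = best_j
    # selection favours allele 1; flip the column if needed so the favoured
    # variant starts from the minor frequency
    if p[j] > 0.5:
        H_list[c][:, j] = 1 - H_list[c][:, j]
    return (c, int(pos_list[c][j]))


def _simulate_donor(rng, founder_pos, pos_list, length_bp, morgan_len,
                    n_dip: int = 1000, generations: int = 20) -> list:
    """Large outside population sharing the founder site grid.

    Donor founders draw independent frequencies at the focal population's
    founder sites (zero elsewhere) and drift for a short burn-in; only its
    final generation is used, as a gamete pool for the admixture pulse.
    """
    donor_H = []
    for c in range(len(pos_list)):
        on_grid = np.isin(pos_list[c], founder_pos[c])
        freq = np.where(on_grid, rng.uniform(0.05, 0.95, size=len(pos_list[c])), 0.0)
        donor_H.append((rng.random((2 * n_dip, len(pos_list[c]))) < freq).astype(np.int8))
    for _t in range(generations):
        parents_a = rng.integers(0, n_dip, size=n_dip)
        offset = 1 + rng.integers(0, n_dip - 1, size=n_dip)
        parents_b = (parents_a + offset) % n_dip
        for c in range(len(donor_H)):
            g1 = _make_gametes(donor_H[c], pos_list[c], parents_a, rng, morgan_len, length_bp)
            g2 = _make_gametes(donor_H[c], pos_list[c], parents_b, rng, morgan_len, length_bp)
            H = np.empty_like(donor_H[c])
            H[0::2] = g1
            H[1::2] = g2
            donor_H[c] = H
    return donor_H


def _donor_gametes(donor_H, pos, n, rng, morgan_len, length_bp):
    parents = rng.integers(0, donor_H.shape[0] // 2, size=n)
    return _make_gametes(donor_H, pos, parents, rng, morgan_len, length_bp)


def _build_variant_table(
    H_list, pos_list, hap_rows, sel_site, founder_pos, founder_freq, keep_monomorphic
):
    """Assemble the sample's variant table, haplotype matrix and panel freqs.

    Panel frequencies are the ancestral-pool draws for founder-origin sites
    and 0 for breed-private mutations (which a chip would never carry).
    """
    mats, rows, panel = [], [], []
    sel_index = None
    snp_counter = 0
    for c in range(len(H_list)):
        sub = H_list[c][hap_rows]
        if keep_monomorphic:
            keep = np.ones(sub.shape[1], dtype=bool)
        else:
            counts = sub.sum(axis=0)
            keep = (counts > 0) & (counts < sub.shape[0])
        sub = sub[:, keep]
        pos = pos_list[c][keep]
        j = np.searchsorted(founder_pos[c], pos)
        j = np.clip(j, 0, len(founder_pos[c]) - 1)
        is_founder = founder_pos[c][j] == pos
        pf = np.where(is_founder, founder_freq[c][j], 0.0)
        panel.append(pf)
        for k, bp in enumerate(pos):
            if sel_site is not None and sel_site[0] == c and bp == sel_site[1]:
                sel_index = snp_counter
            rows.append((f"snp{c+1}_{k+1}", str(c + 1), int(bp), "A", "B"))
            snp_counter += 1
        mats.append(sub)
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "bp", "allele1", "allele2"])
    mat = np.concatenate(mats, axis=1) if mats else np.empty((len(hap_rows), 0), dtype=np.int8)
    return variants, mat, sel_index, np.concatenate(panel) if panel else np.empty(0)


def _relocate_selected(haps: HaplotypeSet, sel_site):
    if sel_site is None:
        return None
    chrom, bp = str(sel_site[0] + 1), sel_site[1]
    hit = haps.variants.index[
        (haps.variants["chrom"] == chrom) & (haps.variants["bp"] == bp)
    ]
    return int(hit[0]) if len(hit) else None


def _orient_to_minor(haps: HaplotypeSet) -> HaplotypeSet:
    """Flip sites where allele 1 is major so haplotype 1-alleles are minor.

    Keeps the invariant that the two haplotype rows of a sample sum to its
    genotype code after the genotype matrix is minor-oriented.
    """
    p = haps.haplotypes.mean(axis=0)
    flip = p > 0.5
    mat = haps.haplotypes.copy()
    mat[:, flip] = 1 - mat[:, flip]
    variants = haps.variants.copy()
    a1 = variants["allele1"].to_numpy().copy()
    a2 = variants["allele2"].to_numpy().copy()
    a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
    variants["allele1"] = a1
    variants["allele2"] = a2
    return HaplotypeSet(list(haps.sample_ids), variants, mat)


# ---------------------------------------------------------------------------
# chip-like ascertainment
# ---------------------------------------------------------------------------

def ascertain_snps(
    haps: HaplotypeSet,
    n_target: int,
    maf_floor: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    panel_freqs: np.ndarray | None = None,
    must_include: np.ndarray | None = None,
) -> HaplotypeSet:
    """Pick ``n_target`` sites on a near-uniform bp grid, subject to a MAF floor.

    Mirrors the roughly uniform spacing of array SNPs: per chromosome, ideal
    grid positions are laid out evenly and the nearest unused eligible site is
    taken for each. ``panel_freqs`` optionally supplies the frequencies the
    MAF floor is applied to (e.g. an outgroup discovery panel); by default the
    sample's own frequencies are used.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = haps.haplotypes.mean(axis=0) if panel_freqs is None else np.asarray(panel_freqs)
    maf = np.minimum(p, 1 - p)
    eligible_all = maf >= maf_floor
    if int(eligible_all.sum()) < n_target:
        raise ValueError(
            f"cannot ascertain {n_target} SNPs: only {int(eligible_all.sum())} "
            f"sites pass the MAF floor {maf_floor}"
        )
    chroms = haps.variants["chrom"].to_numpy()
    bp = haps.variants["bp"].to_numpy()
    uniq = list(dict.fromkeys(chroms))
    n_elig = {c: int((eligible_all & (chroms == c)).sum()) for c in uniq}
    total_elig = sum(n_elig.values())
    # proportional allocation, largest remainders
    raw = {c: n_target * n_elig[c] / total_elig for c in uniq}
    alloc = {c: int(np.floor(raw[c])) for c in uniq}
    leftovers = sorted(uniq, key=lambda c: raw[c] - alloc[c], reverse=True)
    for c in leftovers:
        if sum(alloc.values()) == n_target:
            break
        if alloc[c] < n_elig[c]:
            alloc[c] += 1
    chosen: list[int] = []
    for c in uniq:
        idx = np.flatnonzero(eligible_all & (chroms == c))
        k = min(alloc[c], idx.size)
        if k == 0:
            continue
        if k == idx.size:
            chosen.extend(idx.tolist())
            continue
        grid = np.linspace(bp[idx[0]], bp[idx[-1]], k)
        used = np.zeros(idx.size, dtype=bool)
        site_bp = bp[idx]
        for g in grid:
            order = np.argsort(np.abs(site_bp - g))
            for j in order:
                if not used[j]:
                    used[j] = True
                    chosen.append(int(idx[j]))
                    break
    keep = np.array(sorted(set(chosen) | set(must_include.tolist() if must_include is not None else [])))
    return haps.subset_snps(keep)


# ---------------------------------------------------------------------------
# designed sib-mating lines (for inbreeding-recovery experiments)
# ---------------------------------------------------------------------------

def simulate_sib_lines(
    depths: list,
    seed: int = 0,
    n_chrom: int = 2,
    chrom_length_bp: int = 20_000_000,
    founder_sites_per_chrom: int = 600,
    base_ne: int = 60,
    base_generations: int = 15,
) -> tuple[SimulationResult, pd.DataFrame]:
    """Full-sib mating lines of given depths on top of a simulated base stock.

    For each requested depth d, two base-population founders produce a pair
    of full sibs which are then sib-mated for d-1 further generations; the
    last offspring of each line is genotyped. Depth 0 returns a base founder
    itself. Returns the combined result (genotypes of one terminal individual
    per line, full pedigree) and a table with each line's expected pedigree
    inbreeding (F after d generations of sib mating: 0, 0.25, 0.375, ...).
    """
    base = simulate(
        WFScenario(
            ne_history=[base_ne] * base_generations,
            n_chrom=n_chrom,
            chrom_length_bp=chrom_length_bp,
            founder_sites_per_chrom=founder_sites_per_chrom,
            mutation_rate=0.0,
            sample_size=base_ne,
            seed=seed,
        )
    )
    rng = np.random.default_rng(seed + 1)
    haps = base.haplotypes
    L = chrom_length_bp
    morgan_len = L * 1e-8
    chrom_idx = [
        haps.variants.index[haps.variants["chrom"] == str(c + 1)].to_numpy()
        for c in range(n_chrom)
    ]
    pos = [haps.variants.loc[ix, "bp"].to_numpy() for ix in chrom_idx]

    # expected F under repeated full-sib mating: F_t = (1 + 2F_{t-1} + F_{t-2})/4
    def sib_f(d: int) -> float:
        f2, f1 = 0.0, 0.0
        for _ in range(d):
            f2, f1 = f1, (1 + 2 * f1 + f2) / 4.0
        return f1

    ped_rows = []
    out_ids, out_haps = [], []
    expected = []
    founder_pool = list(range(base_ne))
    rng.shuffle(founder_pool)
    pool_iter = iter(founder_pool)

    def gamete(ind_haps: list) -> list:
        # ind_haps: [hapA, hapB] per chromosome
        out = []
        for c in range(n_chrom):
            H = np.stack([ind_haps[c][0], ind_haps[c][1]])
            g = _make_gametes(H, pos[c], np.array([0]), rng, morgan_len, L)[0]
            out.append(g)
        return out

    for li, d in enumerate(depths):
        fa, mo = next(pool_iter), next(pool_iter)
        fa_id, mo_id = f"L{li}F0", f"L{li}M0"
        ped_rows += [(fa_id, "0", "0", 0), (mo_id, "0", "0", 0)]

        def ind_of(sample_index: int) -> list:
            return [
                [
                    haps.haplotypes[2 * sample_index, chrom_idx[c]],
                    haps.haplotypes[2 * sample_index + 1, chrom_idx[c]],
                ]
                for c in range(n_chrom)
            ]

        if d == 0:
            out_ids.append(fa_id)
            out_haps.append(ind_of(fa))
            expected.append((fa_id, 0, 0.0))
            continue
        # generation 1 kids descend from unrelated founders (F = 0); each of
        # the following d generations is one round of full-sib mating
        sire, dam = ind_of(fa), ind_of(mo)
        sire_id, dam_id = fa_id, mo_id
        for gen in range(1, d + 2):
            kids = []
            for k in range(2):
                h1, h2 = gamete(sire), gamete(dam)
                kids.append([[h1[c], h2[c]] for c in range(n_chrom)])
                ped_rows.append((f"L{li}G{gen}K{k}", sire_id, dam_id, gen))
            sire, dam = kids
            sire_id, dam_id = f"L{li}G{gen}K0", f"L{li}G{gen}K1"
        out_ids.append(sire_id)
        out_haps.append(sire)
        expected.append((sire_id, d, sib_f(d)))

    mat = np.empty((2 * len(out_ids), haps.n_snps), dtype=np.int8)
    for i, ind in enumerate(out_haps):
        mat[2 * i] = np.concatenate([ind[c][0] for c in range(n_chrom)])
        mat[2 * i + 1] = np.concatenate([ind[c][1] for c in range(n_chrom)])
    line_haps = HaplotypeSet(out_ids, haps.variants.copy(), mat)
    result = SimulationResult(
        haplotypes=line_haps,
        genotypes=line_haps.to_genotypes(),
        pedigree=pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "generation"]),
        true_ne=[base_ne],
        selected_site=None,
    )
    table = pd.DataFrame(expected, columns=["sample_id", "depth", "expected_f_ped"])
    return result, table


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _tiny_toy() -> SimulationResult:
    """Hand-checkable 3-sample, 8-SNP dataset on two chromosomes."""
    variants = pd.DataFrame(
        {
            "snp_id": [f"t{k}" for k in range(1, 9)],
            "chrom": ["1"] * 5 + ["2"] * 3,
            "bp": [100_000, 400_000, 900_000, 1_500_000, 2_000_000,
                   200_000, 800_000, 1_600_000],
            "allele1": ["A"] * 8,
            "allele2": ["B"] * 8,
        }
    )
    hap = np.array(
        [
            [0, 0, 0, 0, 0, 0, 1, 0],
            [0, 0, 0, 0, 0, 1, 1, 0],
            [1, 0, 1, 0, 0, 0, 0, 1],
            [1, 0, 1, 0, 0, 0, 0, 1],
            [0, 1, 0, 1, 1, 1, 0, 0],
            [0, 1, 0, 0, 1, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    haps = HaplotypeSet(["toy1", "toy2", "toy3"], variants, hap)
    ped = pd.DataFrame(
        {
            "id": ["toy1", "toy2", "toy3"],
            "sire": ["0", "0", "0"],
            "dam": ["0", "0", "0"],
            "generation": [0, 0, 0],
        }
    )
    return SimulationResult(haps, haps.to_genotypes(), ped, [3], None)


def bottleneck28_scenario(seed: int = 0) -> WFScenario:
    """A ~50x scaled-down analogue of a strongly bottlenecked breed history.

    Long plateau near Ne 13 preceded by a slightly larger ancestral size,
    a small recovery in the most recent generations and a 1/16 admixture
    pulse five generations back; 28 sampled diploids. The plateau length is
    set so founder heterozygosity (~0.30) drifts down to ~0.05, i.e. a mean
    SNP homozygosity around 0.95 like a severely bottlenecked breed.
    """
    history = [25] * 30 + [13] * 60 + [16, 19, 19, 30, 30, 30]
    return WFScenario(
        ne_history=history,
        n_chrom=3,
        chrom_length_bp=25_000_000,
        founder_sites_per_chrom=1100,
        mutation_rate=1e-9,
        n_segsites_target=2400,
        admixture=(5, 1.0 / 16.0),
        sample_size=28,
        seed=seed,
    )


def sweep_demo_scenario(seed: int = 0) -> WFScenario:
    """Two-chromosome scenario with one positively selected standing variant.

    The neutral background (constant Ne 150 over 80 generations) keeps
    long-range haplotype homozygosity moderate: neutral cores still carry
    frequent haplotypes (frequency-bin controls exist) while their extended
    homozygosity decays within a couple of Mb. The recent strong sweep
    (s = 0.8 over the last 12 generations, acting on a young standing
    variant) then shows as a long, frequent haplotype — a run of
    elevated-REHH cores — against its frequency class. Sixteen chromosomes
    keep the swept region a small fraction of each frequency bin.
    """
    history = [150] * 80
    return WFScenario(
        ne_history=history,
        n_chrom=16,
        chrom_length_bp=15_000_000,
        founder_sites_per_chrom=500,
        mutation_rate=0.0,
        n_segsites_target=7200,
        selected_locus=SelectedLocus(chrom=1, bp=7_500_000, s=0.8, onset_generation=12),
        sample_size=56,
        seed=seed,
    )


def make_fixture(name: str, out_dir, seed: int = 0) -> dict:
    """Write a named fixture (.ped/.map, phased TSV, pedigree CSV, truth JSON)."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "tiny_toy":
        result = _tiny_toy()
    elif name == "bottleneck28":
        result = simulate(bottleneck28_scenario(seed))
    else:
        result = simulate(sweep_demo_scenario(seed))

    prefix = out / name
    write_plink_text(result.genotypes, f"{prefix}.ped", f"{prefix}.map")
    write_haplotypes_tsv(result.haplotypes, f"{prefix}.haps.tsv")
    result.pedigree.to_csv(f"{prefix}.pedigree.csv", index=False)
    truth = {
        "true_ne": [int(n) for n in result.true_ne],
        "selected_site": result.selected_site,
        "n_samples": result.genotypes.n_samples,
        "n_snps": result.genotypes.n_snps,
    }
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {
        "ped": f"{prefix}.ped",
        "map": f"{prefix}.map",
        "haps": f"{prefix}.haps.tsv",
        "pedigree": f"{prefix}.pedigree.csv",
        "truth": f"{prefix}.truth.json",
    }
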