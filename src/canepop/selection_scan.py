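"""Long-range haplotype test: EHH, REHH and frequency-binned significance.

Extended haplotype homozygosity (EHH) of a core haplotype is the probability
that two randomly drawn chromosomes carrying that core are identical at every
SNP from the core edge out to a test distance. Relative EHH (REHH) divides by
the pair-count-weighted mean EHH of all other haplotypes at the same core,
cancelling local recombination-rate variation. Recent positive selection
leaves haplotypes that are both frequent and long, i.e. high-frequency cores
with REHH far above their frequency class; scores are z-values of ln REHH
within 20 equal-width core-frequency bins, converted to one-sided upper-tail
normal p-values and reported as -log10 P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import HaplotypeSet

logger = logging.getLogger(__name__)


@dataclass
class CoreRegion:
    """A window of consecutive SNPs and the distinct haplotypes across it."""

    chrom: str
    snp_lo: int  # positional indices into the chromosome's SNPs, inclusive
    snp_hi: int
    start_bp: int
    end_bp: int
    haplotypes: dict = field(default_factory=dict)  # allele string -> row indices

    @property
    def counts(self) -> dict:
        return {h: len(rows) for h, rows in self.haplotypes.items()}


def _chrom_arrays(haps: HaplotypeSet, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    idx = haps.variants.index[haps.variants["chrom"] == chrom].to_numpy()
    return haps.haplotypes[:, idx], haps.variants.loc[idx, "bp"].to_numpy()


def _hap_string(row: np.ndarray) -> str:
    return "".join("1" if a else "0" for a in row)


def define_cores(haps: HaplotypeSet, core_snps: int = 10, step_snps: int | None = None) -> list[CoreRegion]:
    """Tile each chromosome with fixed-size core windows (remainder dropped)."""
    if step_snps is None:
        step_snps = core_snps
    cores: list[CoreRegion] = []
    for chrom in haps.variants["chrom"].unique():
        H, bp = _chrom_arrays(haps, str(chrom))
        m = H.shape[1]
        for lo in range(0, m - core_snps + 1, step_snps):
            hi = lo + core_snps - 1
            groups: dict[str, list[int]] = {}
            for r in range(H.shape[0]):
                groups.setdefault(_hap_string(H[r, lo : hi + 1]), []).append(r)
            cores.append(
                CoreRegion(
                    str(chrom), lo, hi, int(bp[lo]), int(bp[hi]),
                    {h: np.array(rows) for h, rows in groups.items()},
                )
            )
    return cores


def _pair_homozygosity(H: np.ndarray) -> float:
    """Fraction of chromosome pairs identical across all columns of H."""
    n = H.shape[0]
    if n < 2:
        return 0.0
    total = n * (n - 1) // 2
    _, counts = np.unique(H, axis=0, return_counts=True)
    same = int((counts * (counts - 1) // 2).sum())
    return same / total


def ehh(
    haps: HaplotypeSet,
    core: CoreRegion,
    haplotype: str,
    distance_bp: float,
    direction: str,
) -> float:
    """EHH of one core haplotype at a physical test distance.

    Among the carriers of the core haplotype, the fraction of pairs identical
    at every SNP from the core edge out to the last SNP within
    ``distance_bp`` in the given direction ('up' = decreasing bp, 'down' =
    increasing bp). With no SNP in the window the value is 1; a single
    carrier gives 0 (no pair information).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if distance_bp < 0:
        raise ValueError("distance_bp must be >= 0")
    if haplotype not in core.haplotypes:
        raise KeyError(f"haplotype {haplotype!r} absent at this core")
    H, bp = _chrom_arrays(haps, core.chrom)
    rows = core.haplotypes[haplotype]
    if len(rows) < 2:
        return 0.0
    if direction == "down":
        mask = (bp > core.end_bp) & (bp <= core.end_bp + distance_bp)
    else:
        mask = (bp < core.start_bp) & (bp >= core.start_bp - distance_bp)
    cols = np.flatnonzero(mask)
    if cols.size == 0:
        return 1.0
    return _pair_homozygosity(H[np.ix_(rows, cols)])


def rehh(
    haps: HaplotypeSet,
    core: CoreRegion,
    haplotype: str,
    distance_bp: float,
    direction: str,
) -> float:
    """EHH of a haplotype relative to all other haplotypes at the same core.

    The reference is the pair-count-weighted mean EHH over the other core
    haplotypes (weights C(n_h', 2)); returns NaN when no other haplotype
    contributes pairs or the reference EHH is zero.
    """
    num = ehh(haps, core, haplotype, distance_bp, direction)
    wsum = 0.0
    acc = 0.0
    for other, rows in core.haplotypes.items():
        if other == haplotype or len(rows) < 2:
            continue
        w = len(rows) * (len(rows) - 1) / 2.0
        acc += w * ehh(haps, core, other, distance_bp, direction)
        wsum += w
    if wsum == 0 or acc == 0:
        return float("nan")
    return num / (acc / wsum)


RESULT_COLUMNS = [
    "chrom", "core_start", "core_end", "haplotype", "frequency",
    "ehh_up", "ehh_down", "rehh_up", "rehh_down", "rehh", "low_freq",
]


def scan_cores(
    haps: HaplotypeSet,
    core_snps: int = 10,
    distance_bp: float = 1_000_000,
    step_snps: int | None = None,
) -> pd.DataFrame:
    """EHH/REHH for every haplotype of every core; REHH is the max direction.

    Haplotypes with frequency < 0.1 are still scored but flagged ``low_freq``
    (the long-range haplotype test has little power below that frequency).
    Each core's EHH values are computed once per direction and shared between
    the REHH numerators and the pair-weighted reference.
    """
    if step_snps is None:
        step_snps = core_snps
    n_chrom_total = 2 * haps.n_samples
    rows = []
    for chrom in haps.variants["chrom"].unique():
        H, bp = _chrom_arrays(haps, str(chrom))
        m = H.shape[1]
        for lo in range(0, m - core_snps + 1, step_snps):
            hi = lo + core_snps - 1
            groups: dict[str, list[int]] = {}
            for r in range(H.shape[0]):
                groups.setdefault(_hap_string(H[r, lo : hi + 1]), []).append(r)
            names = list(groups)
            e: dict[str, dict[str, float]] = {}
            for direction in ("up", "down"):
                if direction == "down":
                    mask = (bp > bp[hi]) & (bp <= bp[hi] + distance_bp)
                else:
                    mask = (bp < bp[lo]) & (bp >= bp[lo] - distance_bp)
                cols = np.flatnonzero(mask)
                vals = {}
                for h in names:
                    rows_h = groups[h]
                    if len(rows_h) < 2:
                        vals[h] = 0.0
                    elif cols.size == 0:
                        vals[h] = 1.0
                    else:
                        vals[h] = _pair_homozygosity(H[np.ix_(rows_h, cols)])
                e[direction] = vals
            pair_w = {h: len(groups[h]) * (len(groups[h]) - 1) / 2.0 for h in names}
            for h in names:
                freq = len(groups[h]) / n_chrom_total
                rel = {}
                for direction in ("up", "down"):
                    wsum = sum(pair_w[o] for o in names if o != h and pair_w[o] > 0)
                    acc = sum(
                        pair_w[o] * e[direction][o]
                        for o in names
                        if o != h and pair_w[o] > 0
                    )
                    rel[direction] = (
                        e[direction][h] / (acc / wsum)
                        if wsum > 0 and acc > 0
                        else float("nan")
                    )
                r_up, r_dn = rel["up"], rel["down"]
                r = (
                    np.nanmax([r_up, r_dn])
                    if not (np.isnan(r_up) and np.isnan(r_dn))
                    else np.nan
                )
                rows.append(
                    (str(chrom), int(bp[lo]), int(bp[hi]), h, freq,
                     e["up"][h], e["down"][h], r_up, r_dn, r, freq < 0.1)
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def score_rehh(results: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Frequency-binned z-scores of ln REHH mapped to -log10 one-sided P.

    Core-haplotype frequencies on (0, 1] are split into ``n_bins`` equal-width
    bins; within each bin the mean and sd of ln REHH standardise members.
    Bins with fewer than two defined REHH values or zero sd leave their
    members unscored (NaN, ``scored = False``).
    """
    out = results.copy()
    freq = out["frequency"].to_numpy(dtype=float)
    bin_id = np.minimum(np.ceil(freq * n_bins).astype(int) - 1, n_bins - 1)
    bin_id = np.maximum(bin_id, 0)
    out["bin_id"] = bin_id
    out["neg_log10_p"] = np.nan
    out["scored"] = False
    with np.errstate(divide="ignore"):  # REHH 0 -> unscorable, handled below
        ln_rehh = np.log(out["rehh"].to_numpy(dtype=float))
    for b in range(n_bins):
        members = np.flatnonzero((bin_id == b) & np.isfinite(ln_rehh))
        if members.size < 2:
            continue
        mu = ln_rehh[members].mean()
        sd = ln_rehh[members].std(ddof=1)
        if sd == 0:
            continue
        z = (ln_rehh[members] - mu) / sd
        p = stats.norm.sf(z)
        out.loc[out.index[members], "neg_log10_p"] = -np.log10(p)
        out.loc[out.index[members], "scored"] = True
    return out


def significant_regions(
    results: pd.DataFrame, min_freq: float = 0.50, min_score: float = 3.0
) -> pd.DataFrame:
    """Scored cores with frequency >= min_freq and -log10 P > min_score."""
    df = results[results["scored"] & (results["frequency"] >= min_freq)
                 & (results["neg_log10_p"] > min_score)]
    cols = ["chrom", "core_start", "core_end", "frequency", "neg_log10_p", "haplotype"]
    return df[cols].sort_values(["chrom", "core_start"]).reset_index(drop=True)


def export_regions_bed(
    table: pd.DataFrame,
    path,
    flank_bp: float = 500_000,
    chrom_sizes: dict | None = None,
) -> None:
    """Write candidate regions extended by ``flank_bp`` both sides as BED.

    Intervals are clipped at chromosome bounds (when sizes are known) but
    deliberately NOT merged: adjacent cores can represent a single sweep yet
    are reported separately. BED output is 0-based half-open.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            start0 = max(int(row.core_start) - 1 - int(flank_bp), 0)
            end = int(row.core_end) + int(flank_bp)
            if chrom_sizes and str(row.chrom) in chrom_sizes:
                end = min(end, int(chrom_sizes[str(row.chrom)]))
            fh.write(f"{row.chrom}\t{start0}\t{end}\t{row.neg_log10_p:.3f}\n")
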