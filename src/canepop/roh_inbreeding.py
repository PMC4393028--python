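"""Runs of homozygosity, consensus ROHs, F_ROH and F_IS.

A ROH is a maximal stretch of consecutive autosomal SNPs in one individual
with no heterozygous call, at most ``max_missing`` missing calls, and
homozygous (non-missing) SNPs at both ends. A run is reported when it spans
at least ``min_snps`` SNPs and at least ``min_length_bp`` bp. The SNP-count
threshold can be derived from dataset-wide homozygosity so that the expected
number of chance runs across the whole analysis stays below an error rate
alpha:

    l = log(alpha / (n_snp * n_ind)) / log(hom)

F_ROH is the fraction of the SNP-covered autosomal genome lying inside an
individual's ROHs; F_IS contrasts observed and expected homozygous genotype
counts per individual, (O - E) / (n - E).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class ROHParams:
    """Calling rules for ROH detection (defaults follow common chip practice)."""

    min_snps: int = 50
    min_length_bp: int = 1_000_000
    max_het: int = 0
    max_missing: int = 5

    def __post_init__(self) -> None:
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")
        if self.max_het != 0:
            raise NotImplementedError("heterozygote-tolerant calling is not supported")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class ConsensusROH:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class InbreedingRecord:
    sample_id: str
    f_is: float
    obs_hom: int
    exp_hom: float
    n_genotyped: int
    f_roh: dict = field(default_factory=dict)  # (min_snps, min_length_bp) -> fraction


def min_snp_threshold(alpha: float, n_snp: float, n_ind: int, hom: float) -> int:
    """Minimum homozygous-run SNP count keeping chance ROHs below alpha.

    ``hom`` is the mean per-SNP homozygosity of the dataset; the threshold
    grows as homozygosity approaches 1. Rounded to the nearest integer.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < hom < 1:
        raise ValueError("hom must be in (0, 1); hom=1 leaves the threshold undefined")
    if n_snp * n_ind < 1:
        raise ValueError("n_snp * n_ind must be >= 1")
    return round(math.log(alpha / (n_snp * n_ind)) / math.log(hom))


def _maximal_runs(status: np.ndarray, max_missing: int) -> list[tuple[int, int]]:
    """Maximal windows [i, j] with no het, <= max_missing missing, hom ends.

    ``status``: 0 = hom, 1 = het, 2 = missing. Windows are maximal under
    containment; when more than ``max_missing`` missing calls fall between two
    heterozygous calls the maximal windows overlap.
    """
    runs: list[tuple[int, int]] = []
    m = len(status)
    het = np.flatnonzero(status == 1)
    block_bounds = np.concatenate([[-1], het, [m]])
    for b in range(len(block_bounds) - 1):
        lo, hi = block_bounds[b] + 1, block_bounds[b + 1] - 1
        if hi < lo:
            continue
        miss = np.flatnonzero(status[lo : hi + 1] == 2) + lo
        windows: list[tuple[int, int]] = []
        if len(miss) <= max_missing:
            windows.append((lo, hi))
        else:
            fence = np.concatenate([[lo - 1], miss, [hi + 1]])
            for t in range(len(miss) - max_missing + 1):
                windows.append((fence[t] + 1, fence[t + max_missing + 1] - 1))
        for wlo, whi in windows:
            hom_idx = np.flatnonzero(status[wlo : whi + 1] == 0) + wlo
            if hom_idx.size == 0:
                continue
            runs.append((int(hom_idx[0]), int(hom_idx[-1])))
    # dedupe and drop windows contained in another (trimming can nest them)
    runs = sorted(set(runs))
    kept = [
        r
        for r in runs
        if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)
    ]
    return kept


def detect_roh(ds: GenotypeDataset, sample_id: str, params: ROHParams) -> list[ROHSegment]:
    """Call ROHs for one individual, per chromosome, never spanning chromosomes."""
    i = ds.sample_ids.index(sample_id)
    g = ds.genotypes[i]
    segments: list[ROHSegment] = []
    for chrom, grp in ds.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        codes = g[idx]
        status = np.where(codes == MISSING, 2, np.where(codes == 1, 1, 0)).astype(np.int8)
        bp = grp["bp"].to_numpy()
        for lo, hi in _maximal_runs(status, params.max_missing):
            n = hi - lo + 1
            length = int(bp[hi] - bp[lo])
            if n >= params.min_snps and length >= params.min_length_bp:
                segments.append(
                    ROHSegment(sample_id, str(chrom), int(bp[lo]), int(bp[hi]), n)
                )
    return segments


def detect_roh_all(ds: GenotypeDataset, params: ROHParams) -> dict[str, list[ROHSegment]]:
    return {sid: detect_roh(ds, sid, params) for sid in ds.sample_ids}


def consensus_roh(
    segments_by_sample: dict[str, list[ROHSegment]], variants: pd.DataFrame
) -> list[ConsensusROH]:
    """Intersect every sample's ROH coverage on SNP support.

    A SNP is covered for a sample when it lies inside any of that sample's
    segments; maximal runs of SNPs covered in all samples become consensus
    intervals with SNP-position endpoints. No minimum length is applied.
    """
    out: list[ConsensusROH] = []
    for chrom, grp in variants.groupby("chrom", sort=False):
        bp = grp["bp"].to_numpy()
        covered_all = np.ones(len(bp), dtype=bool)
        for segs in segments_by_sample.values():
            cov = np.zeros(len(bp), dtype=bool)
            for s in segs:
                if s.chrom == str(chrom):
                    cov |= (bp >= s.start_bp) & (bp <= s.end_bp)
            covered_all &= cov
            if not covered_all.any():
                break
        idx = np.flatnonzero(covered_all)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for a, b in zip(starts, ends):
            out.append(
                ConsensusROH(str(chrom), int(bp[idx[a]]), int(bp[idx[b]]), int(idx[b] - idx[a] + 1))
            )
    return out


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for lo, hi in sorted(ivals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def froh(
    segments: list[ROHSegment] | list[ConsensusROH],
    denominator_bp: float,
    min_length_bp: int = 0,
) -> float:
    """Fraction of the genome in ROHs of at least ``min_length_bp``.

    Overlapping segments (possible when missing calls split a region into
    overlapping maximal windows) are merged per chromosome before summing, so
    the result is a true genome fraction.
    """
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        if s.length_bp >= min_length_bp:
            by_chrom.setdefault(s.chrom, []).append((s.start_bp, s.end_bp))
    total = sum(
        hi - lo for ivals in by_chrom.values() for lo, hi in _merge_intervals(ivals)
    )
    return total / denominator_bp


def snp_covered_length(variants: pd.DataFrame) -> int:
    """Default F_ROH denominator: sum over chromosomes of last - first SNP bp."""
    return int(
        sum(grp["bp"].iloc[-1] - grp["bp"].iloc[0] for _, grp in variants.groupby("chrom"))
    )


def roh_generations(min_length_bp: float, recomb_scale: float = 1e-8) -> int:
    """Generations back probed by ROHs of a given minimum length.

    IBD segments from a common ancestor g generations back have mean length
    1/(2g) Morgan, so a length floor of L Morgan looks back ~1/(2L)
    generations.
    """
    if min_length_bp <= 0:
        raise ValueError("min_length_bp must be positive")
    return round(1.0 / (2.0 * min_length_bp * recomb_scale))


def fis(ds: GenotypeDataset, small_sample_correction: bool = True) -> list[InbreedingRecord]:
    """Per-individual fixation index F_IS = (O - E) / (n - E).

    O is the observed homozygous-SNP count over the SNPs genotyped in that
    individual; E sums expected homozygosity 1 - 2pq (with the 2N/(2N-1)
    small-sample factor by default) over the same SNPs. SNPs with fewer than
    two genotyped samples are excluded from both counts.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = ds.genotypes
    present = g != MISSING
    n_called = present.sum(axis=0)
    usable = n_called >= 2
    p = ds.allele2_freq()
    exp_het = 2.0 * p * (1.0 - p)
    if small_sample_correction:
        with np.errstate(divide="ignore", invalid="ignore"):
            exp_het = exp_het * (2.0 * n_called / (2.0 * n_called - 1.0))
    exp_hom_snp = 1.0 - exp_het
    records = []
    for i, sid in enumerate(ds.sample_ids):
        mask = present[i] & usable
        n_i = int(mask.sum())
        o_i = int(((g[i] == 0) | (g[i] == 2))[mask].sum())
        e_i = float(exp_hom_snp[mask].sum())
        denom = n_i - e_i
        f = (o_i - e_i) / denom if denom != 0 else float("nan")
        records.append(InbreedingRecord(sid, f, o_i, e_i, n_i))
    return records


def roh_length_histogram(
    segments: list[ROHSegment], edges: tuple[float, float] = (5e6, 10e6)
) -> dict[str, int]:
    """Counts of segments per length category; boundary goes to the lower one."""
    lo_edge, hi_edge = edges
    counts = {"short": 0, "mid": 0, "long": 0}
    for s in segments:
        if s.length_bp <= lo_edge:
            counts["short"] += 1
        elif s.length_bp <= hi_edge:
            counts["mid"] += 1
        else:
            counts["long"] += 1
    return counts


def correlate_measures(
    table: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r and two-sided p for chosen column pairs of a per-sample table."""
    if len(table) < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for a, b in pairs:
        x = table[a].to_numpy(dtype=float)
        y = table[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((a, b, float("nan"), float("nan"), True))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((a, b, float(r), float(p), False))
    return pd.DataFrame(rows, columns=["x", "y", "r", "p", "degenerate"])


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def segments_to_bed(segments, path) -> None:
    """Write segments as BED (0-based half-open; internal coords are 1-based closed)."""
    with open(path, "w") as fh:
        for s in segments:
            name = getattr(s, "sample_id", "consensus")
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{name}\n")


def segments_to_frame(segments) -> pd.DataFrame:
    rows = [
        {
            "sample_id": getattr(s, "sample_id", "consensus"),
            "chrom": s.chrom,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "n_snps": s.n_snps,
            "length_bp": s.length_bp,
        }
        for s in segments
    ]
    cols = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]
    return pd.DataFrame(rows, columns=cols)
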