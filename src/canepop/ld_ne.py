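"""Pairwise LD (r²), distance-binned decay, and the LD-based Ne trajectory.

The ancestral effective population size at a genetic distance c (Morgan) is
obtained by inverting Sved's equilibrium relation E[r²] = 1/(1 + 4Nc):

    Ne = (1 - r²) / (4 c r²)

Physical distance maps to genetic distance through a uniform recombination
scale (default 1e-8 Morgan/bp, i.e. 100 Mb = 1 Morgan), and LD at distance c
reflects ancestry roughly g = 1/(2c) generations back — the same relation
that gives IBD segments from an ancestor g generations ago a mean length of
1/(2g) Morgan. The per-generation increase of inbreeding is dF = 1/(2 Ne).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, HaplotypeSet

logger = logging.getLogger(__name__)

#: 100 Mb = 1 Morgan
DEFAULT_RECOMB_SCALE = 1e-8

PAIR_COLUMNS = ["chrom", "dist_bp", "r2"]
BIN_COLUMNS = ["lo_bp", "hi_bp", "n_pairs", "mean_r2"]


def _r2_from_haplotypes(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r² matrix from phased 0/1 haplotypes; returns (r2, polymorphic mask)."""
    n = H.shape[0]
    p = H.mean(axis=0)
    poly = (p > 0) & (p < 1)
    Hp = H[:, poly].astype(np.float64)
    pp = p[poly]
    joint = (Hp.T @ Hp) / n  # p11
    D = joint - np.outer(pp, pp)
    denom = np.outer(pp * (1 - pp), pp * (1 - pp))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = D * D / denom
    return r2, poly


def _r2_from_genotypes(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complete-case squared Pearson correlation of genotype codes.

    Vectorised over all pairs via masked cross-products; pairs with fewer
    than two jointly informative samples, or zero variance in the joint
    sample, come out NaN and are skipped by the caller.
    """
    M = (G != MISSING).astype(np.float64)
    X = np.where(G == MISSING, 0, G).astype(np.float64)
    n = M.T @ M
    Sx = X.T @ M
    Sy = Sx.T
    Sxy = X.T @ X
    Sxx = (X * X).T @ M
    Syy = Sxx.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * Sxy - Sx * Sy
        varx = n * Sxx - Sx * Sx
        vary = n * Syy - Sy * Sy
        r2 = (cov * cov) / (varx * vary)
    r2[n < 2] = np.nan
    # exclude SNPs monomorphic over all samples from pairing
    p = np.ma.masked_equal(G, MISSING).mean(axis=0) / 2.0
    poly = np.asarray((p > 0) & (p < 1))
    return r2, poly


def pairwise_r2(
    data: GenotypeDataset | HaplotypeSet,
    min_dist_bp: float = 1_000,
    max_dist_bp: float = 50_000_000,
) -> pd.DataFrame:
    """Within-chromosome r² for SNP pairs with min_dist <= distance <= max_dist.

    Phased input uses haplotype frequencies (r² = D²/(p1 q1 p2 q2)); genotype
    input uses the squared Pearson correlation of 0/1/2 codes over samples
    with both calls present (composite LD). Monomorphic SNPs never pair.
    """
    phased = isinstance(data, HaplotypeSet)
    frames = []
    n_skipped = 0
    for chrom, grp in data.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            continue
        if phased:
            r2, poly = _r2_from_haplotypes(data.haplotypes[:, idx])
        else:
            r2, poly = _r2_from_genotypes(data.genotypes[:, idx])
            r2 = r2[np.ix_(poly, poly)]
        bp = grp["bp"].to_numpy()[poly]
        if bp.size < 2:
            continue
        dist = np.abs(bp[:, None] - bp[None, :])
        iu = np.triu_indices(bp.size, k=1)
        d = dist[iu].astype(np.int64)
        r = r2[iu]
        in_range = (d >= min_dist_bp) & (d <= max_dist_bp)
        bad = np.isnan(r) & in_range
        n_skipped += int(bad.sum())
        sel = in_range & ~np.isnan(r)
        frames.append(
            pd.DataFrame({"chrom": str(chrom), "dist_bp": d[sel], "r2": r[sel]})
        )
    if n_skipped:
        logger.info("pairwise_r2: skipped %d uninformative pairs", n_skipped)
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def bin_ld(pairs: pd.DataFrame, bin_width_bp: float = 100_000) -> pd.DataFrame:
    """Group pairs into half-open distance bins [k*w, (k+1)*w); empty bins omitted.

    The bin mean is the unweighted arithmetic mean of member r² values.
    """
    if bin_width_bp <= 0:
        raise ValueError("bin_width_bp must be positive")
    if pairs.empty:
        return pd.DataFrame(columns=BIN_COLUMNS)
    k = np.floor(pairs["dist_bp"].to_numpy() / bin_width_bp).astype(np.int64)
    df = pairs.assign(_k=k).groupby("_k")["r2"].agg(["size", "mean"]).reset_index()
    return pd.DataFrame(
        {
            "lo_bp": df["_k"] * bin_width_bp,
            "hi_bp": (df["_k"] + 1) * bin_width_bp,
            "n_pairs": df["size"].astype(int),
            "mean_r2": df["mean"],
        }
    )


def generations_for_distance(dist_bp: float, recomb_scale: float = DEFAULT_RECOMB_SCALE) -> int:
    """Generations back probed by LD at a physical distance, g = round(1/(2c))."""
    if dist_bp <= 0:
        raise ValueError("dist_bp must be positive")
    g = round(1.0 / (2.0 * dist_bp * recomb_scale))
    if g < 1:
        warnings.warn("distance maps to g < 1; clamped to 1 generation")
        return 1
    return g


def estimate_ne(bins: pd.DataFrame, recomb_scale: float = DEFAULT_RECOMB_SCALE) -> pd.DataFrame:
    """Fill c, Ne, g and dF for each distance bin (Sved inversion).

    c is the bin-midpoint physical distance times the recombination scale.
    Bins with mean r² of exactly 0 or 1 cannot be inverted; they are kept but
    flagged ``estimated = False`` with NaN estimates.
    """
    if bins.empty:
        raise ValueError("no LD bins to estimate from")
    out = bins.copy()
    mid = (out["lo_bp"].to_numpy() + out["hi_bp"].to_numpy()) / 2.0
    c = mid * recomb_scale
    r2 = out["mean_r2"].to_numpy(dtype=float)
    ok = (r2 > 0) & (r2 < 1)
    ne = np.full_like(c, np.nan)
    ne[ok] = (1.0 - r2[ok]) / (4.0 * c[ok] * r2[ok])
    out["c_morgan"] = c
    out["ne"] = ne
    out["g"] = [generations_for_distance(m, recomb_scale) for m in mid]
    out["delta_f"] = 1.0 / (2.0 * ne)
    out["estimated"] = ok
    return out


def ne_trajectory(estimated_bins: pd.DataFrame) -> pd.DataFrame:
    """Collapse bins to one Ne per generation.

    Several bins can round to the same g; the trajectory reports the
    pair-count-weighted mean Ne (and its dF = 1/(2 Ne)) per generation.
    """
    df = estimated_bins[estimated_bins["estimated"]]
    rows = []
    for g, grp in df.groupby("g"):
        w = grp["n_pairs"].to_numpy(dtype=float)
        ne = float(np.average(grp["ne"].to_numpy(), weights=w))
        rows.append({"g": int(g), "ne": ne, "delta_f": 1.0 / (2.0 * ne), "n_pairs": int(w.sum())})
    return pd.DataFrame(rows).sort_values("g").reset_index(drop=True)
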