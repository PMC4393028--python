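"""PLINK-format genotype I/O, SNP filters, and diversity summaries.

Genotypes are held as an integer matrix of minor-allele counts (0/1/2) with a
distinct sentinel for missing calls. Coordinates are 1-based physical bp and
every interval in the package is closed ``[start_bp, end_bp]`` with length
``end_bp - start_bp``, matching PLINK's reporting conventions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the 0/1/2 count matrix.
MISSING = np.int8(-1)

_SEX_LABELS = {"X", "Y", "XY", "MT", "M", "0"}

VARIANT_COLUMNS = ["snp_id", "chrom", "bp", "allele1", "allele2"]


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported PLINK files."""


def _check_variant_map(variants: pd.DataFrame) -> None:
    missing_cols = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing_cols:
        raise ValueError(f"variant map lacks columns {sorted(missing_cols)}")
    dup = variants.duplicated(subset=["chrom", "bp"])
    if dup.any():
        rows = variants.loc[dup, ["chrom", "bp"]].head()
        raise ValueError(f"duplicate (chrom, bp) entries, e.g.\n{rows}")
    for chrom, grp in variants.groupby("chrom", sort=False):
        bp = grp["bp"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"bp not strictly increasing on chromosome {chrom}")


@dataclass
class GenotypeDataset:
    """Samples x SNPs matrix of allele2 (minor-allele) counts.

    Attributes
    ----------
    sample_ids : list of str
    variants : pandas.DataFrame
        Columns ``snp_id, chrom, bp, allele1, allele2``; ``chrom`` is a string
        label (autosomes are numeric strings, sex chromosomes X/Y/XY/MT).
    genotypes : numpy.ndarray of int8, shape (n_samples, n_snps)
        Count of ``allele2`` per call; ``MISSING`` (-1) marks no-calls.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        if self.genotypes.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} SNPs"
            )
        _check_variant_map(self.variants)
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def allele2_freq(self) -> np.ndarray:
        """Sample frequency of allele2 per SNP (NaN where all calls missing)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        with np.errstate(invalid="ignore"):
            return np.ma.filled(g.mean(axis=0) / 2.0, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele2_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=0)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        return GenotypeDataset(
            list(self.sample_ids),
            self.variants.iloc[keep].reset_index(drop=True),
            self.genotypes[:, keep].copy(),
        )


@dataclass
class HaplotypeSet:
    """Phased 0/1 haplotypes, two rows per sample, aligned to a variant map.

    Row ``2*i`` and ``2*i + 1`` are the two haplotypes of ``sample_ids[i]``;
    allele 1 corresponds to ``allele2`` of the variant map so that the two
    rows of a sample sum to its genotype code.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray  # (2*n_samples, n_snps) int8 in {0,1}

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        if self.haplotypes.shape != (2 * len(self.sample_ids), len(self.variants)):
            raise ValueError("haplotype matrix must be (2*n_samples, n_snps)")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("phased haplotypes must be 0/1 with no missing alleles")
        _check_variant_map(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def to_genotypes(self) -> GenotypeDataset:
        g = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        return GenotypeDataset(list(self.sample_ids), self.variants.copy(), g)

    def subset_snps(self, keep: np.ndarray) -> "HaplotypeSet":
        keep = np.asarray(keep)
        return HaplotypeSet(
            list(self.sample_ids),
            self.variants.iloc[keep].reset_index(drop=True),
            self.haplotypes[:, keep].copy(),
        )


@dataclass
class DiversitySummary:
    """Dataset-level SNP diversity: MAF, informativeness, homozygosity, F_IS."""

    mean_maf: float
    prop_informative: float
    mean_obs_hom: float
    mean_exp_hom: float
    mean_fis: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

def _read_map(map_path) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PlinkFormatError(f"{map_path}: line {lineno}: expected 4 fields")
        chrom, snp_id, _cm, bp = parts[0], parts[1], parts[2], parts[3]
        rows.append((snp_id, chrom, int(bp)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"])


def _orient_minor(ds: GenotypeDataset, tie_lexicographic: bool = False) -> GenotypeDataset:
    """Recode so allele2 is the minor allele in this dataset.

    Ties at p = 0.5 keep the current allele order unless ``tie_lexicographic``,
    in which case the lexicographically later label becomes allele2.
    """
    p = ds.allele2_freq()
    variants = ds.variants.copy()
    g = ds.genotypes.copy()
    a1 = variants["allele1"].to_numpy().copy()
    a2 = variants["allele2"].to_numpy().copy()
    flip = p > 0.5
    if tie_lexicographic:
        tie = np.isclose(p, 0.5)
        flip = flip | (tie & (a1 > a2))
    idx = np.flatnonzero(flip)
    if idx.size:
        mask = g[:, idx] != MISSING
        g[:, idx] = np.where(mask, 2 - g[:, idx], MISSING)
        a1[idx], a2[idx] = a2[idx].copy(), a1[idx].copy()
    variants["allele1"] = a1
    variants["allele2"] = a2
    return GenotypeDataset(list(ds.sample_ids), variants, g)


def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read a whitespace-delimited .ped/.map pair into a GenotypeDataset.

    Alleles are recoded to counts of the per-dataset minor allele ("0" is the
    missing allele code; a half-missing pair is an error). A SNP with more
    than two distinct alleles raises :class:`PlinkFormatError`.
    """
    variants = _read_map(map_path)
    n_snps = len(variants)
    sample_ids: list[str] = []
    raw: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise PlinkFormatError(
                f"{ped_path}: line {lineno}: expected {6 + 2 * n_snps} fields "
                f"for {n_snps} SNPs, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        pairs = []
        for j in range(n_snps):
            a, b = parts[6 + 2 * j], parts[7 + 2 * j]
            if (a == "0") != (b == "0"):
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno}: half-missing genotype at SNP "
                    f"{variants['snp_id'][j]}; refusing to fabricate a call"
                )
            pairs.append((a, b))
        raw.append(pairs)

    n_samples = len(sample_ids)
    g = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    allele1 = np.empty(n_snps, dtype=object)
    allele2 = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for i in range(n_samples):
            for a in raw[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise PlinkFormatError(
                f"SNP {variants['snp_id'][j]}: {len(counts)} alleles observed"
            )
        if not counts:
            alleles = ["A", "B"]  # all-missing column: arbitrary labels
        else:
            # major first; ties broken so the lexicographically later label
            # is allele2 (the minor slot)
            alleles = sorted(counts, key=lambda a: (-counts[a], a))
            if len(alleles) == 1:
                alleles.append("B" if alleles[0] != "B" else "A")
        a1, a2 = alleles[0], alleles[1]
        allele1[j], allele2[j] = a1, a2
        for i in range(n_samples):
            a, b = raw[i][j]
            if a != "0":
                g[i, j] = (a == a2) + (b == a2)

    variants["allele1"] = allele1
    variants["allele2"] = allele2
    ds = GenotypeDataset(sample_ids, variants, g)
    return _orient_minor(ds, tie_lexicographic=True)


def write_plink_text(ds: GenotypeDataset, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for row in ds.variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.bp}\n")
    a1 = ds.variants["allele1"].to_numpy()
    a2 = ds.variants["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, code in enumerate(ds.genotypes[i]):
                if code == MISSING:
                    fields += ["0", "0"]
                elif code == 0:
                    fields += [a1[j], a1[j]]
                elif code == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam), v1.00 SNP-major
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B])

# 2-bit codes -> allele2 count: 00=hom allele1, 01=missing, 10=het, 11=hom allele2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BYTE_TABLE = np.array(
    [[_BED_DECODE[(b >> (2 * k)) & 0b11] for k in range(4)] for b in range(256)],
    dtype=np.int8,
)


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK v1 binary fileset (SNP-major only).

    The result is identical to :func:`read_plink_text` on equivalent content:
    codes are re-oriented to the per-dataset minor allele.
    """
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    sample_ids = fam[1].tolist()
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None, dtype=str,
        names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
    )
    variants = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "bp": bim["bp"].astype(int),
            "allele1": bim["a1"],
            "allele2": bim["a2"],
        }
    )
    data = Path(bed_path).read_bytes()
    if data[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes")
    if data[2] == 0x00:
        raise PlinkFormatError(f"{bed_path}: individual-major layout is unsupported")
    if data[2] != 0x01:
        raise PlinkFormatError(f"{bed_path}: unknown mode byte {data[2]:#x}")
    n, m = len(sample_ids), len(variants)
    nbytes = (n + 3) // 4
    if len(data) != 3 + m * nbytes:
        raise PlinkFormatError(
            f"{bed_path}: expected {3 + m * nbytes} bytes for {n} samples x "
            f"{m} SNPs, found {len(data)} (truncated or wrong .bim/.fam?)"
        )
    body = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(m, nbytes)
    g = _BYTE_TABLE[body].reshape(m, nbytes * 4)[:, :n].T.copy()
    ds = GenotypeDataset(sample_ids, variants, g)
    return _orient_minor(ds, tie_lexicographic=True)


def write_plink_binary(ds: GenotypeDataset, bed_path, bim_path, fam_path) -> None:
    with open(fam_path, "w") as fh:
        for sid in ds.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(bim_path, "w") as fh:
        for row in ds.variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.bp}\t{row.allele1}\t{row.allele2}\n")
    n, m = ds.n_samples, ds.n_snps
    nbytes = (n + 3) // 4
    # map count codes to 2-bit bed codes
    code_map = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}
    encode = np.zeros(4, dtype=np.uint8)
    for k, v in code_map.items():
        encode[int(k) % 4] = v  # index -1 -> 3
    codes = encode[ds.genotypes.T % 4]  # (m, n) of 2-bit values
    padded = np.zeros((m, nbytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    body = (padded.reshape(m, nbytes, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(body.tobytes())


# ---------------------------------------------------------------------------
# Haplotype TSV
# ---------------------------------------------------------------------------

def write_haplotypes_tsv(haps: HaplotypeSet, path) -> None:
    """Write phased haplotypes: two rows per sample, one 0/1 column per SNP."""
    with open(path, "w") as fh:
        fh.write("sample_id\thap\t" + "\t".join(haps.variants["snp_id"]) + "\n")
        for i, sid in enumerate(haps.sample_ids):
            for h in (0, 1):
                row = haps.haplotypes[2 * i + h]
                fh.write(f"{sid}\t{h}\t" + "\t".join(map(str, row)) + "\n")


def read_haplotypes_tsv(path, variants: pd.DataFrame) -> HaplotypeSet:
    df = pd.read_csv(path, sep="\t")
    snp_cols = [c for c in df.columns if c not in ("sample_id", "hap")]
    wanted = list(variants["snp_id"])
    missing = set(wanted) - set(snp_cols)
    if missing:
        raise ValueError(
            f"haplotype TSV lacks {len(missing)} SNPs of the variant map, "
            f"e.g. {sorted(missing)[:5]}"
        )
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    mat = df[wanted].to_numpy(dtype=np.int8)
    return HaplotypeSet(sample_ids, variants.copy(), mat)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_call_rate(ds: GenotypeDataset, min_rate: float) -> GenotypeDataset:
    """Keep SNPs whose fraction of non-missing calls is strictly > min_rate."""
    if not 0 <= min_rate <= 1:
        raise ValueError("min_rate must be in [0, 1]")
    keep = np.flatnonzero(ds.call_rate() > min_rate)
    return _orient_minor(ds.subset_snps(keep))


def drop_sex_chromosomes(ds: GenotypeDataset, sex_labels: set[str] | None = None) -> GenotypeDataset:
    """Drop SNPs on sex chromosomes / unplaced labels, keeping all samples."""
    labels = _SEX_LABELS if sex_labels is None else set(sex_labels)
    chrom = ds.variants["chrom"].astype(str)
    keep = np.flatnonzero(~chrom.isin(labels).to_numpy())
    return _orient_minor(ds.subset_snps(keep))


def filter_maf(
    ds: GenotypeDataset,
    min_maf: float,
    freq_source: pd.Series | None = None,
) -> GenotypeDataset:
    """Remove SNPs with MAF < min_maf.

    ``freq_source`` optionally supplies per-SNP allele2 frequencies keyed by
    snp_id (e.g. from an external multibreed reference panel); by default the
    dataset's own sample frequencies are used.
    """
    if freq_source is None:
        maf = ds.maf()
    else:
        missing_ids = [s for s in ds.variants["snp_id"] if s not in freq_source.index]
        if missing_ids:
            raise KeyError(
                f"frequency table lacks {len(missing_ids)} SNPs: {missing_ids[:5]}"
            )
        p = freq_source.loc[ds.variants["snp_id"]].to_numpy(dtype=float)
        maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero(~(maf < min_maf))
    return _orient_minor(ds.subset_snps(keep))


def summarize_diversity(ds: GenotypeDataset) -> DiversitySummary:
    """Mean MAF, informative fraction, observed/expected homozygosity, F_IS."""
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    from .roh_inbreeding import fis

    maf = ds.maf()
    ok = ~np.isnan(maf)
    records = fis(ds)
    return DiversitySummary(
        mean_maf=float(np.nanmean(maf[ok])),
        prop_informative=float((maf[ok] > 0).mean()),
        mean_obs_hom=float(np.mean([r.obs_hom for r in records])),
        mean_exp_hom=float(np.mean([r.exp_hom for r in records])),
        mean_fis=float(np.mean([r.f_is for r in records])),
    )
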