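"""Configuration-driven end-to-end pipeline with a consolidated report.

Runs the whole analysis on a PLINK-prefixed dataset: SNP filters with logged
counts, LD decay and the Ne/dF trajectory, ROH calling at several SNP-count
thresholds (including an ``auto`` threshold derived from dataset
homozygosity), consensus ROHs, F_ROH / F_IS / F_Ped with their correlation
matrix, the EHH/REHH scan on phased haplotypes, and BED exports. Everything
is deterministic given the config (TSVs are the contract; plots are
convenience).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotype_io as gio
from . import ld_ne, pedigree, roh_inbreeding, selection_scan

logger = logging.getLogger("canepop.pipeline")


@dataclass
class PipelineConfig:
    plink_prefix: str
    out_dir: str
    haplotypes_tsv: str | None = None
    pedigree_csv: str | None = None
    min_call_rate: float = 0.90
    min_maf: float = 0.0
    roh_min_snps: list = field(default_factory=lambda: [50, 65, "auto"])
    roh_min_length_bp: int = 1_000_000
    roh_max_missing: int = 5
    roh_alpha: float = 0.05
    ld_bin_width_bp: float = 100_000
    ld_min_dist_bp: float = 1_000
    ld_max_dist_bp: float = 50_000_000
    recomb_morgan_per_bp: float = 1e-8
    scan_core_snps: int = 10
    scan_distance_bp: float = 1_000_000
    scan_n_bins: int = 20
    scan_min_freq: float = 0.50
    scan_min_score: float = 3.0
    scan_flank_bp: float = 500_000
    pedigree_depths: list = field(default_factory=lambda: [5, 11])
    froh_denominator_bp: float | None = None  # default: SNP-covered length
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"plink_prefix", "out_dir"} - set(raw)
        if missing:
            raise ValueError(f"config requires keys: {sorted(missing)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in [0, 1]")
        for t in self.roh_min_snps:
            if t != "auto" and (not isinstance(t, int) or t < 2):
                raise ValueError(f"bad ROH threshold {t!r}")


def _log_stage(stage: str, n_in: int, n_kept: int) -> None:
    logger.info("%s: %d in, %d kept, %d filtered", stage, n_in, n_kept, n_in - n_kept)


def report_table1(
    segments_by_threshold: dict,
    consensus_by_threshold: dict,
    denominator_bp: float,
    n_samples: int,
) -> pd.DataFrame:
    """Per-threshold ROH summary: counts, lengths, consensus stats, mean F_ROH."""
    rows = []
    for min_snps, by_sample in segments_by_threshold.items():
        all_segs = [s for segs in by_sample.values() for s in segs]
        cons = consensus_by_threshold[min_snps]
        n_per_ind = [len(by_sample[sid]) for sid in by_sample]
        lengths = np.array([s.length_bp for s in all_segs], dtype=float)
        cons_lengths = np.array([c.length_bp for c in cons], dtype=float)
        frohs = [
            roh_inbreeding.froh(segs, denominator_bp) for segs in by_sample.values()
        ]
        rows.append(
            {
                "min_snps": min_snps,
                "mean_n_roh": float(np.mean(n_per_ind)) if n_per_ind else 0.0,
                "shortest_roh_mb": float(lengths.min() / 1e6) if lengths.size else 0.0,
                "mean_length_mb": float(lengths.mean() / 1e6) if lengths.size else 0.0,
                "total_length_gb": float(lengths.sum() / n_samples / 1e9) if lengths.size else 0.0,
                "n_consensus": len(cons),
                "mean_consensus_mb": float(cons_lengths.mean() / 1e6) if cons_lengths.size else 0.0,
                "total_consensus_gb": float(cons_lengths.sum() / 1e9) if cons_lengths.size else 0.0,
                "mean_froh": float(np.mean(frohs)),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report tables and writes them under out_dir."""
    config.validate()
    out = Path(config.out_dir)
    for sub in ("ld", "roh", "inbreeding", "scan", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    try:
        ds = gio.read_plink_text(
            f"{config.plink_prefix}.ped", f"{config.plink_prefix}.map"
        )
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise RuntimeError(f"stage genotype_io failed: {exc}") from exc
    if ds.n_samples == 0:
        raise ValueError("stage genotype_io: empty sample set")
    logger.info("loaded %d samples x %d SNPs", ds.n_samples, ds.n_snps)

    n0 = ds.n_snps
    ds = gio.filter_call_rate(ds, config.min_call_rate)
    _log_stage("call_rate_filter", n0, ds.n_snps)
    n1 = ds.n_snps
    ds = gio.drop_sex_chromosomes(ds)
    _log_stage("sex_chromosome_filter", n1, ds.n_snps)
    if config.min_maf > 0:
        n2 = ds.n_snps
        ds = gio.filter_maf(ds, config.min_maf)
        _log_stage("maf_filter", n2, ds.n_snps)

    results: dict = {}

    # --- LD decay and Ne trajectory -------------------------------------
    pairs = ld_ne.pairwise_r2(ds, config.ld_min_dist_bp, config.ld_max_dist_bp)
    bins = ld_ne.bin_ld(pairs, config.ld_bin_width_bp)
    est = ld_ne.estimate_ne(bins, config.recomb_morgan_per_bp)
    traj = ld_ne.ne_trajectory(est)
    est.to_csv(out / "ld" / "ld_bins.tsv", sep="\t", index=False)
    traj.to_csv(out / "ld" / "ne_trajectory.tsv", sep="\t", index=False)
    results["ld_bins"] = est
    results["ne_trajectory"] = traj

    # --- ROH, consensus, F_ROH ------------------------------------------
    hom = float(np.mean([(ds.genotypes[i][ds.genotypes[i] != gio.MISSING] != 1).mean()
                         for i in range(ds.n_samples)]))
    n_snp_mean = float((ds.genotypes != gio.MISSING).sum(axis=1).mean())
    auto_l = roh_inbreeding.min_snp_threshold(
        config.roh_alpha, n_snp_mean, ds.n_samples, hom
    )
    logger.info("auto ROH threshold: %d SNPs (hom=%.4f, n_snp=%.0f)", auto_l, hom, n_snp_mean)

    denom = config.froh_denominator_bp or roh_inbreeding.snp_covered_length(ds.variants)
    segments_by_threshold: dict = {}
    consensus_by_threshold: dict = {}
    froh_cols = {}
    for t in config.roh_min_snps:
        min_snps = auto_l if t == "auto" else int(t)
        params = roh_inbreeding.ROHParams(
            min_snps=min_snps,
            min_length_bp=config.roh_min_length_bp,
            max_missing=config.roh_max_missing,
        )
        by_sample = roh_inbreeding.detect_roh_all(ds, params)
        cons = roh_inbreeding.consensus_roh(by_sample, ds.variants)
        segments_by_threshold[min_snps] = by_sample
        consensus_by_threshold[min_snps] = cons
        froh_cols[f"f_roh_{min_snps}"] = [
            roh_inbreeding.froh(by_sample[sid], denom) for sid in ds.sample_ids
        ]
        all_segs = [s for segs in by_sample.values() for s in segs]
        roh_inbreeding.segments_to_frame(all_segs).to_csv(
            out / "roh" / f"segments_{min_snps}.tsv", sep="\t", index=False
        )
        roh_inbreeding.segments_to_bed(all_segs, out / "roh" / f"segments_{min_snps}.bed")
        roh_inbreeding.segments_to_bed(cons, out / "roh" / f"consensus_{min_snps}.bed")
        hist = roh_inbreeding.roh_length_histogram(all_segs)
        pd.DataFrame([hist]).to_csv(
            out / "roh" / f"length_histogram_{min_snps}.tsv", sep="\t", index=False
        )

    table1 = report_table1(segments_by_threshold, consensus_by_threshold, denom, ds.n_samples)
    table1.to_csv(out / "report" / "roh_summary.tsv", sep="\t", index=False)
    results["roh_summary"] = table1

    # --- inbreeding table and correlations ------------------------------
    fis_records = roh_inbreeding.fis(ds)
    inb = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "f_is": [r.f_is for r in fis_records],
            **froh_cols,
        }
    )
    if config.pedigree_csv:
        ped = pedigree.Pedigree.from_csv(config.pedigree_csv)
        for d in config.pedigree_depths:
            inb[f"f_ped_{d}"] = [pedigree.f_ped(ped, sid, d) for sid in ds.sample_ids]
            inb[f"completeness_{d}"] = [
                pedigree.completeness(ped, sid, d) for sid in ds.sample_ids
            ]
    inb.to_csv(out / "inbreeding" / "inbreeding.tsv", sep="\t", index=False)
    measure_cols = [c for c in inb.columns if c.startswith(("f_is", "f_roh", "f_ped"))]
    corr_pairs = [
        (a, b) for i, a in enumerate(measure_cols) for b in measure_cols[i + 1 :]
    ]
    corr = roh_inbreeding.correlate_measures(inb, corr_pairs)
    corr.to_csv(out / "inbreeding" / "correlations.tsv", sep="\t", index=False)
    results["inbreeding"] = inb
    results["correlations"] = corr

    # --- selection scan --------------------------------------------------
    if config.haplotypes_tsv:
        haps = gio.read_haplotypes_tsv(config.haplotypes_tsv, ds.variants)
        scored = selection_scan.score_rehh(
            selection_scan.scan_cores(
                haps, config.scan_core_snps, config.scan_distance_bp
            ),
            config.scan_n_bins,
        )
        scored.to_csv(out / "scan" / "scored_cores.tsv", sep="\t", index=False)
        hits = selection_scan.significant_regions(
            scored, config.scan_min_freq, config.scan_min_score
        )
        hits.to_csv(out / "scan" / "significant_regions.tsv", sep="\t", index=False)
        selection_scan.export_regions_bed(
            hits, out / "scan" / "significant_regions.bed", config.scan_flank_bp
        )
        results["scan"] = scored
        results["scan_hits"] = hits

    if config.make_plots:
        _make_plots(est, traj, out / "report")
    return results


def _make_plots(bins: pd.DataFrame, traj: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    mid = (bins["lo_bp"] + bins["hi_bp"]) / 2 / 1e6
    ax.plot(mid, bins["mean_r2"], lw=1)
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel("mean $r^2$")
    fig.savefig(out_dir / "ld_decay.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(traj["g"], traj["ne"], where="mid")
    ax.set_xlabel("generations ago")
    ax.set_ylabel("$N_e$")
    ax.set_xscale("log")
    fig.savefig(out_dir / "ne_trajectory.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
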