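import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canepop import roh_inbreeding as roh
from canepop.genotype_io import MISSING
from canepop.roh_inbreeding import ConsensusROH, ROHParams, ROHSegment

from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent oracle: exhaustive window enumeration
# ---------------------------------------------------------------------------

def oracle_detect(codes, bp, params: ROHParams):
    """All maximal (i, j) windows satisfying the calling constraints."""
    m = len(codes)

    def valid(i, j):
        win = codes[i : j + 1]
        if codes[i] in (1, MISSING) or codes[j] in (1, MISSING):
            return False
        if (win == 1).sum() > 0:
            return False
        if (win == MISSING).sum() > params.max_missing:
            return False
        return True

    windows = [
        (i, j) for i in range(m) for j in range(i, m) if valid(i, j)
    ]
    maximal = [
        (i, j)
        for (i, j) in windows
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in windows)
    ]
    out = []
    for i, j in maximal:
        n = j - i + 1
        length = bp[j] - bp[i]
        if n >= params.min_snps and length >= params.min_length_bp:
            out.append((int(bp[i]), int(bp[j]), n))
    return sorted(out)


class TestDetectROH:
    def test_sixty_hom_snps_over_1_2_mb(self):
        bp = np.linspace(1_000_000, 2_200_000, 60).astype(int)
        g = np.zeros((1, 60), dtype=np.int8)
        ds = make_dataset(g, bp=list(bp))
        segs = roh.detect_roh(ds, "ind0", ROHParams(min_snps=50))
        assert len(segs) == 1
        assert segs[0].n_snps == 60
        assert segs[0].length_bp == 1_200_000

    def test_single_het_splits_run_below_threshold(self):
        bp = np.linspace(1_000_000, 2_200_000, 60).astype(int)
        g = np.zeros((1, 60), dtype=np.int8)
        g[0, 29] = 1
        ds = make_dataset(g, bp=list(bp))
        segs = roh.detect_roh(ds, "ind0", ROHParams(min_snps=50))
        assert segs == []

    def test_missing_tolerated_up_to_limit(self):
        bp = np.linspace(1_000_000, 2_200_000, 60).astype(int)
        g = np.zeros((1, 60), dtype=np.int8)
        g[0, [10, 20, 30, 40, 50]] = MISSING
        ds = make_dataset(g, bp=list(bp))
        segs = roh.detect_roh(ds, "ind0", ROHParams(min_snps=50, max_missing=5))
        assert len(segs) == 1 and segs[0].n_snps == 60
        segs4 = roh.detect_roh(ds, "ind0", ROHParams(min_snps=50, max_missing=4))
        assert segs4 == []  # overlapping sub-windows all < 50 SNPs

    def test_missing_never_at_segment_ends(self):
        bp = np.linspace(1_000_000, 3_000_000, 60).astype(int)
        g = np.zeros((1, 60), dtype=np.int8)
        g[0, 0] = MISSING
        g[0, 59] = MISSING
        ds = make_dataset(g, bp=list(bp))
        (seg,) = roh.detect_roh(ds, "ind0", ROHParams(min_snps=50))
        assert seg.start_bp == bp[1] and seg.end_bp == bp[58]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        runs = 20
        for rep in range(runs):
            m = rng.integers(10, 60)
            codes = rng.choice(
                [0, 1, 2, MISSING], size=m, p=[0.55, 0.1, 0.25, 0.1]
            ).astype(np.int8)
            bp = np.sort(rng.choice(np.arange(1, 5_000_000), size=m, replace=False))
            params = ROHParams(
                min_snps=int(rng.integers(2, 8)),
                min_length_bp=int(rng.integers(1, 2_000_000)),
                max_missing=int(rng.integers(0, 4)),
            )
            ds = make_dataset(codes[None, :], bp=list(bp))
            got = sorted(
                (s.start_bp, s.end_bp, s.n_snps)
                for s in roh.detect_roh(ds, "ind0", params)
            )
            assert got == oracle_detect(codes, bp, params), (
                f"trial {trial} rep {rep}: codes={codes.tolist()} "
                f"params={params}"
            )

    def test_runs_never_span_chromosomes(self):
        g = np.zeros((1, 20), dtype=np.int8)
        ds = make_dataset(
            g,
            chrom=["1"] * 10 + ["2"] * 10,
            bp=list(np.linspace(1e6, 3e6, 10).astype(int)) * 2,
        )
        segs = roh.detect_roh(ds, "ind0", ROHParams(min_snps=5, min_length_bp=1))
        assert len(segs) == 2
        assert {s.chrom for s in segs} == {"1", "2"}


class TestThreshold:
    def test_study_scale_value(self):
        assert roh.min_snp_threshold(0.05, 168467, 28, 0.95) == 358

    def test_unit_case(self):
        assert roh.min_snp_threshold(0.5, 1, 1, 0.5) == 1

    def test_high_precision_oracle(self):
        import math

        expected = round(math.log(0.05 / (10000 * 10)) / math.log(0.9))
        assert expected == 138
        assert roh.min_snp_threshold(0.05, 10000, 10, 0.9) == 138

    def test_hom_one_rejected(self):
        with pytest.raises(ValueError):
            roh.min_snp_threshold(0.05, 1000, 10, 1.0)

    def test_threshold_increases_with_homozygosity(self):
        grid = [0.5, 0.7, 0.9, 0.95, 0.99]
        vals = [roh.min_snp_threshold(0.05, 1e5, 28, h) for h in grid]
        assert vals == sorted(vals) and len(set(vals)) == len(vals)


class TestConsensus:
    def _seg(self, sid, lo, hi, chrom="1"):
        return ROHSegment(sid, chrom, lo, hi, 2)

    def test_interval_intersection(self):
        variants = make_dataset(
            np.zeros((1, 16), dtype=np.int8),
            bp=list(range(1_000_000, 17_000_000, 1_000_000)),
        ).variants
        segs = {
            "A": [self._seg("A", 1_000_000, 10_000_000)],
            "B": [self._seg("B", 5_000_000, 15_000_000)],
        }
        cons = roh.consensus_roh(segs, variants)
        assert len(cons) == 1
        assert (cons[0].start_bp, cons[0].end_bp) == (5_000_000, 10_000_000)

    def test_disjoint_gives_empty(self):
        variants = make_dataset(
            np.zeros((1, 10), dtype=np.int8),
            bp=list(range(1_000_000, 11_000_000, 1_000_000)),
        ).variants
        segs = {
            "A": [self._seg("A", 1_000_000, 3_000_000)],
            "B": [self._seg("B", 7_000_000, 9_000_000)],
        }
        assert roh.consensus_roh(segs, variants) == []

    def test_matches_per_snp_and_oracle(self):
        rng = np.random.default_rng(42)
        bp = np.sort(rng.choice(np.arange(1, 20_000_000), 200, replace=False))
        variants = make_dataset(np.zeros((1, 200), dtype=np.int8), bp=list(bp)).variants
        segs = {}
        for sid in "ABCDE":
            mine = []
            for _ in range(rng.integers(1, 5)):
                lo, hi = np.sort(rng.choice(bp, 2, replace=False))
                mine.append(self._seg(sid, int(lo), int(hi)))
            segs[sid] = mine
        cons = roh.consensus_roh(segs, variants)
        covered = np.ones(len(bp), dtype=bool)
        for sid, mine in segs.items():
            cov = np.zeros(len(bp), dtype=bool)
            for s in mine:
                cov |= (bp >= s.start_bp) & (bp <= s.end_bp)
            covered &= cov
        got = np.zeros(len(bp), dtype=bool)
        for c in cons:
            got |= (bp >= c.start_bp) & (bp <= c.end_bp)
        assert (got == covered).all()


class TestFroh:
    def test_study_scale_arithmetic(self):
        segs = [ROHSegment("x", "1", 0, 1_990_000_000, 99)]
        assert round(roh.froh(segs, 2_290_000_000), 2) == 0.87

    def test_no_segments(self):
        assert roh.froh([], 1_000_000) == 0.0

    def test_min_length_filter_matches_sum_oracle(self):
        rng = np.random.default_rng(9)
        segs = []
        for k in range(30):
            lo = int(rng.integers(0, 50_000_000))
            segs.append(ROHSegment("x", str(k), lo, lo + int(rng.integers(1, 2e7)), 5))
        expected = sum(s.length_bp for s in segs if s.length_bp >= 10_000_000)
        assert roh.froh(segs, 1e9, min_length_bp=10_000_000) == pytest.approx(
            expected / 1e9
        )

    def test_overlapping_segments_merged(self):
        segs = [
            ROHSegment("x", "1", 1_000_000, 5_000_000, 5),
            ROHSegment("x", "1", 3_000_000, 8_000_000, 5),
        ]
        assert roh.froh(segs, 7_000_000) == pytest.approx(1.0)

    def test_froh_monotone_in_min_length(self):
        rng = np.random.default_rng(2)
        segs = [
            ROHSegment("x", "1", int(lo), int(lo + rng.integers(1, 1e7)), 5)
            for lo in np.cumsum(rng.integers(1e7, 2e7, 10))
        ]
        vals = [roh.froh(segs, 1e9, m) for m in (0, 2e6, 5e6, 8e6)]
        assert vals == sorted(vals, reverse=True)


class TestGenerations:
    @pytest.mark.parametrize(
        "length,expected", [(500e3, 100), (780e3, 64), (4.3e6, 12)]
    )
    def test_length_generation_equivalence(self, length, expected):
        assert roh.roh_generations(length) == expected


class TestFis:
    def test_all_homozygous_individual_gets_one(self):
        g = np.array([[0, 2, 0], [1, 1, 0], [0, 1, 1], [2, 0, 0]], dtype=np.int8)
        recs = roh.fis(make_dataset(g))
        assert recs[3].f_is == pytest.approx(1.0)
        assert recs[3].obs_hom == 3

    def test_o_equals_e_gives_zero(self):
        g = np.array([[0, 2], [1, 1], [2, 0], [1, 1]], dtype=np.int8)
        recs = roh.fis(make_dataset(g))
        for r in recs:
            if abs(r.obs_hom - r.exp_hom) < 1e-12:
                assert r.f_is == pytest.approx(0.0)

    def test_worked_table_with_correction(self):
        # 4 samples x 5 SNPs, one missing call; independent loop arithmetic
        g = np.array(
            [
                [0, 1, 2, 0, 1],
                [1, 1, 0, 0, MISSING],
                [2, 0, 0, 1, 1],
                [0, 2, 1, 0, 0],
            ],
            dtype=np.int8,
        )
        recs = roh.fis(make_dataset(g))
        for i, rec in enumerate(recs):
            o = e = n = 0
            for j in range(5):
                calls = [g[k, j] for k in range(4) if g[k, j] != MISSING]
                if g[i, j] == MISSING or len(calls) < 2:
                    continue
                p = sum(calls) / (2 * len(calls))
                corr = 2 * len(calls) / (2 * len(calls) - 1)
                e += 1 - 2 * p * (1 - p) * corr
                o += g[i, j] in (0, 2)
                n += 1
            assert rec.obs_hom == o
            assert rec.exp_hom == pytest.approx(e)
            assert rec.f_is == pytest.approx((o - e) / (n - e))


class TestHistogramAndCorrelation:
    def test_histogram_cases(self):
        assert roh.roh_length_histogram([]) == {"short": 0, "mid": 0, "long": 0}
        seg7 = ROHSegment("x", "1", 0, 7_000_000, 5)
        assert roh.roh_length_histogram([seg7])["mid"] == 1
        seg5 = ROHSegment("x", "1", 0, 5_000_000, 5)  # boundary -> lower
        assert roh.roh_length_histogram([seg5])["short"] == 1
        rng = np.random.default_rng(1)
        segs = [
            ROHSegment("x", "1", 0, int(rng.integers(1, 2e7)), 5) for _ in range(100)
        ]
        counts = roh.roh_length_histogram(segs)
        lens = np.array([s.length_bp for s in segs])
        assert counts["short"] == (lens <= 5e6).sum()
        assert counts["mid"] == ((lens > 5e6) & (lens <= 10e6)).sum()
        assert counts["long"] == (lens > 10e6).sum()

    def test_correlations(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"a": x, "b": x, "c": -x, "d": x**2 + 3 * x})
        out = roh.correlate_measures(table, [("a", "b"), ("a", "c"), ("a", "d")])
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["r"].iloc[1] == pytest.approx(-1.0)
        r_direct, p_direct = stats.pearsonr(x, x**2 + 3 * x)
        assert out["r"].iloc[2] == pytest.approx(r_direct)
        assert out["p"].iloc[2] == pytest.approx(p_direct)

    def test_zero_variance_flagged(self):
        table = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        out = roh.correlate_measures(table, [("a", "b")])
        assert out["degenerate"].iloc[0]
        assert np.isnan(out["r"].iloc[0])


class TestMonotonicityOnSimulatedData:
    def test_raising_thresholds_never_increases_calls(self, bottleneck28):
        ds = bottleneck28.genotypes
        prev_counts = None
        prev_total = None
        for min_snps in (30, 50, 80):
            by_sample = roh.detect_roh_all(ds, ROHParams(min_snps=min_snps))
            counts = sum(len(v) for v in by_sample.values())
            total = sum(s.length_bp for v in by_sample.values() for s in v)
            if prev_counts is not None:
                assert counts <= prev_counts
                assert total <= prev_total
            prev_counts, prev_total = counts, total

    def test_consensus_bounded_by_min_sample_total(self, bottleneck28):
        ds = bottleneck28.genotypes
        by_sample = roh.detect_roh_all(ds, ROHParams(min_snps=40))
        cons = roh.consensus_roh(by_sample, ds.variants)
        cons_total = sum(c.length_bp for c in cons)
        per_sample_totals = [
            sum(s.length_bp for s in v) for v in by_sample.values()
        ]
        assert cons_total <= min(per_sample_totals)


class TestInbreedingRecovery:
    def test_sib_lines_froh_tracks_pedigree_f(self, sib_lines):
        result, truth = sib_lines
        ds = result.genotypes
        denom = roh.snp_covered_length(ds.variants)
        params = ROHParams(min_snps=25, min_length_bp=1_000_000)
        frohs = {
            sid: roh.froh(roh.detect_roh(ds, sid, params), denom)
            for sid in ds.sample_ids
        }
        truth = truth.set_index("sample_id")
        f_ped = [truth.loc[sid, "expected_f_ped"] for sid in ds.sample_ids]
        f_roh = [frohs[sid] for sid in ds.sample_ids]
        # mean F_ROH rises with sibbing depth
        by_depth = truth.assign(froh=f_roh).groupby("depth")["froh"].mean()
        assert by_depth.iloc[-1] > by_depth.iloc[0]
        rho, _ = stats.spearmanr(f_ped, f_roh)
        assert rho > 0.8


class TestBedExport:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        segs = [ROHSegment("3", "3", 1_000_001, 2_000_000, 50)]
        path = tmp_path / "segs.bed"
        roh.segments_to_bed(segs, path)
        chrom, start, end, name = path.read_text().split()
        assert (chrom, int(start), int(end)) == ("3", 1_000_000, 2_000_000)
        # round trip back to 1-based closed
        assert int(start) + 1 == segs[0].start_bp
        assert int(end) == segs[0].end_bp
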