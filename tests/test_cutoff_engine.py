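"""Serial-cut grid, per-gene scan, optimal-cut selection, cohort-wide scan."""

from fractions import Fraction
from math import ceil

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from survscreen import (
    candidate_positions,
    cut_at_median,
    rank_patients,
    scan_all,
    scan_gene,
    select_optimal,
)
from survscreen.cutpoints import CutoffScan, STATUS_DEGENERATE, STATUS_TIE, STATUS_VALID
from survscreen.exceptions import EmptyGridError, GeneAnalysisError
from survscreen import GeneEffectSpec, SimConfig, simulate_dataset

from conftest import ZERO_COVARIATE_EFFECTS
from oracles import exhaustive_rescan


class TestCandidateGrid:
    def test_reference_cohort_grid(self):
        grid = candidate_positions(414, 0.30, 0.70)
        assert grid.positions[0] == 125
        assert grid.positions[-1] == 290
        assert len(grid) == 166

    def test_ten_patient_grid(self):
        assert list(candidate_positions(10, 0.30, 0.70).positions) == [4, 5, 6, 7]

    def test_matches_exact_enumeration_for_all_sizes(self):
        # oracle: {k : lo*N < k <= ceil(hi*N)} with exact rational arithmetic
        for n in range(10, 601):
            for lo, hi in [(0.30, 0.70), (0.25, 0.75), (0.40, 0.45)]:
                lo_f, hi_f = Fraction(str(lo)), Fraction(str(hi))
                expected = [
                    k for k in range(1, n)
                    if lo_f * n < k <= ceil(hi_f * n)
                ]
                got = list(candidate_positions(n, lo, hi).positions)
                assert got == expected, (n, lo, hi)

    def test_integer_boundary_is_exclusive_at_the_low_end(self):
        # lo*N integral: the boundary rank itself is excluded
        grid = candidate_positions(410, 0.30, 0.70)
        assert grid.positions[0] == 124  # 0.3*410 = 123 exactly

    def test_narrow_band_keeps_single_position_per_convention(self):
        # lo just below hi: floor(lo*N)+1 == ceil(hi*N) -> one position
        grid = candidate_positions(400, 0.5001, 0.5002)
        assert list(grid.positions) == [201]

    def test_band_clipped_past_the_last_rank_raises(self):
        with pytest.raises(EmptyGridError):
            candidate_positions(10, 0.99, 0.995)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            candidate_positions(9)


class TestRankPatients:
    def test_matches_naive_sort(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=50)
        ids = np.array([f"P{i:02d}" for i in rng.permutation(50)])
        order = rank_patients(values, ids)
        naive = [i for _, _, i in sorted((v, pid, i) for i, (v, pid) in enumerate(zip(values, ids)))]
        assert list(order) == naive

    def test_all_equal_values_fall_back_to_id_order(self):
        ids = np.array(["P3", "P1", "P2"])
        order = rank_patients(np.zeros(3), ids)
        assert list(ids[order]) == ["P1", "P2", "P3"]


class TestScanGene:
    def _cohort(self, n=60, seed=3):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=n)
        times = np.ceil(rng.exponential(100, n))
        events = rng.binomial(1, 0.7, n)
        return values, times, events

    def test_every_valid_position_reproduces_its_logrank_p(self):
        values, times, events = self._cohort()
        scan = scan_gene(values, times, events)
        order = np.argsort(values, kind="stable")
        st, se = times[order], events[order]
        for pos, status, p in zip(scan.positions, scan.status, scan.p_values):
            if status != STATUS_VALID:
                continue
            ref = logrank_test(st[:pos], st[pos:], se[:pos], se[pos:])
            assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_all_equal_expression_fails_with_tie_skips(self):
        _, times, events = self._cohort()
        scan = scan_gene(np.zeros(60), times, events)
        assert (scan.status == STATUS_TIE).all()
        assert scan.failed

    def test_event_free_cohort_is_degenerate_everywhere(self):
        values, times, _ = self._cohort()
        scan = scan_gene(values, times, np.zeros(60, int))
        assert (scan.status == STATUS_DEGENERATE).all()

    def test_tied_block_shrinks_the_valid_range(self):
        # first 144 sorted values identical -> cuts 125..143 skipped as ties,
        # leaving the contiguous valid range 144..290 (147 evaluated p values)
        rng = np.random.default_rng(9)
        n = 414
        values = np.concatenate([np.zeros(144), np.sort(rng.normal(1, 0.3, n - 144))])
        times = np.ceil(rng.exponential(800, n))
        events = np.ones(n, int)
        scan = scan_gene(values, times, events)
        valid_ranks = scan.positions[scan.valid]
        assert valid_ranks[0] == 144 and valid_ranks[-1] == 290
        assert len(valid_ranks) == 147

    def test_profile_statuses_cover_grid_exactly_once(self):
        values, times, events = self._cohort()
        scan = scan_gene(values, times, events)
        assert len(scan.status) == len(scan.positions)
        valid_p = scan.p_values[scan.valid]
        assert ((valid_p > 0) & (valid_p <= 1)).all()


class TestSelectOptimal:
    def _manual_scan(self, p_values, n=20):
        positions = np.arange(6, 6 + len(p_values))
        status = np.where(np.isnan(p_values), STATUS_TIE, STATUS_VALID)
        return CutoffScan(
            gene="g",
            order=np.arange(n),
            positions=positions,
            status=status,
            p_values=np.asarray(p_values, float),
            sorted_values=np.linspace(0, 1, n),
            sorted_times=np.linspace(1, n, n),
            sorted_events=np.ones(n, int),
        )

    def test_minimum_p_wins(self):
        scan = self._manual_scan([0.04, 0.001, 0.02])
        cut = select_optimal(scan)
        assert cut.rank_k == 7 and cut.p_min == 0.001 and not cut.used_fallback
        assert cut.n_low + cut.n_high == 20

    def test_tie_at_minimum_resolved_to_smallest_rank(self):
        scan = self._manual_scan([0.01, 0.001, 0.001, 0.04])
        assert select_optimal(scan).rank_k == 7

    def test_reported_p_min_is_profile_minimum(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(1e-4, 0.04, 11)
        scan = self._manual_scan(list(p))
        assert select_optimal(scan).p_min == p.min()

    def test_no_significant_cut_falls_back_to_median(self):
        scan = self._manual_scan([0.3, 0.8, 0.5])
        cut = select_optimal(scan, sig_level=0.05)
        assert cut.used_fallback and cut.rank_k == 10  # floor(20/2)

    def test_recovers_planted_threshold_and_matches_exhaustive_rescan(self):
        cfg = SimConfig(
            n_patients=400,
            n_genes=1,
            effects=(GeneEffectSpec("threshold", q=0.4, hr=3.0),),
            baseline_rate=4e-4,
            dropout_rate=2e-4,
            covariate_log_hazards=dict(ZERO_COVARIATE_EFFECTS),
            seed=77,
        )
        dataset, _ = simulate_dataset(cfg)
        values, _ = dataset.gene_values("G00001")
        scan = scan_gene(values, dataset.times, dataset.events)
        cut = select_optimal(scan)
        assert abs(cut.rank_k - 160) <= 20  # within 5 percentile points of truth
        oracle = exhaustive_rescan(values, dataset.times, dataset.events, scan.positions)
        best = min(oracle, key=lambda k: (oracle[k], k))
        assert cut.rank_k == best
        assert cut.p_min == pytest.approx(oracle[best], abs=1e-10)


class TestMedianCut:
    def test_median_cut_halves_untied_cohort(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=101)
        times = np.ceil(rng.exponential(100, 101))
        cut = cut_at_median(values, times, np.ones(101, int))
        assert cut.n_low == 50 and cut.n_high == 51

    def test_single_valued_gene_excluded(self):
        with pytest.raises(GeneAnalysisError):
            cut_at_median(np.zeros(30), np.arange(1, 31), np.ones(30, int))


class TestScanAll:
    def test_constructed_failures_are_categorized_not_fatal(self, small_cohort):
        dataset, _ = small_cohort
        expr = dataset.expression.values.copy()
        for g in list(expr.index[:3]):
            expr.loc[g] = 1.0  # all-tied: no usable cut, no usable median
        from survscreen.cohort import ExpressionMatrix

        tainted = dataset.with_expression(ExpressionMatrix(expr, expr.isna()))
        table, failures = scan_all(tainted)
        assert len(table) == len(expr) - 3
        assert len(failures) == 3
        assert set(failures["category"]) == {"one-group-logrank"}

    def test_empty_gene_set_gives_empty_table(self, small_cohort):
        dataset, _ = small_cohort
        table, failures = scan_all(dataset, genes=[])
        assert table.empty and failures.empty

    def test_same_input_twice_is_identical(self, small_cohort):
        dataset, _ = small_cohort
        t1, f1 = scan_all(dataset)
        t2, f2 = scan_all(dataset)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_null_masked_patients_are_excluded_per_gene(self, small_cohort):
        dataset, _ = small_cohort
        values = dataset.expression.values.copy()
        gene = values.index[1]
        values.loc[gene, values.columns[:10]] = np.nan
        from survscreen.cohort import ExpressionMatrix

        masked = dataset.with_expression(ExpressionMatrix(values, values.isna()))
        table, _ = scan_all(masked)
        row = table.set_index("gene").loc[gene]
        assert row["n_used"] == dataset.n_patients - 10
        assert row["n_low"] + row["n_high"] == row["n_used"]
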