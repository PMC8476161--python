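"""Empirical P values, FDR, control tests, and correlation structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcrobust.ms_engine import MSEnsemble, compute_ms_ensemble
from gcrobust.robustness_stats import (
    ControlResult,
    RobustnessStatsError,
    band_control_test,
    bh_significant,
    build_report,
    cross_correlation_matrix,
    empirical_p,
    joint_control_test,
    ms_control_test,
    ms_correlation_profile,
    per_code_significance_counts,
)

from conftest import bh_stepup_reference


def _toy_ensemble(values_by_metric: dict[str, np.ndarray], seed: int = 0) -> MSEnsemble:
    any_arr = next(iter(values_by_metric.values()))
    ids = [f"p{k}" for k in range(any_arr.shape[1])]
    return MSEnsemble(
        values={m: np.asarray(v, dtype=float) for m, v in values_by_metric.items()},
        property_ids=ids,
        n_codes=any_arr.shape[0] - 1,
        seed=seed,
    )


class TestEmpiricalP:
    def test_extremes(self):
        col = np.linspace(1.0, 2.0, 10)
        assert empirical_p(0.5, col) == 0.0
        assert empirical_p(2.5, col) == 1.0

    @given(
        sgc=st.floats(min_value=-5, max_value=5, allow_nan=False),
        n=st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_p_lies_on_the_resolution_grid(self, sgc, n):
        rng = np.random.default_rng(abs(hash((sgc, n))) % 2**31)
        col = rng.normal(size=n)
        p = empirical_p(sgc, col)
        assert 0.0 <= p <= 1.0
        assert (p * n) == pytest.approx(round(p * n), abs=1e-9)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(RobustnessStatsError, match="empty"):
            empirical_p(1.0, np.array([]))


class TestBenjaminiHochberg:
    def test_hand_executed_example(self):
        """Step-up on (0.01, 0.02, 0.04, 0.5) at alpha 0.05 flags the first two."""
        p = np.array([0.01, 0.02, 0.04, 0.5])
        adj, flags = bh_significant(p, alpha=0.05)
        np.testing.assert_array_equal(flags, [True, True, False, False])
        assert adj[0] == pytest.approx(0.04)  # min(0.01*4/1, 0.02*4/2, ...) monotone
        np.testing.assert_array_equal(flags, bh_stepup_reference(p, 0.05))

    def test_all_zero_p_all_flagged(self):
        _, flags = bh_significant(np.zeros(7), alpha=0.05)
        assert flags.all()

    def test_order_equivariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        adj, flags = bh_significant(p, 0.05)
        adj_p, flags_p = bh_significant(p[perm], 0.05)
        np.testing.assert_allclose(adj_p, adj[perm])
        np.testing.assert_array_equal(flags_p, flags[perm])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_stepup_definition(self, p_list):
        p = np.array(p_list)
        _, flags = bh_significant(p, 0.05)
        np.testing.assert_array_equal(flags, bh_stepup_reference(p, 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(RobustnessStatsError):
            bh_significant([0.1, 1.5], 0.05)


class TestPerCodeCounts:
    def test_minimum_code_is_flagged_single_property(self):
        vals = np.array([[3.0], [1.0], [2.0], [4.0]])  # code 1 is the minimum
        ens = _toy_ensemble({"MS1": vals})
        counts = per_code_significance_counts(ens, alpha=0.05)
        assert counts["MS1"].tolist() == [0, 1, 0, 0]

    def test_fast_path_equals_naive_loop(self):
        """Rank-based path == per-focal brute force on a 50x5 fixture."""
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.1, 5.0, size=(50, 5))
        vals[7, 2] = vals[9, 2]  # inject a tie
        ens = _toy_ensemble({"MS1": vals})
        counts = per_code_significance_counts(ens, alpha=0.2)["MS1"].to_numpy()
        for i in range(50):
            p = np.array(
                [
                    np.sum(np.delete(vals[:, j], i) < vals[i, j]) / 49
                    for j in range(5)
                ]
            )
            _, flags = bh_significant(p, alpha=0.2)
            assert counts[i] == flags.sum()

    def test_counts_bounded_by_property_count(self, small_fake_table):
        ens = compute_ms_ensemble(small_fake_table, 40, seed=2, metrics=("MS1", "MS3"))
        counts = per_code_significance_counts(ens, alpha=0.05)
        assert (counts <= len(small_fake_table)).all().all()


class TestControls:
    def test_band_is_closed_interval_with_strict_target(self):
        control = np.array([79, 80, 100, 120, 121])
        target = np.array([9, 10, 11, 12, 13])
        res = band_control_test(control, target, 100, 11, band=(0.8, 1.2))
        # endpoints 80 and 120 are inside; their targets are (10, 11, 12)
        # and only 12 is strictly greater than the SGC's 11
        assert (res.control_size, res.n_beyond) == (3, 1)
        assert res.fraction == pytest.approx(1 / 3)

    def test_empty_band_is_reported_not_zero(self):
        res = band_control_test(np.array([10, 20]), np.array([1, 2]), 100, 5)
        assert res.empty and res.fraction is None

    def test_ms_control_self_identity(self):
        """Control == target column: fraction = #(< sgc) / #(<= sgc)."""
        rng = np.random.default_rng(5)
        col = rng.normal(size=500)
        col[17] = col[3]  # tie with the threshold draw
        sgc = col[3]
        res = ms_control_test(col, col, sgc, sgc)
        assert res.control_size == np.sum(col <= sgc)
        assert res.n_beyond == np.sum(col < sgc)

    def test_joint_single_constraint_reduces_to_ms_control(self, small_fake_table):
        ens = compute_ms_ensemble(small_fake_table, 300, seed=1, metrics=("MS1", "MS3"))
        pid = small_fake_table.ids[0]
        joint = joint_control_test(ens, [("MS1", pid, None)], ("MS3", pid, None))
        direct = ms_control_test(
            ens.rgc("MS1", pid), ens.rgc("MS3", pid),
            ens.sgc("MS1", pid), ens.sgc("MS3", pid),
        )
        assert (joint.control_size, joint.n_beyond) == (
            direct.control_size, direct.n_beyond,
        )

    def test_joint_constraints_shrink_monotonically(self, small_fake_table):
        """Adding constraints never grows the control set (random chains)."""
        ens = compute_ms_ensemble(small_fake_table, 200, seed=3, metrics=("MS1", "MS3"))
        rng = np.random.default_rng(44)
        for _ in range(10):
            pids = list(rng.choice(small_fake_table.ids, size=3, replace=False))
            sizes = []
            for k in range(1, 4):
                constraints = [("MS1", pid, None) for pid in pids[:k]]
                res = joint_control_test(ens, constraints, ("MS3", pids[0], None))
                sizes.append(res.control_size)
            assert sizes == sorted(sizes, reverse=True)

    def test_impossible_constraints_give_empty_outcome(self, small_fake_table):
        ens = compute_ms_ensemble(small_fake_table, 50, seed=3, metrics=("MS1", "MS3"))
        pid = small_fake_table.ids[0]
        res = joint_control_test(ens, [("MS1", pid, -1.0)], ("MS3", pid, None))
        assert res.empty and res.fraction is None

    def test_empty_constraint_list_rejected(self, small_fake_table):
        ens = compute_ms_ensemble(small_fake_table, 10, seed=0, metrics=("MS1", "MS3"))
        with pytest.raises(RobustnessStatsError):
            joint_control_test(ens, [], ("MS3", small_fake_table.ids[0], None))


class TestCorrelations:
    def test_identical_columns_give_r_one(self):
        rng = np.random.default_rng(8)
        col = rng.uniform(0.5, 3.0, size=(101, 1))
        ens = _toy_ensemble({"MS1": col, "MS3": col.copy()})
        prof = ms_correlation_profile(ens, [("MS1", "MS3")])
        assert prof["r(MS1,MS3)"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_reported_as_nan(self):
        const = np.full((20, 1), 2.0)
        varying = np.random.default_rng(0).uniform(1.0, 2.0, size=(20, 1))
        ens = _toy_ensemble({"MS1": const, "MS3": varying})
        prof = ms_correlation_profile(ens, [("MS1", "MS3")])
        assert np.isnan(prof["r(MS1,MS3)"].iloc[0])

    def test_cross_matrix_diagonal_matches_profile(self, small_fake_table):
        ens = compute_ms_ensemble(small_fake_table, 400, seed=10, metrics=("MS1", "MS3"))
        prof = ms_correlation_profile(ens, [("MS1", "MS3")])
        cross = cross_correlation_matrix(ens, "MS1", "MS3")
        np.testing.assert_allclose(
            np.diag(cross.to_numpy()), prof["r(MS1,MS3)"].to_numpy(), rtol=1e-10
        )

    def test_too_few_codes_rejected(self, small_fake_table):
        ens = compute_ms_ensemble(small_fake_table, 2, seed=0, metrics=("MS1", "MS3"))
        with pytest.raises(RobustnessStatsError):
            ms_correlation_profile(ens)


class TestReportAssembly:
    def test_report_is_well_formed(self, small_fake_table):
        ens = compute_ms_ensemble(
            small_fake_table, 500, seed=21,
            metrics=("MS1", "MS2", "MS3", "MS3-like", "MS3-unlike"),
        )
        report = build_report(ens, alpha=0.05, compute_n_counts=True)
        pp = report.per_property
        assert len(pp) == len(small_fake_table)
        for metric in ("MS1", "MS2", "MS3"):
            assert ((pp[f"P_{metric}"] >= 0) & (pp[f"P_{metric}"] <= 1)).all()
            assert (
                pp[f"sig_{metric}"] == (pp[f"adjP_{metric}"] <= 0.05)
            ).all()
        assert set(report.sgc_counts) >= {"MS1", "MS2", "MS3"}
        assert all(v <= len(small_fake_table) for v in report.sgc_counts.values())
        assert {"test", "comparison", "statistic", "p_value"} <= set(report.tests.columns)
        assert report.n_counts is not None
        assert (report.controls["test"] == "band_control").sum() == 2

    def test_report_written_to_disk(self, tmp_path, small_fake_table):
        ens = compute_ms_ensemble(small_fake_table, 100, seed=2, metrics=("MS1", "MS3"))
        report = build_report(ens)
        report.write(tmp_path)
        assert (tmp_path / "per_property.tsv").exists()
        assert (tmp_path / "controls.tsv").exists()
        assert (tmp_path / "run_metadata.tsv").exists()
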