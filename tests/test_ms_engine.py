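"""The MS statistic: reference double loop, fast ensemble path, and ensembles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcrobust.error_models import (
    MistranslationParams,
    PairWeightMatrix,
    aggregate_weights_to_sets,
    frameshift_weights,
    uniform_mismatch_weights,
)
from gcrobust.genetic_code import AMINO_ACIDS, build_sgc, code_from_permutation
from gcrobust.ms_engine import (
    MSComputationError,
    MSEnsemble,
    compute_ms,
    compute_ms_ensemble,
    metric_weights,
    sample_permutations,
)
from gcrobust.properties_io import PropertyTable

from conftest import naive_ms


class TestComputeMS:
    def test_constant_property_gives_zero(self):
        sgc = build_sgc()
        const = dict.fromkeys(AMINO_ACIDS, 3.7)
        for metric in ("MS1", "MS3"):
            assert compute_ms(const, sgc, metric_weights(metric)) == 0.0

    @given(scale=st.floats(min_value=0.01, max_value=100, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_quadratic_homogeneity(self, scale, polar_values):
        sgc = build_sgc()
        w = uniform_mismatch_weights()
        base = compute_ms(polar_values, sgc, w)
        scaled = compute_ms(polar_values * scale, sgc, w)
        assert scaled == pytest.approx(scale**2 * base, rel=1e-12)

    def test_indicator_property_closed_form(self):
        """MS of a one-hot property = weight incident to that block / total."""
        sgc = build_sgc()
        w = uniform_mismatch_weights()
        W = aggregate_weights_to_sets(w)
        for aa_idx in (0, 7, 12):  # A, I, P — different block sizes
            indicator = np.zeros(20)
            indicator[aa_idx] = 1.0
            got = compute_ms(indicator, sgc, w)
            incident = W[aa_idx, :].sum() + W[:, aa_idx].sum() - 2 * W[aa_idx, aa_idx]
            assert got == pytest.approx(incident / W.sum(), rel=1e-12)
            # and against the raw double loop oracle
            assert got == pytest.approx(
                naive_ms(indicator, np.arange(20), w.matrix), rel=1e-12
            )

    def test_all_zero_weights_rejected(self, polar_values):
        empty = PairWeightMatrix(matrix=np.zeros((64, 64)), model="empty")
        with pytest.raises(MSComputationError, match="zero"):
            compute_ms(polar_values, build_sgc(), empty)


class TestEnsemble:
    def test_aggregated_form_equals_double_loop(self, small_fake_table):
        """20x20 quadratic form == naive 64x64 loop on random triples."""
        rng = np.random.default_rng(31)
        perms = sample_permutations(rng, 10)
        metrics = ("MS1", "MS2", "MS3", "MS3-like", "MS3-unlike")
        ens = compute_ms_ensemble(
            small_fake_table, 10, seed=0, metrics=metrics, permutations=perms
        )
        checked = 0
        for metric in metrics:
            w = metric_weights(metric)
            for k in (0, 3, 7, 10):
                perm = np.arange(20) if k == 0 else perms[k - 1]
                for p, pid in enumerate(small_fake_table.ids[:3]):
                    expected = naive_ms(small_fake_table.values[p], perm, w.matrix)
                    assert ens.values[metric][k, p] == pytest.approx(expected, abs=1e-12)
                    checked += 1
        assert checked >= 50

    def test_identity_permutation_row_equals_sgc(self, polar_table):
        identity = np.arange(20)[None, :]
        ens = compute_ms_ensemble(
            polar_table, 1, seed=0, metrics=("MS1", "MS3"), permutations=identity
        )
        for metric in ("MS1", "MS3"):
            assert ens.values[metric][1, 0] == ens.values[metric][0, 0]

    def test_ms2_equals_ms1_under_unit_params(self, small_fake_table):
        ens = compute_ms_ensemble(
            small_fake_table, 50, seed=4, metrics=("MS1", "MS2"),
            params=MistranslationParams(),
        )
        np.testing.assert_array_equal(ens.values["MS1"], ens.values["MS2"])

    def test_seed_determinism_and_block_independence(self, small_fake_table):
        a = compute_ms_ensemble(small_fake_table, 300, seed=8, metrics=("MS1",))
        b = compute_ms_ensemble(small_fake_table, 300, seed=8, metrics=("MS1",))
        np.testing.assert_array_equal(a.values["MS1"], b.values["MS1"])
        c = compute_ms_ensemble(small_fake_table, 300, seed=9, metrics=("MS1",))
        assert not np.array_equal(a.values["MS1"], c.values["MS1"])

    def test_plus_minus_one_frameshift_equivalence(self, small_fake_table):
        """MS from the -1 enumerator equals MS3 for 100 (code, property) pairs."""
        from conftest import minus_one_frameshift_matrix

        w_minus = PairWeightMatrix(matrix=minus_one_frameshift_matrix(), model="fs:-1")
        w_plus = frameshift_weights("all")
        rng = np.random.default_rng(77)
        perms = sample_permutations(rng, 20)
        ens = compute_ms_ensemble(
            small_fake_table, 20, seed=0, metrics=("MS3",), permutations=perms
        )
        for k in range(21):
            perm = np.arange(20) if k == 0 else perms[k - 1]
            code = code_from_permutation(perm)
            for p in range(len(small_fake_table)):
                plus = ens.values["MS3"][k, p]
                minus = compute_ms(small_fake_table.values[p], code, w_minus)
                assert minus == pytest.approx(plus, abs=1e-12)

    def test_permutation_mean_closed_form_small(self, polar_values):
        """Mean MS over explicit permutations -> closed form as count grows.

        Under a uniform random relabeling, off-diagonal set pairs carry an
        exchangeable pair of distinct amino acids, so
        E[MS] = (W_between / W_total) * mean_{x != y}(P_x - P_y)^2.
        Brute-force average over 200 explicit permutations, checked within
        3 Monte-Carlo standard errors.
        """
        table = PropertyTable(
            ids=["polar_requirement"], values=polar_values[None, :], provenance="real"
        )
        rng = np.random.default_rng(100)
        perms = sample_permutations(rng, 200)
        for metric in ("MS1", "MS3"):
            W = aggregate_weights_to_sets(metric_weights(metric))
            w_between = W.sum() - W.trace()
            diff = polar_values[:, None] - polar_values[None, :]
            mean_sq = (diff**2).sum() / (20 * 19)
            expected = w_between / W.sum() * mean_sq
            ens = compute_ms_ensemble(
                table, 200, seed=0, metrics=(metric,), permutations=perms
            )
            draws = ens.rgc(metric)[:, 0]
            se = draws.std(ddof=1) / np.sqrt(draws.size)
            assert abs(draws.mean() - expected) < 3 * se

    def test_save_load_round_trip(self, tmp_path, small_fake_table):
        ens = compute_ms_ensemble(small_fake_table, 25, seed=6, metrics=("MS1", "MS3"))
        ens.save(tmp_path / "store")
        back = MSEnsemble.load(tmp_path / "store")
        assert back.property_ids == ens.property_ids
        assert back.n_codes == ens.n_codes and back.seed == ens.seed
        for metric in ens.metrics:
            np.testing.assert_allclose(back.values[metric], ens.values[metric], rtol=1e-9)

    def test_invalid_inputs_rejected(self, small_fake_table):
        with pytest.raises(MSComputationError):
            compute_ms_ensemble(small_fake_table, 0, seed=1)
        with pytest.raises(MSComputationError, match="unknown metric"):
            compute_ms_ensemble(small_fake_table, 5, seed=1, metrics=("MS9",))
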