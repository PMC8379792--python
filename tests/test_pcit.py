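import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_pcit, random_correlation
from regwire.pcit import (
    correlation_matrix,
    partial_correlation,
    pcit,
    pcit_per_condition,
    tolerance,
)
from regwire.synthetic import SimSpec, sim_norm
from regwire.types import ConditionDesign, CorrelationMatrix, ExpressionMatrix


def _corr(values):
    values = np.asarray(values, dtype=float)
    return CorrelationMatrix(values, [f"N{i}" for i in range(values.shape[0])])


class TestPartialCorrelation:
    def test_uncorrelated_conditioning_gene(self):
        assert partial_correlation(0.8, 0.0, 0.0) == pytest.approx(0.8)

    def test_equicorrelated_closed_form(self):
        # all r equal: partial = r/(1+r)
        assert partial_correlation(0.5, 0.5, 0.5) == pytest.approx(1 / 3)

    def test_direct_arithmetic(self):
        assert partial_correlation(0.9, 0.9, 0.9) == pytest.approx(0.09 / 0.19)

    def test_collinear_trio_errors(self):
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(0.5, 1.0, 0.3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            partial_correlation(1.5, 0.0, 0.0)

    @given(
        st.floats(-0.99, 0.99),
        st.floats(-0.99, 0.99),
        st.floats(-0.99, 0.99),
    )
    def test_matches_definition(self, rxy, rxz, ryz):
        expected = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert partial_correlation(rxy, rxz, ryz) == pytest.approx(expected)


class TestTolerance:
    def test_all_half_trio(self):
        # each partial 1/3, each ratio 2/3
        assert tolerance(0.5, 0.5, 0.5) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("rxy", [0.3, 0.6, 0.9])
    def test_vanishing_flanks_limit(self, rxy):
        # r_xz = r_yz = t -> 0: the xy ratio tends to 1 while each flank
        # ratio tends to (1-r_xy)/sqrt(1-r_xy^2) = sqrt((1-r_xy)/(1+r_xy))
        flank = math.sqrt((1 - rxy) / (1 + rxy))
        expected = (1 + 2 * flank) / 3
        assert tolerance(rxy, 1e-9, 1e-9) == pytest.approx(expected, abs=1e-6)

    def test_zero_direct_is_nan(self, caplog):
        with caplog.at_level(logging.WARNING, logger="regwire.pcit"):
            assert math.isnan(tolerance(0.0, 0.5, 0.5))
        assert any("non-informative" in r.getMessage() for r in caplog.records)

    @given(
        st.floats(0.01, 0.95),
        st.floats(0.01, 0.95),
        st.floats(0.01, 0.95),
    )
    def test_relabeling_invariance(self, a, b, c):
        assert tolerance(a, b, c) == pytest.approx(tolerance(b, a, c))
        assert tolerance(a, b, c) == pytest.approx(tolerance(c, b, a))


class TestPcit:
    def test_two_nodes_vacuous(self):
        res = pcit(_corr([[1, 0.3], [0.3, 1]]))
        assert res.significant[0, 1] and res.significant[1, 0]
        assert not res.significant.diagonal().any()

    def test_hand_evaluated_trio(self):
        # trio (0.1, 0.6, 0.6): partials -0.40625, 0.67837..., 0.67837...;
        # eps = (-4.0625 + 1.13062 + 1.13062)/3 = -0.60042; |eps|*0.6 = 0.36
        # -> (x,y) discarded; 0.6 > |eps|*0.1 -> flanks retained
        res = pcit(_corr([[1, 0.1, 0.6], [0.1, 1, 0.6], [0.6, 0.6, 1]]))
        assert not res.significant[0, 1]
        assert res.significant[0, 2] and res.significant[1, 2]

    def test_dominated_weak_pair_discarded(self):
        # non-PSD stress trio (0.05, 0.9, 0.9): eps ~ -25.2 so the scaled
        # comparisons saturate and the oracle discards ALL three pairs
        r = [[1, 0.05, 0.9], [0.05, 1, 0.9], [0.9, 0.9, 1]]
        res = pcit(_corr(r))
        oracle = naive_pcit(np.array(r))
        np.testing.assert_array_equal(res.significant, oracle)
        assert not res.significant[0, 1]

    def test_equicorrelated_block_retained(self):
        r = np.full((4, 4), 0.8)
        np.fill_diagonal(r, 1.0)
        res = pcit(_corr(r))
        assert res.significant[np.triu_indices(4, 1)].all()

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        r = random_correlation(n, rng)
        res = pcit(_corr(r))
        np.testing.assert_array_equal(res.significant, naive_pcit(r))

    def test_oracle_equivalence_sparse_zero_entries(self):
        # exact zeros exercise the non-informative-trio path
        rng = np.random.default_rng(99)
        r = random_correlation(8, rng)
        mask = rng.random((8, 8)) < 0.3
        mask = np.triu(mask, 1)
        r[mask | mask.T] = 0.0
        np.fill_diagonal(r, 1.0)
        res = pcit(_corr(r))
        np.testing.assert_array_equal(res.significant, naive_pcit(r))

    def test_saturated_entries_clamped_not_fatal(self, caplog):
        rng = np.random.default_rng(5)
        r = random_correlation(5, rng)
        r[0, 1] = r[1, 0] = 1.0
        with caplog.at_level(logging.WARNING, logger="regwire.pcit"):
            res = pcit(_corr(r))
        assert any("clamping" in rec.getMessage() for rec in caplog.records)
        np.testing.assert_array_equal(res.significant, naive_pcit(r))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(17)
        r = random_correlation(9, rng)
        perm = rng.permutation(9)
        res1 = pcit(_corr(r))
        res2 = pcit(CorrelationMatrix(r[np.ix_(perm, perm)], [f"N{i}" for i in perm]))
        np.testing.assert_array_equal(
            res1.significant[np.ix_(perm, perm)], res2.significant
        )

    def test_max_pair_survives_when_eps_below_one(self):
        # strongest |r| cannot be dominated when every tolerance is <= 1
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r = random_correlation(6, rng, n_obs=30)
            n = r.shape[0]
            eps_ok = True
            for x in range(n):
                for y in range(x + 1, n):
                    for z in range(y + 1, n):
                        e = tolerance(r[x, y], r[x, z], r[y, z])
                        if not math.isnan(e) and abs(e) > 1:
                            eps_ok = False
            if not eps_ok:
                continue
            off = np.abs(r - np.eye(n))
            i, j = np.unravel_index(off.argmax(), off.shape)
            res = pcit(_corr(r))
            assert res.significant[i, j]

    def test_symmetric_false_diagonal(self):
        rng = np.random.default_rng(2)
        res = pcit(_corr(random_correlation(7, rng)))
        np.testing.assert_array_equal(res.significant, res.significant.T)
        assert not res.significant.diagonal().any()

    def test_weights_are_input_correlations(self):
        rng = np.random.default_rng(3)
        r = random_correlation(5, rng)
        res = pcit(_corr(r))
        np.testing.assert_array_equal(res.weights, r)

    def test_as_printed_variant_differs_by_rule(self):
        # with |eps| < 1 everywhere the printed first inequality is never
        # satisfied, so nothing is discarded
        r = [[1, 0.1, 0.6], [0.1, 1, 0.6], [0.6, 0.6, 1]]
        res = pcit(_corr(r), variant="as_printed")
        assert res.significant[0, 1]

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            pcit(_corr(np.eye(2)), variant="bogus")


class TestCorrelationMatrix:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            values,
            [f"G{i}" for i in range(values.shape[0])],
            [f"S{j}" for j in range(values.shape[1])],
            "normalized",
        )

    def test_identical_rows(self):
        m = self._matrix([[1, 2, 3, 4], [1, 2, 3, 4]])
        c = correlation_matrix(m)
        assert c.values[0, 1] == pytest.approx(1.0)

    def test_negated_row(self):
        m = self._matrix([[1, 2, 3, 4], [4, 3, 2, 1]])
        assert correlation_matrix(m).values[0, 1] == pytest.approx(-1.0)

    def test_latent_factor_convergence(self):
        spec = SimSpec(
            n_genes=5, n_tfs=1, n_samples_per_condition=500,
            planted_tf_rho=(0.6, 0.6), planted_module_size=5, de_effect=0.0, seed=8,
        )
        m, d, _, truth = sim_norm(spec)
        c = correlation_matrix(m.subset_genes(truth.module_genes), d.samples_for("cond1"))
        off = c.values[np.triu_indices(5, 1)]
        np.testing.assert_allclose(off, 0.6, atol=0.1)

    def test_sample_minimum(self):
        m = self._matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(m)


class TestPcitPerCondition:
    def _sim(self, seed, rho=(0.8, 0.0)):
        spec = SimSpec(
            n_genes=12, n_tfs=1, n_samples_per_condition=60,
            planted_tf_rho=rho, planted_module_size=8, de_effect=0.0, seed=seed,
        )
        return sim_norm(spec)

    def test_identical_conditions_identical_networks(self):
        rng = np.random.default_rng(0)
        half = rng.random((6, 10))
        vals = np.hstack([half, half])
        m = ExpressionMatrix(
            vals, [f"G{i}" for i in range(6)], [f"S{j}" for j in range(20)], "normalized"
        )
        d = ConditionDesign(
            {f"S{j}": ("A" if j < 10 else "B") for j in range(20)}, reference="A"
        )
        p_ref, p_alt = pcit_per_condition(m, d)
        np.testing.assert_array_equal(p_ref.significant, p_alt.significant)

    def test_planted_module_condition_specific(self):
        recovered = 0
        for seed in range(5):
            m, d, _, truth = self._sim(seed)
            p_ref, p_alt = pcit_per_condition(m, d, nodes=truth.module_genes)
            n_ref = p_ref.significant.sum() // 2
            n_alt = p_alt.significant.sum() // 2
            if n_ref > n_alt:
                recovered += 1
        assert recovered >= 4

    def test_node_subset_and_order(self):
        m, d, _, truth = self._sim(3)
        nodes = truth.module_genes[:5]
        p_ref, _ = pcit_per_condition(m, d, nodes=nodes)
        assert p_ref.node_ids == nodes
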