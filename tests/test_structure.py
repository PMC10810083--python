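import itertools

import numpy as np
import pytest
from scipy import stats

from cofluct import edges, structure, synth
from cofluct.structure import (
    Bipartition,
    NoValidBipartitionError,
    StructuralConnectome,
    coupling_timeseries,
    extract_bipartition,
    gamma_sweep,
    geometry_preserving_null,
    independent_permutation_null,
    induced_modularity,
    structural_modularity_matrix,
)


def _random_sc(n, rng):
    w = rng.random((n, n))
    np.fill_diagonal(w, 0.0)
    return StructuralConnectome(w)


def _bipartition_from_modules(labels):
    return Bipartition(np.where(labels == labels[0], 1, -1))


def _induced_oracle(sc, plus, minus):
    """Literal double-loop evaluation of the within-community sums."""
    w = sc.weights
    k_in = w.sum(axis=1)
    k_out = w.sum(axis=0)
    two_m = w.sum()
    q = 0.0
    for group in (plus, minus):
        for i in group:
            for j in group:
                if i != j:
                    q += w[i, j] - k_in[i] * k_out[j] / two_m
    return q


class TestConnectome:
    def test_strength_identity(self, rng):
        sc = _random_sc(8, rng)
        assert sc.in_strength.sum() == pytest.approx(sc.total_weight, abs=1e-12)
        assert sc.out_strength.sum() == pytest.approx(sc.total_weight, abs=1e-12)

    def test_rejects_negative_and_diagonal(self):
        with pytest.raises(ValueError):
            StructuralConnectome(np.array([[0.0, -1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            StructuralConnectome(np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_full_modularity_matrix_sums_to_zero(self, rng):
        sc = _random_sc(10, rng)
        assert structural_modularity_matrix(sc).sum() == pytest.approx(0.0, abs=1e-9)


class TestInducedModularity:
    def test_uniform_graph_closed_form(self):
        n, w = 8, 0.7
        mat = np.full((n, n), w)
        np.fill_diagonal(mat, 0.0)
        sc = StructuralConnectome(mat)
        bp = Bipartition(np.array([1, 1, 1, -1, -1, -1, 0, 0]))
        got = induced_modularity(sc, bp)
        oracle = _induced_oracle(sc, bp.plus_nodes, bp.minus_nodes)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_double_loop_oracle_6_nodes(self, rng):
        sc = _random_sc(6, rng)
        bp = Bipartition(np.array([1, 1, -1, -1, -1, 0]))
        got = induced_modularity(sc, bp)
        assert got == pytest.approx(_induced_oracle(sc, [0, 1], [2, 3, 4]), abs=1e-10)

    def test_label_swap_invariance(self, rng):
        sc = _random_sc(7, rng)
        bp = Bipartition(np.array([1, 1, 1, -1, -1, 0, 0]))
        swapped = Bipartition(-bp.labels)
        assert induced_modularity(sc, bp) == pytest.approx(
            induced_modularity(sc, swapped), abs=1e-12)

    def test_node_relabel_invariance(self, rng):
        sc = _random_sc(7, rng)
        bp = Bipartition(np.array([1, 1, -1, -1, 0, 0, 0]))
        perm = rng.permutation(7)
        sc2 = StructuralConnectome(sc.weights[np.ix_(perm, perm)])
        bp2 = Bipartition(bp.labels[perm])
        assert induced_modularity(sc, bp) == pytest.approx(
            induced_modularity(sc2, bp2), abs=1e-10)

    def test_empty_community_rejected(self, rng):
        sc = _random_sc(5, rng)
        with pytest.raises(ValueError):
            induced_modularity(sc, Bipartition(np.array([1, 1, 0, 0, 0])))

    def test_planted_beats_all_rotations(self, default_dataset):
        sc = default_dataset["sc"]
        truth = default_dataset["truth"]
        bp = _bipartition_from_modules(truth.module_labels)
        q0 = induced_modularity(sc, bp)
        for off in range(1, sc.n_nodes):
            rolled = Bipartition(np.roll(bp.labels, off))
            assert q0 >= induced_modularity(sc, rolled) - 1e-10


class TestExtractBipartition:
    def test_rank_one_mixed_sign(self, rng):
        v = np.where(rng.random(20) < 0.5, 1.0, -1.0)
        v[0], v[1] = 1.0, -1.0  # both signs guaranteed
        cent = edges.CoFluctuationPattern(np.outer(v, v) - np.diag(v**2))
        bp = extract_bipartition(cent, n_iter=50, seed=0)
        assert bp.n_plus + bp.n_minus == 20
        agree = max(np.mean(bp.labels == v), np.mean(bp.labels == -v))
        assert agree == 1.0

    def test_all_positive_centroid_errors(self):
        cent = edges.CoFluctuationPattern(np.ones((10, 10)) - np.eye(10))
        with pytest.raises(NoValidBipartitionError):
            extract_bipartition(cent, n_iter=20, seed=0)

    def test_planted_mode_recovery(self, rng):
        v = np.repeat([1.0, -1.0], 15)
        pats = []
        for _ in range(20):
            vv = v + rng.normal(0, 0.3, 30)
            m = np.outer(vv, vv)
            np.fill_diagonal(m, 0.0)
            pats.append(m)
        cent = edges.CoFluctuationPattern(np.mean(pats, axis=0))
        bp = extract_bipartition(cent, n_iter=100, seed=1)
        agree = max(np.mean(bp.labels == v), np.mean(bp.labels == -v))
        assert agree >= 0.95


class TestIndependentNull:
    def test_planted_significant(self, default_dataset):
        sc = default_dataset["sc"]
        bp = _bipartition_from_modules(default_dataset["truth"].module_labels)
        res = independent_permutation_null(sc, bp, n_perm=1000, seed=0)
        assert res.p_value < 0.05

    def test_uniform_graph_not_significant(self):
        n = 12
        mat = np.full((n, n), 0.5)
        np.fill_diagonal(mat, 0.0)
        sc = StructuralConnectome(mat)
        bp = Bipartition(np.array([1] * 4 + [-1] * 4 + [0] * 4))
        res = independent_permutation_null(sc, bp, n_perm=200, seed=1)
        assert np.ptp(res.null_values) < 1e-9  # null concentrated at the oracle value
        assert res.p_value > 0.5

    def test_exhaustive_enumeration_6_nodes(self, rng):
        sc = _random_sc(6, rng)
        bp = Bipartition(np.array([1, 1, -1, -1, 0, 0]))
        observed = induced_modularity(sc, bp)
        nodes = range(6)
        count = total = 0
        for plus in itertools.combinations(nodes, 2):
            rest = [x for x in nodes if x not in plus]
            for minus in itertools.combinations(rest, 2):
                q = _induced_oracle(sc, list(plus), list(minus))
                total += 1
                count += q >= observed - 1e-12
        exact = count / total
        res = independent_permutation_null(sc, bp, n_perm=4000, seed=2)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(res.p_value - exact) <= max(3 * se, 2 / 4000)

    def test_p_uniform_without_structure(self):
        # structureless connectome: p-values roughly uniform over instances
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(40):
            sc = _random_sc(14, rng)
            bp = Bipartition(np.array([1] * 4 + [-1] * 4 + [0] * 6))
            pvals.append(independent_permutation_null(sc, bp, 99, seed=int(
                rng.integers(2**31))).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGeometryNull:
    def test_rotation_identity_equals_observed(self, default_dataset):
        sc = default_dataset["sc"]
        truth = default_dataset["truth"]
        bp = _bipartition_from_modules(truth.module_labels)
        bsc = structural_modularity_matrix(sc)
        order = structure._rotation_order(truth.node_coordinates)
        lab = bp.labels[order]
        rolled = np.empty_like(lab)
        rolled[order] = np.roll(lab, 0)
        q0 = structure._induced_from_bsc(
            bsc, np.flatnonzero(rolled == 1), np.flatnonzero(rolled == -1))
        assert q0 == pytest.approx(induced_modularity(sc, bp), abs=1e-10)

    def test_rotation_size_conservation(self, default_dataset):
        truth = default_dataset["truth"]
        order = structure._rotation_order(truth.node_coordinates)
        bp = _bipartition_from_modules(truth.module_labels)
        lab = bp.labels[order]
        for off in range(1, lab.size):
            rolled = np.roll(lab, off)
            assert (rolled == 1).sum() == bp.n_plus
            assert (rolled == -1).sum() == bp.n_minus

    def test_rotation_stricter_than_independent(self, default_dataset):
        sc = default_dataset["sc"]
        truth = default_dataset["truth"]
        bp = _bipartition_from_modules(truth.module_labels)
        ind = independent_permutation_null(sc, bp, n_perm=500, seed=3)
        rot = geometry_preserving_null(
            sc, bp, truth.node_coordinates, n_perm=500, strategy="rotation", seed=3)
        assert rot.null_values.mean() > ind.null_values.mean()
        assert rot.p_value < 0.05

    def test_variogram_strategy_runs(self, default_dataset):
        sc = default_dataset["sc"]
        truth = default_dataset["truth"]
        bp = _bipartition_from_modules(truth.module_labels)
        res = geometry_preserving_null(
            sc, bp, truth.node_coordinates, n_perm=20, strategy="variogram",
            seed=4, variogram_rtol=0.3)
        assert res.null_values.size == 20
        assert 0 < res.p_value <= 1


class TestGammaSweep:
    def test_single_gamma_matches_single_call(self, rng):
        v = np.repeat([1.0, -1.0], 10)
        cent = edges.CoFluctuationPattern(np.outer(v, v) - np.eye(20))
        mat = rng.random((20, 20))
        np.fill_diagonal(mat, 0.0)
        sc = StructuralConnectome(mat)
        sweep = gamma_sweep(cent, sc, [1.0], n_iter=50, n_perm=100, seed=5)
        bp = extract_bipartition(cent, gamma=1.0, n_iter=50, seed=5)
        np.testing.assert_array_equal(sweep[1.0]["bipartition"].labels, bp.labels)

    def test_rank_one_stable_across_gammas(self, rng):
        v = np.repeat([1.0, -1.0], 10)
        cent = edges.CoFluctuationPattern(np.outer(v, v) - np.eye(20))
        mat = rng.random((20, 20))
        np.fill_diagonal(mat, 0.0)
        sc = StructuralConnectome(mat)
        sweep = gamma_sweep(cent, sc, [0.5, 1.0, 2.0], n_iter=50, n_perm=50, seed=6)
        labels = [sweep[g]["bipartition"].labels for g in (0.5, 1.0, 2.0)]
        for a, b in itertools.combinations(labels, 2):
            agreement = max(np.mean(a == b), np.mean(a == -b))
            assert agreement >= 0.9

    def test_invalid_gamma_reported_not_raised(self):
        cent = edges.CoFluctuationPattern(np.ones((10, 10)) - np.eye(10))
        mat = np.full((10, 10), 0.5)
        np.fill_diagonal(mat, 0.0)
        sweep = gamma_sweep(cent, StructuralConnectome(mat), [1.0], n_iter=20,
                            n_perm=50, seed=7)
        assert sweep[1.0]["valid"] is False

    def test_empty_gammas_rejected(self, rng):
        cent = edges.CoFluctuationPattern(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            gamma_sweep(cent, _random_sc(4, rng), [])


class TestCoupling:
    def test_sc_proportional_to_frame(self, default_dataset):
        ets = default_dataset["ets"]
        rms = default_dataset["rms"]
        t = 5
        pat = edges.frame_pattern(ets, t).values
        w = pat - pat.min() + 0.1  # strictly positive, same ranks
        np.fill_diagonal(w, 0.0)
        sc = StructuralConnectome(w)
        coup = coupling_timeseries(ets, sc, rms)
        assert coup.coupling[t] == pytest.approx(1.0, abs=1e-10)

    def test_per_frame_loop_oracle(self, rng):
        z = edges.standardize_timeseries(
            edges.ParcelTimeSeries(rng.standard_normal((8, 30))))
        ets = edges.compute_edge_timeseries(z)
        rms = edges.compute_rms(ets)
        sc = _random_sc(8, rng)
        coup = coupling_timeseries(ets, sc, rms)
        sc_vec = edges.vectorize_pattern(0.5 * (sc.weights + sc.weights.T))
        for t in range(30):
            expected = stats.spearmanr(ets.values[:, t], sc_vec).statistic
            assert coup.coupling[t] == pytest.approx(expected, abs=1e-10)

    def test_rms_coupling_positive_on_aligned_data(self, default_dataset):
        coup = coupling_timeseries(
            default_dataset["ets"], default_dataset["sc"], default_dataset["rms"])
        rho = stats.spearmanr(coup.rms, coup.coupling).statistic
        assert rho > 0

    def test_constant_sc_rejected(self, default_dataset):
        n = default_dataset["sc"].n_nodes
        mat = np.full((n, n), 1.0)
        np.fill_diagonal(mat, 0.0)
        # symmetrized constant off-diagonal -> zero rank spread
        with pytest.raises(ValueError, match="constant"):
            coupling_timeseries(default_dataset["ets"], StructuralConnectome(mat),
                                default_dataset["rms"])
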