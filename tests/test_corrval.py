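"""Signature building, predicted correlations, F-score, dendrograms,
Mantel test and overlap enrichment."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_stack
from fruitnet.corrval import (CorrComparison, PerturbationSignature,
                              build_signature, build_signatures, f_score_curve,
                              mantel, overlap_enrichment,
                              precision_recall_f, predicted_correlation,
                              predicted_correlation_matrix,
                              signature_dendrogram)
from fruitnet.perturb import KO, OE


def _sig(met, plus=(), minus=(), eps=0.01):
    return PerturbationSignature(met, set(plus), set(minus), eps)


class TestBuildSignature:
    def _stack(self):
        rng = np.random.default_rng(0)
        W = np.zeros((6, 6))
        V = np.zeros((3, 6))
        V[0, 0] = 2.0    # m0 strongly driven up by g0
        V[1, 1] = -2.0   # m1 strongly driven down by g1
        V[2, :] = 0.0    # m2 has no drivers
        baselines = rng.normal(0, 1.0, size=(10, 6))
        return build_stack(W, V, ranges=(-2.0, 2.0), baselines=baselines)

    def test_sign_logic(self):
        stack = self._stack()
        sigs = build_signatures(stack, epsilon=0.01)
        assert ("g0", OE) in sigs["m0"].omega_plus
        assert ("g0", KO) in sigs["m0"].omega_minus
        assert ("g1", OE) in sigs["m1"].omega_minus
        assert ("g1", KO) in sigs["m1"].omega_plus

    def test_undriven_metabolite_has_empty_sets(self):
        stack = self._stack()
        sig = build_signature(stack, "m2")
        assert sig.is_empty()

    def test_membership_matches_linear_effect_oracle(self):
        # uncoupled gene layer: effect of clamping g at c on metabolite k is
        # exactly v_kg * (c - g_line) per line
        rng = np.random.default_rng(1)
        W = np.zeros((5, 5))
        V = rng.normal(size=(2, 5))
        baselines = rng.normal(0, 0.8, size=(8, 5))
        stack = build_stack(W, V, ranges=(-2.0, 2.0), baselines=baselines)
        eps = 0.01
        sigs = build_signatures(stack, epsilon=eps)
        from fruitnet.steadystate import clamp_value, predict_metabolome

        wt = pd.DataFrame({
            ln: predict_metabolome(stack, stack.expression.loc[ln])
            for ln in stack.baseline_lines
        }).T
        sd = wt.std(ddof=0)
        for k, met in enumerate(stack.metabolite_names):
            for j, gene in enumerate(stack.gene_names):
                for mode in (KO, OE):
                    c = clamp_value(stack.genes, gene, mode)
                    deltas = [
                        V[k, j] * (c - stack.expression.loc[ln, gene]) / sd[met]
                        for ln in stack.baseline_lines
                    ]
                    rel = float(np.mean(deltas))
                    in_plus = (gene, mode) in sigs[met].omega_plus
                    in_minus = (gene, mode) in sigs[met].omega_minus
                    assert in_plus == (rel > eps)
                    assert in_minus == (rel < -eps)

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(KeyError):
            build_signature(self._stack(), "nope")

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            build_signatures(self._stack(), epsilon=0.0)


class TestPredictedCorrelation:
    def test_identical_signatures_give_one(self):
        a = _sig("a", plus=[("g1", OE), ("g2", KO)], minus=[("g3", OE)])
        b = _sig("b", plus=[("g1", OE), ("g2", KO)], minus=[("g3", OE)])
        assert predicted_correlation(a, b) == 1.0

    def test_mirrored_signatures_give_minus_one(self):
        a = _sig("a", plus=[("g1", OE)], minus=[("g2", KO)])
        b = _sig("b", plus=[("g2", KO)], minus=[("g1", OE)])
        assert predicted_correlation(a, b) == -1.0

    def test_disjoint_signatures_give_zero(self):
        a = _sig("a", plus=[("g1", OE)])
        b = _sig("b", plus=[("g2", OE)])
        assert predicted_correlation(a, b) == 0.0

    def test_symmetry(self):
        a = _sig("a", plus=[("g1", OE), ("g2", OE)], minus=[("g4", KO)])
        b = _sig("b", plus=[("g2", OE)], minus=[("g4", KO), ("g5", OE)])
        assert predicted_correlation(a, b) == predicted_correlation(b, a)

    def test_subset_counts_as_full_overlap_with_min_normalization(self):
        a = _sig("a", plus=[("g1", OE), ("g2", OE), ("g3", OE)])
        b = _sig("b", plus=[("g1", OE)])
        assert predicted_correlation(a, b) == 1.0
        assert predicted_correlation(a, b, normalization="jaccard") == pytest.approx(1 / 3)

    def test_empty_pair_is_nan(self):
        a = _sig("a")
        b = _sig("b")
        assert np.isnan(predicted_correlation(a, b))

    def test_epsilon_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predicted_correlation(_sig("a", eps=0.01), _sig("b", eps=0.05))


class TestPrecisionRecallF:
    def _matrices(self, pred_pairs, emp_pairs, n=8):
        labels = [f"m{i}" for i in range(n)]
        P = pd.DataFrame(np.eye(n), index=labels, columns=labels)
        E = P.copy()
        for i, j in pred_pairs:
            P.iloc[i, j] = P.iloc[j, i] = 0.9
        for i, j in emp_pairs:
            E.iloc[i, j] = E.iloc[j, i] = 0.9
        return P, E

    def test_perfect_prediction(self):
        P, E = self._matrices([(0, 1), (2, 3)], [(0, 1), (2, 3)])
        c = precision_recall_f(P, E, 0.5)
        assert (c.precision, c.recall, c.f_score) == (1.0, 1.0, 1.0)

    def test_half_half_gives_f_half(self):
        # P = R = 0.5 -> F = 0.5
        P, E = self._matrices([(0, 1), (2, 3)], [(0, 1), (4, 5)])
        c = precision_recall_f(P, E, 0.5)
        assert c.precision == 0.5
        assert c.recall == 0.5
        assert c.f_score == 0.5

    def test_asymmetric_case(self):
        # P = 0.6 (3/5 called correct), R = 0.3 (3/10 found) -> F = 0.4
        pred = [(0, 1), (0, 2), (0, 3), (4, 5), (4, 6)]
        emp = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
               (5, 6), (5, 7), (6, 7), (4, 7)]
        P, E = self._matrices(pred, emp)
        c = precision_recall_f(P, E, 0.5)
        assert c.precision == pytest.approx(0.6)
        assert c.recall == pytest.approx(0.3)
        assert c.f_score == pytest.approx(0.4)

    def test_no_empirical_calls_recall_missing(self):
        P, E = self._matrices([(0, 1)], [])
        c = precision_recall_f(P, E, 0.5)
        assert c.recall is None

    def test_empirical_floor_restricts_pairs(self):
        labels = ["a", "b", "c"]
        P = pd.DataFrame(np.eye(3), index=labels, columns=labels)
        E = P.copy()
        P.loc["a", "b"] = P.loc["b", "a"] = 0.9
        E.loc["a", "b"] = E.loc["b", "a"] = 0.2  # weak empirical pair
        c = precision_recall_f(P, E, 0.6, min_empirical_r=0.5)
        assert c.n_pairs == 0  # all pairs below the empirical floor

    def test_curve_matches_single_calls(self):
        P, E = self._matrices([(0, 1), (2, 3)], [(0, 1), (4, 5)])
        curve = f_score_curve(P, E, [0.5, 0.95])
        assert curve.loc[0, "f_score"] == 0.5
        assert np.isnan(curve.loc[1, "f_score"]) or curve.loc[1, "f_score"] is None


class TestDendrogram:
    def test_identical_pair_joins_first_at_zero(self):
        sigs = {
            "a": _sig("a", plus=[("g1", OE), ("g2", KO)]),
            "b": _sig("b", plus=[("g1", OE), ("g2", KO)]),
            "c": _sig("c", plus=[("g9", OE)]),
        }
        dend = signature_dendrogram(sigs)
        first = dend.linkage[0]
        assert {dend.labels[int(first[0])], dend.labels[int(first[1])]} == {"a", "b"}
        assert first[2] == pytest.approx(0.0)
        assert "a" in dend.newick and "c" in dend.newick

    def test_leaf_count_matches_metabolites(self, small_stack):
        sigs = build_signatures(small_stack, epsilon=0.05)
        dend = signature_dendrogram(sigs)
        assert len(dend.labels) == len(small_stack.metabolite_names)
        import re

        leaves = re.findall(r"M\d+", dend.newick)
        assert len(set(leaves)) == len(dend.labels)

    def test_ultrametric_distances_reproduced_by_average_linkage(self):
        labels = ["a", "b", "c", "d"]
        D = np.array([
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.4],
            [0.8, 0.8, 0.4, 0.0],
        ])
        corr = pd.DataFrame(1.0 - D, index=labels, columns=labels)
        dend = signature_dendrogram(corr, linkage="average")
        np.testing.assert_allclose(dend.cophenetic().to_numpy(), D, atol=1e-12)

    def test_too_few_leaves_rejected(self):
        corr = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            signature_dendrogram(corr)


class TestMantel:
    def _dist(self, rng, n=20):
        M = rng.random((n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        return M

    def test_identical_matrices(self):
        rng = np.random.default_rng(2)
        D = self._dist(rng)
        res = mantel(D, D.copy(), n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        D = self._dist(rng)
        res = mantel(D, 3.0 * D + 1.0, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        D = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="constant"):
            mantel(D, D)

    def test_agrees_with_skbio_reference(self):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(4)
        A, B = self._dist(rng, 15), self._dist(rng, 15)
        ours = mantel(A, B, n_perm=999, seed=1)
        ref = sk_mantel(DistanceMatrix(A), DistanceMatrix(B), permutations=0)
        # scikit-bio is the independent oracle for the statistic itself
        assert ours.r == pytest.approx(float(ref[0]), abs=1e-12)

    def test_null_p_values_uniform(self):
        # reduced-scale calibration check (the full 200x999 case lives in
        # the acceptance suite)
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(60):
            res = mantel(self._dist(rng), self._dist(rng), n_perm=199,
                         seed=int(rng.integers(2**31)))
            ps.append(res.p_value)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestOverlapEnrichment:
    def test_full_overlap(self):
        proposed = {("g1", KO), ("g2", OE)}
        observed = {"g1": "down", "g2": "up"}
        res = overlap_enrichment(proposed, observed, [f"g{i}" for i in range(20)],
                                 n_random=100, seed=0)
        assert res.overlap_pct == 100.0

    def test_empty_observed_gives_zero(self):
        proposed = {("g1", KO)}
        res = overlap_enrichment(proposed, {}, [f"g{i}" for i in range(10)],
                                 n_random=50, seed=0)
        assert res.overlap_pct == 0.0

    def test_empty_proposed_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(set(), {"g1": "up"}, ["g1"], n_random=10)

    def test_direction_mismatch_not_counted(self):
        proposed = {("g1", OE)}
        observed = {"g1": "down"}
        res = overlap_enrichment(proposed, observed, [f"g{i}" for i in range(10)],
                                 n_random=50, seed=0)
        assert res.overlap_pct == 0.0

    def test_null_mean_matches_random_expectation(self):
        # random (gene, mode) proposals match a directional observed gene
        # with probability |observed| / (2 |universe|)
        universe = [f"g{i}" for i in range(40)]
        observed = {g: "up" for g in universe[:10]}
        proposed = {(g, OE) for g in universe[30:36]}
        res = overlap_enrichment(proposed, observed, universe,
                                 n_random=4000, seed=1)
        expect = 100.0 * 10 / (2 * 40)
        sem = res.null_sd_pct / np.sqrt(res.n_random)
        assert abs(res.null_mean_pct - expect) < 4 * sem + 1e-9

    def test_mannwhitney_reported_for_multiple_lines(self):
        universe = [f"g{i}" for i in range(30)]
        proposed = {(g, KO) for g in universe[:5]}
        observed = [{g: "down" for g in universe[:5]},
                    {g: "down" for g in universe[:4]},
                    {g: "down" for g in universe[:3]}]
        res = overlap_enrichment(proposed, observed, universe,
                                 n_random=200, seed=2)
        assert res.u_statistic is not None
        assert res.p_mannwhitney < 0.05
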