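"""Objective scoring, landscape scans, greedy search vs brute-force oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import build_stack
from fruitnet.optimize import (ObjectiveSpec, efficiency, evaluate_objective,
                               greedy_multi, landscape_stats,
                               objective_from_dict, rank_perturbations,
                               scan_pairs, scan_single)
from fruitnet.perturb import KO, OE, WT, PerturbationSet
from fruitnet.steadystate import clamp_value


def _toy_stack(n_genes=5, n_mets=3, seed=0, coupled=False, n_lines=2,
               ranges=(-2.0, 2.0)):
    """Small stack; pass wide `ranges` when a linear (unbounded) oracle is
    used for comparison, so no bound can activate."""
    rng = np.random.default_rng(seed)
    if coupled:
        W = rng.normal(size=(n_genes, n_genes)) * (rng.random((n_genes, n_genes)) < 0.3)
        np.fill_diagonal(W, 0.0)
        r = np.max(np.abs(np.linalg.eigvals(W)))
        if r > 0:
            W *= 0.7 / r
    else:
        W = np.zeros((n_genes, n_genes))
    V = rng.normal(size=(n_mets, n_genes))
    baselines = rng.normal(0, 0.5, size=(n_lines, n_genes))
    return build_stack(W, V, ranges=ranges, baselines=baselines)


class TestEvaluateObjective:
    def test_single_trait_weight_one(self):
        spec = ObjectiveSpec(maximize={"m0": 1.0})
        vals = pd.Series({"m0": 3.2, "m1": -1.0})
        assert evaluate_objective(spec, vals) == 3.2

    def test_balanced_symmetry_cancels(self):
        spec = ObjectiveSpec(maximize=["m0", "m1"], minimize=["m2", "m3"])
        vals = pd.Series({"m0": 2.0, "m1": 2.0, "m2": 2.0, "m3": 2.0})
        assert evaluate_objective(spec, vals) == pytest.approx(0.0)

    def test_alpha_one_reduces_to_primary(self):
        primary = ObjectiveSpec(maximize={"m0": 1.0})
        bi = ObjectiveSpec(maximize={"m0": 1.0},
                           secondary=ObjectiveSpec(maximize={"m1": 1.0}),
                           alpha=1.0)
        wt = pd.DataFrame({"m0": [0.0, 2.0], "m1": [1.0, 3.0]})
        from fruitnet.optimize import calibrate_objective

        stats = calibrate_objective(bi, wt)
        vals = pd.Series({"m0": 1.5, "m1": -4.0})
        z_primary = (evaluate_objective(primary, vals) - 1.0) / 1.0  # mean 1, sd 1
        assert evaluate_objective(bi, vals, stats) == pytest.approx(z_primary)

    def test_target_mode(self):
        spec = ObjectiveSpec(maximize={"t0": 1.0}, mode="target", target_value=2.0)
        assert evaluate_objective(spec, pd.Series({"t0": 2.0})) == 0.0
        assert evaluate_objective(spec, pd.Series({"t0": 3.5})) == -1.5

    def test_validation(self):
        with pytest.raises(ValueError, match="both"):
            ObjectiveSpec(maximize=["m0"], minimize=["m0"])
        with pytest.raises(ValueError):
            ObjectiveSpec(maximize={"m0": -1.0})
        with pytest.raises(ValueError):
            ObjectiveSpec(maximize=["m0"], alpha=1.5)
        with pytest.raises(KeyError):
            evaluate_objective(ObjectiveSpec(maximize=["nope"]), pd.Series({"m0": 1.0}))

    def test_round_trip_from_dict(self):
        spec = objective_from_dict({
            "maximize": {"m0": 2.0}, "minimize": ["m1", "m2"],
            "secondary": {"maximize": ["t0"]}, "alpha": 0.7,
        })
        assert spec.maximize == {"m0": 2.0}
        assert spec.minimize == {"m1": 0.5, "m2": 0.5}
        assert spec.secondary.maximize == {"t0": 1.0}


class TestEfficiency:
    def test_no_change_is_zero(self):
        assert efficiency(1.7, 1.7) == 0.0

    def test_improvement_scale(self):
        assert efficiency(3.2731, 1.0) == pytest.approx(227.31)

    def test_negative_wild_type_sign_handling(self):
        assert efficiency(-1.0, -2.0) == pytest.approx(50.0)

    def test_zero_wild_type_uses_population_sd(self):
        with pytest.warns(UserWarning, match="population sd"):
            assert efficiency(0.5, 0.0, fallback_sd=2.0) == pytest.approx(25.0)
        with pytest.raises(ValueError):
            efficiency(0.5, 0.0)


class TestScans:
    def test_single_scan_record_count_and_order(self):
        stack = _toy_stack(n_genes=10)
        spec = ObjectiveSpec(maximize={"m0": 1.0})
        records = scan_single(stack, spec)
        assert len(records) == 1 + 2 * 10
        assert records[0].perturbation.label() == "WT"
        assert records[1].perturbation.label() == "g0:KO"
        assert records[2].perturbation.label() == "g0:OE"

    def test_wild_type_efficiency_exactly_zero(self):
        stack = _toy_stack()
        for spec in (ObjectiveSpec(maximize={"m0": 1.0}),
                     ObjectiveSpec(minimize={"m1": 1.0}),
                     ObjectiveSpec(maximize=["m0"], minimize=["m2"])):
            wt = scan_single(stack, spec)[0]
            assert (wt.efficiency == 0.0).all()

    def test_sole_positive_driver_wins_by_overexpression(self):
        W = np.zeros((4, 4))
        V = np.zeros((1, 4))
        V[0, 2] = 1.5  # only g2 feeds the objective, positively
        stack = build_stack(W, V, ranges=(-1.0, 1.0),
                            baselines=np.zeros((2, 4)))
        spec = ObjectiveSpec(maximize={"m0": 1.0})
        records = scan_single(stack, spec)
        best = max(records, key=lambda r: r.mean_score)
        assert best.perturbation.label() == "g2:OE"

    def test_single_scan_matches_enumeration_oracle(self):
        # independent oracle: per-record projected fixed-point sweep run to
        # convergence, a different algorithm than the scan's low-rank solves
        from conftest import naive_steady_oracle

        stack = _toy_stack(n_genes=6, coupled=True, seed=3)
        spec = ObjectiveSpec(maximize={"m0": 1.0}, minimize={"m1": 1.0})
        records = scan_single(stack, spec)
        W = stack.genes.coef.to_numpy()
        V = stack.metabolites.coef.to_numpy()
        genes = list(stack.gene_names)
        lo = stack.genes.gene_ranges["min"].to_numpy()
        hi = stack.genes.gene_ranges["max"].to_numpy()
        for rec in records[1:]:
            (gene, mode), = rec.perturbation.items()
            j = genes.index(gene)
            c = clamp_value(stack.genes, gene, mode)
            for line in stack.baseline_lines:
                gobs = stack.expression.loc[line].to_numpy()
                e = gobs - (W @ gobs)
                g = naive_steady_oracle(
                    W, np.zeros(len(genes)), e, lo, hi,
                    np.array([j]), np.array([c]),
                )
                m = V @ g
                want = m[0] - m[1]
                assert rec.scores[line] == pytest.approx(want, abs=1e-7)

    def test_pair_scan_combinatorics(self):
        stack = _toy_stack(n_genes=5)
        spec = ObjectiveSpec(maximize={"m0": 1.0})
        records = scan_pairs(stack, spec)
        # WT + C(5,2) pairs x 4 mode combos
        assert len(records) == 1 + 10 * 4

    def test_pair_scan_budget_and_seed(self):
        stack = _toy_stack(n_genes=6)
        spec = ObjectiveSpec(maximize={"m0": 1.0})
        a = scan_pairs(stack, spec, budget=7, seed=5)
        b = scan_pairs(stack, spec, budget=7, seed=5)
        assert len(a) == 1 + 7
        assert [r.perturbation.label() for r in a] == [r.perturbation.label() for r in b]
        with pytest.raises(ValueError):
            scan_pairs(stack, spec, budget=0)

    def test_pair_landscape_contains_singles_with_degenerate_rows(self):
        stack = _toy_stack(n_genes=4, coupled=True, seed=9)
        spec = ObjectiveSpec(maximize={"m0": 1.0})
        singles = scan_single(stack, spec)
        pairs = scan_pairs(stack, spec, include_degenerate=True)
        best_single = max(r.mean_score for r in singles)
        best_pair = max(r.mean_score for r in pairs)
        assert best_pair >= best_single - 1e-12

    def test_additive_pathways_pair_score_adds(self):
        # no gene-gene coupling: effects on the objective are additive
        stack = _toy_stack(n_genes=6, coupled=False, seed=2, n_lines=1)
        spec = ObjectiveSpec(maximize={"m0": 1.0})
        singles = {r.perturbation.label(): r for r in scan_single(stack, spec)}
        wt = singles["WT"].mean_score
        pairs = scan_pairs(stack, spec)
        for rec in pairs[1:]:
            items = sorted(rec.perturbation.items())
            expect = sum(
                singles[f"{g}:{m}"].mean_score - wt for g, m in items
            ) + wt
            assert rec.mean_score == pytest.approx(expect, abs=1e-8)


class TestGreedy:
    def _brute_force(self, stack, spec):
        """Exhaustive 3^n oracle by direct linear solves (wide ranges)."""
        genes = list(stack.gene_names)
        W = stack.genes.coef.to_numpy()
        V = stack.metabolites.coef.to_numpy()
        A = np.eye(len(genes)) - W
        lines = stack.baseline_lines
        best = (-np.inf, None)
        for combo in itertools.product((WT, KO, OE), repeat=len(genes)):
            clamps = {g: m for g, m in zip(genes, combo) if m != WT}
            scores = []
            for line in lines:
                gobs = stack.expression.loc[line].to_numpy()
                e = gobs - (W @ gobs)
                cidx = [genes.index(g) for g in clamps]
                cvals = [clamp_value(stack.genes, g, m) for g, m in clamps.items()]
                free = [i for i in range(len(genes)) if i not in cidx]
                g = np.empty(len(genes))
                for i, v in zip(cidx, cvals):
                    g[i] = v
                rhs = e[free]
                if cidx:
                    rhs = rhs + W[np.ix_(free, cidx)] @ np.asarray(cvals)
                g[free] = np.linalg.solve(A[np.ix_(free, free)], rhs)
                m = V @ g
                scores.append(spec._scored(pd.Series(m, index=stack.metabolite_names)))
            mean = float(np.mean(scores))
            if mean > best[0]:
                best = (mean, clamps)
        return best

    def test_greedy_bounded_by_brute_force_optimum(self):
        stack = _toy_stack(n_genes=8, n_mets=2, coupled=True, seed=4, n_lines=2,
                           ranges=(-50.0, 50.0))
        spec = ObjectiveSpec(maximize={"m0": 1.0})
        opt_score, _ = self._brute_force(stack, spec)
        best, traj = greedy_multi(stack, spec, max_rounds=12)
        final = traj["mean_score"].iloc[-1]
        assert final <= opt_score + 1e-8

    def test_greedy_exact_on_additive_toys(self):
        stack = _toy_stack(n_genes=8, n_mets=2, coupled=False, seed=5, n_lines=2)
        spec = ObjectiveSpec(maximize={"m0": 1.0}, minimize={"m1": 1.0})
        opt_score, opt_clamps = self._brute_force(stack, spec)
        best, traj = greedy_multi(stack, spec, max_rounds=20)
        assert traj["mean_score"].iloc[-1] == pytest.approx(opt_score, abs=1e-8)

    def test_trajectory_non_decreasing(self):
        stack = _toy_stack(n_genes=6, coupled=True, seed=6)
        spec = ObjectiveSpec(maximize={"m0": 1.0})
        _, traj = greedy_multi(stack, spec, max_rounds=10)
        assert (np.diff(traj["mean_score"]) >= -1e-12).all()

    def test_first_commit_is_best_single(self):
        stack = _toy_stack(n_genes=6, coupled=True, seed=7)
        spec = ObjectiveSpec(maximize={"m1": 1.0})
        singles = scan_single(stack, spec)
        best_single = max(r.mean_score for r in singles)
        _, traj = greedy_multi(stack, spec, max_rounds=1)
        assert traj["mean_score"].iloc[-1] == pytest.approx(best_single, abs=1e-10)


class TestRankingAndLandscape:
    def _fake_records(self):
        from fruitnet.optimize import ScanRecord

        lines = ["L0", "L1"]

        def rec(label_gene, mode, scores, effs):
            return ScanRecord(
                PerturbationSet({label_gene: mode}),
                pd.Series(scores, index=lines),
                pd.Series(effs, index=lines),
            )

        return [
            rec("g0", KO, [1.0, 1.0], [5.0, 5.0]),    # mean eff 5, max 1
            rec("g1", KO, [9.0, -5.0], [3.0, 3.0]),   # mean eff 3, max 9
        ]

    def test_rank_by_mean_efficiency(self):
        table = rank_perturbations(self._fake_records(), "mean_efficiency")
        assert list(table["genes"]) == ["g0", "g1"]

    def test_criterion_switch_changes_order(self):
        table = rank_perturbations(self._fake_records(), "mean_max_property")
        assert list(table["genes"]) == ["g1", "g0"]

    def test_stable_tie_order(self):
        recs = self._fake_records()
        recs[1].efficiency[:] = 5.0  # tie on mean efficiency
        table = rank_perturbations(recs, "mean_efficiency")
        assert list(table["genes"]) == ["g0", "g1"]

    def test_empty_records(self):
        assert rank_perturbations([], "mean_efficiency").empty

    def test_landscape_hand_count(self):
        recs = self._fake_records()
        stats = landscape_stats(recs, [0.0, 4.0, 10.0])
        # thr 0: both records exceed in both lines -> count 2 per line
        assert stats.loc[0, "count_mean"] == 2.0
        assert stats.loc[0, "prob_mean"] == 1.0
        # thr 4: only g0 (eff 5) exceeds -> count 1, probs (1, 0) -> mean 0.5
        assert stats.loc[1, "count_mean"] == 1.0
        assert stats.loc[1, "prob_mean"] == 0.5
        # thr 10: nothing
        assert stats.loc[2, "count_mean"] == 0.0
        assert stats.loc[2, "prob_mean"] == 0.0
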