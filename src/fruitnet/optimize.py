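"""Objective scoring and perturbation-landscape exploration.

Objectives are signed weighted sums of metabolite/trait values (balanced
1/|set| weights by default), optionally tuned to a target value or combined
into a bi-objective trade-off.  The landscape of genome redesigns is
explored three ways: exhaustive single-gene knockout/over-expression scans,
pairwise scans (exhaustive or budgeted random sampling), and a greedy
multi-perturbation search that commits the best single change per sweep.

Efficiency of a perturbation for one line is the relative improvement of
its objective over the wild-type prediction for that line, in percent:
100 * (s_pert - s_wt) / |s_wt| (population-sd denominator when the
wild-type score is numerically zero).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import ModelStack
from .perturb import KO, OE, WT, PerturbationSet
from .steadystate import GenomeState, SteadySolver

MODES = (KO, OE)


def _as_weights(spec_part) -> Dict[str, float]:
    """Coerce a list of ids (balanced weights) or an id->weight mapping."""
    if not spec_part:
        return {}
    if isinstance(spec_part, Mapping):
        out = {str(k): float(v) for k, v in spec_part.items()}
    else:
        ids = list(spec_part)
        out = {str(k): 1.0 / len(ids) for k in ids}
    for k, w in out.items():
        if w <= 0:
            raise ValueError(f"objective weight for {k!r} must be positive")
    return out


@dataclass
class ObjectiveSpec:
    """Signed weighted combination of metabolites and/or traits.

    mode ``"maximize"`` scores the raw combination, ``"minimize"`` its
    negative, ``"target"`` the negative absolute deviation from
    `target_value`.  A `secondary` spec turns this into a bi-objective:
    alpha * z(primary) + (1 - alpha) * z(secondary), z-scored against the
    wild-type population across lines.
    """

    maximize: Mapping[str, float] | Sequence[str] = ()
    minimize: Mapping[str, float] | Sequence[str] = ()
    mode: str = "maximize"
    target_value: Optional[float] = None
    secondary: Optional["ObjectiveSpec"] = None
    alpha: float = 0.5
    name: str = "objective"

    def __post_init__(self) -> None:
        self.maximize = _as_weights(self.maximize)
        self.minimize = _as_weights(self.minimize)
        overlap = set(self.maximize) & set(self.minimize)
        if overlap:
            raise ValueError(f"ids in both maximize and minimize sets: {sorted(overlap)}")
        if self.mode not in ("maximize", "minimize", "target"):
            raise ValueError(f"unknown objective mode {self.mode!r}")
        if self.mode == "target" and self.target_value is None:
            raise ValueError("target mode needs a target_value")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not self.maximize and not self.minimize:
            raise ValueError("objective references no metabolite or trait")

    def ids(self) -> List[str]:
        out = list(self.maximize) + list(self.minimize)
        if self.secondary is not None:
            out += self.secondary.ids()
        return out

    def raw(self, values: pd.Series) -> float:
        total = 0.0
        for k, w in self.maximize.items():
            if k not in values.index:
                raise KeyError(f"objective id {k!r} not found in the predicted state")
            total += w * float(values[k])
        for k, w in self.minimize.items():
            if k not in values.index:
                raise KeyError(f"objective id {k!r} not found in the predicted state")
            total -= w * float(values[k])
        return total

    def _scored(self, values: pd.Series) -> float:
        r = self.raw(values)
        if self.mode == "minimize":
            return -r
        if self.mode == "target":
            return -abs(r - self.target_value)
        return r

    # -- vectorized path (used by the scanners) ---------------------------
    def _weight_vector(self, col_pos: Mapping[str, int]) -> np.ndarray:
        w = np.zeros(len(col_pos))
        for k, wt in self.maximize.items():
            if k not in col_pos:
                raise KeyError(f"objective id {k!r} not found in the predicted state")
            w[col_pos[k]] += wt
        for k, wt in self.minimize.items():
            if k not in col_pos:
                raise KeyError(f"objective id {k!r} not found in the predicted state")
            w[col_pos[k]] -= wt
        return w

    def _scored_rows(self, values: np.ndarray, col_pos: Mapping[str, int]) -> np.ndarray:
        r = values @ self._weight_vector(col_pos)
        if self.mode == "minimize":
            return -r
        if self.mode == "target":
            return -np.abs(r - self.target_value)
        return r

    def score_rows(self, values: np.ndarray, col_pos: Mapping[str, int],
                   wt_stats: Optional[dict] = None) -> np.ndarray:
        """Scores for an (L x features) value matrix; same semantics as
        :func:`evaluate_objective` row by row."""
        primary = self._scored_rows(values, col_pos)
        if self.secondary is None:
            return primary
        if wt_stats is None:
            raise ValueError("bi-objective scoring needs wild-type population stats")
        mu1, sd1 = wt_stats["primary"]
        mu2, sd2 = wt_stats["secondary"]
        z1 = (primary - mu1) / sd1
        z2 = (self.secondary._scored_rows(values, col_pos) - mu2) / sd2
        return self.alpha * z1 + (1.0 - self.alpha) * z2


def calibrate_objective(spec: ObjectiveSpec, wt_values: pd.DataFrame) -> Optional[dict]:
    """Wild-type population statistics for bi-objective z-scoring.

    `wt_values` has one row per line (metabolites + traits concatenated).
    Returns None for plain single objectives.
    """
    if spec.secondary is None:
        return None

    def stats(sub: ObjectiveSpec):
        scores = np.array([sub._scored(row) for _, row in wt_values.iterrows()])
        sd = float(scores.std(ddof=0))
        return float(scores.mean()), sd if sd > 0 else 1.0

    return {"primary": stats(ObjectiveSpec(spec.maximize, spec.minimize, spec.mode,
                                           spec.target_value, name=spec.name)),
            "secondary": stats(spec.secondary)}


def evaluate_objective(
    spec: ObjectiveSpec, state: GenomeState | pd.Series, wt_stats: Optional[dict] = None
) -> float:
    """Score one predicted state under the objective."""
    values = state.values() if isinstance(state, GenomeState) else state
    primary = spec._scored(values)
    if spec.secondary is None:
        return primary
    if wt_stats is None:
        raise ValueError("bi-objective scoring needs wild-type population stats "
                         "(see calibrate_objective)")
    mu1, sd1 = wt_stats["primary"]
    mu2, sd2 = wt_stats["secondary"]
    z1 = (primary - mu1) / sd1
    z2 = (spec.secondary._scored(values) - mu2) / sd2
    return spec.alpha * z1 + (1.0 - spec.alpha) * z2


def efficiency(score_pert: float, score_wt: float,
               fallback_sd: Optional[float] = None) -> float:
    """Percent improvement of a perturbed score over the wild-type score.

    100 * (s_pert - s_wt) / |s_wt|; when |s_wt| < 1e-9 the wild-type
    population sd is used as the denominator (flagged by a warning).
    """
    if not np.isfinite(score_pert) and not np.isfinite(score_wt):
        raise ValueError("both scores are non-finite")
    denom = abs(score_wt)
    if denom < 1e-9:
        if fallback_sd is None or fallback_sd <= 0:
            raise ValueError(
                "wild-type score is ~0 and no population sd fallback was given"
            )
        warnings.warn("wild-type score ~0; using population sd as efficiency denominator")
        denom = fallback_sd
    return 100.0 * (score_pert - score_wt) / denom


@dataclass
class ScanRecord:
    """Objective and efficiency of one perturbation across the line set."""

    perturbation: PerturbationSet
    scores: pd.Series          # per line
    efficiency: pd.Series      # per line, percent
    flags: List[str] = field(default_factory=list)

    @property
    def mean_score(self) -> float:
        return float(self.scores.mean())

    @property
    def mean_efficiency(self) -> float:
        return float(self.efficiency.mean())

    @property
    def max_score(self) -> float:
        return float(self.scores.max())

    @property
    def label(self) -> str:
        return self.perturbation.label()


class _ScanContext:
    """Shared wild-type states/scores for one (stack, spec, lines) scan.

    Per-record work is fully vectorized across lines: the solver batches
    the low-rank clamp update over every baseline, and the objective is a
    weight-vector product over the predicted metabolite/trait matrix.
    """

    def __init__(self, stack: ModelStack, spec: ObjectiveSpec,
                 lines: Optional[Sequence[str]] = None, delta: Optional[float] = None):
        self.solver = SteadySolver(stack, delta=delta)
        self.spec = spec
        self.lines = list(lines) if lines is not None else list(stack.baseline_lines)
        if not self.lines:
            raise ValueError("no baseline lines available for scanning")
        # layer matrices for vectorized downstream prediction
        self._Vm = stack.metabolites.coef.to_numpy()
        self._bm = stack.metabolites.intercept.to_numpy() + stack.metabolites.calibration
        cols = list(stack.metabolite_names)
        if stack.traits is not None:
            self._U = stack.traits.coef.to_numpy()
            self._bt = stack.traits.intercept.to_numpy() + stack.traits.calibration
            cols += list(stack.trait_names)
        else:
            self._U = None
        self.col_pos = {c: i for i, c in enumerate(cols)}
        self.wt_values = pd.DataFrame(
            self._values(self.solver.solve_lines(None, self.lines)),
            index=self.lines, columns=cols,
        )
        self.wt_stats = calibrate_objective(spec, self.wt_values)
        wt = spec.score_rows(self.wt_values.to_numpy(), self.col_pos, self.wt_stats)
        self.wt_scores = pd.Series(wt, index=self.lines)
        sd = float(self.wt_scores.std(ddof=0))
        self.wt_sd = sd if sd > 0 else 1.0
        self._eff_denom = np.abs(self.wt_scores.to_numpy())
        self._eff_small = self._eff_denom < 1e-9
        self._eff_denom = np.where(self._eff_small, self.wt_sd, self._eff_denom)

    def _values(self, G: np.ndarray) -> np.ndarray:
        M = G @ self._Vm.T + self._bm
        if self._U is None:
            return M
        T = M @ self._U.T + self._bt
        return np.hstack([M, T])

    def mean_score(self, perts: PerturbationSet) -> float:
        G = self.solver.solve_lines(perts, self.lines)
        s = self.spec.score_rows(self._values(G), self.col_pos, self.wt_stats)
        return float(np.mean(s))

    def record(self, perts: PerturbationSet) -> ScanRecord:
        flags: List[str] = []
        try:
            G = self.solver.solve_lines(perts, self.lines)
            s = self.spec.score_rows(self._values(G), self.col_pos, self.wt_stats)
        except Exception as exc:  # non-convergence: flagged, not dropped
            flags.append(str(exc))
            nan = pd.Series(np.nan, index=self.lines)
            return ScanRecord(perts, nan, nan.copy(), flags)
        if not perts:
            eff = np.zeros(len(self.lines))
        else:
            eff = 100.0 * (s - self.wt_scores.to_numpy()) / self._eff_denom
        return ScanRecord(
            perts, pd.Series(s, index=self.lines),
            pd.Series(eff, index=self.lines), flags,
        )


def scan_single(
    stack: ModelStack,
    spec: ObjectiveSpec,
    lines: Optional[Sequence[str]] = None,
    delta: Optional[float] = None,
) -> List[ScanRecord]:
    """All single-gene KO/OE perturbations, plus the wild-type record.

    Deterministic order: wild-type first, then (gene id, KO then OE).
    """
    ctx = _ScanContext(stack, spec, lines, delta)
    records = [ctx.record(PerturbationSet({}))]
    for gene in sorted(stack.gene_names):
        for mode in MODES:
            records.append(ctx.record(PerturbationSet({gene: mode})))
    return records


def scan_pairs(
    stack: ModelStack,
    spec: ObjectiveSpec,
    lines: Optional[Sequence[str]] = None,
    budget: Optional[int] = None,
    seed: int = 0,
    include_degenerate: bool = False,
    delta: Optional[float] = None,
) -> List[ScanRecord]:
    """Two-gene perturbations: each unordered pair in 4 mode combinations.

    Exhaustive when no `budget` is given; otherwise a seeded random sample
    of `budget` combinations.  ``include_degenerate=True`` appends the
    (gene, wild-type) rows, i.e. the single-perturbation records, so the
    pair landscape provably contains the single one.
    """
    if budget is not None and budget < 1:
        raise ValueError("budget must be >= 1")
    ctx = _ScanContext(stack, spec, lines, delta)
    genes = sorted(stack.gene_names)
    combos: List[Tuple[Tuple[str, str], ...]] = []
    for ga, gb in itertools.combinations(genes, 2):
        for ma, mb in itertools.product(MODES, MODES):
            combos.append(((ga, ma), (gb, mb)))
    if budget is not None and budget < len(combos):
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(combos), size=budget, replace=False)
        combos = [combos[i] for i in sorted(picked)]
    records = [ctx.record(PerturbationSet({}))]
    if include_degenerate:
        for gene in genes:
            for mode in MODES:
                records.append(ctx.record(PerturbationSet({gene: mode})))
    for combo in combos:
        records.append(ctx.record(PerturbationSet(dict(combo))))
    return records


def greedy_multi(
    stack: ModelStack,
    spec: ObjectiveSpec,
    lines: Optional[Sequence[str]] = None,
    max_rounds: int = 10,
    delta: Optional[float] = None,
    min_gain: float = 1e-9,
) -> Tuple[PerturbationSet, pd.DataFrame]:
    """Greedy multi-gene redesign maximizing the mean objective across lines.

    Each round tentatively re-assigns every gene to KO/OE/WT given the
    current assignment and commits the single best change; stops when no
    change improves the mean score by more than `min_gain`.  Ties break by
    gene id order.  Returns the final assignment and the trajectory
    (round, gene, mode, mean score).
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    ctx = _ScanContext(stack, spec, lines, delta)
    current = PerturbationSet({})
    current_score = ctx.mean_score(current)
    traj = [{"round": 0, "gene": None, "mode": WT, "mean_score": current_score}]
    genes = sorted(stack.gene_names)
    for rnd in range(1, max_rounds + 1):
        best = None  # (score, gene, mode, pert)
        for gene in genes:
            cur_mode = current.assignments.get(gene, WT)
            for mode in (KO, OE, WT):
                if mode == cur_mode:
                    continue
                cand = current.with_gene(gene, mode)
                s = ctx.mean_score(cand)
                if best is None or s > best[0] + 1e-15:
                    best = (s, gene, mode, cand)
        if best is None or best[0] <= current_score + min_gain:
            break
        current_score, gene, mode, current = best[0], best[1], best[2], best[3]
        traj.append({"round": rnd, "gene": gene, "mode": mode, "mean_score": current_score})
    return current, pd.DataFrame(traj)


def rank_perturbations(
    records: Sequence[ScanRecord], criterion: str = "mean_efficiency"
) -> pd.DataFrame:
    """Ranked table of perturbations (stable sort, descending).

    Criteria: ``"mean_efficiency"`` (mean percent efficiency across lines)
    or ``"mean_max_property"`` (the maximum objective value the perturbation
    reaches across lines).  Columns mirror a top-k report: perturbation,
    criterion value, best line and the efficiency achieved in that line.
    """
    if criterion not in ("mean_efficiency", "mean_max_property"):
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    if not records:
        return pd.DataFrame(
            columns=["perturbation", "genes", "modes", "mean_efficiency",
                     "max_score", "best_line", "best_line_efficiency", "criterion_value"]
        )
    rows = []
    for rec in records:
        key = rec.mean_efficiency if criterion == "mean_efficiency" else rec.max_score
        if rec.scores.notna().any():
            best_line = rec.scores.idxmax()
            best_eff = float(rec.efficiency[best_line])
        else:  # fully flagged record (solve failures): ranked last
            best_line = None
            best_eff = float("nan")
        rows.append({
            "perturbation": rec.label,
            "genes": ";".join(rec.perturbation.genes()),
            "modes": ";".join(m for _, m in sorted(rec.perturbation.items())),
            "mean_efficiency": rec.mean_efficiency,
            "max_score": rec.max_score,
            "best_line": best_line,
            "best_line_efficiency": best_eff,
            "criterion_value": float(key),
        })
    table = pd.DataFrame(rows)
    return table.sort_values(
        "criterion_value", ascending=False, kind="stable", na_position="last"
    ).reset_index(drop=True)


def landscape_stats(
    records: Sequence[ScanRecord], efficiency_thresholds: Sequence[float]
) -> pd.DataFrame:
    """Per-threshold landscape summary.

    For each threshold: the mean +/- sd across lines of the number of
    perturbations whose per-line efficiency exceeds it, and the mean +/- sd
    across perturbations of the fraction of lines in which each exceeds it
    (the probability of selecting that perturbation).
    """
    if not records:
        return pd.DataFrame(columns=["threshold", "count_mean", "count_sd",
                                     "prob_mean", "prob_sd"])
    eff = pd.DataFrame({i: rec.efficiency for i, rec in enumerate(records)})
    # eff: lines x perturbations
    rows = []
    for thr in efficiency_thresholds:
        exceed = eff > thr
        counts = exceed.sum(axis=1)
        probs = exceed.mean(axis=0)
        rows.append({
            "threshold": float(thr),
            "count_mean": float(counts.mean()),
            "count_sd": float(counts.std(ddof=0)),
            "prob_mean": float(probs.mean()),
            "prob_sd": float(probs.std(ddof=0)),
        })
    return pd.DataFrame(rows)


def objective_from_dict(d: Mapping) -> ObjectiveSpec:
    """Build an ObjectiveSpec from a JSON/YAML-style mapping."""
    secondary = d.get("secondary")
    return ObjectiveSpec(
        maximize=d.get("maximize", ()),
        minimize=d.get("minimize", ()),
        mode=d.get("mode", "maximize"),
        target_value=d.get("target_value"),
        secondary=objective_from_dict(secondary) if secondary else None,
        alpha=float(d.get("alpha", 0.5)),
        name=d.get("name", "objective"),
    )
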