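"""Bounded steady-state prediction under gene clamps.

A perturbed genome fixes each targeted gene at the minimum (knockout) or
maximum (over-expression) of its observed expression range, optionally
shrunk by a fraction delta about the midpoint, and solves the remaining
genes from g = W g + b (+ per-line calibration) subject to every free gene
staying inside its own (shrunk) range.  The solver takes a direct linear
solve of the free block first (a low-rank update of the unclamped solution)
and falls back to a projected damped fixed-point iteration when any bound
is active; whenever no bound binds, the two agree.

Metabolites and traits follow linearly from the solved expression state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import LayerModel, ModelStack
from .perturb import KO, OE, PerturbationSet


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"steady-state iteration did not converge "
            f"(residual {residual:.3e} after {iterations} sweeps)"
        )
        self.residual = residual
        self.iterations = iterations


def shrunk_ranges(model: LayerModel, delta: Optional[float] = None) -> pd.DataFrame:
    """Gene ranges contracted symmetrically by fraction delta of their span."""
    if model.gene_ranges is None:
        raise ValueError("layer model has no recorded gene ranges")
    d = model.delta if delta is None else delta
    lo = model.gene_ranges["min"].to_numpy(dtype=float)
    hi = model.gene_ranges["max"].to_numpy(dtype=float)
    span = hi - lo
    out = pd.DataFrame(
        {"min": lo + d * span / 2.0, "max": hi - d * span / 2.0},
        index=model.gene_ranges.index,
    )
    return out


def clamp_value(model: LayerModel, gene: str, mode: str, delta: Optional[float] = None) -> float:
    """Clamped expression value: range minimum for KO, maximum for OE."""
    if model.gene_ranges is None or gene not in model.gene_ranges.index:
        raise KeyError(f"no recorded expression range for gene {gene!r}")
    r = shrunk_ranges(model, delta).loc[gene]
    if mode == KO:
        return float(r["min"])
    if mode == OE:
        return float(r["max"])
    raise ValueError(f"unknown clamp mode {mode!r}")


@dataclass
class GenomeState:
    """Predicted expression/metabolome/traits of one (perturbed) genome."""

    expression: pd.Series
    metabolites: pd.Series
    traits: Optional[pd.Series]
    perturbation: PerturbationSet
    baseline_line: Optional[str] = None
    iterations: int = 0
    residual: float = 0.0
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def values(self) -> pd.Series:
        """Metabolites and traits in one Series (objective lookups)."""
        parts = [self.metabolites]
        if self.traits is not None:
            parts.append(self.traits)
        return pd.concat(parts)


class SteadySolver:
    """Caches factorizations/baseline residuals for repeated perturbed solves."""

    def __init__(self, stack: ModelStack, delta: Optional[float] = None,
                 damping: float = 0.5, tol: float = 1e-10, max_iter: int = 10000):
        self.stack = stack
        g = stack.genes
        self.genes = list(g.coef.index)
        self.idx = {name: i for i, name in enumerate(self.genes)}
        self.W = g.coef.to_numpy(dtype=float)
        self.b = g.intercept.to_numpy(dtype=float) + g.calibration
        n = len(self.genes)
        self.A = np.eye(n) - self.W
        try:
            self.Ainv = np.linalg.inv(self.A)
        except np.linalg.LinAlgError:
            self.Ainv = None
        ranges = shrunk_ranges(g, delta)
        self.lo = ranges["min"].to_numpy(dtype=float)
        self.hi = ranges["max"].to_numpy(dtype=float)
        self.damping = damping
        self.tol = tol
        self.max_iter = max_iter
        self._resid_cache: dict = {}
        self._g0_cache: dict = {}
        self._delta = delta

    # -- baselines ---------------------------------------------------------
    def line_residual(self, line: Optional[str]) -> np.ndarray:
        """Per-line calibration input e = g_obs - (W g_obs + b)."""
        if line is None:
            return np.zeros(len(self.genes))
        if line not in self._resid_cache:
            if self.stack.expression is None or line not in self.stack.expression.index:
                raise KeyError(f"unknown baseline line {line!r}")
            g = self.stack.expression.loc[line].reindex(self.genes).to_numpy(dtype=float)
            self._resid_cache[line] = g - (self.W @ g + self.b)
        return self._resid_cache[line]

    def _g0(self, line: Optional[str]) -> np.ndarray:
        """Unclamped solution (I - W) g = b + e for the line's input."""
        key = line
        if key not in self._g0_cache:
            rhs = self.b + self.line_residual(line)
            if self.Ainv is not None:
                self._g0_cache[key] = self.Ainv @ rhs
            else:
                self._g0_cache[key] = self._iterate(
                    np.zeros(len(self.genes)), np.empty(0, dtype=int),
                    np.empty(0), rhs - self.b, project=False,
                )[0]
        return self._g0_cache[key]

    # -- core solves -------------------------------------------------------
    def _clamp_arrays(self, perts: PerturbationSet):
        perts.validate_against(self.genes)
        cidx = np.array([self.idx[g] for g in perts.genes()], dtype=int)
        cvals = np.array(
            [self.lo[self.idx[g]] if m == KO else self.hi[self.idx[g]]
             for g, m in perts.items()]
        )
        return cidx, cvals

    def _iterate(self, g, cidx, cvals, e, project=True):
        lam = self.damping
        free = np.setdiff1d(np.arange(len(g)), cidx)
        g = g.copy()
        if len(cidx):
            g[cidx] = cvals
        resid = np.inf
        for it in range(1, self.max_iter + 1):
            upd = self.W @ g + self.b + e
            new = (1 - lam) * g + lam * upd
            if project:
                new[free] = np.clip(new[free], self.lo[free], self.hi[free])
            if len(cidx):
                new[cidx] = cvals
            change = float(np.max(np.abs(new - g))) if len(g) else 0.0
            g = new
            if change < self.tol:
                resid = change
                return g, it, resid, True
        resid = float(np.max(np.abs((self.W @ g + self.b + e) - g))) if len(g) else 0.0
        return g, self.max_iter, resid, False

    def solve_expression(
        self,
        perts: PerturbationSet | dict | None = None,
        baseline_line: Optional[str] = None,
        method: str = "auto",
    ) -> pd.Series:
        g, *_ = self._solve_raw(perts, baseline_line, method)
        return pd.Series(g, index=self.genes)

    def _active_set(self, cidx, cvals, e, g0, max_passes=100):
        """Solve the bounded steady state by active-set pivoting.

        Finds the fixed point of g = clip(W g + b + e) with clamped genes
        held: free interior genes satisfy their linear equation, genes at a
        bound satisfy the complementarity sign condition.  Equivalent to the
        projected damped iteration's fixed point but solved by direct
        low-rank algebra, so it does not require the gene matrix to be a
        contraction.  Returns None if the active set fails to settle.
        """
        n = len(self.genes)
        tol = 1e-9
        state = np.zeros(n, dtype=np.int8)  # -1 at lo, +1 at hi, 0 free
        clamped = np.zeros(n, dtype=bool)
        clamped[cidx] = True
        for _ in range(max_passes):
            at_lo = np.flatnonzero((state == -1) & ~clamped)
            at_hi = np.flatnonzero((state == 1) & ~clamped)
            fix_idx = np.concatenate([cidx, at_lo, at_hi]).astype(int)
            fix_vals = np.concatenate([cvals, self.lo[at_lo], self.hi[at_hi]])
            if len(fix_idx):
                H = self.Ainv[:, fix_idx]
                Mc = H[fix_idx, :]
                try:
                    mu = np.linalg.solve(Mc, fix_vals - g0[fix_idx])
                except np.linalg.LinAlgError:
                    return None
                g = g0 + H @ mu
                g[fix_idx] = fix_vals
            else:
                g = g0.copy()
            free = (state == 0) & ~clamped
            viol_lo = free & (g < self.lo - tol)
            viol_hi = free & (g > self.hi + tol)
            if viol_lo.any() or viol_hi.any():
                state[viol_lo] = -1
                state[viol_hi] = 1
                continue
            # KKT release: a bound-active gene whose equation pulls inward
            r = self.W @ g + self.b + e - g
            rel_lo = (state == -1) & ~clamped & (r > tol)
            rel_hi = (state == 1) & ~clamped & (r < -tol)
            if rel_lo.any() or rel_hi.any():
                state[rel_lo] = 0
                state[rel_hi] = 0
                continue
            np.clip(g, self.lo, self.hi, out=g)
            if len(cidx):
                g[cidx] = cvals
            return g
        return None

    def _solve_raw(self, perts, baseline_line, method="auto"):
        perts = PerturbationSet.coerce(perts or {})
        cidx, cvals = self._clamp_arrays(perts)
        e = self.line_residual(baseline_line)

        if method == "one_pass":
            base = (
                self.stack.expression.loc[baseline_line]
                .reindex(self.genes).to_numpy(dtype=float)
                if baseline_line is not None else self._g0(None)
            ).copy()
            if len(cidx):
                base[cidx] = cvals
            g = self.W @ base + self.b + e
            free = np.setdiff1d(np.arange(len(g)), cidx)
            g[free] = np.clip(g[free], self.lo[free], self.hi[free])
            if len(cidx):
                g[cidx] = cvals
            return g, 1, 0.0, True

        direct = None
        if method in ("auto", "direct") and self.Ainv is not None:
            g0 = self._g0(baseline_line)
            if len(cidx) == 0:
                direct = g0.copy()
            else:
                H = self.Ainv[:, cidx]
                Mc = H[cidx, :]
                try:
                    mu = np.linalg.solve(Mc, cvals - g0[cidx])
                    direct = g0 + H @ mu
                    direct[cidx] = cvals
                except np.linalg.LinAlgError:
                    direct = None
        if direct is not None:
            free = np.setdiff1d(np.arange(len(direct)), cidx)
            tol = 1e-9
            in_bounds = np.all(
                (direct[free] >= self.lo[free] - tol)
                & (direct[free] <= self.hi[free] + tol)
            )
            if in_bounds or method == "direct":
                direct[free] = np.clip(direct[free], self.lo[free], self.hi[free])
                return direct, 0, 0.0, True
            # bounds are active: pivot on the active set (direct algebra)
            g = self._active_set(cidx, cvals, e, self._g0(baseline_line))
            if g is not None:
                return g, 0, 0.0, True
            start = direct
        else:
            start = self._g0(baseline_line) if self.Ainv is not None else np.zeros(len(self.genes))

        g, it, resid, ok = self._iterate(np.clip(start, self.lo, self.hi), cidx, cvals, e)
        if not ok:
            raise ConvergenceError(resid, it)
        return g, it, resid, ok

    def solve_lines(
        self,
        perts: PerturbationSet | dict | None = None,
        lines: Optional[list] = None,
        method: str = "auto",
    ) -> np.ndarray:
        """Vectorized solve of one perturbation across many baseline lines.

        Returns an (L x n) array of expression states.  The low-rank update
        of each line's unclamped solution is batched; lines whose direct
        solution violates a bound fall back to the projected iteration
        individually.
        """
        perts = PerturbationSet.coerce(perts or {})
        lines = list(lines) if lines is not None else list(self.stack.baseline_lines)
        cidx, cvals = self._clamp_arrays(perts)
        n = len(self.genes)
        G0 = np.column_stack([self._g0(ln) for ln in lines])  # n x L
        if self.Ainv is None or method == "iterate":
            out = [self._solve_raw(perts, ln, "auto")[0] for ln in lines]
            return np.asarray(out)
        if len(cidx) == 0:
            G = G0.copy()
        else:
            H = self.Ainv[:, cidx]
            Mc = H[cidx, :]
            try:
                mu = np.linalg.solve(Mc, cvals[:, None] - G0[cidx, :])
                G = G0 + H @ mu
                G[cidx, :] = cvals[:, None]
            except np.linalg.LinAlgError:
                out = [self._solve_raw(perts, ln, "auto")[0] for ln in lines]
                return np.asarray(out)
        free = np.setdiff1d(np.arange(n), cidx)
        tol = 1e-9
        ok = np.all(
            (G[free, :] >= self.lo[free, None] - tol)
            & (G[free, :] <= self.hi[free, None] + tol),
            axis=0,
        )
        G[free, :] = np.clip(G[free, :], self.lo[free, None], self.hi[free, None])
        for j, fine in enumerate(ok):
            if not fine:
                e = self.line_residual(lines[j])
                g = self._active_set(cidx, cvals, e, self._g0(lines[j]))
                if g is None:
                    g, _, _, conv = self._iterate(G[:, j], cidx, cvals, e)
                    if not conv:
                        raise ConvergenceError(float("nan"), self.max_iter)
                G[:, j] = g
        return G.T

    def predict_state(
        self,
        perts: PerturbationSet | dict | None = None,
        baseline_line: Optional[str] = None,
        method: str = "auto",
    ) -> GenomeState:
        perts = PerturbationSet.coerce(perts or {})
        g, it, resid, ok = self._solve_raw(perts, baseline_line, method)
        expr = pd.Series(g, index=self.genes)
        mets = predict_metabolome(self.stack, expr)
        traits = predict_traits(self.stack, mets) if self.stack.traits is not None else None
        return GenomeState(
            expression=expr, metabolites=mets, traits=traits,
            perturbation=perts, baseline_line=baseline_line,
            iterations=it, residual=resid, converged=ok,
        )


def solve_expression(
    stack: ModelStack,
    perts=None,
    baseline_line: Optional[str] = None,
    delta: Optional[float] = None,
    method: str = "auto",
    **solver_kwargs,
) -> pd.Series:
    """One-shot wrapper around :class:`SteadySolver` (see class docs)."""
    return SteadySolver(stack, delta=delta, **solver_kwargs).solve_expression(
        perts, baseline_line, method=method
    )


def predict_metabolome(stack: ModelStack, expression: pd.Series) -> pd.Series:
    """m = V g + intercept + calibration."""
    return stack.metabolites.predict_vector(expression)


def predict_traits(stack: ModelStack, metabolome: pd.Series) -> pd.Series:
    """a = U m + intercept + calibration."""
    if stack.traits is None:
        raise ValueError("stack has no trait layer")
    return stack.traits.predict_vector(metabolome)


def predict_state(
    stack: ModelStack,
    perts=None,
    baseline_line: Optional[str] = None,
    delta: Optional[float] = None,
    method: str = "auto",
) -> GenomeState:
    """Solve expression under the perturbation and propagate to traits."""
    return SteadySolver(stack, delta=delta).predict_state(perts, baseline_line, method)
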