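"""Synthetic RIL-like omics panels with planted three-layer ground truth.

The generator plants a sparse stable gene->gene matrix W, gene->metabolite
matrix V and metabolite->trait matrix U, then simulates a panel of
recombinant-inbred-line-like samples: each line draws an independent
exogenous input per gene, the gene steady state solves g = W g + b + e,
metabolites and traits follow linearly with additive Gaussian layer noise,
and expression/metabolites are emitted as replicated measurements for a
nested subset of lines (emulating a panel where only some lines were
arrayed).

Defaults put the panel in the detectable desk-scale regime used throughout
the test-suite: 300 genes, 30 metabolites, 5 traits, 60 expression lines
nested in 160, mean in-degree 5, layer noise sd 0.3, triplicate samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import OmicsPanel
from .perturb import KO, OE, PerturbationSet

_LAYER_KEYS = ("expression", "metabolites", "traits")


@dataclass(frozen=True)
class PanelConfig:
    """Shape and noise regime of a simulated panel.

    ``noise_sd["expression"]`` is the sd of the exogenous per-line input to
    each gene (the source of cross-line variance; standard normal by
    default); the metabolite/trait entries are additive layer noise in
    z-score units.  Replicate measurement noise is 1/3 of the corresponding
    line-level sd.
    """

    n_lines_full: int = 160
    n_lines_expr: int = 60
    n_genes: int = 300
    n_metabolites: int = 30
    n_traits: int = 5
    replicates: int = 3
    predictors_per_target: float = 5.0
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"expression": 1.0, "metabolites": 0.3, "traits": 0.3}
    )
    coef_low: float = 0.2
    coef_high: float = 1.0
    spectral_radius: float = 0.8

    def __post_init__(self) -> None:
        counts = dict(
            n_lines_full=self.n_lines_full, n_lines_expr=self.n_lines_expr,
            n_genes=self.n_genes, n_metabolites=self.n_metabolites,
            n_traits=self.n_traits, replicates=self.replicates,
        )
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_lines_expr > self.n_lines_full:
            raise ValueError("n_lines_expr cannot exceed n_lines_full")
        if self.predictors_per_target < 1:
            raise ValueError("predictors_per_target must be >= 1")
        if self.predictors_per_target > self.n_genes - 1:
            raise ValueError(
                f"predictors_per_target={self.predictors_per_target} exceeds the "
                f"{self.n_genes - 1} available gene predictors"
            )
        for key in _LAYER_KEYS:
            if key not in self.noise_sd:
                raise ValueError(f"noise_sd missing layer {key!r}")
            if self.noise_sd[key] < 0:
                raise ValueError("noise sd must be non-negative")
        if not 0 < self.spectral_radius < 1:
            raise ValueError("spectral_radius must lie in (0, 1)")
        if not 0 < self.coef_low <= self.coef_high:
            raise ValueError("need 0 < coef_low <= coef_high")


@dataclass
class GroundTruth:
    """Planted coefficients of the three-layer linear system."""

    W: np.ndarray                 # gene -> gene, spectral radius < 1
    V: np.ndarray                 # gene -> metabolite
    U: np.ndarray                 # metabolite -> trait
    intercepts: Dict[str, np.ndarray]
    noise_sd: Dict[str, float]
    gene_names: Sequence[str]
    metabolite_names: Sequence[str]
    trait_names: Sequence[str]
    seed: int
    gene_ranges: Optional[pd.DataFrame] = None  # filled by simulate_panel

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.W))))

    def edges(self, layer: str) -> set:
        """Planted support as a set of (target, predictor) name pairs."""
        mats = {
            "genes": (self.W, self.gene_names, self.gene_names),
            "metabolites": (self.V, self.metabolite_names, self.gene_names),
            "traits": (self.U, self.trait_names, self.metabolite_names),
        }
        M, rows, cols = mats[layer]
        tt, pp = np.nonzero(M)
        return {(rows[t], cols[p]) for t, p in zip(tt, pp)}

    def support(self, layer: str) -> dict:
        """Planted support as target -> list-of-predictors."""
        out: Dict[str, list] = {}
        rows = {"genes": self.gene_names, "metabolites": self.metabolite_names,
                "traits": self.trait_names}[layer]
        out = {r: [] for r in rows}
        for t, p in sorted(self.edges(layer)):
            out[t].append(p)
        return out


def _draw_coefs(rng: np.random.Generator, k: int, low: float, high: float) -> np.ndarray:
    mag = rng.uniform(low, high, size=k)
    sign = rng.choice([-1.0, 1.0], size=k)
    return mag * sign


def _in_degrees(rng: np.random.Generator, n_targets: int, mean: float, n_pred: int) -> np.ndarray:
    # 1 + Poisson(mean-1): every target keeps >= 1 predictor, mean matches
    deg = 1 + rng.poisson(max(mean - 1.0, 0.0), size=n_targets)
    return np.clip(deg, 1, n_pred)


def generate_ground_truth(config: PanelConfig, seed: int) -> GroundTruth:
    """Plant a sparse stable three-layer system.

    Coefficient magnitudes are drawn uniform on [coef_low, coef_high] with
    random sign (zero-avoiding, so planted edges are detectable); W is then
    rescaled to the configured spectral radius so the steady state is unique.
    """
    rng = np.random.default_rng(seed)
    n, m, t = config.n_genes, config.n_metabolites, config.n_traits

    W = np.zeros((n, n))
    for i, deg in enumerate(_in_degrees(rng, n, config.predictors_per_target, n - 1)):
        others = np.delete(np.arange(n), i)
        pred = rng.choice(others, size=deg, replace=False)
        W[i, pred] = _draw_coefs(rng, deg, config.coef_low, config.coef_high)
    radius = float(np.max(np.abs(np.linalg.eigvals(W)))) if n > 1 else 0.0
    if radius > 0:
        W *= config.spectral_radius / radius

    V = np.zeros((m, n))
    for k, deg in enumerate(_in_degrees(rng, m, config.predictors_per_target, n)):
        pred = rng.choice(n, size=deg, replace=False)
        V[k, pred] = _draw_coefs(rng, deg, config.coef_low, config.coef_high)

    U = np.zeros((t, m))
    deg_cap = min(m, max(1, int(round(config.predictors_per_target))))
    for p, deg in enumerate(_in_degrees(rng, t, deg_cap, m)):
        pred = rng.choice(m, size=deg, replace=False)
        U[p, pred] = _draw_coefs(rng, deg, config.coef_low, config.coef_high)

    intercepts = {
        "expression": rng.uniform(-0.5, 0.5, size=n),
        "metabolites": rng.uniform(-0.5, 0.5, size=m),
        "traits": rng.uniform(-0.5, 0.5, size=t),
    }
    width = len(str(max(n, m, t)))
    return GroundTruth(
        W=W, V=V, U=U, intercepts=intercepts,
        noise_sd=dict(config.noise_sd),
        gene_names=[f"G{i + 1:0{width}d}" for i in range(n)],
        metabolite_names=[f"M{i + 1:0{width}d}" for i in range(m)],
        trait_names=[f"T{i + 1:0{width}d}" for i in range(t)],
        seed=int(seed),
    )


def _check_stable(truth: GroundTruth) -> None:
    radius = truth.spectral_radius()
    if radius >= 1.0:
        raise ValueError(
            f"ground truth (seed={truth.seed}) has spectral radius "
            f"{radius:.4f} >= 1; the steady state does not converge"
        )


def _replicate_rows(line_ids, values, rep_sd, replicates, rng):
    # a single "replicate" is the line-level measurement itself
    if replicates == 1:
        rep_sd = 0.0
    rows, ids = [], []
    for j, line in enumerate(line_ids):
        for r in range(1, replicates + 1):
            noise = rng.normal(0.0, rep_sd, size=values.shape[1]) if rep_sd > 0 else 0.0
            rows.append(values[j] + noise)
            ids.append(f"{line}_r{r}" if replicates > 1 else line)
    return pd.DataFrame(np.asarray(rows), index=ids)


def simulate_panel(truth: GroundTruth, config: PanelConfig, seed: int) -> OmicsPanel:
    """Simulate an omics panel from a planted truth.

    Per line: exogenous input e ~ N(0, noise_sd["expression"]) per gene,
    steady state g = (I - W)^-1 (b + e); m = V g + b + noise; a = U m + b +
    noise.  Expression and metabolites are emitted as `replicates` noisy
    copies per line (replicate sd = line sd / 3); expression is present for
    the first ``n_lines_expr`` lines only.  Observed per-gene (min, max)
    across the expression lines is recorded into ``truth.gene_ranges``.
    """
    _check_stable(truth)
    n, m, t = config.n_genes, config.n_metabolites, config.n_traits
    if truth.W.shape != (n, n) or truth.V.shape != (m, n) or truth.U.shape != (t, m):
        raise ValueError("ground truth dimensions do not match config")

    rng = np.random.default_rng(seed)
    L = config.n_lines_full
    lines = [f"L{i + 1:03d}" for i in range(L)]
    expr_lines = lines[: config.n_lines_expr]

    E = rng.normal(0.0, config.noise_sd["expression"], size=(L, n))
    A = np.eye(n) - truth.W
    G = np.linalg.solve(A, (truth.intercepts["expression"][:, None] + E.T)).T
    M = G @ truth.V.T + truth.intercepts["metabolites"]
    if config.noise_sd["metabolites"] > 0:
        M = M + rng.normal(0.0, config.noise_sd["metabolites"], size=(L, m))
    Tr = M @ truth.U.T + truth.intercepts["traits"]
    if config.noise_sd["traits"] > 0:
        Tr = Tr + rng.normal(0.0, config.noise_sd["traits"], size=(L, t))

    expr_rep_sd = config.noise_sd["expression"] / 3.0
    met_rep_sd = config.noise_sd["metabolites"] / 3.0
    expression = _replicate_rows(
        expr_lines, G[: config.n_lines_expr], expr_rep_sd, config.replicates, rng
    )
    expression.columns = truth.gene_names
    metabolites = _replicate_rows(lines, M, met_rep_sd, config.replicates, rng)
    metabolites.columns = truth.metabolite_names
    traits = pd.DataFrame(Tr, index=lines, columns=truth.trait_names)

    from .panel import average_replicates

    line_expr = average_replicates(expression)
    truth.gene_ranges = pd.DataFrame(
        {"min": line_expr.min(), "max": line_expr.max()}
    )

    latent = {
        "expression": pd.DataFrame(G, index=lines, columns=truth.gene_names),
        "metabolites": pd.DataFrame(M, index=lines, columns=truth.metabolite_names),
        "traits": pd.DataFrame(Tr, index=lines, columns=truth.trait_names),
    }
    return OmicsPanel(
        expression=expression, metabolites=metabolites, traits=traits,
        latent=latent,
        report={"seed": int(seed), "config": "simulate_panel"},
    )


def make_engineered_lines(
    truth: GroundTruth,
    perts,
    seed: int,
    config: Optional[PanelConfig] = None,
    n_lines_per_pert: int = 1,
) -> OmicsPanel:
    """Simulate engineered lines with genes clamped in the true system.

    For each perturbation set, the listed genes are clamped at their range
    minimum (knockout) or maximum (over-expression) and the free genes solve
    the planted steady state; the result models introgression-line-style
    material for overlap-enrichment tests.  Requires ``truth.gene_ranges``
    (record them by simulating a wild-type panel first).
    """
    _check_stable(truth)
    if truth.gene_ranges is None:
        raise ValueError("truth.gene_ranges is unset; simulate a panel first")
    config = config or PanelConfig()
    rng = np.random.default_rng(seed)
    n = truth.W.shape[0]
    name_to_idx = {g: i for i, g in enumerate(truth.gene_names)}

    G_rows, M_rows, T_rows, ids, pert_labels = [], [], [], [], []
    for p_idx, pert in enumerate(perts):
        pert = PerturbationSet.coerce(pert)
        pert.validate_against(truth.gene_names)
        clamped = np.array([name_to_idx[g] for g in pert.genes()], dtype=int)
        clamp_vals = np.array(
            [
                truth.gene_ranges.loc[g, "min" if mode == KO else "max"]
                for g, mode in pert.items()
            ]
        )
        free = np.setdiff1d(np.arange(n), clamped)
        A_ff = np.eye(len(free)) - truth.W[np.ix_(free, free)]
        for j in range(n_lines_per_pert):
            e = rng.normal(0.0, config.noise_sd["expression"], size=n)
            g = np.empty(n)
            g[clamped] = clamp_vals
            rhs = truth.intercepts["expression"][free] + e[free]
            if len(clamped):
                rhs = rhs + truth.W[np.ix_(free, clamped)] @ clamp_vals
            g[free] = np.linalg.solve(A_ff, rhs)
            m = truth.V @ g + truth.intercepts["metabolites"]
            if config.noise_sd["metabolites"] > 0:
                m = m + rng.normal(0.0, config.noise_sd["metabolites"], size=len(m))
            a = truth.U @ m + truth.intercepts["traits"]
            if config.noise_sd["traits"] > 0:
                a = a + rng.normal(0.0, config.noise_sd["traits"], size=len(a))
            G_rows.append(g)
            M_rows.append(m)
            T_rows.append(a)
            ids.append(f"IL{p_idx + 1:02d}_{j + 1:03d}")
            pert_labels.append(pert.label())

    G = np.asarray(G_rows)
    M = np.asarray(M_rows)
    Tr = np.asarray(T_rows)
    expr_rep_sd = config.noise_sd["expression"] / 3.0
    met_rep_sd = config.noise_sd["metabolites"] / 3.0
    expression = _replicate_rows(ids, G, expr_rep_sd, config.replicates, rng)
    expression.columns = truth.gene_names
    # replicate measurement noise must not move a clamped gene off its clamp
    for p_idx, pert in enumerate(perts):
        pert = PerturbationSet.coerce(pert)
        for g_name, mode in pert.items():
            val = truth.gene_ranges.loc[g_name, "min" if mode == KO else "max"]
            for row in expression.index:
                if row.startswith(f"IL{p_idx + 1:02d}_"):
                    expression.at[row, g_name] = val
    metabolites = _replicate_rows(ids, M, met_rep_sd, config.replicates, rng)
    metabolites.columns = truth.metabolite_names
    traits = pd.DataFrame(Tr, index=ids, columns=truth.trait_names)
    latent = {
        "expression": pd.DataFrame(G, index=ids, columns=truth.gene_names),
        "metabolites": pd.DataFrame(M, index=ids, columns=truth.metabolite_names),
        "traits": pd.DataFrame(Tr, index=ids, columns=truth.trait_names),
    }
    panel = OmicsPanel(
        expression=expression, metabolites=metabolites, traits=traits,
        latent=latent,
        report={"seed": int(seed), "perturbations": pert_labels},
    )
    return panel


# ---------------------------------------------------------------------------
# serialization (edge lists + parameters, JSON)

def truth_to_dict(truth: GroundTruth) -> dict:
    def edge_list(M, rows, cols):
        tt, pp = np.nonzero(M)
        return [[rows[t], cols[p], float(M[t, p])] for t, p in zip(tt, pp)]

    d = {
        "gene_names": list(truth.gene_names),
        "metabolite_names": list(truth.metabolite_names),
        "trait_names": list(truth.trait_names),
        "edges": {
            "genes": edge_list(truth.W, truth.gene_names, truth.gene_names),
            "metabolites": edge_list(truth.V, truth.metabolite_names, truth.gene_names),
            "traits": edge_list(truth.U, truth.trait_names, truth.metabolite_names),
        },
        "intercepts": {k: list(map(float, v)) for k, v in truth.intercepts.items()},
        "noise_sd": {k: float(v) for k, v in truth.noise_sd.items()},
        "seed": truth.seed,
    }
    if truth.gene_ranges is not None:
        d["gene_ranges"] = {
            g: [float(r["min"]), float(r["max"])]
            for g, r in truth.gene_ranges.iterrows()
        }
    return d


def truth_from_dict(d: dict) -> GroundTruth:
    gn, mn, tn = d["gene_names"], d["metabolite_names"], d["trait_names"]
    gi = {g: i for i, g in enumerate(gn)}
    mi = {m: i for i, m in enumerate(mn)}
    ti = {t: i for i, t in enumerate(tn)}
    W = np.zeros((len(gn), len(gn)))
    for t, p, c in d["edges"]["genes"]:
        W[gi[t], gi[p]] = c
    V = np.zeros((len(mn), len(gn)))
    for t, p, c in d["edges"]["metabolites"]:
        V[mi[t], gi[p]] = c
    U = np.zeros((len(tn), len(mn)))
    for t, p, c in d["edges"]["traits"]:
        U[ti[t], mi[p]] = c
    ranges = None
    if "gene_ranges" in d:
        ranges = pd.DataFrame(
            {g: {"min": lo, "max": hi} for g, (lo, hi) in d["gene_ranges"].items()}
        ).T.reindex(gn)
    return GroundTruth(
        W=W, V=V, U=U,
        intercepts={k: np.asarray(v, dtype=float) for k, v in d["intercepts"].items()},
        noise_sd=dict(d["noise_sd"]),
        gene_names=gn, metabolite_names=mn, trait_names=tn,
        seed=int(d["seed"]), gene_ranges=ranges,
    )


def save_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_to_dict(truth), fh)


def load_truth(path) -> GroundTruth:
    with open(path) as fh:
        return truth_from_dict(json.load(fh))
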