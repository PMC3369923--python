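"""Shared fixtures: small planted panels and hand-built toy model stacks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fruitnet import synth
from fruitnet.model import LayerModel, ModelStack, stack_from_truth
from fruitnet.preprocess import standardize


@pytest.fixture(scope="session")
def small_config():
    return synth.PanelConfig(
        n_lines_full=40, n_lines_expr=30, n_genes=30, n_metabolites=8,
        n_traits=3, predictors_per_target=3,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return synth.generate_ground_truth(small_config, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config, small_truth):
    return synth.simulate_panel(small_truth, small_config, seed=8)


@pytest.fixture(scope="session")
def small_stack(small_truth, small_panel):
    return stack_from_truth(small_truth, small_panel)


@pytest.fixture(scope="session")
def std_small_panel(small_panel):
    return standardize(small_panel)


@pytest.fixture(scope="session")
def noiseless_panel():
    cfg = synth.PanelConfig(
        n_lines_full=60, n_lines_expr=60, n_genes=20, n_metabolites=6,
        n_traits=2, predictors_per_target=3, replicates=1,
        noise_sd={"expression": 1.0, "metabolites": 0.0, "traits": 0.0},
    )
    truth = synth.generate_ground_truth(cfg, seed=3)
    panel = synth.simulate_panel(truth, cfg, seed=4)
    return cfg, truth, panel


def build_stack(W, V, U=None, intercepts=None, ranges=(-3.0, 3.0),
                baselines=None, delta=0.0):
    """Hand-built model stack from dense arrays (toy fixtures).

    `ranges` is a (lo, hi) pair applied to every gene, or a DataFrame;
    `baselines` an optional lines x genes DataFrame of wild-type states.
    """
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    n = W.shape[0]
    m = V.shape[0]
    genes = [f"g{i}" for i in range(n)]
    mets = [f"m{k}" for k in range(m)]
    ib = intercepts or {}
    if isinstance(ranges, tuple):
        ranges = pd.DataFrame({"min": ranges[0], "max": ranges[1]}, index=genes)
    gene_layer = LayerModel(
        layer="genes",
        coef=pd.DataFrame(W, index=genes, columns=genes),
        intercept=pd.Series(ib.get("genes", np.zeros(n)), index=genes),
        gene_ranges=ranges, delta=delta,
    )
    met_layer = LayerModel(
        layer="metabolites",
        coef=pd.DataFrame(V, index=mets, columns=genes),
        intercept=pd.Series(ib.get("metabolites", np.zeros(m)), index=mets),
    )
    trait_layer = None
    if U is not None:
        U = np.asarray(U, dtype=float)
        traits = [f"t{p}" for p in range(U.shape[0])]
        trait_layer = LayerModel(
            layer="traits",
            coef=pd.DataFrame(U, index=traits, columns=mets),
            intercept=pd.Series(ib.get("traits", np.zeros(U.shape[0])), index=traits),
        )
    if baselines is not None and not isinstance(baselines, pd.DataFrame):
        baselines = pd.DataFrame(
            np.asarray(baselines, dtype=float),
            index=[f"L{i}" for i in range(len(baselines))], columns=genes,
        )
    stack = ModelStack(genes=gene_layer, metabolites=met_layer,
                       traits=trait_layer, expression=baselines)
    if baselines is not None:
        # keep the explicitly requested ranges (post-init derives them
        # from baselines only when absent)
        stack.genes.gene_ranges = ranges
    return stack


def naive_steady_oracle(W, b, e, lo, hi, clamp_idx, clamp_vals,
                        damping=0.5, max_iter=200000, tol=1e-13):
    """Independent brute-force oracle: damped projected fixed-point sweep.

    Run far past the solver's own budget at a tighter tolerance, so
    agreement is meaningful.
    """
    n = len(b)
    g = np.zeros(n)
    free = np.setdiff1d(np.arange(n), clamp_idx)
    if len(clamp_idx):
        g[clamp_idx] = clamp_vals
    for _ in range(max_iter):
        new = (1 - damping) * g + damping * (W @ g + b + e)
        new[free] = np.clip(new[free], lo[free], hi[free])
        if len(clamp_idx):
            new[clamp_idx] = clamp_vals
        if np.max(np.abs(new - g)) < tol:
            return new
        g = new
    return g
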