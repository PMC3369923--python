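"""Sparse linear layer models and the three-layer model stack.

Each layer is a sparse linear map at steady state:

* gene layer       g = W g + b  (+ per-line calibration)
* metabolite layer m = V g + b
* trait layer      a = U m + b

Coefficients are stored dense (targets x predictors DataFrame) with an
explicit support; at the panel sizes this pipeline targets (hundreds of
features) dense storage is simpler and fast enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

GENE_LAYER = "genes"
MET_LAYER = "metabolites"
TRAIT_LAYER = "traits"
LAYERS = (GENE_LAYER, MET_LAYER, TRAIT_LAYER)


@dataclass
class LayerModel:
    """One inferred (or planted) linear layer.

    Attributes
    ----------
    layer
        ``"genes"``, ``"metabolites"`` or ``"traits"``.
    coef
        targets x predictors coefficient matrix (w_ij, v_ki or u_pk); zero
        entries are absent from the support.
    intercept
        Per-target intercept.
    calibration
        Constant per-layer calibration term (the training-mean of the
        per-line perturbation term), added to every prediction.
    gene_ranges
        For the gene layer: per-gene observed (min, max) DataFrame used for
        knockout/over-expression clamps.
    delta
        Symmetric range-shrink fraction applied to gene_ranges.
    meta
        Fit metadata (z*, t_LASSO, training correlations, ...).
    """

    layer: str
    coef: pd.DataFrame
    intercept: pd.Series
    calibration: float = 0.0
    gene_ranges: Optional[pd.DataFrame] = None
    delta: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer tag {self.layer!r}")
        self.intercept = self.intercept.reindex(self.coef.index)
        if self.layer == GENE_LAYER:
            common = self.coef.index.intersection(self.coef.columns)
            diag = np.asarray(
                [self.coef.at[g, g] for g in common], dtype=float
            )
            if len(diag) and np.any(diag != 0.0):
                raise ValueError("gene layer must not contain self-loops")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")

    @property
    def targets(self) -> pd.Index:
        return self.coef.index

    @property
    def predictors(self) -> pd.Index:
        return self.coef.columns

    def support(self, target: str) -> list:
        row = self.coef.loc[target]
        return list(row.index[row.to_numpy() != 0.0])

    def support_dict(self) -> dict:
        return {t: self.support(t) for t in self.targets}

    def n_edges(self) -> int:
        return int((self.coef.to_numpy() != 0.0).sum())

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """One-pass linear prediction for rows of predictor values."""
        Xa = X.reindex(columns=self.predictors)
        vals = Xa.to_numpy() @ self.coef.to_numpy().T
        out = pd.DataFrame(vals, index=X.index, columns=self.targets)
        return out + self.intercept.to_numpy() + self.calibration

    def predict_vector(self, x: pd.Series) -> pd.Series:
        x = x.reindex(self.predictors)
        vals = self.coef.to_numpy() @ x.to_numpy()
        return pd.Series(
            vals + self.intercept.to_numpy() + self.calibration,
            index=self.targets,
        )


@dataclass
class ModelStack:
    """The fitted three-layer model plus its baseline expression data.

    ``expression`` holds the (replicate-averaged, standardized) training
    expression matrix: each row is a wild-type baseline state whose per-line
    residual calibrates perturbed predictions for that line.
    """

    genes: LayerModel
    metabolites: LayerModel
    traits: Optional[LayerModel] = None
    expression: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes
        if not g.coef.index.equals(g.coef.columns):
            # gene layer must be square and aligned for steady-state solving
            g.coef = g.coef.reindex(
                index=g.coef.index, columns=g.coef.index, fill_value=0.0
            )
        if g.gene_ranges is None and self.expression is not None:
            g.gene_ranges = pd.DataFrame(
                {"min": self.expression.min(), "max": self.expression.max()}
            ).reindex(g.coef.index)

    @property
    def gene_names(self) -> pd.Index:
        return self.genes.coef.index

    @property
    def metabolite_names(self) -> pd.Index:
        return self.metabolites.coef.index

    @property
    def trait_names(self) -> pd.Index:
        if self.traits is None:
            return pd.Index([])
        return self.traits.coef.index

    @property
    def baseline_lines(self) -> list:
        return [] if self.expression is None else list(self.expression.index)


def stack_from_truth(truth, panel=None, delta: float = 0.0) -> ModelStack:
    """Build a ModelStack holding a synthetic ground truth's coefficients.

    The planted coefficient matrices become the layers verbatim; baseline
    expression (and hence gene ranges) come from `panel`'s latent line-level
    expression when supplied, else from ``truth.gene_ranges``.
    """
    # ranges are derived from the baseline expression matrix below when a
    # panel is given, so baseline lines always lie inside their own ranges
    genes = LayerModel(
        layer=GENE_LAYER,
        coef=pd.DataFrame(truth.W, index=truth.gene_names, columns=truth.gene_names),
        intercept=pd.Series(truth.intercepts["expression"], index=truth.gene_names),
        gene_ranges=None if panel is not None else (
            truth.gene_ranges.copy() if truth.gene_ranges is not None else None
        ),
        delta=delta,
    )
    mets = LayerModel(
        layer=MET_LAYER,
        coef=pd.DataFrame(truth.V, index=truth.metabolite_names, columns=truth.gene_names),
        intercept=pd.Series(truth.intercepts["metabolites"], index=truth.metabolite_names),
    )
    traits = LayerModel(
        layer=TRAIT_LAYER,
        coef=pd.DataFrame(truth.U, index=truth.trait_names, columns=truth.metabolite_names),
        intercept=pd.Series(truth.intercepts["traits"], index=truth.trait_names),
    )
    expression = None
    if panel is not None:
        if panel.latent is not None and "expression" in panel.latent:
            expression = panel.latent["expression"].loc[panel.expression_lines]
        elif panel.expression is not None:
            from .panel import average_replicates

            expression = average_replicates(panel.expression)
    return ModelStack(
        genes=genes, metabolites=mets, traits=traits, expression=expression,
        meta={"source": "planted"},
    )
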