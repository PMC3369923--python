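"""Aligned multi-omics panel container.

An :class:`OmicsPanel` holds the three line-by-feature matrices used
throughout the pipeline -- gene expression, metabolite levels and agronomic
traits -- for a panel of recombinant inbred lines (RILs).  Expression (and
optionally metabolites) may be present in replicated form, with row ids of
the shape ``L001_r1``; traits are always one row per line.  Expression is
typically available only for a subset of the lines with metabolome/phenome
data (the 50-of-169 nesting of the motivating dataset).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

_REP_SUFFIX = re.compile(r"_r\d+$")


def line_of(row_id: str) -> str:
    """Map a replicate row id like ``L007_r2`` to its line id ``L007``."""
    return _REP_SUFFIX.sub("", str(row_id))


def replicate_map(index: pd.Index) -> pd.Series:
    """Series mapping each row id of a replicated matrix to its line id."""
    return pd.Series([line_of(i) for i in index], index=index, name="line")


def has_replicates(index: pd.Index) -> bool:
    return any(_REP_SUFFIX.search(str(i)) for i in index)


def average_replicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average replicate rows down to one row per line.

    Row order follows first appearance of each line; a matrix without
    replicate suffixes is returned unchanged (a copy).
    """
    if matrix is None or not has_replicates(matrix.index):
        return None if matrix is None else matrix.copy()
    lines = replicate_map(matrix.index)
    out = matrix.groupby(lines, sort=False).mean()
    out.index.name = matrix.index.name
    return out


@dataclass
class OmicsPanel:
    """Expression, metabolite and trait matrices for one RIL panel.

    Attributes
    ----------
    expression
        lines (or line replicates) x genes; ``None`` when no line carries
        expression data.
    metabolites
        lines (or replicates) x metabolites.
    traits
        lines x traits.
    latent
        Optional noise-free line-level ground-truth matrices emitted by the
        synthetic generator (keys ``expression``/``metabolites``/``traits``).
        Oracle/test plumbing only; real data has no latent block.
    scalers
        Per-matrix ``(mean, sd)`` Series pairs recorded by
        :func:`fruitnet.preprocess.standardize` for inverse mapping.
    report
        Free-form preprocessing report (dropped features, parameters).
    """

    expression: Optional[pd.DataFrame]
    metabolites: pd.DataFrame
    traits: pd.DataFrame
    latent: Optional[dict] = None
    scalers: Optional[dict] = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mat in self.matrices().items():
            if mat.columns.duplicated().any():
                dup = mat.columns[mat.columns.duplicated()][0]
                raise ValueError(f"duplicate feature id {dup!r} in {name}")
            if mat.index.duplicated().any():
                dup = mat.index[mat.index.duplicated()][0]
                raise ValueError(f"duplicate row id {dup!r} in {name}")

    def matrices(self) -> dict:
        out = {}
        if self.expression is not None:
            out["expression"] = self.expression
        out["metabolites"] = self.metabolites
        out["traits"] = self.traits
        return out

    @property
    def lines(self) -> list:
        """All line ids (from the trait matrix, which covers every line)."""
        return list(self.traits.index)

    @property
    def expression_lines(self) -> list:
        """Line ids that carry expression data."""
        if self.expression is None:
            return []
        return list(dict.fromkeys(line_of(i) for i in self.expression.index))

    def averaged(self) -> "OmicsPanel":
        """Replicate-averaged copy (one row per line in every matrix)."""
        return replace(
            self,
            expression=average_replicates(self.expression),
            metabolites=average_replicates(self.metabolites),
            traits=self.traits.copy(),
        )
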