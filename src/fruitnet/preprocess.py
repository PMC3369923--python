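"""Normalization and filtering of raw panel matrices.

The canonical pipeline order is fixed: log transform -> LOWESS detrending
against the panel mean profile -> replicate CV masking -> replicate
averaging -> presence filter -> z-scoring across lines.  Each step is also
exposed on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .panel import OmicsPanel, average_replicates, line_of, replicate_map


def lowess_normalize(matrix: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Remove per-sample intensity-dependent trends (MA-style).

    For each sample (row) y the reference is the across-sample mean profile
    r; the locally weighted regression of M = y - r on A = (y + r)/2 is
    subtracted from y.  A trend-free sample is changed only by a constant
    (the fitted mean offset); a smooth intensity-dependent bias is removed.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if matrix.shape[1] < 10:
        raise ValueError(
            f"need at least 10 features for a stable LOWESS fit, got {matrix.shape[1]}"
        )
    ref = matrix.mean(axis=0).to_numpy()
    out = np.empty(matrix.shape)
    vals = matrix.to_numpy(dtype=float)
    for i in range(vals.shape[0]):
        y = vals[i]
        M = y - ref
        A = 0.5 * (y + ref)
        fit = _sm_lowess(M, A, frac=span, return_sorted=False)
        out[i] = y - fit
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_present(matrix: pd.DataFrame, presence_fraction: float = 0.8) -> pd.DataFrame:
    """Keep features observed in strictly more than `presence_fraction` of samples.

    Remaining missing values are imputed with the feature median.
    """
    if not 0 <= presence_fraction <= 1:
        raise ValueError("presence_fraction must lie in [0, 1]")
    frac = matrix.notna().mean(axis=0)
    kept = matrix.loc[:, frac > presence_fraction].copy()
    if kept.isna().any().any():
        kept = kept.fillna(kept.median(axis=0))
    return kept


def replicate_cv_filter(
    matrix: pd.DataFrame,
    rep_map: pd.Series | None = None,
    cv_max: float = 0.75,
    values_are_log: bool = False,
) -> pd.DataFrame:
    """Mask line x feature cells whose replicate coefficient of variation
    exceeds `cv_max`.

    CV = sd/|mean| over the replicates of a line, computed on the
    measurement (pre-log) scale; set ``values_are_log=True`` to exponentiate
    first.  All replicate rows of a masked cell are set missing.
    """
    if rep_map is None:
        rep_map = replicate_map(matrix.index)
    rep_map = rep_map.reindex(matrix.index)
    if rep_map.isna().any():
        raise ValueError("replicate map does not cover every row of the matrix")
    counts = rep_map.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"line {bad!r} has fewer than 2 replicates")
    vals = np.exp(matrix.to_numpy(dtype=float)) if values_are_log else matrix.to_numpy(dtype=float)
    df = pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)
    grouped = df.groupby(rep_map, sort=False)
    mean = grouped.mean()
    sd = grouped.std(ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean.abs()
    mask_lines = cv > cv_max  # lines x features
    out = matrix.copy()
    if mask_lines.any().any():
        row_mask = mask_lines.loc[rep_map.to_numpy()].to_numpy()
        arr = out.to_numpy(dtype=float)
        arr[row_mask] = np.nan
        out = pd.DataFrame(arr, index=out.index, columns=out.columns)
    return out


def standardize(panel: OmicsPanel) -> OmicsPanel:
    """Replicate-average, then z-score every feature across lines.

    Zero-variance features are dropped with a warning and listed in the
    panel report; per-feature (mean, sd) are stored in ``panel.scalers`` so
    :func:`inverse_standardize` can round-trip.
    """
    avg = panel.averaged()
    scalers: dict = {}
    dropped: dict = {}
    new = {}
    for name, mat in avg.matrices().items():
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=0)
        const = sd < 1e-12
        if const.any():
            names = list(mat.columns[const])
            dropped[name] = names
            warnings.warn(
                f"dropping {len(names)} zero-variance feature(s) from {name}: "
                f"{names[:5]}{'...' if len(names) > 5 else ''}"
            )
            mat = mat.loc[:, ~const]
            mean, sd = mean[~const], sd[~const]
        new[name] = (mat - mean) / sd
        scalers[name] = (mean, sd)
    report = dict(panel.report)
    report["standardize"] = {"dropped": dropped}
    return replace(
        panel,
        expression=new.get("expression"),
        metabolites=new["metabolites"],
        traits=new["traits"],
        scalers=scalers,
        report=report,
    )


def inverse_standardize(panel: OmicsPanel) -> OmicsPanel:
    """Undo :func:`standardize` using the stored per-feature (mean, sd)."""
    if not panel.scalers:
        raise ValueError("panel carries no standardization parameters")
    new = {}
    for name, mat in panel.matrices().items():
        mean, sd = panel.scalers[name]
        new[name] = mat * sd + mean
    return replace(
        panel,
        expression=new.get("expression"),
        metabolites=new["metabolites"],
        traits=new["traits"],
        scalers=None,
    )


def preprocess_panel(
    panel: OmicsPanel,
    span: float = 0.3,
    presence_fraction: float = 0.8,
    cv_max: float | None = None,
    log_transform: bool = False,
    lowess: bool = False,
) -> OmicsPanel:
    """Run the full pipeline in its fixed order and record a report.

    `log_transform` and `lowess` default off because the synthetic generator
    emits data already on the modelling scale; on raw array intensities both
    should be enabled.
    """
    expr = panel.expression
    mets = panel.metabolites
    report = dict(panel.report)
    params = dict(span=span, presence_fraction=presence_fraction, cv_max=cv_max,
                  log_transform=log_transform, lowess=lowess)
    report["preprocess"] = params

    def _per_matrix(mat, replicated):
        if mat is None:
            return None
        if log_transform:
            mat = np.log(mat)
        if lowess:
            mat = lowess_normalize(mat, span=span)
        if cv_max is not None and replicated:
            mat = replicate_cv_filter(mat, cv_max=cv_max, values_are_log=log_transform)
        return mat

    from .panel import has_replicates

    expr = _per_matrix(expr, expr is not None and has_replicates(expr.index))
    mets = _per_matrix(mets, has_replicates(mets.index))
    staged = replace(panel, expression=expr, metabolites=mets, report=report)
    staged = staged.averaged()
    staged = replace(
        staged,
        expression=None if staged.expression is None
        else filter_present(staged.expression, presence_fraction),
        metabolites=filter_present(staged.metabolites, presence_fraction),
    )
    return standardize(staged)
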