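"""Sparse layer inference: CLR screening, LASSO selection, OLS refit.

Each layer of the model is inferred target by target in two nested steps.
First, candidate predictors are screened by mutual information with a CLR
(context likelihood of relatedness) z-score: the MI of a (target,
predictor) pair is standardized against the background of its row and
column and combined as z = sqrt(max(0, z_row)^2 + max(0, z_col)^2); only
predictors with z >= z* survive.  Second, LASSO on the surviving candidates
picks the support, and an ordinary least-squares refit on that support
de-biases the coefficients.  Reliability is quantified by k-fold
cross-validation (screening and selection redone inside every fold) and by
a bootstrap null for PPV/FPR against a reference edge set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import special as sp_special
from scipy import stats as sp_stats
from sklearn.linear_model import Lasso, LassoCV, lars_path
from sklearn.model_selection import KFold

from .model import GENE_LAYER, LAYERS, MET_LAYER, TRAIT_LAYER, LayerModel
from .panel import OmicsPanel

# ---------------------------------------------------------------------------
# mutual information screening


@dataclass
class CandidateScreen:
    """CLR z-scores for every (target, predictor) pair."""

    z: pd.DataFrame          # targets x predictors, self pairs = -inf
    mi: pd.DataFrame
    bins: int


@dataclass
class CandidateSet:
    candidates: Dict[str, List[str]]
    z_star: float
    n_predictors: int
    empty_targets: List[str] = field(default_factory=list)

    @property
    def mean_count(self) -> float:
        return float(np.mean([len(v) for v in self.candidates.values()]))

    @property
    def reduction_factor(self) -> float:
        """Candidate space shrinkage: mean candidates / total predictors."""
        return self.mean_count / self.n_predictors


def _bin_indices(X: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin index per column; constant columns -> one bin."""
    n = X.shape[0]
    ranks = np.apply_along_axis(sp_stats.rankdata, 0, X)  # average ranks
    idx = np.ceil(ranks * bins / n).astype(int) - 1
    return np.clip(idx, 0, bins - 1)


def _mi_from_bins(bt: np.ndarray, BP: np.ndarray, bins: int) -> np.ndarray:
    """MI (nats, plug-in) of one target's bins against every predictor's."""
    n = bt.shape[0]
    P = BP.shape[1]
    out = np.empty(P)
    pt = np.bincount(bt, minlength=bins) / n
    for j in range(P):
        bp = BP[:, j]
        joint = np.bincount(bt * bins + bp, minlength=bins * bins) / n
        joint = joint.reshape(bins, bins)
        pp = joint.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = joint / (pt[:, None] * pp[None, :])
            terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
        out[j] = max(terms.sum(), 0.0)
    return out


def mi_zscores(
    targets_matrix: pd.DataFrame,
    predictors_matrix: pd.DataFrame,
    bins: Optional[int] = None,
) -> CandidateScreen:
    """Mutual-information CLR z-scores for all target/predictor pairs.

    MI is estimated with equal-frequency binning; the default bin count is
    the cube-root rule ``ceil(lines ** (1/3))``, which keeps the
    contingency table populated at panel-scale line counts (sqrt-rule
    binning leaves more cells than samples below ~100 lines and costs
    detection power).  Pairs where target and
    predictor are the same named feature (the gene layer's self-edges) are
    excluded from both the backgrounds and the result (z = -inf).
    """
    if not targets_matrix.index.equals(predictors_matrix.index):
        raise ValueError("targets and predictors must share the line index")
    n = targets_matrix.shape[0]
    if n < 20:
        raise ValueError(f"need at least 20 lines for MI estimation, got {n}")
    if bins is None:
        bins = max(2, int(np.ceil(n ** (1.0 / 3.0))))
    if bins < 2 or bins > n / 5:
        raise ValueError(f"bins={bins} outside the valid range [2, lines/5]")

    BT = _bin_indices(targets_matrix.to_numpy(dtype=float), bins)
    BP = _bin_indices(predictors_matrix.to_numpy(dtype=float), bins)
    T = targets_matrix.shape[1]
    mi = np.empty((T, predictors_matrix.shape[1]))
    for i in range(T):
        mi[i] = _mi_from_bins(BT[:, i], BP, bins)

    mi_df = pd.DataFrame(mi, index=targets_matrix.columns, columns=predictors_matrix.columns)
    # mask self pairs before computing backgrounds
    self_mask = np.zeros(mi.shape, dtype=bool)
    common = targets_matrix.columns.intersection(predictors_matrix.columns)
    if len(common):
        t_pos = {c: i for i, c in enumerate(targets_matrix.columns)}
        p_pos = {c: j for j, c in enumerate(predictors_matrix.columns)}
        for c in common:
            self_mask[t_pos[c], p_pos[c]] = True
    m = np.where(self_mask, np.nan, mi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mu, row_sd = np.nanmean(m, axis=1, keepdims=True), np.nanstd(m, axis=1, keepdims=True)
        col_mu, col_sd = np.nanmean(m, axis=0, keepdims=True), np.nanstd(m, axis=0, keepdims=True)
    zr = (m - row_mu) / np.where(row_sd > 0, row_sd, np.inf)
    zc = (m - col_mu) / np.where(col_sd > 0, col_sd, np.inf)
    z = np.sqrt(np.maximum(zr, 0.0) ** 2 + np.maximum(zc, 0.0) ** 2)
    z[self_mask] = -np.inf
    z_df = pd.DataFrame(z, index=mi_df.index, columns=mi_df.columns)
    return CandidateScreen(z=z_df, mi=mi_df, bins=bins)


def select_candidates(screen: CandidateScreen, z_star: float) -> CandidateSet:
    """Per-target candidate predictor lists at threshold z >= z*."""
    if z_star < 0:
        raise ValueError("z_star must be non-negative")
    cands: Dict[str, List[str]] = {}
    empty = []
    cols = screen.z.columns
    Z = screen.z.to_numpy()
    for i, target in enumerate(screen.z.index):
        sel = list(cols[Z[i] >= z_star])
        cands[target] = sel
        if not sel:
            empty.append(target)
    return CandidateSet(
        candidates=cands, z_star=float(z_star),
        n_predictors=screen.z.shape[1], empty_targets=empty,
    )


# ---------------------------------------------------------------------------
# LASSO support selection + OLS refit


@dataclass
class LassoFit:
    predictors: List[str]
    coef: np.ndarray
    intercept: float
    t_lasso: float


def _ols(y: np.ndarray, X: np.ndarray):
    Z = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return float(beta[0]), beta[1:]


EBIC_GAMMA = 1.0


def _ebic_path_support(X: np.ndarray, y: np.ndarray, gamma: float):
    """Support minimizing the extended BIC along the LASSO (LARS) path.

    EBIC(k) = n log(RSS/n) + k log(n) + 2 gamma log C(p, k); the extended
    term (Chen & Chen) guards against spurious selections when the
    candidate count rivals or exceeds the line count.  Ties along the path
    break toward the smaller support.  Returns (support indices, alpha).
    """
    n, p = X.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, _, coefs = lars_path(X, y - y.mean(), method="lasso")
    best = (np.inf, np.empty(0, dtype=int), 0.0)
    seen_sizes = set()
    for j in range(coefs.shape[1]):
        sup = np.flatnonzero(np.abs(coefs[:, j]) > 1e-12)
        k = len(sup)
        if k > n - 2:
            break
        key = tuple(sup)
        if key in seen_sizes:
            continue
        seen_sizes.add(key)
        if k == 0:
            rss = float(np.sum((y - y.mean()) ** 2))
        else:
            Z = np.column_stack([np.ones(n), X[:, sup]])
            beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            rss = float(np.sum((y - Z @ beta) ** 2))
        rss = max(rss, 1e-300)
        ebic = (
            n * np.log(rss / n)
            + k * np.log(n)
            + 2.0 * gamma * (
                sp_special.gammaln(p + 1)
                - sp_special.gammaln(k + 1)
                - sp_special.gammaln(p - k + 1)
            )
        )
        if ebic < best[0] - 1e-12:
            best = (ebic, sup, float(alphas[j]))
    return best[1], best[2]


def lasso_refit(
    y, X_candidates: pd.DataFrame, t_lasso=None
) -> LassoFit:
    """LASSO support selection followed by an OLS refit on the support.

    `t_lasso` controls the L1 penalty: a float is sklearn's ``alpha``;
    ``None`` (default) picks the support along the regularization path by
    extended BIC (the support-recovery default); ``"cv"`` picks the penalty
    by prediction cross-validation (denser supports, best held-out r).  If
    LASSO keeps more predictors than lines - 2, the support is truncated to
    the largest coefficients (with a warning) so the refit stays determined.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X_candidates.shape[1] == 0:
        t0 = t_lasso if isinstance(t_lasso, (int, float)) else 0.0
        return LassoFit([], np.empty(0), float(np.mean(y)), float(t0))
    X = X_candidates.to_numpy(dtype=float)
    if t_lasso is None:
        support, alpha = _ebic_path_support(X, y, EBIC_GAMMA)
        if len(support) == 0:
            return LassoFit([], np.empty(0), float(np.mean(y)), alpha)
        names = [X_candidates.columns[j] for j in support]
        intercept, beta = _ols(y, X[:, support])
        return LassoFit(names, beta, intercept, alpha)
    if t_lasso == "cv":
        cv = min(5, max(2, n // 10))
        model = LassoCV(cv=cv, alphas=30, max_iter=50000, tol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        t_lasso = float(model.alpha_)
        coef = model.coef_
    else:
        if t_lasso < 0:
            raise ValueError("t_lasso must be >= 0")
        if t_lasso == 0:
            intercept, beta = _ols(y, X)
            return LassoFit(list(X_candidates.columns), beta, intercept, 0.0)
        model = Lasso(alpha=t_lasso, max_iter=100000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        coef = model.coef_
    support = np.flatnonzero(np.abs(coef) > 1e-12)
    if len(support) == 0:
        return LassoFit([], np.empty(0), float(np.mean(y)), float(t_lasso))
    if len(support) > n - 2:
        keep = min(max(n - 2, 1), len(support))
        warnings.warn(
            f"LASSO support ({len(support)}) exceeds lines-2; truncating to {keep}"
        )
        order = support[np.argsort(-np.abs(coef[support]))]
        support = np.sort(order[:keep])
    names = [X_candidates.columns[j] for j in support]
    intercept, beta = _ols(y, X[:, support])
    return LassoFit(names, beta, intercept, float(t_lasso))


# ---------------------------------------------------------------------------
# layer fitting

def _layer_matrices(panel: OmicsPanel, layer: str):
    """(targets, predictors) line-aligned matrices for one layer."""
    avg = panel.averaged()
    if layer == GENE_LAYER:
        if avg.expression is None:
            raise ValueError("panel has no expression data")
        return avg.expression, avg.expression
    if layer == MET_LAYER:
        if avg.expression is None:
            raise ValueError("panel has no expression data")
        lines = avg.expression.index
        return avg.metabolites.loc[lines], avg.expression
    if layer == TRAIT_LAYER:
        lines = avg.traits.index
        return avg.traits, avg.metabolites.loc[lines]
    raise ValueError(f"unknown layer {layer!r}")


def _pearson_columns(A: pd.DataFrame, B: pd.DataFrame) -> pd.Series:
    """Column-wise Pearson r between two aligned DataFrames."""
    out = {}
    for c in A.columns:
        a = A[c].to_numpy(dtype=float)
        b = B[c].to_numpy(dtype=float)
        if np.std(a) < 1e-15 or np.std(b) < 1e-15:
            out[c] = np.nan
        else:
            out[c] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out)


def fit_layer(
    panel: OmicsPanel,
    layer: str,
    z_star: float = 2.0,
    t_lasso: Optional[float] = None,
    bins: Optional[int] = None,
    delta: float = 0.0,
    max_spectral_radius: float = 0.95,
) -> LayerModel:
    """Fit one sparse layer: CLR screen -> LASSO -> OLS refit per target.

    The panel is expected standardized (z-scored across lines).  The gene
    layer records observed per-gene (min, max) ranges and the shrink
    parameter delta; the constant calibration term is the training-mean
    residual (zero up to round-off when intercepts are fitted, kept for the
    serialized contract).

    The gene layer is a steady-state operator, so it must be stable: when
    the fitted coefficient matrix has spectral radius >= 1 (which least
    squares does not prevent), it is rescaled to `max_spectral_radius`.
    Training-line predictions are unaffected (per-line calibration absorbs
    the change); perturbed-genome solves become well-posed.
    """
    Y, X = _layer_matrices(panel, layer)
    screen = mi_zscores(Y, X, bins=bins)
    cset = select_candidates(screen, z_star)
    coef = pd.DataFrame(0.0, index=Y.columns, columns=X.columns)
    intercept = pd.Series(0.0, index=Y.columns)
    t_used: Dict[str, float] = {}
    for target in Y.columns:
        cand = cset.candidates[target]
        fit = lasso_refit(Y[target], X[cand], t_lasso)
        if fit.predictors:
            coef.loc[target, fit.predictors] = fit.coef
        intercept[target] = fit.intercept
        t_used[target] = fit.t_lasso
    radius_raw = None
    rescaled = False
    if layer == GENE_LAYER and coef.shape[0] > 1:
        radius_raw = float(np.max(np.abs(np.linalg.eigvals(coef.to_numpy()))))
        if radius_raw >= max_spectral_radius and radius_raw > 0:
            coef *= max_spectral_radius / radius_raw
            rescaled = True
            warnings.warn(
                f"fitted gene matrix spectral radius {radius_raw:.3f} >= "
                f"{max_spectral_radius}; rescaled for steady-state stability"
            )
    pred = pd.DataFrame(
        X.to_numpy() @ coef.to_numpy().T + intercept.to_numpy(),
        index=Y.index, columns=Y.columns,
    )
    resid = Y - pred
    calibration = float(resid.to_numpy().mean())
    training_r = _pearson_columns(Y, pred + calibration)
    ranges = None
    if layer == GENE_LAYER:
        ranges = pd.DataFrame({"min": X.min(), "max": X.max()})
    return LayerModel(
        layer=layer, coef=coef, intercept=intercept, calibration=calibration,
        gene_ranges=ranges, delta=delta,
        meta={
            "z_star": float(z_star), "bins": screen.bins,
            "t_lasso": t_used, "training_r": training_r,
            "screen_mean_candidates": cset.mean_count,
            "screen_reduction_factor": cset.reduction_factor,
            "empty_targets": cset.empty_targets,
            "spectral_radius_raw": radius_raw,
            "stability_rescaled": rescaled,
        },
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FitReport:
    layer: str
    training_r: pd.Series
    cv_r: pd.Series
    k_folds: int
    seed: int
    ppv: Optional[float] = None
    fpr: Optional[float] = None
    p_ppv: Optional[float] = None
    p_fpr: Optional[float] = None

    @property
    def mean_training_r(self) -> float:
        return float(self.training_r.mean())

    @property
    def mean_cv_r(self) -> float:
        return float(self.cv_r.mean())


def cross_validate(
    panel: OmicsPanel,
    layer: str,
    k_folds: int = 5,
    seed: int = 0,
    z_star: float = 2.0,
    t_lasso: Optional[float] = None,
    bins: Optional[int] = None,
) -> FitReport:
    """Held-out per-target Pearson r with screening/LASSO redone per fold."""
    Y, X = _layer_matrices(panel, layer)
    n = Y.shape[0]
    if not 2 <= k_folds <= n:
        raise ValueError(f"k_folds must lie in [2, {n}]")
    if n // k_folds < 3 and k_folds != n:
        raise ValueError("a fold would hold fewer than 3 lines")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pred = pd.DataFrame(np.nan, index=Y.index, columns=Y.columns)
    for train_idx, test_idx in kf.split(Y):
        Ytr, Xtr = Y.iloc[train_idx], X.iloc[train_idx]
        Xte = X.iloc[test_idx]
        screen = mi_zscores(Ytr, Xtr, bins=bins)
        cset = select_candidates(screen, z_star)
        for target in Y.columns:
            cand = cset.candidates[target]
            fit = lasso_refit(Ytr[target], Xtr[cand], t_lasso)
            yhat = np.full(len(test_idx), fit.intercept)
            if fit.predictors:
                yhat = yhat + Xte[fit.predictors].to_numpy() @ fit.coef
            pred.iloc[test_idx, pred.columns.get_loc(target)] = yhat
    cv_r = _pearson_columns(Y, pred)
    full = fit_layer(panel, layer, z_star=z_star, t_lasso=t_lasso, bins=bins)
    return FitReport(
        layer=layer, training_r=full.meta["training_r"], cv_r=cv_r,
        k_folds=k_folds, seed=int(seed),
    )


# ---------------------------------------------------------------------------
# bootstrap PPV/FPR


@dataclass
class BootstrapRecord:
    ppv: Optional[float]
    fpr: float
    p_ppv: Optional[float]
    p_fpr: float
    null_ppv_mean: float
    null_ppv_sd: float
    null_fpr_mean: float
    null_fpr_sd: float
    n_boot: int


def bootstrap_ppv_fpr(
    inferred_support: Mapping[str, Sequence[str]],
    reference_support: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    n_boot: int = 10000,
    seed: int = 0,
) -> BootstrapRecord:
    """PPV/FPR of inferred vs reference predictor lists, with bootstrap null.

    The null draws, for every target, a random predictor list of the same
    size as the inferred one, sampled from the universe *with replacement*,
    and recomputes PPV and FPR; the empirical p-values are upper-tail for
    PPV and lower-tail for FPR.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    U = len(universe)
    pos = {p: j for j, p in enumerate(universe)}
    targets = list(inferred_support)

    sizes = np.array([len(inferred_support[t]) for t in targets], dtype=int)
    ref_sets = {t: set(reference_support.get(t, ())) for t in targets}
    tp = sum(len(set(inferred_support[t]) & ref_sets[t]) for t in targets)
    fp = int(sizes.sum()) - tp
    total_pos = sum(len(ref_sets[t]) for t in targets)
    total_neg = U * len(targets) - total_pos
    tn = total_neg - fp
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0

    # vectorized null: one flat draw per bootstrap replicate
    ref_mask = np.zeros((len(targets), U), dtype=bool)
    for i, t in enumerate(targets):
        for p in ref_sets[t]:
            if p in pos:
                ref_mask[i, pos[p]] = True
    seg = np.repeat(np.arange(len(targets)), sizes)
    S = int(sizes.sum())
    null_ppv = np.empty(n_boot)
    null_fpr = np.empty(n_boot)
    if S == 0:
        null_ppv[:] = np.nan
        null_fpr[:] = 0.0
    else:
        draws = rng.integers(0, U, size=(n_boot, S))
        hits = ref_mask[seg[None, :], draws]  # n_boot x S
        tp_b = hits.sum(axis=1)
        fp_b = S - tp_b
        null_ppv = tp_b / S
        null_fpr = fp_b / (fp_b + (total_neg - fp_b))
    if ppv is None:
        p_ppv = None
    else:
        p_ppv = float((1 + np.sum(null_ppv >= ppv)) / (n_boot + 1))
    p_fpr = float((1 + np.sum(null_fpr <= fpr)) / (n_boot + 1))
    return BootstrapRecord(
        ppv=None if ppv is None else float(ppv), fpr=float(fpr),
        p_ppv=p_ppv, p_fpr=p_fpr,
        null_ppv_mean=float(np.nan) if S == 0 else float(np.mean(null_ppv)),
        null_ppv_sd=float(np.nan) if S == 0 else float(np.std(null_ppv)),
        null_fpr_mean=float(np.mean(null_fpr)),
        null_fpr_sd=float(np.std(null_fpr)),
        n_boot=int(n_boot),
    )


# ---------------------------------------------------------------------------
# degree diagnostics


@dataclass
class DegreeReport:
    mean_degree: float
    histogram: pd.Series
    exponent: Optional[float]


def powerlaw_mle(degrees: Sequence[int], x_min: int = 1) -> float:
    """Discrete power-law exponent by maximum likelihood (zeta-normalized)."""
    x = np.asarray([d for d in degrees if d >= x_min], dtype=float)
    if len(x) == 0:
        raise ValueError("no degrees >= x_min")
    slx = np.log(x).sum()

    def nll(alpha):
        return len(x) * np.log(sp_special.zeta(alpha, x_min)) + alpha * slx

    res = sp_optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x)


def degree_powerlaw(layer_model: LayerModel) -> DegreeReport:
    """In-degree histogram, mean degree and discrete power-law MLE exponent.

    The exponent is omitted when fewer than 10 targets have nonzero degree.
    """
    degrees = np.array(
        [(layer_model.coef.loc[t].to_numpy() != 0).sum() for t in layer_model.targets]
    )
    hist = pd.Series(degrees).value_counts().sort_index()
    nonzero = degrees[degrees > 0]
    exponent = powerlaw_mle(nonzero) if len(nonzero) >= 10 else None
    return DegreeReport(
        mean_degree=float(degrees.mean()) if len(degrees) else 0.0,
        histogram=hist, exponent=exponent,
    )


# ---------------------------------------------------------------------------
# noise robustness diagnostic

def noise_robustness(
    panel: OmicsPanel,
    layer_model: LayerModel,
    noise_levels: Sequence[float],
    seed: int = 0,
    n_reps: int = 10,
) -> pd.DataFrame:
    """Mean Pearson r between fixed model predictions and noise-corrupted
    targets, per noise level (averaged over `n_reps` noise draws).

    Noise level 0 reproduces the training correlation exactly; the curve is
    non-increasing on average and tends to 0 as the noise dominates.
    """
    if any(s < 0 for s in noise_levels):
        raise ValueError("noise levels must be non-negative")
    Y, X = _layer_matrices(panel, layer_model.layer)
    pred = layer_model.predict(X)
    rng = np.random.default_rng(seed)
    rows = []
    for level in noise_levels:
        rs = []
        reps = 1 if level == 0 else n_reps
        for _ in range(reps):
            noisy = Y + (rng.normal(0.0, level, size=Y.shape) if level > 0 else 0.0)
            rs.append(_pearson_columns(noisy, pred).mean())
        rows.append({"noise_sd": float(level), "mean_r": float(np.mean(rs))})
    return pd.DataFrame(rows)
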