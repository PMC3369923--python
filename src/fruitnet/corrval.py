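"""Perturbation-signature validation of the fitted model.

For every metabolite the model's single-gene knockout/over-expression
perturbations are split into the set raising it (omega+) and the set
lowering it (omega-) beyond a relative threshold (1% of the wild-type
population sd by default).  Two metabolites that respond to the same
perturbations in the same direction are predicted to correlate; the
normalized signed signature overlap gives a predicted correlation matrix
that is compared with the empirical metabolite correlation matrix by
precision/recall/F-score at a cutoff, by hierarchical-clustering
dendrograms, and by a Mantel permutation test between the two distance
matrices.  Directional overlap with genes observed altered in engineered
lines gives an independent enrichment check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sp_hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .model import ModelStack
from .perturb import KO, OE, PerturbationSet
from .steadystate import SteadySolver

Perturbation = Tuple[str, str]  # (gene, mode)


@dataclass
class PerturbationSignature:
    """Directional single-gene perturbation signature of one metabolite."""

    metabolite: str
    omega_plus: Set[Perturbation]
    omega_minus: Set[Perturbation]
    epsilon: float

    def __post_init__(self) -> None:
        overlap = self.omega_plus & self.omega_minus
        if overlap:
            raise ValueError(f"perturbations in both omega sets: {sorted(overlap)}")

    @property
    def omega(self) -> Set[Perturbation]:
        return self.omega_plus | self.omega_minus

    def is_empty(self) -> bool:
        return not (self.omega_plus or self.omega_minus)


def build_signatures(
    stack: ModelStack,
    epsilon: float = 0.01,
    lines: Optional[Sequence[str]] = None,
    metabolites: Optional[Sequence[str]] = None,
    delta: Optional[float] = None,
) -> Dict[str, PerturbationSignature]:
    """Signatures for all (or the given) metabolites in one scan.

    A perturbation joins omega+/omega- of a metabolite when its mean
    relative change across lines -- (m_pert - m_wt) / sd_wt, with sd_wt the
    wild-type population sd of that metabolite -- exceeds +epsilon / falls
    below -epsilon.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    solver = SteadySolver(stack, delta=delta)
    lines = list(lines) if lines is not None else list(stack.baseline_lines)
    if not lines:
        raise ValueError("no baseline lines available")
    met_names = list(metabolites) if metabolites is not None else list(stack.metabolite_names)
    unknown = set(met_names) - set(stack.metabolite_names)
    if unknown:
        raise KeyError(f"unknown metabolite(s): {sorted(unknown)}")

    Vm = stack.metabolites.coef.to_numpy()
    bm = stack.metabolites.intercept.to_numpy() + stack.metabolites.calibration
    all_mets = list(stack.metabolite_names)
    Gwt = solver.solve_lines(None, lines)          # L x n
    Mwt = Gwt @ Vm.T + bm                           # L x m
    sd = Mwt.std(axis=0)
    sd = np.where(sd > 0, sd, np.nan)

    plus: Dict[str, set] = {m: set() for m in met_names}
    minus: Dict[str, set] = {m: set() for m in met_names}
    for gene in sorted(stack.gene_names):
        for mode in (KO, OE):
            pert = PerturbationSet({gene: mode})
            G = solver.solve_lines(pert, lines)
            M = G @ Vm.T + bm
            rel = ((M - Mwt) / sd).mean(axis=0)
            for met in met_names:
                r = rel[all_mets.index(met)]
                if np.isnan(r):
                    continue
                if r > epsilon:
                    plus[met].add((gene, mode))
                elif r < -epsilon:
                    minus[met].add((gene, mode))
    return {
        m: PerturbationSignature(m, plus[m], minus[m], float(epsilon))
        for m in met_names
    }


def build_signature(
    stack: ModelStack,
    metabolite: str,
    epsilon: float = 0.01,
    lines: Optional[Sequence[str]] = None,
    delta: Optional[float] = None,
) -> PerturbationSignature:
    """Signature of a single metabolite (see :func:`build_signatures`)."""
    return build_signatures(stack, epsilon, lines, [metabolite], delta)[metabolite]


def _norm_overlap(a: Set, b: Set, normalization: str) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if normalization == "min":
        return inter / min(len(a), len(b))
    if normalization == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown normalization {normalization!r}")


def predicted_correlation(
    sig_a: PerturbationSignature,
    sig_b: PerturbationSignature,
    normalization: str = "min",
) -> float:
    """Signature-overlap correlation r_pred = S_same - S_opp in [-1, 1].

    S_same is the larger of the normalized overlaps omega+a/omega+b and
    omega-a/omega-b; S_opp the larger of the cross-sign overlaps.  The
    default min-cardinality normalization makes a subset relationship count
    as full overlap; ``normalization="jaccard"`` is the stricter variant.
    Both signatures fully empty -> NaN (excluded downstream).
    """
    if sig_a.epsilon != sig_b.epsilon:
        raise ValueError("signatures were built at different epsilon thresholds")
    if sig_a.is_empty() and sig_b.is_empty():
        return float("nan")
    s_same = max(
        _norm_overlap(sig_a.omega_plus, sig_b.omega_plus, normalization),
        _norm_overlap(sig_a.omega_minus, sig_b.omega_minus, normalization),
    )
    s_opp = max(
        _norm_overlap(sig_a.omega_plus, sig_b.omega_minus, normalization),
        _norm_overlap(sig_a.omega_minus, sig_b.omega_plus, normalization),
    )
    return s_same - s_opp


def predicted_correlation_matrix(
    signatures: Mapping[str, PerturbationSignature], normalization: str = "min"
) -> pd.DataFrame:
    names = list(signatures)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = predicted_correlation(signatures[a], signatures[b], normalization)
            out.loc[a, b] = out.loc[b, a] = r
    return out


@dataclass
class CorrComparison:
    """Precision/recall/F of predicted vs empirical correlation calls."""

    cutoff: float
    precision: Optional[float]
    recall: Optional[float]
    f_score: Optional[float]
    n_called_pred: int
    n_called_emp: int
    n_correct: int
    n_pairs: int


def precision_recall_f(
    pred_matrix: pd.DataFrame,
    emp_matrix: pd.DataFrame,
    cutoff_k: float,
    min_empirical_r: Optional[float] = None,
) -> CorrComparison:
    """Compare correlation calls at cutoff k: a pair is called when
    |r| >= k in the respective matrix; F = 2PR/(P+R).

    `min_empirical_r` restricts the pair universe to pairs whose empirical
    |r| reaches that floor (the convention of dropping weakly correlated
    experimental pairs).  NaN predicted entries are treated as not-called.
    """
    if not 0 < cutoff_k <= 1:
        raise ValueError("cutoff_k must lie in (0, 1]")
    labels = pred_matrix.index
    if not labels.equals(emp_matrix.index):
        emp_matrix = emp_matrix.reindex(index=labels, columns=labels)
        if emp_matrix.isna().all().all():
            raise ValueError("matrices share no labels")
    P = pred_matrix.to_numpy(dtype=float)
    E = emp_matrix.to_numpy(dtype=float)
    iu = np.triu_indices(len(labels), k=1)
    p, e = P[iu], E[iu]
    keep = ~np.isnan(e)
    if min_empirical_r is not None:
        keep &= np.abs(e) >= min_empirical_r
    p, e = p[keep], e[keep]
    called_p = ~np.isnan(p) & (np.abs(p) >= cutoff_k)
    called_e = np.abs(e) >= cutoff_k
    n_correct = int(np.sum(called_p & called_e))
    n_p, n_e = int(called_p.sum()), int(called_e.sum())
    precision = n_correct / n_p if n_p else None
    recall = n_correct / n_e if n_e else None
    if precision is None or recall is None or (precision + recall) == 0:
        f = None if (precision is None or recall is None) else 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return CorrComparison(
        cutoff=float(cutoff_k), precision=precision, recall=recall, f_score=f,
        n_called_pred=n_p, n_called_emp=n_e, n_correct=n_correct, n_pairs=int(keep.sum()),
    )


def f_score_curve(
    pred_matrix: pd.DataFrame,
    emp_matrix: pd.DataFrame,
    cutoffs: Sequence[float],
    min_empirical_r: Optional[float] = None,
) -> pd.DataFrame:
    rows = []
    for k in cutoffs:
        c = precision_recall_f(pred_matrix, emp_matrix, k, min_empirical_r)
        rows.append({"cutoff": c.cutoff, "precision": c.precision,
                     "recall": c.recall, "f_score": c.f_score})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dendrograms


@dataclass
class Dendrogram:
    linkage: np.ndarray
    labels: List[str]
    newick: str
    flagged_pairs: List[Tuple[str, str]] = field(default_factory=list)

    def cophenetic(self) -> pd.DataFrame:
        d = sp_hierarchy.cophenet(self.linkage)
        mat = squareform(d)
        return pd.DataFrame(mat, index=self.labels, columns=self.labels)


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, list(labels))
    return str(tree).strip()


def signature_dendrogram(
    corr_or_signatures,
    linkage: str = "average",
) -> Dendrogram:
    """Hierarchical clustering of metabolites by shared perturbations.

    Accepts either a dict of signatures (distance 1 - r_pred) or a
    correlation DataFrame directly.  Undefined distances are imputed to the
    maximum distance 2 and flagged.  The tree is serialized as Newick.
    """
    if isinstance(corr_or_signatures, Mapping):
        corr = predicted_correlation_matrix(corr_or_signatures)
    else:
        corr = corr_or_signatures
    labels = list(corr.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 metabolites for a dendrogram")
    D = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    flagged = []
    iu = np.triu_indices(len(labels), k=1)
    for i, j in zip(*iu):
        if np.isnan(D[i, j]):
            flagged.append((labels[i], labels[j]))
            D[i, j] = D[j, i] = 2.0
    Z = sp_hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return Dendrogram(
        linkage=Z, labels=labels, newick=_linkage_to_newick(Z, labels),
        flagged_pairs=flagged,
    )


# ---------------------------------------------------------------------------
# Mantel test


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    n_labels: int


def mantel(
    dist_a: pd.DataFrame | np.ndarray,
    dist_b: pd.DataFrame | np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    Pearson correlation of the off-diagonal entries; the null relabels one
    matrix `n_perm` times; one-sided upper p = (1 + #{r_perm >= r}) /
    (n_perm + 1).
    """
    A = _as_square(dist_a)
    B = _as_square(dist_b, like=dist_a)
    if A.shape != B.shape:
        raise ValueError("distance matrices differ in size")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    if np.std(a) < 1e-15 or np.std(B[iu]) < 1e-15:
        raise ValueError("constant distance matrix: Mantel r undefined")
    a = (a - a.mean()) / a.std()
    rng = np.random.default_rng(seed)

    def corr_with(Bm):
        b = Bm[iu]
        return float(np.mean(a * (b - b.mean()) / b.std()))

    r_obs = corr_with(B)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(B[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    return MantelResult(
        r=r_obs, p_value=(1 + count) / (n_perm + 1), n_perm=n_perm, n_labels=n
    )


def _as_square(d, like=None) -> np.ndarray:
    if isinstance(d, pd.DataFrame):
        if isinstance(like, pd.DataFrame) and not d.index.equals(like.index):
            d = d.reindex(index=like.index, columns=like.index)
        arr = d.to_numpy(dtype=float)
    else:
        arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    return arr


# ---------------------------------------------------------------------------
# overlap enrichment against engineered lines


@dataclass
class OverlapEnrichment:
    overlap_pct: float            # mean over observed sets
    per_set_pct: List[float]
    null_mean_pct: float
    null_sd_pct: float
    p_empirical: float
    u_statistic: Optional[float]
    p_mannwhitney: Optional[float]
    n_random: int


def overlap_enrichment(
    proposed: Set[Perturbation],
    observed_altered_genes,
    universe: Sequence[str],
    n_random: int = 1000,
    seed: int = 0,
) -> OverlapEnrichment:
    """Direction-consistent overlap of proposed perturbations with genes
    observed altered in engineered lines, against a random-selection null.

    `observed_altered_genes` is a mapping gene -> "up"/"down" (or a list of
    such mappings, one per engineered line).  A KO proposal matches an
    observed "down" gene, an OE proposal an observed "up" gene.  The null
    redraws `n_random` random same-size (gene, mode) selections from the
    universe; a Mann-Whitney U compares the per-line observed overlaps with
    the null overlaps when several lines are given.
    """
    proposed = set(proposed)
    if not proposed:
        raise ValueError("empty proposed perturbation set")
    if isinstance(observed_altered_genes, Mapping):
        observed_sets = [observed_altered_genes]
    else:
        observed_sets = list(observed_altered_genes)
    universe = list(universe)
    for p, _mode in proposed:
        if p not in universe:
            raise KeyError(f"proposed gene {p!r} not in universe")

    match_dir = {KO: "down", OE: "up"}

    def pct(sel: Set[Perturbation], obs: Mapping[str, str]) -> float:
        hits = sum(1 for g, mode in sel if obs.get(g) == match_dir[mode])
        return 100.0 * hits / len(sel)

    per_set = [pct(proposed, obs) for obs in observed_sets]
    obs_mean = float(np.mean(per_set))

    rng = np.random.default_rng(seed)
    k = len(proposed)
    null = np.empty(n_random)
    modes = np.array([KO, OE])
    for i in range(n_random):
        genes = rng.choice(len(universe), size=min(k, len(universe)), replace=False)
        sel = {(universe[g], modes[rng.integers(2)]) for g in genes}
        null[i] = float(np.mean([pct(sel, obs) for obs in observed_sets]))
    p_emp = float((1 + np.sum(null >= obs_mean)) / (n_random + 1))
    u = p_u = None
    if len(per_set) > 1:
        res = mannwhitneyu(per_set, null, alternative="greater")
        u, p_u = float(res.statistic), float(res.pvalue)
    return OverlapEnrichment(
        overlap_pct=obs_mean, per_set_pct=per_set,
        null_mean_pct=float(null.mean()), null_sd_pct=float(null.std(ddof=0)),
        p_empirical=p_emp, u_statistic=u, p_mannwhitney=p_u, n_random=int(n_random),
    )
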