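"""Signed weighted co-expression networks, module detection and module DE.

Workflow: genes passing a liberal differential-expression cut (q < 0.15)
form a signed weighted network with adjacency a_ij = ((1 + r_ij)/2)^beta,
where beta is the smallest soft power reaching scale-free topology fit 0.9.
Modules come from average-linkage clustering on 1 - TOM (signed topological
overlap), cut at a quantile height and pruned at a minimum size. Module
expression is the mean of member genes' nuisance-corrected log-CPM; module
differential expression reuses the moderated-t engine; the module graph
links modules whose expression correlates above 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import moderated_linear_fit, bh_adjust, build_design_matrix

__all__ = [
    "NetworkParams", "ModuleSet", "select_soft_power", "signed_tom",
    "tom_from_adjacency", "detect_modules", "module_expression", "residualize",
    "module_differential_expression", "hub_genes", "module_graph",
]

MODULE_DE_COVARIATES = ("age_group", "sex", "batch", "site", "rin", "gc",
                        "pc1", "pc2")
MODULE_EXPR_NUISANCE = ("sex", "batch", "rin", "gc")


@dataclass
class NetworkParams:
    powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_target: float = 0.9
    min_module_size: int = 15
    cut_height_fraction: float = 0.99  # of the top merge height
    max_block_size: int = 8000

    def __post_init__(self):
        if any(p < 1 for p in self.powers):
            raise ValueError("candidate powers must be positive integers")
        if self.min_module_size < 2:
            raise ValueError("min module size must be >= 2")


@dataclass
class ModuleSet:
    """Module assignments plus module-level statistics."""
    assignments: pd.Series            # gene_id -> int label (0 = unassigned)
    power: int
    module_expression: pd.DataFrame | None = None   # modules x samples
    hubs: dict[int, str] = field(default_factory=dict)
    de: pd.DataFrame | None = None    # per-module log2fc, p, q
    edges: pd.DataFrame | None = None

    @property
    def labels(self) -> list[int]:
        return sorted(l for l in self.assignments.unique() if l != 0)


def _signed_adjacency(expr: np.ndarray, power: int) -> np.ndarray:
    r = np.corrcoef(expr)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite correlations (constant rows?)")
    a = ((1.0 + r) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return a


def _drop_constant_rows(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.to_numpy(float).std(axis=1)
    if np.any(sd == 0):
        warnings.warn(f"removed {int((sd == 0).sum())} constant gene rows "
                      "before correlation")
        expr = expr.loc[sd > 0]
    return expr


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index.

    Bins connectivities k_i, regresses log10 p(k) on log10 mean-k per bin;
    returns R^2, negated when the slope is positive (hub-free topology).
    """
    k = adjacency.sum(axis=1) - 1.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = np.polyval([slope, intercept], xs)
    ss_res = float(np.sum((np.array(ys) - pred) ** 2))
    ss_tot = float(np.sum((np.array(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def select_soft_power(expr: pd.DataFrame,
                      params: NetworkParams | None = None) -> int:
    """Smallest candidate power whose scale-free fit reaches the target;
    falls back to the argmax power with a warning when none does."""
    params = params or NetworkParams()
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    expr = _drop_constant_rows(expr)
    x = expr.to_numpy(float)
    best_p, best_fit = params.powers[0], -np.inf
    for p in params.powers:
        fit = scale_free_fit(_signed_adjacency(x, p))
        if fit >= params.scale_free_target:
            return p
        if fit > best_fit:
            best_p, best_fit = p, fit
    warnings.warn(f"no candidate power reached scale-free fit "
                  f"{params.scale_free_target}; using argmax power {best_p} "
                  f"(fit {best_fit:.3f})")
    return best_p


def signed_tom(expr: pd.DataFrame | np.ndarray, power: int) -> np.ndarray:
    """Signed topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; diagonal 1.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    a = _signed_adjacency(np.asarray(expr, dtype=float), power)
    return tom_from_adjacency(a)


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Topological overlap from a symmetric adjacency with unit diagonal."""
    a = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
    L = a @ a - 2.0 * a          # removes u=i and u=j terms (a_ii = 1)
    k = a.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, (L + a) / np.where(denom > 0, denom, 1.0),
                       0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(tom: np.ndarray,
                   params: NetworkParams | None = None,
                   gene_ids: list[str] | None = None) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    The cut sits at the largest gap among the upper half of merge heights —
    the gap separating within-module merges from near-root merges — which
    stays meaningful even when TOM dissimilarities saturate toward 1 at high
    soft powers; ``cut_height_fraction`` of the top merge height is the
    fallback for degenerate trees. Clusters smaller than ``min_module_size`` become label 0
    (unassigned);
    remaining modules are labelled 1, 2, ... by descending size (ties by
    smallest member gene id).
    """
    params = params or NetworkParams()
    tom = np.asarray(tom, float)
    if tom.shape[0] != tom.shape[1] or not np.allclose(tom, tom.T, atol=1e-8):
        raise ValueError("TOM must be square symmetric")
    if tom.shape[0] > params.max_block_size:
        raise ValueError(
            f"{tom.shape[0]} genes exceeds max block size "
            f"{params.max_block_size}; raise max_block_size if memory allows")
    gene_ids = gene_ids or [f"g{i}" for i in range(tom.shape[0])]
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    h = np.sort(Z[:, 2])
    upper = h[h.size // 2:]
    if upper.size >= 2:
        gaps = np.diff(upper)
        cut = float(upper[int(np.argmax(gaps))]) + 1e-12
    else:
        cut = float(params.cut_height_fraction * h[-1])
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = [lab for lab in sizes.index if sizes[lab] >= params.min_module_size]
    if not keep:
        raise ValueError("all clusters below min module size; "
                         "try a smaller min_module_size")
    order = sorted(keep, key=lambda lab: (-sizes[lab],
                                          min(g for g, r in zip(gene_ids, raw)
                                              if r == lab)))
    relabel = {lab: i + 1 for i, lab in enumerate(order)}
    labels = np.array([relabel.get(r, 0) for r in raw])
    return pd.Series(labels, index=gene_ids, name="module")


def residualize(values: np.ndarray, samples: pd.DataFrame,
                nuisance: tuple[str, ...]) -> np.ndarray:
    """OLS residuals of each row against intercept + nuisance covariates.

    With an empty nuisance set rows are returned unchanged (mean retained).
    """
    v = np.atleast_2d(np.asarray(values, float))
    if not nuisance:
        return v.copy()
    cols = [np.ones(len(samples))]
    for c in nuisance:
        col = samples[c]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, v.T, rcond=None)
    fitted = (X @ beta).T
    # keep the intercept so module means stay on the expression scale
    return v - fitted + fitted.mean(axis=1, keepdims=True)


def module_expression(logcpm: pd.DataFrame, samples: pd.DataFrame,
                      assignments: pd.Series,
                      nuisance: tuple[str, ...] = MODULE_EXPR_NUISANCE
                      ) -> pd.DataFrame:
    """Modules x samples mean of nuisance-corrected member expression."""
    labels = sorted(l for l in assignments.unique() if l != 0)
    if not labels:
        raise ValueError("no assigned modules")
    corrected = residualize(logcpm.to_numpy(float), samples, nuisance)
    corrected = pd.DataFrame(corrected, index=logcpm.index,
                             columns=logcpm.columns)
    rows = {lab: corrected.loc[assignments[assignments == lab].index].mean(axis=0)
            for lab in labels}
    return pd.DataFrame(rows).T.rename_axis("module")


def module_differential_expression(module_expr: pd.DataFrame,
                                   samples: pd.DataFrame,
                                   contrast: str = "case",
                                   covariates: tuple[str, ...] = MODULE_DE_COVARIATES
                                   ) -> pd.DataFrame:
    """Moderated-t differential expression of module means.

    With a single module empirical-Bayes moderation is impossible; the fit
    falls back to ordinary OLS (df_prior 0) and flags it.
    """
    X, names, ci = build_design_matrix(samples.loc[module_expr.columns],
                                       contrast, covariates)
    single = module_expr.shape[0] < 2
    fit = moderated_linear_fit(module_expr.to_numpy(float), X, ci,
                               df_prior=0.0 if single else None)
    out = pd.DataFrame({
        "module": module_expr.index,
        "log2fc": fit.coef,
        "t": fit.t,
        "p": fit.p,
        "q": bh_adjust(fit.p),
        "ols_fallback": single,
    })
    return out.reset_index(drop=True)


def hub_genes(assignments: pd.Series,
              adjacency: np.ndarray | None = None,
              gene_ids: list[str] | None = None,
              interaction_table: pd.DataFrame | None = None,
              score_threshold: float = 0.15) -> dict[int, str]:
    """Per-module hub gene by maximal intramodular connectivity.

    Connectivity is the sum of within-module adjacency (default) or, given
    an external interaction table (columns gene_a, gene_b, score), the
    within-module degree over edges with score > ``score_threshold``.
    Ties break to the lexicographically smaller gene id.
    """
    if (adjacency is None) == (interaction_table is None):
        raise ValueError("provide exactly one connectivity source")
    hubs: dict[int, str] = {}
    for lab in sorted(l for l in assignments.unique() if l != 0):
        members = list(assignments[assignments == lab].index)
        if not members:
            raise ValueError(f"module {lab} is empty")
        if adjacency is not None:
            ids = gene_ids or list(assignments.index)
            pos = {g: i for i, g in enumerate(ids)}
            idx = [pos[g] for g in members]
            sub = adjacency[np.ix_(idx, idx)]
            conn = sub.sum(axis=1) - np.diag(sub)
        else:
            mset = set(members)
            deg = {g: 0 for g in members}
            for r in interaction_table.itertuples():
                if r.score > score_threshold and r.gene_a in mset \
                        and r.gene_b in mset:
                    deg[r.gene_a] += 1
                    deg[r.gene_b] += 1
            conn = np.array([deg[g] for g in members], float)
        # tie-break: among max connectivity, smallest gene id
        top = conn.max()
        hubs[lab] = min(g for c, g in zip(conn, members) if c == top)
    return hubs


def module_graph(module_expr: pd.DataFrame,
                 r_threshold: float = 0.5) -> pd.DataFrame:
    """Undirected edges between modules with Pearson r strictly above the
    threshold (positive correlations only)."""
    if module_expr.shape[0] < 2:
        raise ValueError("need >= 2 modules")
    r = np.corrcoef(module_expr.to_numpy(float))
    labels = list(module_expr.index)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if r[i, j] > r_threshold:
                rows.append(dict(module_a=labels[i], module_b=labels[j],
                                 r=float(r[i, j])))
    return pd.DataFrame(rows, columns=["module_a", "module_b", "r"])
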