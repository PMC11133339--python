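"""Precision-weighted moderated linear-model differential expression.

This is the engine every association stage of the pipeline reuses: gene-level
case/control differential expression, module-level differential expression,
the differentially-methylated-CpG scan, and the conditional mediation models.

The model is the classic empirical-Bayes moderated t: each row (gene, module
or CpG) gets a weighted least-squares fit against a shared design matrix; the
per-row residual variances are then shrunk toward a common prior estimated by
method-of-moments on the log residual variances, and the t-statistic for the
contrast coefficient uses the shrunken (posterior) standard deviation with
``d0 + d`` degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "DesignSpec",
    "ModeratedFit",
    "log_cpm_transform",
    "estimate_precision_weights",
    "moderated_linear_fit",
    "bh_adjust",
    "estimate_latent_factors",
    "build_design_matrix",
    "run_differential_expression",
]

# Covariates of the primary case/control model (binary age group; site and
# batch enter as treatment-coded factors with lexicographic reference level).
DEFAULT_COVARIATES = ("age_group", "sex", "batch", "site", "rin", "gc", "pc1", "pc2")


@dataclass
class DesignSpec:
    """What to contrast and what to adjust for.

    contrast      -- name of the 0/1 outcome column in the sample table.
    covariates    -- adjustment columns (categoricals expanded on build).
    latent_k      -- number of residual-PCA latent factors; 0 = off,
                     "auto" = parallel analysis.
    use_weights   -- estimate mean-variance precision weights.
    """

    contrast: str = "case"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    latent_k: int | str = 0
    use_weights: bool = True


@dataclass
class ModeratedFit:
    """Per-row moderated fit for one design column of interest."""

    coef: np.ndarray            # per-row contrast coefficient
    stderr_unscaled: np.ndarray  # sqrt of the contrast diagonal of (X'WX)^-1
    sigma: np.ndarray           # per-row residual sd s
    df_residual: float          # residual df d (same for all rows)
    df_prior: float             # shared prior df d0 (may be inf)
    var_prior: float            # shared prior variance s0^2
    sigma_post: np.ndarray = field(default=None)  # posterior sd  s~
    t: np.ndarray = field(default=None)
    p: np.ndarray = field(default=None)

    @property
    def df_total(self) -> float:
        return self.df_prior + self.df_residual


def log_cpm_transform(counts: np.ndarray, lib_size: np.ndarray | None = None,
                      prior: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with a pseudocount.

    value = log2((count + prior) / (libsize + 1) * 1e6); libsize is the
    per-sample column sum unless given.
    """
    counts = np.asarray(counts, dtype=float)
    if lib_size is None:
        lib_size = counts.sum(axis=0)
    lib_size = np.asarray(lib_size, dtype=float)
    if np.any(lib_size <= 0):
        raise ValueError("library sizes must be positive")
    return np.log2((counts + prior) / (lib_size + 1.0) * 1e6)


def _row_wls(y: np.ndarray, X: np.ndarray, w: np.ndarray | None,
             coef_index: int | None = None):
    """Row-wise weighted least squares against a shared design.

    Returns (coef matrix or column, unscaled stderr, sigma, df, fitted)."""
    n, p = X.shape
    G = y.shape[0]
    d = n - p
    if d <= 0:
        raise ValueError("fewer samples than design columns")
    if w is None:
        Q, R = np.linalg.qr(X)
        B = np.linalg.solve(R, Q.T @ y.T).T          # G x p
        fitted = B @ X.T
        resid = y - fitted
        rss = np.einsum("ij,ij->i", resid, resid)
        XtXinv = np.linalg.inv(R.T @ R)
        unscaled = np.sqrt(np.diag(XtXinv))          # p
        sigma = np.sqrt(rss / d)
        if coef_index is None:
            return B, unscaled, sigma, d, fitted
        se = np.full(G, unscaled[coef_index])
        return B[:, coef_index], se, sigma, d, fitted
    # per-row weights: loop (G solves of an n x p system)
    coefs = np.empty((G, p))
    unscaled = np.empty((G, p))
    sigma = np.empty(G)
    fitted = np.empty_like(y)
    for g in range(G):
        sw = np.sqrt(w[g])
        Xw = X * sw[:, None]
        yw = y[g] * sw
        Q, R = np.linalg.qr(Xw)
        b = np.linalg.solve(R, Q.T @ yw)
        coefs[g] = b
        fitted[g] = X @ b
        rss = float(np.sum((yw - Xw @ b) ** 2))
        sigma[g] = np.sqrt(rss / d)
        unscaled[g] = np.sqrt(np.diag(np.linalg.inv(R.T @ R)))
    if coef_index is None:
        return coefs, unscaled, sigma, d, fitted
    return coefs[:, coef_index], unscaled[:, coef_index], sigma, d, fitted


def estimate_precision_weights(logcpm: np.ndarray, design: np.ndarray,
                               lib_size: np.ndarray,
                               span: float = 0.5,
                               min_genes: int = 50) -> np.ndarray:
    """Mean-variance precision weights for log-CPM values.

    Fits each row by OLS, regresses sqrt residual sd on mean log2 count by
    LOWESS (span 0.5), and sets each observation's weight to the inverse of
    the predicted variance at its fitted log-count. With fewer than
    ``min_genes`` rows the trend is unreliable and unit weights are returned
    with a warning.
    """
    logcpm = np.asarray(logcpm, dtype=float)
    G, n = logcpm.shape
    if G < min_genes:
        warnings.warn(
            f"only {G} rows (< {min_genes}); mean-variance trend unreliable, "
            "using unit weights")
        return np.ones_like(logcpm)
    coefs, _, sigma, d, fitted = _row_wls(logcpm, design, None)
    offset = np.mean(np.log2(lib_size + 1.0)) - np.log2(1e6)
    sx = logcpm.mean(axis=1) + offset          # mean log2 count per row
    sy = np.sqrt(sigma)                        # quarter-root variance
    ok = sigma > 0
    trend = lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    # predicted sqrt-sd at each observation's fitted log-count, clamped ends
    fitted_logcount = fitted + (np.log2(lib_size + 1.0) - np.log2(1e6))
    pred = np.interp(fitted_logcount, trend[:, 0], trend[:, 1])
    pred = np.clip(pred, 1e-6, None)
    return pred ** -4


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _squeeze_var(sigma2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Treats the residual variances as scaled F draws and matches moments of
    log(s^2); returns (d0, s0sq), d0 = inf when no excess spread remains.
    """
    s2 = sigma2[np.isfinite(sigma2) & (sigma2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_linear_fit(y: np.ndarray, design: np.ndarray,
                         coef_index: int,
                         weights: np.ndarray | None = None,
                         df_prior: float | None = None) -> ModeratedFit:
    """Row-wise (weighted) least squares with empirical-Bayes moderated t.

    ``coef_index`` selects the design column whose coefficient is tested.
    ``df_prior`` overrides the estimated prior df (0 disables moderation and
    reproduces ordinary per-row OLS/WLS t exactly).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _name_collinear_columns(X)
        raise ValueError(f"design matrix is rank deficient (columns {bad})")
    b, unscaled, sigma, d, _ = _row_wls(y, X, weights, coef_index)
    if df_prior is None:
        d0, s0sq = _squeeze_var(sigma ** 2, d)
    else:
        d0 = float(df_prior)
        s0sq = float(np.mean(sigma ** 2)) if d0 > 0 else 0.0
    if np.isinf(d0):
        sigma_post = np.full_like(sigma, np.sqrt(s0sq))
    elif d0 == 0:
        sigma_post = sigma.copy()
    else:
        sigma_post = np.sqrt((d0 * s0sq + d * sigma ** 2) / (d0 + d))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / (unscaled * sigma_post)
    df_total = d0 + d
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedFit(coef=b, stderr_unscaled=unscaled, sigma=sigma,
                        df_residual=d, df_prior=d0, var_prior=s0sq,
                        sigma_post=sigma_post, t=t, p=p)


def _name_collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of columns involved in a rank deficiency (by pivoted QR)."""
    from scipy.linalg import qr
    _, R, piv = qr(X, pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return sorted(int(piv[i]) for i in range(len(diag)) if diag[i] < tol)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def estimate_latent_factors(y: np.ndarray, design: np.ndarray,
                            k: int | str = "auto",
                            n_permutations: int = 20,
                            quantile: float = 0.95,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Latent-factor (unmeasured confounder) estimate by residual PCA.

    Regresses the design out of ``y`` and returns the top right singular
    vectors (sample scores) of the residual matrix. ``k="auto"`` keeps
    components whose eigenvalues exceed the 95th percentile of eigenvalues
    from column-permuted residual matrices (parallel analysis).
    Returns an (n_samples, k) matrix; k may be 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n = y.shape[1]
    _, _, _, _, fitted = _row_wls(y, X, None)
    resid = y - fitted
    resid = resid - resid.mean(axis=1, keepdims=True)
    max_rank = min(resid.shape) - X.shape[1]
    if isinstance(k, str):
        if k != "auto":
            raise ValueError("k must be an integer or 'auto'")
        rng = rng or np.random.default_rng(0)
        _, s, Vt = np.linalg.svd(resid, full_matrices=False)
        ev = s ** 2
        null_ev = np.empty((n_permutations, ev.size))
        for b in range(n_permutations):
            perm = np.empty_like(resid)
            for j in range(resid.shape[0]):
                perm[j] = rng.permutation(resid[j])
            null_ev[b] = np.linalg.svd(perm, compute_uv=False) ** 2
        thresh = np.quantile(null_ev, quantile, axis=0)
        keep = 0
        while keep < min(ev.size, max_rank) and ev[keep] > thresh[keep]:
            keep += 1
        k = keep
    else:
        if k >= max_rank:
            raise ValueError(f"k={k} >= residual rank {max_rank}")
        if k > 0:
            _, s, Vt = np.linalg.svd(resid, full_matrices=False)
    if k == 0:
        return np.empty((n, 0))
    return Vt[:k].T * s[:k]


def build_design_matrix(samples: pd.DataFrame, contrast: str,
                        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                        latent: np.ndarray | None = None
                        ) -> tuple[np.ndarray, list[str], int]:
    """Intercept + contrast + covariates (+ latent factors) design.

    Categorical covariates are treatment-coded with the lexicographically
    smallest level as reference so design matrices are reproducible.
    Returns (matrix, column names, index of the contrast column).
    """
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    y = samples[contrast]
    if y.dtype == object or str(y.dtype) == "category" or y.dtype == bool:
        levels = sorted(pd.unique(y.astype(str)))
        if len(levels) != 2:
            raise ValueError(f"contrast {contrast!r} must be binary")
        cols.append((y.astype(str) == levels[1]).to_numpy(float))
        names.append(f"{contrast}[{levels[1]}]")
    else:
        cols.append(y.to_numpy(float))
        names.append(contrast)
    contrast_index = 1
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"missing covariate column {cov!r}")
        col = samples[cov]
        if col.isna().any():
            raise ValueError(f"missing values in covariate {cov!r}")
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    if latent is not None and latent.size:
        X = np.hstack([X, latent])
        names += [f"latent{i + 1}" for i in range(latent.shape[1])]
    return X, names, contrast_index


def run_differential_expression(counts: pd.DataFrame, samples: pd.DataFrame,
                                design: DesignSpec | None = None,
                                seed: int = 0) -> pd.DataFrame:
    """Full case/control differential-expression stage.

    Composes log-CPM transform, optional precision weights, optional latent
    factors, the moderated fit and BH adjustment. ``counts`` is genes x
    samples with gene ids as index; ``samples`` rows align with columns.
    Returns a DataFrame (gene_id, log2fc, t, p, q) sorted by p.
    """
    design = design or DesignSpec()
    if list(counts.columns) != list(samples.index):
        samples = samples.loc[counts.columns]
    y_col = samples[design.contrast]
    vals = pd.unique(y_col)
    if len(vals) < 2:
        raise ValueError(f"contrast {design.contrast!r} is constant in this subset")
    lib = counts.to_numpy(float).sum(axis=0)
    logcpm = log_cpm_transform(counts.to_numpy(float), lib)
    X0, names, ci = build_design_matrix(samples, design.contrast, design.covariates)
    latent = None
    if design.latent_k != 0:
        latent = estimate_latent_factors(
            logcpm, X0, k=design.latent_k, rng=np.random.default_rng(seed))
    X, names, ci = build_design_matrix(samples, design.contrast,
                                       design.covariates, latent)
    w = None
    if design.use_weights:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = estimate_precision_weights(logcpm, X, lib)
    fit = moderated_linear_fit(logcpm, X, ci, weights=w)
    out = pd.DataFrame({
        "gene_id": counts.index,
        "log2fc": fit.coef,
        "t": fit.t,
        "p": fit.p,
        "q": bh_adjust(fit.p),
    })
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
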