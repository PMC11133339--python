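"""eQTM -> DMC -> conditional-mediation cascade.

Stage order (each consumes only survivors of the previous):
  1. pair selection — for each disease-associated gene, CpGs within 5 kb of
     the transcription start site (inclusive, either direction) or inside a
     promoter-capture HiC enhancer linked to the gene;
  2. eQTM scan — per-pair linear model of expression on methylation beta
     with the full covariate set plus latent factors; significant at p < 0.05;
  3. DMC scan — moderated linear model of beta on case status over the
     unique eQTM CpGs; Bonferroni threshold 0.05 / M;
  4. peak CpG per gene by joint model; conditional adjustment of the gene's
     disease effect for methylation at the peak CpG, reporting attenuation.

Expression is modelled as log2-CPM; methylation effects are on the beta
scale throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .de import (bh_adjust, build_design_matrix, estimate_latent_factors,
                 log_cpm_transform, moderated_linear_fit)
from .io import CpGAnnotation, GeneAnnotation, InteractionMap

__all__ = [
    "EqtmPair", "select_pairs", "eqtm_scan", "dmc_scan", "peak_eqtm",
    "conditional_mediation", "case_only_severity_assoc", "MediationResult",
]

EQTM_COVARIATES = ("case", "age_group", "sex", "batch", "site", "rin", "gc",
                   "pc1", "pc2")
DMC_COVARIATES = ("age_group", "sex", "site", "batch", "pc1", "pc2")
TSS_WINDOW = 5000


@dataclass(frozen=True)
class EqtmPair:
    gene_id: str
    cpg_id: str
    category: str       # 'tss5kb' or 'enhancer'
    distance: int       # strand-oriented bp from TSS (downstream positive)


@dataclass
class MediationResult:
    gene_id: str
    cpg_id: str
    log2fc_unadj: float
    p_unadj: float
    log2fc_adj: float
    p_adj: float
    attenuation: float | None
    verdict: str        # 'consistent-with-mediation' | 'not-attenuated'
    caution: bool = False


def select_pairs(genes: list[str], annotation: list[GeneAnnotation],
                 cpgs: list[CpGAnnotation],
                 interactions: InteractionMap | None = None,
                 window: int = TSS_WINDOW) -> list[EqtmPair]:
    """Candidate gene-CpG pairs by TSS window or linked enhancer.

    A pair satisfying both criteria is labelled tss5kb. Genes without
    annotation are skipped with a warning.
    """
    by_id = {g.gene_id: g for g in annotation}
    enh_trees: dict[tuple[str, str], IntervalTree] = {}
    if interactions is not None:
        for chrom, start, end, gid in interactions.links:
            enh_trees.setdefault((gid, chrom), IntervalTree()).addi(start, end)
    pairs: list[EqtmPair] = []
    seen: set[tuple[str, str]] = set()
    skipped = 0
    for gid in genes:
        g = by_id.get(gid)
        if g is None:
            skipped += 1
            continue
        for c in cpgs:
            if (gid, c.cpg_id) in seen:
                continue
            in_tss = c.chrom == g.chrom and abs(c.position - g.tss) <= window
            in_enh = False
            tree = enh_trees.get((gid, c.chrom))
            if tree is not None and tree.overlaps_point(c.position):
                in_enh = True
            if not (in_tss or in_enh):
                continue
            signed = (c.position - g.tss) if g.strand == "+" \
                else (g.tss - c.position)
            pairs.append(EqtmPair(gid, c.cpg_id,
                                  "tss5kb" if in_tss else "enhancer",
                                  int(signed)))
            seen.add((gid, c.cpg_id))
    if skipped:
        warnings.warn(f"{skipped} genes lacked annotation and were skipped")
    return pairs


def _common_samples(logcpm: pd.DataFrame, beta: pd.DataFrame,
                    samples: pd.DataFrame) -> list[str]:
    common = [s for s in logcpm.columns if s in set(beta.columns)
              and s in set(samples.index)]
    if not common:
        raise ValueError("no samples shared between expression and methylation")
    return common


def _ols_pvec(y: np.ndarray, X: np.ndarray, idx: int) -> tuple[float, float]:
    """Slope and two-sided p for column idx of a single OLS fit."""
    n, p = X.shape
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - rank
    s2 = float(resid @ resid) / df
    XtXinv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(s2 * XtXinv[idx, idx])
    t = coef[idx] / se if se > 0 else np.inf
    return float(coef[idx]), float(2.0 * stats.t.sf(abs(t), df))


def eqtm_scan(logcpm: pd.DataFrame, beta: pd.DataFrame,
              pairs: list[EqtmPair], samples: pd.DataFrame,
              latent_k: int | str = 60, seed: int = 0,
              sig_threshold: float = 0.05) -> pd.DataFrame:
    """Per-pair linear model of expression on methylation beta.

    Run on the samples shared by both matrices. Covariates: case status,
    age group, sex, batch, site, RIN, GC, ancestry PCs, plus ``latent_k``
    residual-PCA latent factors estimated from the expression matrix.
    Constant-beta CpGs are skipped and logged. Significance is p < 0.05.
    """
    common = _common_samples(logcpm, beta, samples)
    sub = samples.loc[common]
    expr = logcpm[common]
    meth = beta[common]
    X0, _, _ = build_design_matrix(sub, "case", EQTM_COVARIATES[1:])
    latent = None
    if latent_k == "auto":
        latent = estimate_latent_factors(expr.to_numpy(float), X0, k="auto",
                                         rng=np.random.default_rng(seed))
    elif latent_k:
        k = min(latent_k, len(common) - X0.shape[1] - 2)
        if k > 0:
            latent = estimate_latent_factors(expr.to_numpy(float), X0, k=k,
                                             rng=np.random.default_rng(seed))
    if latent is not None and latent.size == 0:
        latent = None
    X_cov, _, _ = build_design_matrix(sub, "case", EQTM_COVARIATES[1:], latent)
    rows = []
    skipped = 0
    for pair in pairs:
        if pair.gene_id not in expr.index or pair.cpg_id not in meth.index:
            skipped += 1
            continue
        b = meth.loc[pair.cpg_id].to_numpy(float)
        if np.ptp(b) == 0:
            skipped += 1
            continue
        X = np.column_stack([b[:, None], X_cov])
        slope, p = _ols_pvec(expr.loc[pair.gene_id].to_numpy(float), X, 0)
        rows.append(dict(gene_id=pair.gene_id, cpg_id=pair.cpg_id,
                         category=pair.category, distance=pair.distance,
                         slope=slope, p=p, significant=p < sig_threshold,
                         n=len(common)))
    if skipped:
        warnings.warn(f"{skipped} pairs skipped (missing rows or constant beta)")
    return pd.DataFrame(rows, columns=["gene_id", "cpg_id", "category",
                                       "distance", "slope", "p",
                                       "significant", "n"])


def dmc_scan(beta: pd.DataFrame, samples: pd.DataFrame,
             latent_k: int | str = 12, seed: int = 0,
             alpha: float = 0.05) -> pd.DataFrame:
    """Differential methylation over the eQTM CpG universe.

    Moderated linear fit of beta on case status with the DMC covariate set
    plus latent factors; Bonferroni threshold alpha / M where M is the
    number of CpGs actually tested.

    ``latent_k`` may be an integer or "auto" (parallel analysis). A fixed
    count suits panels the size it was chosen for; on small CpG panels a
    fixed k overfits noise and "auto" keeps the scan calibrated.
    """
    M = beta.shape[0]
    if M == 0:
        raise ValueError("empty CpG set")
    sub = samples.loc[beta.columns]
    X0, _, ci = build_design_matrix(sub, "case", DMC_COVARIATES)
    latent = None
    if latent_k == "auto":
        latent = estimate_latent_factors(beta.to_numpy(float), X0, k="auto",
                                         rng=np.random.default_rng(seed))
    elif latent_k:
        k = min(latent_k, min(M, len(sub)) - X0.shape[1] - 2)
        if k > 0:
            latent = estimate_latent_factors(beta.to_numpy(float), X0, k=k,
                                             rng=np.random.default_rng(seed))
    if latent is not None and latent.size == 0:
        latent = None
    X, _, ci = build_design_matrix(sub, "case", DMC_COVARIATES, latent)
    fit = moderated_linear_fit(beta.to_numpy(float), X, ci)
    threshold = alpha / M
    return pd.DataFrame({
        "cpg_id": beta.index,
        "effect": fit.coef,       # beta-scale case - control difference
        "t": fit.t,
        "p": fit.p,
        "bonferroni_threshold": threshold,
        "significant": fit.p < threshold,
    }).reset_index(drop=True)


def peak_eqtm(gene_id: str, cpg_ids: list[str], logcpm: pd.DataFrame,
              beta: pd.DataFrame, samples: pd.DataFrame,
              cpg_positions: dict[str, int] | None = None) -> str:
    """Peak CpG for a gene by joint model over its eQTM CpGs.

    One OLS of expression on all CpGs plus covariates; the peak is the CpG
    with the smallest joint-model p. Near-collinear CpGs (|r| > 0.999) keep
    the first by genomic position (falling back to list order) with a
    warning. Single-CpG genes return that CpG.
    """
    if not cpg_ids:
        raise ValueError("no eQTM CpGs supplied")
    if len(cpg_ids) == 1:
        return cpg_ids[0]
    common = _common_samples(logcpm, beta, samples)
    order = cpg_ids
    if cpg_positions:
        order = sorted(cpg_ids, key=lambda c: cpg_positions.get(c, 0))
    B = beta.loc[order, common].to_numpy(float)
    keep = []
    for i in range(len(order)):
        collinear = False
        for j in keep:
            r = np.corrcoef(B[i], B[j])[0, 1]
            if abs(r) > 0.999:
                collinear = True
                break
        if collinear:
            warnings.warn(f"{order[i]} nearly collinear with an earlier CpG; "
                          "dropped from the joint model")
        else:
            keep.append(i)
    kept_ids = [order[i] for i in keep]
    if len(kept_ids) == 1:
        return kept_ids[0]
    X_cov, _, _ = build_design_matrix(samples.loc[common], "case",
                                      EQTM_COVARIATES[1:])
    X = np.column_stack([B[keep].T, X_cov])
    y = logcpm.loc[gene_id, common].to_numpy(float)
    ps = [_ols_pvec(y, X, i)[1] for i in range(len(kept_ids))]
    return kept_ids[int(np.argmin(ps))]


def conditional_mediation(gene_id: str, cpg_id: str, logcpm: pd.DataFrame,
                          beta: pd.DataFrame, samples: pd.DataFrame,
                          attenuation_threshold: float = 0.5,
                          p_threshold: float = 0.05) -> MediationResult:
    """Disease-expression effect before and after adjusting for methylation.

    Two linear fits of the gene's log2-CPM on case status + covariates,
    differing only by the methylation beta column. Verdict is
    consistent-with-mediation iff attenuation >= 0.5 and the adjusted
    disease effect loses significance (p_adj > 0.05); thresholds
    configurable. A CpG nearly collinear with case status (point-biserial
    |r| > 0.99) is reported with a caution flag.
    """
    common = _common_samples(logcpm, beta, samples)
    sub = samples.loc[common]
    y = logcpm.loc[gene_id, common].to_numpy(float)
    b = beta.loc[cpg_id, common].to_numpy(float)
    X_un, _, ci = build_design_matrix(sub, "case", EQTM_COVARIATES[1:])
    lfc_un, p_un = _ols_pvec(y, X_un, ci)
    X_adj = np.column_stack([X_un, b])
    lfc_adj, p_adj = _ols_pvec(y, X_adj, ci)
    caution = False
    case = sub["case"].to_numpy(float)
    if np.std(b) > 0:
        r = float(np.corrcoef(case, b)[0, 1])
        caution = abs(r) > 0.99
    attenuation = None
    verdict = "not-attenuated"
    if lfc_un != 0:
        attenuation = 1.0 - lfc_adj / lfc_un
        if attenuation >= attenuation_threshold and p_adj > p_threshold:
            verdict = "consistent-with-mediation"
    return MediationResult(gene_id=gene_id, cpg_id=cpg_id,
                           log2fc_unadj=lfc_un, p_unadj=p_un,
                           log2fc_adj=lfc_adj, p_adj=p_adj,
                           attenuation=attenuation, verdict=verdict,
                           caution=caution)


def case_only_severity_assoc(beta_row: pd.Series, samples: pd.DataFrame,
                             covariates: tuple[str, ...] = ("age_group", "sex",
                                                            "site", "pc1", "pc2")
                             ) -> pd.DataFrame:
    """Case-only regressions of methylation on severity (CASI) and ICS use.

    Returns standardized coefficients and p-values for each predictor.
    Requires ``casi`` and ``ics_group`` columns; predictors without variance
    raise.
    """
    cases = samples[samples["case"] == 1]
    common = [s for s in cases.index if s in set(beta_row.index)]
    cases = cases.loc[common]
    y = beta_row[common].to_numpy(float)
    rows = []
    for name in ("casi", "ics_group"):
        col = cases[name]
        if name == "ics_group":
            x = (col.astype(str) == "moderate-high").to_numpy(float)
        else:
            x = col.to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"no variance in predictor {name!r}")
        xs = (x - x.mean()) / x.std()
        ys = (y - y.mean()) / y.std() if y.std() > 0 else y - y.mean()
        X_cov, _, _ = build_design_matrix(
            cases.assign(_pred=xs), "_pred", covariates)
        coef, p = _ols_pvec(ys, X_cov, 1)
        rows.append(dict(predictor=name, std_coef=coef, p=p, n=len(common)))
    return pd.DataFrame(rows)
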