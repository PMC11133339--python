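"""Replication of internal differential-expression hits against an external
meta-analysis summary table: identifier harmonization, hypergeometric
enrichment of the overlap, and direction concordance."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["ReplicationReport", "harmonize_ids", "hypergeometric_enrichment",
           "direction_concordance", "replication_report"]


@dataclass
class ReplicationReport:
    n_total: int            # genes tested in both analyses
    n_internal_sig: int
    n_external_sig: int
    n_overlap: int
    enrichment_p: float
    concordance: float | None    # fraction of overlap with equal sign
    n_nominal: int          # external p < 0.05, same direction, not in overlap
    external_sig_column: str = "q"

    def __post_init__(self):
        if not (self.n_overlap <= min(self.n_internal_sig, self.n_external_sig)
                <= self.n_total):
            raise ValueError("inconsistent replication counts")


def harmonize_ids(internal: pd.DataFrame, external: pd.DataFrame
                  ) -> pd.DataFrame:
    """Inner join of internal DEG results with the external table on gene id.

    External duplicates resolve to the row with the largest number of
    contributing studies k (ties: larger |effect|, then lexicographic id
    keeps the table deterministic).
    """
    ext = external.copy()
    ext["_abs_effect"] = ext["effect"].abs()
    ext = (ext.sort_values(["gene_id", "k", "_abs_effect"],
                           ascending=[True, False, False], kind="mergesort")
           .drop_duplicates("gene_id", keep="first")
           .drop(columns="_abs_effect"))
    merged = internal.merge(ext, on="gene_id", suffixes=("_int", "_ext"))
    if merged.empty:
        raise ValueError("no overlapping gene ids; check identifier spaces "
                         "(expected Ensembl-style ids on both sides)")
    return merged


def hypergeometric_enrichment(n_total: int, n_external_sig: int,
                              n_internal_sig: int, n_overlap: int) -> float:
    """Upper-tail P(X >= n_overlap), X ~ Hypergeom(n_total, n_external_sig,
    n_internal_sig)."""
    if not (0 <= n_overlap <= min(n_internal_sig, n_external_sig) <= n_total):
        raise ValueError("inconsistent counts for hypergeometric test")
    return float(hypergeom.sf(n_overlap - 1, n_total, n_external_sig,
                              n_internal_sig))


def direction_concordance(matched: pd.DataFrame, internal_sig: pd.Series,
                          external_sig: pd.Series
                          ) -> tuple[float | None, int]:
    """Sign concordance in the double-significant overlap, plus the count of
    nominal replications (external p < 0.05, same sign, outside the
    overlap). Zero-sign effects are excluded with a warning."""
    signs_int = np.sign(matched["log2fc"])
    signs_ext = np.sign(matched["effect"])
    zero = (signs_int == 0) | (signs_ext == 0)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes with zero-sign effects excluded")
    overlap = internal_sig & external_sig & ~zero
    concordance = None
    if overlap.any():
        concordance = float((signs_int[overlap] == signs_ext[overlap]).mean())
    nominal = (internal_sig & ~zero & ~(internal_sig & external_sig)
               & (matched["p_ext"] < 0.05)
               & (signs_int == signs_ext))
    return concordance, int(nominal.sum())


def replication_report(internal: pd.DataFrame, external: pd.DataFrame,
                       internal_q: float = 0.05,
                       external_q: float = 0.05) -> ReplicationReport:
    """Full replication stage.

    ``internal``: DEG table with gene_id, log2fc, p, q.
    ``external``: summary table with gene_id, effect, p, k and optionally q;
    external significance uses q when present, else p with a flag.
    """
    matched = harmonize_ids(internal, external)
    sig_col = "q_ext" if "q_ext" in matched.columns else (
        "q" if "q" in external.columns else "p_ext")
    internal_sig = matched["q_int" if "q_int" in matched else "q"] < internal_q
    external_sig = matched[sig_col] < external_q
    n_total = len(matched)
    n_overlap = int((internal_sig & external_sig).sum())
    concordance, n_nominal = direction_concordance(matched, internal_sig,
                                                   external_sig)
    p = hypergeometric_enrichment(n_total, int(external_sig.sum()),
                                  int(internal_sig.sum()), n_overlap)
    return ReplicationReport(
        n_total=n_total, n_internal_sig=int(internal_sig.sum()),
        n_external_sig=int(external_sig.sum()), n_overlap=n_overlap,
        enrichment_p=p, concordance=concordance, n_nominal=n_nominal,
        external_sig_column="q" if sig_col.startswith("q") else "p")
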