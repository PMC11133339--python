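"""Size-factor normalization and the two-part gene inclusion filter.

Size factors use the median-of-ratios method: each sample's factor is the
median, over genes expressed in every sample, of that sample's count divided
by the gene's geometric mean across samples. A gene passes the inclusion
filter when its mean normalized count is at least ``threshold`` (default 20)
and it is detected (count > 0, hence CPM > 0 at any library size) in at
least the fraction of samples equal to the case proportion of the analysed
subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormalizationResult", "size_factors", "mean_normalized_count",
           "filter_genes"]


@dataclass
class NormalizationResult:
    size_factors: np.ndarray          # per-sample, positive
    mean_normalized_count: np.ndarray  # per-gene


def size_factors(counts: np.ndarray | pd.DataFrame,
                 allow_pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    Reference genes are rows with all-nonzero counts. If none exist, either
    raise (default) or, with ``allow_pseudo_reference=True``, use each
    gene's geometric mean over its nonzero samples as the reference.
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2:
        raise ValueError("counts must be 2-D (genes x samples)")
    if m.shape[1] == 1:
        return np.ones(1)
    all_nonzero = np.all(m > 0, axis=1)
    if not all_nonzero.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has nonzero counts in all samples; rerun with "
                "allow_pseudo_reference=True to use a pseudo-reference")
        nz = m > 0
        use = nz.sum(axis=1) > 0
        logg = np.where(nz[use], np.log(np.where(nz[use], m[use], 1.0)), 0.0)
        geo = np.exp(logg.sum(axis=1) / nz[use].sum(axis=1))
        ratios = np.where(nz[use], m[use] / geo[:, None], np.nan)
        return np.nanmedian(ratios, axis=0)
    ref = m[all_nonzero]
    geo = np.exp(np.mean(np.log(ref), axis=1))
    return np.median(ref / geo[:, None], axis=0)


def mean_normalized_count(counts: np.ndarray | pd.DataFrame,
                          factors: np.ndarray) -> np.ndarray:
    """Per-gene mean of count / size-factor over samples."""
    m = np.asarray(counts, dtype=float)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    return (m / factors).mean(axis=1)


def filter_genes(counts: pd.DataFrame, samples: pd.DataFrame,
                 threshold: float = 20.0,
                 allow_pseudo_reference: bool = False) -> list[str]:
    """Gene ids passing the inclusion filter on the analysed subset.

    Retained iff mean normalized count >= threshold (inclusive) AND the gene
    has count > 0 in at least ceil(case_fraction * n_samples) samples, where
    case_fraction is the case proportion of ``samples``.
    """
    n_cases = int((samples["case"] == 1).sum())
    n_controls = int((samples["case"] == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("subset must contain both cases and controls")
    n = n_cases + n_controls
    min_detected = math.ceil(n_cases / n * n)
    f = size_factors(counts, allow_pseudo_reference=allow_pseudo_reference)
    mnc = mean_normalized_count(counts, f)
    detected = (counts.to_numpy() > 0).sum(axis=1)
    keep = (mnc >= threshold) & (detected >= min_detected)
    return [g for g, k in zip(counts.index, keep) if k]
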