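"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are 0-based half-open internally (BED convention);
the transcription start site of a '+' gene is ``start`` and of a '-' gene is
``end - 1``. Categorical sample-sheet columns keep lexicographically ordered
levels so downstream design matrices are reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "CpGAnnotation",
    "InteractionMap",
    "read_count_matrix",
    "read_beta_matrix",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_cpg_manifest",
    "write_cpg_manifest",
    "read_interactions",
    "write_interactions",
    "read_sample_table",
    "write_sample_table",
    "write_result_table",
    "read_result_table",
]

REQUIRED_SAMPLE_COLUMNS = (
    "case", "age_group", "sex", "site", "batch", "rin", "gc", "pc1", "pc2",
)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval; tss derived from strand."""
    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class CpGAnnotation:
    cpg_id: str
    chrom: str
    position: int  # 0-based

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"{self.cpg_id}: negative position")


@dataclass
class InteractionMap:
    """Enhancer-interval -> gene links from promoter-capture HiC."""
    links: list[tuple[str, int, int, str]]  # (chrom, start, end, gene_id)
    n_dropped: int = 0

    def genes(self) -> set[str]:
        return {g for *_, g in self.links}


def read_count_matrix(path, format: str = "tsv") -> pd.DataFrame:
    """Genes x samples integer count matrix.

    ``format="tsv"``: first column gene ids, header row sample ids.
    ``format="mtx-triplet"``: MatrixMarket coordinate file; row/col names are
    read from sibling files ``<path>.rownames`` / ``<path>.colnames``.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx-triplet":
        from scipy.io import mmread
        mat = np.asarray(mmread(str(path)).todense())
        rows = [l.strip() for l in open(f"{path}.rownames") if l.strip()]
        cols = [l.strip() for l in open(f"{path}.colnames") if l.strip()]
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        raise ValueError(f"unknown format {format!r}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    vals = df.to_numpy()
    if not np.all(np.isfinite(vals.astype(float))):
        raise ValueError("non-finite count entries")
    if np.any(vals.astype(float) % 1 != 0):
        raise ValueError("non-integer count")
    if np.any(vals.astype(float) < 0):
        raise ValueError("negative count")
    return df.astype(np.int64)


def read_beta_matrix(path) -> pd.DataFrame:
    """CpGs x samples methylation beta proportions in [0, 1]."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("beta values outside [0, 1]")
    return df


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """BED6 gene annotation (chrom, start, end, name, score, strand)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED columns")
            out.append(GeneAnnotation(gene_id=f[3], chrom=f[0],
                                      start=int(f[1]), end=int(f[2]),
                                      strand=f[5]))
    return out


def write_gene_annotation(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n")


def read_cpg_manifest(path) -> list[CpGAnnotation]:
    """TSV manifest: cpg_id, chrom, position (0-based)."""
    df = pd.read_csv(path, sep="\t")
    if df["cpg_id"].duplicated().any():
        raise ValueError("duplicate cpg ids in manifest")
    return [CpGAnnotation(r.cpg_id, r.chrom, int(r.position))
            for r in df.itertuples()]


def write_cpg_manifest(cpgs: list[CpGAnnotation], path) -> None:
    pd.DataFrame([(c.cpg_id, c.chrom, c.position) for c in cpgs],
                 columns=["cpg_id", "chrom", "position"]).to_csv(
        path, sep="\t", index=False)


def read_interactions(path, annotation: list[GeneAnnotation] | None = None,
                      promoter_window: int = 5000) -> InteractionMap:
    """BEDPE enhancer-gene links.

    Anchor A is the enhancer. The target gene comes from an optional 7th
    (name) column holding a gene id; otherwise anchor B is resolved by
    overlap with any gene's TSS +/- ``promoter_window``. Unresolvable rows
    are dropped with a warning, duplicates deduplicated.
    """
    by_id = {g.gene_id: g for g in (annotation or [])}
    links: list[tuple[str, int, int, str]] = []
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: expected >= 6 BEDPE columns")
            c1, s1, e1 = f[0], int(f[1]), int(f[2])
            c2, s2, e2 = f[3], int(f[4]), int(f[5])
            if s1 >= e1 or s2 >= e2:
                raise ValueError(f"{path}:{ln}: malformed interval")
            gene_id = None
            if len(f) >= 7 and f[6] in by_id:
                gene_id = f[6]
            elif len(f) >= 7 and f[6] not in {".", ""} and not annotation:
                gene_id = f[6]
            else:
                for g in (annotation or []):
                    if g.chrom == c2 and s2 < g.tss + promoter_window + 1 \
                            and e2 > g.tss - promoter_window:
                        gene_id = g.gene_id
                        break
            if gene_id is None:
                dropped += 1
                continue
            links.append((c1, s1, e1, gene_id))
    if dropped:
        warnings.warn(f"{dropped} interaction rows unresolvable to a gene; dropped")
    seen, uniq = set(), []
    for l in links:
        if l not in seen:
            seen.add(l)
            uniq.append(l)
    return InteractionMap(links=uniq, n_dropped=dropped)


def write_interactions(imap: InteractionMap, path) -> None:
    """BEDPE with the gene id in column 7 and its TSS point as anchor B."""
    with open(path, "w") as fh:
        for chrom, start, end, gene in imap.links:
            fh.write(f"{chrom}\t{start}\t{end}\t{chrom}\t0\t1\t{gene}\n")


def read_sample_table(path) -> pd.DataFrame:
    """Sample sheet with the pipeline's required covariates.

    Index = sample_id; categorical columns (sex, site, batch, age_group)
    become ordered categoricals with lexicographic levels; numeric covariates
    must be complete (the models carry no missing-data rule).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing required column(s): {missing}")
    for c in REQUIRED_SAMPLE_COLUMNS:
        if df[c].isna().any():
            raise ValueError(f"missing values in covariate {c!r}")
    for c in ("sex", "site", "batch", "age_group"):
        levels = sorted(df[c].astype(str).unique())
        df[c] = pd.Categorical(df[c].astype(str), categories=levels, ordered=True)
    df["case"] = df["case"].astype(int)
    return df


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=True, index_label="sample_id")


def write_result_table(df: pd.DataFrame, path, float_digits: int = 6) -> None:
    """Result TSV with fixed column order and 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
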