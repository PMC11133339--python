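"""Synthetic multi-omics cohorts with known ground truth.

Generates case/control cohorts with the statistical structure the analysis
assumes — negative-binomial RNA-seq counts with planted fold-changes,
correlated gene modules carrying case/control shifts, beta-valued
methylation with planted CpG -> gene -> disease mediation triplets, and the
full covariate sheet (site, batch, age group, sex, RIN, GC, ancestry PCs) —
so every downstream stage can be tested against known truth.

Default design mirrors a 253-case / 283-control cohort recruited across
seven sites with unequal case fractions. Counts follow NB(mean, dispersion)
with Var = mu + phi * mu^2; methylation noise lives on the M-value (logit)
scale and is reported as beta proportions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as _io

__all__ = [
    "CohortDesign", "PlantedEffects", "ModuleTruth", "EqtmTruth",
    "PhenotypeRecord", "generate_cohort", "derive_phenotype_flags",
    "generate_counts", "generate_methylation", "default_gene_universe",
    "default_cpg_universe", "simulate_risk_cohort", "mediation_effects",
    "write_bundle", "synthetic_replication_table", "default_effects",
]

DEFAULT_SITES = (
    ("Barbados", 0.45, 0.12),
    ("Brazil", 0.55, 0.10),
    ("Chicago", 0.47, 0.25),
    ("Denver", 0.40, 0.10),
    ("NewYork", 0.45, 0.15),
    ("Nigeria", 0.50, 0.13),
    ("Washington", 0.50, 0.15),
)


@dataclass
class CohortDesign:
    """Cohort size, site structure and sampling parameters."""

    n_cases: int = 253
    n_controls: int = 283
    sites: tuple[tuple[str, float, float], ...] = DEFAULT_SITES
    adult_fraction: float = 0.70
    seed: int = 0
    library_size_log_mean: float = math.log(8e6)
    library_size_log_sd: float = 0.25
    n_batches: int = 4

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        shares = sum(s[2] for s in self.sites)
        if abs(shares - 1.0) > 1e-9:
            raise ValueError(f"site sample-shares sum to {shares}, expected 1")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class ModuleTruth:
    """One planted co-expression module.

    ``loading`` scales a per-sample latent factor into each member gene's
    log2 expression; ``case_shift`` is the latent mean difference between
    cases and controls (the module-level signal the risk model sees).
    """
    label: str
    genes: tuple[str, ...]
    loading: float = 0.5
    case_shift: float = 0.0


@dataclass
class EqtmTruth:
    """One planted CpG -> gene (-> disease) triplet.

    slope: log2-CPM change per unit methylation beta.
    mediation: 'complete' (case status shifts the CpG; expression follows
    beta with no direct case term), 'partial' (both paths), or 'none'
    (CpG drives expression but carries no case shift).
    """
    gene_id: str
    cpg_id: str
    slope: float
    mediation: str = "none"
    cpg_case_shift: float = -0.3  # beta-scale case - control difference
    direct_log2fc: float = 0.0   # direct case term (partial/none types)

    def __post_init__(self):
        if self.mediation not in {"complete", "partial", "none"}:
            raise ValueError(f"unknown mediation type {self.mediation!r}")
        if not np.isfinite(self.slope):
            raise ValueError("eQTM slope must be finite")


@dataclass
class PlantedEffects:
    """Ground truth for one synthetic cohort."""

    deg_truth: tuple[tuple[str, float], ...] = ()
    module_truth: tuple[ModuleTruth, ...] = ()
    module_corr: np.ndarray | None = None  # inter-module latent correlation
    eqtm_truth: tuple[EqtmTruth, ...] = ()
    dispersion: float = 0.1
    biological_noise_sd: float = 0.35  # per-gene log2 sample-to-sample noise

    def __post_init__(self):
        seen: set[str] = set()
        for m in self.module_truth:
            for g in m.genes:
                if g in seen:
                    raise ValueError(f"gene {g} appears in more than one module")
                seen.add(g)
        for gid, lfc in self.deg_truth:
            if not np.isfinite(lfc):
                raise ValueError(f"non-finite log2FC for {gid}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def null_genes(self, universe: list[str]) -> list[str]:
        planted = {g for g, _ in self.deg_truth}
        planted |= {g for m in self.module_truth for g in m.genes}
        planted |= {t.gene_id for t in self.eqtm_truth}
        return [g for g in universe if g not in planted]


@dataclass
class PhenotypeRecord:
    """Raw questionnaire fields for one subject."""
    sample_id: str
    ever_asthma: bool
    casi: int
    total_ige: float    # KU/L
    phadiatop: float    # PAU
    medication_4b: int  # 0..5
    nasal_steroid_use: bool
    withheld_5d: bool


def default_gene_universe(n_genes: int = 2000) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def default_cpg_universe(n_cpgs: int = 5000) -> list[str]:
    return [f"cg{i:06d}" for i in range(n_cpgs)]


def _rng(design: CohortDesign, stream: int) -> np.random.Generator:
    """Independent child stream keyed on (seed, stream id)."""
    return np.random.default_rng([design.seed, stream])


def _site_allocation(design: CohortDesign) -> list[tuple[str, int, int]]:
    """(site, n_cases, n_controls) per site, matching totals exactly."""
    n = design.n_samples
    sizes = [int(round(share * n)) for _, _, share in design.sites]
    sizes[-1] += n - sum(sizes)
    cases = [int(round(cf * sz)) for (_, cf, _), sz in zip(design.sites, sizes)]
    # fix total case count on the largest site
    drift = design.n_cases - sum(cases)
    i = int(np.argmax(sizes))
    cases[i] = min(max(cases[i] + drift, 0), sizes[i])
    if sum(cases) != design.n_cases:  # pathological designs: spread remainder
        drift = design.n_cases - sum(cases)
        for j in range(len(cases)):
            room = sizes[j] - cases[j] if drift > 0 else cases[j]
            step = int(np.clip(drift, -room, room))
            cases[j] += step
            drift -= step
            if drift == 0:
                break
    return [(name, c, sz - c)
            for (name, _, _), sz, c in zip(design.sites, sizes, cases)]


def generate_cohort(design: CohortDesign
                    ) -> tuple[pd.DataFrame, list[PhenotypeRecord]]:
    """Sample sheet plus raw phenotype records for a cohort design.

    Covariate distributions (declared defaults): sex male ~ Bernoulli(0.38);
    age group adult ~ Bernoulli(adult_fraction); RIN ~ N(7.5, 0.8) clipped to
    [1, 10]; GC ~ N(0.47, 0.02); ancestry PCs ~ N(0, 0.05); batch assigned
    round-robin within site.
    """
    rng = _rng(design, 1)
    rows = []
    records: list[PhenotypeRecord] = []
    idx = 0
    for site, n_case, n_ctrl in _site_allocation(design):
        for case in ([1] * n_case + [0] * n_ctrl):
            sid = f"S{idx:04d}"
            batch = f"B{(idx % design.n_batches) + 1}"
            adult = rng.random() < design.adult_fraction
            male = rng.random() < 0.38
            rin = float(np.clip(rng.normal(7.5, 0.8), 1.0, 10.0))
            gc = float(rng.normal(0.47, 0.02))
            pc1, pc2 = rng.normal(0.0, 0.05, size=2)
            rows.append(dict(sample_id=sid, case=case, site=site, batch=batch,
                             age_group="adult" if adult else "pediatric",
                             sex="M" if male else "F", rin=rin, gc=gc,
                             pc1=float(pc1), pc2=float(pc2)))
            if case:
                casi = 1 + int(rng.poisson(3.0))
                ige = float(rng.lognormal(5.5, 1.2))
                phadiatop = float(rng.lognormal(0.0, 1.0))
                med = int(rng.integers(0, 6))
            else:
                casi = 0
                ige = float(rng.lognormal(3.5, 1.2))
                phadiatop = float(rng.lognormal(-1.5, 1.0))
                med = 0
            ns = bool(case and rng.random() < 0.27)
            records.append(PhenotypeRecord(
                sample_id=sid, ever_asthma=bool(case), casi=casi,
                total_ige=ige, phadiatop=phadiatop, medication_4b=med,
                nasal_steroid_use=ns,
                withheld_5d=bool(ns and rng.random() < 0.53)))
            idx += 1
    samples = pd.DataFrame(rows).set_index("sample_id")
    for c in ("sex", "site", "batch", "age_group"):
        levels = sorted(samples[c].unique())
        samples[c] = pd.Categorical(samples[c], categories=levels, ordered=True)
    flags = derive_phenotype_flags(records)
    return samples.join(flags), records


def derive_phenotype_flags(records: list[PhenotypeRecord]) -> pd.DataFrame:
    """Derived phenotype columns.

    atopy            := phadiatop >= 0.36 PAU  OR  total IgE > 100 KU/L
    current_asthma   := ever_asthma AND CASI >= 1
    ics_group        := 'moderate-high' iff question-4b score in 2..5,
                        else 'low' (no treatment or albuterol as needed).
    """
    rows = []
    for r in records:
        if r.casi < 0 or r.total_ige < 0:
            raise ValueError(f"{r.sample_id}: negative CASI or IgE")
        rows.append(dict(
            sample_id=r.sample_id,
            casi=r.casi,
            current_asthma=bool(r.ever_asthma and r.casi >= 1),
            atopy=bool(r.phadiatop >= 0.36 or r.total_ige > 100.0),
            ics_group="moderate-high" if 2 <= r.medication_4b <= 5 else "low",
            nasal_steroid_use=r.nasal_steroid_use,
            withheld_5d=r.withheld_5d,
        ))
    return pd.DataFrame(rows).set_index("sample_id")


def _mediation_mvalues(design: CohortDesign, effects: PlantedEffects,
                       case: np.ndarray, m_noise_sd: float = 0.45
                       ) -> dict[str, np.ndarray]:
    """Per-triplet CpG M-values, shared by count and methylation generation.

    For triplets with a case shift, control/case beta means straddle 0.5 by
    +/- shift/2 so the realised beta-scale difference matches the planted
    shift. Drawn from a child stream keyed only on the design seed so
    ``generate_counts`` and ``generate_methylation`` agree.
    """
    rng = np.random.default_rng([design.seed, 77])
    out: dict[str, np.ndarray] = {}
    for t in effects.eqtm_truth:
        shift = t.cpg_case_shift if t.mediation in {"complete", "partial"} else 0.0
        beta_ctrl = 0.5 - shift / 2.0
        beta_case = 0.5 + shift / 2.0
        mu = np.where(case == 1, logit(beta_case), logit(beta_ctrl))
        out[t.cpg_id] = mu + rng.normal(0.0, m_noise_sd, size=case.shape)
    return out


def generate_counts(design: CohortDesign, effects: PlantedEffects,
                    samples: pd.DataFrame,
                    gene_ids: list[str] | None = None) -> pd.DataFrame:
    """NB count matrix with planted fold-changes, modules and nuisance.

    mean_gs = libsize_s * baseline_g * 2^(case*log2FC) * 2^(loading*latent)
              * 2^(slope*(beta-1/2))  [mediation genes]
              * batch/GC multipliers;   Var = mu + phi mu^2.
    """
    gene_ids = gene_ids or default_gene_universe()
    referenced = ({g for g, _ in effects.deg_truth}
                  | {g for m in effects.module_truth for g in m.genes}
                  | {t.gene_id for t in effects.eqtm_truth})
    missing = referenced - set(gene_ids)
    if missing:
        raise ValueError(f"effects reference genes outside the universe: "
                         f"{sorted(missing)[:5]}")
    G, n = len(gene_ids), len(samples)
    case = samples["case"].to_numpy(int)
    rng_base = _rng(design, 2)      # gene baselines: stable per seed
    rng = _rng(design, 3)           # everything else
    log_base = rng_base.normal(0.0, 1.5, size=G)
    baseline = np.exp(log_base)
    baseline /= baseline.sum()
    lib = rng.lognormal(design.library_size_log_mean,
                        design.library_size_log_sd, size=n)

    log2fold = np.zeros((G, n))
    gi = {g: i for i, g in enumerate(gene_ids)}
    for g, lfc in effects.deg_truth:
        log2fold[gi[g]] += lfc * case

    # module latents: MVN over modules with case/control mean shifts
    K = len(effects.module_truth)
    if K:
        R = effects.module_corr
        if R is None:
            R = np.eye(K)
        L = np.linalg.cholesky(np.asarray(R, float))
        z = rng.normal(size=(n, K)) @ L.T
        shifts = np.array([m.case_shift for m in effects.module_truth])
        z = z + case[:, None] * shifts[None, :]
        for k, m in enumerate(effects.module_truth):
            for g in m.genes:
                log2fold[gi[g]] += m.loading * z[:, k]

    # mediation triplets: expression follows methylation beta
    mvals = _mediation_mvalues(design, effects, case)
    for t in effects.eqtm_truth:
        beta = expit(mvals[t.cpg_id])
        row = gi[t.gene_id]
        log2fold[row] += t.slope * (beta - 0.5)
        if t.mediation in {"partial", "none"} and t.direct_log2fc:
            log2fold[row] += t.direct_log2fc * case

    # nuisance: per-gene batch offsets and GC sensitivity (adjusted covariates)
    batches = samples["batch"].astype(str).to_numpy()
    blevels = sorted(set(batches))
    bcode = np.array([blevels.index(b) for b in batches])
    batch_fx = rng.normal(0.0, 0.1, size=(G, len(blevels)))
    log2fold += batch_fx[:, bcode]
    gc = samples["gc"].to_numpy(float)
    gc_fx = rng.normal(0.0, 2.0, size=G)
    log2fold += gc_fx[:, None] * (gc - gc.mean())[None, :]

    # per-gene biological variation beyond counting noise; keeps disease
    # status a minor share of total variance, as in real cohorts
    if effects.biological_noise_sd > 0:
        log2fold += rng.normal(0.0, effects.biological_noise_sd, size=(G, n))

    mu = lib[None, :] * baseline[:, None] * np.exp2(log2fold)
    phi = effects.dispersion
    r = 1.0 / phi
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=gene_ids, columns=samples.index)


def generate_methylation(design: CohortDesign, effects: PlantedEffects,
                         samples: pd.DataFrame,
                         cpg_ids: list[str] | None = None,
                         m_noise_sd: float = 0.45) -> pd.DataFrame:
    """Beta-valued methylation matrix (CpGs x samples).

    Null CpGs get Gaussian M-values around a per-CpG baseline; planted
    triplet CpGs reproduce exactly the M-values the count generator used,
    so mediated expression is consistent across the two matrices.
    """
    cpg_ids = cpg_ids or default_cpg_universe()
    missing = {t.cpg_id for t in effects.eqtm_truth} - set(cpg_ids)
    if missing:
        raise ValueError(f"effects reference CpGs outside the universe: "
                         f"{sorted(missing)[:5]}")
    n = len(samples)
    case = samples["case"].to_numpy(int)
    rng = _rng(design, 4)
    ci = {c: i for i, c in enumerate(cpg_ids)}
    mu0 = rng.normal(0.0, 1.5, size=len(cpg_ids))
    M = mu0[:, None] + rng.normal(0.0, m_noise_sd, size=(len(cpg_ids), n))
    for cpg, mv in _mediation_mvalues(design, effects, case,
                                      m_noise_sd=m_noise_sd).items():
        M[ci[cpg]] = mv
    return pd.DataFrame(expit(M), index=cpg_ids, columns=samples.index)


def simulate_risk_cohort(n: int, beta: float, k_modules: int = 3,
                         intercept: float | None = None,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Direct draw from the additive cumulative-risk model.

    Each subject carries ``k_modules`` independent Bernoulli(0.5) risk
    indicators; disease status follows logit P = intercept + beta * count.
    Returns (count, status). Default intercept centers prevalence at 0.5
    for the median count.
    """
    rng = np.random.default_rng(seed)
    ind = rng.random((n, k_modules)) < 0.5
    count = ind.sum(axis=1)
    if intercept is None:
        intercept = -beta * k_modules / 2.0
    p = expit(intercept + beta * count)
    status = (rng.random(n) < p).astype(int)
    return count, status


def mediation_effects(n_complete: int = 10, n_none: int = 10,
                      slope: float = 2.0, cpg_case_shift: float = -0.3,
                      direct_log2fc: float = 0.6,
                      gene_ids: list[str] | None = None,
                      cpg_ids: list[str] | None = None) -> PlantedEffects:
    """Standard mediation test bundle: complete triplets whose disease
    signal flows entirely through the CpG, and none-type triplets whose
    genes carry an equal-sized direct disease effect with a case-independent
    eQTM CpG."""
    gene_ids = gene_ids or default_gene_universe()
    cpg_ids = cpg_ids or default_cpg_universe()
    triplets = []
    for i in range(n_complete):
        triplets.append(EqtmTruth(gene_ids[i], cpg_ids[i], slope=slope,
                                  mediation="complete",
                                  cpg_case_shift=cpg_case_shift))
    for i in range(n_none):
        j = n_complete + i
        triplets.append(EqtmTruth(gene_ids[j], cpg_ids[j], slope=slope,
                                  mediation="none",
                                  direct_log2fc=direct_log2fc))
    return PlantedEffects(eqtm_truth=tuple(triplets))


def synthetic_replication_table(effects: PlantedEffects,
                                gene_ids: list[str],
                                seed: int = 0,
                                frac_replicated: float = 0.6) -> pd.DataFrame:
    """SYNTHETIC external meta-analysis summary table over the full gene
    universe.

    Stand-in for a real replication resource: planted disease genes
    replicate (small p, same direction) with probability
    ``frac_replicated``; all other genes carry null p-values and random
    small effects. Columns: gene_id, effect, p, q, k.
    """
    rng = np.random.default_rng(seed)
    planted = dict(effects.deg_truth)
    for m in effects.module_truth:
        for g in m.genes:
            planted.setdefault(g, m.loading * m.case_shift)
    for t in effects.eqtm_truth:
        lfc = t.slope * t.cpg_case_shift if t.mediation != "none" \
            else t.direct_log2fc
        planted.setdefault(t.gene_id, lfc)
    rows = []
    for g in gene_ids:
        lfc = planted.get(g, 0.0)
        sig = lfc != 0.0 and rng.random() < frac_replicated
        p = float(rng.uniform(1e-8, 1e-4)) if sig else float(rng.uniform())
        eff = (np.sign(lfc) if lfc else rng.choice([-1.0, 1.0])) \
            * abs(rng.normal(0.5, 0.2))
        rows.append(dict(gene_id=g, effect=float(eff), p=p,
                         k=int(rng.integers(2, 9))))
    df = pd.DataFrame(rows)
    from .de import bh_adjust
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def _gene_annotation(gene_ids: list[str]) -> list[_io.GeneAnnotation]:
    """Synthetic annotation: genes tiled on chr1 every 100 kb, 10 kb long,
    alternating strand."""
    out = []
    for i, g in enumerate(gene_ids):
        start = 50_000 + i * 100_000
        out.append(_io.GeneAnnotation(g, "chr1", start, start + 10_000,
                                      "+" if i % 2 == 0 else "-"))
    return out


def _cpg_annotation(cpg_ids: list[str], genes: list[_io.GeneAnnotation],
                    effects: PlantedEffects, seed: int
                    ) -> tuple[list[_io.CpGAnnotation], _io.InteractionMap]:
    """Synthetic CpG manifest + enhancer links.

    Triplet CpGs alternate between lying inside the 5 kb TSS window and
    sitting in a distal enhancer linked to the gene; other CpGs land within
    5 kb of a random gene TSS (eligible pairs) or far from any gene.
    """
    rng = np.random.default_rng([seed, 5])
    by_gene = {g.gene_id: g for g in genes}
    placed: dict[str, tuple[str, int]] = {}
    links: list[tuple[str, int, int, str]] = []
    for i, t in enumerate(effects.eqtm_truth):
        g = by_gene[t.gene_id]
        if i % 2 == 0:
            placed[t.cpg_id] = (g.chrom, g.tss + int(rng.integers(-4500, 4500)))
        else:
            enh_start = g.tss + 40_000
            links.append((g.chrom, enh_start, enh_start + 2_000, g.gene_id))
            placed[t.cpg_id] = (g.chrom, enh_start + 1_000)
    for c in cpg_ids:
        if c in placed:
            continue
        if rng.random() < 0.6:
            g = genes[int(rng.integers(0, len(genes)))]
            placed[c] = (g.chrom, max(0, g.tss + int(rng.integers(-4500, 4500))))
        else:
            placed[c] = ("chr1", int(rng.integers(0, 40_000)))
    manifest = [_io.CpGAnnotation(c, *placed[c]) for c in cpg_ids]
    return manifest, _io.InteractionMap(links=links)


def write_bundle(design: CohortDesign, effects: PlantedEffects, outdir,
                 gene_ids: list[str] | None = None,
                 cpg_ids: list[str] | None = None) -> dict:
    """Generate a full cohort and write every pipeline input to ``outdir``.

    Files: counts.tsv, beta.tsv, samples.tsv, genes.bed, cpgs.tsv,
    interactions.bedpe, external_meta.tsv (synthetic replication resource
    over the full gene universe), truth.json. Returns the in-memory bundle
    as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_ids = gene_ids or default_gene_universe()
    cpg_ids = cpg_ids or default_cpg_universe()
    samples, records = generate_cohort(design)
    counts = generate_counts(design, effects, samples, gene_ids)
    beta = generate_methylation(design, effects, samples, cpg_ids)
    genes = _gene_annotation(gene_ids)
    manifest, interactions = _cpg_annotation(cpg_ids, genes, effects,
                                             design.seed)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    beta.to_csv(outdir / "beta.tsv", sep="\t", index_label="cpg_id",
                float_format="%.6g")
    _io.write_sample_table(samples, outdir / "samples.tsv")
    _io.write_gene_annotation(genes, outdir / "genes.bed")
    _io.write_cpg_manifest(manifest, outdir / "cpgs.tsv")
    _io.write_interactions(interactions, outdir / "interactions.bedpe")
    external = synthetic_replication_table(effects, gene_ids,
                                           seed=design.seed)
    external.to_csv(outdir / "external_meta.tsv", sep="\t", index=False,
                    float_format="%.6g")
    truth = {
        "design": {k: v for k, v in asdict(design).items() if k != "sites"},
        "sites": [list(s) for s in design.sites],
        "deg_truth": [list(t) for t in effects.deg_truth],
        "module_truth": [dict(label=m.label, genes=list(m.genes),
                              loading=m.loading, case_shift=m.case_shift)
                         for m in effects.module_truth],
        "eqtm_truth": [dict(gene_id=t.gene_id, cpg_id=t.cpg_id,
                            slope=t.slope, mediation=t.mediation,
                            cpg_case_shift=t.cpg_case_shift,
                            direct_log2fc=t.direct_log2fc)
                       for t in effects.eqtm_truth],
        "dispersion": effects.dispersion,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return dict(samples=samples, records=records, counts=counts, beta=beta,
                genes=genes, cpgs=manifest, interactions=interactions,
                external=external, truth=truth)


def default_effects(gene_ids: list[str] | None = None,
                    cpg_ids: list[str] | None = None,
                    n_deg: int = 60, n_modules: int = 3,
                    module_size: int = 30,
                    seed: int = 0) -> PlantedEffects:
    """Default planted truth for the demo bundle: a spread of fold-changes,
    three correlated case-shifted modules, and a mix of mediation triplets."""
    gene_ids = gene_ids or default_gene_universe()
    cpg_ids = cpg_ids or default_cpg_universe()
    rng = np.random.default_rng([seed, 6])
    ptr = 0
    deg = []
    for _ in range(n_deg):
        lfc = float(rng.choice([-1.0, -0.6, -0.4, 0.4, 0.6, 1.0]))
        deg.append((gene_ids[ptr], lfc))
        ptr += 1
    modules = []
    shifts = [0.5, -0.5, 0.4]
    for k in range(n_modules):
        genes = tuple(gene_ids[ptr:ptr + module_size])
        ptr += module_size
        modules.append(ModuleTruth(label=f"M{k + 1}", genes=genes,
                                   loading=0.6, case_shift=shifts[k % 3]))
    corr = np.eye(n_modules)
    for a in range(n_modules):
        for b in range(a + 1, n_modules):
            corr[a, b] = corr[b, a] = 0.3
    triplets = []
    for i in range(6):
        med = "complete" if i < 3 else "none"
        triplets.append(EqtmTruth(gene_ids[ptr], cpg_ids[i], slope=2.0,
                                  mediation=med,
                                  direct_log2fc=0.6 if med == "none" else 0.0))
        ptr += 1
    return PlantedEffects(deg_truth=tuple(deg), module_truth=tuple(modules),
                          module_corr=corr, eqtm_truth=tuple(triplets))
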