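import warnings

import numpy as np
import pandas as pd
import pytest

from triaxis.io import CpGAnnotation, GeneAnnotation, InteractionMap
from triaxis.methylation import (case_only_severity_assoc,
                                 conditional_mediation, dmc_scan, eqtm_scan,
                                 peak_eqtm, select_pairs)


def pairs_bruteforce(genes, annotation, cpgs, interactions, window=5000):
    """Literal window/enhancer predicate over all (gene, CpG) combinations."""
    by_id = {g.gene_id: g for g in annotation}
    out = set()
    for gid in genes:
        g = by_id.get(gid)
        if g is None:
            continue
        for c in cpgs:
            tss_hit = (c.chrom == g.chrom and abs(c.position - g.tss) <= window)
            enh_hit = any(gid2 == gid and c.chrom == ch and s <= c.position < e
                          for ch, s, e, gid2 in (interactions.links
                                                 if interactions else []))
            if tss_hit or enh_hit:
                out.add((gid, c.cpg_id, "tss5kb" if tss_hit else "enhancer"))
    return out


def _samples(rng, n=120):
    df = pd.DataFrame({
        "case": (np.arange(n) % 2),
        "age_group": rng.choice(["adult", "pediatric"], n),
        "sex": rng.choice(["F", "M"], n),
        "site": rng.choice(["A", "B", "C"], n),
        "batch": rng.choice(["B1", "B2"], n),
        "rin": rng.normal(7, 1, n), "gc": rng.normal(0.47, 0.02, n),
        "pc1": rng.normal(0, 0.05, n), "pc2": rng.normal(0, 0.05, n),
        "casi": 0, "ics_group": "low",
    }, index=[f"S{i}" for i in range(n)])
    cases = df["case"] == 1
    df.loc[cases, "casi"] = rng.integers(1, 12, int(cases.sum()))
    df.loc[cases, "ics_group"] = rng.choice(["low", "moderate-high"],
                                            int(cases.sum()))
    return df


class TestSelectPairs:
    ANN = [GeneAnnotation("g1", "chr1", 100_000, 110_000, "+"),
           GeneAnnotation("g2", "chr1", 300_000, 310_000, "-")]

    def test_window_boundaries_inclusive(self):
        cpgs = [CpGAnnotation("c_in", "chr1", 104_999),
                CpGAnnotation("c_edge", "chr1", 105_000),
                CpGAnnotation("c_out", "chr1", 105_001)]
        pairs = select_pairs(["g1"], self.ANN, cpgs)
        got = {p.cpg_id: p for p in pairs}
        assert set(got) == {"c_in", "c_edge"}
        assert got["c_in"].distance == 4_999

    def test_strand_oriented_distance(self):
        # g2 is '-' strand: tss = 309_999; upstream = larger coordinates
        cpgs = [CpGAnnotation("c", "chr1", 309_000)]
        (p,) = select_pairs(["g2"], self.ANN, cpgs)
        assert p.distance == 999  # downstream of the '-' TSS

    def test_enhancer_link_and_priority_of_tss_label(self):
        imap = InteractionMap(links=[("chr1", 200_000, 201_000, "g1"),
                                     ("chr1", 100_000, 120_000, "g1")])
        cpgs = [CpGAnnotation("c_enh", "chr1", 200_500),
                CpGAnnotation("c_both", "chr1", 101_000)]
        pairs = {p.cpg_id: p for p in
                 select_pairs(["g1"], self.ANN, cpgs, imap)}
        assert pairs["c_enh"].category == "enhancer"
        assert pairs["c_both"].category == "tss5kb"  # satisfies both

    def test_missing_annotation_warns_and_skips(self):
        with pytest.warns(UserWarning, match="lacked annotation"):
            pairs = select_pairs(["unknown"], self.ANN,
                                 [CpGAnnotation("c", "chr1", 100_000)])
        assert pairs == []

    def test_matches_bruteforce_on_random_toys(self, rng):
        for trial in range(5):
            g = np.random.default_rng(trial)
            starts = [int(g.integers(0, 5e5)) * 2 for _ in range(20)]
            ann = [GeneAnnotation(f"g{i}", f"chr{g.integers(1, 3)}",
                                  s, s + 10_000, str(g.choice(["+", "-"])))
                   for i, s in enumerate(starts)]
            cpgs = [CpGAnnotation(f"c{i}", f"chr{g.integers(1, 3)}",
                                  int(g.integers(0, 1_010_000)))
                    for i in range(80)]
            links = [(a.chrom, a.tss + 20_000, a.tss + 22_000, a.gene_id)
                     for a in ann[:5]]
            imap = InteractionMap(links=links)
            genes = [a.gene_id for a in ann]
            got = {(p.gene_id, p.cpg_id, p.category)
                   for p in select_pairs(genes, ann, cpgs, imap)}
            assert got == pairs_bruteforce(genes, ann, cpgs, imap)


class TestEqtmScan:
    def test_exact_linear_relation_recovered(self, rng):
        samples = _samples(rng)
        n = len(samples)
        beta = pd.DataFrame([rng.uniform(0.2, 0.8, n)], index=["c1"],
                            columns=samples.index)
        expr = pd.DataFrame([2.0 * beta.loc["c1"]], index=["g1"],
                            columns=samples.index)
        from triaxis.methylation import EqtmPair
        res = eqtm_scan(expr, beta, [EqtmPair("g1", "c1", "tss5kb", 0)],
                        samples, latent_k=0)
        assert res.iloc[0]["slope"] == pytest.approx(2.0, abs=1e-8)
        assert res.iloc[0]["p"] < 1e-20
        assert res.iloc[0]["significant"]

    def test_intersection_rule_drops_unshared_samples(self, rng):
        samples = _samples(rng)
        beta = pd.DataFrame([rng.uniform(0.2, 0.8, len(samples))],
                            index=["c1"], columns=samples.index)
        expr_cols = samples.index[:-10]  # ten samples lack methylation
        expr = pd.DataFrame([rng.normal(size=len(expr_cols))], index=["g1"],
                            columns=expr_cols)
        from triaxis.methylation import EqtmPair
        res = eqtm_scan(expr, beta, [EqtmPair("g1", "c1", "tss5kb", 0)],
                        samples, latent_k=0)
        assert res.iloc[0]["n"] == len(expr_cols)

    def test_constant_beta_skipped_with_warning(self, rng):
        samples = _samples(rng)
        n = len(samples)
        beta = pd.DataFrame([np.full(n, 0.5)], index=["c1"],
                            columns=samples.index)
        expr = pd.DataFrame([rng.normal(size=n)], index=["g1"],
                            columns=samples.index)
        from triaxis.methylation import EqtmPair
        with pytest.warns(UserWarning, match="skipped"):
            res = eqtm_scan(expr, beta, [EqtmPair("g1", "c1", "tss5kb", 0)],
                            samples, latent_k=0)
        assert res.empty


class TestDmcScan:
    def test_bonferroni_threshold_from_tested_count(self, rng):
        samples = _samples(rng)
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, (915, len(samples))),
                            index=[f"c{i}" for i in range(915)],
                            columns=samples.index)
        res = dmc_scan(beta, samples, latent_k=0)
        assert res["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / 915)

    def test_planted_shift_recovered_and_significant(self, rng):
        samples = _samples(rng, n=300)
        n = len(samples)
        case = samples["case"].to_numpy(float)
        from scipy.special import expit, logit
        rows = []
        for i in range(50):
            mu = np.where(case == 1, logit(0.35), logit(0.65)) if i == 0 \
                else np.full(n, logit(0.5))
            rows.append(expit(mu + rng.normal(0, 0.15, n)))
        beta = pd.DataFrame(rows, index=[f"c{i}" for i in range(50)],
                            columns=samples.index)
        res = dmc_scan(beta, samples, latent_k=0).set_index("cpg_id")
        assert res.loc["c0", "effect"] == pytest.approx(-0.3, abs=0.05)
        assert res.loc["c0", "significant"]

    def test_empty_set_rejected(self, rng):
        samples = _samples(rng)
        with pytest.raises(ValueError, match="empty"):
            dmc_scan(pd.DataFrame(columns=samples.index), samples)


class TestPeakEqtm:
    def test_single_cpg_returned_directly(self, rng):
        assert peak_eqtm("g", ["c9"], None, None, None) == "c9"

    def test_driver_cpg_beats_correlated_passenger(self):
        hits = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            samples = _samples(g)
            n = len(samples)
            a = g.uniform(0.2, 0.8, n)
            b = 0.7 * a + 0.3 * g.uniform(0.2, 0.8, n)  # r ~ 0.9 with a
            expr = pd.DataFrame([3.0 * a + g.normal(0, 0.2, n)],
                                index=["g1"], columns=samples.index)
            beta = pd.DataFrame([a, b], index=["cA", "cB"],
                                columns=samples.index)
            peak = peak_eqtm("g1", ["cA", "cB"], expr, beta, samples)
            hits += (peak == "cA")
        assert hits >= 9

    def test_collinear_cpg_dropped_with_warning(self, rng):
        samples = _samples(rng)
        n = len(samples)
        a = rng.uniform(0.2, 0.8, n)
        beta = pd.DataFrame([a, a + 1e-9], index=["cA", "cB"],
                            columns=samples.index)
        expr = pd.DataFrame([2 * a], index=["g1"], columns=samples.index)
        with pytest.warns(UserWarning, match="collinear"):
            peak = peak_eqtm("g1", ["cA", "cB"], expr, beta, samples,
                             cpg_positions={"cA": 10, "cB": 20})
        assert peak == "cA"  # first by position kept


class TestConditionalMediation:
    def test_complete_mediation_verdict(self, rng):
        samples = _samples(rng, n=300)
        case = samples["case"].to_numpy(float)
        from scipy.special import expit, logit
        m = np.where(case == 1, logit(0.35), logit(0.65)) \
            + rng.normal(0, 0.15, len(samples))
        b = expit(m)
        expr = pd.DataFrame([2.0 * b + rng.normal(0, 0.2, len(samples))],
                            index=["g1"], columns=samples.index)
        beta = pd.DataFrame([b], index=["c1"], columns=samples.index)
        res = conditional_mediation("g1", "c1", expr, beta, samples)
        assert res.attenuation > 0.5
        assert res.p_adj > 0.05
        assert res.verdict == "consistent-with-mediation"

    def test_direct_effect_not_attenuated(self, rng):
        samples = _samples(rng, n=300)
        case = samples["case"].to_numpy(float)
        b = rng.uniform(0.3, 0.7, len(samples))  # no case association
        expr = pd.DataFrame([0.6 * case + 2.0 * b
                             + rng.normal(0, 0.2, len(samples))],
                            index=["g1"], columns=samples.index)
        beta = pd.DataFrame([b], index=["c1"], columns=samples.index)
        res = conditional_mediation("g1", "c1", expr, beta, samples)
        assert abs(res.attenuation) < 0.2
        assert res.verdict == "not-attenuated"

    def test_constant_cpg_leaves_effect_unchanged(self, rng):
        samples = _samples(rng, n=200)
        case = samples["case"].to_numpy(float)
        expr = pd.DataFrame([0.5 * case + rng.normal(0, 0.3, len(samples))],
                            index=["g1"], columns=samples.index)
        beta = pd.DataFrame([np.zeros(len(samples))], index=["c1"],
                            columns=samples.index)
        res = conditional_mediation("g1", "c1", expr, beta, samples)
        assert res.log2fc_adj == pytest.approx(res.log2fc_unadj, abs=1e-10)


class TestCaseOnlySeverity:
    def test_planted_casi_trend_recovered(self, rng):
        samples = _samples(rng, n=400)
        casi = samples["casi"].to_numpy(float)
        noise = rng.normal(0, 0.02, len(samples))
        b = pd.Series(0.5 - 0.02 * casi + noise, index=samples.index)
        res = case_only_severity_assoc(b, samples).set_index("predictor")
        assert res.loc["casi", "std_coef"] < -0.5
        assert res.loc["casi", "p"] < 1e-6
        assert abs(res.loc["ics_group", "std_coef"]) < \
            abs(res.loc["casi", "std_coef"])

    def test_standardization_unit_invariance(self, rng):
        samples = _samples(rng, n=300)
        b = pd.Series(rng.uniform(0.3, 0.7, len(samples)),
                      index=samples.index)
        res1 = case_only_severity_assoc(b, samples).set_index("predictor")
        doubled = samples.copy()
        doubled["casi"] = doubled["casi"] * 2
        res2 = case_only_severity_assoc(b, doubled).set_index("predictor")
        assert res1.loc["casi", "std_coef"] == \
            pytest.approx(res2.loc["casi", "std_coef"], rel=1e-9)

    def test_constant_predictor_rejected(self, rng):
        samples = _samples(rng)
        samples.loc[samples["case"] == 1, "casi"] = 5
        b = pd.Series(rng.uniform(size=len(samples)), index=samples.index)
        with pytest.raises(ValueError, match="no variance"):
            case_only_severity_assoc(b, samples)
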