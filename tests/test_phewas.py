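"""Collapsing tests, CMH combination, quantitative PheWAS and hit triage."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, hypergeom, kstest

from caseforge import (
    binary_collapsing_test,
    classify_hits,
    cmh_pan_ancestry,
    load_chip_exclusion_genes,
    quantitative_collapsing_test,
    run_phewas,
)


def _ids(start, n):
    return np.arange(start, start + n)


class TestBinaryCollapsing:
    def test_cross_product_odds_ratio_and_exact_p(self):
        # 20 carriers / 100 cases vs 50 carriers / 1,900 controls:
        # OR = (20 * 1850) / (80 * 50) = 9.25
        cases = _ids(0, 100)
        controls = _ids(100, 1900)
        carriers = np.r_[cases[:20], controls[:50]]
        res = binary_collapsing_test(cases, controls, carriers)
        assert (res.a, res.b, res.c, res.d) == (20, 80, 50, 1850)
        assert res.odds_ratio == pytest.approx(9.25)
        # exhaustive hypergeometric enumeration oracle for the two-sided p
        M, K, N = 2000, 70, 100
        support = np.arange(max(0, N + K - M), min(K, N) + 1)
        pmf = hypergeom.pmf(support, M, K, N)
        p_oracle = pmf[pmf <= pmf[support == 20][0] * (1 + 1e-7)].sum()
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_no_carriers_anywhere_p_one_flagged(self):
        res = binary_collapsing_test(_ids(0, 50), _ids(50, 200), [])
        assert res.p_value == 1.0
        assert res.haldane and res.direction == 0

    def test_label_swap_inverts_odds_ratio(self):
        cases = _ids(0, 80)
        controls = _ids(80, 400)
        carriers = np.r_[cases[:15], controls[:20]]
        fwd = binary_collapsing_test(cases, controls, carriers)
        rev = binary_collapsing_test(controls, cases, carriers)
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio)
        assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-12)
        assert rev.direction == -fwd.direction

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            binary_collapsing_test([], _ids(0, 10), [])


class TestRunPhewas:
    def _inputs(self):
        parts = pd.DataFrame({
            "eid": _ids(0, 600),
            "sex": ["F", "M"] * 300,
            "age": np.full(600, 55),
        })
        carriers = pd.DataFrame({
            "gene": ["GENE1"] * 30 + ["DNMT3A"] * 30,
            "qv_model": "ptv",
            "eid": np.r_[_ids(0, 30), _ids(30, 30)],
        })
        levels = {"baseline": _ids(0, 100), "L0": _ids(0, 120)}
        pool = _ids(100, 500)
        return levels, pool, carriers, parts

    def test_clonal_hematopoiesis_genes_excluded(self):
        levels, pool, carriers, parts = self._inputs()
        out = run_phewas(levels, pool, carriers, parts, icd10="N18", seed=0)
        assert "DNMT3A" not in set(out["gene"])
        assert "GENE1" in set(out["gene"])
        assert "DNMT3A" in load_chip_exclusion_genes()

    def test_identical_cohorts_identical_statistics(self):
        levels, pool, carriers, parts = self._inputs()
        levels = {"L1": _ids(0, 100), "L2": _ids(0, 100)}
        out = run_phewas(levels, pool, carriers, parts, icd10="N18", seed=0)
        g = out.loc[out["gene"] == "GENE1"].set_index("level")
        assert g.loc["L1", "p_value"] == g.loc["L2", "p_value"]
        assert g.loc["L1", "odds_ratio"] == g.loc["L2", "odds_ratio"]

    def test_planted_effect_reaches_genome_wide_significance(self):
        # expected counts under a strong planted effect: 150/500 carrier
        # cases vs 5% carrier controls at n = 20,000 drive p << 1e-8
        cases = _ids(0, 500)
        controls = _ids(500, 19_500)
        carriers = np.r_[cases[:150], controls[:975]]
        res = binary_collapsing_test(cases, controls, carriers)
        assert res.p_value < 1e-8 and res.odds_ratio > 1


class TestQuantitativeCollapsing:
    def test_shifted_carriers_reach_significance(self):
        rng = np.random.default_rng(0)
        n = 5000
        parts = pd.DataFrame({"eid": _ids(0, n),
                              "sex": rng.choice(["F", "M"], n),
                              "age": rng.integers(40, 70, n)})
        y = rng.normal(size=n)
        carriers = _ids(0, 50)
        y[:50] += 2.0
        eff, p = quantitative_collapsing_test(
            pd.Series(y, index=_ids(0, n)), carriers, parts)
        assert p < 1e-8 and eff == pytest.approx(2.0, abs=0.5)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        n = 400
        parts = pd.DataFrame({"eid": _ids(0, n),
                              "sex": rng.choice(["F", "M"], n),
                              "age": rng.integers(40, 70, n)})
        carriers = _ids(0, 40)
        ps = []
        for _ in range(200):
            y = pd.Series(rng.normal(size=n), index=_ids(0, n))
            ps.append(quantitative_collapsing_test(y, carriers, parts)[1])
        assert kstest(ps, "uniform").pvalue > 0.005

    def test_constant_biomarker_degenerate(self):
        parts = pd.DataFrame({"eid": _ids(0, 100), "sex": ["F"] * 100,
                              "age": np.full(100, 50)})
        y = pd.Series(np.ones(100), index=_ids(0, 100))
        eff, p = quantitative_collapsing_test(y, _ids(0, 10), parts)
        assert p == 1.0 and eff == 0.0

    def test_too_few_carriers_raises(self):
        parts = pd.DataFrame({"eid": _ids(0, 100), "sex": ["F"] * 100,
                              "age": np.full(100, 50)})
        y = pd.Series(np.random.default_rng(0).normal(size=100),
                      index=_ids(0, 100))
        with pytest.raises(ValueError):
            quantitative_collapsing_test(y, [0], parts)


def _cmh_oracle(tables):
    """Textbook CMH statistic: (sum a - sum E[a])^2 / sum Var(a)."""
    num = 0.0
    var = 0.0
    for t in tables:
        a, b = t[0]
        c, d = t[1]
        n = a + b + c + d
        num += a - (a + b) * (a + c) / n
        var += ((a + b) * (c + d) * (a + c) * (b + d)) / (n**2 * (n - 1))
    return num**2 / var


class TestCMH:
    def test_null_strata_give_zero_statistic(self):
        t = np.array([[10, 90], [20, 180]])  # OR exactly 1
        stat, p, orr = cmh_pan_ancestry([t, t * 2])
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)
        assert orr == pytest.approx(1.0)

    def test_single_stratum_matches_textbook_formula(self):
        t = np.array([[20, 80], [50, 850]])
        stat, p, _ = cmh_pan_ancestry([t])
        assert stat == pytest.approx(_cmh_oracle([t]), rel=1e-12)
        # one stratum: CMH = (n-1)/n times the Pearson chi-square
        chi2 = chi2_contingency(t, correction=False).statistic
        n = t.sum()
        assert stat == pytest.approx((n - 1) / n * chi2, rel=1e-10)

    def test_duplicating_a_stratum_increases_evidence(self):
        t = np.array([[20, 80], [30, 870]])
        s1, _, _ = cmh_pan_ancestry([t])
        s2, _, _ = cmh_pan_ancestry([t, t])
        assert s2 > s1
        assert s2 == pytest.approx(_cmh_oracle([t, t]), rel=1e-12)

    def test_all_degenerate_strata_raise(self):
        with pytest.raises(ValueError):
            cmh_pan_ancestry([np.array([[0, 0], [5, 10]])])


class TestTriage:
    def _fiz(self, dominating=("bm0",)):
        return pd.DataFrame(
            {"fis": [0.5, 0.3, 0.2], "fiz": [1.5, 0.1, -0.5],
             "dominating": [f in dominating for f in ("bm0", "bm1", "bm2")]},
            index=["bm0", "bm1", "bm2"],
        )

    def _tables(self, p_baseline, quant_p=1e-3):
        milton = pd.DataFrame([{"gene": "G1", "icd10": "N18", "qv_model": "ptv",
                                "level": "L2", "p_value": 1e-10,
                                "odds_ratio": 5.0, "direction": 1}])
        baseline = pd.DataFrame([{"gene": "G1", "icd10": "N18",
                                  "p_value": p_baseline, "direction": 1}])
        quant = pd.DataFrame([{"gene": "G1", "feature": "bm0",
                               "p_value": quant_p}])
        return milton, baseline, quant

    def test_known_binary_when_baseline_significant_same_direction(self):
        milton, baseline, quant = self._tables(1e-12)
        out = classify_hits(milton, baseline, quant, {"N18": self._fiz()})
        assert out["label"].tolist() == ["known-binary"]

    def test_known_quant_when_dominating_biomarker_significant(self):
        milton, baseline, quant = self._tables(1e-4, quant_p=1e-12)
        out = classify_hits(milton, baseline, quant, {"N18": self._fiz()})
        assert out["label"].tolist() == ["known-quant"]

    def test_putative_novel_otherwise(self):
        milton, baseline, quant = self._tables(1e-4, quant_p=1e-3)
        out = classify_hits(milton, baseline, quant, {"N18": self._fiz()})
        assert out["label"].tolist() == ["putative-novel"]

    def test_opposite_direction_not_known_binary(self):
        milton, baseline, quant = self._tables(1e-12, quant_p=0.5)
        baseline["direction"] = -1
        out = classify_hits(milton, baseline, quant, {"N18": self._fiz()})
        assert out["label"].tolist() == ["putative-novel"]

    def test_missing_fiz_aborts(self):
        milton, baseline, quant = self._tables(1e-12)
        with pytest.raises(ValueError):
            classify_hits(milton, baseline, quant, {})

    def test_every_significant_hit_gets_exactly_one_label(self):
        milton = pd.DataFrame([
            {"gene": g, "icd10": "N18", "qv_model": "ptv", "level": "L1",
             "p_value": p, "odds_ratio": 2.0, "direction": 1}
            for g, p in (("G1", 1e-9), ("G2", 1e-12), ("G3", 1e-4))
        ])
        baseline = pd.DataFrame([{"gene": "G1", "icd10": "N18",
                                  "p_value": 1e-10, "direction": 1}])
        quant = pd.DataFrame([{"gene": "G2", "feature": "bm0", "p_value": 1e-10}])
        out = classify_hits(milton, baseline, quant, {"N18": self._fiz()})
        # G3 is not significant, so only two rows, each with one label
        assert len(out) == 2
        assert set(out["gene"]) == {"G1", "G2"}
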