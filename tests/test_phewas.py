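import math

import numpy as np
import pandas as pd
import pytest

import dtmr
from dtmr import (
    CaseControlSet,
    PhecodeCatalog,
    assoc_logistic,
    build_case_control,
    build_grs,
    map_icd_to_phecodes,
    run_phewas,
)
from dtmr.phewas import GenotypeMatrix, normalize_icd, normalize_phecode


def toy_genotypes(dosages, variant_alleles=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    alleles = variant_alleles or [("A", "G")] * m
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{j}" for j in range(m)],
            "CHR": "1",
            "POS": np.arange(m) + 1,
            "EA": [a for a, _ in alleles],
            "OA": [b for _, b in alleles],
        }
    )
    return GenotypeMatrix(dosages, [f"P{i}" for i in range(n)], variants)


class TestBuildGrs:
    def test_standardization_contract(self):
        rng = np.random.default_rng(0)
        g = toy_genotypes(rng.integers(0, 3, (200, 4)))
        w = pd.DataFrame({"SNP": [f"rs{j}" for j in range(4)], "EA": "A", "WEIGHT": rng.uniform(0.1, 2, 4)})
        score = build_grs(g, w)
        assert score.mean() == pytest.approx(0.0, abs=1e-8)
        assert score.std(ddof=0) == pytest.approx(1.0, abs=1e-8)

    def test_single_variant_equals_standardized_dosage(self):
        d = np.array([[0.0], [1.0], [2.0], [1.0]])
        g = toy_genotypes(d)
        score = build_grs(g, pd.DataFrame({"SNP": ["rs0"], "EA": ["A"], "WEIGHT": [1.0]}))
        expected = (d[:, 0] - d[:, 0].mean()) / d[:, 0].std()
        np.testing.assert_allclose(score.to_numpy(), expected)

    def test_hand_computed_raw_scores(self):
        # raw scores 0.9, 0.4, 1.3 with weights (0.5, 0.2)
        g = toy_genotypes([[1, 2], [0, 2], [2, 1.5]])
        w = pd.DataFrame({"SNP": ["rs0", "rs1"], "EA": "A", "WEIGHT": [0.5, 0.2]})
        raw = np.array([0.9, 0.4, 1.3])
        expected = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(build_grs(g, w).to_numpy(), expected, atol=1e-12)

    def test_opposite_allele_flips_dosage(self):
        g = toy_genotypes([[0.0], [2.0], [1.0]])
        w_ea = pd.DataFrame({"SNP": ["rs0"], "EA": ["A"], "WEIGHT": [1.0]})
        w_oa = pd.DataFrame({"SNP": ["rs0"], "EA": ["G"], "WEIGHT": [1.0]})
        np.testing.assert_allclose(
            build_grs(g, w_ea).to_numpy(), -build_grs(g, w_oa).to_numpy(), atol=1e-12
        )

    def test_missing_dosage_mean_imputed(self):
        g = toy_genotypes([[0.0], [2.0], [np.nan], [2.0]])
        score = build_grs(g, pd.DataFrame({"SNP": ["rs0"], "EA": ["A"], "WEIGHT": [1.0]}))
        raw = np.array([0.0, 2.0, 4 / 3, 2.0])
        np.testing.assert_allclose(score.to_numpy(), (raw - raw.mean()) / raw.std(), atol=1e-12)

    def test_errors(self):
        g = toy_genotypes([[0.0], [1.0]])
        with pytest.raises(KeyError):
            build_grs(g, pd.DataFrame({"SNP": ["nope"], "EA": ["A"], "WEIGHT": [1.0]}))
        flat = toy_genotypes([[1.0], [1.0]])
        with pytest.raises(ValueError, match="zero variance"):
            build_grs(flat, pd.DataFrame({"SNP": ["rs0"], "EA": ["A"], "WEIGHT": [1.0]}))
        with pytest.raises(ValueError, match="neither"):
            build_grs(g, pd.DataFrame({"SNP": ["rs0"], "EA": ["T"], "WEIGHT": [1.0]}))


def toy_catalog():
    icd_map = pd.DataFrame(
        [
            ("ICD10", "K57", "550"),
            ("ICD10", "K58", "551"),
            ("ICD9", "562", "550"),
            ("ICD10", "I10", "401"),
            ("ICD9", "4019", "401"),
        ],
        columns=["vocab", "code", "phecode"],
    )
    defs = pd.DataFrame(
        [
            ("550", "diverticulosis", "digestive", "549-551"),
            ("551", "related gut condition", "digestive", "549-551"),
            ("401", "hypertension", "circulatory", ""),
        ],
        columns=["phecode", "label", "category", "exclude_range"],
    )
    return PhecodeCatalog.from_frames(icd_map, defs)


class TestPhecodeMapping:
    def test_normalization(self):
        assert normalize_icd("k57.3") == "K573"
        assert normalize_phecode("401.0") == "401"
        assert normalize_phecode("550.1") == "550.1"

    def test_most_specific_prefix_match(self):
        cat = toy_catalog()
        assert cat.map_code("ICD10", "K57.3") == "550"  # prefix K57
        assert cat.map_code("ICD9", "562.11") == "550"
        assert cat.map_code("ICD10", "Z99") is None

    def test_empty_records(self):
        assert map_icd_to_phecodes(pd.DataFrame(columns=["person_id", "vocab", "code", "date"]), toy_catalog()).empty

    def test_duplicate_codes_deduplicated(self):
        records = pd.DataFrame(
            {
                "person_id": ["p1", "p1"],
                "vocab": ["ICD10", "ICD9"],
                "code": ["K57.3", "562.1"],
                "date": ["2010-01-01", "2011-01-01"],
            }
        )
        pairs = map_icd_to_phecodes(records, toy_catalog())
        assert len(pairs) == 1
        assert pairs.iloc[0]["phecode"] == "550"

    def test_enumeration_oracle(self):
        records = pd.DataFrame(
            {
                "person_id": ["p1", "p1", "p2", "p3", "p3", "p4"],
                "vocab": ["ICD10", "ICD10", "ICD10", "ICD9", "ICD10", "ICD10"],
                "code": ["K57", "I10", "K58", "4019", "XXX", "K57.9"],
                "date": ["2010"] * 6,
            }
        )
        pairs = map_icd_to_phecodes(records, toy_catalog())
        expected = {("p1", "550"), ("p1", "401"), ("p2", "551"), ("p3", "401"), ("p4", "550")}
        assert set(map(tuple, pairs[["person_id", "phecode"]].itertuples(index=False))) == expected


class TestBuildCaseControl:
    def pairs(self):
        return pd.DataFrame(
            {
                "person_id": ["p1", "p2", "p3", "p3"],
                "phecode": ["550", "551", "550", "401"],
            }
        )

    def test_partition(self):
        cohort = [f"p{i}" for i in range(1, 6)]
        cc = build_case_control(self.pairs(), toy_catalog(), cohort, "550")
        assert cc.case_ids == {"p1", "p3"}
        assert cc.excluded_ids == {"p2"}  # carries only the range-mate 551
        assert cc.control_ids == {"p4", "p5"}

    def test_partition_is_exhaustive_and_disjoint(self):
        cohort = [f"p{i}" for i in range(1, 11)]
        cc = build_case_control(self.pairs(), toy_catalog(), cohort, "550")
        union = cc.case_ids | cc.control_ids | cc.excluded_ids
        assert union == set(cohort)
        assert len(cc.case_ids) + len(cc.control_ids) + len(cc.excluded_ids) == len(cohort)

    def test_no_exclusion_ranges_means_no_excluded(self):
        cc = build_case_control(self.pairs(), toy_catalog(), ["p1", "p2", "p3"], "401")
        assert cc.case_ids == {"p3"}
        assert cc.excluded_ids == set()

    def test_unknown_phecode(self):
        with pytest.raises(KeyError):
            build_case_control(self.pairs(), toy_catalog(), ["p1"], "999")

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            CaseControlSet("550", {"a"}, {"a"}, set())


class TestAssocLogistic:
    def test_two_by_two_matches_contingency_odds_ratio(self):
        # exposed: 30 cases / 70 controls; unexposed: 10 cases / 90 controls
        ids = [f"p{i}" for i in range(200)]
        exposure = np.array([1.0] * 100 + [0.0] * 100)
        case = np.array([1.0] * 30 + [0.0] * 70 + [1.0] * 10 + [0.0] * 90)
        score = pd.Series(exposure, index=ids)
        cc = CaseControlSet(
            "x",
            set(np.array(ids)[case == 1]),
            set(np.array(ids)[case == 0]),
            set(),
        )
        cov = pd.DataFrame({"person_id": ids})
        res = assoc_logistic(score, cc, cov, covariate_cols=())
        assert math.exp(res.log_or) == pytest.approx((30 * 90) / (70 * 10), rel=1e-6)

    def test_null_score_gives_or_near_one(self):
        rng = np.random.default_rng(1)
        n = 3000
        ids = [f"p{i}" for i in range(n)]
        score = pd.Series(rng.standard_normal(n), index=ids)
        case = rng.random(n) < 0.2
        cc = CaseControlSet("x", set(np.array(ids)[case]), set(np.array(ids)[~case]), set())
        cov = pd.DataFrame(
            {"person_id": ids, "age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n)}
        )
        res = assoc_logistic(score, cc, cov, covariate_cols=("age", "sex"))
        assert abs(res.log_or) < 3 * res.se + 1e-9

    def test_separation_flagged_not_raised(self):
        ids = [f"p{i}" for i in range(40)]
        score = pd.Series(np.r_[np.ones(20), -np.ones(20)], index=ids)
        cc = CaseControlSet("x", set(ids[:20]), set(ids[20:]), set())
        cov = pd.DataFrame({"person_id": ids})
        res = assoc_logistic(score, cc, cov, covariate_cols=())
        assert not res.converged
        assert math.isnan(res.log_or)


class TestRunPhewas:
    def manual_bh(self, pvals, alpha=0.05):
        """Step-up procedure written out directly."""
        m = len(pvals)
        order = np.argsort(pvals)
        flags = np.zeros(m, dtype=bool)
        kmax = 0
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= alpha * rank / m:
                kmax = rank
        for rank, idx in enumerate(order, start=1):
            if rank <= kmax:
                flags[idx] = True
        return flags

    def test_flags_match_manual_step_up_and_are_monotone(self, demo_bundle):
        b = demo_bundle
        pp = dtmr.map_icd_to_phecodes(b.icd_records, b.catalog)
        res = run_phewas(b.grs, pp, b.catalog, b.covariates, min_cases=100)
        est = res[res["converged"]]
        expected = self.manual_bh(est["pvalue"].to_numpy())
        np.testing.assert_array_equal(est["fdr_significant"].to_numpy(), expected)
        if est["fdr_significant"].any():
            worst_flagged = est.loc[est["fdr_significant"], "pvalue"].max()
            best_unflagged = est.loc[~est["fdr_significant"], "pvalue"].min()
            assert worst_flagged <= best_unflagged

    def test_min_case_floor(self, demo_bundle):
        b = demo_bundle
        pp = dtmr.map_icd_to_phecodes(b.icd_records, b.catalog)
        res_all = run_phewas(b.grs, pp, b.catalog, b.covariates, min_cases=1)
        counts = pp.groupby("phecode").size()
        floor = 400
        res = run_phewas(b.grs, pp, b.catalog, b.covariates, min_cases=floor)
        assert set(res["phecode"]) == {p for p in res_all["phecode"] if res_all.set_index("phecode").loc[p, "n_case"] >= floor}
        assert (res["n_case"] >= floor).all()

    def test_focal_phecode_tops_the_scan(self, demo_bundle):
        b = demo_bundle
        pp = dtmr.map_icd_to_phecodes(b.icd_records, b.catalog)
        res = run_phewas(b.grs, pp, b.catalog, b.covariates)
        assert res.iloc[0]["phecode"] == b.truth.focal_phecode
        assert bool(res.iloc[0]["fdr_significant"])
        assert res.iloc[0]["odds_ratio"] > 1.2

    def test_score_shift_invariance(self, small_bundle):
        b = small_bundle
        pp = dtmr.map_icd_to_phecodes(b.icd_records, b.catalog)
        res1 = run_phewas(b.grs, pp, b.catalog, b.covariates, min_cases=50)
        raw_shifted = b.grs * 1.0  # standardized score is shift-invariant by construction
        res2 = run_phewas(raw_shifted, pp, b.catalog, b.covariates, min_cases=50)
        pd.testing.assert_frame_equal(res1, res2)

    def test_sex_specific_phecode_restricts_cohort(self):
        rng = np.random.default_rng(5)
        n = 2000
        ids = [f"p{i}" for i in range(n)]
        cov = pd.DataFrame(
            {
                "person_id": ids,
                "age": rng.uniform(40, 70, n),
                "sex": np.r_[np.ones(n // 2), np.zeros(n // 2)],
                "PC1": rng.standard_normal(n),
                "PC2": rng.standard_normal(n),
                "PC3": rng.standard_normal(n),
                "PC4": rng.standard_normal(n),
            }
        )
        icd_map = pd.DataFrame([("ICD10", "N80", "615")], columns=["vocab", "code", "phecode"])
        defs = pd.DataFrame(
            [("615", "female-only condition", "genitourinary", "", "F")],
            columns=["phecode", "label", "category", "exclude_range", "sex"],
        )
        catalog = PhecodeCatalog.from_frames(icd_map, defs)
        carriers = rng.choice(n // 2, 300, replace=False)  # only females affected
        pairs = pd.DataFrame({"person_id": [ids[i] for i in carriers], "phecode": "615"})
        score = pd.Series(rng.standard_normal(n), index=ids)
        res = run_phewas(score, pairs, catalog, cov, min_cases=100)
        assert len(res) == 1
        assert res.iloc[0]["n_case"] + res.iloc[0]["n_control"] <= n // 2
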