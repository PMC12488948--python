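import numpy as np
import pandas as pd
import pytest

from polyscore import phewas, score, risk_eval
import polyscore as ps


FIXTURE_MAP = pd.DataFrame(
    {
        "icd_code": ["X1", "X2", "Y1"],
        "vocabulary": ["ICD9CM", "ICD10CM", "ICD9CM"],
        "phecode": ["P1", "P1", "P2"],
        "phenotype": ["thing one", "thing one", "thing two"],
        "category": ["circulatory system", "circulatory system", "neoplasms"],
    }
)


def records(rows):
    return pd.DataFrame(rows, columns=["person_id", "code", "vocabulary"])


class TestMapping:
    def test_repeat_codes_accumulate(self):
        counts, unmapped = phewas.map_icd_to_phecodes(
            records([("a", "X1", "ICD9CM"), ("a", "X1", "ICD9CM")]), FIXTURE_MAP
        )
        assert counts.set_index(["person_id", "phecode"]).loc[("a", "P1"), "count"] == 2
        assert len(unmapped) == 0

    def test_single_record_counts_once_and_vocabularies_distinct(self):
        counts, _ = phewas.map_icd_to_phecodes(
            records([("a", "X1", "ICD9CM"), ("a", "X2", "ICD10CM")]), FIXTURE_MAP
        )
        # both vocabularies map into the same phecode
        assert counts["count"].iloc[0] == 2

    def test_unmapped_code_tallied_not_fatal(self):
        counts, unmapped = phewas.map_icd_to_phecodes(
            records([("a", "X1", "ICD9CM"), ("a", "ZZZ", "ICD9CM")]), FIXTURE_MAP
        )
        assert unmapped["ZZZ"] == 1
        assert len(counts) == 1

    def test_unknown_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            phewas.map_icd_to_phecodes(records([("a", "X1", "SNOMED")]), FIXTURE_MAP)


class TestPhenomeDefinition:
    def _counts(self, spec):
        return pd.DataFrame(
            [(p, ph, c) for (p, ph, c) in spec],
            columns=["person_id", "phecode", "count"],
        )

    def test_count_rules(self):
        counts = self._counts([("a", "P1", 2), ("b", "P1", 1)])
        status = phewas.define_phenome(counts, ["a", "b", "c"])
        assert status.loc["a", "P1"] == "case"
        assert status.loc["b", "P1"] == "excluded"
        assert status.loc["c", "P1"] == "control"

    def test_count_one_as_control_option(self):
        counts = self._counts([("a", "P1", 1)])
        status = phewas.define_phenome(counts, ["a"], count_one_as_control=True)
        assert status.loc["a", "P1"] == "control"

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        people = [f"p{i}" for i in range(50)]
        cnt = rng.poisson(0.8, (50, 3))
        counts = pd.DataFrame(
            [
                (people[i], f"P{j}", cnt[i, j])
                for i in range(50)
                for j in range(3)
                if cnt[i, j] > 0
            ],
            columns=["person_id", "phecode", "count"],
        )
        status = phewas.define_phenome(counts, people)
        for col in status.columns:
            vc = status[col].value_counts()
            assert vc.sum() == 50
            assert set(vc.index) <= {"case", "control", "excluded"}

    def test_exclusion_range_removes_related_controls(self):
        pmap = pd.DataFrame(
            {
                "icd_code": ["A", "B"],
                "vocabulary": ["ICD9CM", "ICD9CM"],
                "phecode": ["250.2", "250.7"],
                "phenotype": ["x", "y"],
                "category": ["endocrine/metabolic"] * 2,
                "exclusion_low": [249.0, np.nan],
                "exclusion_high": [251.0, np.nan],
            }
        )
        counts = self._counts([("a", "250.2", 3)])
        status = phewas.define_phenome(counts, ["a", "b"], phecode_map=pmap)
        # 'a' is a 250.2 case; as a carrier they cannot be a 250.7 control
        # (250.7 lies in 250.2's exclusion range 249-251)
        assert "250.7" not in status.columns or status.loc["a", "250.7"] == "excluded"
        counts2 = self._counts([("a", "250.2", 3), ("b", "250.7", 2)])
        status2 = phewas.define_phenome(counts2, ["a", "b"], phecode_map=pmap)
        assert status2.loc["a", "250.7"] == "excluded"
        assert status2.loc["b", "250.7"] == "case"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            phewas.define_phenome(self._counts([("a", "P1", -1)]), ["a"])


class TestRunPhewas:
    def test_small_case_count_skipped(self, rng):
        n = 200
        ids = [f"i{k}" for k in range(n)]
        cohort = pd.DataFrame(
            {
                "individual_id": ids,
                "age": rng.uniform(40, 80, n),
                "sex": rng.integers(0, 2, n).astype(float),
            }
        )
        scores = pd.DataFrame({"individual_id": ids, "z_score": rng.normal(0, 1, n)})
        phenome = pd.DataFrame(
            {"P1": ["case"] * 9 + ["control"] * (n - 9)},
            index=pd.Index(ids, name="person_id"),
        )
        res = phewas.run_phewas(scores, phenome, cohort, covariates=("age", "sex"))
        assert res["flag"].iloc[0] == "skipped: <10 cases"
        assert np.isnan(res["beta"].iloc[0])

    def test_recovers_linked_phecode_effect(self, small_sim):
        """End-to-end: records -> counts -> phenome -> scan recovers the
        generative per-SD OR of a linked phecode within its CI."""
        panel, wts, coh2, records_df, truth = ps.simulate_cohort(
            ps.SimConfig(n_per_population=5000, populations=("EUR",),
                         n_studies=1, seed=61)
        )
        pmap = phewas.load_phecode_map()
        counts, unmapped = phewas.map_icd_to_phecodes(records_df, pmap)
        assert len(unmapped) == 0
        phenome = phewas.define_phenome(counts, coh2["individual_id"])
        scores = pd.DataFrame(
            {"individual_id": coh2["individual_id"], "z_score": coh2["z_true"]}
        )
        res = phewas.run_phewas(
            scores, phenome, coh2, covariates=("age", "sex"), phecode_map=pmap
        ).set_index("phecode")
        row = res.loc["401.1"]  # true per-SD log-OR ln(1.34), prevalence 0.25
        assert pd.isna(row["flag"])
        assert abs(row["beta"] - np.log(1.34)) < 1.96 * row["se"] + 0.05
        # null phecode stays near OR 1
        null_row = res.loc["782.3"]
        assert abs(null_row["beta"]) < 3 * null_row["se"]
        assert row["category"] == "circulatory system"


class TestThresholdsAndSummary:
    @pytest.mark.parametrize(
        "n,expected",
        [(1815, 2.75e-5), (1777, 2.81e-5), (1171, 4.27e-5),
         (1813, 2.76e-5), (1695, 2.95e-5), (20, 2.50e-3), (1, 0.05)],
    )
    def test_bonferroni_thresholds(self, n, expected):
        assert phewas.bonferroni_threshold(n) == pytest.approx(expected, rel=5e-3)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            phewas.bonferroni_threshold(0)

    @staticmethod
    def results_frame(n_tested, n_sig, categories=None, seed=0):
        rng = np.random.default_rng(seed)
        thr = 0.05 / n_tested
        p = np.concatenate(
            [rng.uniform(0, thr * 0.5, n_sig), rng.uniform(0.05, 1.0, n_tested - n_sig)]
        )
        cats = (
            categories
            if categories is not None
            else ["endocrine/metabolic"] * n_tested
        )
        return pd.DataFrame(
            {
                "phecode": [f"c{i}" for i in range(n_tested)],
                "category": cats,
                "beta": rng.normal(0.2, 0.1, n_tested),
                "se": 0.05,
                "p": p,
                "n_cases": 100,
                "n_controls": 1000,
            }
        )

    def test_percentages_recomputed_from_counts(self):
        cats = ["circulatory system"] * 123 + ["endocrine/metabolic"] * (1815 - 123)
        res = self.results_frame(1815, 732, categories=cats)
        summary = phewas.summarize_phewas({"ALL": res})
        pop = summary["populations"]["ALL"]
        assert pop["pct_significant"] == 40.3
        assert pop["by_category"]["circulatory system"]["pct_of_significant"] == 16.8
        assert pop["by_category"]["circulatory system"]["n"] == 123

    def test_afr_share(self):
        summary = phewas.summarize_phewas({"AFR": self.results_frame(1777, 213)})
        assert summary["populations"]["AFR"]["pct_significant"] == 12.0

    def test_identical_populations_correlate_perfectly(self):
        res = self.results_frame(100, 40)
        summary = phewas.summarize_phewas({"A": res, "B": res.copy()})
        assert summary["effect_correlations"]["A|B"] == pytest.approx(1.0)
        assert summary["overlap"]["A|B"]["both"] == 40
        assert summary["overlap"]["A|B"]["only_A"] == 0

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            phewas.summarize_phewas({})
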