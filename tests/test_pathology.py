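import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medipdmr import pathology as pa
from oracles import fisher_enumeration


class TestDiseaseCall:
    def test_zero_sd_controls_any_excess_is_disease(self):
        assert pa.disease_call_high([2, 2, 2], 3) == "present"
        assert pa.disease_call_high([2, 2, 2], 2) == "absent"

    def test_boundary_is_absent(self):
        # controls [1,2,3]: mean 2, SD 1, threshold 4 -> exactly 4 is absent
        assert pa.disease_call_high([1, 2, 3], 4) == "absent"
        assert pa.disease_call_high([1, 2, 3], 4.0001) == "present"
        assert pa.disease_call_high([1, 2, 3], 10) == "present"

    def test_low_side_variant_for_follicle_loss(self):
        # mean 100, SD 10 -> loss below 80
        controls = [90, 100, 110]
        assert pa.disease_call_high(controls, 75, side="low") == "present"
        assert pa.disease_call_high(controls, 85, side="low") == "absent"

    def test_insufficient_controls_error(self):
        with pytest.raises(ValueError):
            pa.disease_call_high([2], 3)


class TestCutoffs:
    def test_formula(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(3000, 400, 2000)
        cut = pa.derive_cutoffs(vals, k=1.5)
        mean, sd = vals.mean(), vals.std(ddof=1)
        assert cut.lean_cut == pytest.approx(mean - 1.5 * sd)
        assert cut.obese_cut == pytest.approx(mean + 1.5 * sd)

    def test_k_zero_collapses_to_mean(self):
        with pytest.warns(UserWarning):
            cut = pa.derive_cutoffs([1.0, 3.0], k=0)
        assert cut.lean_cut == cut.obese_cut == 2.0

    def test_constant_controls_warn(self):
        with pytest.warns(UserWarning, match="constant|degenerate"):
            pa.derive_cutoffs([5.0, 5.0, 5.0])

    def test_tail_fractions_at_k_1_5(self):
        """Gaussian controls: ~6.7% flagged per tail at 1.5 SD."""
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 10_000)
        cut = pa.derive_cutoffs(vals, k=1.5)
        calls = [pa.classify_metabolic(v, cut) for v in vals]
        lean = np.mean([c == "lean" for c in calls])
        obese = np.mean([c == "obese" for c in calls])
        assert lean == pytest.approx(0.0668, abs=0.02)
        assert obese == pytest.approx(0.0668, abs=0.02)


class TestClassifyMetabolic:
    def test_published_adipocyte_cutoffs(self):
        f = pa.ADIPOCYTE_AREA_CUTOFFS["female"]
        assert pa.classify_metabolic(2500, f) == "lean"
        assert pa.classify_metabolic(3000, f) == "normal"
        assert pa.classify_metabolic(4000, f) == "obese"
        # male lean bound is lower (2425)
        assert pa.classify_metabolic(2500, pa.ADIPOCYTE_AREA_CUTOFFS["male"]) == "normal"

    def test_published_bmi_cutoffs(self):
        assert pa.classify_metabolic(1.0, pa.BMI_CUTOFFS["male"]) == "obese"
        assert pa.classify_metabolic(0.85, pa.BMI_CUTOFFS["male"]) == "normal"
        assert pa.classify_metabolic(0.5, pa.BMI_CUTOFFS["female"]) == "lean"

    def test_boundary_values_are_normal(self):
        assert pa.classify_metabolic(3912, pa.ADIPOCYTE_AREA_CUTOFFS["female"]) == "normal"
        assert pa.classify_metabolic(2671, pa.ADIPOCYTE_AREA_CUTOFFS["female"]) == "normal"

    def test_missing_value(self):
        assert pa.classify_metabolic(None, pa.BMI_CUTOFFS["male"]) == "not-examined"
        assert pa.classify_metabolic(float("nan"), pa.BMI_CUTOFFS["male"]) == "not-examined"


class TestAdipocyteMeanArea:
    def test_five_images_of_25_cells_average_exactly_100(self):
        rng = np.random.default_rng(2)
        images = [list(rng.uniform(1000, 5000, 25)) for _ in range(5)]
        got = pa.adipocyte_mean_area(images, top_n=20)
        pooled = np.concatenate([np.sort(img)[-20:] for img in images])
        assert len(pooled) == 100
        assert got == pytest.approx(pooled.mean())

    def test_constant_areas(self):
        assert pa.adipocyte_mean_area([[7.0] * 30] * 3) == 7.0

    def test_short_image_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="cells"):
            got = pa.adipocyte_mean_area([[10.0, 20.0]], top_n=20)
        assert got == 15.0

    def test_no_images_error(self):
        with pytest.raises(ValueError):
            pa.adipocyte_mean_area([])


class TestSimpleMeasures:
    def test_bmi(self):
        assert pa.bmi(300, 20) == pytest.approx(0.75)
        assert pa.bmi(0, 20) == 0.0
        with pytest.raises(ValueError):
            pa.bmi(300, 0)

    def test_weight_per_dna(self):
        assert pa.weight_per_dna(100, 10) == 10.0
        assert pa.weight_per_dna(7.3, 7.3) == 1.0
        with pytest.raises(ValueError):
            pa.weight_per_dna(100, 0)


def make_cohort(rows):
    return pd.DataFrame(rows, columns=["animal_id", "lineage", "testis", "lean", "tumor"])


class TestIncidence:
    def test_multiple_disease_animal_not_in_single_tally(self):
        cohort = make_cohort([
            ("a", "exposure", "present", "present", "absent"),
            ("b", "exposure", "present", "absent", "absent"),
            ("c", "exposure", "absent", "absent", "absent"),
        ])
        out = pa.incidence(cohort, ["testis", "lean", "tumor"]).iloc[0]
        assert out["n_single"] == 1 and out["n_multiple"] == 1 and out["n_zero"] == 1

    def test_disease_free_cohort(self):
        cohort = make_cohort([(f"a{i}", "control", "absent", "absent", "absent")
                              for i in range(10)])
        out = pa.incidence(cohort, ["testis", "lean", "tumor"]).iloc[0]
        assert out["single_rate"] == 0.0 and out["multiple_rate"] == 0.0
        assert out["n_animals"] == 10

    def test_tallies_conserve_group_size(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(200):
            calls = rng.choice(["present", "absent", "not-examined"], 3)
            rows.append((f"r{i}", rng.choice(["control", "exposure"]), *calls))
        cohort = make_cohort(rows)
        out = pa.incidence(cohort, ["testis", "lean", "tumor"],
                           group_by=("lineage",))
        for row in out.itertuples():
            assert row.n_zero + row.n_single + row.n_multiple == row.n_animals

    def test_matches_exhaustive_per_animal_tally(self):
        rng = np.random.default_rng(4)
        rows = [(f"r{i}", "exposure",
                 *rng.choice(["present", "absent"], 3)) for i in range(50)]
        cohort = make_cohort(rows)
        out = pa.incidence(cohort, ["testis", "lean", "tumor"]).iloc[0]
        per_animal = [sum(v == "present" for v in r[2:]) for r in rows]
        assert out["n_single"] == sum(c == 1 for c in per_animal)
        assert out["n_multiple"] == sum(c >= 2 for c in per_animal)


class TestFisher:
    def test_identical_groups(self):
        assert pa.fisher_test(5, 10, 5, 10) == 1.0

    def test_symmetry(self):
        assert pa.fisher_test(1, 10, 8, 10) == pytest.approx(
            pa.fisher_test(8, 10, 1, 10))

    def test_against_enumeration_oracle(self):
        assert pa.fisher_test(1, 10, 8, 10) == pytest.approx(
            fisher_enumeration(1, 10, 8, 10), abs=1e-10)
        for a, ta, b, tb in [(0, 5, 5, 5), (3, 12, 9, 15), (2, 8, 2, 9)]:
            assert pa.fisher_test(a, ta, b, tb) == pytest.approx(
                fisher_enumeration(a, ta, b, tb), abs=1e-10)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            pa.fisher_test(0, 0, 1, 5)


class TestTTest:
    def test_identical_groups(self):
        t, p = pa.t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shifted_group_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        t, p = pa.t_test(a, b)
        # pooled SE = sqrt(1 * (1/3 + 1/3)), t = -10 / SE, df = 4
        se = np.sqrt(2 / 3)
        expected_t = -10 / se
        assert t == pytest.approx(expected_t)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), df=4))

    def test_equal_n_pooled_equals_welch_statistic(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 8)
        t_pooled, _ = pa.t_test(a, b)
        t_welch, _ = pa.t_test(a, b, welch=True)
        assert t_pooled == pytest.approx(t_welch)

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = pa.t_test([2, 2, 2], [2, 2, 2])
        assert (t, p) == (0.0, 1.0)


class TestCompareIncidence:
    def test_fisher_columns_and_denominators(self):
        cohort = make_cohort(
            [(f"c{i}", "control", "absent", "absent", "absent") for i in range(10)]
            + [(f"e{i}", "exposure", "present" if i < 5 else "absent",
                "absent", "not-examined") for i in range(10)]
        )
        out = pa.compare_incidence(cohort, ["testis", "lean", "tumor"])
        testis = out[(out["lineage"] == "exposure") & (out["statistic"] == "testis")].iloc[0]
        assert testis["affected"] == 5 and testis["total"] == 10
        tumor = out[(out["lineage"] == "exposure") & (out["statistic"] == "tumor")].iloc[0]
        assert tumor["total"] == 0  # all not-examined excluded
        assert testis["fisher_p"] == pytest.approx(pa.fisher_test(5, 10, 0, 10))
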