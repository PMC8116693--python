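"""Distance metric, fractional variations, γ ratios, preference counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungvar.cohort import CohortConfig, generate_cohort
from lungvar.metrics import (
    DegenerateStructureError,
    UndefinedGammaError,
    compare_methods_table,
    count_preferences,
    distance_metric,
    fit_binomial_preference,
    fractional_variation,
    gamma_ratio,
    gamma_table,
    radial_distance_table,
    variation_table,
)

from conftest import isotropic_noise


class TestDistanceMetric:
    def test_three_four_five(self):
        landmarks = {
            "Ref_SC": np.array([0.0, 60.0, 0.0]),
            "Carina": np.array([3.0, 64.0, 0.0]),
        }
        dm = distance_metric(landmarks)
        assert dm.radial["Carina"] == pytest.approx(5.0)

    def test_coincident_structures_zero(self):
        ref = np.array([1.0, 2.0, 3.0])
        dm = distance_metric({"Ref_SC": ref, "Apex": ref.copy(), "Carina": ref.copy()})
        assert all(r == 0.0 for r in dm.radial.values())

    def test_reference_and_spine_excluded(self):
        dm = distance_metric(
            {
                "Ref_SC": np.zeros(3),
                "Spine_Aux1": np.ones(3),
                "Diaphragm": np.array([0.0, 0.0, -120.0]),
            }
        )
        assert set(dm.radial) == {"Diaphragm"}

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="Ref_SC"):
            distance_metric({"Apex": np.zeros(3)})

    def test_noise_free_cohort_matches_canonical_geometry(self, zero_noise_cohort):
        rdist = radial_distance_table(zero_noise_cohort.landmarks)
        for (subject, sid), group in rdist.groupby(["subject_id", "structure_id"]):
            anatomy = zero_noise_cohort.anatomy(subject)
            expected = np.linalg.norm(
                anatomy.canonical_positions[sid] - anatomy.reference_position
            )
            np.testing.assert_allclose(group["r_mm"], expected, atol=1e-9)

    def test_radial_distance_invariant_to_setup_transform(self):
        """r is computed within a scan, so rigid setup motion cancels."""
        base = CohortConfig(
            n_subjects=2, sex_split=(1, 1),
            method_noise_sd=isotropic_noise(0.0, 1.0), seed=31,
            setup_translation_sd=6.0, setup_rotation_sd=3.0,
        )
        cohort = generate_cohort(base)
        rdist = radial_distance_table(cohort.landmarks)
        spread = rdist.groupby(["subject_id", "structure_id"])["r_mm"].std()
        assert spread.max() < 1e-9


class TestFractionalVariation:
    def test_constant_distances(self):
        assert fractional_variation([80.0] * 8).fractional_variation == 0.0

    def test_two_point_example(self):
        summary = fractional_variation([99.0, 101.0])
        assert summary.sd_mm == pytest.approx(np.sqrt(2.0))
        assert summary.fractional_variation == pytest.approx(0.014142, abs=1e-6)

    def test_zero_mean_degenerate(self):
        with pytest.raises(DegenerateStructureError):
            fractional_variation([0.0, 0.0])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fractional_variation([5.0])

    @given(
        st.lists(st.floats(1.0, 500.0), min_size=2, max_size=16),
        st.floats(0.1, 50.0),
    )
    def test_scale_invariance(self, values, factor):
        base = fractional_variation(values).fractional_variation
        scaled = fractional_variation([v * factor for v in values]).fractional_variation
        assert scaled == pytest.approx(base, rel=1e-9)

    @given(st.lists(st.floats(1.0, 500.0), min_size=2, max_size=16))
    def test_matches_two_pass_oracle(self, values):
        """Equivalence against an explicit two-pass SD/mean computation."""
        n = len(values)
        mean = sum(values) / n
        sd = (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5
        summary = fractional_variation(values)
        assert summary.fractional_variation == pytest.approx(sd / mean, rel=1e-9)


class TestGammaRatio:
    def test_equal_variations(self):
        assert gamma_ratio(0.02, 0.02) == 0.0

    def test_half_ratio(self):
        assert gamma_ratio(0.01, 0.02) == pytest.approx(-0.30103, abs=1e-5)

    @given(st.floats(1e-4, 1.0), st.floats(1e-4, 1.0))
    def test_antisymmetry(self, a, b):
        assert gamma_ratio(a, b) == pytest.approx(-gamma_ratio(b, a), abs=1e-12)

    def test_nonpositive_input_undefined(self):
        with pytest.raises(UndefinedGammaError):
            gamma_ratio(0.0, 0.02)

    def test_gamma_invariant_to_global_rescaling(self, small_cohort):
        landmarks = small_cohort.landmarks
        scaled = landmarks.copy()
        scaled[["x_mm", "y_mm", "z_mm"]] *= 10.0
        g0 = gamma_table(variation_table(radial_distance_table(landmarks)))
        g1 = gamma_table(variation_table(radial_distance_table(scaled)))
        np.testing.assert_allclose(g0["gamma"], g1["gamma"], atol=1e-9)


class TestCompareMethodsTable:
    def _hand_table(self):
        rows = []
        fv = {
            "eDIBH": [0.010, 0.020, 0.015, 0.030, 0.025],
            "HFPV": [0.020, 0.050, 0.030, 0.010, 0.060],
        }
        for method, values in fv.items():
            for i, v in enumerate(values):
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "structure_id": "Diaphragm",
                        "method": method,
                        "fractional_variation": v,
                    }
                )
        return pd.DataFrame(rows), fv

    def test_medians_match_sort_and_pick(self):
        table, fv = self._hand_table()
        out = compare_methods_table(table)
        row = out.iloc[0]
        assert row["edibh_median_pct"] == pytest.approx(100 * sorted(fv["eDIBH"])[2])
        assert row["hfpv_median_pct"] == pytest.approx(100 * sorted(fv["HFPV"])[2])
        assert row["edibh_max_pct"] == pytest.approx(100 * max(fv["eDIBH"]))
        assert not row["reliable"]  # only 5 pairs

    def test_identical_pairs_degenerate_p_one(self):
        table, _ = self._hand_table()
        sym = table.copy()
        sym.loc[sym["method"] == "HFPV", "fractional_variation"] = sym.loc[
            sym["method"] == "eDIBH", "fractional_variation"
        ].to_numpy()
        out = compare_methods_table(sym)
        assert out.iloc[0]["p_value"] == 1.0

    def test_diaphragm_power_with_threefold_noise(self):
        """HFPV noise 3x eDIBH at 20 subjects: diaphragm significant in >=90%
        of replicates."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            config = CohortConfig(
                n_subjects=20, sex_split=(10, 10),
                method_noise_sd=isotropic_noise(2.0, 3.0), seed=seed,
            )
            variation = variation_table(
                radial_distance_table(generate_cohort(config).landmarks)
            )
            out = compare_methods_table(variation)
            p = out.loc[out["structure_id"] == "Diaphragm", "p_value"].iloc[0]
            hits += p < 0.05
        assert hits >= 0.9 * n_seeds


def make_gamma_table(negative_counts, entries=10):
    """Synthetic γ grid with a prescribed number of negative entries per
    subject (stand-in for a measured subject × structure grid)."""
    rows = []
    for i, k in enumerate(negative_counts):
        for j in range(entries):
            gamma = -0.3 if j < k else 0.3
            rows.append(
                {
                    "subject_id": f"S{i:02d}",
                    "structure_id": f"E{j}",
                    "eDIBH": 0.01,
                    "HFPV": 0.01,
                    "gamma": gamma,
                    "defined": True,
                }
            )
    return pd.DataFrame(rows)


class TestCountPreferences:
    def test_all_negative_subject_is_green(self):
        summary = count_preferences(make_gamma_table([10]))
        assert summary.per_subject.iloc[0]["classification"] == "green"
        assert summary.per_subject.iloc[0]["n_negative"] == 10

    def test_clearly_distinguished_fraction(self):
        """11 green and 4 orange subjects -> 73 % of clear subjects favour
        eDIBH."""
        counts = [9] * 11 + [2] * 4 + [5] * 6
        summary = count_preferences(make_gamma_table(counts))
        assert summary.n_green == 11
        assert summary.n_orange == 4
        assert round(100 * summary.clear_fraction_edibh) == 73

    def test_overall_fraction(self):
        """140 negative entries of 200 -> overall fraction 0.70."""
        counts = [7] * 20  # 20 subjects x 10 entries, 7 negative each
        summary = count_preferences(make_gamma_table(counts))
        assert summary.n_defined == 200
        assert summary.n_negative == 140
        assert summary.overall_negative_fraction == pytest.approx(0.70)

    def test_zero_gamma_not_counted_negative(self):
        table = make_gamma_table([5])
        table.loc[0, "gamma"] = 0.0  # was negative; now a tie
        summary = count_preferences(table)
        assert summary.per_subject.iloc[0]["n_negative"] == 4

    def test_missing_entries_reported(self):
        table = make_gamma_table([8]).iloc[:-2]  # drop 2 entries
        summary = count_preferences(table)
        assert summary.per_subject.iloc[0]["n_missing"] == 2


class TestBinomialPreference:
    def test_all_perfect(self):
        assert fit_binomial_preference([10, 10, 10])["p_pooled"] == 1.0

    def test_pooled_fraction(self):
        assert fit_binomial_preference([7, 7])["p_pooled"] == pytest.approx(0.70)

    def test_pooled_matches_grid_search_oracle(self):
        counts = np.array([9, 8, 10, 3, 7, 6, 2, 9])
        est = fit_binomial_preference(counts)["p_pooled"]
        from scipy import stats

        grid = np.arange(0.001, 1.0, 0.001)
        loglik = np.array(
            [stats.binom.logpmf(counts, 10, p).sum() for p in grid]
        )
        assert abs(est - grid[np.argmax(loglik)]) <= 0.001

    def test_clear_subject_variant_uses_only_clear_subjects(self):
        out = fit_binomial_preference([10, 9, 2, 5, 6])
        assert out["n_clear_subjects"] == 3
        assert 0.0 < out["p_clear_subjects"] < 1.0

    def test_counts_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fit_binomial_preference([11])
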