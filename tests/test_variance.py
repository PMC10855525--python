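"""CV arithmetic, grouping schemes, replicate technical CV, global correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import tearvar as tv
from tearvar import variance
from tearvar.tables import ProteinQuantTable


class TestCvPercent:
    @pytest.mark.parametrize("values, expected", [
        ([5, 5, 5], 0.0),
        ([1, 2, 3], 50.0),          # sd=1, mean=2
        ([10, 10, 10, 10], 0.0),
    ])
    def test_hand_values(self, values, expected):
        assert variance.cv_percent(values) == pytest.approx(expected)

    @pytest.mark.parametrize("values", [[7], [], [0, 0, 0], [np.nan, 3]])
    def test_degenerate_inputs_are_missing(self, values):
        assert np.isnan(variance.cv_percent(values))

    @given(st.lists(st.floats(0.1, 1e6), min_size=2, max_size=20),
           st.floats(0.001, 1e3))
    def test_scale_invariance(self, values, c):
        base = variance.cv_percent(values)
        scaled = variance.cv_percent([v * c for v in values])
        if np.isnan(base):
            assert np.isnan(scaled)
        else:
            assert scaled == pytest.approx(base, rel=1e-6)


class TestBuildGrouping:
    def test_intra_eye_six_groups_of_five(self, default_dataset):
        scheme = variance.build_grouping(default_dataset.samples, "intra_eye")
        groups = scheme.groups()
        assert len(groups) == 6
        assert all(len(v) == 5 for v in groups.values())

    def test_randomized_groups_are_person_balanced(self, default_dataset):
        scheme = variance.build_grouping(default_dataset.samples,
                                         "interpersonal_randomized", seed=11)
        groups = scheme.groups()
        assert len(groups) == 3
        person = default_dataset.samples.df["person"]
        for members in groups.values():
            assert len(members) == 10
            counts = person.loc[members].value_counts()
            assert counts.max() - counts.min() <= 1

    def test_randomized_reproducible_and_seed_required(self, default_dataset):
        a = variance.build_grouping(default_dataset.samples,
                                    "interpersonal_randomized", seed=5)
        b = variance.build_grouping(default_dataset.samples,
                                    "interpersonal_randomized", seed=5)
        assert a.assignment.equals(b.assignment)
        with pytest.raises(ValueError):
            variance.build_grouping(default_dataset.samples, "interpersonal_randomized")

    def test_overall_single_group(self, default_dataset):
        scheme = variance.build_grouping(default_dataset.samples, "overall")
        assert len(scheme.groups()) == 1


def test_group_cv_matches_bruteforce_loop(default_dataset):
    table = default_dataset.proteins.subset_proteins(
        default_dataset.proteins.protein_ids[:5])
    scheme = variance.build_grouping(default_dataset.samples, "intrapersonal")
    cvt = variance.group_cv(table, scheme)
    for pid in table.protein_ids:
        per_group = []
        for label, cols in scheme.groups().items():
            vals = [table.values.at[pid, c] for c in cols]
            vals = [v for v in vals if np.isfinite(v)]
            if len(vals) < 3 or np.mean(vals) <= 0:
                expected = np.nan
            else:
                expected = 100 * np.std(vals, ddof=1) / np.mean(vals)
            got = cvt.cv.at[pid, label]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)
                per_group.append(expected)
        if per_group:
            assert cvt.summary[pid] == pytest.approx(np.median(per_group))


def test_constant_within_person_gives_zero_intrapersonal_cv(default_dataset):
    samples = default_dataset.samples
    cols = samples.biological_ids()
    vals = pd.DataFrame(index=["P0"], columns=cols, dtype=float)
    for person in samples.persons:
        ids = [s for s in cols if samples.df.at[s, "person"] == person]
        vals.loc["P0", ids] = float(hash(person) % 7 + 1)
    table = ProteinQuantTable(vals, pd.Series({"P0": "G0"}))
    scheme = variance.build_grouping(samples, "intrapersonal")
    cvt = variance.group_cv(table, scheme)
    assert cvt.summary["P0"] == pytest.approx(0.0)


def test_overall_cv_exceeds_intrapersonal_with_person_effects(default_dataset):
    table = default_dataset.proteins
    intra = variance.group_cv(table, variance.build_grouping(
        default_dataset.samples, "intrapersonal"))
    overall = variance.group_cv(table, variance.build_grouping(
        default_dataset.samples, "overall"))
    assert overall.median_cv() >= intra.median_cv()


class TestTechnicalCV:
    def test_identical_columns(self):
        vals = pd.DataFrame({"r1": [1.0, 2, 3], "r2": [1.0, 2, 3], "r3": [1.0, 2, 3]},
                            index=list("abc"))
        res = variance.technical_cv(ProteinQuantTable(vals, pd.Series(list("abc"), index=list("abc"))))
        assert res.median == pytest.approx(0.0)
        assert res.frac_below_10 == 1.0
        assert res.frac_below_20 == 1.0

    def test_single_column_rejected(self):
        vals = pd.DataFrame({"r1": [1.0, 2]}, index=list("ab"))
        with pytest.raises(ValueError):
            variance.technical_cv(ProteinQuantTable(vals, pd.Series(list("ab"), index=list("ab"))))

    def test_bias_correction_recovers_generating_cv(self):
        """Median-unbiased correction: triplicate lognormal noise at CV 20%
        is recovered near 20%, while the raw median sits well below."""
        rng = np.random.default_rng(0)
        base = rng.uniform(1e5, 1e7, 400)
        reps = base[:, None] * np.exp(rng.normal(0, np.sqrt(np.log(1.04)), (400, 3)))
        vals = pd.DataFrame(reps, columns=["r1", "r2", "r3"])
        vals.index = [f"P{i}" for i in range(400)]
        table = ProteinQuantTable(vals, pd.Series(vals.index, index=vals.index))
        corrected = variance.technical_cv(table).median
        raw = variance.technical_cv(table, bias_correction=False).median
        assert corrected == pytest.approx(20.0, abs=2.0)
        assert raw < corrected


class TestThresholdFraction:
    def test_all_zero(self):
        s = pd.Series([0.0, 0.0, 0.0])
        assert variance.cv_threshold_fraction(s, 20) == 1.0

    def test_half(self):
        s = pd.Series([10.0, 30.0])
        assert variance.cv_threshold_fraction(s, 20) == 0.5

    def test_matches_bruteforce_on_summary(self, default_dataset):
        scheme = variance.build_grouping(default_dataset.samples, "intrapersonal")
        cvt = variance.group_cv(default_dataset.proteins, scheme)
        got = variance.cv_threshold_fraction(cvt, 50)
        finite = cvt.summary.dropna()
        assert got == pytest.approx(sum(v < 50 for v in finite) / len(finite))

    def test_strictness(self):
        s = pd.Series([20.0, 19.999])
        assert variance.cv_threshold_fraction(s, 20) == 0.5


class TestGlobalCorrelations:
    def test_protein_proportional_to_volume(self, default_dataset):
        samples = default_dataset.samples
        cols = samples.biological_ids()
        vals = pd.DataFrame(
            [samples.df.loc[cols, "volume"].to_numpy() * 3.0],
            index=["P0"], columns=cols)
        table = ProteinQuantTable(vals, pd.Series({"P0": "G0"}))
        per, _ = variance.global_correlations(table, samples, "volume")
        assert per.loc["P0", "r"] == pytest.approx(1.0)

    def test_hand_computed_four_points(self):
        from tearvar.tables import SampleTable

        cols = ["a", "b", "c", "d"]
        sdf = pd.DataFrame({"person": "D1", "eye": ["OD", "OS", "OD", "OS"],
                            "day": [1, 1, 2, 2], "volume": [1.0, 2, 3, 4],
                            "tpc": 1.0, "role": "biological"}, index=cols)
        samples = SampleTable(sdf)
        vals = pd.DataFrame([[1.0, 3.0, 2.0, 4.0]], index=["P0"], columns=cols)
        table = ProteinQuantTable(vals, pd.Series({"P0": "G0"}))
        per, _ = variance.global_correlations(table, samples, "volume")
        # cov = 4/3, sx = sy = sqrt(5/3) -> r = 0.8 (hand computation)
        assert per.loc["P0", "r"] == pytest.approx(0.8)

    def test_independent_volume_and_tpc_rarely_correlate(self):
        strong = 0
        for seed in range(20):
            ds = tv.generate_dataset(tv.SimConfig(
                seed=400 + seed, volume_tpc_correlation=0.0, n_proteins=20,
                outlier_probability=0.0))
            _, (r, _) = variance.global_correlations(ds.proteins, ds.samples, "volume")
            strong += abs(r) >= 0.5
        assert strong <= 1  # >= 95% of seeds below 0.5

    def test_constant_variable_is_missing(self, clean_dataset):
        samples = clean_dataset.samples.copy()
        samples.df["volume"] = 2.0
        per, (r, p) = variance.global_correlations(clean_dataset.proteins, samples,
                                                   "volume")
        assert per["r"].isna().all()
        assert np.isnan(r)
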