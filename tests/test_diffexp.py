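"""Permutation-FDR differential analysis: nulls, power, symmetry, paired tests."""

import numpy as np
import pandas as pd
import pytest

import tearvar as tv
from tearvar import diffexp, normalize
from tearvar.tables import ProteinQuantTable, SampleTable


def _two_person_samples(n_per=10):
    cols = [f"{p}_s{i}" for p in ("D1", "D2") for i in range(n_per)]
    sdf = pd.DataFrame({
        "person": [c.split("_")[0] for c in cols],
        "eye": ["OD" if int(c.split("s")[-1]) % 2 == 0 else "OS" for c in cols],
        "day": [int(c.split("s")[-1]) // 2 + 1 for c in cols],
        "volume": 1.0, "tpc": 1.0, "role": "biological"}, index=cols)
    return SampleTable(sdf)


def _table(arr, columns):
    idx = [f"P{i}" for i in range(arr.shape[0])]
    return ProteinQuantTable(pd.DataFrame(arr, index=idx, columns=columns, dtype=float),
                             pd.Series(idx, index=idx))


def test_literal_copies_yield_zero_significant():
    rng = np.random.default_rng(0)
    samples = _two_person_samples(5)
    block = rng.lognormal(8, 1, (40, 5))
    arr = np.hstack([block, block])  # D2 columns literally copy D1
    res = diffexp.pairwise_differential(_table(arr, samples.sample_ids), samples,
                                        "D1", "D2", seed=1)
    assert int(res.stats["significant"].sum()) == 0
    assert np.allclose(res.stats["log2fc"], 0.0)


def test_null_false_positive_rate_controlled():
    """Identically distributed persons: average significant fraction stays at
    or below the FDR target."""
    rng = np.random.default_rng(1)
    fps = []
    for seed in range(15):
        samples = _two_person_samples(10)
        arr = rng.lognormal(8, 0.5, (150, 20))
        res = diffexp.pairwise_differential(_table(arr, samples.sample_ids),
                                            samples, "D1", "D2", seed=seed)
        fps.append(res.stats["significant"].mean())
    assert np.mean(fps) <= 0.05


def test_power_on_injected_shift():
    """20 proteins shifted 4x between persons, noise CV ~20%: nearly all
    recovered with at most a stray false positive."""
    recovered, false_pos = [], []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        samples = _two_person_samples(10)
        arr = rng.lognormal(8, np.sqrt(np.log(1.04)), (200, 20)) * 1000
        arr[:20, :10] *= 4.0
        res = diffexp.pairwise_differential(_table(arr, samples.sample_ids),
                                            samples, "D1", "D2", seed=seed)
        sig = res.significant_ids
        recovered.append(sum(f"P{i}" in sig for i in range(20)))
        false_pos.append(sum(pid in sig for pid in res.stats.index[20:]))
    assert np.median(recovered) >= 18
    assert np.median(false_pos) <= 1


def test_volcano_symmetry(default_dataset):
    normed = normalize.normalize(default_dataset.proteins, "cluster", k=4).table
    ab = diffexp.pairwise_differential(normed, default_dataset.samples,
                                       "D1", "D2", seed=3)
    ba = diffexp.pairwise_differential(normed, default_dataset.samples,
                                       "D2", "D1", seed=3)
    pd.testing.assert_series_equal(ab.stats["log2fc"], -ba.stats["log2fc"],
                                   check_names=False)
    pd.testing.assert_series_equal(ab.stats["p"], ba.stats["p"], check_names=False)
    assert ab.significant_ids == ba.significant_ids


def test_presence_filter_and_minimum_group_size(default_dataset):
    normed = default_dataset.proteins
    res = diffexp.pairwise_differential(normed, default_dataset.samples,
                                        "D1", "D2", min_presence=0.7, seed=0)
    obs = normed.observed()
    ids_a = [s for s in default_dataset.samples.biological_ids()
             if default_dataset.samples.df.at[s, "person"] == "D1"]
    kept = res.stats.index
    assert (obs.loc[kept, ids_a].mean(axis=1) >= 0.7).all()
    with pytest.raises(ValueError):
        diffexp.pairwise_differential(normed, default_dataset.samples, "D1", "D2",
                                      sample_set="representative",
                                      representative={"D1": ids_a[:2], "D2": ids_a[:2]})


class TestPairedEye:
    def test_identical_eyes_nothing_significant(self):
        rng = np.random.default_rng(2)
        cols = [f"D1_{e}_d{d}" for d in range(1, 6) for e in ("OD", "OS")]
        sdf = pd.DataFrame({
            "person": "D1", "eye": [c.split("_")[1] for c in cols],
            "day": [int(c[-1]) for c in cols],
            "volume": 1.0, "tpc": 1.0, "role": "biological"}, index=cols)
        samples = SampleTable(sdf)
        block = rng.lognormal(8, 1, (30, 5))
        arr = np.empty((30, 10))
        arr[:, 0::2] = block
        arr[:, 1::2] = block
        res = diffexp.paired_eye_test(_table(arr, cols), samples, "D1")
        assert int(res.stats["significant"].sum()) == 0
        assert np.allclose(res.stats["log2fc"], 0.0)

    def test_sign_flip_p_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        cols = [f"D1_{e}_d{d}" for d in range(1, 6) for e in ("OD", "OS")]
        sdf = pd.DataFrame({
            "person": "D1", "eye": [c.split("_")[1] for c in cols],
            "day": [int(c[-1]) for c in cols],
            "volume": 1.0, "tpc": 1.0, "role": "biological"}, index=cols)
        samples = SampleTable(sdf)
        arr = rng.lognormal(8, 0.5, (3, 10))
        res = diffexp.paired_eye_test(_table(arr, cols), samples, "D1", s0=0.1)
        log2 = np.log2(arr)
        delta = log2[:, 0::2] - log2[:, 1::2]
        from itertools import product

        for i, pid in enumerate(res.stats.index):
            d_obs = delta[i]

            def stat(x):
                return np.mean(x) / (np.std(x, ddof=1) / np.sqrt(len(x)) + 0.1)

            ref = abs(stat(d_obs))
            count = 0
            total = 0
            for signs in product([1, -1], repeat=5):
                total += 1
                count += abs(stat(d_obs * np.array(signs))) >= ref - 1e-12
            assert res.stats["p"].iloc[i] == pytest.approx(count / total)

    def test_no_eye_effect_in_generator(self, default_dataset):
        normed = normalize.normalize(default_dataset.proteins, "cluster", k=4).table
        for person in default_dataset.samples.persons:
            res = diffexp.paired_eye_test(normed, default_dataset.samples, person)
            assert int(res.stats["significant"].sum()) == 0


class TestCrossComparison:
    def _fake_result(self, universe, sig, label):
        stats_df = pd.DataFrame({
            "gene": [f"G{p}" for p in universe],
            "log2fc": 0.0, "t": 0.0, "p": 1.0, "d": 0.0,
            "significant": [p in sig for p in universe]}, index=universe)
        return diffexp.DiffResult(comparison=label, stats=stats_df, threshold_d=None)

    def test_set_algebra(self):
        u = ["A", "B", "C", "D"]
        results = [self._fake_result(u, {"A", "B"}, "r1"),
                   self._fake_result(u, {"B", "C"}, "r2"),
                   self._fake_result(u, {"B"}, "r3")]
        out = diffexp.cross_comparison_summary(results)
        assert set(out.index[out["in_all"]]) == {"B"}
        assert set(out.index[out["in_at_least_2"]]) == {"B"}
        assert set(out.index) == {"A", "B", "C"}

    def test_duplicated_result(self):
        u = ["A", "B"]
        r = self._fake_result(u, {"A"}, "r1")
        out = diffexp.cross_comparison_summary([r, r])
        assert set(out.index[out["in_all"]]) == {"A"}

    def test_class_annotation(self):
        assert diffexp.annotate_protein_class("IGHA1") == "Ig"
        assert diffexp.annotate_protein_class("KRT10") == "keratin"
        assert diffexp.annotate_protein_class("CST4") == "cystatin"
        assert diffexp.annotate_protein_class("LTF") == "other"

    def test_truth_shifted_proteins_in_all_set(self, default_dataset):
        """A protein shifted in one person appears in both of that person's
        pairwise comparisons; with three persons each truth protein sits in
        exactly 2 of 3 comparisons."""
        ds = default_dataset
        normed = normalize.normalize(ds.proteins, "cluster", k=4).table
        results = []
        pairs = [("D1", "D2"), ("D1", "D3"), ("D2", "D3")]
        for i, (a, b) in enumerate(pairs):
            results.append(diffexp.pairwise_differential(normed, ds.samples, a, b,
                                                         seed=10 + i))
        out = diffexp.cross_comparison_summary(results)
        truth_ids = [r["protein_group_id"] for r in ds.truth["differential"]
                     if r["protein_group_id"] in out.index.union(results[0].stats.index)]
        in2 = set(out.index[out["in_at_least_2"]])
        hits = sum(pid in in2 for pid in truth_ids)
        assert hits >= 0.6 * len(truth_ids)
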