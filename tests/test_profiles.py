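import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circasplice.profiles import (
    TemporalProfile,
    acrophase_amplitude,
    bonferroni_posthoc,
    fold_changes,
    hierarchical_order,
    moving_average,
    profile_correlation,
    significance_code,
    smooth_zscore,
    snr_rank,
    sota_cluster,
    twoway_anova,
)


def make_profile(means, times=None):
    times = tuple(range(0, 6 * len(means), 6)) if times is None else tuple(times)
    return TemporalProfile(times, tuple(means), (0.0,) * len(means), (3,) * len(means))


class TestFoldChanges:
    def test_up(self):
        folds = fold_changes(make_profile([2.0, 4.0]))
        assert folds[6] == pytest.approx(2.0)
        assert folds[0] == pytest.approx(1.0)

    def test_down_signed(self):
        folds = fold_changes(make_profile([2.0, 1.0]))
        assert folds[6] == pytest.approx(-2.0)

    def test_flat(self):
        folds = fold_changes(make_profile([3.0, 3.0, 3.0]))
        assert all(v == pytest.approx(1.0) for v in folds.values())

    def test_sign_flip_preserves_magnitude(self):
        up = fold_changes(make_profile([2.0, 5.0]))[6]
        down = fold_changes(make_profile([5.0, 2.0]))[6]
        assert up == pytest.approx(-down)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fold_changes(make_profile([1.0, -2.0]))


class TestAcrophaseAmplitude:
    def test_positive_peak(self):
        m = acrophase_amplitude({0: 1.0, 6: 1.2, 12: 2.5, 18: -1.43})
        assert m.acrophase == 12
        assert m.amplitude == pytest.approx(2.5)

    def test_negative_amplitude(self):
        m = acrophase_amplitude({0: 1.0, 6: -3.0, 12: 1.1, 18: 1.0})
        assert m.acrophase == 12
        assert m.amplitude == pytest.approx(-3.0)

    def test_flat_tie_rule(self):
        m = acrophase_amplitude({0: 1.0, 6: 1.0, 12: 1.0})
        assert m.acrophase == 0
        assert m.amplitude == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            acrophase_amplitude({})


class TestProfileCorrelation:
    def test_exact_linearity(self):
        r, r2, p = profile_correlation(make_profile([1, 2, 3]), make_profile([2, 4, 6]))
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-6)

    def test_sign_flip(self):
        r, _, _ = profile_correlation(make_profile([1, 2, 4]), make_profile([4, 2, 1]))
        assert r < 0

    def test_oracle(self, rng):
        a = make_profile(rng.uniform(1, 5, 8))
        b = make_profile(rng.uniform(1, 5, 8))
        r, r2, p = profile_correlation(a, b)
        x, y = np.array(a.means), np.array(b.means)
        n = len(x)
        r_ref = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        t = r_ref * np.sqrt((n - 2) / (1 - r_ref**2))
        p_ref = 2 * stats.t.sf(abs(t), n - 2)
        assert r == pytest.approx(r_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            profile_correlation(make_profile([1, 1, 1]), make_profile([1, 2, 3]))


class TestSmoothZscore:
    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            smooth_zscore([2.0] * 8)

    def test_window_one_is_plain_zscore(self):
        z = smooth_zscore(np.arange(10.0), window=1)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_oracle_window5(self):
        x = np.cos(2 * np.pi * np.arange(12) / 12)
        smoothed = moving_average(x, 5)
        # brute-force truncated windows
        for i in range(12):
            lo, hi = max(0, i - 2), min(12, i + 3)
            assert smoothed[i] == pytest.approx(np.mean(x[lo:hi]), abs=1e-12)
        z = smooth_zscore(x, 5)
        ref = (smoothed - smoothed.mean()) / smoothed.std(ddof=0)
        assert np.allclose(z, ref, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth_zscore([1.0, 2.0], window=5)


class TestSnrRank:
    def test_identical_noiseless_top(self, rng):
        rhythm = np.cos(2 * np.pi * np.arange(12) / 12) + 2
        noisy = rhythm + rng.normal(0, 0.3, 12)
        table = snr_rank({"clean": rhythm, "noisy": noisy}, {"clean": rhythm, "noisy": noisy + rng.normal(0, 0.3, 12)})
        assert table.loc["clean", "reproducibility"] == pytest.approx(1.0)
        assert table.loc["clean", "rank"] == 1

    def test_flat_profile_lowest(self, rng):
        rhythm = np.cos(2 * np.pi * np.arange(12) / 12) + 2
        flat = np.full(12, 2.0)
        table = snr_rank({"r": rhythm, "flat": flat}, {"r": rhythm, "flat": flat})
        assert table.loc["flat", "snr"] == 0.0
        assert table.loc["flat", "rank"] == 2

    def test_day_average(self):
        table = snr_rank({"a": [1.0, 3.0]}, {"a": [3.0, 5.0]}, window=1)
        assert np.allclose(table.loc["a", "averaged"], [2.0, 4.0])

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError, match="mismatch"):
            snr_rank({"a": [1, 2, 3]}, {"a": [1, 2]})


def cosine_profile(phase, times, noise=0.0, rng=None):
    x = np.cos(2 * np.pi * (np.asarray(times, float) - phase) / 24)
    if noise and rng is not None:
        x = x + rng.normal(0, noise, len(x))
    return (x - x.mean()) / x.std()


class TestSotaCluster:
    times = np.arange(0, 24, 3)

    def test_duplicates_cocluster(self):
        prof = {f"p{i}": cosine_profile(0, self.times) for i in range(4)}
        prof.update({f"q{i}": cosine_profile(12, self.times) for i in range(4)})
        out = sota_cluster(prof, max_clusters=2)
        assert len({out.labels[f"p{i}"] for i in range(4)}) == 1
        assert len({out.labels[f"q{i}"] for i in range(4)}) == 1

    def test_antiphase_partition(self):
        prof = {f"a{i}": cosine_profile(0, self.times) for i in range(5)}
        prof.update({f"b{i}": cosine_profile(12, self.times) for i in range(5)})
        out = sota_cluster(prof, max_clusters=2)
        a_labels = {out.labels[f"a{i}"] for i in range(5)}
        b_labels = {out.labels[f"b{i}"] for i in range(5)}
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_four_phase_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(17)
        prof, truth = {}, []
        for phase in (0, 6, 12, 18):
            for i in range(10):
                prof[f"{phase}_{i}"] = cosine_profile(phase, self.times, noise=0.15, rng=rng)
                truth.append(phase)
        out = sota_cluster(prof, max_clusters=4, seed=1)
        labels = [out.labels[k] for k in prof]
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_determinism(self):
        rng = np.random.default_rng(2)
        prof = {f"p{i}": cosine_profile(rng.choice([0, 12]), self.times, 0.2, rng) for i in range(12)}
        a = sota_cluster(prof, max_clusters=3, seed=7)
        b = sota_cluster(prof, max_clusters=3, seed=7)
        assert a.labels == b.labels

    def test_too_few_profiles(self):
        with pytest.raises(ValueError, match="profiles"):
            sota_cluster({"a": [1.0, 2.0]}, max_clusters=2)

    def test_centroids_on_profile_grid(self):
        prof = {f"p{i}": cosine_profile(p, self.times) for i, p in enumerate((0, 0, 12, 12))}
        out = sota_cluster(prof, max_clusters=2)
        for c in out.centroids.values():
            assert len(c) == len(self.times)


def average_linkage_oracle(profiles):
    """Brute-force all-pairs average linkage with 1 - Pearson r distance."""
    ids = list(profiles)
    clusters = {i: [i] for i in range(len(ids))}
    dist = {}
    mats = [np.asarray(profiles[k], float) for k in ids]
    for i, j in itertools.combinations(range(len(ids)), 2):
        dist[(i, j)] = 1 - np.corrcoef(mats[i], mats[j])[0, 1]
    merges = []
    next_id = len(ids)
    while len(clusters) > 1:
        best = min(
            (
                (np.mean([dist[tuple(sorted((a, b)))] for a in clusters[ci] for b in clusters[cj]]), ci, cj)
                for ci, cj in itertools.combinations(sorted(clusters), 2)
            )
        )
        d, ci, cj = best
        merges.append((ci, cj, d))
        clusters[next_id] = clusters.pop(ci) + clusters.pop(cj)
        next_id += 1
    return merges


class TestHierarchicalOrder:
    def test_identical_pair_merges_first(self):
        t = np.arange(8.0)
        prof = {
            "a": np.cos(t), "b": np.cos(t), "c": -np.cos(t),
        }
        order, linkage = hierarchical_order(prof)
        first = {int(linkage[0, 0]), int(linkage[0, 1])}
        assert first == {0, 1}  # a and b

    def test_merge_count(self, rng):
        prof = {f"p{i}": rng.normal(size=6) for i in range(7)}
        _, linkage = hierarchical_order(prof)
        assert linkage.shape[0] == 6

    def test_oracle_merge_sequence(self, rng):
        prof = {f"p{i}": rng.normal(size=10) for i in range(5)}
        _, linkage = hierarchical_order(prof)
        merges = average_linkage_oracle(prof)
        for row, (ci, cj, d) in zip(linkage, merges):
            assert {int(row[0]), int(row[1])} == {ci, cj}
            assert row[2] == pytest.approx(d, abs=1e-10)

    def test_constant_profile_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            hierarchical_order({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})


def balanced_design(n_a=2, n_b=4, n=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_a):
        for b in range(n_b):
            for _ in range(n):
                rows.append((rng.normal(a * 0.5 + b * 0.3), f"A{a}", f"B{b}"))
    frame = pd.DataFrame(rows, columns=["y", "A", "B"])
    return frame


class TestTwowayAnova:
    def test_pure_additive_no_interaction(self):
        rows = []
        for a in range(2):
            for b in range(3):
                for r in range(2):
                    rows.append((1.0 * a + 2.0 * b, a, b))
        frame = pd.DataFrame(rows, columns=["y", "A", "B"])
        res = twoway_anova(frame["y"], frame["A"], frame["B"])
        assert res.ss["AB"] == pytest.approx(0.0, abs=1e-10)
        assert res.p_interaction == 1.0

    def test_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        frame = balanced_design(seed=5)
        res = twoway_anova(frame["y"], frame["A"], frame["B"])
        fit = ols("y ~ C(A) * C(B)", data=frame).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res.p_main_A == pytest.approx(table.loc["C(A)", "PR(>F)"], abs=1e-10)
        assert res.p_main_B == pytest.approx(table.loc["C(B)", "PR(>F)"], abs=1e-10)
        assert res.p_interaction == pytest.approx(table.loc["C(A):C(B)", "PR(>F)"], abs=1e-10)

    def test_ss_partition(self):
        frame = balanced_design(seed=6)
        res = twoway_anova(frame["y"], frame["A"], frame["B"])
        assert res.ss["A"] + res.ss["B"] + res.ss["AB"] + res.ss["error"] == pytest.approx(
            res.ss["total"], abs=1e-8
        )

    def test_null_p_uniform(self):
        ps = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=2 * 2 * 3)
            a = np.repeat([0, 1], 6)
            b = np.tile(np.repeat([0, 1], 3), 2)
            ps.append(twoway_anova(y, a, b).p_interaction)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unbalanced_rejected(self):
        frame = balanced_design().iloc[:-1]
        with pytest.raises(ValueError, match="nbalanced|replicates"):
            twoway_anova(frame["y"], frame["A"], frame["B"])


class TestBonferroniPosthoc:
    def test_identical_cells_ns(self):
        rows = [(v, a, b) for a in (0, 1) for b in (0, 1) for v in (1.0, 2.0, 3.0)]
        frame = pd.DataFrame(rows, columns=["y", "A", "B"])
        out = bonferroni_posthoc(frame["y"], frame["A"], frame["B"], [((0, 0), (1, 0))])
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)
        assert out["code"].iloc[0] == "Ns"

    def test_single_comparison_unadjusted(self):
        frame = balanced_design(n_a=2, n_b=2, seed=8)
        out = bonferroni_posthoc(
            frame["y"], frame["A"], frame["B"], [(("A0", "B0"), ("A1", "B0"))]
        )
        assert out["p_bonferroni"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_multiplication_and_cap(self):
        assert significance_code(0.06) == "Ns"
        assert significance_code(0.03) == "*"
        assert significance_code(0.004) == "**"
        assert significance_code(5e-5) == "****"
        frame = balanced_design(n_a=2, n_b=2, seed=9)
        planned = [(("A0", "B0"), ("A1", "B0")), (("A0", "B1"), ("A1", "B1"))]
        out = bonferroni_posthoc(frame["y"], frame["A"], frame["B"], planned)
        assert np.allclose(out["p_bonferroni"], np.minimum(1.0, out["p_raw"] * 2))

    def test_empty_planned_rejected(self):
        frame = balanced_design()
        with pytest.raises(ValueError, match="empty"):
            bonferroni_posthoc(frame["y"], frame["A"], frame["B"], [])


class TestTemporalProfile:
    def test_from_replicates(self):
        prof = TemporalProfile.from_replicates([0, 6], [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert prof.means == (2.0, 5.0)
        assert prof.ns == (3, 3)
        assert prof.sems[0] == pytest.approx(1.0 / np.sqrt(3))

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError, match="increasing"):
            TemporalProfile((6.0, 0.0), (1.0, 2.0), (0.0, 0.0), (1, 1))
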