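"""Region aggregation, demographic correlation, source comparison, age RMSE."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cortexgnn as cg
from cortexgnn.downstream_stats import table_to_matrix


def make_subject(values, labels, sid="s0", hemi="L"):
    """Minimal subject carrying a thickness array on a tetrahedron-like mesh."""
    n = len(values)
    verts = np.zeros((n, 3))
    verts[:, 0] = np.arange(n)
    verts[:, 1] = 1.0
    mesh = cg.SurfaceMesh(vertices=verts, faces=np.empty((0, 3), dtype=int))
    return cg.Subject(id=sid, hemisphere=hemi, mesh=mesh,
                      labels=np.asarray(labels), thickness=np.asarray(values, float),
                      curvature=np.zeros(n), connectivity=None,
                      age=30.0, mmse=30, education=16)


class TestRegionMeans:
    def test_simple_arithmetic(self):
        s = make_subject([1, 1, 3, 3], [0, 0, 1, 1])
        assert np.array_equal(cg.region_means(s, "thickness", n_regions=2),
                              [1.0, 3.0])

    def test_missing_region_is_nan_and_skipped_downstream(self):
        s = make_subject([1, 1, 3, 3], [0, 0, 1, 1])
        means = cg.region_means(s, "thickness",
                                labels=np.array([0, 0, 0, 0]), n_regions=8)
        assert np.isnan(means[1:]).all()
        table = cg.build_region_table([s], "thickness",
                                      labels_by_subject={("s0", "L"): np.zeros(4, int)},
                                      n_regions=8)
        assert set(table.region) == {0}

    def test_two_hemispheres_give_length_70_vector(self):
        """At K=35 per hemisphere the cross-hemisphere feature vector for the
        age regression has length 70."""
        cohort = cg.generate_cohort(cg.CohortParams(
            n_subjects=3, subdivisions=2, k_regions=35,
            include_connectivity=False, seed=2))
        table = cg.build_region_table(cohort.subjects, "thickness", n_regions=35)
        x, ids = table_to_matrix(table)
        assert x.shape == (3, 70)

    def test_predicted_labels_swap_only_label_source(self, small_cohort):
        s = small_cohort.filter("L")[0]
        ref = cg.region_means(s, "thickness", n_regions=10)
        pred_labels = np.roll(s.labels, 1)
        swapped = cg.region_means(s, "thickness", labels=pred_labels, n_regions=10)
        assert not np.allclose(ref, swapped, equal_nan=True)


class TestCorrelate:
    def make_table(self, values_by_subject):
        rows = [{"subject_id": sid, "hemisphere": "L", "region": 0, "value": v}
                for sid, v in values_by_subject.items()]
        return pd.DataFrame(rows)

    def test_exact_linear_data(self):
        table = self.make_table({f"s{i}": float(i) for i in range(10)})
        cov = {f"s{i}": 20.0 + 2 * i for i in range(10)}
        res = cg.correlate(table, cov)
        region_row = res[res.region == 0].iloc[0]
        assert region_row.r == pytest.approx(1.0)
        assert region_row.p < 1e-10

    def test_permuted_covariate_null_calibration(self):
        """Under a permuted covariate the p < 0.05 rate stays inside the
        binomial 99% interval of the nominal 0.05 over 1000 repeats."""
        rng = np.random.default_rng(0)
        n = 40
        values = rng.normal(size=n)
        cov = rng.normal(size=n)
        hits = 0
        reps = 1000
        for _ in range(reps):
            perm = rng.permutation(n)
            _, p = stats.pearsonr(values, cov[perm])
            hits += p < 0.05
        lo, hi = stats.binom.interval(0.99, reps, 0.05)
        assert lo <= hits <= hi

    def test_planted_cohort_recovers_negative_correlation(self):
        cohort = cg.generate_cohort(cg.CohortParams(
            n_subjects=97, hemispheres=("L",), include_connectivity=False, seed=3))
        table = cg.build_region_table(cohort.subjects, "thickness", n_regions=35)
        ages = {s.id: s.age for s in cohort.subjects}
        res = cg.correlate(table, ages)
        cohort_row = res[res.region == -1].iloc[0]
        assert cohort_row.r < 0
        assert cohort_row.p < 0.05

    def test_affine_rescaling_preserves_r(self):
        table = self.make_table({f"s{i}": float(v) for i, v in
                                 enumerate([2.1, 2.5, 1.9, 3.0, 2.2, 2.8])})
        cov = {f"s{i}": a for i, a in enumerate([25, 30, 22, 33, 27, 31])}
        r1 = cg.correlate(table, cov).iloc[0].r
        table2 = table.assign(value=3.5 * table.value - 1.2)
        r2 = cg.correlate(table2, cov).iloc[0].r
        assert r1 == pytest.approx(r2)

    def test_zero_variance_skipped(self):
        table = self.make_table({f"s{i}": 2.5 for i in range(6)})
        cov = {f"s{i}": 20.0 + i for i in range(6)}
        res = cg.correlate(table, cov)
        assert res.empty


def test_age_signal_regions_pass_bonferroni_more_than_null_covariate():
    """The planted age effect drives region-level Bonferroni passes; the
    near-ceiling MMSE score is null by construction, so across seeds the
    age tests must pass the corrected threshold more often."""
    alpha_b = cg.bonferroni_threshold(0.05, 35)
    age_passes = mmse_passes = 0
    for seed in range(10):
        cohort = cg.generate_cohort(cg.CohortParams(
            n_subjects=97, hemispheres=("L",), include_connectivity=False,
            seed=100 + seed))
        table = cg.build_region_table(cohort.subjects, "thickness", n_regions=35)
        ages = {s.id: s.age for s in cohort.subjects}
        mmse = {s.id: float(s.mmse) for s in cohort.subjects}
        res_age = cg.correlate(table, ages, covariate_name="age")
        res_mmse = cg.correlate(table, mmse, covariate_name="mmse")
        age_passes += int((res_age[res_age.region >= 0].p < alpha_b).sum())
        mmse_passes += int((res_mmse[res_mmse.region >= 0].p < alpha_b).sum())
    assert age_passes > mmse_passes


class TestBonferroni:
    def test_study_threshold(self):
        assert round(cg.bonferroni_threshold(0.05, 35), 4) == 0.0014

    def test_identity_at_m_one(self):
        assert cg.bonferroni_threshold(0.037, 1) == 0.037

    def test_strictly_decreasing_in_m(self):
        ts = [cg.bonferroni_threshold(0.05, m) for m in range(1, 50)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_pass_count_nonincreasing_in_m(self):
        rng = np.random.default_rng(1)
        ps = rng.uniform(size=200)
        counts = [(ps < cg.bonferroni_threshold(0.05, m)).sum()
                  for m in range(1, 40)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            cg.bonferroni_threshold(0.05, 0)


class TestCompareSources:
    def test_identical_p_values_give_one(self):
        p = np.linspace(0.01, 0.9, 10)
        assert cg.compare_sources(p, p.copy()) == 1.0

    def test_matches_exhaustive_sign_enumeration(self):
        """n=6 untied pairs: exact two-sided p equals enumeration of all 2^6
        sign assignments of the signed-rank statistic."""
        d = np.array([0.11, -0.23, 0.05, 0.42, -0.08, 0.17])
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        total = 0
        n_extreme = 0
        mean_w = ranks.sum() / 2
        for signs in itertools.product([0, 1], repeat=6):
            w = sum(r for r, s in zip(ranks, signs) if s)
            total += 1
            if abs(w - mean_w) >= abs(w_plus - mean_w) - 1e-12:
                n_extreme += 1
        p_oracle = n_extreme / total
        p = cg.compare_sources(d, np.zeros(6))
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_shifted_p_values_detected(self):
        rng = np.random.default_rng(2)
        pa = rng.uniform(0.0, 0.4, size=30)
        assert cg.compare_sources(pa, pa + 0.5) < 0.05

    def test_all_tied_pairs_convention(self):
        assert cg.compare_sources(np.zeros(5), np.zeros(5)) == 1.0


class TestAgePrediction:
    def make_table_and_ages(self, n=60, signal=False, seed=0):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(22, 35, size=n)
        rows = []
        for i in range(n):
            for hemi in ("L", "R"):
                for r in range(5):
                    v = rng.normal()
                    if signal and hemi == "L" and r == 0:
                        v = ages[i] * 0.1  # exact linear signal in one region
                    rows.append({"subject_id": f"s{i:02d}", "hemisphere": hemi,
                                 "region": r, "value": v})
        return pd.DataFrame(rows), {f"s{i:02d}": ages[i] for i in range(n)}

    def test_mean_baseline_tracks_age_sd(self):
        table, ages = self.make_table_and_ages()
        _, baseline = cg.age_prediction_rmse(table, ages, "mean-baseline", seed=0)
        sd = np.std(list(ages.values()), ddof=0)
        assert abs(baseline - sd) / sd < 0.05

    def test_linear_signal_recovered_by_ridge(self):
        table, ages = self.make_table_and_ages(signal=True)
        rmse, baseline = cg.age_prediction_rmse(table, ages, "linear-ridge", seed=0)
        sd = np.std(list(ages.values()), ddof=0)
        assert rmse < 0.1 * sd
        assert rmse < baseline

    @pytest.mark.parametrize("kind", ["linear-ridge", "decision-tree", "k-nearest"])
    def test_pure_noise_floors_at_age_sd(self, kind):
        table, ages = self.make_table_and_ages(signal=False, seed=4)
        rmse, _ = cg.age_prediction_rmse(table, ages, kind, seed=1)
        sd = np.std(list(ages.values()), ddof=0)
        assert rmse >= 0.9 * sd

    def test_unknown_regressor_rejected(self):
        table, ages = self.make_table_and_ages(n=20)
        with pytest.raises(ValueError, match="unknown regressor"):
            cg.age_prediction_rmse(table, ages, "quantum", seed=0)
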