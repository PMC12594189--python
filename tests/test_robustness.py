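"""Sex/allometry permutation tests, bgPCA hit rates, REP congruence, CS checks."""

import numpy as np
import pytest

from morphme import (
    MixedDesignSpec,
    average_reps,
    bgpca_crossval,
    cs_repeated_measures,
    default_params,
    distance_matrix_congruence,
    generate_dataset,
    gpa,
    mixed_design_test,
    null_params,
    pc1_congruence,
    permutation_regression,
)
from morphme.procrustes import gpa_arrays

from conftest import build_dataset


def _one_rep_shape(dataset, rep):
    return gpa(dataset.subset_reps([rep]))


def _sex_dummy(shape):
    return np.array([1.0 if m.sex == "M" else 0.0 for m in shape.meta])


class TestPermutationRegression:
    def test_strong_effect_hits_permutation_floor(self):
        p = default_params(n_individuals=20, sex_counts=(10, 10), n_landmarks=8,
                           sex_effect_scale=20.0, bias_scale=0.0)
        ds, _ = generate_dataset(p, seed=0)
        shape = _one_rep_shape(ds, "d0001a")
        res = permutation_regression(shape, _sex_dummy(shape), n_perm=999, seed=1)
        assert res.p == pytest.approx(0.001)

    def test_rsq_matches_normal_equations_oracle(self, rng):
        p = default_params(n_individuals=9, sex_counts=(5, 4), n_landmarks=6)
        ds, _ = generate_dataset(p, seed=4)
        shape = _one_rep_shape(ds, "d0002")
        x = shape.cs
        res = permutation_regression(shape, x, n_perm=99, seed=0)
        # brute force: per-column OLS with intercept via normal equations
        Y = shape.tangent
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        fitted = X @ beta
        ss_model = np.sum((fitted - Y.mean(axis=0)) ** 2)
        ss_total = np.sum((Y - Y.mean(axis=0)) ** 2)
        assert res.rsq == pytest.approx(ss_model / ss_total, abs=1e-12)

    def test_constant_predictor_rejected(self, small_dataset):
        ds, _ = small_dataset
        shape = _one_rep_shape(ds, "d0001a")
        with pytest.raises(ValueError, match="constant"):
            permutation_regression(shape, np.ones(shape.n_records), n_perm=99, seed=0)

    def test_duplicate_individuals_rejected(self, small_dataset):
        ds, _ = small_dataset
        shape = gpa(ds.subset_reps(["d0001a", "d0001b"]))
        with pytest.raises(ValueError, match="one record per individual"):
            permutation_regression(shape, np.ones(shape.n_records) + np.arange(shape.n_records),
                                   n_perm=99, seed=0)


class TestBgPca:
    def test_separated_groups_reach_full_hit_rate(self):
        p = default_params(n_individuals=20, sex_counts=(10, 10), n_landmarks=8,
                           sex_effect_scale=25.0, bias_scale=0.0)
        ds, _ = generate_dataset(p, seed=2)
        res = bgpca_crossval(_one_rep_shape(ds, "d0001a"))
        assert res.average_hit_rate == 100.0
        assert res.scores.shape[1] == 1

    def test_null_hit_rate_near_chance(self):
        hrs = []
        for seed in range(12):
            p = null_params(n_individuals=20, sex_counts=(10, 10), n_landmarks=8)
            ds, _ = generate_dataset(p, seed=seed)
            hrs.append(bgpca_crossval(_one_rep_shape(ds, "d0001a")).average_hit_rate)
        assert 30 < np.mean(hrs) < 70

    def test_singleton_group_rejected(self, rng):
        coords = {(f"i{k}", "r0"): rng.standard_normal((5, 2)) for k in range(4)}
        ds = build_dataset(coords, {"i0": "M", "i1": "F", "i2": "F", "i3": "F"})
        with pytest.raises(ValueError, match="fewer than 2"):
            bgpca_crossval(gpa(ds))


class TestAverageReps:
    def test_averaging_identical_reps_returns_the_rep(self, rng):
        base = {f"i{k}": rng.standard_normal((5, 2)) * 3 + 50 for k in range(4)}
        coords = {}
        for k, b in base.items():
            coords[(k, "r0")] = b
            coords[(k, "r1")] = b
        ds = build_dataset(coords, {k: "F" if i % 2 else "M"
                                    for i, k in enumerate(base)})
        avg = average_reps(ds, ["r0", "r1"])
        one = ds.subset_reps(["r0"])
        # superimpose averaged and original records together: pairwise
        # distances between corresponding records must vanish
        coords = np.concatenate([avg.coords_array(), one.coords_array()])
        shape = gpa_arrays(coords, avg.metas + one.metas, avg.landmark_labels)
        flat = shape.flat()
        n = avg.n_records
        d = np.linalg.norm(flat[:n] - flat[n:], axis=1)
        assert np.max(d) < 1e-9

    def test_averaging_shrinks_error_variance(self):
        """Averaging k REPs cuts residual digitization variance ~k-fold."""
        p = null_params(n_individuals=20, sex_counts=(10, 10), n_landmarks=8)
        reps_all = list(p.rep_labels)
        disp_single, disp_avg = [], []
        for seed in range(8):
            ds, truth = generate_dataset(p, seed=100 + seed)
            one = gpa(ds.subset_reps(["d0001a"]))
            avg = gpa(average_reps(ds, reps_all[:4]))
            # dispersion around the individual's true shape is not observable;
            # use distance to the other half-average as an error proxy
            avg2 = gpa(average_reps(ds, reps_all[4:]))
            d_one = np.linalg.norm(one.tangent - gpa(
                average_reps(ds, reps_all[4:])).tangent, axis=1)
            d_avg = np.linalg.norm(avg.tangent - avg2.tangent, axis=1)
            disp_single.append(np.mean(d_one**2))
            disp_avg.append(np.mean(d_avg**2))
        ratio = np.mean(disp_single) / np.mean(disp_avg)
        # var(single vs 4-avg) = (1 + 1/4) s2; var(4-avg vs 4-avg) = (1/2) s2
        assert 1.8 < ratio < 3.5

    def test_empty_rep_set_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError, match="empty"):
            average_reps(ds, [])


class TestMixedDesign:
    def test_same_rep_assignment_equals_within_rep_analysis(self, small_dataset):
        ds, _ = small_dataset
        spec = MixedDesignSpec({"F": "d0002", "M": "d0002"})
        res = mixed_design_test(ds, spec, n_perm=99, seed=31)
        # replicate the sub-seed stream to run the within-REP analysis
        rng = np.random.default_rng(31)
        s1, s2 = (int(rng.integers(0, 2**31 - 1)) for _ in range(2))
        shape = _one_rep_shape(ds, "d0002")
        ref_sex = permutation_regression(shape, _sex_dummy(shape), n_perm=99, seed=s1)
        ref_allo = permutation_regression(shape, shape.cs, n_perm=99, seed=s2)
        assert res["sex"].rsq == ref_sex.rsq
        assert res["sex"].p == ref_sex.p
        assert res["allometry"].rsq == ref_allo.rsq
        assert res["bgpca"].average_hit_rate == bgpca_crossval(shape).average_hit_rate

    def test_orthogonal_bias_inflates_sex_effect(self):
        """Bias orthogonal to the sex difference still lengthens the contrast
        (the diagonal of a rectangle beats its side)."""
        p = default_params(seed=0, bias_scale=0.0)
        sex_dir = p.sex_effect / np.linalg.norm(p.sex_effect)
        rng = np.random.default_rng(99)
        from morphme.procrustes import project_to_tangent

        d = project_to_tangent(rng.standard_normal(2 * p.n_landmarks), p.template)
        d -= (d @ sex_dir) * sex_dir
        d /= np.linalg.norm(d)
        p.rep_bias["d7300"] = (0.018 * 135.0 * d).reshape(p.n_landmarks, 2)
        ds, _ = generate_dataset(p, seed=4)
        recent = [r for r in ds.rep_labels if r != "d7300"]
        mixed = mixed_design_test(
            ds, MixedDesignSpec({"F": "d7300", "M": recent}), n_perm=99, seed=1
        )
        within = []
        for rep in ds.rep_labels:
            shape = _one_rep_shape(ds, rep)
            within.append(
                permutation_regression(shape, _sex_dummy(shape), n_perm=99, seed=2).rsq
            )
        assert mixed["sex"].rsq > max(within)

    def test_missing_sex_in_assignment_rejected(self):
        with pytest.raises(ValueError, match="missing sexes"):
            MixedDesignSpec({"F": "d0001a"})


class TestCongruence:
    def test_identical_copy_r_equals_one(self, small_dataset):
        ds, _ = small_dataset
        s = _one_rep_shape(ds, "d0001a")
        summ = pc1_congruence([s, s], ["a", "b"])
        assert summ.r[0] == pytest.approx(1.0)
        dsum = distance_matrix_congruence([s, s], ["a", "b"])
        assert dsum.r[0] == pytest.approx(1.0)

    def test_pair_counts_eight_and_seven_reps(self, small_dataset):
        ds, _ = small_dataset
        shapes = [_one_rep_shape(ds, r) for r in ds.rep_labels]
        assert len(pc1_congruence(shapes).r) == 28
        assert len(distance_matrix_congruence(shapes[:-1]).r) == 21

    def test_pc1_sign_flip_invariance(self, small_dataset):
        ds, _ = small_dataset
        s1 = _one_rep_shape(ds, "d0001a")
        s2 = _one_rep_shape(ds, "d0001b")
        base = pc1_congruence([s1, s2]).r[0]
        flipped = type(s2)(
            aligned=s2.aligned, consensus=s2.consensus, cs=s2.cs,
            tangent=-s2.tangent, meta=s2.meta, landmark_labels=s2.landmark_labels,
        )
        assert pc1_congruence([s1, flipped]).r[0] == pytest.approx(base, abs=1e-12)

    def test_condensed_vector_length(self, small_dataset):
        ds, _ = small_dataset
        s = _one_rep_shape(ds, "d0001a")
        from morphme import procrustes_distance_matrix

        n = s.n_records
        assert len(procrustes_distance_matrix(s).condensed()) == n * (n - 1) // 2

    def test_too_few_individuals_rejected(self, rng):
        coords = {(f"i{k}", r): rng.standard_normal((4, 2))
                  for k in range(2) for r in ("r0", "r1")}
        ds = build_dataset(coords, {"i0": "F", "i1": "M"})
        shapes = [_one_rep_shape(ds, r) for r in ("r0", "r1")]
        with pytest.raises(ValueError, match="3 individuals"):
            pc1_congruence(shapes)


class TestCsRepeatedMeasures:
    def test_identical_cs_gives_zero_rep_ss(self, rng):
        base = {f"i{k}": rng.standard_normal((5, 2)) for k in range(6)}
        coords = {}
        for k, b in base.items():
            for r in ("r0", "r1", "r2"):
                theta = rng.uniform(0, 2 * np.pi)
                R = np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
                coords[(k, r)] = b @ R.T  # CS preserved exactly
        ds = build_dataset(coords, {k: "F" if i % 2 else "M"
                                    for i, k in enumerate(base)})
        res = cs_repeated_measures(ds)
        for sex in res.f:
            assert res.f[sex] == pytest.approx(0.0, abs=1e-12)

    def test_injected_cs_offset_detected(self):
        p = null_params(n_individuals=15, sex_counts=(8, 7), n_landmarks=8)
        p.sigma_landmark = np.full(8, 0.1)
        ds, _ = generate_dataset(p, seed=3)
        # inflate one REP's size by ~1 mm of CS: scale its raw coordinates
        records = []
        for m, c in ds.records:
            if m.rep_label == "d0041":
                centred = c.coords - c.coords.mean(0)
                cs = np.sqrt(np.sum(centred**2))
                c = type(c)(coords=c.coords.mean(0) + centred * (1 + 1.0 / cs),
                            landmark_labels=c.landmark_labels)
            records.append((m, c))
        ds2 = type(ds)(records)
        res = cs_repeated_measures(ds2)
        assert res.p["F"] < 0.005 and res.p["M"] < 0.005

    def test_medians_match_direct_oracle(self, small_dataset):
        ds, _ = small_dataset
        res = cs_repeated_measures(ds)
        coords = ds.coords_array()
        centred = coords - coords.mean(axis=1, keepdims=True)
        cs = np.sqrt(np.sum(centred**2, axis=(1, 2)))
        for sex in ("F", "M"):
            for rep in ds.rep_labels:
                vals = [cs[i] for i, m in enumerate(ds.metas)
                        if m.sex == sex and m.rep_label == rep]
                assert res.medians[sex][rep] == pytest.approx(np.median(vals))

    def test_single_rep_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError):
            cs_repeated_measures(ds.subset_reps(["d0001a"]))
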