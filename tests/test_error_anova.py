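"""Hierarchical shape ANOVA, ME decomposition, EV axes and time-lag series."""

import numpy as np
import pytest

from morphme import (
    default_params,
    generate_dataset,
    gpa,
    me_anova,
    null_params,
    pairwise_timelag_series,
    procrustes_anova,
    ev_ordination,
)
from morphme.error_anova import me_ss_decomposition
from morphme.procrustes import ShapeData, gpa_arrays, project_to_tangent
from morphme.landmark_io import SpecimenMeta

from conftest import build_dataset


def _tiny_dataset(seed=0, n_ind=3, n_rep=2, n_lm=4):
    rng = np.random.default_rng(seed)
    sexes = {}
    coords = {}
    for k in range(n_ind):
        ind = f"i{k}"
        sexes[ind] = "F" if k % 2 == 0 else "M"
        base = rng.standard_normal((n_lm, 2))
        for j in range(n_rep):
            coords[(ind, f"r{j}")] = base + 0.05 * rng.standard_normal((n_lm, 2))
    return build_dataset(coords, sexes)


def _rss(X, Y):
    """Residual sum of squares of the least-squares fit of Y on X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return float(np.sum((Y - X @ beta) ** 2))


def _dummies(codes):
    levels = sorted(set(codes))
    return np.column_stack([[1.0 if c == l else 0.0 for c in codes] for l in levels])


class TestProcrustesAnovaDf:
    def test_study_design_df(self, study_dataset):
        ds, _ = study_dataset
        res = procrustes_anova(gpa(ds))
        assert res.row("sex").df == 48
        assert res.row("individual").df == 2688
        assert res.row("totME").df == 19488

    def test_sequential_ss_sum_to_total(self, study_dataset):
        ds, _ = study_dataset
        res = procrustes_anova(gpa(ds))
        total = sum(r.ss for r in res.rows)
        assert total == pytest.approx(res.ss_total, rel=1e-9)

    def test_single_rep_is_an_error(self, study_dataset):
        ds, _ = study_dataset
        shape = gpa(ds.subset_reps(["d0001a"]))
        with pytest.raises(ValueError, match="single REP"):
            procrustes_anova(shape)

    def test_zero_me_limit(self):
        p = null_params(n_individuals=6, sex_counts=(3, 3), n_landmarks=6)
        p.sigma_landmark = np.zeros_like(p.sigma_landmark)
        ds, _ = generate_dataset(p, seed=1)
        res = procrustes_anova(gpa(ds))
        assert res.row("totME").ss == pytest.approx(0.0, abs=1e-20)


class TestTypeIOracle:
    def test_sequential_projection_matches_lstsq(self):
        ds = _tiny_dataset(seed=4)
        shape = gpa(ds)
        Y = shape.tangent
        sex = _dummies([m.sex for m in shape.meta])
        ind = _dummies([m.individual_id for m in shape.meta])
        ones = np.ones((Y.shape[0], 1))
        rss0 = _rss(ones, Y)
        rss1 = _rss(np.hstack([ones, sex]), Y)
        rss2 = _rss(np.hstack([ones, sex, ind]), Y)
        res = procrustes_anova(shape)
        assert res.row("sex").ss == pytest.approx(rss0 - rss1, abs=1e-10)
        assert res.row("individual").ss == pytest.approx(rss1 - rss2, abs=1e-10)
        assert res.row("totME").ss == pytest.approx(rss2, abs=1e-10)


class TestTypeIIOracle:
    def test_model_comparison_matches_lstsq(self):
        ds = _tiny_dataset(seed=7, n_ind=4, n_rep=3)
        shape = gpa(ds)
        Y = shape.tangent
        metas = shape.meta
        ind = _dummies([m.individual_id for m in metas])
        rep = _dummies([m.rep_label for m in metas])
        sex_codes = [m.sex for m in metas]
        sex = _dummies(sex_codes)
        # individual-mean centring == residuals of Y on the individual dummies
        beta, *_ = np.linalg.lstsq(ind, Y, rcond=None)
        Z = Y - ind @ beta
        inter = np.column_stack([
            rep[:, i] * sex[:, j]
            for i in range(rep.shape[1]) for j in range(sex.shape[1])
        ])
        ones = np.ones((Y.shape[0], 1))
        rss_sex = _rss(np.hstack([ones, sex]), Z)
        rss_sex_rep = _rss(np.hstack([ones, sex, rep]), Z)
        rss_full = _rss(inter, Z)
        dec = me_ss_decomposition(shape)
        assert dec["ss"]["systME"] == pytest.approx(rss_sex - rss_sex_rep, abs=1e-10)
        assert dec["ss"]["systME_x_group"] == pytest.approx(
            rss_sex_rep - rss_full, abs=1e-10
        )
        assert dec["ss"]["randME"] == pytest.approx(rss_full, abs=1e-10)
        # individual SS against the grand mean, from the uncentred data
        rss_ind0 = _rss(ones, Y)
        rss_ind1 = _rss(ind, Y)
        assert dec["ss"]["individual"] == pytest.approx(rss_ind0 - rss_ind1, abs=1e-10)

    def test_df_identities(self, study_dataset):
        ds, _ = study_dataset
        dec = me_ss_decomposition(gpa(ds))
        assert dec["df"]["systME"] == 7
        assert dec["df"]["systME_x_group"] == 7
        assert dec["df"]["randME"] == 392
        assert dec["df"]["individual"] == 57


class TestMeAnova:
    def _null_shape(self, n_ind=10, R=4, p=6, seed=3):
        """Hand-built ShapeData whose centred REP means are exactly zero."""
        rng = np.random.default_rng(seed)
        ind_means = rng.standard_normal((n_ind, p))
        noise = rng.standard_normal((n_ind, R, p)) * 0.1
        noise -= noise.mean(axis=1, keepdims=True)   # centre within individual
        noise -= noise.mean(axis=0, keepdims=True)   # kill all REP means
        Y = ind_means[:, None, :] + noise
        metas = []
        for i in range(n_ind):
            for j in range(R):
                metas.append(SpecimenMeta(
                    individual_id=f"i{i:02d}", sex="F" if i % 2 else "M",
                    rep_label=f"r{j}", day_offset=j + 1))
        L = p // 2 + 2
        return ShapeData(
            aligned=np.zeros((n_ind * R, L, 2)), consensus=np.zeros((L, 2)),
            cs=np.ones(n_ind * R), tangent=Y.reshape(n_ind * R, p),
            meta=metas, landmark_labels=[f"L{i}" for i in range(L)],
        )

    def test_zero_rep_means_give_zero_snr_and_p_near_one(self):
        shape = self._null_shape()
        res = me_anova(shape, n_perm=99, seed=1)
        syst = res.row("systME")
        assert syst.ss == pytest.approx(0.0, abs=1e-20)
        assert syst.statistic < 1e-15
        assert syst.p > 0.95

    def test_strong_bias_hits_permutation_floor(self):
        p = null_params(n_individuals=12, sex_counts=(6, 6), n_landmarks=8)
        p.rep_bias["d0121"][3, 0] = 3.0  # huge single-landmark bias in one REP
        ds, _ = generate_dataset(p, seed=2)
        res = me_anova(gpa(ds), n_perm=199, seed=0)
        assert res.row("systME").p == pytest.approx(1 / 200)

    def test_snr_rsq_invariant_to_rigid_motion_and_scale(self, small_dataset, rng):
        ds, _ = small_dataset
        res1 = me_anova(gpa(ds), n_perm=99, seed=5)
        coords = ds.coords_array().copy()
        theta = 0.9
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        coords = 2.5 * coords @ R.T + np.array([100.0, -50.0])
        res2 = me_anova(
            gpa_arrays(coords, ds.metas, ds.landmark_labels), n_perm=99, seed=5
        )
        for eff in ("individual", "systME", "systME_x_group"):
            assert res1.row(eff).statistic == pytest.approx(
                res2.row(eff).statistic, rel=1e-8
            )
            assert res1.row(eff).rsq == pytest.approx(res2.row(eff).rsq, rel=1e-8)

    def test_constant_group_drops_interaction_with_warning(self):
        rng = np.random.default_rng(0)
        coords = {}
        for k in range(4):
            base = rng.standard_normal((5, 2))
            for j in range(3):
                coords[(f"i{k}", f"r{j}")] = base + 0.01 * rng.standard_normal((5, 2))
        ds = build_dataset(coords, {f"i{k}": "F" for k in range(4)})
        with pytest.warns(UserWarning, match="interaction dropped"):
            res = me_anova(gpa(ds), n_perm=99, seed=0)
        assert all(r.effect != "systME_x_group" for r in res.rows)

    def test_power_increases_with_bias(self):
        """systME rejection rate is non-decreasing in the injected bias size."""
        rates = []
        for scale in (0.0, 1.5, 4.0):
            rejections = 0
            for rep in range(20):
                p = null_params(n_individuals=10, sex_counts=(5, 5), n_landmarks=8)
                p.rep_bias["d7300"][3, 1] = 0.6 * scale
                ds, _ = generate_dataset(p, seed=1000 + rep)
                res = me_anova(gpa(ds), n_perm=99, seed=rep)
                rejections += res.row("systME").p <= 0.05
            rates.append(rejections / 20)
        assert rates[0] <= rates[1] + 0.15
        assert rates[2] >= rates[0]
        assert rates[2] >= 0.9

    def test_seed_mandatory(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError, match="seed"):
            me_anova(gpa(ds), n_perm=99)


class TestEvOrdination:
    def test_axis_count_is_reps_minus_one(self, small_dataset):
        ds, _ = small_dataset
        ev = ev_ordination(gpa(ds))
        assert ev.eigenvectors.shape[0] == ds.n_reps - 1
        assert len(ev.axis_variance_fraction) == ds.n_reps - 1
        assert np.all(np.diff(ev.axis_variance_fraction) <= 1e-12)
        assert ev.axis_variance_fraction.sum() == pytest.approx(1.0)

    def test_two_reps_single_axis_full_variance(self, small_dataset):
        ds, _ = small_dataset
        ev = ev_ordination(gpa(ds.subset_reps(["d0001a", "d7300"])))
        assert ev.eigenvectors.shape[0] == 1
        assert ev.axis_variance_fraction[0] == pytest.approx(1.0)

    def test_ev1_aligns_with_injected_bias_direction(self):
        p = null_params(seed=0)
        p.sigma_landmark = np.full(p.n_landmarks, 0.15)  # homogeneous noise
        rng = np.random.default_rng(77)
        direction = project_to_tangent(
            rng.standard_normal((p.n_landmarks, 2)).ravel(), p.template
        ).reshape(p.n_landmarks, 2)
        p.rep_bias["d7300"] = 0.03 * 135.0 * direction
        ds, _ = generate_dataset(p, seed=6)
        shape = gpa(ds)
        ev = ev_ordination(shape)
        b_t = project_to_tangent(direction.ravel(), shape.consensus)
        assert abs(ev.eigenvectors[0] @ b_t) > 0.99


class TestTimelagSeries:
    def test_eight_reps_give_seven_comparisons(self, small_dataset):
        ds, _ = small_dataset
        series = pairwise_timelag_series(ds, "d0001a", n_perm=99, seed=0)
        assert len(series.comparisons) == 7
        lags = [c.day_lag for c in series.comparisons]
        assert lags == sorted(lags)
        assert all(c.rep_label != "d0001a" for c in series.comparisons)

    def test_identical_copy_has_zero_systme(self, rng):
        base = {f"i{k}": rng.standard_normal((5, 2)) for k in range(4)}
        coords = {}
        for k, b in base.items():
            noisy = b + 0.01 * rng.standard_normal((5, 2))
            coords[(k, "r0")] = noisy
            coords[(k, "r1")] = noisy  # exact copy of the same digitization
        ds = build_dataset(coords, {k: "F" if i % 2 else "M"
                                    for i, k in enumerate(base)})
        series = pairwise_timelag_series(ds, "r0", n_perm=99, seed=0)
        assert series.comparisons[0].result.row("systME").ss == pytest.approx(
            0.0, abs=1e-20
        )

    def test_bias_in_largest_lag_peaks_there(self):
        p = null_params(n_individuals=16, sex_counts=(8, 8), n_landmarks=8)
        p.rep_bias["d7300"][3, 0] = 1.2
        ds, _ = generate_dataset(p, seed=9)
        series = pairwise_timelag_series(ds, "d0001a", n_perm=99, seed=1)
        rsq = {c.rep_label: c.result.row("systME").rsq for c in series.comparisons}
        assert max(rsq, key=rsq.get) == "d7300"

    def test_unknown_reference_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(KeyError):
            pairwise_timelag_series(ds, "nope", n_perm=99, seed=0)
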