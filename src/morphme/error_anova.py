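"""Hierarchical shape ANOVA and the systematic-vs-random error decomposition.

Two complementary ANOVAs are implemented on Procrustes tangent
coordinates of a complete individual x REP grid:

* ``procrustes_anova`` — the classical hierarchical (type I, sequential)
  decomposition group -> individual(within group) -> residual, where the
  residual is total measurement error (totME).  Goodall-type F ratios
  test each level against the hierarchically lower one, with degrees of
  freedom multiplied by the shape dimensionality ``2L - 4``.

* ``me_anova`` — the measurement-error decomposition: each individual's
  REP records are centred on the individual's own mean, and the centred
  data are split (type II sums of squares) into a systematic component
  (REP main effect: the average displacement of a whole digitization
  session), its interaction with the grouping factor, and a random
  residual.  The test statistic is a signal-to-noise ratio
  ``SNR = SS_effect / SS_randME``, assessed by a residual-randomization
  permutation test that shuffles REP labels within each individual's
  centred records.  The individual effect is also reported as an SNR
  against random error (tested by freely permuting records across
  individuals, the natural exchangeability for that effect).

Effect sizes are reported as ``Rsq = SS_effect / SS_total`` with the
total taken from the uncentred data, so type II component Rsq values
need not sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landmark_io import DigitizationDataset
from .procrustes import ShapeData, gpa, pca

__all__ = [
    "EffectRow",
    "ProcrustesAnovaResult",
    "MeAnovaResult",
    "EvOrdination",
    "TimelagComparison",
    "TimelagSeries",
    "procrustes_anova",
    "me_anova",
    "me_ss_decomposition",
    "ev_ordination",
    "pairwise_timelag_series",
]


@dataclass
class EffectRow:
    """One ANOVA table row."""

    effect: str
    df: int
    ss: float
    ms: float
    statistic: float
    statistic_kind: str  # "F", "SNR" or "Pillai"
    p: float
    rsq: float


@dataclass
class ProcrustesAnovaResult:
    """Sequential (type I) hierarchical shape ANOVA."""

    rows: list[EffectRow]
    ss_total: float
    ss_type: str = "I"
    pillai: dict | None = None  # optional approximate MANOVA of the group effect

    def row(self, effect: str) -> EffectRow:
        for r in self.rows:
            if r.effect == effect:
                return r
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return _rows_frame(self.rows)


@dataclass
class MeAnovaResult:
    """Type II systematic/random measurement-error decomposition."""

    rows: list[EffectRow]
    ss_total: float
    n_perm: int
    seed: int | None
    ss_type: str = "II"
    interaction_dropped: bool = False

    def row(self, effect: str) -> EffectRow:
        for r in self.rows:
            if r.effect == effect:
                return r
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return _rows_frame(self.rows)


def _rows_frame(rows: list[EffectRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "effect": r.effect, "df": r.df, "SS": r.ss, "MS": r.ms,
                "statistic": r.statistic, "kind": r.statistic_kind,
                "p": r.p, "Rsq": r.rsq,
            }
            for r in rows
        ]
    )


@dataclass
class EvOrdination:
    """Ordination on eigenvectors maximizing systematic over random error."""

    scores: np.ndarray                   # (n_records, R-1)
    axis_variance_fraction: np.ndarray   # (R-1,), non-increasing, sums to 1
    eigenvectors: np.ndarray             # (R-1, 2L) rows, unit norm
    rep_labels_per_record: list[str]


@dataclass
class TimelagComparison:
    rep_label: str
    day_lag: int
    result: MeAnovaResult


@dataclass
class TimelagSeries:
    reference: str
    comparisons: list[TimelagComparison] = field(default_factory=list)


# -- index helpers ------------------------------------------------------------


def _design_indices(shape: ShapeData):
    """Individual, REP and group codes for each record, in record order."""
    metas = shape.meta
    individuals = sorted({m.individual_id for m in metas})
    day_rep = sorted({(m.day_offset, m.rep_label) for m in metas})
    reps = [r for _, r in day_rep]
    ind_idx = np.array([individuals.index(m.individual_id) for m in metas])
    rep_idx = np.array([reps.index(m.rep_label) for m in metas])
    sexes = sorted({m.sex for m in metas})
    sex_idx = np.array([sexes.index(m.sex) for m in metas])
    return individuals, reps, sexes, ind_idx, rep_idx, sex_idx


def _check_complete_grid(ind_idx, rep_idx, n_ind, n_rep):
    counts = np.zeros((n_ind, n_rep), dtype=int)
    np.add.at(counts, (ind_idx, rep_idx), 1)
    if not np.all(counts == 1):
        raise ValueError("records do not form a complete individual x REP grid")


# -- Procrustes ANOVA ---------------------------------------------------------


def procrustes_anova(
    shape: ShapeData,
    group: np.ndarray | None = None,
    individual: np.ndarray | None = None,
    pillai: bool = False,
) -> ProcrustesAnovaResult:
    """Sequential hierarchical ANOVA: group -> individual -> totME.

    Degrees of freedom are multiplied by the shape dimensionality
    ``2L - 4``; Goodall-type F statistics test group over individual
    and individual over total measurement error, with parametric
    p-values from the F distribution.  Optionally a Pillai-trace MANOVA
    of the group effect (computed on individual-mean PC scores, an
    approximation) is attached.
    """
    Y = shape.tangent
    metas = shape.meta
    if group is None:
        group = np.array([m.sex for m in metas])
    if individual is None:
        individual = np.array([m.individual_id for m in metas])
    group = np.asarray(group)
    individual = np.asarray(individual)
    n = Y.shape[0]
    inds, ind_codes = np.unique(individual, return_inverse=True)
    groups, grp_codes = np.unique(group, return_inverse=True)
    n_ind, G = len(inds), len(groups)
    if n == n_ind:
        raise ValueError(
            "total ME is undefined with a single REP (no replication)"
        )
    k = 2 * shape.n_landmarks - 4

    g = Y.mean(axis=0)
    grp_means = np.stack([Y[grp_codes == j].mean(axis=0) for j in range(G)])
    ind_means = np.stack([Y[ind_codes == i].mean(axis=0) for i in range(n_ind)])
    grp_of_ind = np.array([grp_codes[ind_codes == i][0] for i in range(n_ind)])

    ss_total = float(np.sum((Y - g) ** 2))
    ss_grp = float(np.sum((grp_means[grp_codes] - g) ** 2))
    ss_ind = float(np.sum((ind_means[ind_codes] - grp_means[grp_of_ind][ind_codes]) ** 2))
    ss_tot_me = float(np.sum((Y - ind_means[ind_codes]) ** 2))

    df_grp = (G - 1) * k
    df_ind = (n_ind - G) * k
    df_me = (n - n_ind) * k
    ms_grp = ss_grp / df_grp if df_grp else np.nan
    ms_ind = ss_ind / df_ind
    ms_me = ss_tot_me / df_me
    f_grp = ms_grp / ms_ind if df_grp else np.nan
    f_ind = ms_ind / ms_me
    p_grp = float(stats.f.sf(f_grp, df_grp, df_ind)) if df_grp else np.nan
    p_ind = float(stats.f.sf(f_ind, df_ind, df_me))

    rows = []
    if df_grp:
        rows.append(EffectRow("sex", df_grp, ss_grp, ms_grp, f_grp, "F", p_grp,
                              ss_grp / ss_total))
    rows.append(EffectRow("individual", df_ind, ss_ind, ms_ind, f_ind, "F", p_ind,
                          ss_ind / ss_total))
    rows.append(EffectRow("totME", df_me, ss_tot_me, ms_me, np.nan, "F", np.nan,
                          ss_tot_me / ss_total))
    result = ProcrustesAnovaResult(rows=rows, ss_total=ss_total)
    if pillai and G > 1:
        result.pillai = _pillai_group_manova(ind_means, grp_of_ind, G)
    return result


def _pillai_group_manova(ind_means: np.ndarray, grp: np.ndarray, G: int) -> dict:
    """Approximate Pillai-trace MANOVA of the group effect on individual means.

    Computed on the leading PC scores of the individual mean shapes
    (enough to keep the error SSCP full rank); flagged approximate
    because exact MANOVA conventions for shape data vary across
    implementations.
    """
    n = ind_means.shape[0]
    full_scores = pca(ind_means).scores
    q = min(full_scores.shape[1], n - G - 1)
    scores = full_scores[:, :q]
    grand = scores.mean(axis=0)
    H = np.zeros((q, q))
    E = np.zeros((q, q))
    for j in range(G):
        sub = scores[grp == j]
        mj = sub.mean(axis=0)
        H += len(sub) * np.outer(mj - grand, mj - grand)
        E += (sub - mj).T @ (sub - mj)
    pill = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(q, G - 1)
    df1 = q * (G - 1)
    df2 = s * (n - G - q + s)
    f_stat = (pill / (s - pill + 1e-300)) * (df2 / df1) if s == 1 else np.nan
    p = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else np.nan
    return {
        "pillai": pill, "F": f_stat, "df1": df1, "df2": df2, "p": p,
        "approximate": True, "n_pcs": q,
    }


# -- ME ANOVA -----------------------------------------------------------------


def _ratio(num: float, den: float) -> float:
    """SS ratio with the 0/0 -> 0 convention (no signal, no noise)."""
    if den > 0:
        return num / den
    return 0.0 if num == 0 else np.inf


def _me_ss_from_grid(Z3: np.ndarray, sex_of_ind: np.ndarray, with_interaction: bool):
    """SS components from individual-centred data on the (n_ind, R, p) grid."""
    n_ind, R, p = Z3.shape
    u = Z3.mean(axis=0)                       # (R, p) REP means
    ss_syst = n_ind * float(np.sum(u**2))
    if with_interaction:
        ss_cells = 0.0
        resid = Z3.copy()
        for s in np.unique(sex_of_ind):
            mask = sex_of_ind == s
            c = Z3[mask].mean(axis=0)         # (R, p) cell means for this group
            ss_cells += mask.sum() * float(np.sum(c**2))
            resid[mask] -= c
        ss_inter = ss_cells - ss_syst
        ss_rand = float(np.sum(resid**2))
    else:
        ss_inter = np.nan
        ss_rand = float(np.sum((Z3 - u) ** 2))
    return ss_syst, ss_inter, ss_rand


def me_ss_decomposition(
    shape: ShapeData,
    group: np.ndarray | None = None,
    individual: np.ndarray | None = None,
) -> dict:
    """Type II SS decomposition without permutation tests.

    Returns a dict with ``ss``, ``df``, ``snr`` and ``rsq`` per effect
    (individual, systME, systME_x_group, randME) plus the total SS.
    Used internally by :func:`me_anova` and directly by Monte-Carlo
    calibration, where only the point decomposition is needed.
    """
    Y = shape.tangent
    _, reps, sexes, ind_idx, rep_idx, sex_idx = _design_indices(shape)
    if group is not None:
        sexes, sex_idx = np.unique(np.asarray(group), return_inverse=True)
        sexes = list(sexes)
    if individual is not None:
        _, ind_idx = np.unique(np.asarray(individual), return_inverse=True)
    n_ind = ind_idx.max() + 1
    R = len(reps)
    n, p = Y.shape
    if R < 2:
        raise ValueError("ME decomposition needs at least 2 REPs")
    _check_complete_grid(ind_idx, rep_idx, n_ind, R)
    G = len(sexes)

    # arrange records on the (individual, REP) grid
    order = np.lexsort((rep_idx, ind_idx))
    Y3 = Y[order].reshape(n_ind, R, p)
    sex_of_ind = sex_idx[order].reshape(n_ind, R)[:, 0]

    g = Y.mean(axis=0)
    m = Y3.mean(axis=1)                       # (n_ind, p) individual means
    ss_total = float(np.sum((Y - g) ** 2))
    ss_ind = R * float(np.sum((m - g) ** 2))
    Z3 = Y3 - m[:, None, :]

    with_inter = G > 1
    ss_syst, ss_inter, ss_rand = _me_ss_from_grid(Z3, sex_of_ind, with_inter)

    df_syst = R - 1
    df_inter = (R - 1) * (G - 1) if with_inter else 0
    df_ind = n_ind - 1
    df_rand = n - 1 - df_ind - df_syst - df_inter
    return {
        "ss": {"individual": ss_ind, "systME": ss_syst,
               "systME_x_group": ss_inter, "randME": ss_rand},
        "df": {"individual": df_ind, "systME": df_syst,
               "systME_x_group": df_inter, "randME": df_rand},
        "snr": {"individual": _ratio(ss_ind, ss_rand),
                "systME": _ratio(ss_syst, ss_rand),
                "systME_x_group": _ratio(ss_inter, ss_rand) if with_inter else np.nan},
        "rsq": {"individual": _ratio(ss_ind, ss_total),
                "systME": _ratio(ss_syst, ss_total),
                "systME_x_group": _ratio(ss_inter, ss_total) if with_inter else np.nan,
                "randME": _ratio(ss_rand, ss_total)},
        "ss_total": ss_total,
        "grid": (Y3, Z3, sex_of_ind, reps, order),
        "with_interaction": with_inter,
    }


def me_anova(
    shape: ShapeData,
    group: np.ndarray | None = None,
    individual: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> MeAnovaResult:
    """Measurement-error ANOVA with SNR permutation tests.

    systME and its group interaction are tested by shuffling REP labels
    within each individual's centred records (a residual-randomization
    scheme that preserves the individual structure); the individual
    effect is tested by freely permuting records across individuals.
    p-values use the ``(b + 1) / (n_perm + 1)`` convention.  Balanced
    REP counts are assumed; the complete-grid precondition enforces
    this.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if seed is None:
        raise ValueError("seed is mandatory for the permutation test")
    dec = me_ss_decomposition(shape, group=group, individual=individual)
    Y3, Z3, sex_of_ind, reps, order = dec["grid"]
    with_inter = dec["with_interaction"]
    if not with_inter:
        warnings.warn(
            "grouping factor is constant: systME x group interaction dropped",
            stacklevel=2,
        )
    n_ind, R, p = Z3.shape
    n = n_ind * R
    rng = np.random.default_rng(seed)

    obs_snr = dec["snr"]
    exceed = {"individual": 0, "systME": 0, "systME_x_group": 0}
    Yflat = Y3.reshape(n, p)
    for _ in range(n_perm):
        # systME / interaction: REP labels shuffled within individuals
        P = np.argsort(rng.random((n_ind, R)), axis=1)
        Zp = np.take_along_axis(Z3, P[:, :, None], axis=1)
        ss_syst_p, ss_inter_p, ss_rand_p = _me_ss_from_grid(Zp, sex_of_ind, with_inter)
        if _ratio(ss_syst_p, ss_rand_p) >= obs_snr["systME"] - 1e-12:
            exceed["systME"] += 1
        if with_inter and _ratio(ss_inter_p, ss_rand_p) >= obs_snr["systME_x_group"] - 1e-12:
            exceed["systME_x_group"] += 1
        # individual: free permutation of records across individuals
        perm = rng.permutation(n)
        Yp3 = Yflat[perm].reshape(n_ind, R, p)
        mp = Yp3.mean(axis=1)
        ss_ind_p = R * float(np.sum((mp - Yflat.mean(axis=0)) ** 2))
        Zp3 = Yp3 - mp[:, None, :]
        _, _, ss_rand_ip = _me_ss_from_grid(Zp3, sex_of_ind, with_inter)
        if _ratio(ss_ind_p, ss_rand_ip) >= obs_snr["individual"] - 1e-12:
            exceed["individual"] += 1

    def pval(effect):
        return (exceed[effect] + 1) / (n_perm + 1)

    ss, df, rsq = dec["ss"], dec["df"], dec["rsq"]
    rows = [
        EffectRow("individual", df["individual"], ss["individual"],
                  ss["individual"] / df["individual"], obs_snr["individual"],
                  "SNR", pval("individual"), rsq["individual"]),
        EffectRow("systME", df["systME"], ss["systME"],
                  ss["systME"] / df["systME"], obs_snr["systME"],
                  "SNR", pval("systME"), rsq["systME"]),
    ]
    if with_inter:
        rows.append(
            EffectRow("systME_x_group", df["systME_x_group"], ss["systME_x_group"],
                      ss["systME_x_group"] / df["systME_x_group"],
                      obs_snr["systME_x_group"], "SNR",
                      pval("systME_x_group"), rsq["systME_x_group"])
        )
    rows.append(
        EffectRow("randME", df["randME"], ss["randME"],
                  ss["randME"] / df["randME"], np.nan, "SNR", np.nan,
                  rsq["randME"])
    )
    return MeAnovaResult(
        rows=rows, ss_total=dec["ss_total"], n_perm=n_perm, seed=seed,
        interaction_dropped=not with_inter,
    )


# -- EV ordination ------------------------------------------------------------


def ev_ordination(
    shape: ShapeData,
    group: np.ndarray | None = None,
    rcond: float = 1e-10,
    shrinkage: str | float | None = "lw",
) -> EvOrdination:
    """Project centred records onto axes maximizing systematic over random error.

    Solves the generalized eigenproblem of the systematic-error
    cross-product matrix relative to the random-error cross-product
    matrix.  The random-error matrix is always rank-deficient in shape
    space, so eigenvalues below ``rcond`` times the largest are dropped
    (Moore-Penrose pseudo-inverse); by default its spectrum is
    additionally shrunk within the informative subspace by a
    Ledoit-Wolf estimate (``shrinkage="lw"``; a float in [0, 1] fixes
    the intensity, ``None`` disables it).  Shrinkage removes the pure
    sampling anisotropy of the whitening step — without it, the
    Marchenko-Pastur dispersion of the ~400-residual by ~50-dimension
    sample covariance visibly tilts the leading axes even when the true
    random error is isotropic — while leaving genuinely heterogeneous
    error structure in place.  The leading ``R - 1`` axes are returned;
    variance fractions refer to the systematic-error subspace only.
    """
    dec = me_ss_decomposition(shape, group=group)
    Y3, Z3, sex_of_ind, reps, order = dec["grid"]
    n_ind, R, p = Z3.shape
    if R < 2:
        raise ValueError("EV ordination needs at least 2 REPs")
    u = Z3.mean(axis=0)                             # (R, p)
    E_syst = n_ind * (u.T @ u)
    resid = Z3.copy()
    for s in np.unique(sex_of_ind):
        mask = sex_of_ind == s
        resid[mask] -= Z3[mask].mean(axis=0)
    flatr = resid.reshape(-1, p)
    E_rand = flatr.T @ flatr

    evals, evecs = np.linalg.eigh(E_rand)
    keep = evals > rcond * evals.max()
    if not np.any(keep):
        raise ValueError("random-error matrix has no usable eigenvalues")
    B = evecs[:, keep]
    if shrinkage is None:
        W = B @ np.diag(evals[keep] ** -0.5) @ B.T
    else:
        proj = flatr @ B
        if shrinkage == "lw":
            from sklearn.covariance import ledoit_wolf

            cov_s, _ = ledoit_wolf(proj, assume_centered=True)
        else:
            alpha = float(shrinkage)
            cov_s = proj.T @ proj / len(proj)
            mu = np.trace(cov_s) / cov_s.shape[0]
            cov_s = (1 - alpha) * cov_s + alpha * mu * np.eye(cov_s.shape[0])
        lam, V = np.linalg.eigh(cov_s)
        W = B @ (V @ np.diag(lam ** -0.5) @ V.T) @ B.T
    M = W @ E_syst @ W
    M = (M + M.T) / 2
    gvals, gvecs = np.linalg.eigh(M)
    order_ax = np.argsort(gvals)[::-1][: R - 1]
    axes = W @ gvecs[:, order_ax]
    axes /= np.linalg.norm(axes, axis=0, keepdims=True)
    # deterministic sign: largest-|loading| positive
    flip = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(axes.shape[1])])
    flip[flip == 0] = 1
    axes = axes * flip

    # systematic-error variance captured by each axis, within-subspace
    # fractions; axes re-ordered so the fractions are non-increasing
    proj = u @ axes                                 # (R, R-1)
    ax_var = n_ind * np.sum(proj**2, axis=0)
    reorder = np.argsort(-ax_var, kind="stable")
    axes = axes[:, reorder]
    ax_var = ax_var[reorder]
    total = ax_var.sum()
    frac = ax_var / total if total > 0 else np.full(R - 1, np.nan)

    Zflat = Z3.reshape(-1, p)
    scores = Zflat @ axes
    # record order on the grid: individual-major, REP-minor
    rep_per_record = [reps[j] for _ in range(n_ind) for j in range(R)]
    return EvOrdination(
        scores=scores,
        axis_variance_fraction=frac,
        eigenvectors=axes.T,
        rep_labels_per_record=rep_per_record,
    )


# -- pairwise time-lag series -------------------------------------------------


def pairwise_timelag_series(
    dataset: DigitizationDataset,
    reference: str,
    n_perm: int = 999,
    seed: int | None = 0,
) -> TimelagSeries:
    """ME ANOVA of the reference REP against every other REP, ordered by lag.

    Each comparison rebuilds a two-REP dataset, re-superimposes it (the
    Procrustes fit depends on which records are included) and runs the
    measurement-error ANOVA; comparisons are ordered by day lag from the
    reference.
    """
    reps = dataset.rep_labels
    if reference not in reps:
        raise KeyError(f"reference REP {reference!r} not in dataset ({reps})")
    ref_day = dataset.day_offset_of(reference)
    others = sorted(
        (r for r in reps if r != reference),
        key=lambda r: (abs(dataset.day_offset_of(r) - ref_day), r),
    )
    rng = np.random.default_rng(seed)
    series = TimelagSeries(reference=reference)
    for rep in others:
        sub = dataset.subset_reps([reference, rep])
        shape = gpa(sub)
        res = me_anova(shape, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)))
        series.comparisons.append(
            TimelagComparison(
                rep_label=rep,
                day_lag=abs(dataset.day_offset_of(rep) - ref_day),
                result=res,
            )
        )
    return series
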