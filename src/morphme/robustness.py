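"""Robustness of biological shape signal across digitization sessions.

Given one record per individual (a single REP, or a composite averaged
over REPs), this module tests the biological effects a morphometrician
typically cares about — mean sex differences and static allometry
(shape on centroid size) — with permutation regressions in the full
tangent space, scores leave-one-out cross-validated classification of
the sexes by nearest group mean (the between-group-PCA hit rate), and
measures the congruence of shape patterns between REPs (PC1 score
correlations and Procrustes distance-matrix correlations).  The
mixed-design test reproduces the "visiting scientist" failure mode in
silico: composing females from one digitization session and males from
another lets a session bias masquerade as (or inflate) sexual
dimorphism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import pearsonr

from .landmark_io import DigitizationDataset, LandmarkConfiguration, SpecimenMeta
from .procrustes import ShapeData, gpa_arrays, pca, procrustes_distance_matrix

__all__ = [
    "RegressionTestResult",
    "BgPcaResult",
    "CongruenceSummary",
    "MixedDesignSpec",
    "CsAnovaResult",
    "permutation_regression",
    "bgpca_crossval",
    "average_reps",
    "mixed_design_test",
    "pc1_congruence",
    "distance_matrix_congruence",
    "cs_repeated_measures",
]


@dataclass
class RegressionTestResult:
    """Permutation test of a single-predictor multivariate shape regression."""

    predictor_kind: str
    rsq: float
    pseudo_f: float
    p: float
    n_perm: int
    seed: int | None


@dataclass
class BgPcaResult:
    """Between-group PCA with leave-one-out nearest-mean classification."""

    group_means: dict[str, np.ndarray]
    scores: np.ndarray              # (n, G-1) bgPC scores
    hit_rate_per_group: dict[str, float]   # percent correct
    average_hit_rate: float                # percent, averaged over groups
    assignments: list[str]
    ties: int = 0


@dataclass
class CongruenceSummary:
    """Pairwise between-REP correlations with trimmed-range summaries."""

    kind: str                       # "PC1_abs_pearson" or "distance_matrix_pearson"
    pairs: list[tuple[str, str]]
    r: np.ndarray
    median: float
    p10: float
    p90: float


@dataclass
class MixedDesignSpec:
    """Which REP (or averaging set of REPs) supplies each sex's records."""

    assignment: dict[str, str | list[str]]

    def __post_init__(self) -> None:
        missing = {"F", "M"} - set(self.assignment)
        if missing:
            raise ValueError(f"assignment missing sexes: {sorted(missing)}")

    def source(self, sex: str) -> list[str]:
        src = self.assignment[sex]
        return [src] if isinstance(src, str) else list(src)


@dataclass
class CsAnovaResult:
    """Repeated-measures ANOVA of centroid size over REPs, per sex."""

    f: dict[str, float]
    p: dict[str, float]
    df: dict[str, tuple[int, int]]
    medians: dict[str, dict[str, float]]        # sex -> rep -> median CS (mm)
    sex_median_difference: dict[str, float]     # rep -> median(M) - median(F)


# -- permutation regression ---------------------------------------------------


def permutation_regression(
    shape: ShapeData,
    predictor: np.ndarray,
    kind: str = "predictor",
    n_perm: int = 999,
    seed: int | None = 0,
) -> RegressionTestResult:
    """Multivariate regression of all tangent coordinates on one predictor.

    ``Rsq = SS_model / SS_total`` from the least-squares fit; the
    pseudo-F is the distance-based one-predictor statistic
    ``(SS_model / 1) / (SS_residual / (n - 2))``.  Significance comes
    from permuting the predictor across individuals, with
    ``p = (b + 1) / (n_perm + 1)``.
    """
    Y = shape.tangent
    x = np.asarray(predictor, dtype=float)
    n = Y.shape[0]
    if x.shape != (n,):
        raise ValueError(f"predictor must have length {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    ids = [m.individual_id for m in shape.meta]
    if len(set(ids)) != n:
        raise ValueError("expected one record per individual")
    Yc = Y - Y.mean(axis=0)
    ss_total = float(np.sum(Yc**2))

    def model_ss(xv: np.ndarray) -> float:
        xc = xv - xv.mean()
        beta = (xc @ Yc) / (xc @ xc)
        return float((xc @ xc) * np.sum(beta**2))

    ss_model = model_ss(x)
    rsq = ss_model / ss_total
    pseudo_f = (ss_model / 1.0) / ((ss_total - ss_model) / (n - 2))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if model_ss(rng.permutation(x)) >= ss_model - 1e-12:
            exceed += 1
    return RegressionTestResult(
        predictor_kind=kind, rsq=rsq, pseudo_f=pseudo_f,
        p=(exceed + 1) / (n_perm + 1), n_perm=n_perm, seed=seed,
    )


# -- bgPCA cross-validated classification -------------------------------------


def bgpca_crossval(shape: ShapeData, groups: np.ndarray | None = None) -> BgPcaResult:
    """Leave-one-out nearest-group-mean classification in full tangent space.

    For each record the group means are recomputed without it and the
    record is assigned to the nearest mean by Euclidean distance (ties
    broken toward the first group and counted).  Classifying in full
    tangent space is equivalent to classifying on the between-group PC
    scores; the bgPC scores (projections onto the axes of group-mean
    variation) are returned for plotting.
    """
    Y = shape.tangent
    if groups is None:
        groups = np.array([m.sex for m in shape.meta])
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    G = len(labels)
    if G < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = labels[int(np.argmin(counts))]
        raise ValueError(f"group {small!r} has fewer than 2 members")

    sums = np.zeros((G, Y.shape[1]))
    np.add.at(sums, codes, Y)
    assignments = []
    ties = 0
    correct = np.zeros(G)
    for i in range(Y.shape[0]):
        d = np.empty(G)
        for j in range(G):
            if j == codes[i]:
                mean_j = (sums[j] - Y[i]) / (counts[j] - 1)
            else:
                mean_j = sums[j] / counts[j]
            d[j] = np.linalg.norm(Y[i] - mean_j)
        best = int(np.argmin(d))
        if np.sum(np.isclose(d, d[best])) > 1:
            ties += 1
            best = int(np.flatnonzero(np.isclose(d, d[best]))[0])
        assignments.append(labels[best])
        if best == codes[i]:
            correct[codes[i]] += 1

    hr = {labels[j]: 100.0 * correct[j] / counts[j] for j in range(G)}
    group_means = {labels[j]: sums[j] / counts[j] for j in range(G)}
    grand = Y.mean(axis=0)
    mean_mat = np.stack([group_means[l] - grand for l in labels])
    # between-group axes: PCA of the group means (G-1 non-null axes)
    _, _, vt = np.linalg.svd(mean_mat, full_matrices=False)
    axes = vt[: G - 1]
    flip = np.sign(axes[np.arange(G - 1), np.argmax(np.abs(axes), axis=1)])
    flip[flip == 0] = 1
    axes = axes * flip[:, None]
    scores = (Y - grand) @ axes.T
    return BgPcaResult(
        group_means=group_means,
        scores=scores,
        hit_rate_per_group=hr,
        average_hit_rate=float(np.mean(list(hr.values()))),
        assignments=assignments,
        ties=ties,
    )


# -- REP averaging and the mixed ("visiting scientist") design ----------------


def average_reps(
    dataset: DigitizationDataset,
    reps: list[str],
    shape: ShapeData | None = None,
    rep_label: str = "composite",
) -> DigitizationDataset:
    """One averaged record per individual over the given REPs.

    The per-individual arithmetic mean of GPA-aligned coordinates is
    rescaled by the individual's mean centroid size over the source
    REPs, producing raw-like (mm) configurations that downstream
    analyses re-superimpose.  Averaging k REPs with independent noise
    shrinks the residual error variance about k-fold.
    """
    reps = list(reps)
    if not reps:
        raise ValueError("empty REP set")
    sub = dataset.subset_reps(reps)
    if shape is None:
        shape = gpa_arrays(sub.coords_array(), sub.metas, sub.landmark_labels)
    aligned = shape.aligned
    metas = shape.meta
    individuals = sorted({m.individual_id for m in metas})
    ind_idx = np.array([individuals.index(m.individual_id) for m in metas])
    records = []
    for i, ind in enumerate(individuals):
        mask = ind_idx == i
        mean_shape = aligned[mask].mean(axis=0)
        mean_cs = float(shape.cs[mask].mean())
        sex = next(m.sex for m in metas if m.individual_id == ind)
        day = min(m.day_offset for m in metas if m.individual_id == ind)
        meta = SpecimenMeta(individual_id=ind, sex=sex, rep_label=rep_label,
                            day_offset=day)
        cfg = LandmarkConfiguration(
            coords=mean_shape * mean_cs,
            landmark_labels=shape.landmark_labels,
        )
        records.append((meta, cfg))
    return DigitizationDataset(records)


def mixed_design_test(
    dataset: DigitizationDataset,
    spec: MixedDesignSpec,
    n_perm: int = 999,
    seed: int | None = 0,
) -> dict:
    """Sex and allometry tests on a sex-by-session composite dataset.

    Each sex's individuals are drawn from the assigned REP (or the
    average of an assigned REP set), the composite is re-superimposed
    from raw coordinates — records from different Procrustes fits are
    never mixed — and the sex permutation regression, the allometry
    (CS) permutation regression and the cross-validated hit rate are
    computed.  With both sexes assigned the same single REP this
    reduces exactly to the within-REP analysis.
    """
    rng = np.random.default_rng(seed)
    parts: list[tuple[SpecimenMeta, LandmarkConfiguration]] = []
    for sex in ("F", "M"):
        source = spec.source(sex)
        if len(source) == 1:
            sub = dataset.subset_reps(source)
        else:
            sub = average_reps(dataset, source, rep_label="+".join(source))
        for meta, cfg in sub.records:
            if meta.sex == sex:
                parts.append((meta, cfg))
    coords = np.stack([c.coords for _, c in parts])
    metas = [m for m, _ in parts]
    shape = gpa_arrays(coords, metas, parts[0][1].landmark_labels)
    sex_dummy = np.array([1.0 if m.sex == "M" else 0.0 for m in shape.meta])
    sex_res = permutation_regression(
        shape, sex_dummy, kind="sex_dummy", n_perm=n_perm,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    allo_res = permutation_regression(
        shape, shape.cs, kind="linear_CS", n_perm=n_perm,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    bg = bgpca_crossval(shape)
    return {"sex": sex_res, "allometry": allo_res, "bgpca": bg, "shape": shape}


# -- congruence between REPs --------------------------------------------------


def _congruence(per_rep: list[tuple[str, np.ndarray]], kind: str) -> CongruenceSummary:
    pairs = []
    rs = []
    for a in range(len(per_rep)):
        for b in range(a + 1, len(per_rep)):
            la, va = per_rep[a]
            lb, vb = per_rep[b]
            r = pearsonr(va, vb)[0]
            if kind == "PC1_abs_pearson":
                r = abs(r)
            pairs.append((la, lb))
            rs.append(float(r))
    rs = np.asarray(rs)
    return CongruenceSummary(
        kind=kind, pairs=pairs, r=rs,
        median=float(np.median(rs)),
        p10=float(np.percentile(rs, 10)),
        p90=float(np.percentile(rs, 90)),
    )


def _check_same_individuals(shapes: list[ShapeData]):
    if len(shapes) < 2:
        raise ValueError("need at least 2 REPs")
    ids0 = [m.individual_id for m in shapes[0].meta]
    if len(ids0) < 3:
        raise ValueError("need at least 3 individuals")
    for s in shapes[1:]:
        if [m.individual_id for m in s.meta] != ids0:
            raise ValueError("REPs must contain the same individuals in the same order")


def pc1_congruence(shapes: list[ShapeData], rep_labels: list[str] | None = None) -> CongruenceSummary:
    """Absolute Pearson correlation of PC1 scores between every REP pair.

    The absolute value is used because the sign of a principal
    component is arbitrary.  Summarized by the median and the 10th/90th
    percentiles of the pairwise correlations.
    """
    _check_same_individuals(shapes)
    if rep_labels is None:
        rep_labels = [s.meta[0].rep_label for s in shapes]
    per_rep = [
        (lbl, pca(s.tangent).scores[:, 0]) for lbl, s in zip(rep_labels, shapes)
    ]
    return _congruence(per_rep, "PC1_abs_pearson")


def distance_matrix_congruence(
    shapes: list[ShapeData], rep_labels: list[str] | None = None
) -> CongruenceSummary:
    """Matrix correlation of within-REP Procrustes distances between REP pairs.

    The lower triangles (diagonal excluded, length n(n-1)/2) of the
    within-REP distance matrices are vectorized and correlated.
    """
    _check_same_individuals(shapes)
    if rep_labels is None:
        rep_labels = [s.meta[0].rep_label for s in shapes]
    per_rep = [
        (lbl, procrustes_distance_matrix(s).condensed())
        for lbl, s in zip(rep_labels, shapes)
    ]
    return _congruence(per_rep, "distance_matrix_pearson")


# -- centroid-size bias check -------------------------------------------------


def cs_repeated_measures(dataset: DigitizationDataset) -> CsAnovaResult:
    """One-way repeated-measures ANOVA of centroid size over REPs, per sex.

    Within each sex, REP is the within-subject factor:
    ``F = MS_REP / MS_residual`` on ``(R - 1, (R - 1)(n - 1))`` degrees
    of freedom (uncorrected for sphericity).  Per-REP per-sex CS
    medians and the male-minus-female median differences are reported
    alongside, to compare the session effect with the size of the
    biological contrast.
    """
    if dataset.n_reps < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 REPs")
    reps = dataset.rep_labels
    R = len(reps)
    coords = dataset.coords_array()
    centred = coords - coords.mean(axis=1, keepdims=True)
    cs = np.sqrt(np.sum(centred**2, axis=(1, 2)))
    metas = dataset.metas
    f_stats, p_vals, dfs, medians = {}, {}, {}, {}
    for sex in sorted({m.sex for m in metas}):
        idx = [i for i, m in enumerate(metas) if m.sex == sex]
        inds = sorted({metas[i].individual_id for i in idx})
        mat = np.full((len(inds), R), np.nan)
        for i in idx:
            mat[inds.index(metas[i].individual_id), reps.index(metas[i].rep_label)] = cs[i]
        n_i = len(inds)
        grand = mat.mean()
        ss_rep = n_i * float(np.sum((mat.mean(axis=0) - grand) ** 2))
        ss_subj = R * float(np.sum((mat.mean(axis=1) - grand) ** 2))
        ss_total = float(np.sum((mat - grand) ** 2))
        ss_resid = ss_total - ss_rep - ss_subj
        df1, df2 = R - 1, (R - 1) * (n_i - 1)
        f = (ss_rep / df1) / (ss_resid / df2)
        f_stats[sex] = float(f)
        p_vals[sex] = float(f_dist.sf(f, df1, df2))
        dfs[sex] = (df1, df2)
        medians[sex] = {rep: float(np.median(mat[:, j])) for j, rep in enumerate(reps)}
    sex_diff = {}
    if "F" in medians and "M" in medians:
        sex_diff = {rep: medians["M"][rep] - medians["F"][rep] for rep in reps}
    return CsAnovaResult(
        f=f_stats, p=p_vals, df=dfs, medians=medians,
        sex_median_difference=sex_diff,
    )
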