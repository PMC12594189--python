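"""Synthetic repeated-digitization datasets with known ground truth.

The generator emulates a repeated-digitization measurement-error study
on photographs of ventral crania: a fixed template shape, individual
shape variation much larger than digitization noise, a small sex
effect, static allometry (shape covarying with log centroid size),
heterogeneous per-landmark digitization noise, and a per-REP
systematic bias (directional misplacement shared by all individuals
within a digitization session).  Because every REP of an individual is
digitized on the same photograph, one rotation/translation is drawn
per individual and reused for all its REPs — noise and bias are the
only things that differ between REPs, which is exactly the structure
the error analysis assumes.

Default parameters are sized so that, after Procrustes superimposition,
individual variation accounts for roughly 80-90% of shape variance,
total measurement error for 10-17%, and the systematic component for
about 2%, with the oldest session's bias about three times the recent
ones; per-landmark raw-coordinate noise spans a near five-fold range
of summed X+Y variances (about 0.2-0.9 mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import DigitizationDataset, LandmarkConfiguration, SpecimenMeta
from .procrustes import project_to_tangent

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "marmot_template",
    "default_params",
    "null_params",
    "generate_dataset",
    "expected_variance_components",
]

# Study design constants: 8 digitization sessions, labelled by day offset,
# with the ~20-year-old original digitization placed last in the series.
DEFAULT_DAY_OFFSETS: dict[str, int] = {
    "d0001a": 1,
    "d0001b": 1,
    "d0002": 2,
    "d0004": 4,
    "d0011": 11,
    "d0041": 41,
    "d0121": 121,
    "d7300": 7300,
}

# Half-outline of a marmot-like ventral cranium (26 landmarks: midline
# points at x=0, right-side points at x>0), anterior at y=0.  Centred
# and scaled to unit centroid size by marmot_template().
_TEMPLATE_RAW = np.array([
    [0.00, 0.00],   # L1  anterior midline tip of the rostrum
    [0.02, -0.06],  # L2  incisor alveolus
    [0.03, -0.10],  # L3  incisive foramen, anterior
    [0.04, -0.16],  # L4  incisive foramen, posterior
    [0.10, -0.22],  # L5  masseteric tubercle
    [0.08, -0.30],  # L6  anterior toothrow
    [0.12, -0.38],  # L7  posterior maxillary foramen
    [0.07, -0.44],  # L8  posterior palatine foramen
    [0.00, -0.48],  # L9  maxilla-palatine midline suture
    [0.05, -0.54],  # L10 posterior palatine edge
    [0.00, -0.60],  # L11 basisphenoid-presphenoid midline
    [0.20, -0.62],  # L12 alisphenoid-squamosal suture
    [0.42, -0.66],  # L13 posterior zygomatic tip
    [0.30, -0.72],  # L14 auditory meatus, anterior
    [0.33, -0.78],  # L15 auditory meatus, posterior
    [0.16, -0.68],  # L16 foramen ovale
    [0.08, -0.74],  # L17 basisphenoid-basioccipital-bulla
    [0.14, -0.84],  # L18 jugular foramen
    [0.10, -0.92],  # L19 occipital condyle, lateral
    [0.04, -0.96],  # L20 occipital condyle, medial
    [0.00, -1.00],  # L21 posterior midline of occipital foramen
    [0.05, -0.02],  # L22 upper incisor alveolus
    [0.16, -0.14],  # L23 lateral rostrum
    [0.30, -0.30],  # L24 anterior orbit
    [0.38, -0.45],  # L25 zygomatic curvature change
    [0.40, -0.56],  # L26 squamosal zygomatic root
])


def marmot_template(n_landmarks: int = 26) -> np.ndarray:
    """Mean shape template: (L, 2), centred, unit centroid size."""
    if n_landmarks == 26:
        t = _TEMPLATE_RAW.copy()
    elif 3 <= n_landmarks < 26:
        t = _TEMPLATE_RAW[:n_landmarks].copy()
    else:
        raise ValueError("template supports 3 to 26 landmarks")
    t -= t.mean(axis=0)
    t /= np.sqrt(np.sum(t**2))
    return t


def _stretch_direction(template: np.ndarray, axis: int) -> np.ndarray:
    """Unit tangent-space direction stretching the template along one axis."""
    d = np.zeros_like(template)
    d[:, axis] = template[:, axis] - template[:, axis].mean()
    return project_to_tangent(d.ravel(), template)


@dataclass
class SyntheticParams:
    """Generator settings; defaults via :func:`default_params`."""

    n_individuals: int
    sex_counts: tuple[int, int]              # (n_females, n_males)
    template: np.ndarray                     # (L, 2), unit CS
    sigma_individual: float                  # per-coordinate shape SD
    sex_effect: np.ndarray                   # (2L,) male-minus-female, shape units
    allometry_slope: np.ndarray              # (2L,) shape change per unit log-CS
    cs_median: dict[str, float]              # per-sex median CS, mm
    cs_log_sd: float                         # lognormal dispersion of CS
    sigma_landmark: np.ndarray               # (L,) digitization noise SD, mm
    rep_bias: dict[str, np.ndarray]          # rep_label -> (L, 2) bias, mm
    day_offsets: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DAY_OFFSETS))
    sex_specific_bias: dict[tuple[str, str], np.ndarray] | None = None
    rotation_jitter_deg: float = 3.0         # photographic pose jitter between individuals
    translation_sd: float = 5.0              # mm, per-individual placement on the image
    seed: int = 0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        L = self.template.shape[0]
        self.sex_effect = np.asarray(self.sex_effect, dtype=float).reshape(2 * L)
        self.allometry_slope = np.asarray(self.allometry_slope, dtype=float).reshape(2 * L)
        self.sigma_landmark = np.asarray(self.sigma_landmark, dtype=float).reshape(L)
        if self.sigma_individual < 0 or np.any(self.sigma_landmark < 0):
            raise ValueError("all SDs must be >= 0")
        if sum(self.sex_counts) != self.n_individuals:
            raise ValueError("sex_counts must sum to n_individuals")
        missing = set(self.day_offsets) - set(self.rep_bias)
        if missing:
            raise ValueError(f"rep_bias missing for REPs: {sorted(missing)}")
        for label, b in self.rep_bias.items():
            self.rep_bias[label] = np.asarray(b, dtype=float).reshape(L, 2)

    @property
    def n_landmarks(self) -> int:
        return self.template.shape[0]

    @property
    def rep_labels(self) -> list[str]:
        pairs = sorted((d, r) for r, d in self.day_offsets.items())
        return [r for _, r in pairs]


@dataclass
class GroundTruth:
    """Everything injected into a generated dataset, for recovery tests."""

    true_shapes: np.ndarray          # (n_ind, L, 2) unit-CS-scale shapes
    log_cs: np.ndarray               # (n_ind,)
    sexes: list[str]                 # per individual
    individual_ids: list[str]
    rep_bias: dict[str, np.ndarray]  # the injected (L, 2) mm bias per REP
    noise: np.ndarray                # (n_ind, R, L, 2) mm noise draws
    rotations: np.ndarray            # (n_ind,) radians
    translations: np.ndarray         # (n_ind, 2) mm
    params: SyntheticParams
    seed: int


def _bias_direction(rng: np.random.Generator, template: np.ndarray,
                    sigma_landmark: np.ndarray) -> np.ndarray:
    """Random unit bias direction, weighted toward noisier landmarks.

    Imprecise landmarks tend also to be the ones an operator re-sees in
    a slightly different place after a time lag, so the default bias
    loads more heavily on high-noise landmarks.  The direction is
    projected into the tangent space at the template so its whole
    magnitude is shape-effective (similarity components would be
    absorbed by the superimposition).
    """
    raw = rng.standard_normal(template.shape) * sigma_landmark[:, None]
    return project_to_tangent(raw.ravel(), template).reshape(template.shape)


def default_params(
    n_individuals: int = 58,
    sex_counts: tuple[int, int] = (32, 26),
    n_landmarks: int = 26,
    seed: int = 0,
    sex_effect_scale: float = 1.0,
    allometry_scale: float = 1.0,
    bias_scale: float = 1.0,
) -> SyntheticParams:
    """Marmot-like default parameter set.

    The scale multipliers rescale the injected sex effect, allometric
    slope, and per-REP biases relative to the calibrated defaults
    (``0`` switches an effect off).  Bias directions are drawn from a
    fixed design RNG, so they are constants of the parameter set, not
    functions of the dataset seed.
    """
    template = marmot_template(n_landmarks)
    L = n_landmarks
    # per-landmark noise: summed X+Y variances span ~0.2-0.9 mm^2
    var_sum = np.linspace(0.2, 0.9, L)
    sigma_landmark = np.sqrt(var_sum / 2.0)

    sex_dir = _stretch_direction(template, axis=1)   # relative elongation in males
    allo_dir = _stretch_direction(template, axis=0)  # relative widening with size
    sex_effect = 0.0205 * sex_effect_scale * sex_dir
    allometry_slope = 0.54 * allometry_scale * allo_dir

    design_rng = np.random.default_rng(20240131)  # fixed: biases are design constants
    cs_scale = 135.0  # mm, typical adult CS; converts shape units to mm
    # shape-unit bias magnitudes per REP: none on the reference morning
    # session, tiny within-day drift, moderate for day-to-months lags,
    # and ~3x larger variance for the decades-old session
    magnitudes = {
        "d0001a": 0.0, "d0001b": 0.0047,
        "d0002": 0.0105, "d0004": 0.0086, "d0011": 0.0090,
        "d0041": 0.0094, "d0121": 0.0098,
        "d7300": 0.0183,
    }
    rep_bias = {}
    for label in DEFAULT_DAY_OFFSETS:
        direction = _bias_direction(design_rng, template, sigma_landmark)
        rep_bias[label] = bias_scale * magnitudes[label] * cs_scale * direction
    return SyntheticParams(
        n_individuals=n_individuals,
        sex_counts=sex_counts,
        template=template,
        sigma_individual=0.0078,
        sex_effect=sex_effect,
        allometry_slope=allometry_slope,
        cs_median={"F": 133.5, "M": 136.5},
        cs_log_sd=0.04,
        sigma_landmark=sigma_landmark,
        rep_bias=rep_bias,
        seed=seed,
    )


def null_params(seed: int = 0, **kwargs) -> SyntheticParams:
    """Defaults with zero bias and sexes fully exchangeable (type-I studies).

    Besides removing the per-REP biases and the direct sex effect, the
    per-sex size distributions are equalized: with sexual size
    dimorphism left in, allometric shape covariation would induce a
    genuine sex-linked shape difference, so a true null for tests of
    sexual dimorphism requires identical CS distributions as well.
    """
    params = default_params(seed=seed, sex_effect_scale=0.0, bias_scale=0.0, **kwargs)
    mid = float(np.mean(list(params.cs_median.values())))
    params.cs_median = {"F": mid, "M": mid}
    return params


def generate_dataset(
    params: SyntheticParams, seed: int | None = None
) -> tuple[DigitizationDataset, GroundTruth]:
    """Draw one complete individual x REP digitization dataset.

    For individual *i* the true shape is ``template + sex_effect * I(male)
    + allometry_slope * (log CS_i - mean log CS) + N(0, sigma_individual^2)``
    per coordinate.  The raw record for REP *r* is ``CS_i * R_i(S_i) + t_i
    + rep_bias_r (+ sex-specific bias) + per-landmark noise`` — rotation
    and translation are per-individual constants (same photograph in
    every REP), so they cancel in raw-coordinate variances across REPs.
    Deterministic given (params, seed).
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    L = params.n_landmarks
    n = params.n_individuals
    nf, nm = params.sex_counts
    sexes = ["F"] * nf + ["M"] * nm
    width = max(2, len(str(n)))
    ids = [f"ind{i + 1:0{width}d}" for i in range(n)]
    rep_labels = params.rep_labels
    R = len(rep_labels)

    medians = np.array([params.cs_median[s] for s in sexes])
    log_cs = np.log(medians) + params.cs_log_sd * rng.standard_normal(n)
    cs = np.exp(log_cs)
    centered_log_cs = log_cs - log_cs.mean()

    sex_ind = (np.array(sexes) == "M").astype(float)
    true_flat = (
        params.template.ravel()[None, :]
        + sex_ind[:, None] * params.sex_effect[None, :]
        + centered_log_cs[:, None] * params.allometry_slope[None, :]
        + params.sigma_individual * rng.standard_normal((n, 2 * L))
    )
    true_shapes = true_flat.reshape(n, L, 2)

    jitter = np.deg2rad(params.rotation_jitter_deg)
    thetas = rng.uniform(-jitter, jitter, size=n)
    translations = params.translation_sd * rng.standard_normal((n, 2)) + 200.0
    noise = rng.standard_normal((n, R, L, 2)) * params.sigma_landmark[None, None, :, None]

    records = []
    for i in range(n):
        c, s = np.cos(thetas[i]), np.sin(thetas[i])
        rot = np.array([[c, -s], [s, c]])
        posed = cs[i] * true_shapes[i] @ rot.T + translations[i]
        for j, rep in enumerate(rep_labels):
            raw = posed + params.rep_bias[rep] + noise[i, j]
            if params.sex_specific_bias:
                extra = params.sex_specific_bias.get((rep, sexes[i]))
                if extra is not None:
                    raw = raw + np.asarray(extra, dtype=float).reshape(L, 2)
            meta = SpecimenMeta(
                individual_id=ids[i], sex=sexes[i],
                rep_label=rep, day_offset=params.day_offsets[rep],
            )
            cfg = LandmarkConfiguration(
                coords=raw,
                landmark_labels=[f"L{k + 1}" for k in range(L)],
                source_image=f"{ids[i]}.jpg",
            )
            records.append((meta, cfg))
    dataset = DigitizationDataset(records)
    truth = GroundTruth(
        true_shapes=true_shapes,
        log_cs=log_cs,
        sexes=sexes,
        individual_ids=ids,
        rep_bias={k: v.copy() for k, v in params.rep_bias.items()},
        noise=noise,
        rotations=thetas,
        translations=translations,
        params=params,
        seed=seed,
    )
    return dataset, truth


def expected_variance_components(
    params: SyntheticParams, n_sim: int = 50, seed: int = 0
) -> dict[str, dict[str, float]]:
    """Monte-Carlo expectation of the error-ANOVA Rsq decomposition.

    Generates *n_sim* fresh datasets from *params*, superimposes each
    and computes the systematic/random error decomposition without
    permutation tests; returns mean and SD of Rsq per effect.  This is
    the calibration oracle used to size bias magnitudes toward a target
    systematic-error regime.
    """
    if n_sim < 50:
        raise ValueError("n_sim must be >= 50 for a stable Monte-Carlo estimate")
    if params.sigma_individual == 0 and np.all(params.sigma_landmark == 0):
        raise ValueError(
            "degenerate parameters: no individual variation and no noise"
        )
    from .error_anova import me_ss_decomposition
    from .procrustes import gpa

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_sim)
    rows: dict[str, list[float]] = {}
    for s in sub_seeds:
        dataset, _ = generate_dataset(params, seed=int(s))
        shape = gpa(dataset)
        ss = me_ss_decomposition(shape)
        for effect in ("individual", "systME", "systME_x_group", "randME"):
            rows.setdefault(effect, []).append(ss["rsq"][effect])
    return {
        effect: {
            "mean_rsq": float(np.mean(vals)),
            "sd_rsq": float(np.std(vals, ddof=1)),
        }
        for effect, vals in rows.items()
    }
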