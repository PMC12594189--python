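# morphme

Measurement-error analysis for repeatedly digitized 2D landmark data.

## The problem

Landmark-based geometric morphometrics often studies subtle shape
differences — sexual dimorphism, allometry, cryptic species — that can
be comparable in magnitude to digitization error.  When the same
structures are digitized in several sessions separated by hours, days
or years (a routine situation for scientists visiting museum
collections), each session can carry its own *systematic* error: the
operator re-sees some landmarks in a slightly, but consistently,
different place.  Unlike random placement noise, such a session bias is
directional and can masquerade as biological signal, especially when
group composition is confounded with digitization session ("visiting
scientist effect").

`morphme` is for morphometricians who want to quantify this risk in
their own repeated-digitization data, and for methodologists who want a
tested sandbox in which the whole analysis chain can be rerun on
synthetic data with known ground truth.

## What it computes

Given a complete individual × session (REP) grid of 2D landmark
configurations, all digitized on the same photographs:

- **Generalized Procrustes analysis** — configurations centred, scaled
  to unit centroid size CS = √Σᵢ‖xᵢ − x̄‖², and rotated (no
  reflections) to a consensus; statistics run on tangent-plane
  coordinates with 2L − 4 informative dimensions for L landmarks.
- **Hierarchical Procrustes ANOVA** (type I) — sex → individual →
  residual (= total measurement error), Goodall-type F ratios with df
  multiplied by 2L − 4.
- **Measurement-error ANOVA** (type II) — after centring each
  individual's REPs on its own mean, the centred variation splits into
  systematic error (REP main effect), its interaction with sex, and a
  random residual.  Each component is tested with a signal-to-noise
  ratio statistic, SNR = SS(effect) / SS(randME), against a
  residual-randomization permutation null (REP labels shuffled within
  individuals); effect sizes are Rsq = SS(effect) / SS(total).
- **EV ordination** — axes maximizing systematic relative to random
  error variance (R − 1 axes for R REPs), for visualizing which
  sessions drift.
- **Pairwise time-lag series** — the reference session tested against
  every other, ordered by day lag.
- **Per-landmark absolute imprecision** — var(X) + var(Y) across REPs
  per landmark per individual (mm²), summarized by medians and 90th
  percentiles, standardized by their medians over landmarks, and
  thresholded (strict > 1.5 / > 1.0 on both axes) into "precise" and
  "most precise" reduced configurations.
- **Signal robustness** — per-REP permutation regressions of shape on a
  sex dummy and on CS, cross-validated between-group-PCA hit rates,
  PC1 and distance-matrix congruence between REPs, and the mixed-REP
  biased-design simulation in which each sex is drawn from a different
  session.
- **Synthetic generator** — datasets with known individual variation,
  sex effect, allometry, heterogeneous per-landmark noise and per-REP
  bias, for parameter-recovery and type-I-error studies.

## Worked example

```python
import morphme as mm

params = mm.default_params(seed=1)          # 58 individuals x 8 REPs x 26 landmarks
dataset, truth = mm.generate_dataset(params, seed=1)
shape = mm.gpa(dataset)

me = mm.me_anova(shape, n_perm=999, seed=1)
print(me.to_frame().round(4).to_string(index=False))
```

```
        effect  df     SS     MS  statistic kind     p    Rsq
    individual  57 1.5192 0.0267     5.4484  SNR 0.001 0.8231
        systME   7 0.0430 0.0061     0.1541  SNR 0.001 0.0233
systME_x_group   7 0.0047 0.0007     0.0169  SNR 0.693 0.0025
        randME 392 0.2788 0.0007        NaN  SNR   NaN 0.1511
```

Individual variation dominates (Rsq 82%), random digitization error
accounts for ~15%, and the injected session bias shows up as a small
(Rsq 2.3%) but highly significant (p = 0.001) systematic component that
does not differ between the sexes (interaction p = 0.69).  The
pairwise time-lag series localizes the bias:

```python
series = mm.pairwise_timelag_series(dataset, "d0001a", n_perm=199, seed=1)
for c in series.comparisons:
    row = c.result.row("systME")
    print(f"d0001a vs {c.rep_label:7s} lag {c.day_lag:>5d} d  "
          f"systME Rsq {row.rsq:.4f}  SNR {row.statistic:.3f}  p {row.p:.3f}")
```

```
d0001a vs d0001b  lag     0 d  systME Rsq 0.0020  SNR 0.023  p 0.090
d0001a vs d0002   lag     1 d  systME Rsq 0.0077  SNR 0.086  p 0.005
d0001a vs d0004   lag     3 d  systME Rsq 0.0074  SNR 0.087  p 0.005
d0001a vs d0011   lag    10 d  systME Rsq 0.0063  SNR 0.070  p 0.005
d0001a vs d0041   lag    40 d  systME Rsq 0.0059  SNR 0.065  p 0.005
d0001a vs d0121   lag   120 d  systME Rsq 0.0072  SNR 0.082  p 0.005
d0001a vs d7300   lag  7299 d  systME Rsq 0.0238  SNR 0.276  p 0.005
```

Two sessions digitized the same day are statistically indistinguishable;
every later session carries a significant bias, and the decades-old
session (`d7300`) carries roughly three times the bias of the recent
ones — the time-lag signature the package is built to detect.

The full study (ANOVAs, EV ordination, per-REP signal tests, precision
tables, configuration reduction, mixed-design simulation, CS checks)
runs from one config:

```bash
morphme run-all --seed 1 --n-perm 999 --output-dir study_out
```

or programmatically via `morphme.run_study(StudyConfig(...))`, which
returns a deterministic, JSON-serializable report.

## Layout

```
src/morphme/
  landmark_io.py   TPS read/write, metadata, individual x REP grid assembly
  procrustes.py    CS, GPA, shape distances, tangent diagnostics, PCA, phenograms
  synthetic.py     ground-truth generator and Monte-Carlo calibration oracle
  error_anova.py   Procrustes ANOVA, ME ANOVA, EV ordination, time-lag series
  precision.py     per-landmark variances, standardization, configuration selection
  robustness.py    sex/allometry permutation tests, bgPCA, congruence, CS checks
  pipeline.py      end-to-end study orchestration with a structured report
  cli.py           typer CLI (simulate, gpa, me-anova, timelag, precision, ...)
```

See `docs/methods.md` for the statistical model, parameter defaults and
numerical choices.
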