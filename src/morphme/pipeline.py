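"""End-to-end orchestration of the repeated-digitization error study.

``run_study`` executes, in order: dataset assembly (from TPS files +
metadata, or the synthetic generator) -> Procrustes superimposition ->
outlier report and tangent-space diagnostic -> hierarchical Procrustes
ANOVA and measurement-error ANOVA (plus a variant excluding the oldest
REP) -> EV ordination -> pairwise time-lag series -> per-REP tests of
sexual dimorphism and static allometry with cross-validated hit rates
and between-REP congruence -> per-landmark precision analysis and
threshold-based configuration reduction -> error-ANOVA reruns on the
reduced configurations -> the mixed-design ("visiting scientist")
simulation -> centroid-size bias checks.  All randomness flows from the
single config seed through documented sub-seeds, so a config + seed
pair reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import error_anova, precision, procrustes, robustness, synthetic
from .landmark_io import (
    DigitizationDataset, assemble_dataset, read_metadata, read_tps,
    subset_landmarks,
)

__all__ = ["StudyConfig", "run_study", "load_config"]

logger = logging.getLogger("morphme.pipeline")

SCHEMA_VERSION = 1


@dataclass
class StudyConfig:
    """Archivable configuration of one full study run."""

    seed: int = 0
    n_perm: int = 999
    alpha: float = 0.005                      # reporting threshold only; p-values are raw
    reference_rep: str = "d0001a"
    oldest_rep: str = "d7300"
    precise_threshold: float = 1.5
    most_precise_threshold: float = 1.0
    # input: either TPS files per REP + metadata CSV, or synthetic defaults
    tps_by_rep: dict[str, str] | None = None
    metadata_csv: str | None = None
    synthetic_bias_scale: float = 1.0
    output_dir: str | None = None
    run_reduced_configurations: bool = True
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.precise_threshold <= 0 or self.most_precise_threshold <= 0:
            raise ValueError("thresholds must be positive")


def load_config(path) -> StudyConfig:
    """Read a StudyConfig from a YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version {version}")
    return StudyConfig(**data)


def _load_dataset(config: StudyConfig) -> DigitizationDataset:
    if config.tps_by_rep:
        if not config.metadata_csv:
            raise ValueError("metadata_csv is required with TPS input")
        meta = read_metadata(config.metadata_csv)
        configs_by_rep = {
            rep: read_tps(path) for rep, path in config.tps_by_rep.items()
        }
        return assemble_dataset(configs_by_rep, meta)
    params = synthetic.default_params(
        seed=config.seed, bias_scale=config.synthetic_bias_scale
    )
    dataset, _ = synthetic.generate_dataset(params, seed=config.seed)
    return dataset


def _anova_rows(res) -> list[dict]:
    return [
        {
            "effect": r.effect, "df": int(r.df), "SS": r.ss, "MS": r.ms,
            "statistic": r.statistic, "kind": r.statistic_kind,
            "p": r.p, "Rsq": r.rsq,
        }
        for r in res.rows
    ]


def _me_block(dataset, n_perm, seed) -> dict:
    shape = procrustes.gpa(dataset)
    proc = error_anova.procrustes_anova(shape)
    me = error_anova.me_anova(shape, n_perm=n_perm, seed=seed)
    ev = error_anova.ev_ordination(shape)
    return {
        "procrustes_anova": {
            "ss_type": proc.ss_type,
            "ss_total": proc.ss_total,
            "rows": _anova_rows(proc),
        },
        "me_anova": {
            "ss_type": me.ss_type,
            "ss_total": me.ss_total,
            "n_perm": me.n_perm,
            "seed": me.seed,
            "rows": _anova_rows(me),
        },
        "ev_axis_variance_fraction": ev.axis_variance_fraction.tolist(),
    }


def _signal_block(dataset, n_perm, rng) -> dict:
    """Per-REP sex/allometry tests plus congruence summaries."""
    per_rep = {}
    shapes = []
    for rep in dataset.rep_labels:
        sub = dataset.subset_reps([rep])
        shape = procrustes.gpa(sub)
        shapes.append(shape)
        sex = np.array([1.0 if m.sex == "M" else 0.0 for m in shape.meta])
        sex_res = robustness.permutation_regression(
            shape, sex, kind="sex_dummy", n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        allo_res = robustness.permutation_regression(
            shape, shape.cs, kind="linear_CS", n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bg = robustness.bgpca_crossval(shape)
        per_rep[rep] = {
            "sex_rsq": sex_res.rsq, "sex_p": sex_res.p,
            "allometry_rsq": allo_res.rsq, "allometry_p": allo_res.p,
            "hit_rate": bg.average_hit_rate,
        }
    # 5th/95th trimmed-range flags across REPs (reporting convention)
    summary = {}
    for key in ("sex_rsq", "allometry_rsq", "hit_rate"):
        vals = np.array([per_rep[r][key] for r in dataset.rep_labels])
        lo, hi = np.percentile(vals, [5, 95])
        summary[key] = {
            "p5": float(lo), "p95": float(hi),
            "outliers": [
                r for r in dataset.rep_labels
                if per_rep[r][key] < lo or per_rep[r][key] > hi
            ],
        }
    pc1 = robustness.pc1_congruence(shapes, dataset.rep_labels)
    dmat = robustness.distance_matrix_congruence(shapes, dataset.rep_labels)
    return {
        "per_rep": per_rep,
        "trimmed_range": summary,
        "congruence": {
            c.kind: {
                "n_r": len(c.r), "median": c.median, "p10": c.p10, "p90": c.p90,
            }
            for c in (pc1, dmat)
        },
    }


def run_study(config: StudyConfig) -> dict:
    """Run the full study and return the structured report (JSON-ready dict)."""
    rng = np.random.default_rng(config.seed)
    dataset = _load_dataset(config)
    logger.info(
        "dataset: %d individuals x %d REPs x %d landmarks (%d records), seed=%d",
        dataset.n_individuals, dataset.n_reps, dataset.n_landmarks,
        dataset.n_records, config.seed,
    )

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(config),
        "design": {
            "n_individuals": dataset.n_individuals,
            "n_reps": dataset.n_reps,
            "n_landmarks": dataset.n_landmarks,
            "n_records": dataset.n_records,
            "n_digitized_landmarks": dataset.n_records * dataset.n_landmarks,
            "rep_labels": dataset.rep_labels,
        },
    }

    shape = procrustes.gpa(dataset)
    outliers = procrustes.flag_outliers(shape)
    diag = procrustes.tangent_diagnostic(shape)
    report["diagnostics"] = {
        "tangent_r": diag.r,
        "tangent_slope": diag.slope,
        "top_outliers": [[k, d] for k, d in outliers[:5]],
        "note": "outliers are flagged but retained: misplacements are part of the error being studied",
    }
    for key, dist in outliers[:2]:
        logger.warning("flagged (retained) outlier %s at distance %.4g", key, dist)

    # R1: error ANOVAs on all REPs and without the oldest REP
    r1 = {"all_reps": _me_block(dataset, config.n_perm,
                                int(rng.integers(0, 2**31 - 1)))}
    if config.oldest_rep in dataset.rep_labels:
        recent = [r for r in dataset.rep_labels if r != config.oldest_rep]
        r1["without_oldest"] = _me_block(
            dataset.subset_reps(recent), config.n_perm,
            int(rng.integers(0, 2**31 - 1)),
        )
    series = error_anova.pairwise_timelag_series(
        dataset, config.reference_rep, n_perm=config.n_perm,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    r1["timelag_series"] = [
        {
            "rep": c.rep_label,
            "day_lag": c.day_lag,
            "systME_rsq": c.result.row("systME").rsq,
            "systME_snr": c.result.row("systME").statistic,
            "systME_p": c.result.row("systME").p,
            "randME_rsq": c.result.row("randME").rsq,
            "individual_rsq": c.result.row("individual").rsq,
        }
        for c in series.comparisons
    ]
    report["R1_error_anova"] = r1

    # R2: robustness of the biological signal across REPs
    report["R2_signal"] = _signal_block(dataset, config.n_perm, rng)

    # R3: per-landmark precision
    V = precision.per_landmark_variances(dataset)
    summary = precision.standardize_and_combine(
        precision.summarize_precision(V)
    )
    precise, most_precise = precision.select_precise_configurations(
        summary, config.precise_threshold, config.most_precise_threshold
    )
    cloud = precision.deviation_cloud(dataset, dataset.individuals[0])
    report["R3_precision"] = {
        "table": summary.table.reset_index().to_dict(orient="records"),
        "precise_landmarks": precise,
        "most_precise_landmarks": most_precise,
        "deviation_cloud_reference": cloud.reference_id,
    }

    # R4: reruns on the reduced configurations
    if config.run_reduced_configurations:
        r4 = {}
        for name, keep in (("precise", precise), ("most_precise", most_precise)):
            if len(keep) == dataset.n_landmarks or len(keep) < 3:
                continue
            sub = subset_landmarks(dataset, keep)
            block = _me_block(sub, config.n_perm, int(rng.integers(0, 2**31 - 1)))
            block["n_landmarks"] = len(keep)
            sub_series = error_anova.pairwise_timelag_series(
                sub, config.reference_rep, n_perm=config.n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            block["timelag_systME_rsq"] = {
                c.rep_label: c.result.row("systME").rsq
                for c in sub_series.comparisons
            }
            r4[name] = block
        report["R4_reduced_configurations"] = r4

    # S: mixed-design ("visiting scientist") simulation + CS checks
    reps = dataset.rep_labels
    mixed = {}
    if len(reps) >= 2:
        small = robustness.MixedDesignSpec(
            {"F": reps[0], "M": reps[1]}
        )
        mixed["small_bias"] = _mixed_entry(dataset, small, config, rng)
        if config.oldest_rep in reps and len(reps) > 2:
            recent = [r for r in reps if r != config.oldest_rep]
            large = robustness.MixedDesignSpec(
                {"F": config.oldest_rep, "M": recent}
            )
            mixed["large_bias_F_oldest"] = _mixed_entry(dataset, large, config, rng)
            large_rev = robustness.MixedDesignSpec(
                {"M": config.oldest_rep, "F": recent}
            )
            mixed["large_bias_M_oldest"] = _mixed_entry(dataset, large_rev, config, rng)
    cs_check = robustness.cs_repeated_measures(dataset)
    report["S_mixed_design"] = mixed
    report["S_cs_check"] = {
        "F": {"F_stat": cs_check.f.get("F"), "p": cs_check.p.get("F"),
              "df": list(cs_check.df.get("F", ()))},
        "M": {"F_stat": cs_check.f.get("M"), "p": cs_check.p.get("M"),
              "df": list(cs_check.df.get("M", ()))},
        "medians": cs_check.medians,
        "sex_median_difference": cs_check.sex_median_difference,
    }

    if config.output_dir:
        _write_outputs(report, config.output_dir)
    return report


def _mixed_entry(dataset, spec, config, rng) -> dict:
    res = robustness.mixed_design_test(
        dataset, spec, n_perm=config.n_perm,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return {
        "assignment": {k: v for k, v in spec.assignment.items()},
        "sex_rsq": res["sex"].rsq, "sex_p": res["sex"].p,
        "allometry_rsq": res["allometry"].rsq, "allometry_p": res["allometry"].p,
        "hit_rate": res["bgpca"].average_hit_rate,
    }


def _write_outputs(report: dict, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    import pandas as pd

    for block, fname in (
        ("R1_error_anova", "r1_me_anova_all.csv"),
    ):
        rows = report.get(block, {}).get("all_reps", {}).get("me_anova", {}).get("rows")
        if rows:
            pd.DataFrame(rows).to_csv(out / fname, index=False)
    prec = report.get("R3_precision", {}).get("table")
    if prec:
        pd.DataFrame(prec).to_csv(out / "r3_precision.csv", index=False)
    sig = report.get("R2_signal", {}).get("per_rep")
    if sig:
        pd.DataFrame(sig).T.rename_axis("rep").reset_index().to_csv(
            out / "r2_signal.csv", index=False
        )


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
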