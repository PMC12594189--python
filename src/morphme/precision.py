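"""Per-landmark absolute imprecision of raw digitized coordinates.

Because every REP of an individual is digitized on the same photograph,
the raw X and Y coordinates of a landmark are directly comparable
across REPs, and their variance (summed over X and Y, in mm^2) measures
how precisely that landmark can be re-located.  Per-landmark variances
are summarized across individuals (median, 90th percentile, mean, SD),
the medians and 90th percentiles are standardized by their respective
medians over landmarks — a standardized median of 0.5 means the
landmark is half as imprecise as the average landmark — and the two
standardized statistics are summed into a single combined imprecision
index.  Landmarks exceeding 1.5 (or 1.0) on *both* standardized axes
are flagged; dropping the flagged landmarks yields the "precise"
("most precise") reduced configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmark_io import DigitizationDataset

__all__ = [
    "PerLandmarkVariance",
    "PrecisionSummary",
    "DeviationCloud",
    "per_landmark_variances",
    "summarize_precision",
    "standardize_and_combine",
    "select_precise_configurations",
    "deviation_cloud",
]


@dataclass
class PerLandmarkVariance:
    """V[i, l] = var(X across REPs) + var(Y across REPs), mm^2."""

    V: np.ndarray                  # (n_individuals, L)
    individuals: list[str]
    landmark_labels: list[str]


@dataclass
class PrecisionSummary:
    """Per-landmark variance summaries and standardized imprecision indices."""

    table: pd.DataFrame  # one row per landmark, in dataset label order

    @property
    def landmark_labels(self) -> list[str]:
        return list(self.table.index)

    def ordered_by_median(self) -> pd.DataFrame:
        """Landmarks re-ordered by increasing median variance (plot convention)."""
        return self.table.sort_values("median", kind="stable")


@dataclass
class DeviationCloud:
    """Raw-coordinate deviations from each individual's REP mean.

    Deviations are anchored at the reference individual's mean landmark
    positions so the per-landmark scatter can be drawn on one
    configuration; the choice of reference shifts the anchors but not
    the scatter.
    """

    reference_id: str
    anchors: np.ndarray            # (L, 2) reference mean coordinates
    deviations: np.ndarray         # (n_records, L, 2)
    landmark_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        n, L, _ = self.deviations.shape
        rows = []
        for i in range(n):
            for l in range(L):
                dx, dy = self.deviations[i, l]
                rows.append(
                    {
                        "landmark": self.landmark_labels[l],
                        "dx": dx, "dy": dy,
                        "anchored_x": self.anchors[l, 0] + dx,
                        "anchored_y": self.anchors[l, 1] + dy,
                    }
                )
        return pd.DataFrame(rows)


def _grid_coords(dataset: DigitizationDataset) -> np.ndarray:
    """Raw coordinates on the (n_individuals, R, L, 2) grid."""
    n_ind, R = dataset.n_individuals, dataset.n_reps
    return dataset.coords_array().reshape(n_ind, R, dataset.n_landmarks, 2)


def per_landmark_variances(dataset: DigitizationDataset) -> PerLandmarkVariance:
    """Sample variance (denominator R-1) of X plus Y across REPs, per landmark.

    Operates on raw (never superimposed) coordinates: the same-pose
    assumption — all REPs of an individual digitized on one photograph —
    is what makes these variances meaningful.
    """
    if dataset.n_reps < 2:
        raise ValueError("variance undefined with a single REP")
    X = _grid_coords(dataset)
    V = X.var(axis=1, ddof=1).sum(axis=-1)   # (n_ind, L)
    return PerLandmarkVariance(
        V=V, individuals=dataset.individuals,
        landmark_labels=dataset.landmark_labels,
    )


def summarize_precision(V: PerLandmarkVariance) -> PrecisionSummary:
    """Median, 90th percentile, mean and SD of per-landmark variances."""
    tbl = pd.DataFrame(
        {
            "median": np.median(V.V, axis=0),
            "p90": np.percentile(V.V, 90, axis=0),  # linear interpolation
            "mean": V.V.mean(axis=0),
            "sd": V.V.std(axis=0, ddof=1) if V.V.shape[0] > 1 else 0.0,
        },
        index=pd.Index(V.landmark_labels, name="landmark"),
    )
    return PrecisionSummary(table=tbl)


def standardize_and_combine(summary: PrecisionSummary) -> PrecisionSummary:
    """Standardize medians and 90th percentiles by their medians over landmarks.

    ``std_median = median_l / median_over_landmarks(medians)`` (same for
    p90); ``combined`` is their sum.  Flags mark landmarks exceeding the
    1.0 / 1.5 thresholds on both axes (strict inequality).  Invariant to
    rescaling all variances by a constant.
    """
    tbl = summary.table.copy()
    med_of_med = float(np.median(tbl["median"]))
    med_of_p90 = float(np.median(tbl["p90"]))
    if med_of_med == 0 or med_of_p90 == 0:
        raise ValueError("no imprecision to standardize: all-zero variances")
    tbl["std_median"] = tbl["median"] / med_of_med
    tbl["std_p90"] = tbl["p90"] / med_of_p90
    tbl["combined"] = tbl["std_median"] + tbl["std_p90"]
    tbl["above_1_0"] = (tbl["std_median"] > 1.0) & (tbl["std_p90"] > 1.0)
    tbl["above_1_5"] = (tbl["std_median"] > 1.5) & (tbl["std_p90"] > 1.5)
    return PrecisionSummary(table=tbl)


def select_precise_configurations(
    summary: PrecisionSummary,
    precise_threshold: float = 1.5,
    most_precise_threshold: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Landmark subsets below the imprecision thresholds.

    ``precise`` keeps every landmark NOT exceeding *precise_threshold*
    on both standardized axes; ``most_precise`` does the same at
    *most_precise_threshold*.  Comparisons are strict, so a landmark
    exactly on a threshold is retained; most_precise is a subset of
    precise whenever the thresholds are ordered.
    """
    tbl = summary.table
    if "std_median" not in tbl.columns:
        raise ValueError("summary must be standardized first (standardize_and_combine)")
    exceeds_hi = (tbl["std_median"] > precise_threshold) & (tbl["std_p90"] > precise_threshold)
    exceeds_lo = (tbl["std_median"] > most_precise_threshold) & (tbl["std_p90"] > most_precise_threshold)
    precise = [l for l, bad in exceeds_hi.items() if not bad]
    most_precise = [l for l, bad in exceeds_lo.items() if not bad]
    if not precise or not most_precise:
        raise ValueError(
            "threshold selection removed every landmark; raise the thresholds"
        )
    return precise, most_precise


def deviation_cloud(dataset: DigitizationDataset, reference_id: str) -> DeviationCloud:
    """Per-record landmark deviations from the individual's REP-mean location.

    Within each individual and landmark the deviations sum to zero
    across REPs; the per-landmark scatter is identical for any choice of
    reference individual (only the anchor coordinates change).
    """
    if reference_id not in dataset.individuals:
        raise KeyError(f"unknown reference individual {reference_id!r}")
    X = _grid_coords(dataset)
    deviations = X - X.mean(axis=1, keepdims=True)
    ref_idx = dataset.individuals.index(reference_id)
    anchors = X[ref_idx].mean(axis=0)
    n_rec = dataset.n_records
    return DeviationCloud(
        reference_id=reference_id,
        anchors=anchors,
        deviations=deviations.reshape(n_rec, dataset.n_landmarks, 2),
        landmark_labels=dataset.landmark_labels,
    )
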