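"""Reading, writing and assembly of 2D landmark digitization data.

Landmark configurations travel in the plain-text TPS interchange format
(``LM=`` blocks of ``x y`` pairs with optional ``ID=``, ``IMAGE=`` and
``SCALE=`` records).  A digitization study is a complete individual ×
repetition (REP) grid: every individual digitized once in every REP,
with sex and day-offset metadata attached from a CSV table.  Because
all REPs of an individual are digitized on the same photograph, raw
coordinates are directly comparable across REPs, which is what makes
per-landmark absolute-precision analysis possible downstream.

Coordinates are real-valued millimetres once the TPS ``SCALE=`` factor
has been applied; no y-axis flip is performed (all REPs share the same
images, so any consistent convention cancels in the error analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "SpecimenMeta",
    "DigitizationDataset",
    "TpsParseError",
    "DesignError",
    "read_tps",
    "write_tps",
    "read_metadata",
    "assemble_dataset",
    "subset_landmarks",
]


class TpsParseError(ValueError):
    """Raised when a TPS file cannot be parsed."""


class DesignError(ValueError):
    """Raised when records do not form a complete individual x REP grid."""


@dataclass
class LandmarkConfiguration:
    """One digitized landmark configuration (L landmarks in 2D, mm)."""

    coords: np.ndarray
    landmark_labels: list[str] = field(default_factory=list)
    source_image: str = ""
    scale_applied: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coords must be an L x 2 matrix, got shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("all landmark coordinates must be finite")
        if not self.landmark_labels:
            self.landmark_labels = [f"L{i + 1}" for i in range(len(self.coords))]
        if len(self.landmark_labels) != len(self.coords):
            raise ValueError("landmark_labels length must match coords rows")
        if len(set(self.landmark_labels)) != len(self.landmark_labels):
            raise ValueError("landmark_labels must be unique")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SpecimenMeta:
    """Identity of one digitization record."""

    individual_id: str
    sex: str
    rep_label: str
    day_offset: int

    def __post_init__(self) -> None:
        sex = str(self.sex).upper()
        if sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        object.__setattr__(self, "sex", sex)
        object.__setattr__(self, "day_offset", int(self.day_offset))


@dataclass
class DigitizationDataset:
    """A complete individual x REP grid of landmark configurations.

    Records are stored sorted by ``(individual_id, day_offset,
    rep_label)``; every individual appears in every REP exactly once and
    all configurations share landmark count and labels.
    """

    records: list[tuple[SpecimenMeta, LandmarkConfiguration]]

    def __post_init__(self) -> None:
        if not self.records:
            raise DesignError("dataset must contain at least one record")
        labels0 = self.records[0][1].landmark_labels
        for meta, cfg in self.records:
            if cfg.landmark_labels != labels0:
                raise DesignError(
                    f"record ({meta.individual_id}, {meta.rep_label}) has "
                    "landmark labels differing from the rest of the dataset"
                )
        # rep_label <-> day_offset mapping must be consistent
        day_by_rep: dict[str, int] = {}
        for meta, _ in self.records:
            prev = day_by_rep.setdefault(meta.rep_label, meta.day_offset)
            if prev != meta.day_offset:
                raise DesignError(
                    f"REP {meta.rep_label!r} maps to inconsistent day offsets "
                    f"({prev} and {meta.day_offset})"
                )
        # sex must be a property of the individual
        sex_by_ind: dict[str, str] = {}
        for meta, _ in self.records:
            prev = sex_by_ind.setdefault(meta.individual_id, meta.sex)
            if prev != meta.sex:
                raise DesignError(
                    f"individual {meta.individual_id!r} has inconsistent sex codes"
                )
        cells = [(m.individual_id, m.rep_label) for m, _ in self.records]
        if len(set(cells)) != len(cells):
            dupes = sorted({c for c in cells if cells.count(c) > 1})
            raise DesignError(f"duplicated (individual, rep) cells: {dupes}")
        inds = sorted({m.individual_id for m, _ in self.records})
        reps = sorted({m.rep_label for m, _ in self.records})
        missing = sorted(set((i, r) for i in inds for r in reps) - set(cells))
        if missing:
            raise DesignError(f"missing (individual, rep) cells: {missing}")
        self.records = sorted(
            self.records,
            key=lambda rec: (rec[0].individual_id, rec[0].day_offset, rec[0].rep_label),
        )

    # -- structural accessors -------------------------------------------------

    @property
    def landmark_labels(self) -> list[str]:
        return self.records[0][1].landmark_labels

    @property
    def n_landmarks(self) -> int:
        return self.records[0][1].n_landmarks

    @property
    def individuals(self) -> list[str]:
        return sorted({m.individual_id for m, _ in self.records})

    @property
    def rep_labels(self) -> list[str]:
        """REP labels ordered by day offset (then label)."""
        pairs = sorted({(m.day_offset, m.rep_label) for m, _ in self.records})
        return [r for _, r in pairs]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_reps(self) -> int:
        return len(self.rep_labels)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def metas(self) -> list[SpecimenMeta]:
        return [m for m, _ in self.records]

    def coords_array(self) -> np.ndarray:
        """Raw coordinates stacked as an (n_records, L, 2) array."""
        return np.stack([c.coords for _, c in self.records])

    def sex_of(self, individual_id: str) -> str:
        for m, _ in self.records:
            if m.individual_id == individual_id:
                return m.sex
        raise KeyError(individual_id)

    def day_offset_of(self, rep_label: str) -> int:
        for m, _ in self.records:
            if m.rep_label == rep_label:
                return m.day_offset
        raise KeyError(rep_label)

    def subset_reps(self, reps: list[str]) -> "DigitizationDataset":
        """New dataset restricted to the given REP labels."""
        reps = list(reps)
        unknown = set(reps) - set(self.rep_labels)
        if unknown:
            raise KeyError(f"unknown REP labels: {sorted(unknown)}")
        return DigitizationDataset(
            [(m, c) for m, c in self.records if m.rep_label in reps]
        )


# -- TPS format ---------------------------------------------------------------


def read_tps(path, apply_scale: bool = True) -> list[LandmarkConfiguration]:
    """Read a 2D TPS file into a list of landmark configurations.

    Each block starts with ``LM=<count>`` followed by that many ``x y``
    lines; ``ID=``, ``IMAGE=`` and ``SCALE=`` records are optional.
    When *apply_scale* is true and a ``SCALE=`` record is present the
    coordinates are multiplied by the scale factor (pixels to mm);
    without a ``SCALE=`` record coordinates are returned unscaled and
    flagged ``scale_applied=False``.  3D blocks (``LM3=``) are rejected:
    this reader is strictly two-dimensional.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    configs: list[LandmarkConfiguration] = []
    i = 0
    block_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            raise TpsParseError(
                f"line {i + 1}: 3D block (LM3=) not supported; this reader is 2D only"
            )
        if not upper.startswith("LM="):
            raise TpsParseError(
                f"line {i + 1}: expected LM= block header, got {line!r}"
            )
        block_no += 1
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(f"line {i + 1}: bad LM= count {line!r}") from exc
        i += 1
        pts = []
        while i < len(lines) and len(pts) < n_lm:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row:
                break  # keyword record before all coordinates were found
            parts = row.split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"line {i + 1}: expected 'x y' coordinate pair, got {row!r}"
                )
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TpsParseError(
                    f"line {i + 1}: non-numeric coordinate in {row!r}"
                ) from exc
            i += 1
        if len(pts) != n_lm:
            raise TpsParseError(
                f"block {block_no}: LM={n_lm} but found {len(pts)} coordinate pairs"
            )
        image = ""
        scale = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            upper = row.upper()
            if upper.startswith(("LM=", "LM3=")):
                break
            if "=" not in row:
                raise TpsParseError(
                    f"line {i + 1}: unexpected content after block {block_no}: {row!r}"
                )
            key, value = row.split("=", 1)
            key = key.strip().upper()
            if key == "IMAGE":
                image = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TpsParseError(
                        f"line {i + 1}: non-numeric SCALE value {value!r}"
                    ) from exc
            # ID= and other keyword records are read and ignored
            i += 1
        coords = np.asarray(pts, dtype=float)
        applied = False
        if apply_scale and scale is not None:
            coords = coords * scale
            applied = True
        configs.append(
            LandmarkConfiguration(
                coords=coords, source_image=image, scale_applied=applied
            )
        )
    if not configs:
        raise TpsParseError("no LM= blocks found")
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as TPS blocks; ``read_tps`` inverts it exactly.

    Coordinates are assumed to be mm already, so ``SCALE=1.0`` is
    emitted.  Raises on an empty list rather than writing an empty file.
    """
    if not configs:
        raise ValueError("cannot write an empty list of configurations")
    n_lm = configs[0].n_landmarks
    for cfg in configs:
        if cfg.n_landmarks != n_lm:
            raise ValueError("all configurations must share the landmark count")
    with open(path, "w") as fh:
        for idx, cfg in enumerate(configs):
            fh.write(f"LM={cfg.n_landmarks}\n")
            for x, y in cfg.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            if cfg.source_image:
                fh.write(f"IMAGE={cfg.source_image}\n")
            fh.write(f"ID={idx}\n")
            fh.write("SCALE=1.0\n")


# -- metadata and assembly ----------------------------------------------------

_META_COLUMNS = ("individual_id", "sex", "rep_label", "day_offset")


def read_metadata(path) -> pd.DataFrame:
    """Read the record metadata CSV (individual_id, sex, rep_label, day_offset)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "rep_label": str})
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return df


def assemble_dataset(
    configs_by_rep: dict[str, list[LandmarkConfiguration]],
    metadata: pd.DataFrame,
) -> DigitizationDataset:
    """Assemble the individual x REP grid, re-keying records by individual ID.

    *metadata* must have one row per (individual, rep) cell in the order
    the configurations appear within each REP's file — specimen order
    may differ between REPs (it is typically randomized before each
    digitization session), so records are matched positionally within
    each REP and then re-sorted by individual.
    """
    metadata = metadata.copy()
    missing = set(_META_COLUMNS) - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    records: list[tuple[SpecimenMeta, LandmarkConfiguration]] = []
    seen_reps = set()
    for rep_label, configs in configs_by_rep.items():
        seen_reps.add(rep_label)
        rows = metadata[metadata["rep_label"] == rep_label]
        if len(rows) != len(configs):
            raise DesignError(
                f"REP {rep_label!r}: {len(configs)} configurations but "
                f"{len(rows)} metadata rows"
            )
        for (_, row), cfg in zip(rows.iterrows(), configs):
            meta = SpecimenMeta(
                individual_id=str(row["individual_id"]),
                sex=str(row["sex"]),
                rep_label=rep_label,
                day_offset=int(row["day_offset"]),
            )
            records.append((meta, cfg))
    meta_reps = set(metadata["rep_label"].unique())
    if meta_reps - seen_reps:
        raise DesignError(
            f"metadata mentions REPs without configurations: {sorted(meta_reps - seen_reps)}"
        )
    return DigitizationDataset(records)


def subset_landmarks(
    dataset: DigitizationDataset, keep: list[str]
) -> DigitizationDataset:
    """Restrict the dataset to the given landmark labels (raw coordinates).

    Subsetting operates on raw coordinates: downstream shape analyses
    must re-superimpose the reduced configurations, since removing
    landmarks changes the Procrustes fit.
    """
    keep = list(keep)
    if not keep:
        raise ValueError("keep must be a non-empty list of landmark labels")
    if len(set(keep)) != len(keep):
        raise ValueError("keep contains duplicated labels")
    labels = dataset.landmark_labels
    unknown = set(keep) - set(labels)
    if unknown:
        raise KeyError(f"unknown landmark labels: {sorted(unknown)}")
    idx = [labels.index(k) for k in labels if k in keep]  # preserve file order
    kept_labels = [labels[i] for i in idx]
    new_records = [
        (
            meta,
            replace(
                cfg,
                coords=cfg.coords[idx].copy(),
                landmark_labels=kept_labels,
            ),
        )
        for meta, cfg in dataset.records
    ]
    return DigitizationDataset(new_records)
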