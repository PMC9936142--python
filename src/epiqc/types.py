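"""Core in-memory containers shared across the package.

The pipeline passes around a small set of value objects: a 4D EPI series
(:class:`FunctionalSeries`), its binary brain mask (:class:`BrainMask`),
rigid-body motion parameters (:class:`MotionTrace`), the computed image
quality metrics (:class:`QCMetrics`), the per-scan verdict
(:class:`Classification`) and the subjects-by-raters label matrix
(:class:`RatingsTable`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DimensionalityError,
    DuplicationError,
    GeometryError,
    VocabularyError,
)

#: The three-category quality vocabulary used throughout.
LABELS = ("include", "uncertain", "exclude")


@dataclass
class FunctionalSeries:
    """A 4D functional (EPI) time series.

    Parameters
    ----------
    data:
        Intensities indexed ``(x, y, z, t)``, arbitrary units.
    voxel_size:
        Voxel dimensions in mm, one entry per spatial axis.
    tr:
        Repetition time in seconds (time to acquire one volume).
    affine:
        4x4 voxel-to-world transform. Carried through to outputs but never
        interpreted by the metrics.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"functional series must be 4D, got {self.data.ndim}D"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise GeometryError(f"voxel size must be 3 positive values, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("functional series contains non-finite intensities")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """A 3D binary brain mask in functional space."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_matches(self, series: FunctionalSeries) -> None:
        if self.data.shape != series.spatial_shape:
            raise GeometryError(
                f"mask shape {self.data.shape} does not match series "
                f"spatial shape {series.spatial_shape}"
            )


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters plus derived displacements.

    ``rotations`` are radians, ``translations`` mm, both ``(n_volumes, 3)``.
    Derived fields are filled by :func:`epiqc.motion.displacement_series`.
    """

    rotations: np.ndarray
    translations: np.ndarray
    abs_displacement: np.ndarray | None = None
    rel_displacement: np.ndarray | None = None
    exceedances: "ExceedanceCounts | None" = None

    def __post_init__(self) -> None:
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        if self.rotations.shape != self.translations.shape or self.rotations.shape[1] != 3:
            raise GeometryError("rotations and translations must both be (n, 3)")
        if not (np.all(np.isfinite(self.rotations)) and np.all(np.isfinite(self.translations))):
            raise ValueError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.rotations.shape[0]


@dataclass
class ExceedanceCounts:
    """Counts of relative-motion events above the protocol thresholds."""

    n_gt_voxel: int
    n_gt_high: int
    n_gt_low: int
    max_abs: float
    thresholds: dict[str, float]


@dataclass
class QCMetrics:
    """All image quality metrics computed for one scan."""

    # scaled squared difference family
    ssd_voxelwise: np.ndarray | None = None          # (x, y, z, t-1)
    ssd_mean_per_transition: np.ndarray | None = None
    ssd_variance_per_transition: np.ndarray | None = None
    ssd_slicewise_mean: np.ndarray | None = None     # (z, t-1)
    ssd_slicewise_min: np.ndarray | None = None
    ssd_slicewise_max: np.ndarray | None = None
    ssd_sum_map: np.ndarray | None = None            # (x, y, z)
    # temporal SNR
    snr_global: float | None = None
    snr_slicewise: np.ndarray | None = None          # (z,), NaN where no mask voxels
    slice_mask_fraction: np.ndarray | None = None    # (z,) fraction of slice voxels in mask
    # carpet plot
    carpet: np.ndarray | None = None                 # (n_bins, t)
    carpet_bin_assignment: np.ndarray | None = None  # (n_mask_voxels,) bin index
    # maps and display thresholds
    variance_map: np.ndarray | None = None
    png_threshold_variance: float | None = None
    png_threshold_ssd: float | None = None
    # global signal
    global_mean_timecourse: np.ndarray | None = None
    global_mean_timecourse_normalised: np.ndarray | None = None
    # mask coverage advisory
    coverage: "CoverageSummary | None" = None


@dataclass
class CoverageSummary:
    """Advisory summary of how well the mask covers high-intensity tissue."""

    outside_fraction: float
    cutoff: float
    touches_first_slice: bool
    touches_last_slice: bool

    @property
    def advisory(self) -> bool:
        return (
            self.outside_fraction > 0.05
            or self.touches_first_slice
            or self.touches_last_slice
        )


@dataclass
class Reason:
    """One coded reason attached to a classification."""

    code: str       # e.g. "motion_rel_count", "snr", "n_volumes"
    grade: str      # "exclusion", "marginal" or "advisory"
    observed: object
    threshold: object

    def __str__(self) -> str:
        return f"{self.code}[{self.grade}]: observed={self.observed} threshold={self.threshold}"


@dataclass
class Classification:
    """The protocol's output for one scan: a label plus coded evidence."""

    label: str
    reasons: list[Reason] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise VocabularyError(f"label must be one of {LABELS}, got {self.label!r}")

    def codes(self, grade: str | None = None) -> list[str]:
        return [r.code for r in self.reasons if grade is None or r.grade == grade]


class RatingsTable:
    """Subjects x raters matrix of quality labels with missing cells.

    Stored as a pandas DataFrame of strings (rows = subjects, columns =
    raters) with NaN marking cells a rater did not review.
    """

    def __init__(self, frame: pd.DataFrame):
        labels = frame.values[pd.notna(frame.values)]
        bad = set(labels) - set(LABELS)
        if bad:
            raise VocabularyError(f"labels outside {LABELS}: {sorted(bad)}")
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise DuplicationError("duplicate subject or rater identifiers")
        empty = frame.isna().all(axis=1)
        if empty.any():
            raise ValueError(
                f"subjects with no ratings at all: {list(frame.index[empty])}"
            )
        self.frame = frame.astype(object)

    @classmethod
    def from_long(cls, records: pd.DataFrame) -> "RatingsTable":
        """Build from a long-format frame with columns subject, rater, label."""
        dup = records.duplicated(subset=["subject", "rater"])
        if dup.any():
            pairs = records.loc[dup, ["subject", "rater"]].values.tolist()
            raise DuplicationError(f"duplicate (subject, rater) pairs: {pairs}")
        rec = records.copy()
        rec["label"] = rec["label"].astype(str).str.strip().str.lower()
        bad = set(rec["label"]) - set(LABELS)
        if bad:
            raise VocabularyError(f"labels outside {LABELS}: {sorted(bad)}")
        wide = rec.pivot(index="subject", columns="rater", values="label")
        wide.index.name = "subject"
        wide.columns.name = "rater"
        return cls(wide)

    @property
    def subjects(self) -> list:
        return list(self.frame.index)

    @property
    def raters(self) -> list:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def n_ratings(self) -> pd.Series:
        """Number of non-missing ratings per subject."""
        return self.frame.notna().sum(axis=1)

    def restrict(self, raters: list) -> "RatingsTable":
        """Complete cases for a rater subset: subjects rated by all of them."""
        sub = self.frame[list(raters)]
        return RatingsTable(sub.dropna(axis=0, how="any"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingsTable):
            return NotImplemented
        return self.frame.equals(other.frame)
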