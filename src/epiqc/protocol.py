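"""The quantitative include/uncertain/exclude protocol.

A scan is excluded when any hard rule fires: a relative motion event larger
than the voxel size, more than five relative events above 0.5 mm, maximum
absolute motion above 2 mm, a valid slice-wise SNR below 99, or any hard
acquisition deviation (voxel size to 2 decimal places, volume count, scan
count). Marginal findings — absolute motion in (1.5, 2] mm or slice-wise
SNR in [99, 150) — make the scan "uncertain"; purely advisory findings
(mask coverage, injected-artefact advisories) also route to "uncertain"
rather than exclusion, mirroring how the visual criteria feed rater
judgement rather than automatic rejection.

Slice-wise SNR values of NaN (slices with no mask voxels) never trigger
exclusion, and slices whose in-mask voxel fraction is below a configurable
floor are treated as advisory only — a mechanised form of the protocol's
"use your discretion" guidance for mostly-non-brain slices.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import IncompleteInputError
from .io import AcquisitionSpec, Deviation, ModalitySpec
from .types import (
    Classification,
    ExceedanceCounts,
    FunctionalSeries,
    QCMetrics,
    Reason,
)

__all__ = ["ProtocolThresholds", "check_acquisition", "classify", "classify_dataset"]


@dataclass
class ProtocolThresholds:
    """Numeric thresholds of the quantitative protocol, with defaults.

    ``rel_gt_voxel_max`` events above voxel size are allowed (default 0);
    more than ``rel_gt_high_max`` events above 0.5 mm exclude; absolute
    motion above ``abs_exclude`` mm excludes, above ``abs_marginal`` mm is
    marginal; slice-wise SNR below ``snr_exclude_below`` excludes, below
    ``snr_marginal_below`` is marginal; voxel sizes are compared after
    rounding to ``voxel_size_decimals`` decimal places.
    """

    rel_gt_voxel_max: int = 0
    rel_gt_high_max: int = 5
    abs_exclude: float = 2.0
    abs_marginal: float = 1.5
    snr_exclude_below: float = 99.0
    snr_marginal_below: float = 150.0
    voxel_size_decimals: int = 2
    slice_mask_fraction_floor: float = 0.05
    snr_slice_mode: str = "per_slice"  # or "mean"

    def __post_init__(self) -> None:
        if not self.abs_marginal < self.abs_exclude:
            raise ValueError("abs_marginal must be below abs_exclude")
        if not self.snr_exclude_below < self.snr_marginal_below:
            raise ValueError("snr_exclude_below must be below snr_marginal_below")

    @classmethod
    def from_file(cls, path) -> "ProtocolThresholds":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def check_acquisition(
    series: FunctionalSeries,
    expected: ModalitySpec | AcquisitionSpec,
    observed_scan_count: int | None = None,
    site: str | None = None,
    modality: str = "EPI",
    thresholds: ProtocolThresholds | None = None,
) -> list[Deviation]:
    """Compare a scan's geometry against the expected acquisition parameters.

    Voxel sizes are compared after rounding both sides to 2 decimal places
    (scanner headers often carry more digits than are meaningful); matrix,
    volume count and scan count are compared exactly. Voxel size, volume
    count and scan count deviations are hard (exclusion-grade); matrix and
    TR mismatches are reported as soft deviations.
    """
    thresholds = thresholds or ProtocolThresholds()
    if isinstance(expected, AcquisitionSpec):
        spec = expected.lookup(site, modality)
        expected_scans = expected.scans_per_subject.get(site)
    else:
        spec = expected
        expected_scans = None

    devs: list[Deviation] = []
    nd = thresholds.voxel_size_decimals
    obs_vox = tuple(round(float(v), nd) for v in series.voxel_size)
    exp_vox = tuple(round(float(v), nd) for v in spec.voxel_size)
    if obs_vox != exp_vox:
        devs.append(Deviation("voxel_size", series.voxel_size, spec.voxel_size, hard=True))
    if series.spatial_shape != spec.matrix:
        devs.append(Deviation("matrix", series.spatial_shape, spec.matrix, hard=False))
    if series.n_volumes != spec.n_volumes:
        devs.append(Deviation("n_volumes", series.n_volumes, spec.n_volumes, hard=True))
    if spec.tr is not None and round(series.tr, nd) != round(spec.tr, nd):
        devs.append(Deviation("tr", series.tr, spec.tr, hard=False))
    if observed_scan_count is not None and expected_scans is not None:
        if observed_scan_count != expected_scans:
            devs.append(Deviation("scan_count", observed_scan_count, expected_scans, hard=True))
    return devs


def _snr_reasons(metrics: QCMetrics, t: ProtocolThresholds) -> list[Reason]:
    snr = np.asarray(metrics.snr_slicewise, dtype=float)
    frac = metrics.slice_mask_fraction
    frac = np.ones_like(snr) if frac is None else np.asarray(frac, dtype=float)
    valid = np.isfinite(snr)  # NaN slices never count against the scan
    eligible = valid & (frac >= t.slice_mask_fraction_floor)
    reasons: list[Reason] = []
    if t.snr_slice_mode == "mean":
        if not eligible.any():
            return reasons
        vals = np.array([snr[eligible].mean()])
    else:
        vals = snr[eligible]
    if vals.size == 0:
        return reasons
    low = float(vals.min())
    if low < t.snr_exclude_below:
        reasons.append(Reason("snr", "exclusion", low, t.snr_exclude_below))
    elif low < t.snr_marginal_below:
        reasons.append(Reason("snr", "marginal", low, t.snr_marginal_below))
    # advisory for low-SNR slices excused by the mask-fraction floor
    excused = valid & ~eligible
    if excused.any() and float(snr[excused].min()) < t.snr_exclude_below:
        reasons.append(
            Reason("snr_advisory", "advisory", float(snr[excused].min()), t.snr_exclude_below)
        )
    return reasons


def classify(
    exceedances: ExceedanceCounts,
    metrics: QCMetrics,
    deviations: list[Deviation] | None = None,
    thresholds: ProtocolThresholds | None = None,
) -> Classification:
    """Apply the quantitative rules to one scan's computed inputs.

    Pure function: same inputs, same classification. Any exclusion-grade
    reason forces "exclude"; otherwise any marginal or advisory reason gives
    "uncertain"; otherwise "include".
    """
    t = thresholds or ProtocolThresholds()
    if exceedances is None or metrics is None or metrics.snr_slicewise is None:
        raise IncompleteInputError(
            "classify needs exceedance counts and SNR metrics for the same scan"
        )
    deviations = deviations or []
    reasons: list[Reason] = []

    if exceedances.n_gt_voxel > t.rel_gt_voxel_max:
        reasons.append(
            Reason("motion_rel_voxel", "exclusion", exceedances.n_gt_voxel, t.rel_gt_voxel_max)
        )
    if exceedances.n_gt_high > t.rel_gt_high_max:
        reasons.append(
            Reason("motion_rel_count", "exclusion", exceedances.n_gt_high, t.rel_gt_high_max)
        )
    if exceedances.max_abs > t.abs_exclude:
        reasons.append(Reason("motion_abs", "exclusion", exceedances.max_abs, t.abs_exclude))
    elif exceedances.max_abs > t.abs_marginal:
        reasons.append(Reason("motion_abs", "marginal", exceedances.max_abs, t.abs_marginal))

    reasons.extend(_snr_reasons(metrics, t))

    for dev in deviations:
        grade = "exclusion" if dev.hard else "advisory"
        reasons.append(Reason(dev.field, grade, dev.observed, dev.expected))

    if metrics.coverage is not None and metrics.coverage.advisory:
        reasons.append(
            Reason(
                "coverage_advisory",
                "advisory",
                metrics.coverage.outside_fraction,
                None,
            )
        )

    if any(r.grade == "exclusion" for r in reasons):
        label = "exclude"
    elif reasons:
        label = "uncertain"
    else:
        label = "include"
    return Classification(label=label, reasons=reasons)


def classify_dataset(
    scans: dict[str, tuple[ExceedanceCounts, QCMetrics, list[Deviation]]],
    thresholds: ProtocolThresholds | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every scan of a dataset.

    ``scans`` maps subject id to (exceedances, metrics, deviations).
    Returns a per-subject table (label, reason codes) and counts per label.
    """
    rows = []
    counts = {"include": 0, "uncertain": 0, "exclude": 0}
    for subject in scans:
        exceed, metrics, deviations = scans[subject]
        c = classify(exceed, metrics, deviations, thresholds)
        counts[c.label] += 1
        rows.append(
            {
                "subject": subject,
                "label": c.label,
                "reasons": ";".join(str(r) for r in c.reasons),
            }
        )
    return pd.DataFrame(rows).set_index("subject"), counts
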