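"""Displacement series and threshold-exceedance counts from motion parameters.

Absolute displacement is measured against the reference volume (volume 0,
the volume the realignment aligned everything else to); relative
displacement between consecutive volumes. Both use the Euclidean norm of
the translation difference, optionally plus a rotational arc length on a
sphere of configurable radius (default 50 mm, the conventional head-radius
stand-in used by framewise-displacement measures).
"""
from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError
from .types import ExceedanceCounts, MotionTrace

__all__ = ["displacement_series", "count_exceedances", "DEFAULT_SPHERE_RADIUS"]

DEFAULT_SPHERE_RADIUS = 50.0  # mm


def _pairwise_displacement(
    rot_a: np.ndarray,
    rot_b: np.ndarray,
    trans_a: np.ndarray,
    trans_b: np.ndarray,
    sphere_radius: float,
    include_rotation: bool,
) -> np.ndarray:
    d = np.linalg.norm(trans_b - trans_a, axis=-1)
    if include_rotation:
        d = d + sphere_radius * np.linalg.norm(rot_b - rot_a, axis=-1)
    return d


def displacement_series(
    trace: MotionTrace,
    sphere_radius: float = DEFAULT_SPHERE_RADIUS,
    include_rotation: bool = True,
) -> MotionTrace:
    """Fill the absolute and relative displacement fields of a trace.

    ``abs_displacement[t]`` is the displacement between volume t and volume
    0; ``rel_displacement[t]`` between volumes t and t+1 (length
    ``n_volumes - 1``). Returns the same trace with the derived fields set.
    """
    n = trace.n_volumes
    if n < 2:
        raise InsufficientDataError("need at least 2 volumes to derive displacements")
    rot, trans = trace.rotations, trace.translations
    trace.abs_displacement = _pairwise_displacement(
        rot[0], rot, trans[0], trans, sphere_radius, include_rotation
    )
    trace.rel_displacement = _pairwise_displacement(
        rot[:-1], rot[1:], trans[:-1], trans[1:], sphere_radius, include_rotation
    )
    return trace


def count_exceedances(
    trace: MotionTrace,
    voxel_size: tuple[float, float, float],
    t_high: float = 0.5,
    t_low: float = 0.1,
    voxel_rule: str = "min",
) -> ExceedanceCounts:
    """Count relative-motion events above the protocol's three thresholds.

    The protocol counts relative movements larger than the voxel size,
    larger than 0.5 mm and larger than 0.1 mm, plus the maximum absolute
    displacement. ``voxel_rule`` picks which voxel dimension defines
    "voxel size": ``"min"`` (strictest, default) or ``"max"``.
    """
    if trace.rel_displacement is None or trace.abs_displacement is None:
        trace = displacement_series(trace)
    rel = np.asarray(trace.rel_displacement)
    pick = min if voxel_rule == "min" else max
    t_voxel = float(pick(voxel_size))
    counts = ExceedanceCounts(
        n_gt_voxel=int(np.sum(rel > t_voxel)),
        n_gt_high=int(np.sum(rel > t_high)),
        n_gt_low=int(np.sum(rel > t_low)),
        max_abs=float(np.max(trace.abs_displacement)),
        thresholds={"voxel": t_voxel, "high": t_high, "low": t_low},
    )
    trace.exceedances = counts
    return counts
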