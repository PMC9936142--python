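"""Readers and writers for every external representation the pipeline touches.

NIfTI-1 volumes go through nibabel; motion parameters are 6-column
whitespace-delimited text in the MCFLIRT dialect (three rotations in radians,
then three translations in mm); ratings are long-format CSV files with
columns ``subject, rater, label``; acquisition specs are YAML or JSON keyed
by site and modality; acquisition deviations are written to a human-readable
``*_notes.txt`` file.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DimensionalityError,
    FormatError,
    LengthMismatchError,
)
from .types import BrainMask, FunctionalSeries, MotionTrace, RatingsTable

__all__ = [
    "AcquisitionSpec",
    "ModalitySpec",
    "Deviation",
    "read_functional",
    "write_functional",
    "read_mask",
    "write_mask",
    "read_motion_params",
    "write_motion_params",
    "read_ratings",
    "write_ratings",
    "read_acquisition_spec",
    "write_notes",
]


# ---------------------------------------------------------------------------
# NIfTI

def read_functional(path: str | os.PathLike) -> FunctionalSeries:
    """Load a 4D NIfTI-1 file as a :class:`FunctionalSeries`.

    Voxel size and TR are taken from the header (``pixdim[1:4]`` and
    ``pixdim[4]``).
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 4:
        raise DimensionalityError(
            f"{path}: expected a 4D functional image, got {img.ndim}D"
        )
    zooms = img.header.get_zooms()
    data = np.asanyarray(img.dataobj)
    return FunctionalSeries(
        data=data,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=float(zooms[3]),
        affine=img.affine,
    )


def write_functional(series: FunctionalSeries, path: str | os.PathLike) -> None:
    """Write a series to NIfTI-1, storing voxel size and TR in the header."""
    img = nib.Nifti1Image(series.data, series.affine)
    img.header.set_zooms(tuple(series.voxel_size) + (series.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> BrainMask:
    """Load a 3D binary mask, re-binarising at 0.5 as the protocol does."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D mask, got {img.ndim}D")
    data = np.asanyarray(img.dataobj)
    return BrainMask((data > 0.5).astype(np.uint8))


def write_mask(mask: BrainMask, path: str | os.PathLike, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Motion parameter files

def read_motion_params(
    path: str | os.PathLike,
    n_volumes: int | None = None,
    rotations_first: bool = True,
) -> MotionTrace:
    """Parse a 6-column motion parameter file (MCFLIRT ``.par`` dialect).

    Parameters
    ----------
    n_volumes:
        If given, the file must contain exactly this many rows.
    rotations_first:
        MCFLIRT writes rotations (radians) in columns 1-3 and translations
        (mm) in columns 4-6. Set False for translations-first files.
    """
    try:
        table = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in motion file {path}: {exc}") from exc
    if table.ndim != 2 or table.shape[1] != 6:
        raise FormatError(
            f"motion file {path} must have 6 columns, got shape {table.shape}"
        )
    if n_volumes is not None and table.shape[0] != n_volumes:
        raise LengthMismatchError(
            f"motion file {path} has {table.shape[0]} rows, expected {n_volumes}"
        )
    if rotations_first:
        rot, trans = table[:, :3], table[:, 3:]
    else:
        trans, rot = table[:, :3], table[:, 3:]
    return MotionTrace(rotations=rot, translations=trans)


def write_motion_params(
    trace: MotionTrace, path: str | os.PathLike, fmt: str = "%.6f"
) -> None:
    """Write a trace in the MCFLIRT column order (rotations then translations)."""
    table = np.hstack([trace.rotations, trace.translations])
    np.savetxt(str(path), table, fmt=fmt, delimiter="  ")


# ---------------------------------------------------------------------------
# Ratings tables

def read_ratings(path: str | os.PathLike) -> RatingsTable:
    """Read a long-format ratings CSV with columns subject, rater, label.

    Labels are case-insensitive; missing cells are simply absent rows.
    """
    frame = pd.read_csv(path, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"subject", "rater", "label"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"ratings file {path} must have columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    return RatingsTable.from_long(frame)


def write_ratings(table: RatingsTable, path: str | os.PathLike) -> None:
    """Write the long-format CSV that :func:`read_ratings` reads."""
    long = (
        table.frame.stack()
        .rename("label")
        .rename_axis(["subject", "rater"])
        .reset_index()
    )
    long.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Acquisition specs and notes files

@dataclass
class ModalitySpec:
    """Expected acquisition parameters for one modality at one site."""

    voxel_size: tuple[float, float, float]
    matrix: tuple[int, int, int]
    n_volumes: int
    tr: float | None = None

    def __post_init__(self) -> None:
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.matrix = tuple(int(v) for v in self.matrix)
        if any(v <= 0 for v in self.voxel_size) or any(v <= 0 for v in self.matrix):
            raise ConfigurationError("voxel size and matrix entries must be positive")
        if self.n_volumes <= 0:
            raise ConfigurationError("n_volumes must be positive")


@dataclass
class AcquisitionSpec:
    """Per-site, per-modality expected acquisition parameters.

    ``sites`` maps site id -> modality name ("EPI", "T1w", ...) ->
    :class:`ModalitySpec`; ``scans_per_subject`` is the expected number of
    scans each subject contributes.
    """

    sites: dict[str, dict[str, ModalitySpec]]
    scans_per_subject: dict[str, int] = field(default_factory=dict)
    subject_ranges: dict[str, tuple[str, str]] = field(default_factory=dict)

    def lookup(self, site: str, modality: str) -> ModalitySpec:
        try:
            return self.sites[site][modality]
        except KeyError as exc:
            raise ConfigurationError(
                f"no acquisition spec entry for site={site!r} modality={modality!r}"
            ) from exc


def read_acquisition_spec(path: str | os.PathLike) -> AcquisitionSpec:
    """Read a YAML or JSON acquisition spec.

    Layout::

        sites:
          task:
            EPI: {voxel_size: [3, 3, 4], matrix: [64, 64, 34], n_volumes: 242, tr: 2}
        scans_per_subject: {task: 2}
    """
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "sites" not in raw:
        raise ConfigurationError(f"acquisition spec {path} must map a 'sites' key")
    sites: dict[str, dict[str, ModalitySpec]] = {}
    for site, modalities in raw["sites"].items():
        sites[site] = {}
        for modality, entry in modalities.items():
            try:
                sites[site][modality] = ModalitySpec(
                    voxel_size=tuple(entry["voxel_size"]),
                    matrix=tuple(entry["matrix"]),
                    n_volumes=int(entry["n_volumes"]),
                    tr=float(entry["tr"]) if "tr" in entry and entry["tr"] is not None else None,
                )
            except KeyError as exc:
                raise ConfigurationError(
                    f"spec entry {site}/{modality} missing field {exc}"
                ) from exc
    ranges = {
        k: (str(v[0]), str(v[1])) for k, v in raw.get("subject_ranges", {}).items()
    }
    return AcquisitionSpec(
        sites=sites,
        scans_per_subject={k: int(v) for k, v in raw.get("scans_per_subject", {}).items()},
        subject_ranges=ranges,
    )


@dataclass
class Deviation:
    """One observed departure from the expected acquisition parameters."""

    field: str
    observed: object
    expected: object
    hard: bool = True  # hard deviations are exclusion-grade per the protocol

    def describe(self) -> str:
        return f"{self.field}: observed {self.observed}, expected {self.expected}"


def write_notes(deviations: list[Deviation], path: str | os.PathLike) -> Path:
    """Write a human-readable notes file describing acquisition deviations.

    The filename must end in ``_notes.txt``; it is appended if absent. An
    empty deviation list produces a single "no deviations" line.
    """
    path = Path(path)
    if not path.name.endswith("_notes.txt"):
        path = path.with_name(path.name.removesuffix(".txt") + "_notes.txt")
    if deviations:
        lines = [d.describe() for d in deviations]
    else:
        lines = ["no deviations from expected acquisition parameters found"]
    path.write_text("\n".join(lines) + "\n")
    return path
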