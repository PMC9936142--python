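"""Synthetic 4D EPI phantoms, injectable artefacts, and simulated raters.

Every stage of the pipeline can be exercised against ground truth built
here: an ellipsoidal "brain" of plateau intensity plus Gaussian noise and a
small common global-signal fluctuation, a matching binary mask, a zero
motion trace; then events injected on top — volume shifts with the matching
entry written into the motion trace, global signal drops calibrated in
standard deviations of the global timecourse, ghosting (a half-field-of-view
shifted attenuated copy), wraparound (circular roll of anatomy through the
field of view), slice spikes, and slow drifts. Rater panels are simulated by
pushing true labels through per-rater confusion matrices with configurable
missingness.

Everything is deterministic under a fixed seed. Noise is Gaussian rather
than Rician and no k-space physics is modelled: adequate for validating the
metrics, not for simulating a scanner.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, VocabularyError
from .types import BrainMask, FunctionalSeries, LABELS, MotionTrace, RatingsTable

__all__ = [
    "PhantomSpec",
    "ArtefactEvent",
    "RaterModel",
    "generate_phantom",
    "inject",
    "simulate_raters",
    "default_rater_panel",
    "STUDY_LABEL_PREVALENCE",
]

ARTEFACT_KINDS = ("motion_shift", "signal_drop", "ghosting", "wraparound", "slice_spike", "drift")


@dataclass
class PhantomSpec:
    """Geometry and signal model of a synthetic EPI series.

    Defaults follow the task-site acquisition of the study dataset: a
    64 x 64 x 34 matrix of 3 x 3 x 4 mm voxels, 242 volumes at TR 2 s. The
    brain is a centred ellipsoid with plateau intensity 500 against
    background 0, with optional bright rim; voxel noise sigma defaults to 5
    (temporal SNR 100 by construction) and a shared in-brain global signal
    fluctuation of sigma 2 intensity units emulates slow physiological
    variation so that "drops of k standard deviations" are meaningful.
    """

    shape: tuple[int, int, int, int] = (64, 64, 34, 242)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)
    tr: float = 2.0
    plateau: float = 500.0
    background: float = 0.0
    rim: float = 0.0               # extra intensity on the outer shell, 0 = off
    semiaxes: tuple[float, float, float] | None = None  # voxels; default 0.4 * extent
    noise_sigma: float = 5.0
    global_signal_sigma: float = 2.0
    seed: int = 0


def _ellipsoid(shape3, semiaxes) -> np.ndarray:
    cx, cy, cz = [(s - 1) / 2.0 for s in shape3]
    ax, ay, az = semiaxes
    x, y, z = np.ogrid[: shape3[0], : shape3[1], : shape3[2]]
    r = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return r <= 1.0


def generate_phantom(
    spec: PhantomSpec | None = None, **overrides
) -> tuple[FunctionalSeries, BrainMask, MotionTrace]:
    """Build a phantom series, its mask, and an all-zero motion trace.

    Keyword overrides are applied on top of ``spec`` (or the defaults), so
    ``generate_phantom(shape=(16, 16, 8, 20), seed=3)`` works directly.
    """
    if spec is None:
        spec = PhantomSpec(**overrides)
    elif overrides:
        spec = PhantomSpec(**{**spec.__dict__, **overrides})
    nx, ny, nz, nt = spec.shape
    semi = spec.semiaxes or (0.4 * nx, 0.4 * ny, 0.4 * nz)
    if any(2 * a > s for a, s in zip(semi, (nx, ny, nz))):
        raise GeometryError(
            f"ellipsoid semiaxes {semi} do not fit inside grid {(nx, ny, nz)}"
        )
    support = _ellipsoid((nx, ny, nz), semi)
    if not support.any():
        raise GeometryError("ellipsoid contains no voxels")

    rng = np.random.default_rng(spec.seed)
    vol = np.full((nx, ny, nz), spec.background, dtype=np.float64)
    vol[support] = spec.plateau
    if spec.rim:
        shell = support & ~_ellipsoid((nx, ny, nz), tuple(0.85 * a for a in semi))
        vol[shell] += spec.rim

    data = np.repeat(vol[..., None], nt, axis=3)
    if spec.global_signal_sigma > 0:
        g = rng.normal(0.0, spec.global_signal_sigma, size=nt)
        data[support, :] += g[None, :]
    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, size=data.shape)

    series = FunctionalSeries(
        data=data, voxel_size=spec.voxel_size, tr=spec.tr
    )
    mask = BrainMask(support.astype(np.uint8))
    trace = MotionTrace(rotations=np.zeros((nt, 3)), translations=np.zeros((nt, 3)))
    return series, mask, trace


# ---------------------------------------------------------------------------
# Artefact injection

@dataclass
class ArtefactEvent:
    """One injectable artefact.

    ``magnitude`` is in the unit natural to the kind: mm for motion_shift,
    standard deviations of the global timecourse for signal_drop, a 0-1
    intensity fraction for ghosting and drift, multiples of the noise sigma
    for slice_spike; wraparound uses ``magnitude`` as the fraction of the
    field of view rolled. ``axis`` picks the spatial axis for shifts,
    ghosting and wraparound; ``slice_index`` the slice for slice_spike.
    """

    kind: str
    onset: int
    duration: int
    magnitude: float
    axis: int = 1          # phase-encode analogue
    slice_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ARTEFACT_KINDS:
            raise VocabularyError(
                f"unknown artefact kind {self.kind!r}; one of {ARTEFACT_KINDS}"
            )
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")

    def volumes(self, n_volumes: int) -> range:
        if self.onset < 0 or self.onset + self.duration > n_volumes:
            raise ValueError(
                f"event window [{self.onset}, {self.onset + self.duration}) "
                f"outside series of {n_volumes} volumes"
            )
        return range(self.onset, self.onset + self.duration)


def inject(
    series: FunctionalSeries,
    mask: BrainMask,
    trace: MotionTrace,
    event: ArtefactEvent,
    noise_sigma: float | None = None,
) -> tuple[FunctionalSeries, MotionTrace]:
    """Return a copy of the series (and trace) with one artefact injected.

    motion_shift rolls the affected volumes by a whole number of voxels
    (``magnitude`` mm divided by the voxel size along ``axis``, rounded)
    and writes the corresponding translation into the trace, so metric and
    motion ground truth stay exact. signal_drop lowers in-mask intensities
    of the affected volumes by a constant calibrated so the z-scored global
    timecourse of the *injected* series reads ``-magnitude`` over the window
    in expectation. slice_spike adds a constant offset of
    ``magnitude x noise_sigma`` to one slice (``noise_sigma`` estimated
    from out-of-mask voxels when not given).
    """
    data = series.data.astype(np.float64, copy=True)
    new_trace = MotionTrace(
        rotations=trace.rotations.copy(), translations=trace.translations.copy()
    )
    vols = list(event.volumes(series.n_volumes))
    kind = event.kind

    if kind == "motion_shift":
        step = series.voxel_size[event.axis]
        shift_vox = int(round(event.magnitude / step))
        data[..., vols] = np.roll(data[..., vols], shift_vox, axis=event.axis)
        new_trace.translations[vols, event.axis] += shift_vox * step
    elif kind == "signal_drop":
        g = series.data[mask.data, :].mean(axis=0)
        sigma = float(np.std(g))
        f = len(vols) / series.n_volumes
        # Calibrate so the *post-injection* z-scored global timecourse reads
        # -magnitude over the window in expectation. z-scoring against the
        # injected series itself attenuates the drop (the window shifts the
        # mean and inflates the SD), and a window fraction f caps the
        # achievable reading at sqrt((1 - f) / f) standard deviations.
        bound = np.sqrt((1.0 - f) / f)
        if abs(event.magnitude) >= bound:
            raise ValueError(
                f"a {event.magnitude} SD drop over {f:.0%} of the volumes is "
                f"not achievable in the normalised timecourse (max {bound:.2f})"
            )
        drop = (
            event.magnitude
            * sigma
            / np.sqrt((1.0 - f) ** 2 - event.magnitude**2 * f * (1.0 - f))
        )
        sel = mask.data[..., None] & np.isin(
            np.arange(series.n_volumes), vols
        )[None, None, None, :]
        data[sel] -= drop
    elif kind == "ghosting":
        half = series.data.shape[event.axis] // 2
        ghost = np.roll(series.data[..., vols], half, axis=event.axis)
        data[..., vols] = data[..., vols] + event.magnitude * ghost
    elif kind == "wraparound":
        shift = int(round(event.magnitude * series.data.shape[event.axis]))
        data[..., vols] = np.roll(data[..., vols], shift, axis=event.axis)
    elif kind == "slice_spike":
        if event.slice_index is None:
            raise ValueError("slice_spike needs slice_index")
        if noise_sigma is None:
            out = ~mask.data
            noise_sigma = float(series.data[out, :].std()) if out.any() else 1.0
        data[:, :, event.slice_index, vols] += event.magnitude * noise_sigma
    elif kind == "drift":
        ramp = np.linspace(0.0, event.magnitude, num=len(vols))
        sel = mask.data
        for ramp_val, t in zip(ramp, vols):
            data[sel, t] *= 1.0 + ramp_val

    new_series = FunctionalSeries(
        data=data, voxel_size=series.voxel_size, tr=series.tr, affine=series.affine
    )
    return new_series, new_trace


# ---------------------------------------------------------------------------
# Simulated raters

#: Prevalence of true labels emulating the study's majority classifications
#: (97 include, 6 uncertain, 26 exclude of 129 subjects).
STUDY_LABEL_PREVALENCE = {"include": 97 / 129, "uncertain": 6 / 129, "exclude": 26 / 129}


@dataclass
class RaterModel:
    """Stochastic rater panel: per-rater confusion matrices plus missingness.

    ``confusion[r]`` is a 3x3 row-stochastic matrix over (include,
    uncertain, exclude): row = true label, column = assigned label.
    ``raters_per_subject`` (if set) assigns each subject to a random subset
    of that many raters, emulating a design where not every rater reviews
    every subject; ``full_panel_rate`` is the fraction of subjects reviewed
    by the whole panel regardless; ``missing_rate`` instead drops each cell
    independently.
    """

    confusion: list[np.ndarray]
    raters_per_subject: int | None = None
    full_panel_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    rater_ids: list[str] | None = None

    def __post_init__(self) -> None:
        mats = []
        for c in self.confusion:
            c = np.asarray(c, dtype=float)
            if c.shape != (3, 3) or np.any(c < 0) or not np.allclose(c.sum(axis=1), 1.0):
                raise ValueError("each confusion matrix must be 3x3 with rows summing to 1")
            mats.append(c)
        self.confusion = mats
        if self.rater_ids is None:
            self.rater_ids = [f"rater{i + 1}" for i in range(len(mats))]

    @property
    def n_raters(self) -> int:
        return len(self.confusion)


def identity_rater_model(n_raters: int = 4, seed: int = 0, **kw) -> RaterModel:
    """Raters who always return the true label."""
    return RaterModel(confusion=[np.eye(3)] * n_raters, seed=seed, **kw)


def default_rater_panel(seed: int = 0) -> RaterModel:
    """A plausible experienced-rater panel.

    Raters mostly agree on clear include/exclude cases but treat the
    "uncertain" category idiosyncratically — the borderline cases that make
    one rater uncertain leave another comfortable either way. One rater
    reaches for "uncertain" more often than the rest. Most subjects are
    reviewed by three of the four raters, with roughly a quarter (29/129,
    the overlap implied by four raters covering 104 subjects each) seen by
    the whole panel.
    """
    base = np.array(
        [
            [0.90, 0.06, 0.04],
            [0.38, 0.27, 0.35],
            [0.06, 0.08, 0.86],
        ]
    )
    cautious = np.array(
        [
            [0.80, 0.15, 0.05],
            [0.25, 0.45, 0.30],
            [0.05, 0.15, 0.80],
        ]
    )
    return RaterModel(
        confusion=[base, base, base, cautious],
        raters_per_subject=3,
        full_panel_rate=29 / 129,
        seed=seed,
    )


def simulate_raters(
    true_labels: list[str],
    model: RaterModel,
    subjects: list[str] | None = None,
) -> RatingsTable:
    """Draw a ratings table from a rater model given true labels per subject."""
    for lab in true_labels:
        if lab not in LABELS:
            raise VocabularyError(f"unknown true label {lab!r}")
    rng = np.random.default_rng(model.seed)
    n_sub = len(true_labels)
    if subjects is None:
        subjects = [f"sub-{i + 1:03d}" for i in range(n_sub)]
    frame = pd.DataFrame(np.nan, index=subjects, columns=model.rater_ids, dtype=object)
    for s, true in zip(subjects, true_labels):
        ti = LABELS.index(true)
        full = model.full_panel_rate and rng.random() < model.full_panel_rate
        if (
            not full
            and model.raters_per_subject is not None
            and model.raters_per_subject < model.n_raters
        ):
            chosen = rng.choice(model.n_raters, size=model.raters_per_subject, replace=False)
        else:
            chosen = np.arange(model.n_raters)
        for r in chosen:
            if model.missing_rate and rng.random() < model.missing_rate:
                continue
            frame.loc[s, model.rater_ids[r]] = LABELS[
                rng.choice(3, p=model.confusion[r][ti])
            ]
    # a subject could lose every rating to missingness; keep it with one draw
    empty = frame.isna().all(axis=1)
    for s in frame.index[empty]:
        r = int(rng.integers(model.n_raters))
        ti = LABELS.index(true_labels[subjects.index(s)])
        frame.loc[s, model.rater_ids[r]] = LABELS[rng.choice(3, p=model.confusion[r][ti])]
    frame.index.name = "subject"
    frame.columns.name = "rater"
    return RatingsTable(frame)
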