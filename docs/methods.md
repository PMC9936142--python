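# Methods

This note records what `epiqc` computes, the choices made where a published
description left room for interpretation, and what the synthetic validation
does and does not demonstrate.

## Image quality metrics

### Scaled squared difference

The SSD of voxel $v$ at transition $t$ is $(I_v(t{+}1)-I_v(t))^2 / D$ with
$D$ the mean squared difference over **all voxels and all transitions** of
the scan — one scalar normaliser per scan, not one per transition. This
makes transition profiles comparable within a scan and gives the testable
invariant that the SSD averages to exactly 1 over its full domain. A scan
whose consecutive volumes are identical has $D=0$; the SSD is then defined
as 0 everywhere and a degenerate-normaliser warning is raised.

The SSD is computed over the whole volume, not restricted to the brain
mask, because the artefacts it is best at catching — ghosting, eye
movement — live outside brain tissue. A mask-restricted variant is
available (`mask=` argument), in which case the normaliser is also
mask-restricted.

"Slice" everywhere means a fixed index along the third spatial axis of the
(x, y, z, t) grid, matching axial slice-wise reporting; indexing is
0-based.

### Temporal SNR

The noise sample is taken from out-of-mask voxels whose temporal-mean
intensity lies at or below a centile (default 25) of the out-of-mask
temporal means; this targets background air and avoids out-of-mask tissue
such as eyes and scalp. The noise SD pools every (voxel, time) sample of
the selected voxels rather than averaging per-voxel temporal SDs — the
simplest reading of "standard deviation of voxels"; a per-voxel variant
would differ only in how between-voxel mean variation enters. The
selection-by-centile and the per-voxel mean removal bias the pooled SD
slightly downward, by roughly $1/(2T)$ relative for $T$ volumes —
negligible beyond ~50 volumes and well inside the construction tolerance
used in the tests (2%).

The `-s` CLI value is interpreted as this centile; an absolute-intensity
cutoff mode (`--noise-mode absolute`) is provided because the flag is also
used that way in the wild. Slice-wise SNR divides each slice's in-mask mean
by the same global noise SD; slices without mask voxels report NaN, and a
zero noise SD yields an infinite-SNR sentinel with a warning.

### Carpet matrix

In-mask voxels are sorted ascending by temporal mean, ties broken by linear
voxel index (stable and reproducible), and split into 50 contiguous bins
whose sizes differ by at most one (`numpy.array_split`; the larger bins
come first). Row 0 is the lowest-intensity bin. The report displays each
row centred on its own mean so banding is visible against the intensity
gradient.

### Display thresholds

The variance map (population variance over time, divide by $n$) is
displayed with an upper cutoff: its values are histogrammed into 1,000
equal-width bins over [min, max] and the **lower edge** of the highest-index
bin holding at least 400 voxels is used. Which representative point of the
bin to use is not specified anywhere we could find; the lower edge is the
conservative choice (thresholds slightly more, never less, than the bin
content justifies). Maps too small for any bin to reach 400 voxels fall
back to the map maximum with a warning; a constant map returns its value.
The sum-SSD map cutoff is the upper edge of the fifth of 50 equal-width
bins, i.e. $\min + 5(\max-\min)/50$. The NIfTI derivatives of both maps are
always unthresholded.

### Global timecourse

The per-volume mean of in-mask intensities is z-scored over volumes
(population SD). z-scoring was chosen over min–max scaling so that signal
drops read directly in standard deviations, which is how such events are
described in practice. A temporally constant series yields zeros with a
warning.

### Mask coverage

An advisory (never exclusion-grade) check reports the fraction of
high-intensity voxels lying outside the mask and whether the mask touches
the first or last slice. "High-intensity" is defined by Otsu's threshold on
the temporal-mean image, re-centred on the midpoint of the two Otsu
classes: with a wide empty gap between background and tissue intensities
every split inside the gap maximises the between-class variance and the
raw Otsu rule returns the lowest, which would count background noise tails
as tissue. The advisory fires above 5% outside-fraction.

## Motion

Absolute displacement at volume $t$ is the Euclidean norm of the
translation difference from volume 0 (the realignment reference), plus —
by default — a rotational arc length: 50 mm × the Euclidean norm of the
rotation difference, the conventional head-radius stand-in used by
framewise-displacement measures. Relative displacement is the same measure
between consecutive volumes. Motion-correction tools do not all publish
their internal displacement formula; this one is documented, closed-form,
and exactly recoverable on synthetic traces, and the rotational term can be
switched off. Whether published thresholds were tuned against RMS
displacement files or translation norms is ambiguous; both readings are
supported (`include_rotation`, `sphere_radius`), with the documented
default above.

"Relative movement greater than the voxel size" uses the **minimum** voxel
dimension — the strictest reading, so borderline scans err toward exclusion;
`voxel_rule="max"` relaxes it.

## Classification protocol

Thresholds (all configurable, defaults in `ProtocolThresholds`): no
relative event above voxel size; at most 5 events above 0.5 mm; absolute
motion ≤ 2 mm with (1.5, 2] marginal; slice-wise SNR ≥ 99 with [99, 150)
marginal; voxel sizes equal to 2 decimal places; exact volume and scan
counts. Marginal findings map to the "uncertain" label. Any
exclusion-grade reason forces "exclude" regardless of the rest; a scan with
no reasons at all is "include".

Two rules mechanise rater discretion:

- NaN slice-wise SNR values (slices with no mask voxels) are ignored
  entirely.
- The slice SNR rule applies only to slices whose in-mask voxel fraction is
  at least 5% of the slice (configurable); sparser slices are reported as
  advisory only. This is a reproducible stand-in for the instruction to use
  judgement on mostly-non-brain slices. Whether the rule should bind per
  slice or on the across-slice mean is ambiguous; per-slice is the default
  and a mean mode is provided.

Coverage findings and soft header deviations (matrix, TR) are advisory:
they route the scan to "uncertain", never to automatic exclusion, because
the corresponding checks are visual judgements in manual protocols.

## Reliability statistics

Fleiss' (1971) kappa over the three nominal categories, with the
null-hypothesis variance for the overall statistic and
$\mathrm{var}_0(\kappa_j) = 2/(Nn(n{-}1))$ for the category-wise statistic;
$z = \kappa/\mathrm{SE}_0$, two-sided p. These are the formulas used by the
R `irr` package's `kappam.fleiss`, which is the de facto reference
implementation; the point estimate is cross-checked against
`statsmodels`' independent implementation in the tests, and the null SEs
are validated by simulation (the z statistics are standard normal under
random labelling to within Monte-Carlo error).

Fleiss' kappa needs a constant number of ratings per subject, so each
statistic is computed on complete cases — subjects rated by every rater in
the requested subset — and `n_subjects_used` is always reported. Pairwise
tests form one Holm family per table (the 6 overall tests together; the 6
tests within a category together); Holm adjustment goes through
`statsmodels.multipletests`.

Krippendorff's alpha (nominal metric) is computed from the coincidence
matrix over all pairable values within subjects: a subject with $m \ge 2$
ratings contributes each ordered pair with weight $1/(m-1)$; subjects with
fewer than two ratings drop out. $\alpha = 1 - D_o/D_e$. The 95% CI is the
percentile interval of 1,000 bootstrap recomputations resampling subjects
with replacement under a fixed seed; resamples with undefined alpha are
skipped. If only one category appears among pairable values, $D_e = 0$ and
alpha is defined as 1 (perfect agreement).

Landis–Koch bands are applied upper-inclusively at the printed edges: poor
< 0, slight [0, 0.2], fair (0.2, 0.4], moderate (0.4, 0.6], substantial
(0.6, 0.8], almost perfect (0.8, 1].

Majority classification assigns a subject every label given by at least two
raters (with four raters a 2–2 split legitimately yields two labels);
subjects where no label reaches two votes are flagged unresolved.

## Synthetic data

The phantom is a centred ellipsoid (default semiaxes 0.4 of each grid
extent) of plateau intensity 500 over background 0, with i.i.d. Gaussian
noise (default SD 5, fixing temporal SNR at 100 by construction) and a
shared in-brain global signal fluctuation (default SD 2 intensity units,
~0.4% of the plateau) emulating slow physiological variation — without it,
"a drop of $k$ standard deviations" of the global timecourse would be
vanishingly small in absolute terms. Default geometry follows a typical
single-band EPI acquisition: 64 × 64 × 34 voxels of 3 × 3 × 4 mm, 242
volumes, TR 2 s. Everything is deterministic under the spec's seed.

Artefact injections and their ground truth:

- **motion_shift**: whole-voxel circular roll of the affected volumes
  (magnitude in mm, rounded to voxels) with the matching translation
  written into the motion trace — displacement ground truth is exact
  because no interpolation occurs.
- **signal_drop**: a constant subtracted from in-mask intensities of the
  affected volumes, calibrated so the z-scored global timecourse of the
  *injected* series reads −magnitude over the window in expectation.
  z-scoring against the injected series itself attenuates a naive drop
  (the window shifts the mean and inflates the SD), and a window covering
  fraction $f$ of the series caps the achievable reading at
  $\sqrt{(1-f)/f}$ SD; magnitudes at or beyond the cap raise an error.
- **ghosting**: adds a half-field-of-view-shifted copy scaled by magnitude
  along the phase-encode analogue (axis 1 by default).
- **wraparound**: circular roll of the affected volumes by a fraction of
  the field of view.
- **slice_spike**: a constant offset of magnitude × noise SD added to one
  slice of the affected volumes (a deterministic offset, so the slice-wise
  SSD argmax is exact ground truth).
- **drift**: multiplicative linear ramp on in-mask signal.

Disjoint-window events of the deterministic kinds commute exactly; a
signal drop's calibration depends on the series it is injected into, so
drop injections are order-sensitive with respect to other events.

The rater simulator draws each rater's label from a per-rater 3×3 confusion
matrix given the subject's true label, with either independent cell
missingness or a reviewers-per-subject design (default panel: 3 of 4 raters
per subject, with 29/129 of subjects seen by the whole panel — the overlap
implied by four raters each covering 104 of 129 subjects). The default
panel's confusion structure encodes experienced raters who agree on clear
include/exclude cases but treat "uncertain" idiosyncratically, one of them
more uncertainty-prone; true-label prevalence defaults to 97:6:26 over 129
subjects. These values are fixed design choices, not fitted quantities.

### What the synthetic validation does not show

Noise is Gaussian, not Rician; there is no k-space model, slice timing, B0
inhomogeneity, spin-history effect, or physiological noise spectrum, and
injected motion is pure translation of whole volumes. Passing tests
demonstrate that the metrics, rules and statistics compute what they claim
on data whose ground truth is known — not that the thresholds are optimal
for real scanners, nor that real rater behaviour follows a confusion-matrix
model.

## Numerical choices

- All metric arithmetic is float64 regardless of storage dtype.
- Variances and z-scores use population denominators (divide by $n$).
- Histogram bins are half-open [lo, hi) with the final bin closed
  (`numpy.histogram` convention).
- Carpet sorting ties break by linear voxel index.
- Bootstrap and all generators use `numpy.random.default_rng` seeded
  explicitly; identical seeds give bit-identical outputs.
- Problem sizes in the test suite are kept small (grids of ~10⁴–10⁵ voxels,
  50–120 volumes) — large enough for the constructions' tolerances, chosen
  so the whole suite runs in well under a minute of CPU; the acceptance
  script uses the full 64 × 64 × 34 × 242 geometry.

## Known limitations

- Fleiss-type statistics silently lose subjects outside the complete-case
  subset; with heavy missingness prefer Krippendorff's alpha.
- The acquisition checker validates headers, volume counts and scan counts
  only; it is not a BIDS validator.
- The HTML report embeds static PNGs; no interactive viewer.
- T1-specific quality checks (ringing, segmentation quality, anatomy) are
  out of scope: the package consumes functional-space inputs only.
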