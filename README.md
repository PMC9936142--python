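# epiqc

Quality control for 4D functional MRI (EPI) time series: image quality
metrics, a quantitative include/uncertain/exclude classification protocol,
and inter-rater reliability analysis for panels of human quality-control
raters — plus a synthetic phantom and rater simulator so that every stage of
the pipeline can be validated against known ground truth without real scans.

## Who this is for

Neuroimaging labs that screen raw or minimally pre-processed fMRI data
before analysis. Manual inspection is slow and subjective; `epiqc` computes
the standard screening metrics from a motion-corrected 4D NIfTI series, a
binary brain mask in functional space, and rigid-body motion parameters
(MCFLIRT `.par` dialect), applies explicit numeric thresholds, and reports
every decision with its evidence. The reliability module quantifies how
consistently human raters apply such a protocol.

## The metrics and statistics

**Scaled squared difference (SSD).** For voxel $v$ and transition $t$,

$$\mathrm{SSD}_{v,t} = \frac{(I_v(t{+}1) - I_v(t))^2}{D}, \qquad
D = \overline{(I_v(t{+}1) - I_v(t))^2}$$

where the bar averages over *all* voxels and transitions of the scan, so the
SSD has mean exactly 1. Sudden global changes, slice artefacts and eye
movement surface as localised excursions far above 1 in the per-transition
mean/variance, slice-wise min/mean/max, and voxel-wise sum maps.

**Temporal SNR.** Mean in-mask intensity divided by the standard deviation
of a noise sample: out-of-mask voxels whose temporal mean lies at or below
the 25th centile of out-of-mask temporal means (i.e. background air,
avoiding eyes and scalp), pooled over all their time points. Reported
globally and per slice (NaN for slices with no mask voxels).

**Carpet matrix.** In-mask voxels sorted by temporal mean into 50
equal-sized bins; each bin's mean time course forms one row. Vertical
banding marks global signal events.

**Classification protocol.** Exclude if any relative motion event exceeds
the voxel size, more than 5 events exceed 0.5 mm, maximum absolute motion
exceeds 2 mm, any valid slice-wise SNR is below 99, or the header deviates
from the expected acquisition (voxel size compared to 2 d.p., volume and
scan counts exactly). Absolute motion in (1.5, 2] mm or slice SNR in
[99, 150) is *uncertain*. Slices with NaN SNR never exclude.

**Reliability.** Fleiss' $\kappa$ (overall, category-wise, and pairwise with
Holm-adjusted two-sided tests against chance), percent agreement,
Krippendorff's $\alpha$ (nominal metric, tolerant of missing ratings) with a
1,000-iteration subject bootstrap for 95% CIs, majority classification, and
Landis–Koch interpretation bands.

## Worked example

```sh
python examples/phantom_qc.py
```

builds a clean phantom (plateau 500, noise SD 2.5) and prints:

```
temporal SNR (global):      200.8   # mean in-mask signal / noise SD
mean voxel-wise SSD:        1.000000   # 1 by construction
relative events > 0.5 mm:   0
max absolute motion (mm):   0.00
classification:             include
report written to scratch/example_qc/phantom_report.html
```

The SNR is 200 because the phantom was built with signal 500 over noise 2.5;
the SSD mean is exactly 1 by normalisation; with no motion events and SNR
above the 150 marginal band the protocol includes the scan. The other
examples inject artefacts and read them back (`inject_artefacts.py`), check
acquisition consistency (`acquisition_check.py`), and simulate a four-rater
panel (`rater_reliability.py`).

The same pipeline is available from the shell:

```sh
epiqc qc -n func.nii.gz -k mask.nii.gz -m func.par -s 25 --out qc/
epiqc reliability ratings.csv --bootstrap 1000 --seed 1 --out rel/
epiqc simulate --preset drop --seed 1 --out fixtures/
```

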