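"""Per-scan QC report: PNG plots, NIfTI derivatives, CSV/JSON sidecars, HTML.

Every number shown in the HTML page is also written to a machine-readable
sidecar (``metrics.json``, ``classification.csv``), and the thresholds in
force are echoed into the report header so a reviewer can audit them. The
variance and sum-SSD maps are thresholded only in the PNGs; the NIfTI
derivatives are unthresholded.
"""
from __future__ import annotations

import json
from pathlib import Path
from string import Template

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import Deviation, write_functional, write_notes
from .protocol import ProtocolThresholds
from .types import (
    BrainMask,
    Classification,
    FunctionalSeries,
    MotionTrace,
    QCMetrics,
)

import nibabel as nib

__all__ = ["ReportBundle", "write_report"]


class ReportBundle(dict):
    """Paths of everything a report run produced (name -> Path)."""

    def existing(self) -> bool:
        return all(Path(p).exists() for p in self.values())


def _save(fig, path: Path) -> Path:
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _plot_ssd_panel(metrics: QCMetrics, trace: MotionTrace, path: Path) -> Path:
    fig, axes = plt.subplots(4, 1, figsize=(9, 10), sharex=True)
    axes[0].plot(metrics.ssd_mean_per_transition, lw=0.8)
    axes[0].set_ylabel("mean SSD")
    axes[1].plot(metrics.ssd_variance_per_transition, lw=0.8, color="tab:orange")
    axes[1].set_ylabel("SSD variance")
    axes[2].plot(metrics.global_mean_timecourse_normalised, lw=0.8, color="tab:green")
    axes[2].set_ylabel("global signal (z)")
    if trace.abs_displacement is not None:
        axes[3].plot(trace.abs_displacement, lw=0.8, label="absolute")
        axes[3].plot(
            np.arange(1, len(trace.rel_displacement) + 1),
            trace.rel_displacement,
            lw=0.8,
            label="relative",
        )
        axes[3].legend(loc="upper right", fontsize=8)
    axes[3].set_ylabel("motion (mm)")
    axes[3].set_xlabel("volume")
    fig.suptitle("Scaled squared difference, global signal and motion")
    fig.tight_layout()
    return _save(fig, path)


def _plot_carpet(metrics: QCMetrics, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(9, 4))
    carpet = metrics.carpet
    # show each row as deviation from its own mean so banding is visible
    centred = carpet - carpet.mean(axis=1, keepdims=True)
    ax.imshow(centred, aspect="auto", cmap="gray", interpolation="nearest")
    ax.set_xlabel("volume")
    ax.set_ylabel("intensity bin (low to high)")
    ax.set_title("Mean voxel time course of bins with equal number of voxels")
    fig.tight_layout()
    return _save(fig, path)


def _plot_slicewise_ssd(metrics: QCMetrics, path: Path) -> Path:
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, grid, name in zip(
        axes,
        (metrics.ssd_slicewise_mean, metrics.ssd_slicewise_min, metrics.ssd_slicewise_max),
        ("mean", "min", "max"),
    ):
        im = ax.imshow(grid, aspect="auto", cmap="viridis", interpolation="nearest")
        ax.set_title(f"slice-wise SSD {name}")
        ax.set_xlabel("transition")
        fig.colorbar(im, ax=ax, shrink=0.8)
    axes[0].set_ylabel("slice")
    fig.tight_layout()
    return _save(fig, path)


def _plot_map(map3d: np.ndarray, threshold: float | None, title: str, path: Path) -> Path:
    nz = map3d.shape[2]
    picks = np.unique(np.linspace(0, nz - 1, min(nz, 6)).astype(int))
    fig, axes = plt.subplots(1, len(picks), figsize=(2.2 * len(picks), 2.6))
    axes = np.atleast_1d(axes)
    shown = np.clip(map3d, None, threshold) if threshold is not None else map3d
    for ax, z in zip(axes, picks):
        ax.imshow(shown[:, :, z].T, cmap="hot", origin="lower")
        ax.set_title(f"z={z}", fontsize=8)
        ax.axis("off")
    fig.suptitle(title)
    fig.tight_layout()
    return _save(fig, path)


def _plot_mask_overlay(series: FunctionalSeries, mask: BrainMask, path: Path) -> Path:
    tmean = series.data.mean(axis=3)
    nz = tmean.shape[2]
    picks = np.unique(np.linspace(0, nz - 1, min(nz, 6)).astype(int))
    fig, axes = plt.subplots(1, len(picks), figsize=(2.2 * len(picks), 2.6))
    axes = np.atleast_1d(axes)
    for ax, z in zip(axes, picks):
        ax.imshow(tmean[:, :, z].T, cmap="gray", origin="lower")
        ax.contour(mask.data[:, :, z].T, levels=[0.5], colors="deepskyblue", linewidths=0.8)
        ax.set_title(f"z={z}", fontsize=8)
        ax.axis("off")
    fig.suptitle("Temporal mean with brain mask outline")
    fig.tight_layout()
    return _save(fig, path)


_HTML = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>epiqc report: $name</title>
<style>body{font-family:sans-serif;margin:2em;max-width:70em}
table{border-collapse:collapse}td,th{border:1px solid #999;padding:0.3em 0.7em}
img{max-width:100%}</style></head><body>
<h1>epiqc report: $name</h1>
<h2>Classification: $label</h2>
<p>Reasons: $reasons</p>
<h2>Thresholds in force</h2>
<pre>$thresholds</pre>
<h2>Summary metrics</h2>
<table>
<tr><th>metric</th><th>value</th></tr>
$metric_rows
</table>
<h2>Plots</h2>
$figures
</body></html>
"""
)


def write_report(
    series: FunctionalSeries,
    mask: BrainMask,
    trace: MotionTrace,
    metrics: QCMetrics,
    classification: Classification,
    out_dir: str | Path,
    name: str = "scan",
    deviations: list[Deviation] | None = None,
    thresholds: ProtocolThresholds | None = None,
) -> ReportBundle:
    """Write the full report bundle for one scan and return its paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or ProtocolThresholds()
    bundle = ReportBundle()

    bundle["ssd_panel"] = _plot_ssd_panel(metrics, trace, out / f"{name}_ssd_panel.png")
    bundle["carpet"] = _plot_carpet(metrics, out / f"{name}_carpet.png")
    bundle["slicewise_ssd"] = _plot_slicewise_ssd(metrics, out / f"{name}_ssd_slicewise.png")
    bundle["variance_map_png"] = _plot_map(
        metrics.variance_map,
        metrics.png_threshold_variance,
        "Variance of voxel intensity (thresholded for display)",
        out / f"{name}_variance.png",
    )
    bundle["ssd_sum_png"] = _plot_map(
        metrics.ssd_sum_map,
        metrics.png_threshold_ssd,
        "Sum of scaled squared difference (thresholded for display)",
        out / f"{name}_ssd_sum.png",
    )
    bundle["mask_overlay"] = _plot_mask_overlay(series, mask, out / f"{name}_mask.png")

    # unthresholded NIfTI derivatives
    for key, grid in (("variance_map_nii", metrics.variance_map), ("ssd_sum_nii", metrics.ssd_sum_map)):
        p = out / f"{name}_{key.removesuffix('_nii')}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32), series.affine), p)
        bundle[key] = p

    exceed = trace.exceedances
    summary = {
        "snr_global": metrics.snr_global,
        "snr_slicewise_min_valid": float(np.nanmin(metrics.snr_slicewise)),
        "n_rel_gt_voxel": exceed.n_gt_voxel if exceed else None,
        "n_rel_gt_0.5mm": exceed.n_gt_high if exceed else None,
        "n_rel_gt_0.1mm": exceed.n_gt_low if exceed else None,
        "max_abs_motion_mm": exceed.max_abs if exceed else None,
        "png_threshold_variance": metrics.png_threshold_variance,
        "png_threshold_ssd": metrics.png_threshold_ssd,
        "coverage_outside_fraction": metrics.coverage.outside_fraction if metrics.coverage else None,
    }
    metrics_json = out / f"{name}_metrics.json"
    metrics_json.write_text(json.dumps(summary, indent=2, default=float))
    bundle["metrics_json"] = metrics_json

    cls_csv = out / f"{name}_classification.csv"
    cls_csv.write_text(
        "subject,label,reasons\n"
        f"{name},{classification.label},\"{';'.join(str(r) for r in classification.reasons)}\"\n"
    )
    bundle["classification_csv"] = cls_csv
    bundle["notes"] = write_notes(deviations or [], out / f"{name}_notes.txt")

    figures = "\n".join(
        f'<h3>{key}</h3><img src="{Path(p).name}">'
        for key, p in bundle.items()
        if str(p).endswith(".png")
    )
    metric_rows = "\n".join(
        f"<tr><td>{k}</td><td>{v}</td></tr>" for k, v in summary.items()
    )
    html = _HTML.substitute(
        name=name,
        label=classification.label,
        reasons="; ".join(str(r) for r in classification.reasons) or "none",
        thresholds=json.dumps(thresholds.to_dict(), indent=2),
        metric_rows=metric_rows,
        figures=figures,
    )
    report_path = out / f"{name}_report.html"
    report_path.write_text(html)
    bundle["html"] = report_path
    return bundle
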