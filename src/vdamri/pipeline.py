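"""End-to-end orchestration: simulate a phantom cohort to disk, analyse it
back into parameter maps and ROI tables, run the longitudinal statistics,
and quantify histology.  The CLI is a thin wrapper over these functions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, dce, histoquant, relaxometry
from .io import (
    load_label_map,
    load_nifti,
    save_histology_field,
    save_label_map,
    save_nifti,
    write_manifest,
)
from .phantom.geometry import build_phantom, parameter_volumes
from .phantom.histology import simulate_histology_fields
from .phantom.presets import ground_truth_from_json, ground_truth_to_json
from .phantom.simulate import (
    simulate_dce_series,
    simulate_dwi_series,
    simulate_multiecho_series,
    simulate_vfa_series,
)
from .protocol import AcquisitionProtocol
from .relaxometry import SignalStack

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_relaxometry",
           "run_dce", "run_stats", "run_histology"]

#: lesion-level histology presets: (necrosis fraction, Ki67+, CD31+) after
#: treatment, extracranial vs intracranial
HISTOLOGY_PRESETS = {
    "extracranial_tumor": {"necrosis": 0.862, "Ki67": 0.122, "CD31": 0.427},
    "intracranial_tumor": {"necrosis": 0.183, "Ki67": 0.323, "CD31": 0.543},
}


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    out_dir: str = "vdamri_out"
    seed: int = 0
    timepoints: tuple = ("pre", "1h", "8h", "24h")
    n_subjects: int = 1
    grid_shape: tuple = (64, 64, 16)
    noise_sd: float = 0.0
    voxel_size_mm: float = 0.5
    rim_width_voxels: int = 1
    alpha: float = 0.05
    pixelwise_maps: bool = True
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)

    def __post_init__(self):
        if isinstance(self.protocol, dict):
            self.protocol = AcquisitionProtocol.from_dict(self.protocol)
        self.timepoints = tuple(self.timepoints)
        unknown = set(self.timepoints) - set(cohort.TIMEPOINTS)
        if unknown:
            raise ValueError(f"unknown timepoints: {sorted(unknown)}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"] = self.protocol.to_dict()
        d["timepoints"] = list(self.timepoints)
        d["grid_shape"] = list(self.grid_shape)
        d.pop("out_dir")  # implied by the file's location; keeps reruns portable
        return d


def _subject_seed(base_seed: int, subject: int, timepoint: str) -> int:
    tp_index = cohort.TIMEPOINTS.index(timepoint)
    return int(np.random.SeedSequence([base_seed, subject, tp_index]).generate_state(1)[0] % (2**31))


def run_simulate(config: RunConfig) -> Path:
    """Simulate the phantom cohort to disk; returns the dataset directory.

    Writes, per subject and timepoint: the VFA stacks (pre- and
    post-contrast), multi-echo and DWI stacks, the 100-frame dynamic series,
    the ROI label map, and the ground truth JSON; plus the protocol and a
    checksum manifest at the root.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prot = config.protocol
    written = []
    prot_path = out / "protocol.yaml"
    prot.to_yaml(prot_path)
    written.append(prot_path)
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(config.to_json(), indent=2, sort_keys=True))
    written.append(cfg_path)

    for s in range(config.n_subjects):
        for tp in config.timepoints:
            seed = _subject_seed(config.seed, s, tp)
            rng_seeds = np.random.SeedSequence(seed).generate_state(6) % (2**31)
            labels, records = build_phantom(config.grid_shape, tp, seed=int(rng_seeds[0]),
                                            voxel_size_mm=config.voxel_size_mm)
            vols = parameter_volumes(labels, records)
            d = out / f"sub-{s:02d}" / f"tp-{tp}"
            d.mkdir(parents=True, exist_ok=True)
            vfa = simulate_vfa_series(vols["t1_ms"], vols["m0"], prot,
                                      config.noise_sd, int(rng_seeds[1]))
            vfa_ce = simulate_vfa_series(vols["ce_t1_ms"], vols["m0"], prot,
                                         config.noise_sd, int(rng_seeds[2]))
            me = simulate_multiecho_series(vols["t2_ms"], vols["m0"], prot,
                                           config.noise_sd, int(rng_seeds[3]))
            dwi = simulate_dwi_series(vols["adc"], vols["m0"], prot.b_values,
                                      config.noise_sd, int(rng_seeds[4]))
            dyn = simulate_dce_series(labels, records, prot, config.noise_sd, int(rng_seeds[5]))
            vx = config.voxel_size_mm
            written += [
                save_nifti(vfa.volumes, d / "vfa.nii.gz", vx),
                save_nifti(vfa_ce.volumes, d / "vfa_ce.nii.gz", vx),
                save_nifti(me.volumes, d / "multiecho.nii.gz", vx),
                save_nifti(dwi.volumes, d / "dwi.nii.gz", vx),
                save_nifti(dyn.frames, d / "dce.nii.gz", vx),
                save_label_map(labels, d / "labels.nii.gz"),
            ]
            gt_path = d / "ground_truth.json"
            ground_truth_to_json(records, gt_path)
            written.append(gt_path)
    write_manifest(written, out / "manifest.json")
    return out


def _check_series(name, arr, n_expected, d):
    if arr.shape[-1] != n_expected:
        raise ValueError(
            f"{name} series in {d} has {arr.shape[-1]} volumes but the "
            f"protocol declares {n_expected}")


def _fit_relaxometry_maps(d: Path, prot: AcquisitionProtocol):
    """Fit T1, CE-T1, T2 and ADC maps for one subject/timepoint directory."""
    labels = load_label_map(d / "labels.nii.gz")
    vfa, _ = load_nifti(d / "vfa.nii.gz")
    vfa_ce, _ = load_nifti(d / "vfa_ce.nii.gz")
    me, _ = load_nifti(d / "multiecho.nii.gz")
    dwi, _ = load_nifti(d / "dwi.nii.gz")
    _check_series("vfa", vfa, len(prot.flip_angles_deg), d)
    _check_series("vfa_ce", vfa_ce, len(prot.flip_angles_deg), d)
    _check_series("multiecho", me, len(prot.echo_times_ms), d)
    _check_series("dwi", dwi, len(prot.b_values), d)

    tissue = labels.labels > 0
    t1_map, _ = relaxometry.fit_t1_vfa(
        SignalStack(vfa, prot.flip_angles_deg), prot.tr_ms, mask=tissue)
    ce_t1_map, _ = relaxometry.fit_t1_vfa(
        SignalStack(vfa_ce, prot.flip_angles_deg), prot.tr_ms, mask=tissue)
    t2_map, _ = relaxometry.fit_t2(SignalStack(me, prot.echo_times_ms), mask=tissue)
    adc_map = relaxometry.fit_adc(SignalStack(dwi, prot.b_values), mask=tissue)
    maps = {"t1": t1_map, "ce_t1": ce_t1_map, "t2": t2_map, "adc": adc_map}
    return labels, maps


def _convert_dce(d: Path, prot: AcquisitionProtocol, t1_map):
    """Convert the dynamic series of one directory to concentration."""
    dyn_frames, _ = load_nifti(d / "dce.nii.gz")
    _check_series("dce", dyn_frames, prot.n_frames, d)
    dyn = dce.DynamicSeries(dyn_frames, prot.frame_times_s, prot.n_pre_frames, prot)
    baseline, _sd = dce.estimate_baseline(dyn)
    conc, valid = dce.signal_to_concentration(dyn, baseline, t1_map.values, prot,
                                              mask=t1_map.validity_mask)
    return dyn, conc, valid


def _analyze_one(d: Path, prot: AcquisitionProtocol, config: RunConfig):
    """Fit all maps and metrics for one subject/timepoint directory."""
    labels, maps = _fit_relaxometry_maps(d, prot)
    t1_map, ce_t1_map, t2_map, adc_map = (maps["t1"], maps["ce_t1"],
                                          maps["t2"], maps["adc"])
    ratio_map = dce.t1_ratio(ce_t1_map, t1_map)
    maps["t1_ratio"] = ratio_map
    dyn, conc, valid = _convert_dce(d, prot, t1_map)

    if config.pixelwise_maps:
        maps["auc30"] = dce.voxelwise_auc_map(conc, valid, dyn, 30.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # 300 s window truncates by design
            maps["auc300"] = dce.voxelwise_auc_map(conc, valid, dyn, 300.0)
        for name, pmap in maps.items():
            save_nifti(pmap.values, d / f"map_{name}.nii.gz", labels.voxel_size_mm)

    rows = []
    curves = []
    metric_maps = {"T1": t1_map, "CE_T1": ce_t1_map, "T2": t2_map,
                   "ADC": adc_map, "T1_ratio": ratio_map}
    for roi in ("brain", "intracranial_tumor", "extracranial_tumor"):
        roi_mask = labels.roi_mask(roi)
        for metric, pmap in metric_maps.items():
            mean, sd, n = cohort.roi_summary(pmap, labels, roi)
            rows.append(dict(roi=roi, metric=metric, value=mean, n_voxels=n, sd=sd))
        curve = dce.roi_mean_curve(conc, valid, dyn, roi_mask, roi)
        for metric, window in (("AUC30", 30.0), ("AUC300", 300.0)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # 300 s window truncates by design
                value = dce.auc(curve, window)
            rows.append(dict(roi=roi, metric=metric, value=value,
                             n_voxels=int(roi_mask.sum()), sd=float("nan")))
        curves.append(pd.DataFrame({"time_s": curve.times_s, "conc_mM": curve.conc_mM,
                                    "roi": roi}))
    pd.concat(curves, ignore_index=True).to_csv(d / "roi_curves.csv", index=False)
    return rows


def run_analyze(config: RunConfig, dataset_dir=None) -> Path:
    """Analyse a simulated (or equivalently laid-out real) dataset.

    Fits all parameter maps, writes them beside the inputs, emits the
    long-format ROI table and the paired-comparison table, and a markdown
    report.  Returns the dataset directory.
    """
    out = Path(dataset_dir if dataset_dir is not None else config.out_dir)
    prot = AcquisitionProtocol.from_yaml(out / "protocol.yaml")
    all_rows = []
    subject_dirs = sorted(out.glob("sub-*"))
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories under {out}")
    for sub_dir in subject_dirs:
        for tp_dir in sorted(sub_dir.glob("tp-*")):
            tp = tp_dir.name.split("-", 1)[1]
            for row in _analyze_one(tp_dir, prot, config):
                row.update(subject=sub_dir.name.split("-", 1)[1], timepoint=tp)
                all_rows.append(row)
    table = pd.DataFrame(all_rows)[["subject", "roi", "timepoint", "metric",
                                    "value", "n_voxels", "sd"]]
    table.to_csv(out / "roi_table.csv", index=False)
    run_stats(config, out)
    _write_report(out, table)
    return out


def _iter_timepoint_dirs(out: Path):
    subject_dirs = sorted(out.glob("sub-*"))
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories under {out}")
    for sub_dir in subject_dirs:
        yield from sorted(sub_dir.glob("tp-*"))


def run_relaxometry(config: RunConfig, dataset_dir=None) -> Path:
    """Fit and write only the relaxometry maps (T1, CE-T1, T2, ADC)."""
    out = Path(dataset_dir if dataset_dir is not None else config.out_dir)
    prot = AcquisitionProtocol.from_yaml(out / "protocol.yaml")
    for d in _iter_timepoint_dirs(out):
        labels, maps = _fit_relaxometry_maps(d, prot)
        for name, pmap in maps.items():
            save_nifti(pmap.values, d / f"map_{name}.nii.gz", labels.voxel_size_mm)
    return out


def run_dce(config: RunConfig, dataset_dir=None) -> Path:
    """Run only the perfusion stage: AUC30/AUC300/T1-ratio maps and curves."""
    out = Path(dataset_dir if dataset_dir is not None else config.out_dir)
    prot = AcquisitionProtocol.from_yaml(out / "protocol.yaml")
    for d in _iter_timepoint_dirs(out):
        labels, maps = _fit_relaxometry_maps(d, prot)
        dyn, conc, valid = _convert_dce(d, prot, maps["t1"])
        out_maps = {"t1_ratio": dce.t1_ratio(maps["ce_t1"], maps["t1"]),
                    "auc30": dce.voxelwise_auc_map(conc, valid, dyn, 30.0)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out_maps["auc300"] = dce.voxelwise_auc_map(conc, valid, dyn, 300.0)
        for name, pmap in out_maps.items():
            save_nifti(pmap.values, d / f"map_{name}.nii.gz", labels.voxel_size_mm)
        curves = []
        for roi in ("brain", "intracranial_tumor", "extracranial_tumor"):
            curve = dce.roi_mean_curve(conc, valid, dyn, labels.roi_mask(roi), roi)
            curves.append(pd.DataFrame({"time_s": curve.times_s,
                                        "conc_mM": curve.conc_mM, "roi": roi}))
        pd.concat(curves, ignore_index=True).to_csv(d / "roi_curves.csv", index=False)
    return out


def run_stats(config: RunConfig, dataset_dir=None) -> Path:
    """Longitudinal statistics over an existing ROI table."""
    out = Path(dataset_dir if dataset_dir is not None else config.out_dir)
    table = pd.read_csv(out / "roi_table.csv")
    present = [tp for tp in cohort.TIMEPOINTS if tp in set(table["timepoint"])]
    if set(config.timepoints) - set(present):
        logger.warning("missing timepoints %s; comparisons restricted to %s",
                       sorted(set(config.timepoints) - set(present)), present)
    _, comparisons = cohort.assemble_longitudinal(table, alpha=config.alpha)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    return out / "comparisons.csv"


def run_histology(config: RunConfig, n_fields: int = 3, n_cells_total: int = 1000) -> Path:
    """Simulate and quantify post-treatment histology per lesion type.

    Three x200 fields per marker and lesion; necrosis, pooled Ki67/CD31
    positive rates, and mean CD31 vessel area are written to
    ``histology_results.csv``.
    """
    out = Path(config.out_dir) / "histology"
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence([config.seed, 1234]).spawn(len(HISTOLOGY_PRESETS) * 2)
    rows = []
    i = 0
    for lesion, preset in HISTOLOGY_PRESETS.items():
        for marker in ("Ki67", "CD31"):
            vessels = (40.0, 80.0, 120.0) if marker == "CD31" else ()
            fields = simulate_histology_fields(
                n_fields, n_cells_total, preset[marker], preset["necrosis"],
                vessel_areas_um2=vessels, seed=ss[i])
            i += 1
            for k, f in enumerate(fields):
                save_histology_field(f, out / f"{lesion}_{marker}_field{k}.png")
            res = histoquant.quantify_fields(fields, marker=marker)
            rows.append(dict(
                lesion=lesion, marker=marker,
                positive_rate_pct=res.positive_rate_pct,
                necrosis_fraction_pct=res.necrosis_fraction_pct,
                mean_vessel_area_um2=res.mean_vessel_area_um2,
                n_cells=res.n_cells_total, n_vessels=res.n_vessels,
                n_fields=res.n_fields))
    df = pd.DataFrame(rows)
    df.to_csv(out / "histology_results.csv", index=False)
    return out / "histology_results.csv"


def _write_report(out: Path, table: pd.DataFrame) -> None:
    """Markdown report: per-metric ROI means by timepoint plus map montages."""
    lines = ["# Phantom cohort analysis report", ""]
    summary = (table.groupby(["metric", "roi", "timepoint"])["value"]
               .mean().reset_index())
    for metric in sorted(summary["metric"].unique()):
        lines.append(f"## {metric}")
        piv = summary[summary["metric"] == metric].pivot(index="roi", columns="timepoint",
                                                         values="value")
        piv = piv[[c for c in ("pre", "1h", "8h", "24h") if c in piv.columns]]
        lines.append("```\n" + piv.to_string(float_format=lambda v: f"{v:.4g}") + "\n```")
        lines.append("")
    montage = _map_montage(out)
    if montage is not None:
        lines.append(f"![parameter maps]({montage.name})")
    (out / "report.md").write_text("\n".join(lines))


def _map_montage(out: Path):
    """Central-slice montage of the first subject's fitted maps."""
    first = sorted(out.glob("sub-*/tp-*/map_t1.nii.gz"))
    if not first:
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tp_dir = first[0].parent
    names = ["t1", "ce_t1", "t1_ratio", "t2", "adc", "auc30"]
    fig, axes = plt.subplots(2, 3, figsize=(10, 6))
    for ax, name in zip(axes.ravel(), names):
        path = tp_dir / f"map_{name}.nii.gz"
        if path.exists():
            vol, _ = load_nifti(path)
            sl = vol[..., vol.shape[2] // 2]
            im = ax.imshow(sl.T, origin="lower", cmap="viridis")
            fig.colorbar(im, ax=ax, fraction=0.046)
        ax.set_title(name)
        ax.axis("off")
    fig.tight_layout()
    path = out / "map_montage.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
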