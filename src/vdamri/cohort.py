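"""ROI summarisation and longitudinal cohort statistics.

Each subject carries three ROIs (contralateral brain as control,
intracranial tumor, extracranial tumor) imaged at four timepoints (pre,
1 h, 8 h, 24 h after treatment).  Differences are tested intraindividually:
Shapiro-Wilk on the paired differences, then a two-sided paired t-test.
When normality fails (p < 0.05) the t result is still reported with a
non-normality flag and a Wilcoxon signed-rank p is added as a sensitivity
column.  Raw p-values are the primary output (two-sided, alpha 0.05); a
Holm-adjusted column is emitted for transparency but not used for flags.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .phantom.geometry import PhantomLabelMap
from .relaxometry import ParameterMap

__all__ = [
    "TIMEPOINTS",
    "METRICS",
    "PairedComparisonResult",
    "roi_summary",
    "split_roi_periphery",
    "paired_compare",
    "assemble_longitudinal",
    "simulate_cohort_table",
    "null_calibration",
]

logger = logging.getLogger(__name__)

TIMEPOINTS = ("pre", "1h", "8h", "24h")
METRICS = ("AUC30", "AUC300", "T1", "CE_T1", "T1_ratio", "T2", "ADC")


@dataclass
class PairedComparisonResult:
    """Outcome of one intraindividual paired comparison."""

    metric: str
    group_a: str
    group_b: str
    n: int
    mean_a: float
    mean_b: float
    normality_p: float
    statistic: float
    p_value: float
    test_used: str = "paired_t"
    normality_flag: bool = False
    wilcoxon_p: float = float("nan")


def roi_summary(pmap: ParameterMap, labels: PhantomLabelMap, roi):
    """Mean, SD and voxel count of a parameter map over one ROI.

    Only voxels valid in the map contribute; raises when the ROI is empty
    or contains no valid voxels.
    """
    mask = labels.roi_mask(roi)
    if pmap.shape != mask.shape:
        raise ValueError("map and label grid shapes differ")
    if not mask.any():
        raise ValueError(f"ROI {roi!r} is empty")
    sel = mask & pmap.validity_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI {roi!r} has no valid voxels")
    vals = pmap.values[sel]
    return float(vals.mean()), float(vals.std(ddof=0)), n


def split_roi_periphery(labels: PhantomLabelMap, roi, rim_width_voxels: int = 1):
    """Split a ROI into a core and a peripheral rim.

    The core is the morphological erosion of the ROI by ``rim_width_voxels``
    (3-D 6-connected structuring element applied iteratively); the rim is
    the ROI minus its core.  Raises when the erosion empties the core.
    """
    if rim_width_voxels < 1:
        raise ValueError("rim_width_voxels must be >= 1")
    mask = labels.roi_mask(roi)
    if not mask.any():
        raise ValueError(f"ROI {roi!r} is empty")
    core = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1),
        iterations=rim_width_voxels,
    )
    if not core.any():
        raise ValueError("rim width erodes the entire ROI; no core remains")
    rim = mask & ~core
    return core, rim


def paired_compare(values_a, values_b, alpha: float = 0.05,
                   metric: str = "", group_a: str = "a", group_b: str = "b"
                   ) -> PairedComparisonResult:
    """Intraindividual paired comparison of two matched vectors.

    Records Shapiro-Wilk normality of the paired differences, then the
    two-sided paired t-test ``t = mean(d) / (sd(d)/sqrt(n))`` with n-1 df.
    Degenerate cases: identical vectors give t = 0, p = 1; zero-variance
    differences with nonzero mean give the limit t = +/-inf, p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("at least 3 pairs are required")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired values must be finite")
    d = a - b
    n = d.size

    if np.ptp(d) == 0:
        norm_p = float("nan")
        flag = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm_p = float(stats.shapiro(d).pvalue)
        flag = norm_p < alpha

    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = float(np.inf) if d.mean() > 0 else float(-np.inf)
            p = 0.0
    else:
        t_stat = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))

    wilcoxon_p = float("nan")
    if flag and np.ptp(d) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                wilcoxon_p = float(stats.wilcoxon(a, b).pvalue)
            except ValueError:
                pass

    return PairedComparisonResult(
        metric=metric, group_a=group_a, group_b=group_b, n=n,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        normality_p=norm_p, statistic=t_stat, p_value=p,
        test_used="paired_t", normality_flag=flag, wilcoxon_p=wilcoxon_p,
    )


_TABLE_COLUMNS = ["subject", "roi", "timepoint", "metric", "value", "n_voxels", "sd"]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"ROI table lacks columns: {sorted(missing)}")
    bad_tp = set(table["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    dup = table.duplicated(subset=["subject", "roi", "timepoint", "metric"])
    if dup.any():
        raise ValueError("ROI table has duplicate (subject, roi, timepoint, metric) rows")
    return table


def _paired_from_pivot(wide: pd.DataFrame, col_a: str, col_b: str, metric: str,
                       name_a: str, name_b: str, alpha: float):
    sub = wide[[col_a, col_b]].dropna()
    dropped = len(wide) - len(sub)
    if dropped:
        logger.warning("%s vs %s (%s): %d subject(s) dropped for missing data",
                       name_a, name_b, metric, dropped)
    if len(sub) < 3:
        logger.warning("%s vs %s (%s): only %d pair(s); test skipped",
                       name_a, name_b, metric, len(sub))
        return None
    return paired_compare(sub[col_a].to_numpy(), sub[col_b].to_numpy(),
                          alpha=alpha, metric=metric, group_a=name_a, group_b=name_b)


def assemble_longitudinal(table: pd.DataFrame, alpha: float = 0.05):
    """Assemble the longitudinal ROI table and its paired comparisons.

    Parameters
    ----------
    table : DataFrame
        Long format with columns ``subject, roi, timepoint, metric, value,
        n_voxels, sd`` (one row per key).

    Returns
    -------
    (table, comparisons) : (DataFrame, DataFrame)
        The validated long table (sorted) and one row per comparison:
        intracranial vs extracranial tumor at each timepoint, and each
        post-treatment timepoint vs pre within each ROI, for every metric.
        A Holm-adjusted p column is appended across all comparisons.
    """
    table = _validate_table(table.copy())
    table = table.sort_values(["metric", "roi", "timepoint", "subject"]).reset_index(drop=True)
    results = []
    for metric in sorted(table["metric"].unique()):
        t_m = table[table["metric"] == metric]
        # lesion contrast at each timepoint
        wide_roi = t_m.pivot_table(index=["subject", "timepoint"], columns="roi",
                                   values="value", aggfunc="first").reset_index()
        for tp in [tp for tp in TIMEPOINTS if tp in set(t_m["timepoint"])]:
            w = wide_roi[wide_roi["timepoint"] == tp]
            if {"intracranial_tumor", "extracranial_tumor"} <= set(w.columns):
                res = _paired_from_pivot(
                    w, "intracranial_tumor", "extracranial_tumor", metric,
                    f"intracranial@{tp}", f"extracranial@{tp}", alpha)
                if res:
                    results.append(res)
        # within-ROI contrast of each post-treatment timepoint vs pre
        wide_tp = t_m.pivot_table(index=["subject", "roi"], columns="timepoint",
                                  values="value", aggfunc="first").reset_index()
        for roi in sorted(t_m["roi"].unique()):
            w = wide_tp[wide_tp["roi"] == roi]
            for tp in ("1h", "8h", "24h"):
                if "pre" in w.columns and tp in w.columns:
                    res = _paired_from_pivot(w, tp, "pre", metric,
                                             f"{roi}@{tp}", f"{roi}@pre", alpha)
                    if res:
                        results.append(res)
    columns = [f.name for f in dataclasses.fields(PairedComparisonResult)]
    comp = pd.DataFrame([vars(r) for r in results], columns=columns)
    if len(comp):
        from statsmodels.stats.multitest import multipletests

        comp["p_holm"] = multipletests(comp["p_value"].fillna(1.0), method="holm")[1]
    else:
        comp["p_holm"] = pd.Series(dtype=float)
    return table, comp


def simulate_cohort_table(n_subjects: int = 15, seed: int | None = 0,
                          between_sd: float = 0.05, within_sd: float = 0.02
                          ) -> pd.DataFrame:
    """Simulate a long-format ROI table around the preset means.

    Each subject carries a multiplicative random effect (log-normal,
    ``between_sd``) per ROI/metric that persists across timepoints, plus
    independent measurement noise (``within_sd``), mimicking the
    intraindividual design of a 15-animal cohort.
    """
    from .phantom.presets import get_preset

    rng = np.random.default_rng(seed)
    rows = []
    metric_of = {
        "AUC30": lambda r: r.auc30_true,
        "AUC300": lambda r: r.auc300_true,
        "T1": lambda r: r.t1_ms,
        "CE_T1": lambda r: r.ce_t1_ms,
        "T1_ratio": lambda r: r.t1_ratio_true,
        "T2": lambda r: r.t2_ms,
        "ADC": lambda r: r.adc_mm2_per_s,
    }
    for s in range(n_subjects):
        subj_effect = {}
        for tp in TIMEPOINTS:
            records = get_preset(tp)
            for roi, rec in records.items():
                for metric, getter in metric_of.items():
                    key = (roi, metric)
                    if key not in subj_effect:
                        subj_effect[key] = rng.lognormal(0.0, between_sd)
                    value = getter(rec) * subj_effect[key] * rng.lognormal(0.0, within_sd)
                    rows.append(dict(subject=f"S{s:02d}", roi=roi, timepoint=tp,
                                     metric=metric, value=value, n_voxels=100,
                                     sd=abs(value) * within_sd))
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def null_calibration(n_reps: int = 10000, n_pairs: int = 15, alpha: float = 0.05,
                     seed: int | None = 7):
    """Type-I calibration of ``paired_compare`` under a simulated null.

    Draws matched normal pairs with no true difference, runs the paired
    comparison per replicate, and returns ``(rejection_rate, p_values)``.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_reps)
    for i in range(n_reps):
        base = rng.normal(0.0, 1.0, size=n_pairs)
        a = base + rng.normal(0.0, 0.5, size=n_pairs)
        b = base + rng.normal(0.0, 0.5, size=n_pairs)
        pvals[i] = paired_compare(a, b, alpha=alpha).p_value
    return float(np.mean(pvals < alpha)), pvals
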