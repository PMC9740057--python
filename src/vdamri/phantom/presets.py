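"""Ground-truth presets and the tissue concentration-curve model.

The contrast-agent tissue curve is a gamma-variate,

    C(t) = A * t^k * exp(-t / b),  t > 0  (mmol/L),

chosen because it rises smoothly from zero, washes out exponentially, and
has the closed-form running integral

    int_0^T C dt = A * b^(k+1) * Gamma(k+1) * P(k+1, T/b),

with P the regularised lower incomplete gamma function — an exact oracle
for the trapezoidal AUC computed by the analysis stage.  Each perfusion
preset stores the initial areas under the curve over the first 30 s (AUC30,
a perfusion surrogate) and 300 s (AUC300, perfusion plus retention), both
in mmol/L*min by convention; the curve's time-scale b is solved by 1-D
root-finding so the AUC300/AUC30 ratio matches, after which the amplitude
follows in closed form.

Preset states describe the rat-head phantom at the four imaging timepoints
(pre-treatment and 1 h / 8 h / 24 h after a vascular-disrupting agent),
with per-ROI T1, post-contrast (CE) T1, T2, ADC and perfusion values.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammainc

__all__ = [
    "GammaVariateParams",
    "GroundTruthRecord",
    "tissue_concentration_curve",
    "curve_integral",
    "solve_gamma_variate",
    "ROI_LABELS",
    "PRESET_NAMES",
    "get_preset",
    "ground_truth_to_json",
    "ground_truth_from_json",
]

#: integer label -> ROI name for the phantom label map
ROI_LABELS = {0: "background", 1: "brain", 2: "intracranial_tumor", 3: "extracranial_tumor"}


@dataclass(frozen=True)
class GammaVariateParams:
    """Parameters of the gamma-variate tissue curve.

    amplitude : scale factor A (mmol/L per s^shape); 0 gives a flat curve
    shape     : dimensionless rise exponent k (> 0)
    scale_s   : washout time constant b in seconds (> 0)
    """

    amplitude: float
    shape: float = 2.0
    scale_s: float = 10.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.shape <= 0 or self.scale_s <= 0:
            raise ValueError("shape and scale_s must be positive")


def tissue_concentration_curve(params: GammaVariateParams, times_s) -> np.ndarray:
    """Evaluate C(t) in mmol/L at nonnegative times (s) since injection."""
    t = np.asarray(times_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative (t=0 at injection)")
    with np.errstate(invalid="ignore"):
        c = params.amplitude * np.power(t, params.shape) * np.exp(-t / params.scale_s)
    return np.where(t > 0, c, 0.0)


def curve_integral(params: GammaVariateParams, t_s: float) -> float:
    """Closed-form integral of C over (0, t_s] in mmol/L*s."""
    a1 = params.shape + 1.0
    return (
        params.amplitude
        * params.scale_s**a1
        * math.gamma(a1)
        * float(gammainc(a1, t_s / params.scale_s))
    )


def solve_gamma_variate(
    auc30_min: float, auc300_min: float, shape: float = 2.0
) -> GammaVariateParams:
    """Solve (amplitude, scale) so the closed-form integrals over (0, 30] s
    and (0, 300] s equal the given targets (mmol/L*min).

    The AUC300/AUC30 ratio is independent of amplitude and strictly
    increasing in the time-scale, so the scale is found by bracketing
    root-finding and the amplitude then follows linearly.
    """
    if auc30_min < 0 or auc300_min < 0:
        raise ValueError("AUC targets must be nonnegative")
    if auc30_min == 0:
        if auc300_min != 0:
            raise ValueError("AUC30 = 0 requires AUC300 = 0 for a causal bolus curve")
        return GammaVariateParams(0.0, shape, 10.0)
    ratio = auc300_min / auc30_min
    a1 = shape + 1.0
    if ratio <= 1.0:
        raise ValueError("AUC300 must exceed AUC30 for a nonnegative curve")
    if ratio >= 10.0**a1:
        raise ValueError("AUC300/AUC30 ratio not reachable by a gamma-variate of this shape")

    def f(scale):
        return gammainc(a1, 300.0 / scale) / gammainc(a1, 30.0 / scale) - ratio

    scale = brentq(f, 1e-3, 5e3, xtol=1e-12, rtol=1e-14)
    base = GammaVariateParams(1.0, shape, scale)
    amplitude = 60.0 * auc30_min / curve_integral(base, 30.0)
    return GammaVariateParams(amplitude, shape, scale)


@dataclass(frozen=True)
class GroundTruthRecord:
    """True tissue parameters for one ROI of one phantom state."""

    roi_label: str
    t1_ms: float
    t2_ms: float
    adc_mm2_per_s: float
    ce_t1_ms: float
    curve_params: GammaVariateParams
    auc30_true: float
    auc300_true: float
    m0: float = 1000.0

    def __post_init__(self):
        if not (self.t1_ms > self.t2_ms > 0):
            raise ValueError("expected t1_ms > t2_ms > 0")
        if self.adc_mm2_per_s <= 0:
            raise ValueError("adc must be positive")
        if not (self.auc300_true >= self.auc30_true >= 0):
            raise ValueError("expected auc300_true >= auc30_true >= 0")
        if self.ce_t1_ms > self.t1_ms:
            raise ValueError("post-contrast T1 cannot exceed pre-contrast T1")
        if self.ce_t1_ms <= 0:
            raise ValueError("ce_t1_ms must be positive")

    @property
    def t1_ratio_true(self) -> float:
        """True post-contrast over pre-contrast T1 quotient."""
        return self.ce_t1_ms / self.t1_ms


def _record(roi, t1, t2, adc, ce_t1, auc30, auc300):
    params = solve_gamma_variate(auc30, auc300)
    return GroundTruthRecord(
        roi_label=roi,
        t1_ms=t1,
        t2_ms=t2,
        adc_mm2_per_s=adc,
        ce_t1_ms=ce_t1,
        curve_params=params,
        auc30_true=auc30,
        auc300_true=auc300,
    )


# Pre-contrast T1 values derived from the printed CE-T1 and the printed
# pre-treatment T1 ratios (extracranial 786.1 / 0.429, intracranial
# 1020.9 / 0.497); post-treatment CE-T1 set so the true ratio equals the
# corresponding printed ratio.  ADC and the contralateral-brain control
# values are literature-typical choices (see docs/methods.md).
_EX_T1_PRE = 786.1 / 0.429
_IN_T1_PRE = 1020.9 / 0.497

# brain control: constant over all timepoints (intact BBB, low leakage)
_BRAIN = dict(t1=1600.0, t2=90.0, adc=0.75e-3, ce_t1=1400.0, auc30=0.012, auc300=0.035)


def _brain_record():
    return _record("brain", _BRAIN["t1"], _BRAIN["t2"], _BRAIN["adc"], _BRAIN["ce_t1"],
                   _BRAIN["auc30"], _BRAIN["auc300"])


_STATES = {
    "pre": {
        "brain": _brain_record(),
        "intracranial_tumor": _record(
            "intracranial_tumor", _IN_T1_PRE, 111.5, 0.70e-3, 1020.9, 0.058, 0.063
        ),
        "extracranial_tumor": _record(
            "extracranial_tumor", _EX_T1_PRE, 128.2, 0.90e-3, 786.1, 0.067, 0.193
        ),
    },
    "1h": {
        "brain": _brain_record(),
        "intracranial_tumor": _record(
            "intracranial_tumor", _IN_T1_PRE, 112.0, 0.72e-3, 0.625 * _IN_T1_PRE, 0.049, 0.055
        ),
        "extracranial_tumor": _record(
            "extracranial_tumor", 1950.0, 132.0, 1.00e-3, 0.429 * 1950.0, 0.008, 0.030
        ),
    },
    "8h": {
        "brain": _brain_record(),
        "intracranial_tumor": _record(
            "intracranial_tumor", _IN_T1_PRE, 112.5, 0.75e-3, 0.60 * _IN_T1_PRE, 0.056, 0.062
        ),
        "extracranial_tumor": _record(
            "extracranial_tumor", 2000.0, 140.0, 1.10e-3, 0.55 * 2000.0, 0.007, 0.028
        ),
    },
    "24h": {
        "brain": _brain_record(),
        "intracranial_tumor": _record(
            "intracranial_tumor", _IN_T1_PRE, 112.0, 0.76e-3, 0.58 * _IN_T1_PRE, 0.057, 0.063
        ),
        "extracranial_tumor": _record(
            "extracranial_tumor", 2000.0, 142.0, 1.15e-3, 0.58 * 2000.0, 0.012, 0.045
        ),
    },
}

# the same phantom state can be requested under the lesion-centric aliases
_ALIASES = {}
for _tp in _STATES:
    _ALIASES[_tp] = _tp
    _ALIASES[f"extracranial_{_tp}"] = _tp
    _ALIASES[f"intracranial_{_tp}"] = _tp

PRESET_NAMES = tuple(sorted(_ALIASES))


def get_preset(name: str) -> dict:
    """Return the map ROI name -> GroundTruthRecord for a preset state.

    Accepts timepoint names ("pre", "1h", "8h", "24h") and lesion-centric
    aliases such as "extracranial_pre" or "intracranial_1h".
    """
    if name not in _ALIASES:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    return dict(_STATES[_ALIASES[name]])


# -- serialization ---------------------------------------------------------


def ground_truth_to_json(records: dict, path) -> None:
    """Write a map ROI name -> GroundTruthRecord to JSON."""
    payload = {}
    for roi, rec in records.items():
        d = dataclasses.asdict(rec)
        d["curve_params"] = dataclasses.asdict(rec.curve_params)
        payload[roi] = d
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def ground_truth_from_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for roi, d in payload.items():
        d = dict(d)
        d["curve_params"] = GammaVariateParams(**d["curve_params"])
        out[roi] = GroundTruthRecord(**d)
    return out
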