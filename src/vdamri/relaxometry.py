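"""Voxel-wise relaxometry: T1 from variable-flip-angle SPGR, T2 from
multi-echo decay, and the apparent diffusion coefficient from multi-b DWI.

All fitters are vectorised over the spatial grid.  The VFA fit uses the
classical linearisation of the spoiled-gradient-echo equation

    S(a) = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),   E1 = exp(-TR/T1),

in which S/sin(a) regressed on S/tan(a) has slope E1, followed by an
optional damped Gauss-Newton refinement of (T1, M0) on the nonlinear model
(the linearised estimator is noise-biased; the refinement removes that bias
while keeping the linear result as a start).  T2 and ADC come from weighted
log-linear regression, excluding nonpositive samples point-wise rather than
clamping them, since clamping biases the slope.

Physical plausibility gates mark divergent voxels invalid instead of letting
them pollute ROI means: T1 in (1, 10000) ms, T2 in (1, 2000) ms,
ADC in (0, 1e-2) mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalStack",
    "ParameterMap",
    "fit_t1_vfa",
    "fit_t2",
    "fit_adc",
    "T1_GATE_MS",
    "T2_GATE_MS",
    "ADC_GATE",
]

T1_GATE_MS = (1.0, 10000.0)
T2_GATE_MS = (1.0, 2000.0)
ADC_GATE = (0.0, 1.0e-2)


@dataclass
class SignalStack:
    """A stack of volumes acquired while one acquisition variable sweeps.

    ``volumes`` has shape spatial + (n,), with the acquisition axis last;
    ``axis_values`` holds the per-volume variable (flip angle in degrees,
    TE in ms, or b in s/mm^2) and must be strictly increasing.
    """

    volumes: np.ndarray
    axis_values: np.ndarray
    axis_name: str = ""
    units: str = ""

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        if self.volumes.shape[-1] != self.axis_values.size:
            raise ValueError("axis_values length must equal the number of volumes")
        if self.axis_values.size >= 2 and np.any(np.diff(self.axis_values) <= 0):
            raise ValueError("axis_values must be strictly increasing")

    @property
    def spatial_shape(self) -> tuple:
        return self.volumes.shape[:-1]


@dataclass
class ParameterMap:
    """A scalar map plus the voxels on which the producing fit succeeded."""

    values: np.ndarray
    units: str
    validity_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.values.shape != self.validity_mask.shape:
            raise ValueError("values and validity_mask must share a shape")
        if np.any(~np.isfinite(self.values[self.validity_mask])):
            raise ValueError("values must be finite wherever validity_mask is True")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def _as_mask(mask, shape):
    if mask is None:
        return np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match the spatial grid")
    return mask


def _weighted_loglinear(signals, x, mask):
    """Per-voxel weighted OLS of ln(S) on x; nonpositive samples get zero
    weight, positive samples weight S^2 (var(ln S) ~ sigma^2/S^2, so this is
    the statistically correct weighting for the log-linearised exponential).

    Returns slope, intercept, and the count of usable samples per voxel.
    """
    w = np.where(signals > 0, signals * signals, 0.0)
    w *= mask[..., None]
    logs = np.where(signals > 0, np.log(np.where(signals > 0, signals, 1.0)), 0.0)
    sw = w.sum(axis=-1)
    swx = (w * x).sum(axis=-1)
    swy = (w * logs).sum(axis=-1)
    swxx = (w * x * x).sum(axis=-1)
    swxy = (w * x * logs).sum(axis=-1)
    denom = sw * swxx - swx * swx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * swxy - swx * swy) / denom
        intercept = (swy - slope * swx) / sw
    n_used = (w > 0).sum(axis=-1)
    ok = (n_used >= 2) & (denom > 0)
    return slope, intercept, n_used, ok


def _spgr(t1_ms, m0, sin_a, cos_a, tr_ms):
    e1 = np.exp(-tr_ms / t1_ms)
    return m0[..., None] * sin_a * (1.0 - e1[..., None]) / (1.0 - e1[..., None] * cos_a)


def _vfa_refine(signals, sin_a, cos_a, tr_ms, t1, m0, ok, n_iter=30):
    """Damped Gauss-Newton polish of (T1, M0) per voxel on the SPGR model."""
    t1 = t1.copy()
    m0 = m0.copy()
    active = ok.copy()
    lam = np.full(t1.shape, 1e-3)

    def sse(t1v, m0v):
        r = _spgr(t1v, m0v, sin_a, cos_a, tr_ms) - signals
        return (r * r).sum(axis=-1)

    cur = np.where(active, sse(np.where(active, t1, 1.0), m0), 0.0)
    for _ in range(n_iter):
        if not active.any():
            break
        t1a = np.where(active, t1, 1000.0)
        e1 = np.exp(-tr_ms / t1a)[..., None]
        denom = 1.0 - e1 * cos_a
        model = m0[..., None] * sin_a * (1.0 - e1) / denom
        r = model - signals
        # dS/dM0 and dS/dT1 (through E1)
        j_m0 = sin_a * (1.0 - e1) / denom
        ds_de1 = m0[..., None] * sin_a * (cos_a - 1.0) / (denom * denom)
        de1_dt1 = (e1[..., 0] * tr_ms / (t1a * t1a))[..., None]
        j_t1 = ds_de1 * de1_dt1
        a11 = (j_t1 * j_t1).sum(axis=-1)
        a12 = (j_t1 * j_m0).sum(axis=-1)
        a22 = (j_m0 * j_m0).sum(axis=-1)
        g1 = (j_t1 * r).sum(axis=-1)
        g2 = (j_m0 * r).sum(axis=-1)
        d11 = a11 * (1.0 + lam)
        d22 = a22 * (1.0 + lam)
        det = d11 * d22 - a12 * a12
        with np.errstate(divide="ignore", invalid="ignore"):
            step_t1 = -(d22 * g1 - a12 * g2) / det
            step_m0 = -(-a12 * g1 + d11 * g2) / det
        solvable = active & np.isfinite(step_t1) & np.isfinite(step_m0) & (det != 0)
        t1_new = np.where(solvable, np.clip(t1 + step_t1, 1.0, 1e5), t1)
        m0_new = np.where(solvable, np.maximum(m0 + step_m0, 1e-12), m0)
        new = np.where(solvable, sse(np.where(solvable, t1_new, 1.0), m0_new), cur)
        improved = solvable & (new < cur)
        t1 = np.where(improved, t1_new, t1)
        m0 = np.where(improved, m0_new, m0)
        lam = np.where(improved, lam * 0.3, lam * 4.0)
        converged = improved & (cur - new <= 1e-12 * (cur + 1e-30))
        cur = np.where(improved, new, cur)
        active = active & ~converged & (lam < 1e8)
    return t1, m0


def fit_t1_vfa(stack: SignalStack, tr_ms: float, mask=None, refine: bool = True):
    """Fit T1 and M0 from a variable-flip-angle SPGR stack.

    Parameters
    ----------
    stack : SignalStack
        Signals with flip angle (degrees) on the acquisition axis.
    tr_ms : float
        Repetition time of the sequence (ms).
    mask : ndarray of bool, optional
        Voxels to fit; defaults to the full grid.
    refine : bool
        Run the nonlinear polish after the linearised fit (default True).

    Returns
    -------
    (t1_map, m0_map) : tuple of ParameterMap
        T1 in ms and M0 in arbitrary signal units.  Voxels whose linearised
        slope E1 falls outside (0, 1), or whose T1 leaves the plausibility
        gate, are marked invalid.
    """
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    angles = stack.axis_values
    if angles.size < 2:
        raise ValueError("at least two flip angles are required")
    if np.any(angles <= 0) or np.any(angles >= 90):
        raise ValueError("flip angles must lie in (0, 90) degrees")
    mask = _as_mask(mask, stack.spatial_shape)
    signals = stack.volumes
    if np.any(signals[mask] < 0):
        raise ValueError("signals must be nonnegative")

    rad = np.deg2rad(angles)
    sin_a, cos_a, tan_a = np.sin(rad), np.cos(rad), np.tan(rad)
    y = signals / sin_a
    x = signals / tan_a
    n = angles.size
    sx = x.sum(axis=-1)
    sy = y.sum(axis=-1)
    sxx = (x * x).sum(axis=-1)
    sxy = (x * y).sum(axis=-1)
    denom = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (n * sxy - sx * sy) / denom
        intercept = (sy - e1 * sx) / n
        t1 = -tr_ms / np.log(e1)
        m0 = intercept / (1.0 - e1)

    ok = (
        mask
        & (denom > 0)
        & (e1 > 0)
        & (e1 < 1)
        & np.isfinite(t1)
        & (t1 > T1_GATE_MS[0])
        & (t1 < T1_GATE_MS[1])
        & np.isfinite(m0)
        & (m0 > 0)
    )
    t1 = np.where(ok, t1, np.nan)
    m0 = np.where(ok, m0, np.nan)

    if refine and ok.any():
        t1r, m0r = _vfa_refine(
            signals, sin_a, cos_a, tr_ms, np.where(ok, t1, 1000.0), np.where(ok, m0, 1.0), ok
        )
        t1 = np.where(ok, t1r, np.nan)
        m0 = np.where(ok, m0r, np.nan)
        gate = ok & (t1 > T1_GATE_MS[0]) & (t1 < T1_GATE_MS[1])
        t1 = np.where(gate, t1, np.nan)
        m0 = np.where(gate, m0, np.nan)
        ok = gate

    prov = {"model": "spgr_vfa", "tr_ms": tr_ms, "refined": bool(refine)}
    return (
        ParameterMap(np.where(ok, t1, 0.0), "ms", ok, prov),
        ParameterMap(np.where(ok, m0, 0.0), "unitless", ok, dict(prov)),
    )


def fit_t2(stack: SignalStack, mask=None):
    """Fit T2 and S0 from a multi-echo stack by weighted log-linear regression.

    Nonpositive samples are dropped voxel-wise; voxels with fewer than two
    usable echoes, or with T2 outside the plausibility gate, are invalid.
    """
    te = stack.axis_values
    if te.size < 2:
        raise ValueError("at least two echo times are required")
    mask = _as_mask(mask, stack.spatial_shape)
    slope, intercept, _, ok = _weighted_loglinear(stack.volumes, te, mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = -1.0 / slope
        s0 = np.exp(intercept)
    ok = ok & np.isfinite(t2) & (t2 > T2_GATE_MS[0]) & (t2 < T2_GATE_MS[1]) & np.isfinite(s0)
    prov = {"model": "monoexp_t2"}
    return (
        ParameterMap(np.where(ok, t2, 0.0), "ms", ok, prov),
        ParameterMap(np.where(ok, s0, 0.0), "unitless", ok, dict(prov)),
    )


def fit_adc(stack: SignalStack, mask=None) -> ParameterMap:
    """Fit the apparent diffusion coefficient (mm^2/s) from a multi-b stack.

    Log-linear slope of ln(S) on b; a constant signal yields ADC = 0, which
    is kept valid (zero slope is physical at the noise floor).
    """
    b = stack.axis_values
    if b.size < 2:
        raise ValueError("at least two b-values are required")
    mask = _as_mask(mask, stack.spatial_shape)
    slope, _, _, ok = _weighted_loglinear(stack.volumes, b, mask)
    adc = -slope
    # snap float roundoff on constant signals to an exact zero slope
    adc = np.where(np.abs(adc) < 1e-12, 0.0, adc)
    ok = ok & np.isfinite(adc) & (adc >= ADC_GATE[0]) & (adc < ADC_GATE[1])
    return ParameterMap(np.where(ok, adc, 0.0), "mm^2/s", ok, {"model": "monoexp_adc"})
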