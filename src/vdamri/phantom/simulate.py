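"""Forward simulation of the MRI acquisitions from ground-truth maps.

Signal models:

* VFA / DCE readout — spoiled gradient echo (SPGR),
  ``S = M0 sin(a) (1 - E1)/(1 - E1 cos(a))`` with ``E1 = exp(-TR/T1)``;
  during contrast passage ``R1(t) = 1/T10 + r1 C(t)``.
* multi-echo — mono-exponential ``S = S0 exp(-TE/T2)``.
* DWI — mono-exponential ``S = S0 exp(-b ADC)``.

Noise is Rician on the magnitude image (independent Gaussian noise of equal
standard deviation on two quadrature channels); a plain Gaussian option is
kept for debugging.  All randomness flows through a caller-supplied seed.
"""

from __future__ import annotations

import numpy as np

from ..dce import DynamicSeries
from ..protocol import AcquisitionProtocol
from ..relaxometry import SignalStack
from .geometry import PhantomLabelMap
from .presets import tissue_concentration_curve

__all__ = [
    "spgr_signal",
    "add_noise",
    "simulate_vfa_series",
    "simulate_multiecho_series",
    "simulate_dwi_series",
    "simulate_dce_series",
]


def spgr_signal(t1_ms, m0, flip_deg, tr_ms):
    """Spoiled-gradient-echo magnitude signal (broadcasts over inputs)."""
    if np.any(np.asarray(tr_ms) <= 0):
        raise ValueError("TR must be positive")
    flip = np.asarray(flip_deg, dtype=float)
    if np.any(flip <= 0) or np.any(flip >= 90):
        raise ValueError("flip angle must lie in (0, 90) degrees")
    rad = np.deg2rad(flip)
    e1 = np.exp(-np.asarray(tr_ms, dtype=float) / np.asarray(t1_ms, dtype=float))
    return m0 * np.sin(rad) * (1.0 - e1) / (1.0 - e1 * np.cos(rad))


def add_noise(signal, sd, rng, model: str = "rician"):
    """Apply magnitude noise; ``sd`` is the per-channel Gaussian sigma."""
    if sd < 0:
        raise ValueError("noise sd must be nonnegative")
    if sd == 0:
        return np.asarray(signal, dtype=float)
    if model == "rician":
        re = signal + rng.normal(0.0, sd, size=np.shape(signal))
        im = rng.normal(0.0, sd, size=np.shape(signal))
        return np.hypot(re, im)
    if model == "gaussian":
        return signal + rng.normal(0.0, sd, size=np.shape(signal))
    raise ValueError(f"unknown noise model {model!r}")


def _check_maps(par_map, m0_map):
    par_map = np.asarray(par_map, dtype=float)
    m0_map = np.asarray(m0_map, dtype=float)
    if par_map.shape != m0_map.shape:
        raise ValueError("parameter and M0 maps must share a shape")
    if np.any(par_map[m0_map > 0] <= 0):
        raise ValueError("relaxation/diffusion values must be positive wherever M0 > 0")
    return par_map, m0_map


def simulate_vfa_series(t1_map, m0_map, protocol: AcquisitionProtocol,
                        noise_sd: float = 0.0, seed: int | None = None) -> SignalStack:
    """Simulate the variable-flip-angle SPGR stack (one volume per angle)."""
    t1_map, m0_map = _check_maps(t1_map, m0_map)
    angles = np.asarray(protocol.flip_angles_deg)
    safe_t1 = np.where(t1_map > 0, t1_map, 1.0)
    sig = spgr_signal(safe_t1[..., None], m0_map[..., None], angles, protocol.tr_ms)
    sig = add_noise(sig, noise_sd, np.random.default_rng(seed))
    return SignalStack(sig, angles, axis_name="flip_angle", units="deg")


def simulate_multiecho_series(t2_map, s0_map, protocol: AcquisitionProtocol,
                              noise_sd: float = 0.0, seed: int | None = None) -> SignalStack:
    """Simulate the multi-echo T2 decay stack (one volume per TE)."""
    t2_map, s0_map = _check_maps(t2_map, s0_map)
    te = np.asarray(protocol.echo_times_ms)
    safe_t2 = np.where(t2_map > 0, t2_map, 1.0)
    sig = s0_map[..., None] * np.exp(-te / safe_t2[..., None])
    sig = add_noise(sig, noise_sd, np.random.default_rng(seed))
    return SignalStack(sig, te, axis_name="echo_time", units="ms")


def simulate_dwi_series(adc_map, s0_map, b_values,
                        noise_sd: float = 0.0, seed: int | None = None) -> SignalStack:
    """Simulate the diffusion-weighted stack (one volume per b-value)."""
    adc_map = np.asarray(adc_map, dtype=float)
    s0_map = np.asarray(s0_map, dtype=float)
    if adc_map.shape != s0_map.shape:
        raise ValueError("ADC and S0 maps must share a shape")
    b = np.asarray(b_values, dtype=float)
    sig = s0_map[..., None] * np.exp(-b * adc_map[..., None])
    sig = add_noise(sig, noise_sd, np.random.default_rng(seed))
    return SignalStack(sig, b, axis_name="b_value", units="s/mm^2")


def simulate_dce_series(label_map: PhantomLabelMap, ground_truth: dict,
                        protocol: AcquisitionProtocol, noise_sd: float = 0.0,
                        seed: int | None = None) -> DynamicSeries:
    """Simulate the 100-frame dynamic contrast-enhanced series.

    Every nonzero ROI follows the SPGR signal of a time-varying
    ``R1(t) = 1/T10 + r1 C(t)`` with its preset gamma-variate curve;
    pre-injection frames sit at the T10 baseline.  Background voxels have
    zero proton density and stay at zero signal (plus noise, if any).
    """
    times = protocol.frame_times_s
    shape = label_map.labels.shape
    frames = np.zeros(shape + (times.size,))
    for lab, name in label_map.label_names.items():
        if lab == 0:
            continue
        if name not in ground_truth:
            raise KeyError(f"missing ground-truth record for ROI {name!r}")
        rec = ground_truth[name]
        conc = tissue_concentration_curve(rec.curve_params, np.maximum(times, 0.0))
        r1_t = 1.0 / (rec.t1_ms / 1000.0) + protocol.r1_relaxivity * conc  # 1/s
        t1_t_ms = 1000.0 / r1_t
        sig = spgr_signal(t1_t_ms, rec.m0, protocol.dce_flip_angle_deg, protocol.dce_tr_ms)
        frames[label_map.labels == lab] = sig
    frames = add_noise(frames, noise_sd, np.random.default_rng(seed))
    return DynamicSeries(frames, times, protocol.n_pre_frames, protocol)
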