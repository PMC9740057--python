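"""Acquisition protocol: the sequence, timing and contrast constants shared
by the phantom simulator and every fitting stage.

The defaults describe a small-animal multiparametric session on a 3 T
clinical magnet: a 9-angle variable-flip-angle (VFA) spoiled-gradient-echo
T1 measurement, a 24-echo T2 measurement, a two-point diffusion measurement,
and a dynamic contrast-enhanced (DCE) run of 20 pre-contrast plus 80
post-contrast frames at 3.6 s temporal resolution with 0.1 mmol/kg Gd-DOTA.
Counts and values are configurable; monotonicity and positivity are
enforced, not the counts themselves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["AcquisitionProtocol", "default_echo_times_ms"]


def default_echo_times_ms(n: int = 24, te_min: float = 10.0, te_max: float = 240.0) -> tuple:
    """Evenly spaced echo times in milliseconds."""
    return tuple(float(t) for t in np.linspace(te_min, te_max, n))


@dataclass(frozen=True)
class AcquisitionProtocol:
    """All sequence/timing/contrast constants governing simulation and fitting.

    Parameters
    ----------
    tr_ms : float
        Repetition time of the VFA spoiled gradient echo (ms).
    flip_angles_deg : tuple of float
        VFA excitation angles in degrees, strictly increasing, in (0, 90).
    echo_times_ms : tuple of float
        Echo times of the multi-echo T2 sequence (ms), strictly increasing.
    b_values : tuple of float
        Diffusion weightings (s/mm^2), strictly increasing, first usually 0.
    n_pre_frames, n_post_frames : int
        DCE frames acquired before / after contrast injection.
    frame_dt_s : float
        DCE temporal resolution (s per frame).
    r1_relaxivity : float
        Longitudinal relaxivity of the contrast agent (L mmol^-1 s^-1);
        default 3.5, typical of Gd-DOTA at 3 T.
    ca_dose_mmol_per_kg : float
        Injected contrast dose (mmol/kg body weight).
    dce_tr_ms, dce_flip_angle_deg : float
        TR and excitation angle of the dynamic spoiled-gradient-echo readout,
        needed to invert signal to concentration.
    """

    tr_ms: float = 15.0
    flip_angles_deg: tuple = (2.0, 3.0, 4.0, 5.0, 7.0, 9.0, 12.0, 15.0, 20.0)
    echo_times_ms: tuple = field(default_factory=default_echo_times_ms)
    b_values: tuple = (0.0, 1000.0)
    n_pre_frames: int = 20
    n_post_frames: int = 80
    frame_dt_s: float = 3.6
    r1_relaxivity: float = 3.5
    ca_dose_mmol_per_kg: float = 0.1
    dce_tr_ms: float = 15.0
    dce_flip_angle_deg: float = 15.0

    def __post_init__(self):
        object.__setattr__(self, "flip_angles_deg", tuple(float(a) for a in self.flip_angles_deg))
        object.__setattr__(self, "echo_times_ms", tuple(float(t) for t in self.echo_times_ms))
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        fa = np.asarray(self.flip_angles_deg)
        if fa.size < 2 or np.any(fa <= 0) or np.any(fa >= 90) or np.any(np.diff(fa) <= 0):
            raise ValueError("flip angles must be >=2 values, strictly increasing, in (0, 90) deg")
        te = np.asarray(self.echo_times_ms)
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be >=2 positive, strictly increasing values")
        bv = np.asarray(self.b_values)
        if bv.size < 2 or np.any(bv < 0) or np.any(np.diff(bv) <= 0):
            raise ValueError("b-values must be >=2 nonnegative, strictly increasing values")
        if self.tr_ms <= 0 or self.dce_tr_ms <= 0:
            raise ValueError("TR must be positive")
        if not (0 < self.dce_flip_angle_deg < 90):
            raise ValueError("DCE flip angle must lie in (0, 90) deg")
        if self.n_pre_frames < 1 or self.n_post_frames < 1:
            raise ValueError("frame counts must be positive")
        if self.frame_dt_s <= 0:
            raise ValueError("frame_dt_s must be positive")
        if self.r1_relaxivity <= 0:
            raise ValueError("r1_relaxivity must be positive")
        if self.ca_dose_mmol_per_kg <= 0:
            raise ValueError("ca_dose_mmol_per_kg must be positive")

    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + self.n_post_frames

    @property
    def frame_times_s(self) -> np.ndarray:
        """Mid-frame times relative to injection at the start of the first
        post-contrast frame; pre-contrast frames carry negative times."""
        idx = np.arange(self.n_frames)
        return (idx - self.n_pre_frames) * self.frame_dt_s + 0.5 * self.frame_dt_s

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("flip_angles_deg", "echo_times_ms", "b_values"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
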