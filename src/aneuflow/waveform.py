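"""Periodic inlet flow-rate waveforms.

Patient flow measurements report only a cycle-mean volumetric flow (mL/min)
and a heart rate (bpm); the waveform shape itself is modeled as a truncated
Fourier series.  The default ``"ica"`` preset is a single-systolic-peak shape
typical of the internal carotid artery, with a peak/mean ratio of about 1.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import WaveformError

__all__ = ["InletWaveform", "make_inlet_waveform", "SHAPE_PRESETS"]

#: Relative cosine-harmonic amplitudes, all phase-aligned to peak at t = 0.15 T.
#: Q(t)/Q_mean = 1 + sum_k c_k cos(2 pi k (t - 0.15 T) / T).
SHAPE_PRESETS: dict[str, tuple[float, ...]] = {
    "ica": (0.40, 0.25, 0.12, 0.05),
    "steady": (),
}

_PEAK_TIME_FRACTION = 0.15


@dataclass(frozen=True)
class InletWaveform:
    """Periodic inlet flow rate Q(t) with Q in mL/min.

    Invariants: T = 60 / heart_rate exactly; Q(t) > 0 for all t; the cycle
    mean of Q equals ``q_mean`` (exact for a Fourier shape).
    """

    q_mean: float                      # cycle-mean flow, mL/min
    heart_rate: float                  # bpm
    coefficients: tuple[float, ...]    # relative harmonic amplitudes
    n_samples: int = 200
    times: np.ndarray = field(init=False, repr=False)
    q: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        t = np.linspace(0.0, self.period, self.n_samples + 1)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "q", self.flow_rate(t))

    @property
    def period(self) -> float:
        """Heart-beat duration T = 60 / heart rate, s."""
        return 60.0 / self.heart_rate

    def flow_rate(self, t) -> np.ndarray:
        """Q(t) in mL/min at arbitrary times (periodic extension)."""
        t = np.asarray(t, dtype=float)
        theta = 2 * np.pi * (t / self.period - _PEAK_TIME_FRACTION)
        shape = np.ones_like(theta)
        for k, c in enumerate(self.coefficients, start=1):
            shape = shape + c * np.cos(k * theta)
        return self.q_mean * shape

    def flow_rate_si(self, t) -> np.ndarray:
        """Q(t) in m^3/s."""
        return self.flow_rate(t) * (1e-6 / 60.0)

    @property
    def peak_to_mean(self) -> float:
        t = np.linspace(0, self.period, 2001)
        return float(self.flow_rate(t).max() / self.q_mean)


def make_inlet_waveform(
    q_mean: float,
    heart_rate: float,
    shape: str | tuple[float, ...] = "ica",
    n_samples: int = 200,
) -> InletWaveform:
    """Build a positive periodic inlet waveform.

    Parameters
    ----------
    q_mean : cycle-mean flow in mL/min (> 0)
    heart_rate : bpm (> 0); the period is T = 60 / heart_rate
    shape : preset name ("ica", "steady") or explicit relative harmonic
        amplitudes; all coefficients zero gives constant Q = q_mean
    n_samples : number of tabulated samples per cycle
    """
    if q_mean <= 0:
        raise WaveformError(f"q_mean must be positive, got {q_mean}")
    if heart_rate <= 0:
        raise WaveformError(f"heart_rate must be positive, got {heart_rate}")
    if isinstance(shape, str):
        try:
            coeffs = SHAPE_PRESETS[shape]
        except KeyError:
            raise WaveformError(
                f"unknown shape preset {shape!r}; choose from "
                f"{sorted(SHAPE_PRESETS)}") from None
    else:
        coeffs = tuple(float(c) for c in shape)
    wf = InletWaveform(q_mean=float(q_mean), heart_rate=float(heart_rate),
                       coefficients=coeffs, n_samples=int(n_samples))
    tt = np.linspace(0, wf.period, 4001)
    qq = wf.flow_rate(tt)
    if np.any(qq <= 0):
        t_bad = tt[int(np.argmin(qq))]
        raise WaveformError(
            f"shape produces non-positive flow Q({t_bad:.4f} s) = "
            f"{qq.min():.4g} mL/min"
        )
    return wf
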