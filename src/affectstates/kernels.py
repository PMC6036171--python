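"""Hemodynamic and electrodermal response kernels.

Both kernels are represented by :class:`Kernel`: a causal, peak-normalised
impulse (or block) response sampled on a regular grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Kernel", "hrf_kernel", "scr_canonical"]


@dataclass(frozen=True)
class Kernel:
    """A sampled response kernel.

    Attributes
    ----------
    times
        Sample times in seconds, starting at 0, step ``dt``.
    values
        Kernel values, peak-normalised so ``max(values) == 1``.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel values must be finite")
        peak = float(np.max(self.values))
        if abs(peak - 1.0) > 1e-9:
            raise ValueError("kernel must be peak-normalised")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum, in seconds."""
        return float(self.times[int(np.argmax(self.values))])

    def convolve(self, signal: np.ndarray) -> np.ndarray:
        """Causal convolution, truncated to ``len(signal)`` samples."""
        return np.convolve(signal, self.values)[: len(signal)]


def _gamma_variate(t: np.ndarray) -> np.ndarray:
    # h(t) = (t/4)^4 exp(4 - t): unit peak at t = 4 s.
    h = np.zeros_like(t)
    pos = t >= 0
    h[pos] = (t[pos] / 4.0) ** 4 * np.exp(4.0 - t[pos])
    return h


def hrf_kernel(dt: float = 0.1, duration: float = 32.0,
               stim_duration: float = 2.0) -> Kernel:
    """Block hemodynamic response: gamma variate convolved with a boxcar.

    The impulse response is the gamma variate ``(t/4)^4 exp(4 - t)``; the
    event response for a stimulus of length ``stim_duration`` (default: the
    2-s image presentation) is its convolution with the corresponding
    boxcar, peak-normalised to 1.

    Parameters
    ----------
    dt
        Sampling step, seconds.
    duration
        Kernel support, seconds. The response is negligible (< 1e-4 of
        peak) beyond ~25 s.
    stim_duration
        Boxcar width, seconds. ``0`` gives the pure impulse response.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    h = _gamma_variate(t)
    if stim_duration > 0:
        width = max(int(round(stim_duration / dt)), 1)
        h = np.convolve(h, np.ones(width))[: len(t)]
    h /= h.max()
    return Kernel(times=t, values=h)


def scr_canonical(dt: float = 0.1, duration: float = 30.0,
                  tau_decay: float = 3.0, tau_rise: float = 0.75) -> Kernel:
    """Canonical skin-conductance response (bi-exponential).

    ``g(t) = exp(-t/tau_decay) - exp(-t/tau_rise)``, peak-normalised.
    With the defaults the peak sits at ``ln(tau_d/tau_r)/(1/tau_r -
    1/tau_d)`` ~= 1.39 s; the response is effectively over within ~20 s.
    The time constants are configurable because published canonical SCR
    shapes vary across acquisition setups.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau_decay <= tau_rise:
        raise ValueError("tau_decay must exceed tau_rise")
    t = np.arange(0.0, duration + dt / 2, dt)
    g = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    g[t < 0] = 0.0
    g /= g.max()
    return Kernel(times=t, values=g)


def scr_peak_latency(tau_decay: float = 3.0, tau_rise: float = 0.75) -> float:
    """Closed-form peak latency of the bi-exponential SCR, seconds."""
    return float(np.log(tau_decay / tau_rise) / (1.0 / tau_rise - 1.0 / tau_decay))
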