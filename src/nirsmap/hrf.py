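"""Canonical haemodynamic response modelling.

The vascular response to a sustained cognitive task is modelled as the
convolution of a task boxcar with a canonical impulse response built from
two gamma densities: a positive response lobe peaking a few seconds after
stimulus onset and a delayed, smaller undershoot.  This is the standard
double-gamma parameterization used throughout task-fNIRS and fMRI analysis;
the exact shape constants are exposed so they can be overridden from
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HRFParams", "canonical_hrf", "make_boxcar", "task_response"]


@dataclass(frozen=True)
class HRFParams:
    """Shape constants of the double-gamma impulse response.

    With unit scale parameters a gamma density of shape ``a`` peaks at
    ``a - 1`` seconds, so the defaults put the response peak at 6 s and
    the undershoot at 16 s; the undershoot is scaled by
    ``undershoot_ratio`` relative to the positive lobe.
    """

    peak_shape: float = 7.0
    peak_scale: float = 1.0
    undershoot_shape: float = 17.0
    undershoot_scale: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.peak_shape <= 1 or self.undershoot_shape <= 1:
            raise ValueError("gamma shape parameters must exceed 1 so h(0) = 0")
        if self.peak_scale <= 0 or self.undershoot_scale <= 0:
            raise ValueError("gamma scale parameters must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be nonnegative")


def canonical_hrf(time_grid, params: HRFParams = HRFParams()) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF on ``time_grid`` (seconds).

    The curve is the difference of two gamma densities and is rescaled so
    its maximum on the supplied grid equals 1.  ``time_grid`` must be
    nonempty, nonnegative and strictly increasing.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0:
        raise ValueError("time_grid is empty")
    if np.any(t < 0):
        raise ValueError("time_grid must be nonnegative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")

    h = stats.gamma.pdf(t, params.peak_shape, scale=params.peak_scale)
    h = h - params.undershoot_ratio * stats.gamma.pdf(
        t, params.undershoot_shape, scale=params.undershoot_scale
    )
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def make_boxcar(task_duration_s: float, rest_duration_s: float, fs: float) -> np.ndarray:
    """Stimulus indicator for one trial: 1 during the task, 0 during rest.

    The series has ``floor((task + rest) * fs)`` samples of which the first
    ``floor(task * fs)`` are ones.
    """
    if task_duration_s <= 0 or rest_duration_s <= 0:
        raise ValueError("durations must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    n_total = int(np.floor((task_duration_s + rest_duration_s) * fs))
    n_task = int(np.floor(task_duration_s * fs))
    box = np.zeros(n_total)
    box[:n_task] = 1.0
    return box


def task_response(
    fs: float,
    task_duration_s: float = 60.0,
    rest_duration_s: float = 30.0,
    params: HRFParams = HRFParams(),
    kernel_duration_s: float = 32.0,
) -> np.ndarray:
    """Expected trial response: boxcar convolved with the canonical HRF.

    Returns the first ``floor((task + rest) * fs)`` samples of the
    convolution, rescaled to unit peak.  This same curve serves both as the
    generative response shape of the synthetic cohorts and as the design
    regressor of the activation GLM.
    """
    box = make_boxcar(task_duration_s, rest_duration_s, fs)
    t_kernel = np.arange(int(np.floor(kernel_duration_s * fs))) / fs
    kernel = canonical_hrf(t_kernel, params)
    resp = np.convolve(box, kernel)[: box.size]
    peak = np.abs(resp).max()
    if peak > 0:
        resp = resp / peak
    return resp
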