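"""Canonical hemodynamic response function and task regressors.

The HRF is the canonical double-gamma: a positive gamma density peaking at
``peak_s`` minus a scaled gamma density peaking at ``undershoot_s``, sampled
at the acquisition rate and normalized to unit peak, so a GLM beta against a
peak-normalized regressor is expressed in signal units (uM of HbO).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .errors import InvalidParameterError
from .protocol import TaskDesign


@dataclass(frozen=True)
class HrfParams:
    peak_s: float = 6.0
    undershoot_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_s <= 0 or self.undershoot_s <= self.peak_s:
            raise InvalidParameterError("require 0 < peak_s < undershoot_s")


def double_gamma_hrf(sampling_rate: float, params: HrfParams | None = None) -> np.ndarray:
    """Sampled canonical HRF, unit peak amplitude."""
    p = params or HrfParams()
    t = np.arange(0.0, p.duration_s, 1.0 / sampling_rate)
    # Gamma pdf with scale 1 and shape a peaks at a-1: place peaks directly.
    h = gamma_dist.pdf(t, a=p.peak_s + 1.0) - p.undershoot_ratio * gamma_dist.pdf(
        t, a=p.undershoot_s + 1.0
    )
    return h / np.max(h)


def condition_boxcar(design: TaskDesign, label: str) -> np.ndarray:
    """0/1 indicator of the condition's blocks at the design's sampling rate."""
    return design.sample_mask(label).astype(float)


def condition_regressor(
    design: TaskDesign,
    label: str,
    hrf_params: HrfParams | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, truncated to record length.

    With ``normalize`` the column is scaled to unit peak; the synthetic
    forward model and the GLM design matrix share this exact construction so
    planted amplitudes are recovered as fitted betas.
    """
    box = condition_boxcar(design, label)
    h = double_gamma_hrf(design.sampling_rate, hrf_params)
    reg = np.convolve(box, h)[: design.n_samples]
    if normalize:
        peak = np.max(np.abs(reg))
        if peak == 0:
            raise InvalidParameterError(f"condition {label!r} has no samples")
        reg = reg / peak
    return reg
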