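"""Canonical hemodynamic response and event-regressor construction.

Both the simulator and the GLM build predicted time courses the same way:
stimulus boxcars convolved with a peak-normalized double-gamma response on
a fine time grid, then sampled at the sparse acquisition times.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = ["canonical_hrf", "sample_event_regressor"]

# Double-gamma parameterization (SPM-style): response peak ~5-6 s,
# undershoot ~16 s, undershoot ratio 1/6.
_PEAK_DELAY_S = 6.0
_UNDERSHOOT_DELAY_S = 16.0
_PEAK_DISP_S = 1.0
_UNDERSHOOT_DISP_S = 1.0
_UNDERSHOOT_RATIO = 6.0


def canonical_hrf(
    t_s: np.ndarray | float,
    *,
    peak_delay_s: float = _PEAK_DELAY_S,
    undershoot_delay_s: float = _UNDERSHOOT_DELAY_S,
    peak_disp_s: float = _PEAK_DISP_S,
    undershoot_disp_s: float = _UNDERSHOOT_DISP_S,
    undershoot_ratio: float = _UNDERSHOOT_RATIO,
) -> np.ndarray:
    """Double-gamma impulse response, peak-normalized to 1.

    Zero for t < 0; the late undershoot is negative.
    """
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    peak = _gamma_dist.pdf(t, peak_delay_s / peak_disp_s, scale=peak_disp_s)
    under = _gamma_dist.pdf(t, undershoot_delay_s / undershoot_disp_s, scale=undershoot_disp_s)
    h = peak - under / undershoot_ratio
    h[t < 0] = 0.0
    # normalize by the analytic peak evaluated on a fine grid
    ref = np.linspace(0.0, 50.0, 5001)
    ref_h = _gamma_dist.pdf(ref, peak_delay_s / peak_disp_s, scale=peak_disp_s) - _gamma_dist.pdf(
        ref, undershoot_delay_s / undershoot_disp_s, scale=undershoot_disp_s
    ) / undershoot_ratio
    h = h / ref_h.max()
    if np.isscalar(t_s):
        return float(h[0])
    return h


def sample_event_regressor(
    onsets_s: np.ndarray,
    durations_s: np.ndarray,
    sample_times_s: np.ndarray,
    *,
    hrf=canonical_hrf,
    dt_s: float = 0.1,
    tail_s: float = 40.0,
) -> np.ndarray:
    """Boxcar-convolved HRF prediction sampled at arbitrary times.

    Builds a fine-grid boxcar for the events, convolves with ``hrf``, and
    linearly interpolates at ``sample_times_s``.  Returns zeros when no
    events are supplied.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    durations = np.broadcast_to(np.asarray(durations_s, dtype=float), onsets.shape)
    samples = np.asarray(sample_times_s, dtype=float)
    if onsets.size == 0:
        return np.zeros_like(samples)

    t_end = max(samples.max() if samples.size else 0.0, (onsets + durations).max()) + tail_s
    grid = np.arange(0.0, t_end + dt_s, dt_s)
    boxcar = np.zeros_like(grid)
    for onset, dur in zip(onsets, durations):
        lo = int(np.floor(onset / dt_s))
        hi = int(np.ceil((onset + dur) / dt_s))
        boxcar[lo : max(hi, lo + 1)] = 1.0

    kernel = hrf(np.arange(0.0, tail_s + dt_s, dt_s))
    predicted = np.convolve(boxcar, kernel)[: grid.size] * dt_s
    return np.interp(samples, grid, predicted)
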