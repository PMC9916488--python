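"""Micturition-cycle detection and per-cycle pressure metrics.

Per cycle the module reports the peak pressure P_max (highest raw P_ves in
the cycle), the micturition threshold P_thresh (pressure when the derivative
of the 0.1 s moving-average-smoothed trace first reaches 65 % of its maximum
within the 20 s before P_max) and the filling volume V_filling (infusion
rate x time from cycle start to threshold).  Recordings without micturition
cycles (the spinal-cord-injury phenotype) are normalised to their minimum
and summarised by the whole-recording P_max and the individual non-voiding
contraction peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .exceptions import DegenerateInputError, ValidationError
from .io import UDIRecording

__all__ = [
    "MicturitionCycle",
    "ContractionEvent",
    "smooth_pressure",
    "detect_cycles",
    "compute_pthresh",
    "compute_filling_volume",
    "normalize_no_cycle",
    "summarize_recording",
]


@dataclass
class ContractionEvent:
    """A single detrusor contraction (voiding or non-voiding)."""

    start_time_s: float
    end_time_s: float
    t_pmax_s: float
    pmax_cmH2O: float
    t_thresh_s: float | None = None
    pthresh_cmH2O: float | None = None
    flagged: bool = False  # threshold rule undefined (non-increasing window)

    def _check(self) -> None:
        if self.t_thresh_s is not None:
            if not self.start_time_s <= self.t_thresh_s <= self.t_pmax_s <= self.end_time_s:
                raise ValidationError("event times out of order")


@dataclass
class MicturitionCycle(ContractionEvent):
    """One filling + voiding event with its volume metrics."""

    v_filling_ul: float | None = None
    voided_volume_ul: float | None = None


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return x.astype(float, copy=True)
    n = x.size
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def smooth_pressure(recording: UDIRecording, window_s: float = 0.1) -> np.ndarray:
    """Moving average of the pressure channel over ``window_s`` seconds.

    The window length in samples is ``round(window_s * sampling_rate)``:
    50 samples at 500 Hz, 500 at 5000 Hz.
    """
    window = int(round(window_s * recording.sampling_rate_hz))
    if window < 1:
        raise DegenerateInputError("smoothing window shorter than one sample")
    if window > recording.n_samples:
        raise DegenerateInputError("smoothing window longer than the trace")
    return _moving_average(recording.pressure_cmH2O, window)


def compute_pthresh(
    time_s: np.ndarray,
    smoothed: np.ndarray,
    raw_pressure: np.ndarray,
    t_pmax_s: float,
    lookback_s: float = 20.0,
    fraction: float = 0.65,
) -> tuple[float, float] | None:
    """Threshold time/pressure by the 65 %-of-maximal-derivative rule.

    On the window ``[t_pmax - lookback_s, t_pmax]`` let ``d[i] =
    smoothed[i+1] - smoothed[i]`` and ``D = max d``; the threshold is the
    earliest sample with ``d >= fraction * D`` and P_thresh is the *raw*
    pressure there.  Returns ``None`` when the window never rises
    (``D <= 0``), flagging the cycle for exclusion.
    """
    i_peak = int(np.searchsorted(time_s, t_pmax_s, side="right")) - 1
    i_lo = int(np.searchsorted(time_s, t_pmax_s - lookback_s, side="left"))
    if i_peak - i_lo < 1:
        raise DegenerateInputError("fewer than 2 samples in the lookback window")
    diffs = np.diff(smoothed[i_lo : i_peak + 1])
    d_max = float(diffs.max())
    if d_max <= 0.0:
        return None
    i_thresh = i_lo + int(np.argmax(diffs >= fraction * d_max))
    return float(time_s[i_thresh]), float(raw_pressure[i_thresh])


def compute_filling_volume(
    start_time_s: float, t_thresh_s: float, infusion_rate_ul_min: float
) -> float:
    """Infused volume from cycle start to threshold (uL)."""
    interval = t_thresh_s - start_time_s
    if interval < 0:
        raise ValidationError("threshold precedes cycle start")
    return infusion_rate_ul_min / 60.0 * interval


def _voided_volume(recording: UDIRecording, t0: float, t1: float) -> float | None:
    if recording.volume_ul is None:
        return None
    i0 = int(np.searchsorted(recording.time_s, t0, side="left"))
    i1 = int(np.searchsorted(recording.time_s, t1, side="right")) - 1
    if i1 <= i0:
        return None
    return float(recording.volume_ul[i1] - recording.volume_ul[i0])


def detect_cycles(
    recording: UDIRecording,
    min_prominence_cmH2O: float = 5.0,
    min_interval_s: float = 10.0,
    window_s: float = 0.1,
    baseline_tolerance_cmH2O: float = 5.0,
    return_fraction: float = 0.1,
    lookback_s: float = 20.0,
    fraction: float = 0.65,
) -> list[MicturitionCycle]:
    """Segment a recording into micturition cycles.

    Peaks of the smoothed pressure with at least ``min_prominence_cmH2O``
    prominence and ``min_interval_s`` separation are candidate P_max events.
    A candidate becomes a cycle only if it rises from and returns to near
    baseline: its start (the pressure minimum since the previous cycle's
    end) must lie within ``baseline_tolerance_cmH2O`` of the recording-wide
    smoothed minimum, and the trace must come back to within
    ``return_fraction`` of the peak prominence above that start level before
    the next candidate.  Recordings with sustained high pressure (no
    baseline return) therefore yield an empty list.
    """
    smoothed = smooth_pressure(recording, window_s)
    fs = recording.sampling_rate_hz
    distance = max(1, int(round(min_interval_s * fs)))
    peaks, props = find_peaks(
        smoothed, prominence=min_prominence_cmH2O, distance=distance
    )
    baseline_level = float(smoothed.min())
    t = recording.time_s
    raw = recording.pressure_cmH2O
    cycles: list[MicturitionCycle] = []
    prev_end_idx = 0
    for peak, prom in zip(peaks, props["prominences"]):
        if peak <= prev_end_idx:
            continue
        seg = smoothed[prev_end_idx : peak + 1]
        start_idx = prev_end_idx + int(np.argmin(seg))
        start_level = float(smoothed[start_idx])
        if start_level > baseline_level + baseline_tolerance_cmH2O:
            continue  # contraction does not rise from baseline
        return_level = start_level + return_fraction * prom
        after = smoothed[peak:]
        below = np.flatnonzero(after <= return_level)
        if below.size == 0:
            continue  # never returns to baseline: incomplete or no-cycle
        end_idx = peak + int(below[0])

        t_pmax = float(t[peak])
        pmax = float(raw[start_idx : end_idx + 1].max())
        thresh = compute_pthresh(t, smoothed, raw, t_pmax, lookback_s, fraction)
        cycle = MicturitionCycle(
            start_time_s=float(t[start_idx]),
            end_time_s=float(t[end_idx]),
            t_pmax_s=t_pmax,
            pmax_cmH2O=pmax,
            flagged=thresh is None,
        )
        if thresh is not None:
            t_th, p_th = thresh
            cycle.t_thresh_s = max(t_th, cycle.start_time_s)
            cycle.pthresh_cmH2O = p_th
            cycle.v_filling_ul = compute_filling_volume(
                cycle.start_time_s, cycle.t_thresh_s, recording.infusion_rate_ul_min
            )
        cycle.voided_volume_ul = _voided_volume(
            recording, cycle.start_time_s, cycle.end_time_s
        )
        cycle._check()
        cycles.append(cycle)
        prev_end_idx = end_idx
    return cycles


def normalize_no_cycle(
    recording: UDIRecording,
    min_prominence_cmH2O: float = 5.0,
    min_interval_s: float = 2.0,
    window_s: float = 0.1,
    lookback_s: float = 20.0,
    fraction: float = 0.65,
) -> tuple[np.ndarray, float, list[ContractionEvent]]:
    """Summarise a recording without micturition cycles.

    The pressure channel is normalised to the lowest value of the entire
    recording; P_max is the highest normalised pressure.  Individual
    non-voiding contractions are the oscillation peaks of the smoothed
    normalised trace (same peak finder as :func:`detect_cycles` but without
    the baseline-return requirement).
    """
    raw = recording.pressure_cmH2O
    normalized = raw - float(raw.min())
    pmax = float(normalized.max())
    norm_rec = recording.copy(pressure_cmH2O=normalized)
    smoothed = smooth_pressure(norm_rec, window_s)
    fs = recording.sampling_rate_hz
    distance = max(1, int(round(min_interval_s * fs)))
    peaks, _ = find_peaks(smoothed, prominence=min_prominence_cmH2O, distance=distance)
    t = recording.time_s
    events: list[ContractionEvent] = []
    bounds = np.concatenate(([0], peaks, [t.size - 1]))
    for j, peak in enumerate(peaks):
        lo = bounds[j] + int(np.argmin(smoothed[bounds[j] : peak + 1]))
        hi = peak + int(np.argmin(smoothed[peak : bounds[j + 2] + 1]))
        thresh = compute_pthresh(t, smoothed, normalized, float(t[peak]),
                                 lookback_s, fraction)
        ev = ContractionEvent(
            start_time_s=float(t[lo]),
            end_time_s=float(t[hi]),
            t_pmax_s=float(t[peak]),
            pmax_cmH2O=float(normalized[lo : hi + 1].max()),
            flagged=thresh is None,
        )
        if thresh is not None:
            t_th, p_th = thresh
            ev.t_thresh_s = max(t_th, ev.start_time_s)
            ev.pthresh_cmH2O = p_th
        ev._check()
        events.append(ev)
    return normalized, pmax, events


def summarize_recording(
    cycles: Sequence[MicturitionCycle], n_cycles: int = 3
) -> dict:
    """Mean P_max / P_thresh / V_filling over the first ``n_cycles`` cycles.

    Fewer available cycles are averaged as-is and flagged via
    ``incomplete``; flagged cycles (undefined threshold) contribute only to
    the P_max mean.
    """
    if len(cycles) == 0:
        raise DegenerateInputError("no cycles to summarize")
    used = list(cycles[:n_cycles])
    pmax = float(np.mean([c.pmax_cmH2O for c in used]))
    thresh_vals = [c.pthresh_cmH2O for c in used if c.pthresh_cmH2O is not None]
    fill_vals = [c.v_filling_ul for c in used if c.v_filling_ul is not None]
    return {
        "n_cycles_used": len(used),
        "incomplete": len(used) < n_cycles,
        "pmax_cmH2O": pmax,
        "pthresh_cmH2O": float(np.mean(thresh_vals)) if thresh_vals else math.nan,
        "v_filling_ul": float(np.mean(fill_vals)) if fill_vals else math.nan,
    }
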