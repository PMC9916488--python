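"""External-urethral-sphincter EMG energy analysis.

The period from the micturition threshold (P_thresh) to the pressure peak
(P_max) is divided into five equal parts; the middle fifth is taken as
"during voiding", parts 1-2 as "before" and parts 4-5 as "after".  The
Hilbert-Huang marginal energy at 0-500 Hz is summed per section and
normalised to the section duration, and the three duration-normalised
energies are expressed as percentages.  A contraction shows *v-shape*
activity when the during-voiding section has strictly the lowest energy —
the signature of coordinated sphincter relaxation; dyssynergic sphincters
instead ramp up with pressure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .cystometry import ContractionEvent
from .emd import HilbertSpectrum, hilbert_huang
from .exceptions import DegenerateInputError, ValidationError
from .io import UDIRecording

__all__ = [
    "SectionEnergies",
    "preprocess_emg",
    "section_energies",
    "classify_vshape",
    "vshape_percentage",
    "mean_activity_pattern",
    "analyze_contractions",
]


@dataclass
class SectionEnergies:
    """Duration-normalised EMG energies around one voiding contraction."""

    e_before: float
    e_during: float
    e_after: float
    pct_before: float
    pct_during: float
    pct_after: float
    section_bounds_s: np.ndarray  # the 6 boundaries of the five-part partition

    def __post_init__(self) -> None:
        for e in (self.e_before, self.e_during, self.e_after):
            if e < 0:
                raise ValidationError("section energies must be nonnegative")
        if abs(self.pct_before + self.pct_during + self.pct_after - 100.0) > 1e-6:
            raise ValidationError("section percentages must sum to 100")

    @property
    def start_time_s(self) -> float:
        return float(self.section_bounds_s[0])


def preprocess_emg(
    recording: UDIRecording,
    band_hz: tuple[float, float] = (10.0, 10000.0),
    notch_hz: float | None = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase band-pass plus powerline notch, acquisition style.

    A requested band edge at or above the Nyquist frequency is clipped just
    below it (with a warning), e.g. the 10-10000 Hz acquisition band becomes
    10-2250 Hz at a 5 kHz sampling rate.
    """
    if recording.emg_v is None:
        raise DegenerateInputError("recording has no EMG channel")
    fs = recording.sampling_rate_hz
    lo, hi = band_hz
    nyq = fs / 2.0
    if hi >= nyq:
        hi = 0.9 * nyq
        warnings.warn(
            f"band upper edge clipped to {hi:g} Hz (Nyquist {nyq:g} Hz)",
            stacklevel=2,
        )
    if not 0 < lo < hi:
        raise ValidationError("band must satisfy 0 < low < high < Nyquist")
    sos = _sig.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    out = _sig.sosfiltfilt(sos, recording.emg_v)
    if notch_hz:
        b, a = _sig.iirnotch(notch_hz, notch_q, fs=fs)
        out = _sig.filtfilt(b, a, out)
    return out


def section_energies(
    spectrum: HilbertSpectrum,
    t_thresh_s: float,
    t_pmax_s: float,
    n_parts: int = 5,
    band_hz: tuple[float, float] = (0.0, 500.0),
) -> SectionEnergies:
    """Before/during/after EMG energies on the five-part partition.

    The energy of a section is the squared instantaneous amplitude,
    integrated over the samples whose instantaneous frequency falls in
    ``band_hz``, summed over all IMFs and divided by the section duration
    (energy per second, independent of the sampling rate).
    """
    if not t_thresh_s < t_pmax_s:
        raise ValidationError("need t_thresh < t_pmax")
    if n_parts != 5:
        raise ValidationError("the partition is defined with five parts")
    bounds = np.linspace(t_thresh_s, t_pmax_s, n_parts + 1)
    t = spectrum.time_s
    if t_thresh_s < t[0] - 1e-9 or t_pmax_s > t[-1] + 1e-9:
        raise DegenerateInputError("spectrum does not cover the analysis window")

    amp2 = spectrum.inst_amplitude**2
    in_band = (spectrum.inst_frequency_hz >= band_hz[0]) & (
        spectrum.inst_frequency_hz < band_hz[1]
    )
    power = (amp2 * in_band).sum(axis=0) / spectrum.sampling_rate_hz

    def _energy(lo: float, hi: float) -> float:
        mask = (t >= lo) & (t < hi)
        return float(power[mask].sum()) / (hi - lo)

    e_before = _energy(bounds[0], bounds[2])
    e_during = _energy(bounds[2], bounds[3])
    e_after = _energy(bounds[3], bounds[5])
    total = e_before + e_during + e_after
    if total <= 0.0:
        raise DegenerateInputError("zero EMG energy in all sections")
    return SectionEnergies(
        e_before=e_before,
        e_during=e_during,
        e_after=e_after,
        pct_before=100.0 * e_before / total,
        pct_during=100.0 * e_during / total,
        pct_after=100.0 * e_after / total,
        section_bounds_s=bounds,
    )


def classify_vshape(section: SectionEnergies) -> bool:
    """True iff the during-voiding energy is strictly the lowest of the three."""
    return (
        section.e_during < section.e_before and section.e_during < section.e_after
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def vshape_percentage(
    contractions: Sequence[SectionEnergies],
    min_contractions: int = 5,
    window_s: float = 600.0,
) -> int | None:
    """Percentage of analyzable contractions with v-shape activity.

    Only contractions starting within the first ``window_s`` seconds count;
    animals with fewer than ``min_contractions`` analyzable contractions are
    excluded (``None``).  The percentage is rounded half-up to an integer.
    """
    inside = [c for c in contractions if c.start_time_s <= window_s]
    if len(inside) < min_contractions:
        return None
    n_v = sum(classify_vshape(c) for c in inside)
    return _round_half_up(100.0 * n_v / len(inside))


def mean_activity_pattern(
    contractions: Sequence[SectionEnergies],
) -> tuple[tuple[float, float, float], bool]:
    """Mean percentage triple across contractions and its v-shape verdict."""
    if len(contractions) == 0:
        raise DegenerateInputError("no contractions to average")
    mb = float(np.mean([c.pct_before for c in contractions]))
    md = float(np.mean([c.pct_during for c in contractions]))
    ma = float(np.mean([c.pct_after for c in contractions]))
    return (mb, md, ma), (md < mb and md < ma)


def analyze_contractions(
    recording: UDIRecording,
    events: Sequence[ContractionEvent],
    band_hz: tuple[float, float] = (0.0, 500.0),
    preprocess_band_hz: tuple[float, float] = (10.0, 10000.0),
    notch_hz: float | None = 50.0,
    pad_fraction: float = 0.25,
    **emd_kwargs,
) -> list[SectionEnergies]:
    """Full EMG pipeline: filter, decompose per contraction, section energies.

    Contractions with an undefined threshold or zero in-band energy are
    skipped (excluded from the per-animal statistics).
    """
    filtered = preprocess_emg(recording, preprocess_band_hz, notch_hz)
    t = recording.time_s
    out: list[SectionEnergies] = []
    for ev in events:
        if ev.t_thresh_s is None or ev.flagged:
            continue
        span = ev.t_pmax_s - ev.t_thresh_s
        if span <= 0:
            continue
        pad = pad_fraction * span
        i0 = max(0, int(np.searchsorted(t, ev.t_thresh_s - pad)))
        i1 = min(t.size, int(np.searchsorted(t, ev.t_pmax_s + pad)) + 1)
        spec = hilbert_huang(
            filtered[i0:i1],
            recording.sampling_rate_hz,
            time_s=t[i0:i1],
            **emd_kwargs,
        )
        try:
            out.append(section_energies(spec, ev.t_thresh_s, ev.t_pmax_s,
                                        band_hz=band_hz))
        except DegenerateInputError:
            continue
    return out
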