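"""Statsmodels-style front end: one analysis object per recording.

``UrodynamicsAnalysis(recording).fit()`` runs the complete pipeline —
smoothing, cycle/contraction detection, threshold and filling-volume
computation, and (when an EMG channel is present) the Hilbert-Huang section
energies with v-shape classification — and returns a
:class:`UrodynamicsResults` carrying the per-cycle table, the per-recording
summary and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cystometry, emg
from .cystometry import ContractionEvent, MicturitionCycle
from .emg import SectionEnergies
from .io import UDIRecording, read_recording

__all__ = ["UrodynamicsAnalysis", "UrodynamicsResults"]


class UrodynamicsAnalysis:
    """Urodynamic recording analysis model.

    Parameters
    ----------
    recording : UDIRecording
        The trace to analyse.
    min_prominence_cmH2O, min_interval_s : float
        Peak-detection settings for candidate contractions.
    smooth_window_s : float
        Moving-average window (0.1 s preset: 50 samples at 500 Hz,
        500 at 5000 Hz).
    lookback_s, derivative_fraction : float
        The threshold rule: earliest time the smoothed-pressure derivative
        reaches ``derivative_fraction`` of its maximum within ``lookback_s``
        before the peak.
    n_summary_cycles : int
        Cycles averaged into the per-recording summary (3 preset).
    analyze_emg : bool or None
        Force EMG analysis on/off; by default it runs when the channel exists.
    """

    def __init__(
        self,
        recording: UDIRecording,
        *,
        min_prominence_cmH2O: float = 5.0,
        min_interval_s: float = 10.0,
        smooth_window_s: float = 0.1,
        baseline_tolerance_cmH2O: float = 5.0,
        lookback_s: float = 20.0,
        derivative_fraction: float = 0.65,
        n_summary_cycles: int = 3,
        energy_band_hz: tuple[float, float] = (0.0, 500.0),
        notch_hz: float | None = 50.0,
        analyze_emg: bool | None = None,
    ) -> None:
        self.recording = recording
        self.min_prominence_cmH2O = min_prominence_cmH2O
        self.min_interval_s = min_interval_s
        self.smooth_window_s = smooth_window_s
        self.baseline_tolerance_cmH2O = baseline_tolerance_cmH2O
        self.lookback_s = lookback_s
        self.derivative_fraction = derivative_fraction
        self.n_summary_cycles = n_summary_cycles
        self.energy_band_hz = energy_band_hz
        self.notch_hz = notch_hz
        self.analyze_emg = (
            recording.emg_v is not None if analyze_emg is None else analyze_emg
        )

    @classmethod
    def from_csv(cls, path, format_spec=None, **kwargs) -> "UrodynamicsAnalysis":
        return cls(read_recording(path, format_spec), **kwargs)

    def fit(self) -> "UrodynamicsResults":
        rec = self.recording
        cycles = cystometry.detect_cycles(
            rec,
            min_prominence_cmH2O=self.min_prominence_cmH2O,
            min_interval_s=self.min_interval_s,
            window_s=self.smooth_window_s,
            baseline_tolerance_cmH2O=self.baseline_tolerance_cmH2O,
            lookback_s=self.lookback_s,
            fraction=self.derivative_fraction,
        )
        no_cycle = len(cycles) == 0
        events: list[ContractionEvent]
        if no_cycle:
            _, pmax, events = cystometry.normalize_no_cycle(
                rec,
                min_prominence_cmH2O=self.min_prominence_cmH2O,
                window_s=self.smooth_window_s,
                lookback_s=self.lookback_s,
                fraction=self.derivative_fraction,
            )
            summary = {
                "n_cycles_used": 0,
                "incomplete": True,
                "pmax_cmH2O": pmax,
                "pthresh_cmH2O": float("nan"),
                "v_filling_ul": float("nan"),
            }
        else:
            events = list(cycles)
            summary = cystometry.summarize_recording(cycles, self.n_summary_cycles)

        sections: list[SectionEnergies] = []
        if self.analyze_emg and rec.emg_v is not None:
            sections = emg.analyze_contractions(
                rec,
                events,
                band_hz=self.energy_band_hz,
                notch_hz=self.notch_hz,
            )
        return UrodynamicsResults(
            model=self,
            cycles=cycles,
            contractions=events,
            no_cycle=no_cycle,
            recording_summary=summary,
            emg_sections=sections,
        )


@dataclass
class UrodynamicsResults:
    """Fitted urodynamic metrics for one recording."""

    model: UrodynamicsAnalysis
    cycles: list[MicturitionCycle]
    contractions: list[ContractionEvent]
    no_cycle: bool
    recording_summary: dict
    emg_sections: list[SectionEnergies] = field(default_factory=list)

    @property
    def pmax_cmH2O(self) -> float:
        return self.recording_summary["pmax_cmH2O"]

    @property
    def pthresh_cmH2O(self) -> float:
        return self.recording_summary["pthresh_cmH2O"]

    @property
    def v_filling_ul(self) -> float:
        return self.recording_summary["v_filling_ul"]

    def cycle_table(self) -> pd.DataFrame:
        """One row per detected cycle/contraction."""
        rows = []
        for i, ev in enumerate(self.contractions):
            rows.append(
                {
                    "event": i,
                    "kind": "no_cycle_contraction" if self.no_cycle else "cycle",
                    "start_time_s": ev.start_time_s,
                    "end_time_s": ev.end_time_s,
                    "t_pmax_s": ev.t_pmax_s,
                    "pmax_cmH2O": ev.pmax_cmH2O,
                    "t_thresh_s": ev.t_thresh_s,
                    "pthresh_cmH2O": ev.pthresh_cmH2O,
                    "v_filling_ul": getattr(ev, "v_filling_ul", None),
                    "voided_volume_ul": getattr(ev, "voided_volume_ul", None),
                    "flagged": ev.flagged,
                }
            )
        return pd.DataFrame(rows)

    def section_table(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.emg_sections):
            rows.append(
                {
                    "contraction": i,
                    "start_time_s": s.start_time_s,
                    "e_before": s.e_before,
                    "e_during": s.e_during,
                    "e_after": s.e_after,
                    "pct_before": s.pct_before,
                    "pct_during": s.pct_during,
                    "pct_after": s.pct_after,
                    "vshape": emg.classify_vshape(s),
                }
            )
        return pd.DataFrame(rows)

    def vshape_percentage(self, min_contractions: int = 5,
                          window_s: float = 600.0) -> int | None:
        return emg.vshape_percentage(self.emg_sections, min_contractions, window_s)

    def summary(self) -> str:
        """Readable per-recording report."""
        rec = self.model.recording
        s = self.recording_summary
        lines = [
            "Urodynamic recording analysis",
            "=" * 34,
            f"animal: {rec.animal_id or '-'}  group: {rec.group or '-'}"
            f"  week: {rec.week}",
            f"sampling rate: {rec.sampling_rate_hz:g} Hz"
            f"  infusion: {rec.infusion_rate_ul_min:g} uL/min"
            f"  duration: {rec.duration_s:.1f} s",
            "",
        ]
        if self.no_cycle:
            lines += [
                "no micturition cycles detected (pressure normalised to the",
                "recording minimum)",
                f"non-voiding contractions: {len(self.contractions)}",
                f"P_max (normalised): {s['pmax_cmH2O']:.2f} cmH2O",
            ]
        else:
            lines += [
                f"micturition cycles detected: {len(self.cycles)}"
                f" (summary over first {s['n_cycles_used']})",
                f"P_max:      {s['pmax_cmH2O']:8.2f} cmH2O",
                f"P_thresh:   {s['pthresh_cmH2O']:8.2f} cmH2O",
                f"V_filling:  {s['v_filling_ul']:8.2f} uL",
            ]
        if self.emg_sections:
            (mb, md, ma), mean_v = emg.mean_activity_pattern(self.emg_sections)
            pct = self.vshape_percentage()
            lines += [
                "",
                f"EMG contractions analysed: {len(self.emg_sections)}",
                f"mean section activity (before/during/after): "
                f"{mb:.1f} / {md:.1f} / {ma:.1f} %",
                f"mean pattern v-shaped: {'yes' if mean_v else 'no'}",
                "v-shape percentage: "
                + ("excluded (<5 contractions)" if pct is None else f"{pct} %"),
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Pressure trace with detected cycles marked; returns the axes."""
        import matplotlib.pyplot as plt

        rec = self.model.recording
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3.5))
        ax.plot(rec.time_s, rec.pressure_cmH2O, lw=0.5, color="0.4",
                label="P_ves")
        smoothed = cystometry.smooth_pressure(rec, self.model.smooth_window_s)
        ax.plot(rec.time_s, smoothed, lw=1.2, color="C0", label="smoothed")
        for ev in self.contractions:
            ax.axvline(ev.t_pmax_s, color="C3", lw=0.8, ls="--")
            if ev.t_thresh_s is not None:
                ax.axvline(ev.t_thresh_s, color="C2", lw=0.8, ls=":")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("pressure (cmH2O)")
        ax.legend(loc="upper right", fontsize=8)
        return ax
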