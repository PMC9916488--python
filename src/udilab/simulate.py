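"""Ground-truth simulator for cystometry / EUS-EMG recordings and DEG tables.

The generator is phenomenological, not biomechanical: pressure traces are
built from a documented piecewise template (baseline + compliance ramp +
smooth contraction pulses for voiding phenotypes; ramp to an oscillating
high-pressure plateau for the spinal-cord-injury phenotype), EMG is
band-limited Gaussian burst noise whose envelope follows the requested
sphincter-coordination pattern, and the scale channel records cumulative
voided volume with an adjustable probability that a void is "trapped"
(visible to the experimenter but never reaching the scale).

Pressure template, voiding phenotypes (``sham``/``pboo``)
---------------------------------------------------------
Cycle ``k`` occupies ``[k*T, (k+1)*T)`` with ``T = intercycle_interval_s``
and pulse width ``w = contraction_width_s``.  With baseline ``b``,
compliance slope ``c`` and amplitude ``A``::

    filling  (tau = t - k*T in [0, T - w)):   p = b + c*tau
    voiding  (u = tau - (T - w) in [0, w)):   p = b + c*(T-w)*(1 - u/w)
                                                  + A*sin(pi*u/w)**2

i.e. the contraction is a raised-sine pulse during which the accumulated
compliance pressure is released linearly, so each cycle ends exactly at
baseline.  The pulse is smooth, making the 65 %-of-maximal-derivative
threshold rule well defined; the analytic threshold crossing stored in the
ground truth solves ``A*pi/w*sin(2*pi*u/w) - c*(T-w)/w = 0.65 * D`` with
``D`` the maximal derivative (attained at ``u = w/4``).

SCI phenotype
-------------
Pressure ramps at the compliance slope to a plateau ``A`` above baseline and
then oscillates (non-voiding contractions)::

    p = b + min(c*t, A) + A_osc * 0.5*(1 - cos(2*pi*f_osc*(t - t_on)))   (t >= t_on)

with plateau onset ``t_on = A/c``.  The trace never returns to baseline and
no voids are emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConfigurationError, DegenerateInputError
from .io import UDIRecording

__all__ = [
    "SimParams",
    "GroundTruth",
    "DEGSimTruth",
    "PRESETS",
    "simulate_recording",
    "simulate_deg_tables",
    "planted_deg_table",
]

Phenotype = Literal["sham", "pboo", "sci"]
EMGPattern = Literal["vshape", "dyssynergic", "flat"]

_PHENOTYPES = ("sham", "pboo", "sci")
_EMG_PATTERNS = ("vshape", "dyssynergic", "flat")


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults follow the pBOO-style acquisition."""

    sampling_rate_hz: float = 500.0
    infusion_rate_ul_min: float = 10.0
    duration_s: float = 370.0
    baseline_pressure_cmH2O: float = 10.0
    compliance_slope_cmH2O_per_s: float = 0.08
    contraction_amplitude_cmH2O: float = 20.0
    contraction_width_s: float = 3.0
    intercycle_interval_s: float = 120.0
    phenotype: Phenotype = "sham"
    emg_pattern: EMGPattern = "vshape"
    emg_burst_rate_hz: float = 8.0
    emg_carrier_band_hz: tuple[float, float] = (50.0, 200.0)
    emg_amplitude_v: float = 0.1
    vshape_suppression_fraction: float = 0.2
    powerline_hz: float = 0.0
    powerline_amplitude: float = 0.0
    noise_sd: float = 0.2
    emg_noise_sd: float = 0.003
    void_trap_probability: float = 0.3
    osc_freq_hz: float = 0.1
    osc_amplitude_cmH2O: float = 10.0
    volume_rate_hz: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in _PHENOTYPES:
            raise ConfigurationError(f"unknown phenotype {self.phenotype!r}")
        if self.emg_pattern not in _EMG_PATTERNS:
            raise ConfigurationError(f"unknown emg_pattern {self.emg_pattern!r}")
        for name in (
            "sampling_rate_hz",
            "infusion_rate_ul_min",
            "duration_s",
            "contraction_amplitude_cmH2O",
            "contraction_width_s",
            "intercycle_interval_s",
            "emg_burst_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "compliance_slope_cmH2O_per_s",
            "powerline_hz",
            "powerline_amplitude",
            "noise_sd",
            "emg_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for name in ("vshape_suppression_fraction", "void_trap_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        lo, hi = self.emg_carrier_band_hz
        if not 0 < lo < hi:
            raise ConfigurationError("emg_carrier_band_hz must satisfy 0 < low < high")
        if hi >= self.sampling_rate_hz / 2:
            raise ConfigurationError(
                "emg_carrier_band_hz upper bound must be below the Nyquist rate"
            )
        n = self.duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ConfigurationError(
                "duration_s x sampling_rate_hz must be a whole number of samples"
            )
        if self.contraction_width_s >= self.intercycle_interval_s:
            raise ConfigurationError(
                "contraction_width_s must be shorter than intercycle_interval_s"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    def replace(self, **changes) -> "SimParams":
        return replace(self, **changes)


#: acquisition presets: 500 Hz / 10 uL/min (pBOO-style) and 5 kHz / 20 uL/min
#: (SCI-style, EMG recorded)
PRESETS: dict[str, SimParams] = {
    "pboo-500hz": SimParams(
        sampling_rate_hz=500.0,
        infusion_rate_ul_min=10.0,
        phenotype="pboo",
        emg_pattern="flat",
        contraction_amplitude_cmH2O=30.0,
    ),
    "sham-5000hz": SimParams(
        sampling_rate_hz=5000.0,
        infusion_rate_ul_min=20.0,
        phenotype="sham",
        emg_pattern="vshape",
        emg_carrier_band_hz=(100.0, 400.0),
    ),
    "sci-5000hz": SimParams(
        sampling_rate_hz=5000.0,
        infusion_rate_ul_min=20.0,
        phenotype="sci",
        emg_pattern="dyssynergic",
        emg_carrier_band_hz=(100.0, 400.0),
        compliance_slope_cmH2O_per_s=0.5,
        contraction_amplitude_cmH2O=25.0,
        duration_s=190.0,
    ),
}


@dataclass
class GroundTruth:
    """Simulator annotations used by parameter-recovery tests.

    All per-contraction lists are index-aligned; ``recorded_void_volumes_ul``
    holds only the voids that actually reached the scale (its length is the
    number of ``False`` entries in ``trapped_void_flags``).
    """

    true_void_times_s: list[float] = field(default_factory=list)
    true_pmax_times_s: list[float] = field(default_factory=list)
    true_thresh_times_s: list[float] = field(default_factory=list)
    emg_pattern_per_contraction: list[str] = field(default_factory=list)
    trapped_void_flags: list[bool] = field(default_factory=list)
    recorded_void_volumes_ul: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.true_pmax_times_s)
        if len(self.true_thresh_times_s) != n or len(self.emg_pattern_per_contraction) != n:
            raise ConfigurationError("per-contraction annotation lists differ in length")
        for t_th, t_pk in zip(self.true_thresh_times_s, self.true_pmax_times_s):
            if not t_th < t_pk:
                raise ConfigurationError("threshold time must precede its peak time")


def _analytic_thresh_offset(amp: float, width: float, release_slope: float,
                            fraction: float = 0.65) -> float:
    """Offset from pulse onset to the 65 %-of-max-derivative crossing.

    The pulse derivative is ``amp*pi/w * sin(2*pi*u/w) - release_slope``; its
    maximum ``D`` occurs at ``u = w/4``.  Solve for the earliest ``u`` with
    derivative ``>= fraction * D``.
    """
    peak_rate = amp * math.pi / width
    d_max = peak_rate - release_slope
    target = fraction * d_max + release_slope
    s = min(1.0, max(-1.0, target / peak_rate))
    return width / (2.0 * math.pi) * math.asin(s)


def _voiding_pressure(t: np.ndarray, p: SimParams) -> tuple[np.ndarray, GroundTruth]:
    """Evaluate the documented cycle template and its ground truth."""
    T = p.intercycle_interval_s
    w = p.contraction_width_s
    b = p.baseline_pressure_cmH2O
    c = p.compliance_slope_cmH2O_per_s
    A = p.contraction_amplitude_cmH2O
    fill = T - w
    ramp_top = c * fill

    tau = np.mod(t, T)
    cycle_idx = np.floor_divide(t, T).astype(int)
    n_cycles = int(math.floor((p.duration_s + 1e-12) / T))
    if n_cycles < 1:
        raise DegenerateInputError(
            f"duration {p.duration_s}s too short for one {T}s cycle"
        )
    filling = tau < fill
    u = tau - fill
    pressure = np.where(
        filling,
        b + c * tau,
        b + ramp_top * (1.0 - u / w) + A * np.sin(np.pi * u / w) ** 2,
    )
    # samples beyond the last complete cycle stay on the filling ramp
    incomplete = cycle_idx >= n_cycles
    pressure[incomplete] = b + c * tau[incomplete]

    # analytic peak of  A*sin(pi*u/w)^2 - ramp_top*u/w  (near u = w/2)
    u_grid = np.linspace(0.0, w, 4097)
    pulse = A * np.sin(np.pi * u_grid / w) ** 2 - ramp_top * u_grid / w
    u_peak = float(u_grid[int(np.argmax(pulse))])
    u_thresh = _analytic_thresh_offset(A, w, ramp_top / w)

    truth = GroundTruth()
    for k in range(n_cycles):
        onset = k * T + fill
        truth.true_void_times_s.append(onset + u_peak)
        truth.true_pmax_times_s.append(onset + u_peak)
        truth.true_thresh_times_s.append(onset + u_thresh)
        truth.emg_pattern_per_contraction.append(p.emg_pattern)
    return pressure, truth


def _sci_pressure(t: np.ndarray, p: SimParams) -> tuple[np.ndarray, GroundTruth]:
    b = p.baseline_pressure_cmH2O
    c = p.compliance_slope_cmH2O_per_s
    A = p.contraction_amplitude_cmH2O
    if c <= 0:
        raise ConfigurationError("SCI phenotype needs a positive compliance slope")
    t_on = A / c
    if t_on >= p.duration_s:
        raise DegenerateInputError(
            "duration too short for the pressure to reach the SCI plateau"
        )
    pressure = b + np.minimum(c * t, A)
    rel = t - t_on
    osc = np.where(
        rel >= 0.0,
        p.osc_amplitude_cmH2O * 0.5 * (1.0 - np.cos(2.0 * np.pi * p.osc_freq_hz * rel)),
        0.0,
    )
    pressure = pressure + osc

    period = 1.0 / p.osc_freq_hz
    u_thresh = _analytic_thresh_offset(p.osc_amplitude_cmH2O, period, 0.0)
    truth = GroundTruth()
    k = 0
    while True:
        peak = t_on + (k + 0.5) * period
        if peak > p.duration_s - period * 0.25:
            break
        truth.true_pmax_times_s.append(peak)
        truth.true_thresh_times_s.append(t_on + k * period + u_thresh)
        truth.emg_pattern_per_contraction.append(p.emg_pattern)
        k += 1
    return pressure, truth


def _emg_envelope(t: np.ndarray, p: SimParams, pressure_clean: np.ndarray,
                  truth: GroundTruth) -> np.ndarray:
    if p.emg_pattern == "flat":
        env = np.ones_like(t)
    elif p.emg_pattern == "dyssynergic":
        # sphincter activity tracks the contraction's pressure excursion:
        # envelope rises linearly from 0.2 at the active-range floor (plateau
        # trough for SCI, baseline for voiding phenotypes) to 1.2 at the peak
        if p.phenotype == "sci":
            lo = p.baseline_pressure_cmH2O + p.contraction_amplitude_cmH2O
        else:
            lo = p.baseline_pressure_cmH2O
        hi = float(pressure_clean.max())
        span = max(hi - lo, 1e-12)
        env = np.clip(0.2 + (pressure_clean - lo) / span, 0.05, None)
    else:  # vshape: suppress the middle fifth of [t_thresh, t_pmax]
        env = np.ones_like(t)
        for t_th, t_pk in zip(truth.true_thresh_times_s, truth.true_pmax_times_s):
            span = t_pk - t_th
            lo = t_th + 0.4 * span
            hi = t_th + 0.6 * span
            ramp = 0.05 * span  # raised-cosine shoulders
            depth = 1.0 - p.vshape_suppression_fraction
            win = np.zeros_like(t)
            core = (t >= lo) & (t <= hi)
            win[core] = 1.0
            lead = (t >= lo - ramp) & (t < lo)
            win[lead] = 0.5 * (1.0 + np.cos(np.pi * (lo - t[lead]) / ramp))
            tail = (t > hi) & (t <= hi + ramp)
            win[tail] = 0.5 * (1.0 + np.cos(np.pi * (t[tail] - hi) / ramp))
            env = env * (1.0 - depth * win)
    # slow burst modulation; fast relative to the five-part sections
    env = env * (1.0 + 0.5 * np.sin(2.0 * np.pi * p.emg_burst_rate_hz * t)) / 1.5
    return env


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    rms = float(np.sqrt(np.mean(x**2)))
    return x / max(rms, 1e-30)


def _volume_trace(t: np.ndarray, p: SimParams, truth: GroundTruth,
                  rng: np.random.Generator) -> np.ndarray:
    """Cumulative scale reading: steps at void times, quantised to scale ticks."""
    vol = np.zeros_like(t)
    per_void = p.infusion_rate_ul_min / 60.0 * p.intercycle_interval_s
    for v_time in truth.true_void_times_s:
        trapped = bool(rng.random() < p.void_trap_probability)
        truth.trapped_void_flags.append(trapped)
        if trapped:
            continue
        truth.recorded_void_volumes_ul.append(per_void)
        tick = math.ceil(v_time * p.volume_rate_hz) / p.volume_rate_hz
        vol[t >= tick - 1e-12] += per_void
    return vol


def simulate_recording(params: SimParams) -> tuple[UDIRecording, GroundTruth]:
    """Simulate one recording with annotated ground truth.

    Identical ``params`` (including ``seed``) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    t = np.arange(n) / params.sampling_rate_hz

    if params.phenotype == "sci":
        pressure_clean, truth = _sci_pressure(t, params)
    else:
        pressure_clean, truth = _voiding_pressure(t, params)

    pressure = pressure_clean + params.noise_sd * rng.standard_normal(n)

    env = _emg_envelope(t, params, pressure_clean, truth)
    emg = params.emg_amplitude_v * env * _band_noise(
        n, params.sampling_rate_hz, params.emg_carrier_band_hz, rng
    )
    emg = emg + params.emg_noise_sd * rng.standard_normal(n)
    if params.powerline_hz > 0 and params.powerline_amplitude > 0:
        emg = emg + params.powerline_amplitude * np.sin(
            2.0 * np.pi * params.powerline_hz * t
        )

    volume = _volume_trace(t, params, truth, rng)

    rec = UDIRecording(
        time_s=t,
        pressure_cmH2O=pressure,
        emg_v=emg,
        volume_ul=volume,
        sampling_rate_hz=params.sampling_rate_hz,
        infusion_rate_ul_min=params.infusion_rate_ul_min,
        volume_rate_hz=params.volume_rate_hz,
        group=params.phenotype,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# DEG-table fixtures


@dataclass
class DEGSimTruth:
    """Planted labels for a simulated pair of DEG tables."""

    shared: list[str]
    concordant: list[str]
    discordant: list[str]
    unique_a: list[str]
    unique_b: list[str]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _deg_frame(rng: np.random.Generator, gene_ids: np.ndarray, is_sig: np.ndarray,
               signs: np.ndarray, effect_size_sd: float) -> pd.DataFrame:
    n = gene_ids.size
    log2fc = rng.normal(0.0, 0.1, size=n)
    pval = rng.uniform(1e-12, 1.0, size=n)
    sig = np.flatnonzero(is_sig)
    log2fc[sig] = signs[sig] * (0.75 + np.abs(rng.normal(2.0, effect_size_sd, sig.size)))
    pval[sig] = 10.0 ** rng.uniform(-12.0, -6.0, size=sig.size)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "pvalue": pval,
            "padj": _bh_adjust(pval),
            "mean_count": np.exp(rng.normal(5.0, 1.5, size=n)),
        }
    )


def simulate_deg_tables(
    n_genes: int,
    overlap_spec: dict,
    seed: int,
    n_unique_a: int = 25,
    n_unique_b: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame, DEGSimTruth]:
    """Simulate two DEG tables with a planted shared/concordant structure.

    ``overlap_spec`` carries ``n_shared`` (genes significant in both tables),
    ``n_concordant`` (shared genes with equal fold-change sign) and
    ``effect_size_sd`` (spread of the planted |log2FC| around 2).  Null genes
    get uniform p-values and near-zero fold changes.
    """
    n_shared = int(overlap_spec["n_shared"])
    n_conc = int(overlap_spec["n_concordant"])
    effect_sd = float(overlap_spec.get("effect_size_sd", 0.5))
    if not 0 <= n_conc <= n_shared:
        raise ConfigurationError("need 0 <= n_concordant <= n_shared")
    if n_shared + n_unique_a + n_unique_b > n_genes:
        raise ConfigurationError("planted genes exceed n_genes")

    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    gene_ids = np.array([f"gene{i:0{width}d}" for i in range(n_genes)])

    sig_a = np.zeros(n_genes, dtype=bool)
    sig_b = np.zeros(n_genes, dtype=bool)
    sig_a[: n_shared + n_unique_a] = True
    sig_b[:n_shared] = True
    sig_b[n_shared + n_unique_a : n_shared + n_unique_a + n_unique_b] = True

    signs_a = rng.choice([-1.0, 1.0], size=n_genes)
    signs_b = signs_a.copy()
    signs_b[n_conc:n_shared] *= -1.0  # discordant block
    signs_b[n_shared:] = rng.choice([-1.0, 1.0], size=n_genes - n_shared)

    table_a = _deg_frame(rng, gene_ids, sig_a, signs_a, effect_sd)
    table_b = _deg_frame(rng, gene_ids, sig_b, signs_b, effect_sd)
    truth = DEGSimTruth(
        shared=list(gene_ids[:n_shared]),
        concordant=list(gene_ids[:n_conc]),
        discordant=list(gene_ids[n_conc:n_shared]),
        unique_a=list(gene_ids[n_shared : n_shared + n_unique_a]),
        unique_b=list(gene_ids[n_shared + n_unique_a : n_shared + n_unique_a + n_unique_b]),
    )
    return table_a, table_b, truth


def planted_deg_table(n_genes: int, n_up: int, n_down: int, seed: int) -> pd.DataFrame:
    """One DEG table with exact planted up/down counts under the strict preset
    (adjusted p < 0.05 and |log2FC| > 0.5); every gene has nonzero counts."""
    if n_up + n_down > n_genes:
        raise ConfigurationError("planted genes exceed n_genes")
    rng = np.random.default_rng(seed)
    signs = np.zeros(n_genes)
    signs[:n_up] = 1.0
    signs[n_up : n_up + n_down] = -1.0
    is_sig = signs != 0.0
    width = max(5, len(str(n_genes)))
    gene_ids = np.array([f"gene{i:0{width}d}" for i in range(n_genes)])
    frame = _deg_frame(rng, gene_ids, is_sig, signs, effect_size_sd=0.5)
    # guard the planted counts against null genes drifting past the thresholds
    null = ~is_sig
    frame.loc[null, "padj"] = np.maximum(frame.loc[null, "padj"], 0.2)
    frame.loc[null, "log2fc"] = np.clip(frame.loc[null, "log2fc"], -0.4, 0.4)
    return frame
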