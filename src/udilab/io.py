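"""Reading and writing urodynamic recordings and run configuration.

Recordings travel as plain comma-separated text: ``#``-prefixed ``key = value``
metadata lines (sampling rate, infusion rate, animal/group/week labels)
followed by a header row and one row per sample.  Times are seconds from the
start of the recording; pressure is cmH2O, EMG is volts, voided volume is the
cumulative microlitre reading of the scale channel.
"""

from __future__ import annotations

import io as _io
import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = ["UDIRecording", "read_recording", "write_recording", "load_config"]

#: significant digits used when serialising sample values (lossless round-trip)
_FLOAT_FMT = "%.12g"


@dataclass
class UDIRecording:
    """Synchronised pressure / EMG / voided-volume time series.

    Parameters
    ----------
    time_s : ndarray
        Monotone non-decreasing sample times in seconds.
    pressure_cmH2O : ndarray
        Intravesical pressure (P_ves), same length as ``time_s``.
    emg_v : ndarray or None
        External-urethral-sphincter EMG voltage, optional.
    volume_ul : ndarray or None
        Cumulative voided volume from the scale channel, optional.
    sampling_rate_hz : float
        Acquisition rate of pressure/EMG (500 Hz or 5000 Hz presets).
    infusion_rate_ul_min : float
        Saline infusion rate (10 or 20 uL/min presets).
    volume_rate_hz : float or None
        Native rate of the scale channel (5 Hz preset); the stored series is
        sample-and-held onto the main time base.
    """

    time_s: np.ndarray
    pressure_cmH2O: np.ndarray
    emg_v: np.ndarray | None = None
    volume_ul: np.ndarray | None = None
    sampling_rate_hz: float = 500.0
    infusion_rate_ul_min: float = 10.0
    volume_rate_hz: float | None = 5.0
    animal_id: str = ""
    group: str = ""
    week: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_cmH2O = np.asarray(self.pressure_cmH2O, dtype=float)
        if self.emg_v is not None:
            self.emg_v = np.asarray(self.emg_v, dtype=float)
        if self.volume_ul is not None:
            self.volume_ul = np.asarray(self.volume_ul, dtype=float)
        n = self.time_s.size
        if n == 0:
            raise ValidationError("recording must contain at least one sample")
        if self.pressure_cmH2O.size != n:
            raise ValidationError(
                f"pressure length {self.pressure_cmH2O.size} != time length {n}"
            )
        for name in ("emg_v", "volume_ul"):
            ch = getattr(self, name)
            if ch is not None and ch.size != n:
                raise ValidationError(f"{name} length {ch.size} != time length {n}")
        if np.any(np.diff(self.time_s) < 0):
            raise FormatError("time column is not monotone non-decreasing")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if n > 1:
            dt = np.median(np.diff(self.time_s))
            expected = 1.0 / self.sampling_rate_hz
            if not math.isclose(dt, expected, rel_tol=1e-6, abs_tol=0.0):
                raise ValidationError(
                    f"median sampling interval {dt:g}s inconsistent with "
                    f"sampling_rate_hz={self.sampling_rate_hz:g}"
                )

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def copy(self, **changes) -> "UDIRecording":
        return replace(self, **changes)


_META_FIELDS = {
    "sampling_rate_hz": float,
    "infusion_rate_ul_min": float,
    "volume_rate_hz": float,
    "animal_id": str,
    "group": str,
    "week": int,
}

_DEFAULT_COLUMNS = {
    "time": "time_s",
    "pressure": "pressure_cmH2O",
    "emg": "emg_v",
    "volume": "volume_ul",
}


def write_recording(recording: UDIRecording, path) -> Path:
    """Serialise a recording to delimited text and return the path written."""
    path = Path(path)
    cols = {"time_s": recording.time_s, "pressure_cmH2O": recording.pressure_cmH2O}
    if recording.emg_v is not None:
        cols["emg_v"] = recording.emg_v
    if recording.volume_ul is not None:
        cols["volume_ul"] = recording.volume_ul
    buf = _io.StringIO()
    for key in _META_FIELDS:
        val = getattr(recording, key)
        if val is None or val == "":
            continue
        buf.write(f"# {key} = {val}\n")
    pd.DataFrame(cols).to_csv(buf, index=False, float_format=_FLOAT_FMT)
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_recording(path, format_spec: Mapping[str, str] | None = None) -> UDIRecording:
    """Read a recording from delimited text.

    ``format_spec`` maps the roles ``time``, ``pressure`` and optionally
    ``emg``/``volume`` to column names in the file; by default the writer's
    own column names are expected.  The sampling rate is taken from the
    metadata header and, when absent, inferred from the time column.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict[str, object] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, raw = body.partition("=")
                key = key.strip()
                if key in _META_FIELDS:
                    meta[key] = _META_FIELDS[key](raw.strip())
    try:
        table = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc

    spec = dict(_DEFAULT_COLUMNS)
    if format_spec:
        spec.update(format_spec)
    for role in ("time", "pressure"):
        if spec[role] not in table.columns:
            raise FormatError(f"mandatory column {spec[role]!r} missing in {path}")

    time = table[spec["time"]].to_numpy(float)
    if np.any(np.diff(time) < 0):
        raise FormatError("time column is not monotone non-decreasing")
    if "sampling_rate_hz" not in meta:
        if time.size < 2:
            raise FormatError("cannot infer sampling rate from a single sample")
        meta["sampling_rate_hz"] = 1.0 / float(np.median(np.diff(time)))

    def _optional(role: str):
        name = spec.get(role)
        return table[name].to_numpy(float) if name in table.columns else None

    return UDIRecording(
        time_s=time,
        pressure_cmH2O=table[spec["pressure"]].to_numpy(float),
        emg_v=_optional("emg"),
        volume_ul=_optional("volume"),
        **meta,
    )


def load_config(path) -> dict:
    """Load a TOML configuration file of simulation/analysis parameters."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)
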