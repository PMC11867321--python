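"""Reading and writing force-plate exports, trial manifests and metric tables.

Force recordings travel as plain delimited text (time + vertical force, or a
force column plus a declared sampling rate), which covers the common
force-plate software export dialects.  Everything is stored internally in SI
units: newtons, seconds, metres.  Jump height is kept in metres here and
converted to centimetres only at the reporting layer.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

#: Canonical column order for metric tables (SI units: W, W, N·s/kg, m, J).
METRIC_COLUMNS = [
    "peak_power_w",
    "mean_power_w",
    "relative_net_impulse_ns_kg",
    "jump_height_m",
    "peak_kinetic_energy_j",
]

JUMP_TYPES = ("CMJ", "SJ")


@dataclass(frozen=True)
class ForceRecording:
    """A uniformly sampled vertical ground-reaction-force trace.

    Parameters
    ----------
    force : ndarray
        Vertical GRF in newtons, one value per sample.
    sampling_rate : float
        Samples per second (Hz).
    start_time : float
        Time of the first sample in seconds.
    participant, jump_type, trial
        Optional trial metadata. ``jump_type`` is ``"CMJ"`` or ``"SJ"``.
    """

    force: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    participant: str | None = None
    jump_type: str | None = None
    trial: int | None = None

    def __post_init__(self) -> None:
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "force", force)
        if force.ndim != 1 or force.size < 2:
            raise FormatError("a recording needs at least 2 force samples")
        if not np.all(np.isfinite(force)):
            bad = int(np.flatnonzero(~np.isfinite(force))[0])
            raise FormatError(f"non-finite force value at sample {bad}")
        if not self.sampling_rate > 0:
            raise FormatError("sampling_rate must be positive")
        if self.jump_type is not None and self.jump_type not in JUMP_TYPES:
            raise FormatError(f"jump_type must be one of {JUMP_TYPES}")

    @property
    def n_samples(self) -> int:
        return self.force.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) * self.dt

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.n_samples) * self.dt

    def with_meta(self, **kwargs) -> "ForceRecording":
        return dataclasses.replace(self, **kwargs)


def read_force_recording(
    path,
    *,
    delimiter: str | None = None,
    time_column: str | int | None = 0,
    force_column: str | int | None = 1,
    sampling_rate: float | None = None,
    header: bool = True,
    time_tolerance: float = 0.01,
    participant: str | None = None,
    jump_type: str | None = None,
    trial: int | None = None,
) -> ForceRecording:
    """Parse a delimited-text force-plate export into a :class:`ForceRecording`.

    Either a time column (uniformity checked to ``time_tolerance``, default
    1% of the median step) or an explicit ``sampling_rate`` must be supplied.
    Columns may be named (header required) or positional 0-based indices.
    The decimal separator is fixed to ``"."``; the delimiter is sniffed from
    comma/tab/semicolon when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    text = path.read_text()
    if delimiter is None:
        first = text.splitlines()[0] if text.splitlines() else ""
        for cand in ("\t", ";", ","):
            if cand in first:
                delimiter = cand
                break
        else:
            delimiter = ","
    try:
        df = pd.read_csv(
            _io.StringIO(text),
            sep=delimiter,
            header=0 if header else None,
            skip_blank_lines=True,
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"could not parse {path}: {exc}") from exc

    def _col(sel, role: str) -> np.ndarray:
        if sel is None:
            raise FormatError(f"{role} column not declared")
        if isinstance(sel, int):
            if sel >= df.shape[1]:
                raise FormatError(
                    f"{role} column index {sel} out of range ({df.shape[1]} columns)"
                )
            series = df.iloc[:, sel]
        else:
            if sel not in df.columns:
                raise FormatError(f"{role} column {sel!r} not found in {list(df.columns)}")
            series = df[sel]
        return pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)

    if sampling_rate is None:
        if time_column is None:
            raise FormatError("either a time column or sampling_rate is required")
        t = _col(time_column, "time")
        if t.size < 2:
            raise FormatError("fewer than 2 samples")
        steps = np.diff(t)
        ref = float(np.median(steps))
        if ref <= 0:
            raise FormatError("time column is not strictly increasing")
        bad = np.flatnonzero(np.abs(steps - ref) > time_tolerance * ref)
        if bad.size:
            row = int(bad[0]) + 1  # row holding the deviating timestamp
            raise FormatError(
                f"non-uniform time step at data row {row}: "
                f"dt={steps[bad[0]]:.6g}s vs median {ref:.6g}s"
            )
        rate = 1.0 / ref
        start = float(t[0])
    else:
        rate = float(sampling_rate)
        start = 0.0
    force = _col(force_column, "force")
    if np.isnan(force).any():
        row = int(np.flatnonzero(np.isnan(force))[0]) + 1
        raise FormatError(f"non-numeric force value at data row {row}")
    return ForceRecording(
        force=force,
        sampling_rate=rate,
        start_time=start,
        participant=participant,
        jump_type=jump_type,
        trial=trial,
    )


def write_force_recording(rec: ForceRecording, path, *, delimiter: str = ",") -> None:
    """Write a recording as two-column delimited text ``time_s, fz_N``."""
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.time, "fz_N": rec.force})
    df.to_csv(path, sep=delimiter, index=False, float_format="%.6f")


@dataclass
class TrialManifest:
    """Table of trials: participant, jump type, trial number, file, optional 1RM."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("participant", "jump_type", "trial", "path")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        key = df[["participant", "jump_type", "trial"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate manifest entry: {dup}")
        if not df["jump_type"].isin(JUMP_TYPES).all():
            raise FormatError(f"jump_type must be one of {JUMP_TYPES}")
        if "measured_1rm_kg" in df.columns:
            rm = pd.to_numeric(df["measured_1rm_kg"], errors="coerce")
            if (rm.dropna() <= 0).any():
                raise FormatError("measured_1rm_kg must be positive where present")

    @classmethod
    def read(cls, path) -> "TrialManifest":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"no such manifest: {path}")
        return cls(pd.read_csv(path))

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return iter(self.table.to_dict("records"))


def write_metrics_table(rows: Sequence[dict], path) -> pd.DataFrame:
    """Write per-trial jump metrics as CSV, one row per trial.

    ``rows`` are dicts carrying trial ids plus the five metrics under the
    :data:`METRIC_COLUMNS` names (SI units).  Refuses physically invalid
    metrics (negative jump height / peak kinetic energy).
    """
    if not rows:
        raise ValueError("no metric rows to write")
    df = pd.DataFrame(list(rows))
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metric rows missing columns: {missing}")
    if (df["jump_height_m"] < 0).any():
        raise ValueError("refusing to write metrics with negative jump height")
    if (df["peak_kinetic_energy_j"] < 0).any():
        raise ValueError("refusing to write metrics with negative peak kinetic energy")
    id_cols = [c for c in df.columns if c not in METRIC_COLUMNS]
    df = df[id_cols + METRIC_COLUMNS]
    df.to_csv(path, index=False, float_format="%.10g")
    return df


def read_metrics_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metrics table missing columns: {missing}")
    return df
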