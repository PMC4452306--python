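"""Delimited-text readers and writers for pipeline artifacts.

All delimited outputs carry a one-line column header; an optional leading
``#`` comment line records provenance (package version, seed, config hash)
and is skipped on read. Times are always in seconds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .nvc_model import FitResult, GammaParams
from .timeseries import TimeSeries

__all__ = [
    "provenance_line",
    "config_hash",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_events_tsv",
    "read_events_tsv",
    "read_channel_table",
    "read_nirs_intensity_table",
    "write_fits_csv",
    "read_fits_csv",
    "write_report_json",
    "write_epoch_csv",
    "read_epochs_dir",
]

FIT_COLUMNS = [
    "epoch_id", "eeg_ch", "nirs_ch", "tau", "n", "n_refined",
    "d", "a", "b", "sse", "r", "converged",
]


def _snap_rate(fs: float, decimals: int = 6) -> float:
    """Round a rate inferred from a time column to absorb float roundoff."""
    return float(np.round(fs, decimals))

def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_line(seed=None, cfg_hash: str | None = None) -> str:
    parts = [f"# nvcouple version={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return " ".join(parts)


def _write_df(df: pd.DataFrame, path, sep: str, seed, cfg_hash) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, cfg_hash) + "\n")
        df.to_csv(fh, sep=sep, index=False)


def write_timeseries_csv(
    path, ts: TimeSeries, value_col: str = "value", seed=None, cfg_hash=None
) -> None:
    df = pd.DataFrame({"time_s": ts.times, value_col: ts.values})
    _write_df(df, path, ",", seed, cfg_hash)


def read_timeseries_csv(path, value_col: str | None = None) -> TimeSeries:
    df = pd.read_csv(path, comment="#")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    fs = _snap_rate(1.0 / float(np.median(np.diff(t))))
    col = value_col or [c for c in df.columns if c != "time_s"][0]
    return TimeSeries(df[col].to_numpy(), fs, t0=float(t[0]))


def write_events_tsv(path, onsets, durations, labels=None, seed=None, cfg_hash=None):
    labels = labels if labels is not None else ["stim"] * len(onsets)
    df = pd.DataFrame(
        {"onset_s": onsets, "duration_s": durations, "label": labels}
    )
    _write_df(df, path, "\t", seed, cfg_hash)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("onset_s", "duration_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def read_channel_table(path, fs: float | None = None) -> dict[str, TimeSeries]:
    """Delimited table, one column per channel, optional ``time_s`` column."""
    df = pd.read_csv(path, comment="#")
    if "time_s" in df.columns:
        # the time column is authoritative; ``fs`` only covers tables without one
        t = df.pop("time_s").to_numpy()
        fs = _snap_rate(1.0 / float(np.median(np.diff(t))))
        t0 = float(t[0])
    else:
        if fs is None:
            raise ValueError(f"{path}: no time_s column; a sampling rate is required")
        t0 = 0.0
    return {c: TimeSeries(df[c].to_numpy(), fs, t0) for c in df.columns}


def read_nirs_intensity_table(path, fs: float = 25.0):
    """Intensity table with ``<channel>_<wavelength>`` columns.

    Returns {channel: {wavelength_nm: values}}.
    """
    df = pd.read_csv(path, comment="#")
    df = df.drop(columns=[c for c in ("time_s",) if c in df.columns])
    channels: dict[str, dict[float, np.ndarray]] = {}
    for col in df.columns:
        name, _, wl = col.rpartition("_")
        if not name:
            raise ValueError(f"{path}: column {col!r} is not <channel>_<wavelength>")
        channels.setdefault(name, {})[float(wl)] = df[col].to_numpy()
    return channels, fs


def write_fits_csv(path, fits: list[FitResult], seed=None, cfg_hash=None) -> None:
    rows = [
        {
            "epoch_id": f.epoch_id,
            "eeg_ch": f.eeg_channel,
            "nirs_ch": f.nirs_channel,
            "tau": f.params.tau,
            "n": f.params.n,
            "n_refined": f.n_refined,
            "d": f.params.d,
            "a": f.a,
            "b": f.b,
            "sse": f.sse,
            "r": f.r,
            "converged": f.converged,
        }
        for f in fits
    ]
    _write_df(pd.DataFrame(rows, columns=FIT_COLUMNS), path, ",", seed, cfg_hash)


def read_fits_csv(path) -> list[FitResult]:
    df = pd.read_csv(path, comment="#")
    fits = []
    for row in df.itertuples(index=False):
        fits.append(
            FitResult(
                params=GammaParams(row.tau, int(row.n), row.d),
                a=row.a,
                b=row.b,
                sse=row.sse,
                r=row.r,
                n_refined=row.n_refined,
                epoch_id=int(row.epoch_id),
                eeg_channel=str(row.eeg_ch),
                nirs_channel=str(row.nirs_ch),
                converged=bool(row.converged),
            )
        )
    return fits


def write_epoch_csv(path, pair, seed=None, cfg_hash=None) -> None:
    """One epoch pair as (time_s, envelope, hbo) plus metadata columns."""
    df = pd.DataFrame(
        {
            "time_s": pair.envelope.times,
            "envelope": pair.envelope.values,
            "hbo": pair.hbo.values,
        }
    )
    df["epoch_id"] = pair.epoch_id
    df["eeg_ch"] = pair.eeg_channel
    df["nirs_ch"] = pair.nirs_channel
    df["stim_onset_s"] = pair.stim_onset_s
    df["stim_dur_s"] = pair.stim_dur_s
    _write_df(df, path, ",", seed, cfg_hash)


def read_epochs_dir(directory) -> list:
    """All ``epoch_*.csv`` files in a directory as EpochPair objects."""
    from .nvc_model import EpochPair

    paths = sorted(Path(directory).glob("epoch_*.csv"))
    if not paths:
        raise ValueError(f"no epoch_*.csv files found in {directory}")
    pairs = []
    for p in paths:
        df = pd.read_csv(p, comment="#")
        t = df["time_s"].to_numpy()
        fs = _snap_rate(1.0 / float(np.median(np.diff(t))))
        pairs.append(
            EpochPair(
                envelope=TimeSeries(df["envelope"].to_numpy(), fs, t0=float(t[0])),
                hbo=TimeSeries(df["hbo"].to_numpy(), fs, t0=float(t[0])),
                stim_onset_s=float(df["stim_onset_s"].iloc[0]),
                stim_dur_s=float(df["stim_dur_s"].iloc[0]),
                eeg_channel=str(df["eeg_ch"].iloc[0]),
                nirs_channel=str(df["nirs_ch"].iloc[0]),
                epoch_id=int(df["epoch_id"].iloc[0]),
            )
        )
    return pairs


def write_report_json(path, payload: dict, seed=None, cfg_hash=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(payload)
    payload["provenance"] = {
        "version": __version__,
        "seed": seed,
        "config": cfg_hash,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
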