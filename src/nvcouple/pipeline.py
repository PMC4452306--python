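"""Run configuration and the two canned studies.

``run_simulation_study`` reproduces the synthetic validation experiment:
for every ground-truth kernel and noise level it extracts the 8 stimulus
epochs, runs the two-step fit, and tabulates recovered parameters and
prediction correlations against the noise amplitude ratio.

``run_experimental_pipeline`` is the recorded-data path: raw EEG and NIRS
tables plus a stimulus-event file go through the preprocessing stream,
epoching, per-epoch fits, and the cluster significance scan.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .cluster_stats import (
    build_features,
    representative_kernels,
    select_optimal,
    significance_scan,
    ward_linkage,
)
from .nvc_model import EpochPair, FitGrid, fit_epoch
from .preprocess import (
    RawNIRSRecord,
    butterworth_filter,
    chauvenet_clean,
    downsample,
    emd,
    extract_epochs,
    hilbert_envelope,
    mbll,
    select_channels,
    smooth_normalize,
)
from .simulator import SimulationConfig, extract_epoch_pairs, simulate_dataset
from .timeseries import TimeSeries

log = logging.getLogger("nvcouple")

__all__ = [
    "ConfigError",
    "PreprocessConfig",
    "ClusterConfig",
    "PathsConfig",
    "RunConfig",
    "validate_config",
    "load_config",
    "run_simulation_study",
    "run_experimental_pipeline",
]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class PreprocessConfig:
    eeg_band: tuple[float, float] = (5.0, 14.0)
    eeg_order: int = 4
    nirs_lowpass_hz: float = 0.5
    nirs_lowpass_order: int = 3
    chauvenet_span: int = 30
    smooth_window_s: float = 4.0
    stim_dur_s: float = 15.0
    pre_s: float = 5.0
    post_s: float = 5.0
    r_min: float = 0.3
    hbo_min_um: float = 0.5
    target_fs: float = 25.0

    def validate(self) -> None:
        lo, hi = self.eeg_band
        if not (0 < lo < hi):
            raise ConfigError(f"eeg_band must be (low, high) with 0 < low < high, got {self.eeg_band}")
        if self.stim_dur_s <= 0 or self.pre_s < 0 or self.post_s < 0:
            raise ConfigError("epoch timing values must be non-negative (stim > 0)")


@dataclass
class ClusterConfig:
    alpha: float = 0.05
    n_min: int = 2
    n_max: int = 12

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (1 <= self.n_min <= self.n_max):
            raise ConfigError("cluster division range must satisfy 1 <= n_min <= n_max")


@dataclass
class PathsConfig:
    eeg: str | None = None
    nirs: str | None = None
    events: str | None = None
    nirs_kind: str = "hbo"  # "hbo" (concentration table) or "intensity"
    eeg_fs: float = 2048.0
    nirs_fs: float = 25.0

    def validate(self) -> None:
        if self.nirs_kind not in ("hbo", "intensity"):
            raise ConfigError(f"nirs_kind must be 'hbo' or 'intensity', got {self.nirs_kind!r}")


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    grid: FitGrid = field(default_factory=FitGrid)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)
    seed: int = 0
    out_dir: str = "nvcouple_out"

    def to_dict(self) -> dict:
        d = {
            "sim": self.sim.to_dict(),
            "grid": dataclasses.asdict(self.grid),
            "preprocess": dataclasses.asdict(self.preprocess),
            "cluster": dataclasses.asdict(self.cluster),
            "paths": dataclasses.asdict(self.paths),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        return d

    @property
    def hash(self) -> str:
        return io.config_hash(self.to_dict())


_TUPLE_FIELDS = {"eeg_band", "tau_range", "d_range", "n_values", "ar_db_list", "gamma_sets"}


def _build_section(cls, raw: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in raw.items()
    }
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def validate_config(raw: dict | None) -> RunConfig:
    """Fill defaults, reject unknown keys, and validate every section."""
    raw = dict(raw or {})
    sections = {
        "sim": (SimulationConfig, SimulationConfig.from_dict),
        "grid": (FitGrid, None),
        "preprocess": (PreprocessConfig, None),
        "cluster": (ClusterConfig, None),
        "paths": (PathsConfig, None),
    }
    top_known = set(sections) | {"seed", "out_dir"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    built = {}
    for name, (cls, loader) in sections.items():
        sub = raw.get(name, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        if loader is not None:
            known = {f.name for f in fields(cls)}
            bad = set(sub) - known
            if bad:
                raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(bad)}")
            try:
                built[name] = loader(sub)
            except (ValueError, TypeError) as exc:
                raise ConfigError(f"invalid section {name!r}: {exc}") from exc
        else:
            built[name] = _build_section(cls, sub, name)
    cfg = RunConfig(
        sim=built["sim"],
        grid=built["grid"],
        preprocess=built["preprocess"],
        cluster=built["cluster"],
        paths=built["paths"],
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "nvcouple_out")),
    )
    cfg.preprocess.validate()
    cfg.cluster.validate()
    cfg.paths.validate()
    return cfg


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return validate_config({})
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------

def run_simulation_study(
    cfg: RunConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parameter-recovery study over every kernel set and noise level.

    Returns ``(r_table, params_table)``: mean prediction correlation per
    (set, AR), and per-epoch recovered parameters.
    """
    sim = cfg.sim
    log.info("simulating dataset (%d pulses, %d kernel sets)", sim.n_pulses, len(sim.gamma_sets))
    ds = simulate_dataset(sim)
    rows = []
    for k, gp in enumerate(sim.gamma_sets):
        for ar in sim.ar_db_list:
            pairs = extract_epoch_pairs(ds, k, ar_db=ar, seed=cfg.seed)
            for pair in pairs:
                fit = fit_epoch(pair, cfg.grid)
                rows.append(
                    {
                        "set": k + 1,
                        "true_tau": gp.tau,
                        "true_n": gp.n,
                        "true_d": gp.d,
                        "ar_db": ar,
                        "epoch": pair.epoch_id,
                        "tau": fit.params.tau,
                        "n": fit.params.n,
                        "n_refined": fit.n_refined,
                        "d": fit.params.d,
                        "a": fit.a,
                        "b": fit.b,
                        "sse": fit.sse,
                        "r": fit.r,
                        "converged": fit.converged,
                    }
                )
        log.info("fitted set %d/%d", k + 1, len(sim.gamma_sets))
    params_table = pd.DataFrame(rows)
    r_table = (
        params_table.groupby(["set", "ar_db"], as_index=False)["r"]
        .mean()
        .rename(columns={"r": "mean_r"})
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io._write_df(r_table, out / "r_vs_ar.csv", ",", cfg.seed, cfg.hash)
        io._write_df(params_table, out / "params_vs_ar.csv", ",", cfg.seed, cfg.hash)
    return r_table, params_table


# ---------------------------------------------------------------------------
# experimental-style pipeline
# ---------------------------------------------------------------------------

def _eeg_envelopes(cfg: RunConfig, eeg: dict[str, TimeSeries]) -> dict[str, TimeSeries]:
    pp = cfg.preprocess
    out = {}
    for name, ts in eeg.items():
        band = butterworth_filter(ts, pp.eeg_band, pp.eeg_order, "bandpass")
        imfs, residual = emd(band, max_imfs=1)
        imf1 = imfs[0] if imfs else residual
        out[name] = downsample(hilbert_envelope(imf1), pp.target_fs)
    return out


def _nirs_hbo(cfg: RunConfig) -> dict[str, TimeSeries]:
    pp = cfg.preprocess
    paths = cfg.paths
    if paths.nirs_kind == "hbo":
        return io.read_channel_table(paths.nirs, fs=paths.nirs_fs)
    channels, fs = io.read_nirs_intensity_table(paths.nirs, fs=paths.nirs_fs)
    out = {}
    for name, intensities in channels.items():
        # joint motion mask: a sample survives only if it passes Chauvenet's
        # criterion at every wavelength, keeping wavelengths aligned
        masks = []
        for w, vals in intensities.items():
            _, kept = chauvenet_clean(TimeSeries(vals, fs), pp.chauvenet_span)
            masks.append(kept)
        kept = np.logical_and.reduce(masks)
        if not kept.all():
            log.info("channel %s: Chauvenet removed %d samples", name, int((~kept).sum()))
        rec = RawNIRSRecord(
            {w: vals[kept] for w, vals in intensities.items()}, fs=fs, channel=name
        )
        hbo, _ = mbll(
            rec,
            lowpass_hz=pp.nirs_lowpass_hz,
            lowpass_order=pp.nirs_lowpass_order,
        )
        out[name] = hbo
    return out


def usable_onsets(onsets, records, pp: PreprocessConfig) -> list[float]:
    """Onsets whose full epoch window fits inside every given record."""
    usable = [
        on
        for on in onsets
        if all(
            on - pp.pre_s >= ts.t0
            and on + pp.stim_dur_s + pp.post_s <= ts.t0 + ts.duration
            for ts in records
        )
    ]
    if len(usable) < len(onsets):
        log.warning(
            "dropped %d onset(s) without a full epoch window", len(onsets) - len(usable)
        )
    return usable


def run_experimental_pipeline(cfg: RunConfig, out_dir: str | Path | None = None):
    """Full recorded-data analysis: preprocess, epoch, fit, cluster.

    Returns ``(fits, report, payload)`` where payload is the JSON-ready
    report dictionary. Intermediate tables are saved when ``out_dir`` is
    given.
    """
    paths = cfg.paths
    for label, p in (("eeg", paths.eeg), ("nirs", paths.nirs), ("events", paths.events)):
        if p is None or not Path(p).exists():
            raise ConfigError(f"required {label} file missing: {p}")

    pp = cfg.preprocess
    events = io.read_events_tsv(paths.events)
    eeg = io.read_channel_table(paths.eeg, fs=paths.eeg_fs)
    log.info("loaded %d EEG channels, %d events", len(eeg), len(events))

    envelopes = _eeg_envelopes(cfg, eeg)
    hbo_channels = _nirs_hbo(cfg)

    n_ref = len(next(iter(envelopes.values())))
    pulse_vals = np.zeros(n_ref)
    for onset, dur in zip(events["onset_s"], events["duration_s"]):
        i0 = int(round(onset * pp.target_fs))
        i1 = int(round((onset + dur) * pp.target_fs))
        pulse_vals[max(i0, 0) : min(i1, n_ref)] = 1.0
    pulse = TimeSeries(pulse_vals, pp.target_fs)

    eeg_ids, nirs_ids = select_channels(
        envelopes, hbo_channels, pulse, r_min=pp.r_min, hbo_min_um=pp.hbo_min_um
    )
    log.info("selected EEG channels %s, NIRS channels %s", eeg_ids, nirs_ids)

    fits = []
    epoch_counter = 0
    records = [envelopes[i] for i in eeg_ids] + [hbo_channels[i] for i in nirs_ids]
    onsets = usable_onsets(list(events["onset_s"]), records, pp)
    for eeg_id in eeg_ids:
        env_epochs = extract_epochs(
            envelopes[eeg_id], onsets, pp.stim_dur_s, pp.pre_s, pp.post_s
        )
        for nirs_id in nirs_ids:
            hbo_epochs = extract_epochs(
                hbo_channels[nirs_id], onsets, pp.stim_dur_s, pp.pre_s, pp.post_s
            )
            for idx, (ge, fe) in enumerate(zip(env_epochs, hbo_epochs)):
                pair = EpochPair(
                    envelope=smooth_normalize(ge, pp.smooth_window_s),
                    hbo=smooth_normalize(fe, pp.smooth_window_s),
                    stim_onset_s=float(onsets[idx]),
                    stim_dur_s=pp.stim_dur_s,
                    eeg_channel=eeg_id,
                    nirs_channel=nirs_id,
                    epoch_id=epoch_counter,
                )
                fits.append(fit_epoch(pair, cfg.grid))
                epoch_counter += 1
    log.info("fitted %d epoch pairs", len(fits))

    payload: dict = {"n_fits": len(fits)}
    report = None
    if len(fits) >= 2:
        fm = build_features(fits)
        tree = ward_linkage(fm)
        n_max = min(cfg.cluster.n_max, len(fits))
        report = significance_scan(
            tree,
            [f.r for f in fits],
            n_range=range(cfg.cluster.n_min, n_max + 1),
            alpha=cfg.cluster.alpha,
        )
        optimal = select_optimal(report)
        payload.update(_report_payload(report, optimal))
        if optimal is not None:
            labels = report.divisions[optimal].labels
            reps = representative_kernels(labels, fits, pp.target_fs)
            payload["representative_kernels"] = {
                str(k): {kk: vv for kk, vv in v.items() if kk != "kernel"}
                for k, v in reps.items()
            }
    else:
        log.warning("fewer than 2 fits; clustering skipped")
        payload["warning"] = "fewer than 2 fits; clustering skipped"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_fits_csv(out / "fits.csv", fits, cfg.seed, cfg.hash)
        io.write_report_json(out / "report.json", payload, cfg.seed, cfg.hash)
    return fits, report, payload


def _report_payload(report, optimal) -> dict:
    payload = {
        "alpha": report.alpha,
        "notes": list(report.notes),
        "optimal_division": optimal,
        "divisions": {},
    }
    for n, div in report.divisions.items():
        payload["divisions"][str(n)] = {
            "z_alpha": div.z_alpha,
            "n_significant": div.n_significant,
            "clusters": [
                {
                    "label": c.label,
                    "size": c.size,
                    "z_mean": c.z_mean,
                    "z_star": c.z_star,
                    "significant": c.significant,
                    "positive": c.positive,
                }
                for c in div.clusters
            ],
        }
    return payload
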