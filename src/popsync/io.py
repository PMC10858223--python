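"""On-disk formats and the pipeline driver.

Formats are deliberately plain: spikes as UTF-8 TSV (unit_id,
spike_time_s) with a waveform companion table and a JSON sidecar; LFP as
flat little-endian int16 channel-interleaved binary (the de-facto ephys
``.dat`` convention) with a JSON sidecar; intervals, trials, and traces
as TSV. All times are seconds on a 0-based session clock; intervals are
half-open ``[start, stop)``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EventIntervalSet,
    LFPRecording,
    PhotometryTrace,
    RespirationTrace,
    SpikeTrainSet,
    SpikeUnit,
    TrialTable,
)
from .errors import ConfigurationError, FormatError, InvalidInputError

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_lfp",
    "write_lfp",
    "read_intervals",
    "write_intervals",
    "read_trials",
    "write_trials",
    "read_trace",
    "write_trace",
    "run_pipeline",
]

FLOAT_FMT = "%.12g"


def _companions(path: Path) -> tuple[Path, Path]:
    return (
        path.with_name(path.stem + "_waveforms.tsv"),
        path.with_name(path.stem + "_meta.json"),
    )


def write_spikes(spikes: SpikeTrainSet, path) -> None:
    """Spike table TSV plus waveform companion and JSON sidecar."""
    path = Path(path)
    rows = [
        (u.unit_id, t) for u in spikes for t in u.spike_times
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "spike_time_s"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)

    wf_path, meta_path = _companions(path)
    wf_rows = []
    meta = {}
    for u in spikes:
        meta[u.unit_id] = dict(
            label=u.label,
            label_confidence=None if np.isnan(u.label_confidence) else u.label_confidence,
            features=list(u.features) if u.features else None,
            waveform_fs=u.waveform_fs,
            peak_channel=u.peak_channel,
        )
        if u.waveform is not None:
            for i, v in enumerate(u.waveform):
                wf_rows.append((u.unit_id, i, v))
    pd.DataFrame(wf_rows, columns=["unit_id", "sample_index", "value"]).to_csv(
        wf_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_spikes(path) -> SpikeTrainSet:
    """Read a spike table written by :func:`write_spikes`.

    A unit whose rows appear in two separate blocks (which silent merging
    would re-sort) is rejected, as are unsorted times within a unit.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "unit_id" not in df.columns or "spike_time_s" not in df.columns:
        raise FormatError("spike table needs unit_id and spike_time_s columns")
    wf_path, meta_path = _companions(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    waveforms = {}
    if wf_path.exists():
        wdf = pd.read_csv(wf_path, sep="\t")
        for uid, g in wdf.groupby("unit_id", sort=False):
            waveforms[str(uid)] = g.sort_values("sample_index")["value"].to_numpy()

    units = []
    seen = set()
    if len(df):
        block_ids = df["unit_id"].astype(str).to_numpy()
        change = np.r_[True, block_ids[1:] != block_ids[:-1]]
        starts = np.flatnonzero(change)
        stops = np.r_[starts[1:], block_ids.size]
        for s, e in zip(starts, stops):
            uid = block_ids[s]
            if uid in seen:
                raise InvalidInputError(f"duplicate unit_id block {uid!r}: rejected")
            seen.add(uid)
            t = df["spike_time_s"].to_numpy()[s:e]
            if np.any(np.diff(t) < 0):
                raise InvalidInputError(f"unit {uid!r}: spike times not sorted")
            m = meta.get(uid, {})
            conf = m.get("label_confidence")
            units.append(
                SpikeUnit(
                    unit_id=uid,
                    spike_times=t,
                    waveform=waveforms.get(uid),
                    waveform_fs=m.get("waveform_fs"),
                    features=tuple(m["features"]) if m.get("features") else None,
                    label=m.get("label", "unclassified"),
                    label_confidence=float("nan") if conf is None else conf,
                    peak_channel=m.get("peak_channel"),
                )
            )
    return SpikeTrainSet(units)


def write_lfp(rec: LFPRecording, dat_path, meta_path) -> None:
    """Little-endian int16 channel-interleaved frames + JSON sidecar."""
    dat_path, meta_path = Path(dat_path), Path(meta_path)
    data = np.asarray(rec.samples)
    if not np.issubdtype(data.dtype, np.integer):
        data = np.round(data).astype("<i2")
    else:
        data = data.astype("<i2")
    data.T.tofile(dat_path)  # frame-major: all channels of sample 0, then 1...
    meta = dict(
        fs=rec.fs,
        n_channels=rec.n_channels,
        channel_depths=list(map(float, rec.channel_depths)),
        channel_ids=list(rec.channel_ids),
        volts_per_unit=rec.volts_per_unit,
    )
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_lfp(dat_path, meta_path) -> LFPRecording:
    dat_path, meta_path = Path(dat_path), Path(meta_path)
    try:
        meta = json.loads(meta_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read LFP sidecar: {exc}") from exc
    for key in ("fs", "n_channels"):
        if key not in meta:
            raise FormatError(f"LFP sidecar missing {key!r}")
    raw = np.fromfile(dat_path, dtype="<i2")
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch != 0:
        raise FormatError(
            f"binary length {raw.size} not divisible by n_channels={n_ch}"
        )
    samples = raw.reshape(-1, n_ch).T
    return LFPRecording(
        samples=samples,
        fs=float(meta["fs"]),
        channel_depths=np.asarray(meta.get("channel_depths", range(n_ch)), dtype=float),
        channel_ids=meta.get("channel_ids"),
        volts_per_unit=float(meta.get("volts_per_unit", 1.0)),
    )


def write_intervals(events: EventIntervalSet, path) -> None:
    df = pd.DataFrame(
        dict(start_s=events.starts, stop_s=events.stops, label=events.label)
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_intervals(path) -> EventIntervalSet:
    df = pd.read_csv(path, sep="\t")
    for col in ("start_s", "stop_s"):
        if col not in df.columns:
            raise FormatError(f"interval table missing {col!r}")
    label = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else "custom"
    return EventIntervalSet(df[["start_s", "stop_s"]].to_numpy(), label=label)


def write_trials(trials: TrialTable, path) -> None:
    df = trials.df.rename(columns={"onset": "onset_s", "offset": "offset_s"})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_trials(path) -> TrialTable:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"onset_s": "onset", "offset_s": "offset"})
    for col in ("onset", "offset", "concentration"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    if "is_control" in df.columns:
        df["is_control"] = df["is_control"].astype(bool)
    return TrialTable(df)


def write_trace(values: np.ndarray, fs: float, path, column: str = "value") -> None:
    """Single-channel trace as one-column TSV with fs in a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({column: np.asarray(values)}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    path.with_suffix(".json").write_text(json.dumps(dict(fs=fs, column=column)))


def read_trace(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    try:
        meta = json.loads(path.with_suffix(".json").read_text())
    except OSError as exc:
        raise FormatError(f"missing trace sidecar for {path}") from exc
    df = pd.read_csv(path, sep="\t")
    return df[meta["column"]].to_numpy(dtype=float), float(meta["fs"])


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: dict, out_dir) -> dict:
    """Chain analysis stages over one session and write results + a log.

    ``config`` keys:

    - ``seed``: master seed (default 0).
    - ``synth``: parameters for a generated session, with ``kind`` in
      {"baseline", "odor", "photometry", "laminar"}; or
    - ``inputs``: paths to on-disk data (``spikes``, ``lfp`` as
      ``[dat, meta]``, ``epochs``, ``trials``, ``respiration``).
    - ``stages``: ordered list among {"popevents", "ccg", "bands", "csd"}.
    - ``params``: optional per-stage parameter overrides.

    Outputs (TSV + ``log.json`` recording every parameter) are
    deterministic given the config and seed. Any stage failure raises
    :class:`ConfigurationError` naming the stage.
    """
    from . import lfp as lfpmod
    from . import paircorr, popevents, synth, unitclass

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = config.get("params", {})
    log = dict(seed=seed, stages={}, config=config)

    spikes = lfp = epochs = None
    duration = config.get("duration")

    if "synth" in config:
        sconf = dict(config["synth"])
        kind = sconf.pop("kind", "baseline")
        if kind == "baseline":
            session = synth.gen_spike_session(seed=seed, **sconf)
            spikes = session.spikes
            duration = session.duration
        elif kind == "odor":
            session = synth.gen_odor_session(seed=seed, **sconf)
            spikes = session.spikes
            duration = session.duration
        elif kind == "laminar":
            lfp = synth.gen_laminar_lfp(seed=seed, **sconf)
            duration = lfp.duration
        else:
            raise ConfigurationError(f"unknown synth kind {kind!r}")
        log["synth"] = dict(kind=kind, **sconf)
    elif "inputs" in config:
        inputs = config["inputs"]
        if "spikes" in inputs:
            spikes = read_spikes(inputs["spikes"])
        if "lfp" in inputs:
            lfp = read_lfp(*inputs["lfp"])
            duration = duration or lfp.duration
        if "epochs" in inputs:
            epochs = read_intervals(inputs["epochs"])
    if duration is None and spikes is not None:
        duration = float(
            np.ceil(max((u.spike_times[-1] for u in spikes if u.n_spikes), default=1.0))
        )
    if epochs is None and duration is not None:
        epochs = EventIntervalSet([[0.0, duration]], label="wake")

    results = {}
    for stage in config.get("stages", []):
        p = dict(params.get(stage, {}))
        try:
            if stage == "popevents":
                if spikes is None:
                    raise ConfigurationError("no spike data for popevents")
                pp = popevents.PopEventParams(**p)
                e_units = spikes.select("E")
                rate = popevents.pooled_rate(e_units, duration, pp)
                events = popevents.detect_popevents(rate, epochs, pp)
                write_intervals(events, out_dir / "popevents.tsv")
                ev_rate, pct_t, pct_s = popevents.popevent_stats(
                    events, epochs, e_units
                )
                results[stage] = dict(
                    n_events=len(events), rate=ev_rate,
                    pct_time=pct_t, pct_spikes=pct_s,
                )
                log["stages"][stage] = events.params
            elif stage == "ccg":
                if spikes is None:
                    raise ConfigurationError("no spike data for ccg")
                max_pairs = p.pop("max_pairs", 30)
                kept = unitclass.filter_min_rate(spikes.select("E"), epochs)
                rows = []
                ids = kept.unit_ids
                for i in range(len(ids)):
                    for j in range(i + 1, len(ids)):
                        if len(rows) >= max_pairs:
                            break
                        ccg = paircorr.compute_ccg(
                            kept[ids[i]].spike_times,
                            kept[ids[j]].spike_times,
                            epochs,
                        )
                        rows.append(
                            dict(
                                ref=ids[i], target=ids[j],
                                peak_integral=paircorr.ccg_peak_integral(ccg),
                            )
                        )
                pd.DataFrame(rows).to_csv(
                    out_dir / "ccg_integrals.tsv", sep="\t", index=False,
                    float_format=FLOAT_FMT,
                )
                results[stage] = dict(
                    n_pairs=len(rows),
                    mean_peak_integral=float(
                        np.mean([r["peak_integral"] for r in rows]) if rows else np.nan
                    ),
                )
                log["stages"][stage] = dict(max_pairs=max_pairs, n_pairs=len(rows))
            elif stage == "bands":
                if lfp is None:
                    raise ConfigurationError("no LFP data for bands")
                channel = p.pop("channel", 0)
                rows = []
                for band in p.pop("bands", list(lfpmod.BANDS)):
                    dec = lfpmod.wavelet_band(lfp.samples[channel], lfp.fs, band)
                    rows.append(
                        dict(band=band, mean_amplitude=float(dec.amplitude.mean()))
                    )
                pd.DataFrame(rows).to_csv(
                    out_dir / "band_amplitude.tsv", sep="\t", index=False,
                    float_format=FLOAT_FMT,
                )
                results[stage] = {r["band"]: r["mean_amplitude"] for r in rows}
                log["stages"][stage] = dict(channel=channel)
            elif stage == "csd":
                if lfp is None:
                    raise ConfigurationError("no LFP data for csd")
                channel = p.pop("channel", 0)
                dec = lfpmod.wavelet_band(lfp.samples[channel], lfp.fs, "gamma")
                _, troughs = lfpmod.detect_gamma_epochs(dec)
                if troughs.size == 0:
                    raise ConfigurationError("no gamma epochs for CSD alignment")
                csd = lfpmod.compute_csd(lfp, troughs, **p)
                pd.DataFrame(
                    csd.values,
                    index=[f"ch{c}" for c in csd.channels],
                    columns=[FLOAT_FMT % lag for lag in csd.lags],
                ).to_csv(out_dir / "csd.tsv", sep="\t", float_format=FLOAT_FMT)
                results[stage] = dict(n_alignments=csd.n_alignments)
                log["stages"][stage] = dict(
                    channel=channel, sign_convention=csd.sign_convention
                )
            else:
                raise ConfigurationError(f"unknown stage {stage!r}")
        except ConfigurationError:
            raise
        except Exception as exc:
            raise ConfigurationError(f"stage {stage!r} failed: {exc}") from exc

    log["results"] = results
    (out_dir / "log.json").write_text(json.dumps(log, indent=1, sort_keys=True,
                                                 default=str))
    return results
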