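"""Trial-structured multichannel recordings: data model, file I/O, selection.

The universal container is :class:`TrialSet`, holding an ``(R, P, T)`` float64
array of R trials x P channels x T samples together with the sampling rate and
per-channel / per-trial metadata.  Channels carry a CA1 region label
(proximal or distal); trials carry the odor identity (A-E), whether the odor
was presented in or out of the memorized sequence, and whether the animal's
response was correct.

Two on-disk layouts are supported:

* ``csv_long`` -- a directory with ``data.csv`` (columns ``trial_id,
  channel_id, sample_index, value``), ``trials.csv``, ``channels.csv`` and a
  small ``config.yaml`` declaring the sampling rate.
* ``hdf5`` -- a single file with datasets ``/data`` (R x P x T float64),
  ``/fs`` (scalar) and string tables ``/trials`` and ``/channels``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConsistencyError, FormatError, ValidationError

ODORS = ("A", "B", "C", "D", "E")
REGIONS = ("proximal", "distal")
SEQUENCES = ("in", "out")
RESPONSES = ("correct", "incorrect")

#: Per-subject trial bookkeeping of the five-odor sequence-memory experiment:
#: (tetrode count, in-sequence correct, in-sequence incorrect,
#:  out-of-sequence correct, out-of-sequence incorrect).
TABLE1 = {
    "Barat": (22, 154, 1, 11, 10),
    "Buchanan": (20, 203, 23, 29, 15),
    "Mitt": (22, 230, 32, 16, 14),
    "Stella": (21, 176, 18, 23, 5),
    "Superchris": (21, 190, 20, 26, 4),
}


@dataclass(frozen=True)
class ChannelInfo:
    """One tetrode channel: identity, CA1 region, optional planar coordinates."""

    channel_id: str
    region: str
    x: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"channel {self.channel_id!r}: region must be one of {REGIONS}, "
                f"got {self.region!r}"
            )


@dataclass(frozen=True)
class TrialInfo:
    """One trial's labels: odor A-E, in/out-of-sequence, correct/incorrect."""

    trial_id: str
    odor: str
    sequence: str
    response: str

    def __post_init__(self) -> None:
        if self.odor not in ODORS:
            raise ValidationError(f"trial {self.trial_id!r}: unknown odor {self.odor!r}")
        if self.sequence not in SEQUENCES:
            raise ValidationError(
                f"trial {self.trial_id!r}: sequence must be 'in' or 'out', got {self.sequence!r}"
            )
        if self.response not in RESPONSES:
            raise ValidationError(
                f"trial {self.trial_id!r}: response must be 'correct' or 'incorrect', "
                f"got {self.response!r}"
            )


@dataclass
class TrialSet:
    """R trials x P channels x T samples of LFP-like data with metadata.

    Samples are stored in 64-bit floating point, nominally in microvolts.
    Per-trial mean removal is *not* performed here; estimators that assume
    zero-mean series demean explicitly.
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo] = field(default_factory=list)
    trials: list[TrialInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(f"data must be (R, P, T), got shape {self.data.shape}")
        r, p, t = self.data.shape
        if r > 0 and t < 2:
            raise ValidationError(f"need T >= 2 samples, got T={t}")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channels) != p:
            raise ConsistencyError(
                f"channel table has {len(self.channels)} rows but data has {p} channels"
            )
        if len(self.trials) != r:
            raise ConsistencyError(
                f"trial table has {len(self.trials)} rows but data has {r} trials"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("channel_id values must be unique")
        tids = [tr.trial_id for tr in self.trials]
        if len(set(tids)) != len(tids):
            raise ValidationError("trial_id values must be unique")
        bad = ~np.isfinite(self.data)
        if bad.any():
            rr, pp, _ = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite sample in trial {self.trials[rr].trial_id!r}, "
                f"channel {self.channels[pp].channel_id!r}"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return i
        raise KeyError(channel_id)

    def region_indices(self, region: str) -> list[int]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return [i for i, c in enumerate(self.channels) if c.region == region]


def select_trials(
    ts: TrialSet,
    odor: set[str] | str | None = None,
    sequence: str | None = None,
    response: str | None = None,
) -> TrialSet:
    """Subset trials by label, combining filters with logical AND.

    An empty result is a valid (R=0) TrialSet, not an error.  Trial order is
    preserved; the operation is idempotent for a fixed filter.
    """
    if odor is not None:
        odors = {odor} if isinstance(odor, str) else set(odor)
        unknown = odors - set(ODORS)
        if unknown:
            raise ValueError(f"unknown odor label(s): {sorted(unknown)}")
    else:
        odors = None
    if sequence is not None and sequence not in SEQUENCES:
        raise ValueError(f"sequence must be 'in' or 'out', got {sequence!r}")
    if response is not None and response not in RESPONSES:
        raise ValueError(f"response must be 'correct' or 'incorrect', got {response!r}")

    keep = [
        i
        for i, tr in enumerate(ts.trials)
        if (odors is None or tr.odor in odors)
        and (sequence is None or tr.sequence == sequence)
        and (response is None or tr.response == response)
    ]
    return TrialSet(
        data=ts.data[keep] if keep else np.empty((0, ts.n_channels, ts.n_samples)),
        fs=ts.fs,
        channels=list(ts.channels),
        trials=[ts.trials[i] for i in keep],
    )


def table1_trialinfos(subject: str) -> list[TrialInfo]:
    """Trial labels matching the printed per-subject counts of the experiment.

    The source table stratifies by sequence condition and response only;
    odor identities are assigned round-robin over A-E within each stratum.
    """
    if subject not in TABLE1:
        raise ValueError(f"unknown subject {subject!r}; known: {sorted(TABLE1)}")
    _, in_c, in_i, out_c, out_i = TABLE1[subject]
    infos: list[TrialInfo] = []
    k = 0
    for n, seq, resp in (
        (in_c, "in", "correct"),
        (in_i, "in", "incorrect"),
        (out_c, "out", "correct"),
        (out_i, "out", "incorrect"),
    ):
        for j in range(n):
            infos.append(TrialInfo(f"trial{k:04d}", ODORS[j % 5], seq, resp))
            k += 1
    return infos


def table1_success_rates(subject: str) -> tuple[float, float]:
    """(in-sequence, out-of-sequence) percent-correct rates for a subject."""
    _, in_c, in_i, out_c, out_i = TABLE1[subject]
    return 100.0 * in_c / (in_c + in_i), 100.0 * out_c / (out_c + out_i)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMATS = ("csv_long", "hdf5")


def write_trialset(ts: TrialSet, path: str, format: str = "hdf5") -> str:
    """Write a TrialSet to disk in the declared layout; returns the path."""
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if format == "hdf5":
        _write_hdf5(ts, path)
    else:
        _write_csv_long(ts, path)
    return path


def read_trialset(path: str, format: str = "hdf5") -> TrialSet:
    """Read and validate a TrialSet from the declared on-disk layout."""
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if format == "hdf5":
        return _read_hdf5(path)
    return _read_csv_long(path)


def _write_hdf5(ts: TrialSet, path: str) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    trial_dt = np.dtype(
        [("trial_id", str_dt), ("odor", str_dt), ("sequence", str_dt), ("response", str_dt)]
    )
    chan_dt = np.dtype(
        [("channel_id", str_dt), ("region", str_dt), ("x", "f8"), ("y", "f8")]
    )
    trials = np.array(
        [(t.trial_id, t.odor, t.sequence, t.response) for t in ts.trials], dtype=trial_dt
    )
    chans = np.array(
        [
            (c.channel_id, c.region, np.nan if c.x is None else c.x, np.nan if c.y is None else c.y)
            for c in ts.channels
        ],
        dtype=chan_dt,
    )
    # track_times=False keeps repeated writes byte-identical
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data, track_times=False)
        f.create_dataset("fs", data=float(ts.fs), track_times=False)
        f.create_dataset("trials", data=trials, track_times=False)
        f.create_dataset("channels", data=chans, track_times=False)


def _read_hdf5(path: str) -> TrialSet:
    with h5py.File(path, "r") as f:
        for name in ("data", "fs", "trials", "channels"):
            if name not in f:
                raise FormatError(f"HDF5 container missing dataset '/{name}'")
        data = np.asarray(f["data"], dtype=np.float64)
        fs = float(f["fs"][()])
        traw = f["trials"][()]
        craw = f["channels"][()]

    def _s(v) -> str:
        return v.decode() if isinstance(v, bytes) else str(v)

    trials = [
        TrialInfo(_s(t["trial_id"]), _s(t["odor"]), _s(t["sequence"]), _s(t["response"]))
        for t in traw
    ]
    channels = [
        ChannelInfo(
            _s(c["channel_id"]),
            _s(c["region"]),
            None if np.isnan(c["x"]) else float(c["x"]),
            None if np.isnan(c["y"]) else float(c["y"]),
        )
        for c in craw
    ]
    return TrialSet(data=data, fs=fs, channels=channels, trials=trials)


def _write_csv_long(ts: TrialSet, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    r, p, t = ts.data.shape
    if r * p * t:
        tid = np.repeat([tr.trial_id for tr in ts.trials], p * t)
        cid = np.tile(np.repeat([c.channel_id for c in ts.channels], t), r)
        idx = np.tile(np.arange(t), r * p)
        long = pd.DataFrame(
            {"trial_id": tid, "channel_id": cid, "sample_index": idx,
             "value": ts.data.ravel()}
        )
    else:
        long = pd.DataFrame(columns=["trial_id", "channel_id", "sample_index", "value"])
    long.to_csv(os.path.join(path, "data.csv"), index=False)
    pd.DataFrame(
        [(tr.trial_id, tr.odor, tr.sequence, tr.response) for tr in ts.trials],
        columns=["trial_id", "odor", "sequence", "response"],
    ).to_csv(os.path.join(path, "trials.csv"), index=False)
    pd.DataFrame(
        [(c.channel_id, c.region, c.x, c.y) for c in ts.channels],
        columns=["channel_id", "region", "x", "y"],
    ).to_csv(os.path.join(path, "channels.csv"), index=False)
    with open(os.path.join(path, "config.yaml"), "w") as fh:
        yaml.safe_dump({"fs": float(ts.fs), "n_samples": int(t)}, fh)


def _read_csv_long(path: str) -> TrialSet:
    for name in ("data.csv", "trials.csv", "channels.csv", "config.yaml"):
        if not os.path.exists(os.path.join(path, name)):
            raise FormatError(f"csv_long layout missing file {name!r} in {path}")
    with open(os.path.join(path, "config.yaml")) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "fs" not in cfg:
        raise FormatError("config.yaml must declare the field 'fs'")
    fs = float(cfg["fs"])
    tdf = pd.read_csv(os.path.join(path, "trials.csv"), dtype=str)
    cdf = pd.read_csv(os.path.join(path, "channels.csv"))
    for col in ("trial_id", "odor", "sequence", "response"):
        if col not in tdf.columns:
            raise FormatError(f"trials.csv missing column {col!r}")
    for col in ("channel_id", "region"):
        if col not in cdf.columns:
            raise FormatError(f"channels.csv missing column {col!r}")
    trials = [
        TrialInfo(row.trial_id, row.odor, row.sequence, row.response)
        for row in tdf.itertuples()
    ]
    channels = [
        ChannelInfo(
            str(row.channel_id),
            str(row.region),
            None if pd.isna(getattr(row, "x", np.nan)) else float(row.x),
            None if pd.isna(getattr(row, "y", np.nan)) else float(row.y),
        )
        for row in cdf.itertuples()
    ]
    ddf = pd.read_csv(os.path.join(path, "data.csv"))
    for col in ("trial_id", "channel_id", "sample_index", "value"):
        if col not in ddf.columns:
            raise FormatError(f"data.csv missing column {col!r}")
    r, p = len(trials), len(channels)
    if len(ddf) == 0:
        t = int(cfg.get("n_samples", 0))
        if r > 0:
            raise ConsistencyError("data.csv is empty but trials.csv declares trials")
        return TrialSet(np.empty((0, p, max(t, 0))), fs, channels, trials)
    t = int(ddf["sample_index"].max()) + 1
    if len(ddf) != r * p * t:
        raise ConsistencyError(
            f"data.csv has {len(ddf)} rows; expected R*P*T = {r}*{p}*{t} = {r * p * t}"
        )
    trial_pos = {tr.trial_id: i for i, tr in enumerate(trials)}
    chan_pos = {c.channel_id: i for i, c in enumerate(channels)}
    data = np.full((r, p, t), np.nan)
    try:
        ti = ddf["trial_id"].astype(str).map(trial_pos).to_numpy()
        ci = ddf["channel_id"].astype(str).map(chan_pos).to_numpy()
    except KeyError as e:  # pragma: no cover - mapping returns NaN instead
        raise ConsistencyError(f"unknown id in data.csv: {e}") from e
    if np.isnan(ti).any() or np.isnan(ci).any():
        raise ConsistencyError("data.csv references ids absent from the metadata tables")
    data[ti.astype(int), ci.astype(int), ddf["sample_index"].to_numpy()] = (
        ddf["value"].astype(np.float64).to_numpy()
    )
    return TrialSet(data=data, fs=fs, channels=channels, trials=trials)
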