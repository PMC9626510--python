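"""Readers and writers: HDF5 session/epoch containers, CSV schedules,
a minimal EDF exporter/importer, model checkpoints, and JSON reports.

All HDF5 artifacts carry a ``schema`` attribute (``name/major.minor``);
readers reject unknown names and newer majors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import META_DTYPE, EpochSet
from .simulate import EVENT_DTYPE, EEGSession, StimulusSchedule

__all__ = [
    "write_session", "read_session", "write_epochs", "read_epochs",
    "schedule_to_csv", "schedule_from_csv", "write_edf", "read_edf",
    "save_checkpoint", "load_checkpoint", "write_report",
]

SESSION_SCHEMA = "arp300-session/1.0"
EPOCHS_SCHEMA = "arp300-epochs/1.0"


def _check_schema(found: str, expected: str, path) -> None:
    name, _, ver = expected.partition("/")
    fname, _, fver = str(found).partition("/")
    if fname != name:
        raise ValueError(f"{path}: unrecognised schema {found!r}, expected {name!r}")
    if int(fver.split(".")[0]) > int(ver.split(".")[0]):
        raise ValueError(
            f"{path}: schema {found!r} is newer than supported {expected!r}"
        )


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def write_session(session: EEGSession, path) -> None:
    import h5py

    sched = session.schedule
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SESSION_SCHEMA
        f.attrs["sampling_rate_hz"] = session.sampling_rate_hz
        f.attrs["environment"] = session.environment
        f.attrs["channel_names"] = [str(c) for c in session.channel_names]
        if session.seed is not None:
            f.attrs["seed"] = session.seed
        f.create_dataset("eeg", data=session.data.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("events", data=sched.events)
        g = f.create_group("schedule")
        for k in ("n_stimuli", "soa_ms", "flash_ms", "prep_ms", "lock_ms"):
            g.attrs[k] = getattr(sched, k)
        tb = np.array(sorted(sched.target_of_block.items()), dtype=np.int64)
        g.create_dataset("target_of_block", data=tb)


def read_session(path) -> EEGSession:
    import h5py

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise ValueError(f"{path}: not a readable HDF5 session file ({e})") from e
    with f:
        _check_schema(f.attrs.get("schema", "?"), SESSION_SCHEMA, path)
        g = f["schedule"]
        events = np.asarray(f["events"][...], dtype=EVENT_DTYPE)
        sched = StimulusSchedule(
            events=events,
            n_stimuli=int(g.attrs["n_stimuli"]),
            soa_ms=int(g.attrs["soa_ms"]),
            flash_ms=int(g.attrs["flash_ms"]),
            prep_ms=int(g.attrs["prep_ms"]),
            lock_ms=int(g.attrs["lock_ms"]),
            target_of_block={int(b): int(s) for b, s in g["target_of_block"][...]},
        )
        return EEGSession(
            data=f["eeg"][...],
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            schedule=sched,
            environment=str(f.attrs.get("environment", "ar")),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def write_epochs(epochs: EpochSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema"] = EPOCHS_SCHEMA
        f.attrs["sampling_rate_hz"] = epochs.sampling_rate_hz
        if epochs.channel_names is not None:
            f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
        f.create_dataset("epochs", data=epochs.tensor.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=np.asarray(epochs.labels, dtype=np.int64))
        f.create_dataset("meta", data=epochs.meta)


def read_epochs(path) -> EpochSet:
    import h5py

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise ValueError(f"{path}: not a readable HDF5 epochs file ({e})") from e
    with f:
        _check_schema(f.attrs.get("schema", "?"), EPOCHS_SCHEMA, path)
        names = f.attrs.get("channel_names")
        return EpochSet(
            tensor=f["epochs"][...],
            labels=f["labels"][...],
            meta=np.asarray(f["meta"][...], dtype=META_DTYPE),
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            channel_names=[str(c) for c in names] if names is not None else None,
        )


def epochs_meta_to_csv(epochs: EpochSet, path) -> None:
    df = pd.DataFrame({name: epochs.meta[name] for name in META_DTYPE.names})
    df["label"] = epochs.labels
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Schedule CSV
# ---------------------------------------------------------------------------

def schedule_to_csv(schedule: StimulusSchedule, path) -> None:
    df = pd.DataFrame({name: schedule.events[name] for name in EVENT_DTYPE.names})
    df["target_of_block"] = [schedule.target_of_block[int(b)] for b in df["block"]]
    with open(path, "w") as fh:
        fh.write(
            f"# n_stimuli={schedule.n_stimuli},soa_ms={schedule.soa_ms},"
            f"flash_ms={schedule.flash_ms},prep_ms={schedule.prep_ms},"
            f"lock_ms={schedule.lock_ms}\n"
        )
        df.to_csv(fh, index=False)


def schedule_from_csv(path) -> StimulusSchedule:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing schedule parameter header line")
        params = dict(kv.split("=") for kv in header[1:].strip().split(","))
        df = pd.read_csv(fh)
    events = np.empty(len(df), dtype=EVENT_DTYPE)
    for name in EVENT_DTYPE.names:
        events[name] = df[name].to_numpy()
    tob = {int(b): int(s) for b, s in
           df[["block", "target_of_block"]].drop_duplicates().to_numpy()}
    return StimulusSchedule(
        events=events,
        n_stimuli=int(params["n_stimuli"]),
        soa_ms=int(params["soa_ms"]),
        flash_ms=int(params["flash_ms"]),
        prep_ms=int(params["prep_ms"]),
        lock_ms=int(params["lock_ms"]),
        target_of_block=tob,
    )


# ---------------------------------------------------------------------------
# Minimal EDF (16-bit, one data record per second, no annotations)
# ---------------------------------------------------------------------------

def write_edf(path, data: np.ndarray, sampling_rate_hz: float,
              channel_names: list[str]) -> None:
    """Export continuous data (channels x samples, microvolt) as plain EDF."""
    data = np.asarray(data, dtype=float)
    ns_ch, n_samp = data.shape
    fs = int(round(sampling_rate_hz))
    if fs != sampling_rate_hz:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((ns_ch, n_rec * fs))
    padded[:, :n_samp] = data

    pmin = np.floor(padded.min(axis=1))
    pmax = np.ceil(padded.max(axis=1))
    pmax = np.where(pmax > pmin, pmax, pmin + 1.0)
    dmin, dmax = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    with open(path, "wb") as fh:
        fh.write(pad("0", 8))
        fh.write(pad("X X X X", 80))  # local patient id (anonymous)
        fh.write(pad("Startdate X X X X", 80))
        fh.write(pad("01.01.00", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(str(256 * (1 + ns_ch)), 8))
        fh.write(pad("", 44))
        fh.write(pad(str(n_rec), 8))
        fh.write(pad("1", 8))  # record duration, seconds
        fh.write(pad(str(ns_ch), 4))
        for name in channel_names:
            fh.write(pad(name, 16))
        for _ in channel_names:
            fh.write(pad("AgAgCl electrode", 80))
        for _ in channel_names:
            fh.write(pad("uV", 8))
        for v in pmin:
            fh.write(pad(f"{v:g}", 8))
        for v in pmax:
            fh.write(pad(f"{v:g}", 8))
        fh.write(pad(str(dmin), 8) * ns_ch)
        fh.write(pad(str(dmax), 8) * ns_ch)
        for _ in channel_names:
            fh.write(pad("", 80))  # prefiltering
        fh.write(pad(str(fs), 8) * ns_ch)
        fh.write(pad("", 32) * ns_ch)

        scale = (dmax - dmin) / (pmax - pmin)
        for r in range(n_rec):
            chunk = padded[:, r * fs:(r + 1) * fs]
            dig = np.round((chunk - pmin[:, None]) * scale[:, None] + dmin)
            dig = np.clip(dig, dmin, dmax).astype("<i2")
            fh.write(dig.tobytes())


def read_edf(path):
    """Read a plain EDF file; returns (data uV, sampling_rate_hz, channel_names).

    Supports the subset written by :func:`write_edf` (equal per-channel
    rates, 1 s records, no annotation channel).
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_rec = int(header[236:244].decode().strip())
        dur = float(header[244:252].decode().strip())
        ns_ch = int(header[252:256].decode().strip())
        sig = fh.read(256 * ns_ch)
        if len(sig) < 256 * ns_ch:
            raise ValueError(f"{path}: truncated EDF signal header")

        # field layout: label 16, transducer 80, dim 8, pmin 8, pmax 8,
        # dmin 8, dmax 8, prefilter 80, n-samples 8, reserved 32
        sizes = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        cuts = np.cumsum([0] + sizes)

        def col(i, w):
            base = cuts[i] * ns_ch
            return [sig[base + j * w: base + (j + 1) * w].decode().strip()
                    for j in range(ns_ch)]
        labels = col(0, 16)
        pmin = np.array([float(v) for v in col(3, 8)])
        pmax = np.array([float(v) for v in col(4, 8)])
        dmin = np.array([float(v) for v in col(5, 8)])
        dmax = np.array([float(v) for v in col(6, 8)])
        nsamp = np.array([int(v) for v in col(8, 8)])
        if len(set(nsamp)) != 1:
            raise ValueError(f"{path}: per-channel sampling rates differ")
        fs = nsamp[0] / dur
        raw = fh.read(2 * n_rec * int(nsamp.sum()))
        need = 2 * n_rec * int(nsamp.sum())
        if len(raw) < need:
            raise ValueError(f"{path}: truncated EDF data records")
        dig = np.frombuffer(raw, dtype="<i2").reshape(n_rec, ns_ch, nsamp[0])
        dig = np.moveaxis(dig, 1, 0).reshape(ns_ch, -1).astype(float)
        scale = (pmax - pmin) / (dmax - dmin)
        data = (dig - dmin[:, None]) * scale[:, None] + pmin[:, None]
        return data, float(fs), labels


# ---------------------------------------------------------------------------
# Model checkpoints (npz with a JSON manifest)
# ---------------------------------------------------------------------------

CKPT_SCHEMA = "arp300-model/1.0"


def save_checkpoint(scorer, path) -> None:
    """Serialise a NetScorer or BaselineScorer with its configuration."""
    from .baselines import BaselineScorer
    from .sepcnn import NetScorer

    arrays = {}
    if isinstance(scorer, NetScorer):
        manifest = {
            "schema": CKPT_SCHEMA,
            "kind": "net",
            "variant": scorer.spec.variant,
            "config": {
                "input_len": scorer.spec.config.input_len,
                "n_channels": scorer.spec.config.n_channels,
                "depth_kernel": scorer.spec.config.depth_kernel,
                "stride": scorer.spec.config.stride,
                "padding": scorer.spec.config.padding,
                "n_pointwise": scorer.spec.config.n_pointwise,
            },
        }
        for i, a in enumerate(scorer.net.state()):
            arrays[f"state_{i}"] = a
    elif isinstance(scorer, BaselineScorer):
        manifest = {
            "schema": CKPT_SCHEMA,
            "kind": "baseline",
            "method": scorer.method,
            "hyper": {k: v for k, v in scorer.linear.hyper.items()
                      if isinstance(v, (int, float, str, bool))},
        }
        arrays["weights"] = scorer.linear.weights
        arrays["bias"] = np.array([scorer.linear.bias])
        arrays["mean"] = scorer._mean
        arrays["std"] = scorer._std
    else:
        raise TypeError(f"cannot checkpoint {type(scorer).__name__}")
    np.savez(path, manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    from .baselines import BaselineScorer, LinearScorer
    from .sepcnn import NetScorer, SepCNNConfig, build_sepcnn, build_standard_cnn, instantiate

    with np.load(path) as z:
        manifest = json.loads(bytes(z["manifest"].tobytes()).decode())
        _check_schema(manifest.get("schema", "?"), CKPT_SCHEMA, path)
        if manifest["kind"] == "net":
            config = SepCNNConfig(**manifest["config"])
            spec = (build_sepcnn(config) if manifest["variant"] == "sepcnn"
                    else build_standard_cnn(config))
            net = instantiate(spec, np.random.default_rng(0))
            state = [z[f"state_{i}"] for i in range(len([k for k in z.files
                                                         if k.startswith("state_")]))]
            net.load_state(state)
            return NetScorer(spec, net)
        scorer = BaselineScorer(manifest["method"], manifest.get("hyper", {}))
        scorer.linear = LinearScorer(z["weights"], float(z["bias"][0]),
                                     manifest["method"], manifest.get("hyper", {}))
        scorer._mean = z["mean"]
        scorer._std = z["std"]
        return scorer


def write_report(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
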