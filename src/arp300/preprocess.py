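"""Continuous session -> classifier-ready epoch tensors.

Pipeline: drop the mastoid channels, zero-phase 0.1-12 Hz band-pass,
extract 600 ms post-flash epochs, decimate by 3 to 200 samples, and
optionally average repeated trials of the same (run, block, stimulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .simulate import EEGSession

__all__ = ["EpochSet", "drop_channels", "bandpass", "extract_epochs",
           "downsample_epochs", "average_repetitions", "preprocess_session"]

META_DTYPE = np.dtype(
    [
        ("run", np.int64),
        ("block", np.int64),
        ("trial", np.int64),
        ("stimulus", np.int64),
    ]
)


@dataclass
class EpochSet:
    """Epoch tensor (epochs x time x channels) with labels and trial metadata."""

    tensor: np.ndarray
    labels: np.ndarray  # 1 = flash of the attended stimulus
    meta: np.ndarray  # structured, META_DTYPE
    sampling_rate_hz: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor)
        self.labels = np.asarray(self.labels)
        self.meta = np.asarray(self.meta)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be epochs x time x channels")
        n = self.tensor.shape[0]
        if len(self.labels) != n or len(self.meta) != n:
            raise ValueError("labels/meta length must equal epoch count")
        if self.channel_names is not None and len(self.channel_names) != self.tensor.shape[2]:
            raise ValueError("channel_names length must match channel dimension")

    @property
    def n_epochs(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[2]

    def subset(self, index: np.ndarray) -> "EpochSet":
        return replace(
            self,
            tensor=self.tensor[index],
            labels=self.labels[index],
            meta=self.meta[index],
        )


def drop_channels(session: EEGSession, names: list[str] = ("A1", "A2")) -> EEGSession:
    """Remove named channels (reference/mastoid), preserving the rest in order."""
    names = list(names)
    missing = [n for n in names if n not in session.channel_names]
    if missing:
        raise ValueError(
            f"unknown channel(s) {missing}; available: {session.channel_names}"
        )
    keep = [i for i, n in enumerate(session.channel_names) if n not in names]
    return EEGSession(
        data=session.data[keep],
        sampling_rate_hz=session.sampling_rate_hz,
        channel_names=[session.channel_names[i] for i in keep],
        schedule=session.schedule,
        environment=session.environment,
        seed=session.seed,
    )


def bandpass(session: EEGSession, lo_hz: float = 0.1, hi_hz: float = 12.0,
             order: int = 4) -> EEGSession:
    """Zero-phase Butterworth band-pass (forward-backward, per channel)."""
    nyq = session.sampling_rate_hz / 2.0
    if not 0 < lo_hz < hi_hz < nyq:
        raise ValueError(
            f"invalid band [{lo_hz}, {hi_hz}] Hz for Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass",
                        fs=session.sampling_rate_hz, output="sos")
    out = np.empty_like(session.data, dtype=np.float32)
    for c in range(session.n_channels):  # channel-wise keeps peak memory low
        out[c] = signal.sosfiltfilt(sos, session.data[c].astype(np.float64))
    return EEGSession(
        data=out,
        sampling_rate_hz=session.sampling_rate_hz,
        channel_names=list(session.channel_names),
        schedule=session.schedule,
        environment=session.environment,
        seed=session.seed,
    )


def extract_epochs(session: EEGSession, window_ms: float = 600.0) -> EpochSet:
    """Cut one [onset, onset + window) epoch per flash; label = attended stimulus.

    Overlapping epochs (SOA shorter than the window) share samples.  A flash
    whose window would run past the end of the recording is an error — the
    recording is expected to extend past the final flash.
    """
    sched = session.schedule
    fs = session.sampling_rate_hz
    win = int(round(window_ms / 1000.0 * fs))
    if win < 1:
        raise ValueError("window too short for the sampling rate")
    n_ev = len(sched.events)
    tensor = np.empty((n_ev, win, session.n_channels), dtype=np.float32)
    starts = np.round(sched.events["onset_ms"] / 1000.0 * fs).astype(np.int64)
    if (starts + win > session.n_samples).any():
        bad = int(np.argmax(starts + win > session.n_samples))
        raise ValueError(
            f"epoch {bad} (onset {sched.events['onset_ms'][bad]} ms) is "
            "truncated by the end of the recording"
        )
    for i, s in enumerate(starts):
        tensor[i] = session.data[:, s:s + win].T
    meta = np.empty(n_ev, dtype=META_DTYPE)
    for f in META_DTYPE.names:
        meta[f] = sched.events[f]
    return EpochSet(
        tensor=tensor,
        labels=sched.labels(),
        meta=meta,
        sampling_rate_hz=fs,
        channel_names=list(session.channel_names),
    )


def downsample_epochs(epochs: EpochSet, factor: int = 3) -> EpochSet:
    """Decimate the time axis by keeping every ``factor``-th sample.

    The preceding 12 Hz low-pass already bounds the spectrum far below the
    post-decimation Nyquist, so no extra anti-alias filtering is applied.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return epochs
    if epochs.n_samples % factor:
        raise ValueError(
            f"epoch length {epochs.n_samples} not divisible by factor {factor}"
        )
    return replace(
        epochs,
        tensor=epochs.tensor[:, ::factor, :],
        sampling_rate_hz=epochs.sampling_rate_hz / factor,
    )


def average_repetitions(epochs: EpochSet, k: int) -> EpochSet:
    """Average the first ``k`` repeated trials of each (run, block, stimulus).

    ``k = 1`` is the identity (single extraction).  Output has one epoch per
    (run, block, stimulus) group, labelled like its members; the ``trial``
    field is set to 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return epochs
    meta = epochs.meta
    keys = {}
    for i in range(epochs.n_epochs):
        key = (int(meta["run"][i]), int(meta["block"][i]), int(meta["stimulus"][i]))
        keys.setdefault(key, []).append(i)
    out_t, out_l, out_m = [], [], []
    for key in sorted(keys):
        idx = sorted(keys[key], key=lambda i: int(meta["trial"][i]))
        if len(idx) < k:
            raise ValueError(
                f"group run={key[0]} block={key[1]} stimulus={key[2]} has only "
                f"{len(idx)} repetitions, k={k} requested"
            )
        take = idx[:k]
        lab = {int(epochs.labels[i]) for i in take}
        if len(lab) != 1:
            raise ValueError("inconsistent labels within a repetition group")
        out_t.append(epochs.tensor[take].mean(axis=0))
        out_l.append(lab.pop())
        out_m.append((key[0], key[1], 0, key[2]))
    return EpochSet(
        tensor=np.asarray(out_t, dtype=epochs.tensor.dtype),
        labels=np.asarray(out_l, dtype=epochs.labels.dtype),
        meta=np.array(out_m, dtype=META_DTYPE),
        sampling_rate_hz=epochs.sampling_rate_hz,
        channel_names=epochs.channel_names,
    )


def preprocess_session(
    session: EEGSession,
    drop: list[str] = ("A1", "A2"),
    lo_hz: float = 0.1,
    hi_hz: float = 12.0,
    window_ms: float = 600.0,
    downsample: int = 3,
) -> EpochSet:
    """Full default pipeline; emits 200-sample x 30-channel epochs."""
    s = drop_channels(session, [n for n in drop if n in session.channel_names])
    s = bandpass(s, lo_hz, hi_hz)
    ep = extract_epochs(s, window_ms)
    return downsample_epochs(ep, downsample)
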