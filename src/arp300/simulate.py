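"""Synthetic oddball-EEG sessions for a nine-target single-stimulus speller.

The generator reproduces the statistical structure of an augmented-reality
(AR) or computer-screen (CS) P300 session: a timed flash schedule
(runs x blocks x trials x stimuli at a fixed stimulus-onset asynchrony), a
target-locked positive ERP deflection added on top of 1/f + alpha + white
background noise, and a parieto-occipital spatial topography.  It is not a
forward-model head simulation; it exists so the full decoding pipeline can
be exercised and validated end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EVENT_DTYPE",
    "StimulusSchedule",
    "SimParams",
    "EEGSession",
    "DEFAULT_CHANNELS",
    "default_topography",
    "make_schedule",
    "simulate_session",
    "grand_average_erp",
]

#: structured dtype of one flash event
EVENT_DTYPE = np.dtype(
    [
        ("run", np.int64),
        ("block", np.int64),
        ("trial", np.int64),
        ("stimulus", np.int64),
        ("onset_ms", np.int64),
    ]
)

#: 30 data channels (10-20 layout names) followed by the two mastoid
#: reference channels that are dropped during preprocessing.
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
    "A1", "A2",
]

#: amplitude gain per channel-name prefix; posterior maximum, mastoids silent
_PREFIX_GAIN = [
    ("A", 0.0),
    ("Oz", 1.0),
    ("O", 0.95),
    ("PO", 0.9),
    ("Pz", 1.0),
    ("P", 0.8),
    ("CP", 0.6),
    ("Cz", 0.5),
    ("C", 0.4),
    ("FC", 0.3),
    ("T", 0.3),
    ("Fp", 0.1),
    ("F", 0.2),
]


def default_topography(channel_names: list[str]) -> np.ndarray:
    """Per-channel ERP gain with a parieto-occipital maximum.

    Mastoid channels (``A1``/``A2``) get gain 0 so they stay noise-only.
    """
    gains = np.empty(len(channel_names))
    for i, name in enumerate(channel_names):
        for prefix, g in _PREFIX_GAIN:
            if name.startswith(prefix):
                gains[i] = g
                break
        else:
            gains[i] = 0.5
    return gains


@dataclass(frozen=True)
class StimulusSchedule:
    """Timed flash events plus the per-block attended stimulus."""

    events: np.ndarray  # structured array, EVENT_DTYPE, sorted by onset
    n_stimuli: int
    soa_ms: int
    flash_ms: int
    prep_ms: int
    lock_ms: int
    target_of_block: dict[int, int]

    def __post_init__(self) -> None:
        if self.events.dtype != EVENT_DTYPE:
            raise ValueError("events must use EVENT_DTYPE")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_trials(self) -> int:
        return len(self.events) // self.n_stimuli

    def labels(self) -> np.ndarray:
        """Binary target label per event (1 = flash of the attended stimulus)."""
        targets = np.array(
            [self.target_of_block[int(b)] for b in self.events["block"]]
        )
        return (self.events["stimulus"] == targets).astype(np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StimulusSchedule):
            return NotImplemented
        return (
            np.array_equal(self.events, other.events)
            and self.n_stimuli == other.n_stimuli
            and self.soa_ms == other.soa_ms
            and self.flash_ms == other.flash_ms
            and self.prep_ms == other.prep_ms
            and self.lock_ms == other.lock_ms
            and self.target_of_block == other.target_of_block
        )


@dataclass
class SimParams:
    """Generator parameters for one simulated participant/environment.

    Latency means default to the AR/CS grand averages (482.47 / 434.53 ms);
    the AR ERP is additionally attenuated by ``ar_amplitude_scale``.
    """

    environment: str = "ar"  # "ar" | "cs"
    p300_latency_mean_ms: float | None = None  # None -> environment default
    p300_latency_sd_ms: float = 15.0
    latency_jitter_ms: float = 45.0  # hard clip on the per-flash latency draw
    p300_amplitude_uv: float = 5.0
    ar_amplitude_scale: float = 0.7
    erp_width_ms: float = 300.0
    topography: np.ndarray | None = None  # per-channel gain; None -> default
    noise_pink_uv: float = 4.0
    noise_alpha_uv: float = 2.0
    noise_white_uv: float = 1.0
    sampling_rate_hz: float = 1000.0
    n_channels: int = 30
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))

    _LATENCY_DEFAULTS = {"ar": 482.47, "cs": 434.53}

    def __post_init__(self) -> None:
        if self.environment not in ("ar", "cs"):
            raise ValueError(f"environment must be 'ar' or 'cs', got {self.environment!r}")
        if self.p300_latency_mean_ms is None:
            self.p300_latency_mean_ms = self._LATENCY_DEFAULTS[self.environment]
        for name in (
            "p300_latency_sd_ms",
            "latency_jitter_ms",
            "p300_amplitude_uv",
            "noise_pink_uv",
            "noise_alpha_uv",
            "noise_white_uv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.ar_amplitude_scale <= 1.0:
            raise ValueError("ar_amplitude_scale must be in (0, 1]")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.topography is None:
            self.topography = default_topography(self.channel_names)
        else:
            self.topography = np.asarray(self.topography, dtype=float)
        if len(self.topography) != len(self.channel_names):
            raise ValueError(
                "topography must have one entry per channel "
                f"({len(self.topography)} != {len(self.channel_names)})"
            )

    @property
    def amplitude_scale(self) -> float:
        """Effective ERP amplitude multiplier (< 1 in the AR environment)."""
        return self.ar_amplitude_scale if self.environment == "ar" else 1.0

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class EEGSession:
    """Continuous multichannel recording plus its stimulus schedule."""

    data: np.ndarray  # channels x samples, microvolt
    sampling_rate_hz: float
    channel_names: list[str]
    schedule: StimulusSchedule
    environment: str = "ar"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if len(self.schedule.events):
            last = self.schedule.events["onset_ms"].max()
            need = int(round((last + 600) / 1000.0 * self.sampling_rate_hz))
            if self.data.shape[1] < need:
                raise ValueError(
                    f"recording too short: {self.data.shape[1]} samples, "
                    f"need >= {need} to cover the last flash + 600 ms"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def make_schedule(
    runs: int,
    blocks_per_run: int,
    trials_per_block: int,
    n_stimuli: int,
    soa_ms: int = 175,
    flash_ms: int = 100,
    prep_ms: int = 2000,
    lock_ms: int = 1500,
    seed: int | None = 0,
    tail_ms: int = 600,
) -> StimulusSchedule:
    """Build the flash schedule of a full session.

    Each trial presents every stimulus exactly once in random order at
    ``soa_ms`` spacing; each trial is preceded by a preparation plus
    target-lock interval and followed by ``tail_ms`` so the last epoch
    fits inside the trial.  The attended stimulus of block *b* is *b*
    (stimuli are cued in fixed order), identical across runs.

    Deterministic given ``seed``.
    """
    for name, v in [
        ("runs", runs),
        ("blocks_per_run", blocks_per_run),
        ("trials_per_block", trials_per_block),
        ("n_stimuli", n_stimuli),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if soa_ms < flash_ms:
        raise ValueError(f"soa_ms ({soa_ms}) must be >= flash_ms ({flash_ms})")
    if prep_ms < 0 or lock_ms < 0 or tail_ms < 0:
        raise ValueError("prep_ms, lock_ms and tail_ms must be >= 0")

    rng = np.random.default_rng(seed)
    trial_span = prep_ms + lock_ms + (n_stimuli - 1) * soa_ms + tail_ms
    n_events = runs * blocks_per_run * trials_per_block * n_stimuli
    events = np.empty(n_events, dtype=EVENT_DTYPE)
    t0 = 0
    i = 0
    for run in range(runs):
        for block in range(blocks_per_run):
            for trial in range(trials_per_block):
                order = rng.permutation(n_stimuli)
                first = t0 + prep_ms + lock_ms
                for pos, stim in enumerate(order):
                    events[i] = (run, block, trial, stim, first + pos * soa_ms)
                    i += 1
                t0 += trial_span
    target_of_block = {b: b % n_stimuli for b in range(blocks_per_run)}
    return StimulusSchedule(
        events=events,
        n_stimuli=n_stimuli,
        soa_ms=soa_ms,
        flash_ms=flash_ms,
        prep_ms=prep_ms,
        lock_ms=lock_ms,
        target_of_block=target_of_block,
    )


def _erp_template(n_samples: int, peak_sample: float, width_samples: float) -> np.ndarray:
    """One-cycle raised-cosine positive pulse, unit peak, centred at the peak."""
    t = np.arange(n_samples, dtype=float)
    phase = (t - peak_sample) / width_samples  # -0.5..0.5 inside the pulse
    out = np.zeros(n_samples)
    inside = np.abs(phase) <= 0.5
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * phase[inside]))
    return out


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC drift
    out = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def simulate_session(
    schedule: StimulusSchedule,
    params: SimParams | None = None,
    seed: int | None = 0,
) -> EEGSession:
    """Render a schedule into a continuous multichannel recording.

    Every flash of the block's attended stimulus adds one raised-cosine ERP
    pulse whose peak latency is drawn from N(mean, sd), clipped to
    +-``latency_jitter_ms``, scaled by the spatial topography and by the
    environment amplitude factor.  Non-target flashes add nothing.  The
    background is pink + 10 Hz alpha + white noise at the configured RMS
    amplitudes, independent per channel.  Bit-reproducible given
    (schedule, params, seed).
    """
    if params is None:
        params = SimParams()
    fs = params.sampling_rate_hz
    rng = np.random.default_rng(seed)

    last_onset = int(schedule.events["onset_ms"].max()) if len(schedule.events) else 0
    duration_ms = last_onset + 700  # last epoch (600 ms) plus margin
    n_samples = int(round(duration_ms / 1000.0 * fs))
    n_ch = len(params.channel_names)

    data = np.zeros((n_ch, n_samples), dtype=np.float32)
    t = np.arange(n_samples) / fs
    for c in range(n_ch):
        ch = np.zeros(n_samples)
        if params.noise_pink_uv > 0:
            ch += params.noise_pink_uv * _pink_noise(rng, n_samples)
        if params.noise_alpha_uv > 0:
            phase = rng.uniform(0, 2 * np.pi)
            ch += params.noise_alpha_uv * np.sqrt(2.0) * np.sin(2 * np.pi * 10.0 * t + phase)
        if params.noise_white_uv > 0:
            ch += params.noise_white_uv * rng.standard_normal(n_samples)
        data[c] = ch

    labels = schedule.labels()
    width = params.erp_width_ms / 1000.0 * fs
    amp = params.p300_amplitude_uv * params.amplitude_scale
    half = int(np.ceil(width / 2)) + 1
    for ev, is_target in zip(schedule.events, labels):
        if not is_target:
            continue
        dev = params.p300_latency_sd_ms * rng.standard_normal()
        if params.latency_jitter_ms > 0:
            dev = float(np.clip(dev, -params.latency_jitter_ms, params.latency_jitter_ms))
        latency_ms = params.p300_latency_mean_ms + dev
        peak = (ev["onset_ms"] + latency_ms) / 1000.0 * fs
        lo = max(0, int(np.floor(peak)) - half)
        hi = min(n_samples, int(np.ceil(peak)) + half)
        if hi <= lo:
            continue
        pulse = _erp_template(hi - lo, peak - lo, width)
        data[:, lo:hi] += (amp * params.topography)[:, None] * pulse[None, :]

    return EEGSession(
        data=data,
        sampling_rate_hz=fs,
        channel_names=list(params.channel_names),
        schedule=schedule,
        environment=params.environment,
        seed=seed,
    )


def grand_average_erp(epochs, channel: str | int):
    """Class-mean waveforms at one channel.

    Parameters
    ----------
    epochs : EpochSet
        Epoch tensor with binary labels.
    channel : str or int
        Channel name (if the epoch set carries names) or column index.

    Returns
    -------
    (target_mean, nontarget_mean) : tuple of 1-D arrays of epoch length.
    """
    if len(epochs.tensor) == 0:
        raise ValueError("empty epoch set")
    if isinstance(channel, str):
        if epochs.channel_names is None:
            raise ValueError("epoch set has no channel names; pass an index")
        try:
            idx = epochs.channel_names.index(channel)
        except ValueError:
            raise ValueError(
                f"channel {channel!r} not found; available: {epochs.channel_names}"
            ) from None
    else:
        idx = int(channel)
        if not 0 <= idx < epochs.tensor.shape[2]:
            raise ValueError(f"channel index {idx} out of range")
    out = []
    for cls, name in ((1, "target"), (0, "non-target")):
        mask = epochs.labels == cls
        if not mask.any():
            raise ValueError(f"no {name} epochs present")
        out.append(epochs.tensor[mask, :, idx].mean(axis=0))
    return out[0], out[1]
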