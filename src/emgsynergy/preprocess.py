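"""Raw EMG -> pooled nonnegative envelope matrix.

The factorization stage operates on an ``n channels x T samples``
nonnegative matrix built in four steps, applied in this order:

1. rectify and lowpass (zero-lag Butterworth) -> amplitude envelope;
2. decimate to the envelope rate (default 100 Hz);
3. drop rest samples, concatenating movement samples across trials;
4. scale each channel to unit power.

"Zero-lag" means forward-backward application (``filtfilt``) of a filter
designed at the nominal order, so the effective magnitude response is of
twice that order. Small negative values produced by filter ringing are
clipped to zero, because the factorization requires a nonnegative input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import DegenerateDataError, IntegrityError
from .ninapro_io import EmgRecording, FOREARM10_ROLES, RING_ROLES

#: Named electrode subsets used throughout the study.
ELECTRODE_SETS: dict[str, tuple[str, ...]] = {
    "ring8": RING_ROLES,
    "forearm10": FOREARM10_ROLES,
}

_EXCLUDED_ROLES = frozenset({"BB", "TB"})


def electrode_set(name: str) -> tuple[str, ...]:
    """Resolve an electrode-set name (``ring8`` or ``forearm10``)."""
    try:
        return ELECTRODE_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown electrode set {name!r}; choose from {sorted(ELECTRODE_SETS)}"
        ) from None


@dataclass
class PooledEnvelope:
    """Nonnegative channel x sample matrix restricted to movement samples.

    Attributes
    ----------
    E
        ``(n_channels, T)`` nonnegative matrix, each row scaled to unit
        root-mean-square power.
    movement_of_sample
        Movement id (> 0) for every column of ``E``.
    channel_scale
        Per-channel divisor applied during normalization.
    """

    E: np.ndarray
    movement_of_sample: np.ndarray
    channel_roles: tuple[str, ...]
    channel_scale: np.ndarray
    envelope_rate: float

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.movement_of_sample = np.asarray(self.movement_of_sample, dtype=int)
        if self.E.ndim != 2:
            raise IntegrityError("E must be 2-D (channels x samples)")
        if self.E.shape[1] != len(self.movement_of_sample):
            raise IntegrityError("movement_of_sample length != number of columns")
        if self.E.shape[0] != len(self.channel_roles):
            raise IntegrityError("channel_roles length != number of rows")
        if (self.E < 0).any():
            raise IntegrityError("pooled envelope must be nonnegative")
        if (self.movement_of_sample <= 0).any():
            raise IntegrityError("pooled envelope must not contain rest samples")

    @property
    def n_channels(self) -> int:
        return self.E.shape[0]

    @property
    def n_samples(self) -> int:
        return self.E.shape[1]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.E.T, columns=list(self.channel_roles))
        df.insert(0, "movement", self.movement_of_sample)
        df.to_csv(path, index=False)


def envelope(recording: EmgRecording, cutoff: float = 3.0,
             order: int = 4) -> EmgRecording:
    """Rectify and lowpass each channel with a zero-lag Butterworth filter.

    Parameters
    ----------
    cutoff
        Lowpass cutoff in Hz (default 3 Hz).
    order
        Nominal filter order (default 4); applied forward and backward.
    """
    sig = recording.signal
    if not np.isfinite(sig).all():
        raise IntegrityError("signal contains non-finite samples")
    if recording.sampling_rate <= 2 * cutoff:
        raise ValueError("sampling_rate must exceed twice the cutoff")
    b, a = scipy.signal.butter(order, cutoff, btype="low",
                               fs=recording.sampling_rate)
    padlen = 3 * max(len(a), len(b))
    if recording.n_samples <= padlen:
        raise ValueError(
            f"signal too short ({recording.n_samples} samples) for "
            f"order-{order} zero-lag filtering"
        )
    env = scipy.signal.filtfilt(b, a, np.abs(sig), axis=0)
    np.clip(env, 0.0, None, out=env)
    return recording.with_signal(env)


def downsample(recording: EmgRecording, target_rate: float = 100.0) -> EmgRecording:
    """Decimate signal and labels to ``target_rate`` by keeping every
    ``sampling_rate/target_rate``-th sample, starting with the first.

    Plain decimation is adequate here because the envelope bandwidth
    (a few Hz) is far below the target Nyquist rate.
    """
    ratio = recording.sampling_rate / target_rate
    step = round(ratio)
    if abs(ratio - step) > 1e-9 or step < 1:
        raise ValueError(
            f"sampling_rate {recording.sampling_rate} is not an integer "
            f"multiple of target_rate {target_rate}"
        )
    return recording.with_signal(
        recording.signal[::step],
        sampling_rate=target_rate,
        movement_label=recording.movement_label[::step],
        repetition_label=recording.repetition_label[::step],
    )


def pool_movements(recording: EmgRecording,
                   keep_roles: tuple[str, ...] = FOREARM10_ROLES) -> PooledEnvelope:
    """Drop rest samples, restrict to ``keep_roles``, normalize channels.

    Channels are kept in their recorded order; samples keep their original
    temporal order. Each kept channel is divided by its own uncentered
    standard deviation (root mean square over the pooled samples), so the
    output stays nonnegative while every row has unit power.

    Raises
    ------
    DegenerateDataError
        If all samples are rest, or a kept channel is constant over the
        pooled samples (zero variance: it carries no movement information).
    """
    keep = set(keep_roles)
    banned = keep & _EXCLUDED_ROLES
    if banned:
        raise ValueError(f"upper-arm channels {sorted(banned)} cannot be pooled")
    if (recording.signal < 0).any():
        raise IntegrityError("pool_movements expects an envelope (nonnegative)")
    missing = keep - set(recording.channel_roles)
    if missing:
        raise KeyError(
            f"recording lacks requested channels: {sorted(missing)} "
            f"(available: {list(recording.channel_roles)})"
        )
    rows = [i for i, role in enumerate(recording.channel_roles) if role in keep]
    mask = recording.movement_label > 0
    if mask.sum() < 2:
        raise DegenerateDataError("fewer than 2 non-rest samples to pool")
    E = recording.signal[np.ix_(mask, rows)].T.copy()
    movement = recording.movement_label[mask]
    centered_sd = E.std(axis=1)
    for i, sd in enumerate(centered_sd):
        if sd <= 1e-12:
            role = recording.channel_roles[rows[i]]
            raise DegenerateDataError(
                f"channel {role} has zero variance over pooled samples"
            )
    scale = np.sqrt(np.mean(E ** 2, axis=1))
    E /= scale[:, None]
    return PooledEnvelope(
        E=E,
        movement_of_sample=movement,
        channel_roles=tuple(recording.channel_roles[i] for i in rows),
        channel_scale=scale,
        envelope_rate=recording.sampling_rate,
    )


def preprocess(recording: EmgRecording, keep_roles: tuple[str, ...] = FOREARM10_ROLES,
               cutoff: float = 3.0, order: int = 4,
               envelope_rate: float = 100.0) -> PooledEnvelope:
    """Full preprocessing chain: envelope -> downsample -> pool."""
    return pool_movements(
        downsample(envelope(recording, cutoff=cutoff, order=order),
                   target_rate=envelope_rate),
        keep_roles=keep_roles,
    )
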