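"""Reading and writing NinaPro-style .mat containers.

The public NinaPro databases store each subject/exercise as a MATLAB
container with an ``emg`` array (samples x channels) plus per-sample label
vectors: ``stimulus`` / ``repetition`` (raw, as cued by the movie) and
``restimulus`` / ``rerepetition`` (refined, movie-aligned corrections).
Label value 0 always means rest.

This module maps those containers onto :class:`EmgRecording` and writes
synthetic fixtures in the same layout so the rest of the pipeline is
agnostic about where a recording came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.io

from .errors import FormatError, IntegrityError

# Channel roles. The dense ring of eight electrodes sits around the forearm
# at the radio-humeral joint; FDS/EDS target the extrinsic finger flexor and
# extensor; BB/TB sit on the upper arm and take no part in hand/wrist
# movements.
RING_ROLES = tuple(f"RING{i}" for i in range(1, 9))
FOREARM10_ROLES = RING_ROLES + ("FDS", "EDS")
ALL_ROLES = FOREARM10_ROLES + ("BB", "TB")

#: Default column -> role assignment for the standard 12-electrode setup.
DEFAULT_CHANNEL_MAP: tuple[str, ...] = ALL_ROLES

_VALID_ROLES = frozenset(ALL_ROLES)


@dataclass
class EmgRecording:
    """A multichannel surface EMG recording with per-sample labels.

    Parameters
    ----------
    signal
        ``(n_samples, n_channels)`` float array, arbitrary amplitude units.
    sampling_rate
        Sampling rate in Hz.
    movement_label
        Integer per sample; 0 means rest.
    repetition_label
        Integer per sample; 0 means rest.
    channel_roles
        One role per signal column, drawn from ``RING1..RING8, FDS, EDS,
        BB, TB``.
    """

    signal: np.ndarray
    sampling_rate: float
    movement_label: np.ndarray
    repetition_label: np.ndarray
    channel_roles: tuple[str, ...]
    subject_id: str = ""
    exercise_id: str = "B"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise IntegrityError("signal must be 2-D (samples x channels)")
        self.movement_label = _flatten_labels(self.movement_label)
        self.repetition_label = _flatten_labels(self.repetition_label)
        self.channel_roles = tuple(self.channel_roles)
        if self.sampling_rate <= 0:
            raise IntegrityError("sampling_rate must be positive")
        t, c = self.signal.shape
        if t == 0:
            raise IntegrityError("recording has no samples")
        if len(self.movement_label) != t or len(self.repetition_label) != t:
            raise IntegrityError(
                f"label length ({len(self.movement_label)}/"
                f"{len(self.repetition_label)}) does not match "
                f"signal length ({t})"
            )
        if len(self.channel_roles) != c:
            raise IntegrityError(
                f"{len(self.channel_roles)} channel roles for {c} channels"
            )
        unknown = set(self.channel_roles) - _VALID_ROLES
        if unknown:
            raise FormatError(f"unknown channel roles: {sorted(unknown)}")
        if (self.movement_label < 0).any():
            raise IntegrityError("movement labels must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    def with_signal(self, signal: np.ndarray, sampling_rate: float | None = None,
                    movement_label: np.ndarray | None = None,
                    repetition_label: np.ndarray | None = None) -> "EmgRecording":
        """Copy of this recording with the signal (and optionally labels)
        replaced; used by preprocessing stages."""
        return EmgRecording(
            signal=signal,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            movement_label=self.movement_label if movement_label is None else movement_label,
            repetition_label=self.repetition_label if repetition_label is None else repetition_label,
            channel_roles=self.channel_roles,
            subject_id=self.subject_id,
            exercise_id=self.exercise_id,
        )


@dataclass
class SubjectClinical:
    """Clinical covariates of one amputee subject."""

    residual_forearm_pct: float
    age: float
    years_since_amputation: float
    phantom_sensation: int
    prosthesis_experience: str = "No"
    amputated_hand: str = "R"

    def __post_init__(self) -> None:
        if not 0 <= self.residual_forearm_pct <= 100:
            raise ValueError("residual_forearm_pct must lie in [0, 100]")
        if self.phantom_sensation not in {0, 1, 2, 3, 4, 5}:
            raise ValueError("phantom_sensation must be an integer in 0..5")


def _flatten_labels(x) -> np.ndarray:
    arr = np.asarray(x)
    arr = np.ravel(arr)
    return arr.astype(int)


def _first_present(container: dict, names: tuple[str, ...]):
    for name in names:
        if name in container:
            return container[name]
    return None


def read_recording(path, subject_id: str = "",
                   channel_map: tuple[str, ...] | None = None,
                   exercise_id: str = "B") -> EmgRecording:
    """Read a NinaPro-style ``.mat`` file into an :class:`EmgRecording`.

    Handles both MATLAB v5 containers (via :mod:`scipy.io`) and
    v7.3/HDF5 containers (via :mod:`h5py`). Refined label vectors
    (``restimulus`` / ``rerepetition``) are preferred over the raw
    ``stimulus`` / ``repetition`` when both are present.

    Parameters
    ----------
    channel_map
        Role for each signal column. Defaults to the standard layout
        (columns 1-8 ring electrodes, 9-10 FDS/EDS, 11-12 BB/TB),
        truncated to the number of channels found.
    """
    data = _load_mat(path)
    if "emg" not in data:
        raise FormatError(f"{path}: missing required array 'emg'")
    emg = np.atleast_2d(np.asarray(data["emg"], dtype=float))
    movement = _first_present(data, ("restimulus", "stimulus"))
    repetition = _first_present(data, ("rerepetition", "repetition"))
    if movement is None:
        raise FormatError(f"{path}: missing movement labels "
                          "(neither 'restimulus' nor 'stimulus')")
    if repetition is None:
        raise FormatError(f"{path}: missing repetition labels "
                          "(neither 'rerepetition' nor 'repetition')")
    rate = data.get("sampling_rate", 2000.0)
    rate = float(np.ravel(np.asarray(rate))[0])
    if channel_map is None:
        channel_map = DEFAULT_CHANNEL_MAP[: emg.shape[1]]
    if not subject_id:
        sid = data.get("subject")
        subject_id = str(int(np.ravel(np.asarray(sid))[0])) if sid is not None else ""
    return EmgRecording(
        signal=emg,
        sampling_rate=rate,
        movement_label=movement,
        repetition_label=repetition,
        channel_roles=channel_map,
        subject_id=subject_id,
        exercise_id=exercise_id,
    )


def _load_mat(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = scipy.io.loadmat(path)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except (NotImplementedError, ValueError) as exc:
        # MATLAB v7.3 containers are HDF5 files
        if not h5py.is_hdf5(path):
            raise FormatError(f"{path}: not a readable MAT container "
                              f"({exc})") from exc
        out = {}
        with h5py.File(path, "r") as f:
            for key in f:
                node = f[key]
                if isinstance(node, h5py.Dataset):
                    # MATLAB stores arrays transposed in HDF5
                    out[key] = np.asarray(node).T
        return out


def write_fixture(recording: EmgRecording, path) -> None:
    """Write a recording as a NinaPro-style v5 ``.mat`` container.

    Both raw and refined label vector names are populated (with identical
    content) so that readers following either convention work.
    ``read_recording(write_fixture(x))`` reproduces signal, labels and
    channel count exactly.
    """
    path = Path(path)
    payload = {
        "emg": recording.signal,
        "stimulus": recording.movement_label.reshape(-1, 1),
        "restimulus": recording.movement_label.reshape(-1, 1),
        "repetition": recording.repetition_label.reshape(-1, 1),
        "rerepetition": recording.repetition_label.reshape(-1, 1),
        "sampling_rate": np.array([[recording.sampling_rate]]),
        "exercise": recording.exercise_id,
    }
    if recording.subject_id:
        try:
            payload["subject"] = np.array([[int(recording.subject_id)]])
        except ValueError:
            pass
    scipy.io.savemat(path, payload)


def export_csv(recording: EmgRecording, path) -> None:
    """Dump a recording as CSV for manual inspection (one row per sample)."""
    import pandas as pd

    df = pd.DataFrame(recording.signal, columns=list(recording.channel_roles))
    df.insert(0, "movement", recording.movement_label)
    df.insert(1, "repetition", recording.repetition_label)
    df.to_csv(path, index=False)


def load_channel_map(path) -> tuple[str, ...]:
    """Parse a plain key-value channel-map config.

    Each non-comment line reads ``<column> = <ROLE>`` with 1-based column
    indices; columns must form a contiguous 1..C range.
    """
    entries: dict[int, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"channel map line {lineno}: expected 'col = ROLE'")
        col_s, role = (part.strip() for part in line.split("=", 1))
        col = int(col_s)
        role = role.upper()
        if role not in _VALID_ROLES:
            raise FormatError(f"channel map line {lineno}: unknown role {role!r}")
        if col in entries:
            raise FormatError(f"channel map line {lineno}: duplicate column {col}")
        entries[col] = role
    if not entries:
        raise FormatError(f"{path}: empty channel map")
    cols = sorted(entries)
    if cols != list(range(1, len(cols) + 1)):
        raise FormatError(f"{path}: columns must be contiguous starting at 1")
    return tuple(entries[c] for c in cols)
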