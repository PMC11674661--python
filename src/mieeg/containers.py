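"""Core data containers: labelled epochs, electrode montage, ground truth.

Units are microvolts throughout; epochs are stored as a dense
``(n_epochs, n_channels, n_samples)`` float array plus metadata, which is
the natural unit every downstream stage (filtering, FASTER, dense-grid
mapping, model training) consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: The four imagery classes of the study task.
CLASSES = ("left_hand", "right_hand", "both_hands", "both_legs")

#: The 64 channel names of the BCI2000 10-10 cap used by the Physionet
#: motor movement/imagery recordings, in recording order.
PHYSIONET_64 = (
    "Fc5", "Fc3", "Fc1", "Fcz", "Fc2", "Fc4", "Fc6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "Cp5", "Cp3", "Cp1", "Cpz", "Cp2", "Cp4", "Cp6",
    "Fp1", "Fpz", "Fp2",
    "Af7", "Af3", "Afz", "Af4", "Af8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "Ft7", "Ft8",
    "T7", "T8", "T9", "T10",
    "Tp7", "Tp8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "Po7", "Po3", "Poz", "Po4", "Po8",
    "O1", "Oz", "O2",
    "Iz",
)

#: Channels used as the ocular proxy (the cap has no dedicated EOG leads).
FRONTAL_EOG_PROXY = ("Fp1", "Fpz", "Fp2", "Af7", "Af8")


@dataclass(frozen=True)
class Montage:
    """Electrode names and unit-sphere positions.

    Positions are radial projections of the template head positions onto
    the unit sphere centred on the head origin, which is the geometry the
    spherical-spline interpolation assumes.
    """

    ch_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.ch_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    def index(self, name: str) -> int:
        return self.ch_names.index(name)

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]

    def subset(self, names) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(tuple(names), self.positions[idx])

    @classmethod
    def physionet64(cls) -> "Montage":
        """The 64-channel 10-10 montage of the study dataset."""
        return _physionet64_cached()


def _standard_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    return {name.lower(): np.asarray(p, dtype=float) for name, p in pos.items()}


_MONTAGE_CACHE: dict[str, Montage] = {}


def _physionet64_cached() -> Montage:
    if "physionet64" not in _MONTAGE_CACHE:
        table = _standard_positions()
        # Positions are given relative to an estimated sphere centre so
        # that radial projection preserves the scalp geometry.
        raw = np.array([table[name.lower()] for name in PHYSIONET_64])
        centre = raw.mean(axis=0)
        centre[2] = raw[:, 2].min() * 0.5  # keep centre inside the head
        shifted = raw - centre
        unit = shifted / np.linalg.norm(shifted, axis=1, keepdims=True)
        _MONTAGE_CACHE["physionet64"] = Montage(PHYSIONET_64, unit)
    return _MONTAGE_CACHE["physionet64"]


@dataclass(frozen=True)
class ArtifactAnnotation:
    """One injected artifact: what, where, and when."""

    kind: str                 # "blink" | "emg" | "bad_channel" | "epoch_bad_channel" | "line_noise"
    epoch: int | None         # None for subject-global artifacts
    channels: tuple[str, ...]
    start: float              # seconds within the epoch (0 for global)
    duration: float           # seconds


@dataclass
class GroundTruth:
    """Everything the synthetic generator injected, for recall scoring."""

    artifacts: list[ArtifactAnnotation] = field(default_factory=list)
    bad_channels: tuple[str, ...] = ()
    class_topographies: dict[str, np.ndarray] = field(default_factory=dict)

    def of_kind(self, kind: str) -> list[ArtifactAnnotation]:
        return [a for a in self.artifacts if a.kind == kind]


@dataclass
class EpochSet:
    """Labelled trials: ``data`` is (n_epochs, n_channels, n_samples) in uV."""

    data: np.ndarray
    fs: float
    ch_names: tuple[str, ...]
    labels: np.ndarray          # (n_epochs,) of strings from CLASSES
    montage: Montage | None = None
    info: dict = field(default_factory=dict)   # provenance: band, AR, subject id...

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal n_epochs")
        self.ch_names = tuple(self.ch_names)
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length must equal n_channels")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        return self.ch_names.index(name)

    def copy(self, **changes) -> "EpochSet":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "info" not in changes:
            out.info = dict(self.info)
        return out

    def select_epochs(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return self.copy(data=self.data[idx], labels=self.labels[idx])

    def to_mne(self):
        """Convert to an :class:`mne.EpochsArray` (volts, as mne expects)."""
        import mne

        info = mne.create_info(list(self.ch_names), self.fs, ch_types="eeg")
        codes = {c: i for i, c in enumerate(sorted(set(self.labels)))}
        events = np.column_stack([
            np.arange(self.n_epochs) * self.n_samples,
            np.zeros(self.n_epochs, dtype=int),
            np.array([codes[l] for l in self.labels]),
        ])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ep = mne.EpochsArray(self.data * 1e-6, info, events=events,
                                 event_id={c: i for c, i in codes.items()}, verbose="error")
        return ep
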