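"""Dense 9x7 spatial representation and cropped-training windows.

The 64-channel 10-10 cap is rearranged into a dense 9x7 rectangle: the
Iz electrode is dropped and the remaining 63 electrodes fill the grid
bijectively, so the epochs become tensors with two spatial axes and one
temporal axis and nothing is interpolated or padded.  The exact
electrode-to-cell table is shipped as a versioned CSV
(``data/dense_grid_9x7.csv``); it was derived once by projecting the
template positions to a 2-D scalp layout, slicing the electrodes into 9
anterior-to-posterior rows of 7, and ordering each row left to right.

Cropped training slides a fixed window through each epoch (1 s windows,
0.1 s steps inside the 2 s epochs give 11 crops); every crop keeps its
parent-epoch id so that splitters can keep all crops of one epoch on the
same side of a train/test split.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .containers import EpochSet, Montage, PHYSIONET_64

N_ROWS, N_COLS = 9, 7
OMITTED = ("Iz",)


@dataclass(frozen=True)
class DenseGridMap:
    """Injective electrode-name -> (row, col) assignment filling 9x7."""

    mapping: dict[str, tuple[int, int]]

    def __post_init__(self):
        cells = list(self.mapping.values())
        if len(set(cells)) != len(cells):
            raise ValueError("grid mapping must be injective")
        for r, c in cells:
            if not (0 <= r < N_ROWS and 0 <= c < N_COLS):
                raise ValueError(f"cell {(r, c)} outside the {N_ROWS}x{N_COLS} grid")

    @property
    def n_occupied(self) -> int:
        return len(self.mapping)

    def is_full(self) -> bool:
        return self.n_occupied == N_ROWS * N_COLS

    def cell(self, name: str) -> tuple[int, int]:
        return self.mapping[name]

    def inverse(self) -> dict[tuple[int, int], str]:
        return {cell: name for name, cell in self.mapping.items()}


def _project_2d(montage: Montage) -> np.ndarray:
    """Azimuthal-equidistant projection of unit-sphere positions to 2-D."""
    pos = montage.positions
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    theta = np.arccos(np.clip(z, -1, 1))        # angle from the vertex
    rho = np.hypot(x, y)
    rho = np.where(rho < 1e-12, 1.0, rho)
    return np.column_stack([theta * x / rho, theta * y / rho])


def derive_dense_grid(montage: Montage, omit=OMITTED) -> DenseGridMap:
    """Compact a 10-10 montage into the dense 9x7 grid.

    Electrodes (minus the omitted set) are sorted front-to-back on the
    2-D scalp projection, sliced into 9 rows of 7, and each row is
    ordered left-to-right.  Deterministic for a fixed montage.
    """
    keep = [n for n in montage.ch_names if n not in omit]
    if len(keep) != N_ROWS * N_COLS:
        raise ValueError(
            f"need exactly {N_ROWS * N_COLS} electrodes after omitting {omit}, got {len(keep)}")
    sub = montage.subset(keep)
    xy = _project_2d(sub)
    order = np.argsort(-xy[:, 1], kind="stable")  # front (+y) first
    mapping: dict[str, tuple[int, int]] = {}
    for r in range(N_ROWS):
        row_idx = order[r * N_COLS:(r + 1) * N_COLS]
        left_to_right = row_idx[np.argsort(xy[row_idx, 0], kind="stable")]
        for c, i in enumerate(left_to_right):
            mapping[keep[i]] = (r, c)
    return DenseGridMap(mapping)


def _load_shipped_grid() -> DenseGridMap:
    mapping = {}
    with resources.files("mieeg.data").joinpath("dense_grid_9x7.csv").open() as fh:
        for rec in csv.DictReader(fh):
            mapping[rec["electrode"]] = (int(rec["row"]), int(rec["col"]))
    return DenseGridMap(mapping)


def build_dense_grid(montage: Montage) -> DenseGridMap:
    """Return the dense 9x7 grid map for the 64-channel 10-10 montage.

    The shipped, versioned table is used for the standard montage so the
    representation is stable across releases; an unknown montage is an
    error.
    """
    if set(montage.ch_names) != set(PHYSIONET_64):
        raise ValueError("dense 9x7 grid is defined for the 64-channel 10-10 montage only")
    return _load_shipped_grid()


def to_dense_3d(epochs: EpochSet, grid: DenseGridMap) -> np.ndarray:
    """Rearrange epochs into a (n_epochs, 9, 7, n_samples) tensor.

    Lossless for the mapped electrodes: cell (r, c) carries exactly the
    mapped electrode's time series, keyed by channel name.
    """
    missing = [n for n in grid.mapping if n not in epochs.ch_names]
    if missing:
        raise ValueError(f"epochs lack mapped channels: {missing}")
    out = np.zeros((epochs.n_epochs, N_ROWS, N_COLS, epochs.n_samples),
                   dtype=epochs.data.dtype)
    for name, (r, c) in grid.mapping.items():
        out[:, r, c, :] = epochs.data[:, epochs.channel_index(name), :]
    return out


@dataclass
class CropSet:
    """Sliding-window crops of epochs, grouped by parent epoch."""

    windows: np.ndarray      # (n_windows, n_channels, window_samples)
    group_id: np.ndarray     # (n_windows,) parent epoch index
    offsets: np.ndarray      # (n_windows,) seconds from epoch start
    labels: np.ndarray       # (n_windows,) inherited class labels
    fs: float
    ch_names: tuple[str, ...]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def crops_per_epoch(self) -> int:
        return int(np.bincount(self.group_id).max())


def crop_epochs(epochs: EpochSet, window: float = 1.0, step: float = 0.1,
                span: float | None = None) -> CropSet:
    """Generate overlapping crops at offsets 0, step, 2*step, ... <= span-window.

    Offsets are quantised to whole samples.  With the defaults on 2 s
    epochs this yields 11 crops per epoch.
    """
    if span is None:
        span = epochs.n_samples / epochs.fs
    if window > span:
        raise ValueError("window must not exceed span")
    if span * epochs.fs > epochs.n_samples + 1e-9:
        raise ValueError("span exceeds epoch length")
    w = int(round(window * epochs.fs))
    s = int(round(step * epochs.fs))
    if s <= 0:
        raise ValueError("step must be positive")
    span_n = int(round(span * epochs.fs))
    starts = np.arange(0, span_n - w + 1, s)
    wins, gids, offs, labs = [], [], [], []
    for e in range(epochs.n_epochs):
        for st in starts:
            wins.append(epochs.data[e, :, st:st + w])
            gids.append(e)
            offs.append(st / epochs.fs)
            labs.append(epochs.labels[e])
    return CropSet(
        windows=np.stack(wins),
        group_id=np.asarray(gids),
        offsets=np.asarray(offs),
        labels=np.asarray(labs),
        fs=epochs.fs,
        ch_names=epochs.ch_names,
    )
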