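"""Readers, writers, and experiment configuration.

Epochs travel in a small internal container: one ``data.npy`` array plus
a JSON sidecar with labels, sampling rate, channel names and provenance
(including ground-truth artifact annotations for synthetic data), so
every artifact on disk is regenerable from its embedded config + seed.
FIF export is available through mne.  The optional Physionet loader
reads the motor movement/imagery EDF recordings, keeps only the imagined
-movement runs, and refuses the four subjects excluded by convention
(88, 92, 100: sampling-frequency/data-structure mismatch; 89: incorrect
labels).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .containers import ArtifactAnnotation, EpochSet, GroundTruth, Montage

EXCLUDED_SUBJECTS = {
    88: "sampling frequency and data structure mismatch",
    92: "sampling frequency and data structure mismatch",
    100: "sampling frequency and data structure mismatch",
    89: "labels were found to be incorrect",
}

#: run number -> {annotation code: class} for the imagined-movement runs.
#: Runs 4/8/12 are left vs right fist imagery, runs 6/10/14 both fists vs
#: both feet; T0 is rest and is never epoched.
IMAGERY_RUN_EVENTS = {
    4: {"T1": "left_hand", "T2": "right_hand"},
    8: {"T1": "left_hand", "T2": "right_hand"},
    12: {"T1": "left_hand", "T2": "right_hand"},
    6: {"T1": "both_hands", "T2": "both_legs"},
    10: {"T1": "both_hands", "T2": "both_legs"},
    14: {"T1": "both_hands", "T2": "both_legs"},
}


# ---------------------------------------------------------------------------
# internal container

def save_epochset(epochs: EpochSet, directory: str | Path,
                  ground_truth: GroundTruth | None = None) -> Path:
    """Write data.npy + meta.json (+ ground_truth.json) into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "data.npy", epochs.data)
    meta = {
        "fs": epochs.fs,
        "ch_names": list(epochs.ch_names),
        "labels": [str(l) for l in epochs.labels],
        "info": _jsonable(epochs.info),
        "units": "microvolts",
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    if ground_truth is not None:
        gt = {
            "bad_channels": list(ground_truth.bad_channels),
            "artifacts": [asdict(a) for a in ground_truth.artifacts],
        }
        (directory / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return directory


def load_epochset(directory: str | Path,
                  with_ground_truth: bool = False):
    directory = Path(directory)
    data = np.load(directory / "data.npy")
    meta = json.loads((directory / "meta.json").read_text())
    montage = None
    if set(meta["ch_names"]) <= set(Montage.physionet64().ch_names):
        montage = Montage.physionet64().subset(meta["ch_names"]) \
            if len(meta["ch_names"]) < 64 else Montage.physionet64()
    epochs = EpochSet(data=data, fs=meta["fs"], ch_names=tuple(meta["ch_names"]),
                      labels=np.array(meta["labels"]), montage=montage,
                      info=meta.get("info", {}))
    if not with_ground_truth:
        return epochs
    gt = None
    gt_path = directory / "ground_truth.json"
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        gt = GroundTruth(
            artifacts=[ArtifactAnnotation(
                kind=a["kind"], epoch=a["epoch"], channels=tuple(a["channels"]),
                start=a["start"], duration=a["duration"]) for a in raw["artifacts"]],
            bad_channels=tuple(raw["bad_channels"]),
        )
    return epochs, gt


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_fif(epochs: EpochSet, path: str | Path) -> Path:
    """Export to an mne FIF epochs file (readable by any mne install)."""
    path = Path(path)
    if not path.name.endswith("-epo.fif"):
        path = path.with_name(path.stem + "-epo.fif")
    epochs.to_mne().save(path, overwrite=True, verbose="error")
    return path


def read_fif(path: str | Path) -> EpochSet:
    import mne

    ep = mne.read_epochs(path, preload=True, verbose="error")
    inv = {v: k for k, v in ep.event_id.items()}
    labels = np.array([inv[e] for e in ep.events[:, 2]])
    ch = tuple(ep.ch_names)
    montage = Montage.physionet64() if set(ch) == set(Montage.physionet64().ch_names) else None
    return EpochSet(data=ep.get_data(copy=True) * 1e6, fs=ep.info["sfreq"],
                    ch_names=ch, labels=labels, montage=montage)


# ---------------------------------------------------------------------------
# Physionet loader (optional real-data path)

def load_physionet_subject(directory: str | Path, subject_id: int,
                           epoch_span: float = 2.0) -> EpochSet:
    """Load one subject's imagined-movement trials from EDF recordings.

    Expects the Physionet layout ``<directory>/S###/S###R##.edf``.  The
    continuous signal of each run is epoched from cue onset; only the
    four imagery classes are kept.  Excluded subjects are refused with
    the reason; a sampling rate other than 160 Hz is an error.
    """
    import mne

    if subject_id in EXCLUDED_SUBJECTS:
        raise ValueError(
            f"subject {subject_id} is excluded: {EXCLUDED_SUBJECTS[subject_id]}")
    subj_dir = Path(directory) / f"S{subject_id:03d}"
    if not subj_dir.exists():
        raise FileNotFoundError(subj_dir)

    all_data, all_labels, ch_names, fs = [], [], None, None
    for run, mapping in sorted(IMAGERY_RUN_EVENTS.items()):
        edf = subj_dir / f"S{subject_id:03d}R{run:02d}.edf"
        if not edf.exists():
            raise FileNotFoundError(edf)
        raw = mne.io.read_raw_edf(edf, preload=True, verbose="error")
        if abs(raw.info["sfreq"] - 160.0) > 1e-6:
            raise ValueError(
                f"run {run}: sampling frequency {raw.info['sfreq']} != 160 Hz")
        raw.rename_channels(lambda s: s.strip("."))
        if ch_names is None:
            ch_names, fs = tuple(raw.ch_names), raw.info["sfreq"]
        events, event_id = mne.events_from_annotations(raw, verbose="error")
        keep = {code: mapping[name] for name, code in event_id.items() if name in mapping}
        n = int(round(epoch_span * fs))
        sig = raw.get_data() * 1e6
        for onset, _, code in events:
            if code not in keep or onset + n > sig.shape[1]:
                continue
            all_data.append(sig[:, onset:onset + n])
            all_labels.append(keep[code])
    if not all_data:
        raise ValueError("no imagery events found")
    return EpochSet(
        data=np.stack(all_data), fs=fs, ch_names=ch_names,
        labels=np.array(all_labels), montage=Montage.physionet64(),
        info={"subject": subject_id, "source": "physionet"},
    )


# ---------------------------------------------------------------------------
# experiment configuration

@dataclass
class ExperimentConfig:
    """Validated, serialisable description of one experiment run."""

    dataset: dict = field(default_factory=lambda: {"synthetic": {}})
    exclusions: tuple[int, ...] = (88, 89, 92, 100)
    band: str = "none"
    artifact_rejection: bool = False
    regime: str = "simple"
    networks: tuple[str, ...] = ("eegnet",)
    seed: int = 0
    output_dir: str = "results"

    def validate(self) -> "ExperimentConfig":
        from .filters import STUDY_BANDS
        from .models import MODEL_NAMES
        from .training import REGIMES

        if self.band not in STUDY_BANDS:
            raise ValueError(f"band must be one of {sorted(STUDY_BANDS)}")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        bad = [n for n in self.networks if n not in MODEL_NAMES + ("stub",)]
        if bad:
            raise ValueError(f"unknown networks: {bad}")
        if not ({"synthetic", "edf_dir"} & set(self.dataset)):
            raise ValueError("dataset must name 'synthetic' or 'edf_dir'")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(_jsonable(asdict(self))))
        return path
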