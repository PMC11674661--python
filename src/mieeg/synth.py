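"""Ground-truthed synthetic motor-imagery EEG.

Each subject gets balanced 4-class trials shaped like the study data
(default 90 trials of 64 channels x 2 s at 160 Hz, microvolts).  The
generative model is deliberately simple but carries the statistical
structure every downstream stage relies on:

* background = per-channel pink (1/f) noise plus a spatially correlated
  component obtained by smoothly mixing a handful of dipole-like pink
  sources into the montage — this is what makes ICA separation and the
  correlation-based channel criteria meaningful;
* class signal = band-limited oscillation (a few amplitude-modulated
  carriers inside ``signal_band``) projected through a class-specific
  scalp topography (hand classes over the contralateral motor strip,
  both-hands over both, legs over the vertex), scaled so that the
  signal-to-background power ratio equals ``snr``;
* artifacts = frontal biphasic blinks, broadband (>20 Hz) EMG bursts on
  a small channel cluster, globally bad channels (flat or huge
  variance), per-epoch bad channels, and common-phase 50 Hz line noise —
  every injection is written to the :class:`GroundTruth`;
* subjects differ by a gain factor and by a rotation/jitter of the class
  topographies scaled by ``subject_variability``, which is what makes
  cross-subject transfer learning a meaningful problem.

Identical (config, seed) always produces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import (
    CLASSES,
    ArtifactAnnotation,
    EpochSet,
    GroundTruth,
    Montage,
)

#: topography centres per class, as montage electrode names
_CLASS_CENTRES = {
    "left_hand": ("C4",),        # contralateral right motor strip
    "right_hand": ("C3",),
    "both_hands": ("C3", "C4"),
    "both_legs": ("Cz",),
}

_FRONTAL_CENTRE = "Fpz"


def _default_artifact_rates() -> dict[str, float]:
    return {
        "blink": 0.10,              # probability per epoch
        "emg": 0.08,                # probability per epoch
        "global_bad_channel": 1.0,  # expected count per subject (Poisson)
        "epoch_bad_channel": 0.05,  # probability per epoch
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic cohort; defaults mirror the study data shape."""

    n_subjects: int = 10
    trials_per_subject: int = 90
    n_channels: int = 64
    fs: float = 160.0
    epoch_span: float = 2.0
    class_set: tuple[str, ...] = CLASSES
    signal_band: tuple[float, float] = (8.0, 13.0)   # mu band by default
    snr: float = 0.5
    artifact_rates: dict = field(default_factory=_default_artifact_rates)
    line_noise_amp: float = 1.0       # uV
    subject_variability: float = 0.3
    seed: int = 0

    def __post_init__(self):
        low, high = self.signal_band
        if not (0 < low < high):
            raise ValueError("signal_band must satisfy 0 < low < high")
        if high >= self.fs / 2:
            raise ValueError("signal_band.high must be below Nyquist (fs/2)")
        if self.n_channels not in (63, 64):
            raise ValueError("montage supports 63 or 64 channels")
        if self.trials_per_subject < len(self.class_set):
            raise ValueError("need at least one trial per class")
        rates = dict(_default_artifact_rates())
        rates.update(self.artifact_rates)
        object.__setattr__(self, "artifact_rates", rates)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_span))

    def replace(self, **kw) -> "SyntheticConfig":
        from dataclasses import replace as _replace
        return _replace(self, **kw)


def _montage_for(config: SyntheticConfig) -> Montage:
    full = Montage.physionet64()
    if config.n_channels == 64:
        return full
    return full.subset([n for n in full.ch_names if n != "Iz"])


def _pink_noise(rng: np.random.Generator, shape, n: int, alpha: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^alpha noise along the last axis (length n)."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal((*shape, len(freqs)))
            + 1j * rng.standard_normal((*shape, len(freqs)))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _gauss_topo(montage: Montage, centre_names, width: float = 0.55,
                centre_jitter: np.ndarray | None = None) -> np.ndarray:
    """Gaussian-on-the-sphere scalp map peaking at the given electrodes."""
    topo = np.zeros(len(montage.ch_names))
    for k, name in enumerate(centre_names):
        c = montage.position(name).copy()
        if centre_jitter is not None:
            c = c + centre_jitter[k]
            c = c / np.linalg.norm(c)
        d = np.linalg.norm(montage.positions - c, axis=1)  # chord distance
        topo += np.exp(-(d ** 2) / (2 * width ** 2))
    m = topo.max()
    return topo / m if m > 0 else topo


def _subject_topographies(config: SyntheticConfig, montage: Montage,
                          rng: np.random.Generator) -> dict[str, np.ndarray]:
    maps = {}
    for cls in config.class_set:
        centres = _CLASS_CENTRES.get(cls, ("Cz",))
        jitter = rng.normal(0.0, 0.25 * config.subject_variability,
                            size=(len(centres), 3))
        gains = 1.0 + rng.normal(0.0, 0.3 * config.subject_variability,
                                 size=len(montage.ch_names))
        maps[cls] = _gauss_topo(montage, centres, centre_jitter=jitter) * np.abs(gains)
    return maps


def _class_oscillation(config: SyntheticConfig, rng: np.random.Generator,
                       n: int) -> np.ndarray:
    """Band-limited amplitude-modulated oscillation, unit variance."""
    low, high = config.signal_band
    t = np.arange(n) / config.fs
    k = 3
    margin = 0.15 * (high - low)
    freqs = rng.uniform(low + margin, high - margin, size=k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    # slow positive envelope (bandwidth << band width) keeps the power
    # inside the carrier band up to leakage
    env = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.3, 0.7) * t
                             + rng.uniform(0, 2 * np.pi))
    x = env * sum(np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases))
    return x / x.std()


def _blink_template(fs: float, duration: float, n: int, start: int) -> np.ndarray:
    """Smooth biphasic pulse placed at ``start`` within an epoch of length n."""
    d = int(round(duration * fs))
    d = max(d, 8)
    tt = np.arange(d) / d
    pulse = np.sin(2 * np.pi * tt) * np.hanning(d)
    out = np.zeros(n)
    stop = min(start + d, n)
    out[start:stop] = pulse[: stop - start]
    return out


def _emg_burst(rng: np.random.Generator, fs: float, duration: float,
               n: int, start: int) -> np.ndarray:
    """Amplitude-modulated high-pass-filtered noise burst (>20 Hz power)."""
    d = int(round(duration * fs))
    d = max(d, 16)
    noise = rng.standard_normal(d + 64)
    sos = sps.butter(4, 25.0, btype="highpass", fs=fs, output="sos")
    hp = sps.sosfiltfilt(sos, noise)[32:32 + d]
    hp = hp / hp.std() * np.hanning(d)
    out = np.zeros(n)
    stop = min(start + d, n)
    out[start:stop] = hp[: stop - start]
    return out


def generate_subject(config: SyntheticConfig, subject_id: int) -> tuple[EpochSet, GroundTruth]:
    """Generate one subject's labelled epochs plus the injection record.

    Deterministic in (config.seed, subject_id).
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, subject_id])
    montage = _montage_for(config)
    n_ch = len(montage.ch_names)
    n = config.n_samples
    n_tr = config.trials_per_subject
    rates = config.artifact_rates

    # balanced labels up to remainder, shuffled
    reps = int(np.ceil(n_tr / len(config.class_set)))
    labels = np.tile(np.asarray(config.class_set, dtype=object), reps)[:n_tr]
    rng.shuffle(labels)

    gain = 1.0 + config.subject_variability * rng.normal(0.0, 0.2)
    gain = float(np.clip(gain, 0.4, 2.5))
    topos = _subject_topographies(config, montage, rng)
    frontal_topo = _gauss_topo(montage, (_FRONTAL_CENTRE,), width=0.45)

    gt = GroundTruth(class_topographies={c: topos[c].copy() for c in config.class_set})

    # spatially correlated background: dipole-like pink sources, smooth mixing
    n_src = 12
    src_dirs = rng.standard_normal((n_src, 3))
    src_dirs /= np.linalg.norm(src_dirs, axis=1, keepdims=True)
    mix = np.exp(-np.linalg.norm(
        montage.positions[:, None, :] - src_dirs[None, :, :], axis=2) ** 2 / (2 * 0.6 ** 2))

    bg_scale = 10.0  # uV background RMS
    data = np.empty((n_tr, n_ch, n), dtype=np.float64)
    t = np.arange(n) / config.fs

    for e in range(n_tr):
        chan_noise = _pink_noise(rng, (n_ch,), n)
        src_noise = _pink_noise(rng, (n_src,), n)
        bg = 0.7 * chan_noise + 0.7 * (mix @ src_noise) / np.sqrt((mix ** 2).sum(1))[:, None]
        bg *= bg_scale
        epoch = bg.copy()

        if config.snr > 0:
            osc = _class_oscillation(config, rng, n)
            topo = topos[str(labels[e])]
            sig = topo[:, None] * osc[None, :]
            bg_pow = np.mean(bg ** 2)
            sig_pow = np.mean(sig ** 2)
            if sig_pow > 0:
                sig *= np.sqrt(config.snr * bg_pow / sig_pow)
            epoch += sig

        if config.line_noise_amp > 0:
            ph = rng.uniform(0, 2 * np.pi)
            gains = 1.0 + 0.2 * rng.standard_normal(n_ch)
            epoch += (config.line_noise_amp * gains[:, None]
                      * np.sin(2 * np.pi * 50.0 * t + ph)[None, :])

        if rng.uniform() < rates["blink"]:
            dur = rng.uniform(0.3, 0.5)
            start = int(rng.uniform(0, max(n - dur * config.fs, 1)))
            amp = rng.uniform(80.0, 150.0)
            pulse = _blink_template(config.fs, dur, n, start)
            epoch += amp * frontal_topo[:, None] * pulse[None, :]
            chs = tuple(np.array(montage.ch_names)[frontal_topo > 0.5])
            gt.artifacts.append(ArtifactAnnotation(
                "blink", e, chs, start / config.fs, dur))

        if rng.uniform() < rates["emg"]:
            dur = rng.uniform(0.2, 0.6)
            start = int(rng.uniform(0, max(n - dur * config.fs, 1)))
            centre = montage.ch_names[rng.integers(n_ch)]
            topo = _gauss_topo(montage, (centre,), width=0.3)
            amp = rng.uniform(25.0, 60.0)
            burst = _emg_burst(rng, config.fs, dur, n, start)
            epoch += amp * topo[:, None] * burst[None, :]
            chs = tuple(np.array(montage.ch_names)[topo > 0.5])
            gt.artifacts.append(ArtifactAnnotation(
                "emg", e, chs, start / config.fs, dur))

        if rng.uniform() < rates["epoch_bad_channel"]:
            ch = int(rng.integers(n_ch))
            epoch[ch] += bg_scale * 15.0 * _pink_noise(rng, (), n)
            gt.artifacts.append(ArtifactAnnotation(
                "epoch_bad_channel", e, (montage.ch_names[ch],), 0.0, config.epoch_span))

        data[e] = epoch

    data *= gain

    # globally bad channels, injected across all epochs
    n_bad = min(int(rng.poisson(rates["global_bad_channel"])), max(n_ch // 8, 1))
    bad_idx = rng.choice(n_ch, size=n_bad, replace=False) if n_bad else np.array([], int)
    bad_names = []
    for ch in bad_idx:
        ch = int(ch)
        if rng.uniform() < 0.5:   # dead (flat) electrode
            data[:, ch, :] = 0.0
        else:                     # huge broadband noise
            data[:, ch, :] += bg_scale * 20.0 * _pink_noise(rng, (n_tr,), n, alpha=0.2)
        name = montage.ch_names[ch]
        bad_names.append(name)
        gt.artifacts.append(ArtifactAnnotation(
            "bad_channel", None, (name,), 0.0, config.epoch_span))
    gt.bad_channels = tuple(bad_names)

    if config.line_noise_amp > 0:
        gt.artifacts.append(ArtifactAnnotation(
            "line_noise", None, tuple(montage.ch_names), 0.0, config.epoch_span))

    epochs = EpochSet(
        data=data, fs=config.fs, ch_names=montage.ch_names,
        labels=labels.astype(str), montage=montage,
        info={"synthetic": True, "subject": subject_id, "seed": config.seed,
              "snr": config.snr, "signal_band": list(config.signal_band),
              "gain": gain},
    )
    return epochs, gt


def generate_cohort(config: SyntheticConfig) -> list[tuple[EpochSet, GroundTruth]]:
    """Generate ``config.n_subjects`` subjects with per-subject derived seeds."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return [generate_subject(config, sid) for sid in range(config.n_subjects)]
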