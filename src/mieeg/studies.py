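"""Desk-scale study replications.

Each function here reruns one headline behaviour of the pipeline on
synthetic ground-truthed data at a size a single CPU handles in minutes,
and returns the measured quantities.  The analysis drivers, the test
suite, and the acceptance script all call these, so every reported
number is recomputed from scratch.

Scale choices (documented in the methods note): band recovery trains one
reduced Shallow ConvNet (8 temporal / 8 spatial filters) on 90/30 trials
of one subject; the transfer study uses 10 subjects x 32 trials with a
2-fold evaluation split and 10-epoch pre-training.  The statistical
structure (64 channels, 160 Hz, 2 s epochs, 4 balanced classes) is never
reduced.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from . import models
from .evaluation import paired_wilcoxon
from .faster import (
    FasterConfig,
    detect_bad_epochs,
    detect_global_bad_channels,
    ica_decompose,
    score_components,
    z_flags,
)
from .filters import BandSpec, butter_bandpass
from .synth import SyntheticConfig, generate_cohort, generate_subject
from .training import TrainSchedule, transfer_protocol

#: artifact-free generator rates
_CLEAN = {"blink": 0.0, "emg": 0.0, "global_bad_channel": 0.0,
          "epoch_bad_channel": 0.0}

#: reduced Shallow ConvNet used by the desk-scale learning studies
_SMALL_SHALLOW = dict(n_filters_time=8, n_filters_spat=8, dropout=0.25)


def zflag_null_rate(seed: int, n_items: int = 20_000, threshold: float = 3.0) -> dict:
    """Flag rate of the +-3 SD criterion on Gaussian-null parameter values.

    The closed-form expectation is 2*Phi(-3) ~ 0.27%.
    """
    rng = np.random.default_rng(seed)
    values = rng.standard_normal(n_items)
    rate = float(z_flags(values, threshold).mean())
    return {
        "null_flag_rate_pct": 100.0 * rate,
        "expected_pct": 100.0 * 2 * norm.cdf(-threshold),
        "n_items": n_items,
    }


def faster_planted_recall(seed: int) -> dict:
    """Recall of the FASTER detectors on gross (>10 SD) planted artifacts.

    Plants two bad channels (one 20x-noise, one dead), two 500 uV-deflection
    epochs, and a strong recurring frontal blink source, then asks each
    detector whether it flagged its plant.
    """
    rng = np.random.default_rng(seed)
    cfg = SyntheticConfig(trials_per_subject=40, snr=0.5, artifact_rates=_CLEAN,
                          line_noise_amp=0.0, seed=int(rng.integers(2 ** 31)))
    epochs, _ = generate_subject(cfg, 0)
    found, planted = 0, 0

    # --- bad channels -------------------------------------------------------
    noisy, dead = rng.choice(epochs.n_channels, size=2, replace=False)
    contaminated = epochs.copy()
    contaminated.data[:, noisy, :] += (20.0 * epochs.data.std()
                                       * rng.standard_normal(contaminated.data[:, noisy, :].shape))
    contaminated.data[:, dead, :] = 0.0
    ch_flags, _ = detect_global_bad_channels(contaminated)
    planted += 2
    found += int(ch_flags[noisy]) + int(ch_flags[dead])

    # --- bad epochs ---------------------------------------------------------
    bad_eps = rng.choice(epochs.n_epochs, size=2, replace=False)
    contaminated = epochs.copy()
    t = np.arange(epochs.n_samples) / epochs.fs
    pulse = 500.0 * np.sin(np.pi * t / t[-1])
    for e in bad_eps:
        contaminated.data[e] += pulse[None, :]
    ep_flags, _ = detect_bad_epochs(contaminated)
    planted += 2
    found += int(ep_flags[bad_eps[0]]) + int(ep_flags[bad_eps[1]])

    # --- blink component ----------------------------------------------------
    blink_cfg = cfg.replace(artifact_rates={**_CLEAN, "blink": 0.8},
                            trials_per_subject=30)
    blinky, _ = generate_subject(blink_cfg, 0)
    fcfg = FasterConfig(seed=seed % (2 ** 31))
    ica = ica_decompose(blinky, fcfg)
    rejected, _, _ = score_components(ica, blinky, fcfg)
    fpz = blinky.channel_index("Fpz")
    y = blinky.data[:, fpz, :].ravel()
    corrs = np.abs([np.corrcoef(c, y)[0, 1] for c in ica.sources])
    planted += 1
    found += int(int(np.argmax(corrs)) in rejected)

    return {"recall": found / planted, "found": found, "planted": planted}


def band_recovery(seed: int, train_epochs: int = 25) -> dict:
    """The frequency-filtering logic on planted band-limited class signal.

    One subject with the discriminative signal confined to 8-13 Hz; a
    reduced Shallow ConvNet is trained after filtering to a band
    containing the signal (5-15 Hz) and to a disjoint band (20-45 Hz).
    """
    cfg = SyntheticConfig(trials_per_subject=120, snr=1.0, signal_band=(8.0, 13.0),
                          artifact_rates=_CLEAN, line_noise_amp=0.0,
                          subject_variability=0.0, seed=seed % (2 ** 31))
    epochs, _ = generate_subject(cfg, 0)
    out = {"n_test": 30, "chance": 0.25,
           "chance_sd": float(np.sqrt(0.25 * 0.75 / 30))}
    from sklearn.model_selection import train_test_split

    for key, band in (("inband", BandSpec(5.0, 15.0)),
                      ("offband", BandSpec(20.0, 45.0))):
        filt = butter_bandpass(epochs, band)
        x = filt.data.astype(np.float32)
        y = filt.labels.astype(str)
        xt, xe, yt, ye = train_test_split(x, y, test_size=30,
                                          random_state=seed % (2 ** 31), stratify=y)
        spec = models.build_shallow_convnet(n_channels=64, T=x.shape[2],
                                            **_SMALL_SHALLOW)
        m = models.fit(spec, xt, yt, epochs=train_epochs, batch_size=16,
                       seed=seed % (2 ** 31))
        out[f"{key}_accuracy"] = m.accuracy(xe, ye)
    return out


def transfer_contrast(seed: int) -> dict:
    """Fine-tuned vs frozen pre-trained accuracy on a high-variability cohort.

    10 subjects, every subject held out once; the paired Wilcoxon p-value
    tests whether fine-tuning on the held-out subject's own trials beats
    the frozen pooled model.
    """
    cfg = SyntheticConfig(n_subjects=10, trials_per_subject=32, snr=1.0,
                          subject_variability=1.0, artifact_rates=_CLEAN,
                          line_noise_amp=0.0, seed=seed % (2 ** 31))
    cohort = [ep for ep, _ in generate_cohort(cfg)]
    sched = TrainSchedule(regime="transfer", k_folds=2, repeats=1,
                          tl_iterations=10, max_epochs=10, finetune_epochs=15,
                          batch_size=16, seed=seed % (2 ** 31))
    table = transfer_protocol(cohort, "shallow_convnet", sched,
                              model_hp=_SMALL_SHALLOW)
    piv = table.groupby(["subject", "variant"])["accuracy"].mean().unstack()
    return {
        "frozen_accuracy": float(piv["frozen"].mean()),
        "finetuned_accuracy": float(piv["finetuned"].mean()),
        "improvement": float((piv["finetuned"] - piv["frozen"]).mean()),
        "wilcoxon_p": paired_wilcoxon(piv["frozen"], piv["finetuned"]),
        "n_subjects": int(len(piv)),
        "table": table,
    }
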