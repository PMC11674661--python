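"""FASTER: statistics, detectors, ICA scoring, spline repair, pipeline."""

import numpy as np
import pytest
from scipy.stats import norm

from mieeg.containers import EpochSet, Montage
from mieeg.faster import (
    FasterConfig,
    detect_bad_epochs,
    detect_global_bad_channels,
    hurst_exponent,
    ica_decompose,
    run_faster,
    score_components,
    spherical_spline_interpolate,
    z_flags,
)
from mieeg.synth import SyntheticConfig, generate_subject

from conftest import CLEAN_RATES


# ---------------------------------------------------------------------------
# hurst

def test_hurst_white_noise_near_half(rng):
    h = hurst_exponent(rng.standard_normal(8192))
    assert h == pytest.approx(0.5, abs=0.1)


def test_hurst_integrated_noise_near_one(rng):
    h = hurst_exponent(np.cumsum(rng.standard_normal(8192)))
    assert h >= 0.9


def test_hurst_scale_invariant(rng):
    x = rng.standard_normal(2048)
    assert hurst_exponent(x) == pytest.approx(hurst_exponent(10 * x), abs=1e-9)


def test_hurst_degenerate_inputs(rng):
    assert np.isnan(hurst_exponent(np.ones(1024)))
    with pytest.raises(ValueError):
        hurst_exponent(rng.standard_normal(64))


# ---------------------------------------------------------------------------
# z_flags

def test_z_flags_no_spread_no_flags():
    assert not z_flags([1.0, 1.0, 1.0, 1.0]).any()


def test_z_flags_planted_outlier(rng):
    v = np.concatenate([rng.standard_normal(50), [20.0]])
    m, sd = v.mean(), v.std()                     # brute-force oracle
    expect = np.abs(v - m) / sd > 3
    assert np.array_equal(z_flags(v, 3.0), expect)
    assert list(np.flatnonzero(z_flags(v, 3.0))) == [50]


def test_z_flags_gaussian_null_rate(rng):
    """Under a Gaussian null the expected flag fraction is 2*Phi(-3)."""
    v = rng.standard_normal(10_000)
    rate = z_flags(v, 3.0).mean()
    assert rate == pytest.approx(2 * norm.cdf(-3), abs=0.002)


def test_z_flags_requires_three_items():
    with pytest.raises(ValueError):
        z_flags([1.0, 2.0])


def test_z_flags_monotone_in_threshold(rng):
    v = rng.standard_normal(500)
    loose = set(np.flatnonzero(z_flags(v, 2.0)))
    tight = set(np.flatnonzero(z_flags(v, 3.0)))
    assert tight <= loose


# ---------------------------------------------------------------------------
# channel / epoch detectors

def _plant_channels(epochs):
    out = epochs.copy()
    flat = out.channel_index("P3")
    noisy = out.channel_index("F4")
    out.data[:, flat, :] = 0.0
    rng = np.random.default_rng(1)
    out.data[:, noisy, :] += np.sqrt(20.0) * out.data.std() * \
        rng.standard_normal(out.data[:, noisy, :].shape)
    return out, flat, noisy


def test_planted_bad_channels_flagged(clean_subject):
    epochs, _ = clean_subject
    planted, flat, noisy = _plant_channels(epochs)
    flags, table = detect_global_bad_channels(planted)
    assert flags[flat] and flags[noisy]
    assert abs(table.iloc[noisy]["variance"]) > 3


def test_clean_data_few_channel_false_positives(clean_subject):
    epochs, _ = clean_subject
    flags, _ = detect_global_bad_channels(epochs)
    assert flags.sum() <= 2


def test_planted_blink_epoch_flagged(clean_subject):
    epochs, _ = clean_subject
    planted = epochs.copy()
    t = np.arange(epochs.n_samples) / epochs.fs
    pulse = 200.0 * np.exp(-((t - 1.0) ** 2) / 0.02)
    planted.data[7] += pulse[None, :]
    flags, _ = detect_bad_epochs(planted)
    assert flags[7]
    assert flags.sum() <= 3


def test_identical_epochs_none_flagged(clean_subject):
    epochs, _ = clean_subject
    same = epochs.copy(data=np.tile(epochs.data[:1], (10, 1, 1)),
                       labels=epochs.labels[:10])
    flags, _ = detect_bad_epochs(same)
    assert not flags.any()


def test_epoch_flags_permutation_equivariant(default_subject):
    epochs, _ = default_subject
    flags, _ = detect_bad_epochs(epochs)
    rng = np.random.default_rng(3)
    perm = rng.permutation(epochs.n_epochs)
    flags_p, _ = detect_bad_epochs(epochs.select_epochs(perm))
    assert set(perm[np.flatnonzero(flags_p)]) == set(np.flatnonzero(flags))


# ---------------------------------------------------------------------------
# ICA

def _mixed_epochs(rng, n_ch=8, n_ep=10, n=400, fs=160.0):
    t = np.arange(n_ep * n) / fs
    s = np.vstack([
        np.sign(np.sin(2 * np.pi * 3 * t)),
        np.sin(2 * np.pi * 7 * t),
        rng.laplace(size=t.size),
    ])
    mix = rng.standard_normal((n_ch, 3))
    x = mix @ s
    data = x.reshape(n_ch, n_ep, n).transpose(1, 0, 2)
    ep = EpochSet(data=data, fs=fs, ch_names=[f"c{i}" for i in range(n_ch)],
                  labels=np.zeros(n_ep, dtype=object))
    return ep, s


def test_ica_recovers_planted_sources(rng):
    epochs, sources = _mixed_epochs(rng)
    ica = ica_decompose(epochs, FasterConfig(ica_n_components=3))
    corr = np.abs(np.corrcoef(np.vstack([sources, ica.sources]))[:3, 3:])
    assert (corr.max(axis=1) > 0.95).all()


def test_ica_reconstruction_identity(rng):
    epochs, _ = _mixed_epochs(rng)
    ica = ica_decompose(epochs, FasterConfig(ica_n_components=3))
    x = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    rel = np.abs(ica.reconstruct() - x).max() / np.abs(x).max()
    assert rel < 1e-6


def test_ica_deterministic(rng):
    epochs, _ = _mixed_epochs(rng)
    a = ica_decompose(epochs, FasterConfig(ica_n_components=3, seed=11))
    b = ica_decompose(epochs, FasterConfig(ica_n_components=3, seed=11))
    assert np.array_equal(a.sources, b.sources)


def test_blink_component_rejected():
    """A planted frontal, spiky, low-frequency source is rejected with an
    ocular-correlation or kurtosis reason."""
    cfg = SyntheticConfig(trials_per_subject=30, snr=0.3,
                          artifact_rates={**CLEAN_RATES, "blink": 0.9},
                          line_noise_amp=0.0, seed=31)
    epochs, gt = generate_subject(cfg, 0)
    assert gt.of_kind("blink")
    ica = ica_decompose(epochs, FasterConfig())
    rejected, records, _ = score_components(ica, epochs, FasterConfig())
    assert rejected
    reasons = {r for rec in records for r in rec["reasons"]}
    assert {"eog_correlation", "kurtosis"} & reasons
    # the rejected set should contain the blink: its component correlates
    # strongly with the frontal proxy channels
    fpz = epochs.channel_index("Fpz")
    y = epochs.data[:, fpz, :].ravel()
    corrs = np.abs([np.corrcoef(c, y)[0, 1] for c in ica.sources])
    assert int(np.argmax(corrs)) in rejected


def test_equal_sinusoid_components_not_rejected():
    fs, n_ep, n = 160.0, 6, 400
    t = np.arange(n_ep * n) / fs
    comps = np.vstack([np.sin(2 * np.pi * (5 + k) * t + 0.3 * k) for k in range(6)])
    mix = np.random.default_rng(5).standard_normal((8, 6))
    data = (mix @ comps).reshape(8, n_ep, n).transpose(1, 0, 2)
    ep = EpochSet(data=data, fs=fs, ch_names=[f"c{i}" for i in range(8)],
                  labels=np.zeros(n_ep, dtype=object))
    ica = ica_decompose(ep, FasterConfig(ica_n_components=6, eog_proxy_channels=()))
    with pytest.warns(UserWarning):
        rejected, _, _ = score_components(ica, ep, FasterConfig(eog_proxy_channels=()))
    assert rejected == []


# ---------------------------------------------------------------------------
# spherical spline

def test_spline_reproduces_constant_field(montage):
    const = np.full((64, 16), 7.5)
    out = spherical_spline_interpolate(const, np.array([5]), montage)
    assert np.allclose(out[5], 7.5, atol=1e-6)


@pytest.mark.parametrize("harmonic", [
    lambda p: p[:, 2],                       # Y_1^0
    lambda p: p[:, 0] * p[:, 1],             # Y_2 sectoral
    lambda p: 3 * p[:, 2] ** 2 - 1,          # Y_2^0
])
def test_spline_recovers_low_order_harmonics(montage, harmonic):
    field = harmonic(montage.positions)
    scale = np.abs(field).max()
    for bad in [0, 10, 30, 42, 63]:
        x = np.tile(field[:, None], (1, 3))
        est = spherical_spline_interpolate(x, np.array([bad]), montage)[bad, 0]
        assert abs(est - field[bad]) / scale < 0.1


def test_spline_empty_bad_set_is_identity(montage, rng):
    x = rng.standard_normal((64, 8))
    out = spherical_spline_interpolate(x, np.array([], dtype=int), montage)
    assert np.array_equal(out, x)


def test_spline_needs_enough_good_channels(montage, rng):
    x = rng.standard_normal((64, 8))
    with pytest.raises(ValueError):
        spherical_spline_interpolate(x, np.arange(61), montage)


# ---------------------------------------------------------------------------
# the full pipeline

@pytest.fixture(scope="module")
def faster_on_clean():
    cfg = SyntheticConfig(trials_per_subject=30, snr=0.5,
                          artifact_rates=CLEAN_RATES, line_noise_amp=0.0, seed=41)
    epochs, _ = generate_subject(cfg, 0)
    cleaned, report = run_faster(epochs, FasterConfig(seed=1))
    return epochs, cleaned, report


def test_clean_data_mostly_retained(faster_on_clean):
    epochs, cleaned, report = faster_on_clean
    assert cleaned.n_epochs >= 0.95 * epochs.n_epochs
    assert len(report.global_bad_channels) <= 2
    assert cleaned.n_channels == epochs.n_channels
    assert cleaned.n_samples == epochs.n_samples
    assert cleaned.ch_names == epochs.ch_names


def test_average_reference_applied(faster_on_clean):
    _, cleaned, _ = faster_on_clean
    mean = cleaned.data.mean(axis=1)
    rms = np.sqrt((cleaned.data ** 2).mean())
    assert np.abs(mean).max() < 1e-9 * max(rms, 1.0)


def test_report_indices_valid(faster_on_clean):
    epochs, cleaned, report = faster_on_clean
    for i in report.rejected_epochs:
        assert 0 <= i < epochs.n_epochs
    for e, ch in report.per_epoch_interpolations:
        assert 0 <= e < epochs.n_epochs
        assert ch in epochs.ch_names


def test_blink_contamination_reduced():
    """After FASTER, frontal channels correlate much less with the known
    blink time course."""
    cfg = SyntheticConfig(trials_per_subject=30, snr=0.3,
                          artifact_rates={**CLEAN_RATES, "blink": 0.8},
                          line_noise_amp=0.0, seed=43)
    epochs, gt = generate_subject(cfg, 0)
    cleaned, report = run_faster(epochs, FasterConfig(seed=2))
    retained = cleaned.info["retained_epochs"]
    fs, n = epochs.fs, epochs.n_samples
    fpz = epochs.channel_index("Fpz")

    def blink_corr(data, epoch_list):
        cors = []
        for a in gt.of_kind("blink"):
            if a.epoch not in epoch_list:
                continue
            template = np.zeros(n)
            d = int(a.duration * fs)
            start = int(a.start * fs)
            tt = np.arange(d) / d
            template[start:start + d] = (np.sin(2 * np.pi * tt) * np.hanning(d))[:n - start]
            row = epoch_list.index(a.epoch)
            cors.append(abs(np.corrcoef(data[row, fpz], template)[0, 1]))
        return np.mean(cors)

    pre = blink_corr(epochs.data[retained], list(retained))
    post = blink_corr(cleaned.data, list(retained))
    assert post < 0.5 * pre


def test_raising_threshold_shrinks_rejections(default_subject):
    epochs, _ = default_subject
    lo_flags, _ = detect_global_bad_channels(epochs, FasterConfig(z_threshold=2.5))
    hi_flags, _ = detect_global_bad_channels(epochs, FasterConfig(z_threshold=4.0))
    assert set(np.flatnonzero(hi_flags)) <= set(np.flatnonzero(lo_flags))
    lo_ep, _ = detect_bad_epochs(epochs, FasterConfig(z_threshold=2.5))
    hi_ep, _ = detect_bad_epochs(epochs, FasterConfig(z_threshold=4.0))
    assert set(np.flatnonzero(hi_ep)) <= set(np.flatnonzero(lo_ep))


def test_second_pass_rejects_little(faster_on_clean):
    _, cleaned, _ = faster_on_clean
    _, report2 = run_faster(cleaned, FasterConfig(seed=3, run_ica=False))
    assert len(report2.rejected_epochs) <= 3
    assert len(report2.global_bad_channels) <= 2
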