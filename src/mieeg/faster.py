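"""Modified FASTER artifact rejection.

FASTER (fully automated statistical thresholding for EEG artifact
rejection) flags items — channels, epochs, independent components,
per-epoch channels — whose summary statistics deviate from the
population of like items by more than ``z_threshold`` (default 3)
standard deviations.  This implementation follows the four-step variant
used in offline motor-imagery work:

1. globally bad channels (variance, mean absolute correlation with the
   other channels, Hurst exponent), later repaired by spherical-spline
   interpolation;
2. bad epochs (amplitude range, deviation from the channel means,
   variance), removed;
3. fast-ICA over the retained channels/epochs; components are rejected
   for excessive correlation with ocular-proxy electrodes or for
   outlying kurtosis, power-spectrum gradient, Hurst exponent, or median
   time-gradient, and the data are rebuilt without them;
4. per-epoch bad channels (variance, median gradient, amplitude range,
   deviation from channel mean within the epoch), repaired per epoch by
   spherical-spline interpolation; finally the data are re-referenced to
   the average of all electrodes.

The original fifth step (outlier rejection across subjects) is
intentionally not implemented.  Z-scores are always computed across the
item population of the current recording only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from scipy.special import eval_legendre

from .containers import FRONTAL_EOG_PROXY, EpochSet, Montage


@dataclass(frozen=True)
class FasterConfig:
    z_threshold: float = 3.0
    eog_proxy_channels: tuple[str, ...] = FRONTAL_EOG_PROXY
    ica_n_components: int | None = None   # None -> number of retained channels
    detect_channels: bool = True
    detect_epochs: bool = True
    run_ica: bool = True
    epoch_interpolation: bool = True
    average_reference: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


@dataclass
class FasterReport:
    """Everything FASTER flagged, with the per-criterion Z-scores."""

    global_bad_channels: list[str] = field(default_factory=list)
    channel_z: pd.DataFrame | None = None
    rejected_epochs: list[int] = field(default_factory=list)
    epoch_z: pd.DataFrame | None = None
    rejected_components: list[dict] = field(default_factory=list)
    component_z: pd.DataFrame | None = None
    per_epoch_interpolations: list[tuple[int, str]] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def n_rejections(self) -> int:
        return (len(self.global_bad_channels) + len(self.rejected_epochs)
                + len(self.rejected_components) + len(self.per_epoch_interpolations))

    def to_dict(self) -> dict:
        return {
            "global_bad_channels": list(self.global_bad_channels),
            "channel_z": None if self.channel_z is None else self.channel_z.to_dict(),
            "rejected_epochs": [int(i) for i in self.rejected_epochs],
            "epoch_z": None if self.epoch_z is None else self.epoch_z.to_dict(),
            "rejected_components": self.rejected_components,
            "component_z": None if self.component_z is None else self.component_z.to_dict(),
            "per_epoch_interpolations": [[int(e), c] for e, c in self.per_epoch_interpolations],
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# statistics

def hurst_exponent(series: np.ndarray) -> float:
    """Rescaled-range (R/S) Hurst estimate with the Anis–Lloyd–Peters
    small-sample correction.

    ~0.5 for uncorrelated noise, ~1 for integrated noise.  Invariant to
    scaling of the input.  Returns NaN for (near-)constant series — such
    channels are flagged through the variance criterion anyway.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    n = x.size
    if n < 128:
        raise ValueError("need at least 128 samples for the Hurst estimate")
    if np.ptp(x) == 0 or not np.isfinite(x).all():
        return np.nan
    sizes = np.unique(np.floor(np.logspace(
        np.log10(16), np.log10(n // 2), num=12)).astype(int))
    log_rs, log_expected, log_n = [], [], []
    for w in sizes:
        n_blocks = n // w
        blocks = x[: n_blocks * w].reshape(n_blocks, w)
        centred = blocks - blocks.mean(axis=1, keepdims=True)
        z = np.cumsum(centred, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = blocks.std(axis=1)
        ok = s > 0
        if not ok.any():
            continue
        rs = np.mean(r[ok] / s[ok])
        if rs <= 0:
            continue
        log_rs.append(np.log(rs))
        log_expected.append(np.log(_expected_rs(w)))
        log_n.append(np.log(w))
    if len(log_rs) < 3:
        return np.nan
    log_rs = np.asarray(log_rs)
    log_expected = np.asarray(log_expected)
    log_n = np.asarray(log_n)
    # regress the deviation from the iid expectation; H = 0.5 + slope
    slope = np.polyfit(log_n, log_rs - log_expected, 1)[0]
    return float(0.5 + slope)


def _expected_rs(w: int) -> float:
    """E[R/S] for iid Gaussian samples of length w (Anis–Lloyd, Peters)."""
    from math import lgamma, exp, sqrt, pi

    i = np.arange(1, w)
    s = np.sum(np.sqrt((w - i) / i))
    if w <= 340:  # exact gamma-function prefactor for small windows
        return ((w - 0.5) / w) * exp(lgamma((w - 1) / 2) - lgamma(w / 2)) / sqrt(pi) * s
    return ((w - 0.5) / w) / sqrt(w * pi / 2) * s


def z_flags(values, threshold: float = 3.0) -> np.ndarray:
    """Two-sided outlier flags: |(v - mean) / sd| > threshold.

    Zero spread flags nothing; non-finite parameter values are always
    flagged (they mark degenerate items such as constant channels).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1-D list of at least 3 values")
    finite = np.isfinite(v)
    flags = ~finite
    if finite.sum() >= 2:
        m = v[finite].mean()
        sd = v[finite].std()
        if sd > 0:
            flags = flags | (np.abs(v - m) / sd > threshold) & finite
    return flags


def z_scores(values) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(v)
    out = np.full(v.shape, np.inf)
    if finite.sum() >= 2:
        m, sd = v[finite].mean(), v[finite].std()
        if sd > 0:
            out[finite] = (v[finite] - m) / sd
        else:
            out[finite] = 0.0
    return out


# ---------------------------------------------------------------------------
# step 1: global bad channels

def detect_global_bad_channels(epochs: EpochSet, cfg: FasterConfig = FasterConfig()):
    """Union of Z-flags over variance, mean |correlation|, Hurst exponent.

    Returns (bool flags per channel, Z-score table).
    """
    if epochs.n_channels < 4:
        raise ValueError("need at least 4 channels")
    x = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    variance = x.var(axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    np.fill_diagonal(corr, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # dead channel: all-nan row
        mean_corr = np.nanmean(np.abs(corr), axis=1)
    # a dead channel has undefined correlations: mark non-finite
    mean_corr[~np.isfinite(mean_corr)] = np.nan
    hurst = np.array([hurst_exponent(ch) for ch in x])

    table = pd.DataFrame({
        "variance": z_scores(variance),
        "correlation": z_scores(mean_corr),
        "hurst": z_scores(hurst),
    }, index=list(epochs.ch_names))
    flags = (z_flags(variance, cfg.z_threshold)
             | z_flags(mean_corr, cfg.z_threshold)
             | z_flags(hurst, cfg.z_threshold))
    return flags, table


# ---------------------------------------------------------------------------
# step 2: bad epochs

def detect_bad_epochs(epochs: EpochSet, cfg: FasterConfig = FasterConfig(),
                      channel_mask: np.ndarray | None = None):
    """Union of Z-flags over amplitude range, channel-mean deviation, variance.

    Parameters are channel-averaged within each epoch; channels excluded
    by ``channel_mask`` (True = keep) do not contribute.
    """
    if epochs.n_epochs < 5:
        raise ValueError("need at least 5 epochs")
    data = epochs.data
    if channel_mask is not None:
        data = data[:, channel_mask, :]
    amp_range = np.ptp(data, axis=2).mean(axis=1)
    ch_means = data.mean(axis=2)                        # (epochs, channels)
    deviation = np.abs(ch_means - ch_means.mean(axis=0)).mean(axis=1)
    variance = data.var(axis=2).mean(axis=1)

    table = pd.DataFrame({
        "amplitude_range": z_scores(amp_range),
        "deviation": z_scores(deviation),
        "variance": z_scores(variance),
    }, index=np.arange(epochs.n_epochs))
    flags = (z_flags(amp_range, cfg.z_threshold)
             | z_flags(deviation, cfg.z_threshold)
             | z_flags(variance, cfg.z_threshold))
    return flags, table


# ---------------------------------------------------------------------------
# step 3: ICA

@dataclass
class ICAResult:
    sources: np.ndarray        # (n_components, n_kept_epochs * n_samples)
    mixing: np.ndarray         # (n_channels_kept, n_components)
    mean: np.ndarray           # (n_channels_kept,)
    channel_idx: np.ndarray    # indices of retained channels in the EpochSet
    epoch_idx: np.ndarray      # indices of retained epochs
    n_samples: int
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Back-project (optionally a component subset) to channel space."""
        s = self.sources if keep is None else self.sources[keep]
        m = self.mixing if keep is None else self.mixing[:, keep]
        return m @ s + self.mean[:, None]


def ica_decompose(epochs: EpochSet, cfg: FasterConfig = FasterConfig(),
                  exclude_channels=(), exclude_epochs=(),
                  max_retries: int = 2) -> ICAResult:
    """Fast-ICA (logcosh/tanh contrast) on the retained channels and epochs.

    The fit excludes flagged channels and epochs; the unmixing/mixing
    pair reconstructs the fitted data to float precision.  A fit that
    does not reach the fixed-point tolerance is retried with a shifted
    seed; if none converges the last iterate is used with a warning and
    ``converged=False`` — on recordings without distinctly non-Gaussian
    sources the fixed point is genuinely weakly identified, while the
    reconstruction identity and component statistics remain valid.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    ch_idx = np.array([i for i in range(epochs.n_channels) if i not in set(exclude_channels)])
    ep_idx = np.array([i for i in range(epochs.n_epochs) if i not in set(exclude_epochs)])
    if ch_idx.size < 2 or ep_idx.size < 1:
        raise ValueError("not enough retained channels/epochs for ICA")
    x = epochs.data[np.ix_(ep_idx, ch_idx)].transpose(1, 0, 2).reshape(ch_idx.size, -1)
    n_comp = cfg.ica_n_components or ch_idx.size

    result = None
    for attempt in range(max_retries):
        ica = FastICA(n_components=n_comp, fun="logcosh", whiten="unit-variance",
                      max_iter=1000, tol=1e-3, random_state=cfg.seed + attempt)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sources = ica.fit_transform(x.T).T
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        result = ICAResult(sources=sources, mixing=ica.mixing_, mean=ica.mean_,
                           channel_idx=ch_idx, epoch_idx=ep_idx,
                           n_samples=epochs.n_samples, converged=converged)
        if converged:
            return result
    warnings.warn("fast-ICA did not reach tolerance; using the last iterate",
                  stacklevel=2)
    return result


def _psd_gradient(source: np.ndarray, fs: float) -> float:
    """Mean gradient of the log power spectrum above the low-frequency bulk."""
    freqs, psd = sps.welch(source, fs=fs, nperseg=min(256, source.size))
    band = freqs >= min(8.0, freqs[-1] / 2)
    logp = np.log10(np.maximum(psd[band], 1e-30))
    return float(np.mean(np.gradient(logp)))


def score_components(ica: ICAResult, epochs: EpochSet,
                     cfg: FasterConfig = FasterConfig()):
    """Reject components by EOG-proxy correlation or outlying statistics.

    Returns (rejected indices, detail records, Z table).  Criteria:
    max |corr| with ocular-proxy channels, kurtosis, power-spectrum
    gradient, Hurst exponent, median time-gradient — each Z-scored
    across the component population.
    """
    proxies = [p for p in cfg.eog_proxy_channels if p in epochs.ch_names]
    if not proxies:
        warnings.warn("no EOG-proxy channels present; skipping the ocular criterion",
                      stacklevel=2)
    s = ica.sources
    n_comp = s.shape[0]

    params = {
        "kurtosis": stats.kurtosis(s, axis=1),
        "power_gradient": np.array([_psd_gradient(c, epochs.fs) for c in s]),
        "hurst": np.array([hurst_exponent(c) for c in s]),
        "median_gradient": np.median(np.abs(np.diff(s, axis=1)), axis=1),
    }
    flag_by = {k: z_flags(v, cfg.z_threshold) for k, v in params.items()}

    eog_corr = np.zeros(n_comp)
    if proxies:
        eog_flags = np.zeros(n_comp, dtype=bool)
        for p in proxies:
            y = epochs.data[np.ix_(ica.epoch_idx,
                                   [epochs.channel_index(p)])].ravel()
            c = np.array([abs(np.corrcoef(comp, y)[0, 1]) if comp.std() > 0 else 0.0
                          for comp in s])
            eog_corr = np.maximum(eog_corr, c)
            eog_flags |= z_flags(c, cfg.z_threshold)
        flag_by["eog_correlation"] = eog_flags
        params["eog_correlation"] = eog_corr

    table = pd.DataFrame({k: z_scores(v) for k, v in params.items()},
                         index=np.arange(n_comp))
    rejected, records = [], []
    for k in range(n_comp):
        reasons = tuple(name for name, fl in flag_by.items() if fl[k])
        if reasons:
            rejected.append(k)
            records.append({"component": k, "reasons": list(reasons),
                            "z": {name: float(table.loc[k, name]) for name in reasons}})
    return rejected, records, table


# ---------------------------------------------------------------------------
# spherical spline interpolation (Perrin-style)

_SPLINE_TERMS = 50
_SPLINE_STIFFNESS = 4
_SPLINE_REG = 1e-7


def _g_spline(cosang: np.ndarray) -> np.ndarray:
    n = np.arange(1, _SPLINE_TERMS + 1)
    coef = (2 * n + 1) / (n ** _SPLINE_STIFFNESS * (n + 1.0) ** _SPLINE_STIFFNESS)
    out = np.zeros_like(cosang, dtype=np.float64)
    for ni, ci in zip(n, coef):
        out += ci * eval_legendre(ni, cosang)
    return out / (4 * np.pi)


def spline_interpolation_matrix(pos_good: np.ndarray, pos_bad: np.ndarray) -> np.ndarray:
    """Matrix M with y_bad = M @ y_good under the spherical-spline model."""
    g_gg = _g_spline(np.clip(pos_good @ pos_good.T, -1, 1))
    g_bg = _g_spline(np.clip(pos_bad @ pos_good.T, -1, 1))
    ng = pos_good.shape[0]
    a = np.empty((ng + 1, ng + 1))
    a[:ng, :ng] = g_gg + _SPLINE_REG * np.eye(ng)
    a[:ng, ng] = 1.0
    a[ng, :ng] = 1.0
    a[ng, ng] = 0.0
    c = np.linalg.pinv(a)
    ext = np.hstack([g_bg, np.ones((pos_bad.shape[0], 1))])
    return ext @ c[:, :ng]


def spherical_spline_interpolate(epoch: np.ndarray, bad: np.ndarray,
                                 montage: Montage) -> np.ndarray:
    """Replace bad-channel rows of (channels x samples) ``epoch`` by the
    spherical-spline estimate from the good channels."""
    bad = np.asarray(bad, dtype=int)
    if bad.size == 0:
        return epoch.copy()
    n_ch = epoch.shape[0]
    good = np.setdiff1d(np.arange(n_ch), bad)
    if good.size < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    m = spline_interpolation_matrix(montage.positions[good], montage.positions[bad])
    out = epoch.copy()
    out[bad] = m @ epoch[good]
    return out


# ---------------------------------------------------------------------------
# step 4 helper: per-epoch bad channels

def detect_epoch_bad_channels(epochs: EpochSet, cfg: FasterConfig = FasterConfig(),
                              exclude_channels=()):
    """Per-epoch channel flags (variance, median gradient, amplitude range,
    deviation from the channel's own mean), Z-scored across channels
    within each epoch."""
    excluded = set(exclude_channels)
    grand_mean = epochs.data.mean(axis=(0, 2))
    flags = np.zeros((epochs.n_epochs, epochs.n_channels), dtype=bool)
    for e in range(epochs.n_epochs):
        x = epochs.data[e]
        variance = x.var(axis=1)
        med_grad = np.median(np.abs(np.diff(x, axis=1)), axis=1)
        amp_range = np.ptp(x, axis=1)
        deviation = np.abs(x.mean(axis=1) - grand_mean)
        f = (z_flags(variance, cfg.z_threshold)
             | z_flags(med_grad, cfg.z_threshold)
             | z_flags(amp_range, cfg.z_threshold)
             | z_flags(deviation, cfg.z_threshold))
        for ci in excluded:
            f[ci] = False
        flags[e] = f
    return flags


# ---------------------------------------------------------------------------
# the full pipeline

def run_faster(epochs: EpochSet, cfg: FasterConfig = FasterConfig()):
    """Run the four FASTER steps and average-reference the result.

    Returns (cleaned EpochSet, FasterReport).  Epoch count may shrink
    (bad epochs are dropped); channel count never changes (bad channels
    are interpolated, not removed).
    """
    report = FasterReport()
    report.notes["z_threshold"] = cfg.z_threshold
    montage = epochs.montage
    if montage is None:
        raise ValueError("run_faster needs a montage (spherical-spline repair)")

    # step 1: globally bad channels
    bad_ch_idx: list[int] = []
    if cfg.detect_channels:
        ch_flags, report.channel_z = detect_global_bad_channels(epochs, cfg)
        bad_ch_idx = list(np.flatnonzero(ch_flags))
        report.global_bad_channels = [epochs.ch_names[i] for i in bad_ch_idx]

    # step 2: bad epochs (parameters from good channels only)
    keep_mask = np.ones(epochs.n_channels, dtype=bool)
    keep_mask[bad_ch_idx] = False
    ep_flags = np.zeros(epochs.n_epochs, dtype=bool)
    if cfg.detect_epochs:
        ep_flags, report.epoch_z = detect_bad_epochs(epochs, cfg, channel_mask=keep_mask)
        report.rejected_epochs = list(np.flatnonzero(ep_flags))
    retained_idx = np.flatnonzero(~ep_flags)
    out = epochs.select_epochs(retained_idx)
    out.info["retained_epochs"] = [int(i) for i in retained_idx]

    # step 3: ICA component rejection (fit excludes flagged items)
    if cfg.run_ica:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ica = ica_decompose(epochs, cfg, exclude_channels=bad_ch_idx,
                                exclude_epochs=list(np.flatnonzero(ep_flags)))
        report.notes["ica_converged"] = ica.converged
        rejected, records, report.component_z = score_components(ica, epochs, cfg)
        report.rejected_components = records
        keep = np.setdiff1d(np.arange(ica.n_components), rejected)
        cleaned = ica.reconstruct(keep=keep)
        cleaned = cleaned.reshape(ica.channel_idx.size, retained_idx.size,
                                  epochs.n_samples).transpose(1, 0, 2)
        out.data[:, ica.channel_idx, :] = cleaned

    # step 4: per-epoch bad channels, then repair all flagged channels
    per_epoch = np.zeros((out.n_epochs, out.n_channels), dtype=bool)
    if cfg.epoch_interpolation:
        per_epoch = detect_epoch_bad_channels(out, cfg, exclude_channels=bad_ch_idx)
        report.per_epoch_interpolations = [
            (int(retained_idx[e]), out.ch_names[c])
            for e, c in zip(*np.nonzero(per_epoch))
        ]
    for e in range(out.n_epochs):
        bad = np.flatnonzero(per_epoch[e])
        bad = np.union1d(bad, np.asarray(bad_ch_idx, dtype=int))
        if bad.size:
            out.data[e] = spherical_spline_interpolate(out.data[e], bad, montage)

    if cfg.average_reference:
        out.data -= out.data.mean(axis=1, keepdims=True)
        out.info["reference"] = "average"

    out.info["faster"] = True
    return out, report
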