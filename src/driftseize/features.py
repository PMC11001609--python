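"""The battery of 59 univariate linear EEG features, per 5-s epoch per channel.

Frequency domain: relative spectral power in eight bands (delta, theta,
alpha, beta, four gamma sub-bands), all 28 pairwise band ratios, spectral
edge frequencies (50/75/90/95th power percentiles) and edge powers
(50/75/90th), alpha peak frequency, total power and mean frequency, plus the
energies of db4 wavelet detail coefficients D1-D5.  Time domain: the four
statistical moments, the three Hjorth parameters and the decorrelation time.

The registry is data-driven: the default composition above is exactly 59
entries, but any alternative list of :class:`FeatureDef` can be supplied.

Conventions (fixed and recorded here rather than configurable per call):
power spectra are Hann-tapered periodograms scaled as density (Parseval:
integral approximately the signal variance); band intervals are half-open
``[low, high)``; the ratio guard is ``eps = 1e-12``; kurtosis is non-excess
(Gaussian -> 3); wavelet boundary mode is ``periodization``; the
decorrelation criterion is the first autocorrelation crossing of ``1/e``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats

from .signal_io import EpochArray

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "TOTAL_BAND",
    "EDGE_RANGE",
    "RATIO_EPS",
    "FeatureDef",
    "FeatureRegistry",
    "FeatureMatrix",
    "default_registry",
    "power_spectrum",
    "band_power",
    "relative_band_power",
    "band_ratio",
    "spectral_edge",
    "summary_spectral_features",
    "wavelet_energies",
    "statistical_moments",
    "hjorth_parameters",
    "decorrelation_time",
    "extract_features",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")


#: The eight analysis bands.  The gamma range is split in four, skipping the
#: 47-53 and 97-103 Hz notch gaps where mains interference is removed.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma1", 30.0, 47.0),
    BandDefinition("gamma2", 53.0, 75.0),
    BandDefinition("gamma3", 75.0, 97.0),
    BandDefinition("gamma4", 103.0, 128.0),
)

TOTAL_BAND: tuple[float, float] = (0.5, 128.0)
EDGE_RANGE: tuple[float, float] = (0.5, 100.0)
RATIO_EPS: float = 1e-12
_ALPHA_BAND: tuple[float, float] = (8.0, 13.0)


def power_spectrum(epoch: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectral density of one epoch (single channel).

    Hann-tapered periodogram with constant detrend; on a 5-s epoch the grid
    resolution is 0.2 Hz.  Returns ``(freqs, psd)``.
    """
    freqs, psd = sps.periodogram(
        np.asarray(epoch, dtype=float),
        fs=rate,
        window="hann",
        detrend="constant",
        scaling="density",
    )
    return freqs, psd


def band_power(
    freqs: np.ndarray, psd: np.ndarray, low: float, high: float
) -> float:
    """Integrated power over the half-open band ``[low, high)``."""
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    mask = (freqs >= low) & (freqs < high)
    return float(psd[mask].sum() * df)


def relative_band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: BandDefinition,
    total_band: tuple[float, float] = TOTAL_BAND,
) -> float:
    """Fraction of total-band power falling inside ``band``; NaN if the
    total power is zero (flat epoch)."""
    total = band_power(freqs, psd, *total_band)
    if total <= 0:
        return float("nan")
    return band_power(freqs, psd, band.low, band.high) / total


def band_ratio(p_a: float, p_b: float, eps: float = RATIO_EPS) -> float:
    return p_a / (p_b + eps)


def spectral_edge(
    freqs: np.ndarray,
    psd: np.ndarray,
    percentile: float = 0.5,
    range: tuple[float, float] = EDGE_RANGE,
) -> tuple[float, float]:
    """Spectral edge frequency and power.

    The edge frequency is the smallest grid frequency below which at least
    ``percentile`` of the power in ``range`` has accumulated; the edge power
    is that cumulative power.  ``(nan, nan)`` when the range holds no power.
    """
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    mask = (freqs >= range[0]) & (freqs < range[1])
    p = psd[mask] * df
    f = freqs[mask]
    total = p.sum()
    if total <= 0:
        return float("nan"), float("nan")
    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, percentile * total - 1e-15))
    idx = min(idx, len(f) - 1)
    return float(f[idx]), float(cum[idx])


def summary_spectral_features(
    freqs: np.ndarray, psd: np.ndarray
) -> tuple[float, float, float]:
    """Alpha peak frequency (argmax in 8-13 Hz), total power over 0.5-128 Hz
    and power-weighted mean frequency over the same range."""
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    amask = (freqs >= _ALPHA_BAND[0]) & (freqs < _ALPHA_BAND[1])
    if psd[amask].max(initial=0.0) <= 0:
        alpha_peak = float("nan")
    else:
        alpha_peak = float(freqs[amask][np.argmax(psd[amask])])
    tmask = (freqs >= TOTAL_BAND[0]) & (freqs < TOTAL_BAND[1])
    total_power = float(psd[tmask].sum() * df)
    if total_power <= 0:
        mean_freq = float("nan")
    else:
        mean_freq = float(
            (freqs[tmask] * psd[tmask]).sum() / psd[tmask].sum()
        )
    return alpha_peak, total_power, mean_freq


def wavelet_energies(
    epoch: np.ndarray, mother: str = "db4", levels: int = 5
) -> np.ndarray:
    """Energies of the detail coefficients D1..Dlevels of a DWT.

    Periodization boundary mode, so the transform is orthogonal and total
    coefficient energy equals signal energy.
    """
    epoch = np.asarray(epoch, dtype=float)
    if len(epoch) < 2**levels:
        raise ValueError(
            f"epoch of {len(epoch)} samples too short for a {levels}-level DWT"
        )
    coeffs = pywt.wavedec(epoch, mother, mode="periodization", level=levels)
    # coeffs = [A_levels, D_levels, ..., D1]; return D1-first
    details = coeffs[1:][::-1]
    return np.array([float(np.sum(d**2)) for d in details])


def statistical_moments(epoch: np.ndarray) -> tuple[float, float, float, float]:
    """Sample mean, variance, skewness and (non-excess) kurtosis.

    Skewness/kurtosis are the standardised central moments; a zero-variance
    epoch yields NaN for both.
    """
    epoch = np.asarray(epoch, dtype=float)
    if len(epoch) < 2:
        raise ValueError("need at least 2 samples")
    mean = float(epoch.mean())
    var = float(epoch.var())
    if var <= 0:
        return mean, var, float("nan"), float("nan")
    skew = float(stats.skew(epoch, bias=True))
    kurt = float(stats.kurtosis(epoch, fisher=False, bias=True))
    return mean, var, skew, kurt


def hjorth_parameters(epoch: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity.

    The derivative is approximated by first differences.  Activity is the
    signal variance; mobility the normalised spread of the derivative;
    complexity the mobility of the derivative relative to the signal's.
    """
    x = np.asarray(epoch, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    var_x = float(x.var())
    dx = np.diff(x)
    var_dx = float(dx.var())
    if var_x <= 0:
        return 0.0, float("nan"), float("nan")
    mobility = float(np.sqrt(var_dx / var_x))
    if var_dx <= 0:
        return var_x, mobility, float("nan")
    ddx = np.diff(dx)
    mobility_dx = float(np.sqrt(ddx.var() / var_dx))
    return var_x, mobility, mobility_dx / mobility


def decorrelation_time(
    epoch: np.ndarray, rate: float, criterion: float = 1.0 / np.e
) -> float:
    """Lag in seconds at which the autocorrelation first drops to
    ``criterion`` (1/e by default).

    Returns the cap ``(n//2)/rate`` when the criterion is never reached
    within half the epoch.  NaN for a zero-variance epoch.
    """
    x = np.asarray(epoch, dtype=float)
    n = len(x)
    if n < 32:
        raise ValueError("need at least 32 samples")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0:
        return float("nan")
    max_lag = n // 2
    # FFT-based autocorrelation, normalised to acf[0] = 1
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx))[: max_lag + 1] / denom
    below = np.nonzero(acf[1:] <= criterion)[0]
    if len(below) == 0:
        return max_lag / rate
    return float(below[0] + 1) / rate


# ---------------------------------------------------------------------------
# Registry


@dataclass(frozen=True)
class FeatureDef:
    """One named feature: a computation kind plus its parameters."""

    name: str
    kind: str
    params: dict = field(default_factory=dict)


@dataclass
class FeatureRegistry:
    """Ordered, serialisable list of feature definitions."""

    entries: list[FeatureDef]
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "bands": [
                {"name": b.name, "low": b.low, "high": b.high} for b in self.bands
            ],
            "entries": [
                {"name": e.name, "kind": e.kind, "params": e.params}
                for e in self.entries
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "FeatureRegistry":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        bands = tuple(
            BandDefinition(b["name"], b["low"], b["high"]) for b in payload["bands"]
        )
        entries = [
            FeatureDef(e["name"], e["kind"], e.get("params", {}))
            for e in payload["entries"]
        ]
        return cls(entries=entries, bands=bands)


def default_registry() -> FeatureRegistry:
    """The default 59-entry feature battery (composition in module docstring)."""
    entries: list[FeatureDef] = []
    for b in DEFAULT_BANDS:
        entries.append(FeatureDef(f"relpow_{b.name}", "rel_power", {"band": b.name}))
    for a, b in combinations(DEFAULT_BANDS, 2):
        entries.append(
            FeatureDef(f"ratio_{a.name}_{b.name}", "band_ratio", {"a": a.name, "b": b.name})
        )
    for pct in (50, 75, 90, 95):
        entries.append(FeatureDef(f"sef{pct}", "edge_freq", {"percentile": pct / 100}))
    for pct in (50, 75, 90):
        entries.append(FeatureDef(f"sep{pct}", "edge_power", {"percentile": pct / 100}))
    entries.append(FeatureDef("alpha_peak_freq", "alpha_peak"))
    entries.append(FeatureDef("total_power", "total_power"))
    entries.append(FeatureDef("mean_frequency", "mean_frequency"))
    for level in range(1, 6):
        entries.append(FeatureDef(f"wavelet_energy_d{level}", "wavelet_energy", {"level": level}))
    for m in ("mean", "variance", "skewness", "kurtosis"):
        entries.append(FeatureDef(f"moment_{m}", "moment", {"which": m}))
    for h in ("activity", "mobility", "complexity"):
        entries.append(FeatureDef(f"hjorth_{h}", "hjorth", {"which": h}))
    entries.append(FeatureDef("decorrelation_time", "decorrelation_time"))
    reg = FeatureRegistry(entries=entries)
    assert len(reg) == 59
    return reg


@dataclass
class FeatureMatrix:
    """Per-epoch feature values, channel-major column layout.

    ``values`` has one row per epoch and ``n_channels * n_features`` columns
    ordered channel by channel (channel 0's 59 features first).  Epochs with
    any non-finite feature value are flagged invalid in ``valid_mask``.
    """

    values: np.ndarray
    feature_names: list[str]
    channel_labels: list[str]
    epoch_start_times: np.ndarray
    valid_mask: np.ndarray
    window_length: float = 5.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.epoch_start_times = np.asarray(self.epoch_start_times, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        expected = len(self.channel_labels) * len(self.feature_names)
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"values must have {expected} columns "
                f"({len(self.channel_labels)} channels x {len(self.feature_names)} features)"
            )

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def column_names(self) -> list[str]:
        return [
            f"{ch}|{feat}"
            for ch in self.channel_labels
            for feat in self.feature_names
        ]


def _channel_feature_row(
    x: np.ndarray, rate: float, registry: FeatureRegistry
) -> np.ndarray:
    """All registry features for one channel of one epoch."""
    freqs, psd = power_spectrum(x, rate)
    band_by_name = {b.name: b for b in registry.bands}
    relpow: dict[str, float] = {}

    def rel(name: str) -> float:
        if name not in relpow:
            relpow[name] = relative_band_power(freqs, psd, band_by_name[name])
        return relpow[name]

    summary: tuple[float, float, float] | None = None
    moments: tuple[float, float, float, float] | None = None
    hjorth: tuple[float, float, float] | None = None
    wav: np.ndarray | None = None

    out = np.empty(len(registry))
    for i, e in enumerate(registry.entries):
        if e.kind == "rel_power":
            v = rel(e.params["band"])
        elif e.kind == "band_ratio":
            v = band_ratio(rel(e.params["a"]), rel(e.params["b"]))
        elif e.kind == "edge_freq":
            v = spectral_edge(freqs, psd, e.params["percentile"])[0]
        elif e.kind == "edge_power":
            v = spectral_edge(freqs, psd, e.params["percentile"])[1]
        elif e.kind in ("alpha_peak", "total_power", "mean_frequency"):
            if summary is None:
                summary = summary_spectral_features(freqs, psd)
            v = summary[("alpha_peak", "total_power", "mean_frequency").index(e.kind)]
        elif e.kind == "wavelet_energy":
            if wav is None:
                wav = wavelet_energies(x)
            v = wav[e.params["level"] - 1]
        elif e.kind == "moment":
            if moments is None:
                moments = statistical_moments(x)
            v = moments[("mean", "variance", "skewness", "kurtosis").index(e.params["which"])]
        elif e.kind == "hjorth":
            if hjorth is None:
                hjorth = hjorth_parameters(x)
            v = hjorth[("activity", "mobility", "complexity").index(e.params["which"])]
        elif e.kind == "decorrelation_time":
            v = decorrelation_time(x, rate)
        else:
            raise ValueError(f"unknown feature kind {e.kind!r}")
        out[i] = v
    return out


def extract_features(
    epochs: EpochArray,
    registry: FeatureRegistry | None = None,
    channel_labels: list[str] | None = None,
    allow_any_size: bool = False,
) -> FeatureMatrix:
    """Compute the feature battery for every epoch and channel.

    Deterministic given its inputs; epochs flagged invalid on input, or
    producing any non-finite value (flat channels, etc.), are propagated as
    invalid rows.  ``allow_any_size`` lifts the 59-entry registry contract
    for experimentation.
    """
    if registry is None:
        registry = default_registry()
    if len(registry) != 59 and not allow_any_size:
        raise ValueError(
            f"registry holds {len(registry)} features, expected 59 "
            "(pass allow_any_size=True to override)"
        )
    n_epochs, n_channels, n_samp = epochs.epochs.shape
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_channels)]
    rate = n_samp / epochs.window_length
    values = np.full((n_epochs, n_channels * len(registry)), np.nan)
    for ei in range(n_epochs):
        if not epochs.valid_mask[ei]:
            continue
        for ci in range(n_channels):
            row = _channel_feature_row(epochs.epochs[ei, ci], rate, registry)
            values[ei, ci * len(registry): (ci + 1) * len(registry)] = row
    valid = epochs.valid_mask & np.isfinite(values).all(axis=1)
    return FeatureMatrix(
        values=values,
        feature_names=registry.names,
        channel_labels=list(channel_labels),
        epoch_start_times=epochs.epoch_start_times.copy(),
        valid_mask=valid,
        window_length=epochs.window_length,
    )
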