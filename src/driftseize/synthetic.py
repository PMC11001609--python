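"""Synthetic drifting EEG: raw recordings and fast feature streams.

Stands in for long-term presurgical monitoring data, which is
access-restricted.  The generator emulates the statistical structure the
pipeline consumes rather than clinically realistic EEG morphology: a 1/f
coloured-noise background per channel, at least four lead seizures spaced by
the 4.5 h independence gap, a preictal period of configurable duration whose
spectral signature differs from the interictal baseline, a short
high-amplitude rhythmic ictal segment, and an optional abrupt or gradual
drift of the preictal signature across seizures.

Two tiers share one :class:`SyntheticSpec`:

* :func:`generate_recording` synthesises raw multichannel signal at the
  sampling rate (slow, exercises the full signal path);
* :func:`generate_feature_stream` draws per-epoch feature rows directly
  from interictal/preictal distributions with the configured mean shift
  (fast, for pipeline-scale experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import FeatureMatrix, default_registry
from .signal_io import Recording, SeizureAnnotation

__all__ = ["SyntheticSpec", "generate_recording", "generate_feature_stream", "compressed_spec"]

#: Default preictal signature: which features shift, and in which direction,
#: in units of that feature's standard deviation (scaled by ``effect_size``).
DEFAULT_PREICTAL_SHIFT: dict[str, float] = {
    "relpow_alpha": 1.0,
    "relpow_delta": -0.7,
    "relpow_theta": 0.5,
    "hjorth_mobility": 0.5,
    "mean_frequency": 0.7,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-shaped synthetic patient.

    ``effect_size`` scales the feature-tier preictal signature in standard
    deviations; ``signal_band_boost`` is the signal-tier preictal effect,
    expressed as the target absolute increase in the boosted bands' total
    relative spectral power (so it is directly verifiable through the
    feature battery).  ``drift`` is ``("none",)``, ``("abrupt", k)``
    (signature sign-flips from seizure index *k* onward) or
    ``("gradual", rate)`` (signature multiplied by ``1 - rate * k`` at
    seizure *k*, floored at -1).
    """

    n_channels: int = 19
    rate: float = 256.0
    n_seizures: int = 4
    interictal_gap_hours: float = 4.5
    true_sop_minutes: float = 20.0
    sph_minutes: float = 10.0
    effect_size: float = 1.5
    signal_band_boost: float = 0.25
    preictal_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREICTAL_SHIFT)
    )
    drift: tuple = ("none",)
    ar_coeff: float = 0.9
    ictal_minutes: float = 3.0
    window_length: float = 5.0
    tail_hours: float = 0.25

    def __post_init__(self) -> None:
        if self.n_seizures < 4:
            raise ValueError("at least 4 lead seizures required (inclusion rule)")
        if self.interictal_gap_hours * 60 < self.true_sop_minutes + self.sph_minutes:
            raise ValueError("interictal gap too short for the preictal period")
        if self.drift[0] not in ("none", "abrupt", "gradual"):
            raise ValueError(f"unknown drift schedule {self.drift!r}")

    @property
    def onsets(self) -> np.ndarray:
        """Seizure onsets in seconds: one per independence gap."""
        gap = self.interictal_gap_hours * 3600.0
        return gap * np.arange(1, self.n_seizures + 1)

    @property
    def duration(self) -> float:
        return float(self.onsets[-1] + self.ictal_minutes * 60.0 + self.tail_hours * 3600.0)

    def annotations(self) -> list[SeizureAnnotation]:
        return [
            SeizureAnnotation(onset=float(t), offset=float(t + self.ictal_minutes * 60.0))
            for t in self.onsets
        ]

    def drift_multiplier(self, seizure_index: int) -> float:
        """Scaling of the preictal signature at a given seizure (0-based)."""
        kind = self.drift[0]
        if kind == "none":
            return 1.0
        if kind == "abrupt":
            return -1.0 if seizure_index >= self.drift[1] else 1.0
        rate = self.drift[1]
        return max(-1.0, 1.0 - rate * seizure_index)


def compressed_spec(**overrides) -> SyntheticSpec:
    """A small test patient on a compressed timeline (~2 h of data).

    Scales the independence gap down to 25 min and the preictal period to
    10 min so that unit and CI runs finish in seconds; all structural
    invariants (>= 4 lead seizures, preictal inside its own gap) still hold
    relative to the scaled clock.
    """
    defaults = dict(
        n_channels=2,
        interictal_gap_hours=25 / 60,
        true_sop_minutes=10.0,
        sph_minutes=2.0,
        ictal_minutes=1.0,
        tail_hours=0.05,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def _one_over_f_noise(
    rng: np.random.Generator,
    n: int,
    rate: float,
    beta: float = 1.0,
    band: tuple[float, float] = (0.5, 128.0),
) -> np.ndarray:
    """Coloured noise with power spectrum ~ 1/f^beta inside ``band``, unit RMS.

    Band-limited to the spectral analysis range so that relative band powers
    of the background sum to ~1 over that range (no hidden infra-slow or
    ultra-fast power).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.zeros_like(freqs)
    inband = (freqs >= band[0]) & (freqs < min(band[1], rate / 2))
    shaping[inband] = freqs[inband] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


# Band-limited oscillation frequencies used to realise a relative-power shift
# in the raw-signal tier (one carrier per named band).
_BAND_CARRIER_HZ = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0,
                    "gamma1": 40.0, "gamma2": 60.0, "gamma3": 85.0, "gamma4": 110.0}


def generate_recording(
    spec: SyntheticSpec, seed: int = 0
) -> tuple[Recording, list[SeizureAnnotation]]:
    """Synthesise a raw multichannel recording with annotated seizures.

    Per channel: unit-RMS 1/f background scaled to 20 uV; during each
    preictal window, band-limited sinusoidal bursts (carriers at band
    centres) realise the positive relative-power entries of the configured
    shift, with amplitudes calibrated so the bands' total relative spectral
    power rises by ``signal_band_boost`` over the 1/f baseline.  A negative
    drift multiplier moves the burst to the theta carrier, inverting the
    spectral signature.  The ictal segment is a 4 Hz high-amplitude
    amplitude-modulated rhythm.  Bit-identical for identical (spec, seed).
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    background_uv = 20.0
    samples = np.empty((spec.n_channels, n))
    annotations = spec.annotations()

    # preictal band boosts from the named shift vector (positive entries only:
    # raw signal can only add oscillatory power)
    boosts = {
        band: coeff
        for name, coeff in spec.preictal_shift.items()
        if name.startswith("relpow_") and coeff > 0
        for band in [name.removeprefix("relpow_")]
    }
    if not boosts:
        boosts = {"alpha": 1.0}
    wsum = sum(boosts.values())
    band_by_name = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
                    "beta": (13.0, 30.0), "gamma1": (30.0, 47.0), "gamma2": (53.0, 75.0),
                    "gamma3": (75.0, 97.0), "gamma4": (103.0, 128.0)}
    # 1/f background: relative band power ~ log band ratio over (0.5, 128) Hz
    log_total = np.log(128.0 / 0.5)

    def tone_amplitude(band: str, target_delta: float) -> float:
        lo, hi = band_by_name[band]
        r = np.log(hi / lo) / log_total  # baseline relative power of the band
        if target_delta >= 1.0 - r:
            raise ValueError("signal_band_boost too large for the band")
        # added fraction x of total power solving (r + x)/(1 + x) - r = delta
        x = target_delta / (1.0 - r - target_delta)
        return background_uv * np.sqrt(2.0 * x)

    for ci in range(spec.n_channels):
        x = _one_over_f_noise(rng, n, spec.rate) * background_uv
        for k, ann in enumerate(annotations):
            mult = spec.drift_multiplier(k)
            pre_lo = ann.onset - (spec.sph_minutes + spec.true_sop_minutes) * 60.0
            pre_hi = ann.onset - spec.sph_minutes * 60.0
            pre = (t >= pre_lo) & (t < pre_hi)
            phase = rng.uniform(0, 2 * np.pi)
            for band, coeff in boosts.items():
                target = spec.signal_band_boost * coeff / wsum * abs(mult)
                use_band = band if mult > 0 else "theta"
                carrier = _BAND_CARRIER_HZ[use_band]
                amp = tone_amplitude(use_band, target)
                x[pre] += amp * np.sin(2 * np.pi * carrier * t[pre] + phase)
            ictal = (t >= ann.onset) & (t < ann.offset)
            x[ictal] += 5 * background_uv * np.sin(2 * np.pi * 4.0 * t[ictal] + phase) * (
                1 + 0.5 * np.sin(2 * np.pi * 0.5 * t[ictal])
            )
        samples[ci] = x

    rec = Recording(
        channel_labels=[f"ch{i:02d}" for i in range(spec.n_channels)],
        sampling_rate=spec.rate,
        samples=samples,
    )
    return rec, annotations


def generate_feature_stream(
    spec: SyntheticSpec, seed: int = 0
) -> tuple[FeatureMatrix, list[SeizureAnnotation]]:
    """Draw per-epoch feature rows directly from class distributions.

    Each of the ``n_channels * 59`` columns gets a base mean ~ N(0, 4) and
    standard deviation ~ U(0.5, 1.5) (drawn from the seed, fixed per
    patient), AR(1) temporal correlation with coefficient ``ar_coeff``
    across epochs, and — inside each seizure's preictal window — a mean
    shift of ``effect_size * coeff * sd`` on the named signature features
    (every channel block alike), scaled by the seizure's drift multiplier.
    Ictal epochs additionally get triple noise amplitude.
    """
    rng = np.random.default_rng(seed)
    registry = default_registry()
    n_feat = len(registry)
    n_cols = spec.n_channels * n_feat
    w = spec.window_length
    n_epochs = int(spec.duration // w)
    times = np.arange(n_epochs) * w
    annotations = spec.annotations()

    base_mean = rng.normal(0.0, 2.0, size=n_cols)
    base_sd = rng.uniform(0.5, 1.5, size=n_cols)

    shift_idx: list[int] = []
    shift_coeff: list[float] = []
    name_to_pos = {n: i for i, n in enumerate(registry.names)}
    for name, coeff in spec.preictal_shift.items():
        pos = name_to_pos[name]
        for ci in range(spec.n_channels):
            shift_idx.append(ci * n_feat + pos)
            shift_coeff.append(coeff)
    shift_idx_arr = np.array(shift_idx, dtype=int)
    shift_coeff_arr = np.array(shift_coeff)

    # ar_coeff is defined per 5-s epoch; rescale so temporal correlation is a
    # property of elapsed time, not of the stream's epoch length
    phi = spec.ar_coeff ** (w / 5.0)
    innov_scale = np.sqrt(1.0 - phi**2)
    noise = rng.standard_normal((n_epochs, n_cols))
    for i in range(1, n_epochs):
        noise[i] = phi * noise[i - 1] + innov_scale * noise[i]

    values = base_mean + base_sd * noise
    for k, ann in enumerate(annotations):
        mult = spec.drift_multiplier(k)
        pre_lo = ann.onset - (spec.sph_minutes + spec.true_sop_minutes) * 60.0
        pre_hi = ann.onset - spec.sph_minutes * 60.0
        pre = (times >= pre_lo) & (times < pre_hi)
        values[np.ix_(pre, shift_idx_arr)] += (
            mult * spec.effect_size * shift_coeff_arr * base_sd[shift_idx_arr]
        )
        ictal = (times >= ann.onset) & (times < ann.offset)
        if ictal.any():
            values[ictal] = base_mean + 3 * base_sd * noise[ictal]

    fm = FeatureMatrix(
        values=values,
        feature_names=registry.names,
        channel_labels=[f"ch{i:02d}" for i in range(spec.n_channels)],
        epoch_start_times=times,
        valid_mask=np.ones(n_epochs, dtype=bool),
        window_length=w,
    )
    return fm, annotations
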