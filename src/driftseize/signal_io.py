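"""Reading, filtering and segmenting continuous EEG recordings.

Time coordinates are seconds from recording start, and every interval is
half-open ``[start, end)``.  Epochs are non-overlapping fixed-length windows
(5 s by default), the unit at which features are computed downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "SeizureAnnotation",
    "EpochArray",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "basic_denoise",
    "segment",
]


@dataclass
class Recording:
    """Continuous multichannel scalp EEG.

    ``samples`` is a ``(n_channels, n_samples)`` array of microvolt values at
    a uniform ``sampling_rate``.  ``start_time`` is an epoch offset in seconds
    (0 for a recording that defines its own clock).
    """

    channel_labels: list[str]
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows for "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class SeizureAnnotation:
    """One annotated seizure, in seconds from recording start."""

    onset: float
    offset: float
    classification: str = "unknown"
    vigilance: str = "unknown"
    pattern: str = "unknown"
    lead: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValueError(
                f"invalid seizure interval [{self.onset}, {self.offset})"
            )


@dataclass
class EpochArray:
    """Non-overlapping fixed-length windows cut from a :class:`Recording`.

    ``epochs`` has shape ``(n_epochs, n_channels, n_samples_per_epoch)``;
    ``valid_mask`` flags epochs usable for feature extraction (False marks
    gaps or artefact-contaminated windows).
    """

    epochs: np.ndarray
    epoch_start_times: np.ndarray
    window_length: float
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.epoch_start_times = np.asarray(self.epoch_start_times, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.epoch_start_times), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(self.epoch_start_times) != self.epochs.shape[0]:
            raise ValueError("epoch_start_times misaligned with epochs")
        if self.epochs.shape[0] > 1:
            steps = np.diff(self.epoch_start_times)
            if not np.allclose(steps, self.window_length):
                raise ValueError("epochs must be contiguous and non-overlapping")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def _annotation_sidecar_path(path: Path) -> Path:
    return path.with_suffix(".annotations.json")


def read_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Read the JSON annotation sidecar (a list of seizure objects)."""
    with open(path) as fh:
        raw = json.load(fh)
    anns = [
        SeizureAnnotation(
            onset=float(a["onset_s"]),
            offset=float(a["offset_s"]),
            classification=a.get("classification", "unknown"),
            vigilance=a.get("vigilance", "unknown"),
            pattern=a.get("pattern", "unknown"),
            lead=bool(a.get("lead", True)),
        )
        for a in raw
    ]
    anns.sort(key=lambda a: a.onset)
    return anns


def write_annotations(annotations: list[SeizureAnnotation], path: str | Path) -> None:
    payload = [
        {
            "onset_s": a.onset,
            "offset_s": a.offset,
            "classification": a.classification,
            "vigilance": a.vigilance,
            "pattern": a.pattern,
            "lead": a.lead,
        }
        for a in annotations
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_recording(
    path: str | Path,
    format: str | None = None,
    require_annotations: bool = True,
) -> tuple[Recording, list[SeizureAnnotation]]:
    """Load a recording plus its mandatory annotation sidecar.

    Parameters
    ----------
    path
        EDF file or CSV file (one column per channel, header row of labels,
        sampling rate stored in a ``# sampling_rate_hz=`` comment on the
        first line, 256 Hz assumed otherwise).
    format
        ``"edf"`` or ``"csv"``; inferred from the suffix when omitted.
    require_annotations
        When True (the default, as the pipeline cannot label data without
        seizure times) a missing ``<name>.annotations.json`` sidecar is an
        error; when False an empty annotation list is returned instead.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "edf":
        rec = _read_edf(path)
    elif format == "csv":
        rec = _read_csv(path)
    else:
        raise ValueError(f"unsupported recording format: {format!r}")

    sidecar = _annotation_sidecar_path(path)
    if sidecar.exists():
        annotations = read_annotations(sidecar)
    elif require_annotations:
        raise FileNotFoundError(
            f"annotation sidecar {sidecar} not found; seizure annotations are "
            "mandatory for pipeline use (pass require_annotations=False to "
            "load the signal alone)"
        )
    else:
        annotations = []
    for a in annotations:
        if a.offset > rec.duration + 1e-9:
            raise ValueError(
                f"annotation [{a.onset}, {a.offset}) extends beyond the "
                f"{rec.duration:.1f}s recording"
            )
    return rec, annotations


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise ValueError(f"unparseable EDF file {path}: {exc}") from exc
    return Recording(
        channel_labels=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        # MNE scales EEG to volts internally; store microvolts
        samples=raw.get_data() * 1e6,
    )


_CSV_RATE_PREFIX = "# sampling_rate_hz="


def _read_csv(path: Path) -> Recording:
    rate = 256.0
    skiprows = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(_CSV_RATE_PREFIX):
        try:
            rate = float(first[len(_CSV_RATE_PREFIX):])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed rate comment line 1") from exc
        skiprows = 1
    try:
        df = pd.read_csv(path, skiprows=skiprows)
    except Exception as exc:
        raise ValueError(f"unparseable CSV file {path}: {exc}") from exc
    return Recording(
        channel_labels=[str(c) for c in df.columns],
        sampling_rate=rate,
        samples=df.to_numpy().T,
    )


def write_recording(
    rec: Recording,
    path: str | Path,
    annotations: list[SeizureAnnotation] | None = None,
) -> None:
    """Write a recording as CSV (one column per channel) plus sidecar.

    CSV keeps full float precision so a read/write round trip is lossless up
    to decimal repr; annotation times round-trip exactly.
    """
    path = Path(path)
    if path.suffix.lower() != ".csv":
        raise ValueError("write_recording supports the CSV format only")
    with open(path, "w") as fh:
        fh.write(f"{_CSV_RATE_PREFIX}{rec.sampling_rate!r}\n")
        pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(
            fh, index=False
        )
    if annotations is not None:
        write_annotations(annotations, _annotation_sidecar_path(path))


def basic_denoise(
    rec: Recording,
    band: tuple[float, float] = (0.5, 100.0),
    notch: tuple[float, ...] = (50.0, 100.0),
) -> Recording:
    """Zero-phase band-pass plus notch filtering.

    Stands in for learned artefact removal: an IIR notch (Q = 20) per
    supplied mains frequency, then a 4th-order Butterworth band-pass, both
    zero-phase (forward-backward).  Mains is removed first so the slow
    band-pass edge response never smears notch transients.  Notch
    frequencies at or above Nyquist are skipped with a log message rather
    than failing, so the same defaults serve decimated toy data.  Edge
    transients are confined to roughly the first/last second of a
    recording; feed continuous recordings, not short snippets.
    """
    low, high = band
    nyq = rec.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz outside (0, Nyquist={nyq}) Hz"
        )
    out = rec.samples
    for f0 in notch:
        if f0 >= nyq:
            logger.info("notch %.1f Hz at/above Nyquist %.1f Hz; skipped", f0, nyq)
            continue
        b, a = sps.iirnotch(f0, Q=20.0, fs=rec.sampling_rate)
        out = sps.filtfilt(b, a, out, axis=1)
    # generous reflect padding keeps the slow band-pass edges clean
    padlen = min(rec.n_samples - 1, 3 * int(rec.sampling_rate))
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    out = sps.sosfiltfilt(sos, out, axis=1, padlen=padlen)
    logger.debug("basic_denoise band=%s notch=%s", band, notch)
    return Recording(
        channel_labels=list(rec.channel_labels),
        sampling_rate=rec.sampling_rate,
        samples=out,
        start_time=rec.start_time,
    )


def segment(rec: Recording, window_length: float = 5.0) -> EpochArray:
    """Cut a recording into non-overlapping ``window_length``-second epochs.

    Epoch *i* covers ``[i*w, (i+1)*w)`` seconds; a trailing partial window is
    discarded.  A recording shorter than one window yields an empty array.
    """
    n_per = window_length * rec.sampling_rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"window_length {window_length}s is not a whole number of samples "
            f"at {rec.sampling_rate} Hz"
        )
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        logger.info("recording shorter than one %.1fs window; empty EpochArray", window_length)
    dropped = rec.n_samples - n_epochs * n_per
    if dropped:
        logger.debug("segment: dropped %d trailing samples", dropped)
    epochs = (
        rec.samples[:, : n_epochs * n_per]
        .reshape(rec.n_channels, n_epochs, n_per)
        .transpose(1, 0, 2)
    )
    return EpochArray(
        epochs=epochs,
        epoch_start_times=np.arange(n_epochs) * window_length,
        window_length=window_length,
    )
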