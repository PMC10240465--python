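"""Recording I/O, filtering, epoching, artifact detection and wake-window
selection.

The preprocessing chain mirrors standard clinical wake-EEG practice: a 1 Hz
zero-phase high-pass, a 57.5–62.5 Hz zero-phase notch for mains interference,
division into contiguous 1-s epochs aligned to the "lights out" annotation,
per-epoch artifact flagging with a linear max-margin classifier, and selection
of the cleanest 3 continuous minutes between "lights out" and sleep onset
("N1").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

logger = logging.getLogger(__name__)

__all__ = [
    "EEG_CHANNELS",
    "Recording",
    "EpochGrid",
    "ArtifactMask",
    "ArtifactDetector",
    "FormatError",
    "DataError",
    "ConfigurationError",
    "read_edf",
    "highpass",
    "notch",
    "make_epoch_grid",
    "epoch_features",
    "train_artifact_detector",
    "detect_artifacts",
    "select_wake_window",
    "drop_noisy_channels",
]

#: the six referenced 10–20 channels used throughout the analysis
EEG_CHANNELS = ("F3", "F4", "C3", "C4", "O1", "O2")

_REF_SUFFIXES = ("-M1", "-M2", "-A1", "-A2")

LIGHTS_OUT = "LIGHTS_OUT"
N1 = "N1"


class FormatError(ValueError):
    """Unreadable or malformed input file."""


class DataError(ValueError):
    """Structurally valid input that cannot support the requested analysis."""


class ConfigurationError(ValueError):
    """Invalid parameter combination."""


@dataclass
class Recording:
    """Multichannel EEG time series in physical units (µV).

    ``annotations`` is a list of ``(label, onset_seconds)`` events; the wake
    window is bracketed by the ``LIGHTS_OUT`` and ``N1`` labels.
    """

    samples: np.ndarray  # (n_channels, n_samples), µV
    fs: float
    channel_labels: tuple
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.shape[0] != len(self.channel_labels):
            raise DataError(
                f"{self.samples.shape[0]} signal rows for "
                f"{len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError("channel labels must be unique")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def annotation_onset(self, label: str) -> float:
        for lab, onset in self.annotations:
            if lab == label:
                return float(onset)
        raise DataError(f"annotation {label!r} not present")

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


@dataclass
class EpochGrid:
    """Non-overlapping, contiguous 1-s epochs of a recording.

    ``data`` has shape ``(n_epochs, n_channels, fs)``; ``origin`` is the sample
    offset of epoch 0 in the parent recording.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple
    origin: int = 0

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3 or self.data.shape[2] != int(round(self.fs)):
            raise DataError("epochs must be (n_epochs, n_channels, fs) 1-s slices")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def concatenate(self) -> np.ndarray:
        """Channels x time array re-assembled from the epochs."""
        return self.data.transpose(1, 0, 2).reshape(self.n_channels, -1)


@dataclass
class ArtifactMask:
    """Per-epoch, per-channel boolean exclusion flags (True = artifact)."""

    flags: np.ndarray  # (n_epochs, n_channels) bool

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise DataError("mask must be (n_epochs, n_channels)")

    @classmethod
    def clean(cls, n_epochs: int, n_channels: int) -> "ArtifactMask":
        return cls(np.zeros((n_epochs, n_channels), dtype=bool))


# ---------------------------------------------------------------------------
# reading


def read_edf(path, keep_channels=EEG_CHANNELS, annotations=None) -> Recording:
    """Read an EDF file into a :class:`Recording` (µV).

    Channel labels are stripped of mastoid-reference suffixes (``-M1`` …);
    channels outside ``keep_channels`` are dropped with a logged warning.
    """
    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises several flavours on bad headers
        raise FormatError(f"cannot read EDF {path}: {exc}") from exc

    labels = []
    for name in raw.ch_names:
        lab = name.strip()
        for suf in _REF_SUFFIXES:
            if lab.upper().endswith(suf):
                lab = lab[: -len(suf)]
        labels.append(lab.strip().upper())

    keep = [i for i, lab in enumerate(labels) if lab in keep_channels]
    dropped = [labels[i] for i in range(len(labels)) if i not in keep]
    if dropped:
        logger.warning("dropping non-EEG/unknown channels: %s", dropped)
    if not keep:
        raise DataError(f"no usable EEG channels among {labels}")

    data = raw.get_data()[keep] * 1e6  # volts -> µV
    kept_labels = tuple(labels[i] for i in keep)
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=kept_labels,
        annotations=list(annotations) if annotations else [],
    )


# ---------------------------------------------------------------------------
# filtering

def _sos_filtfilt(rec: Recording, sos) -> Recording:
    filtered = scipy.signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return replace(rec, samples=filtered)


def highpass(rec: Recording, passband_hz: float = 1.0) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass (applied forward-backward)."""
    if rec.fs <= 2 * passband_hz:
        raise ConfigurationError("sampling rate too low for requested high-pass")
    sos = scipy.signal.butter(4, passband_hz, "highpass", fs=rec.fs, output="sos")
    return _sos_filtfilt(rec, sos)


def notch(rec: Recording, stopband=(57.5, 62.5)) -> Recording:
    """Zero-phase 4th-order Butterworth band-stop for mains interference."""
    if rec.fs <= 2 * stopband[1]:
        raise ConfigurationError("sampling rate too low for requested notch")
    sos = scipy.signal.butter(4, list(stopband), "bandstop", fs=rec.fs, output="sos")
    return _sos_filtfilt(rec, sos)


# ---------------------------------------------------------------------------
# epoching


def make_epoch_grid(rec: Recording, start_s: float = 0.0, n_epochs=None) -> EpochGrid:
    """Cut a recording into contiguous 1-s epochs starting at ``start_s``.

    Epochs are aligned to integer seconds from ``start_s``; a trailing partial
    second is discarded.
    """
    fs = int(round(rec.fs))
    start = int(round(start_s * rec.fs))
    avail = (rec.n_samples - start) // fs
    if n_epochs is None:
        n_epochs = avail
    if n_epochs <= 0 or n_epochs > avail:
        raise DataError(f"{n_epochs} epochs requested, {avail} available")
    block = rec.samples[:, start : start + n_epochs * fs]
    data = block.reshape(rec.n_channels, n_epochs, fs).transpose(1, 0, 2)
    return EpochGrid(
        data=data, fs=rec.fs, channel_labels=rec.channel_labels, origin=start
    )


# ---------------------------------------------------------------------------
# artifact detection


def epoch_features(data: np.ndarray, fs: float) -> np.ndarray:
    """Per-epoch detection features: peak |amplitude|, variance, 1–8 Hz drift
    power fraction and 45–80 Hz high-frequency power ratio.

    ``data`` is ``(..., n_samples)``; returns ``(..., 4)``. Power features are
    log-compressed so the linear margin works on commensurate scales.
    """
    n = data.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.abs(np.fft.rfft(data, axis=-1)) ** 2
    total = spec[..., 1:].sum(axis=-1) + 1e-12
    low = spec[..., (freqs >= 1) & (freqs <= 8)].sum(axis=-1)
    high = spec[..., (freqs >= 45) & (freqs <= 80)].sum(axis=-1)
    feats = np.stack(
        [
            np.log1p(np.abs(data).max(axis=-1)),
            np.log1p(data.var(axis=-1)),
            low / total,
            high / total,
        ],
        axis=-1,
    )
    return feats


@dataclass
class ArtifactDetector:
    """Linear max-margin per-epoch artifact classifier.

    Trained on four summary features of each 1-s epoch; the decision threshold
    is fixed at training time.
    """

    pipeline: object  # sklearn StandardScaler + LinearSVC
    fs: float

    def predict(self, data: np.ndarray) -> np.ndarray:
        """Boolean flags for ``(n_epochs, n_channels, n_samples)`` epochs."""
        feats = epoch_features(data, self.fs)
        flat = feats.reshape(-1, feats.shape[-1])
        return self.pipeline.predict(flat).astype(bool).reshape(feats.shape[:-1])


def train_artifact_detector(
    grid: EpochGrid, truth: ArtifactMask, seed: int = 0
) -> ArtifactDetector:
    """Fit the linear artifact classifier on epochs with ground-truth labels."""
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    y = truth.flags.reshape(-1)
    if y.all() or not y.any():
        raise DataError("artifact detector needs both clean and artifact epochs")
    X = epoch_features(grid.data, grid.fs).reshape(len(y), -1)
    clf = make_pipeline(
        StandardScaler(),
        LinearSVC(C=1.0, class_weight="balanced", random_state=seed, max_iter=5000),
    )
    clf.fit(X, y)
    return ArtifactDetector(pipeline=clf, fs=grid.fs)


def detect_artifacts(grid: EpochGrid, detector: ArtifactDetector) -> ArtifactMask:
    if grid.n_epochs == 0:
        raise DataError("empty epoch grid")
    return ArtifactMask(detector.predict(grid.data))


# ---------------------------------------------------------------------------
# wake-window selection


def select_wake_window(
    rec: Recording, mask: ArtifactMask = None, window_s: int = 180
):
    """Select the cleanest ``window_s`` seconds between LIGHTS_OUT and N1.

    Candidate windows start at integer seconds from LIGHTS_OUT; the window
    minimising the count of artifact-flagged (epoch, channel) cells wins, ties
    broken by the earliest start. Returns ``(start_sample_offset, EpochGrid,
    ArtifactMask)`` for the winning window.
    """
    lights = rec.annotation_onset(LIGHTS_OUT)
    n1 = rec.annotation_onset(N1)
    span = int(np.floor(n1 - lights))
    window_s = int(window_s)
    if span < window_s:
        raise DataError(
            f"only {span} s available between lights-out and N1, "
            f"{window_s} s required"
        )
    grid = make_epoch_grid(rec, start_s=lights, n_epochs=span)
    if mask is None:
        mask = ArtifactMask.clean(span, rec.n_channels)
    if mask.flags.shape != (span, rec.n_channels):
        raise DataError(
            f"mask shape {mask.flags.shape} does not match span grid "
            f"({span}, {rec.n_channels})"
        )
    per_epoch = mask.flags.sum(axis=1)
    csum = np.concatenate([[0], np.cumsum(per_epoch)])
    costs = csum[window_s:] - csum[: span - window_s + 1]
    start_epoch = int(np.argmin(costs))  # argmin returns first minimum: earliest
    fs = int(round(rec.fs))
    sub = EpochGrid(
        data=grid.data[start_epoch : start_epoch + window_s],
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        origin=grid.origin + start_epoch * fs,
    )
    sub_mask = ArtifactMask(mask.flags[start_epoch : start_epoch + window_s])
    return sub.origin, sub, sub_mask


def drop_noisy_channels(mask: ArtifactMask, max_artifact_fraction: float = 0.5):
    """Channels whose artifact fraction exceeds the threshold inside the
    selected window are marked unusable (returned as a boolean keep-vector)."""
    frac = mask.flags.mean(axis=0)
    return frac <= max_artifact_fraction
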