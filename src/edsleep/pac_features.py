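"""Phase–amplitude coupling via the modulation index (MI).

The MI quantifies how strongly the amplitude envelope of a fast rhythm depends
on the phase of a slow rhythm: phases are binned into 18 equal bins, the mean
envelope per bin is normalized into a distribution P, and

    MI = (log N - H(P)) / log N

with H the Shannon entropy — i.e. the Kullback–Leibler divergence of P from
uniform, scaled to [0, 1]. MI is computed on a grid of phase center
frequencies (even numbers 2–20 Hz) crossed with amplitude center frequencies
(multiples of 3 from 30–54 Hz), 90 cells per channel, and then averaged over
rectangular regions of the grid to give band-pair features (delta/theta/
alpha/beta phase x low- or medium-gamma amplitude).

Only stretches of 5 or more consecutive artifact-free 1-s epochs contribute;
each stretch is band-pass filtered (zero-phase Butterworth), Hilbert-
transformed, trimmed by 0.5 s at both ends against filter edge effects, and
concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import ArtifactMask, ConfigurationError, DataError

__all__ = [
    "PHASE_CENTERS",
    "AMP_CENTERS",
    "LOW_GAMMA_CENTERS",
    "MEDIUM_GAMMA_CENTERS",
    "BAND_PAIRS",
    "MiGrid",
    "clean_runs",
    "bandpass_phase",
    "bandpass_amplitude",
    "modulation_index",
    "mi_grid",
    "bandwise_pac",
]

PHASE_CENTERS = tuple(range(2, 21, 2))  # 10 values
AMP_CENTERS = tuple(range(30, 55, 3))  # 9 values

#: amplitude centers pooled per gamma group; low gamma matches the printed
#: 33–52 Hz band, medium gamma (never given explicit bounds) overlaps above it
LOW_GAMMA_CENTERS = (33, 36, 39, 42, 45, 48, 51)
MEDIUM_GAMMA_CENTERS = (45, 48, 51, 54)

_EDGE_TRIM_S = 0.5
_MIN_RUN_EPOCHS = 5


@dataclass
class MiGrid:
    """Phase x amplitude modulation-index matrix for one channel."""

    phase_centers: tuple
    amp_centers: tuple
    mi: np.ndarray  # (n_phase, n_amp) in [0, 1]
    channel: str = ""
    n_samples_used: int = 0


def clean_runs(
    mask: ArtifactMask, channel: int, fs: float, min_len: int = _MIN_RUN_EPOCHS
):
    """Maximal runs of >= ``min_len`` consecutive clean epochs for a channel.

    Returned as ``(start_sample, stop_sample)`` spans relative to the epoch
    grid the mask belongs to. An empty list means PAC is missing for this
    channel.
    """
    flags = mask.flags[:, channel]
    fs = int(round(fs))
    runs = []
    start = None
    for i, bad in enumerate(np.append(flags, True)):  # sentinel closes last run
        if not bad and start is None:
            start = i
        elif bad and start is not None:
            if i - start >= min_len:
                runs.append((start * fs, i * fs))
            start = None
    return runs


def _band_gain(freqs: np.ndarray, low: float, high: float, order: int = 4):
    """Zero-phase gain of an order-``order`` Butterworth band-pass applied
    forward-backward (i.e. the squared magnitude response)."""
    f0_sq = low * high
    bw = high - low
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(freqs > 0, (freqs**2 - f0_sq) / (bw * freqs), np.inf)
    forward = 1.0 / (1.0 + omega ** (2 * order))
    return forward**2


def _analytic_band(
    signal: np.ndarray, low: float, high: float, fs: float, spectrum=None
) -> np.ndarray:
    """Analytic signal of the zero-phase band-passed input, realised
    spectrally: the full FFT is weighted by the Butterworth-squared gain and
    negative frequencies are zeroed (Hilbert), one inverse FFT per band."""
    nyq = fs / 2.0
    if high >= nyq:
        raise ConfigurationError(f"band edge {high} Hz exceeds Nyquist ({nyq} Hz)")
    low = max(low, 0.2)
    n = len(signal) if spectrum is None else len(spectrum)
    X = np.fft.fft(signal) if spectrum is None else spectrum
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    weight = np.zeros(n)
    pos = freqs > 0
    weight[pos] = 2.0 * _band_gain(freqs[pos], low, high)
    if n % 2 == 0:
        weight[n // 2] = _band_gain(np.array([nyq]), low, high)[0]
    return np.fft.ifft(X * weight)


def bandpass_phase(
    signal: np.ndarray, center: float, fs: float, half_bw: float = 2.0
) -> np.ndarray:
    """Instantaneous phase (radians) of the ±2 Hz band around ``center``."""
    return np.angle(_analytic_band(signal, center - half_bw, center + half_bw, fs))


def bandpass_amplitude(signal: np.ndarray, center: float, fs: float) -> np.ndarray:
    """Instantaneous amplitude envelope of the ±center/4 band around
    ``center`` (the band is widened with the carrier so modulation sidebands
    fit inside it)."""
    half_bw = center / 4.0
    return np.abs(_analytic_band(signal, center - half_bw, center + half_bw, fs))


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18
) -> float:
    """Tort-style modulation index of an (phase, envelope) series pair.

    Phases are binned into ``n_bins`` equal bins over [-pi, pi); P(j) is the
    mean amplitude per bin normalized to sum 1; MI = (log N - H(P)) / log N.
    Empty bins contribute P(j) = 0 with 0·log 0 := 0; an all-zero envelope
    gives MI = 0.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise DataError("phase and amplitude series must have equal length")
    if phase.size < n_bins * 10:
        raise DataError(
            f"series of {phase.size} samples too short for {n_bins} phase bins"
        )
    bins = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(int)
    np.clip(bins, 0, n_bins - 1, out=bins)
    sums = np.bincount(bins, weights=amplitude, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        return 0.0
    p = means / total
    nz = p[p > 0]
    entropy = -(nz * np.log(nz)).sum()
    return float((np.log(n_bins) - entropy) / np.log(n_bins))


def mi_grid(
    signal: np.ndarray,
    runs,
    fs: float,
    phase_centers=PHASE_CENTERS,
    amp_centers=AMP_CENTERS,
    channel: str = "",
    n_bins: int = 18,
) -> MiGrid:
    """MI for every (phase center, amplitude center) pair of one channel.

    ``runs`` are sample spans from :func:`clean_runs`; each run is filtered
    and Hilbert-transformed independently, edge-trimmed by 0.5 s, and the
    resulting series concatenated before binning.
    """
    if not runs:
        raise DataError("no qualifying artifact-free runs; PAC missing")
    trim = int(round(_EDGE_TRIM_S * fs))
    phase_series = {pc: [] for pc in phase_centers}
    amp_series = {ac: [] for ac in amp_centers}
    n_used = 0
    for start, stop in runs:
        seg = signal[start:stop]
        n_used += max(len(seg) - 2 * trim, 0)
        spectrum = np.fft.fft(seg)  # shared across all center frequencies
        for pc in phase_centers:
            analytic = _analytic_band(seg, pc - 2.0, pc + 2.0, fs, spectrum)
            phase_series[pc].append(np.angle(analytic)[trim:-trim])
        for ac in amp_centers:
            analytic = _analytic_band(
                seg, ac - ac / 4.0, ac + ac / 4.0, fs, spectrum
            )
            amp_series[ac].append(np.abs(analytic)[trim:-trim])
    phases = {pc: np.concatenate(v) for pc, v in phase_series.items()}
    amps = {ac: np.concatenate(v) for ac, v in amp_series.items()}
    mi = np.empty((len(phase_centers), len(amp_centers)))
    for i, pc in enumerate(phase_centers):
        for j, ac in enumerate(amp_centers):
            mi[i, j] = modulation_index(phases[pc], amps[ac], n_bins=n_bins)
    return MiGrid(
        phase_centers=tuple(phase_centers),
        amp_centers=tuple(amp_centers),
        mi=mi,
        channel=channel,
        n_samples_used=n_used,
    )


def bandwise_pac(
    grid: MiGrid,
    scheme=None,
    low_gamma_centers=LOW_GAMMA_CENTERS,
    medium_gamma_centers=MEDIUM_GAMMA_CENTERS,
) -> dict:
    """Average MI over (phase band x gamma group) regions of the grid.

    Returns a map ``(band, gamma_group) -> value`` with gamma_group in
    {"low_gamma", "medium_gamma"} — 8 features per channel.
    """
    from .spectral_features import DEFAULT_SCHEME

    scheme = scheme or DEFAULT_SCHEME
    phase_bands = ("delta", "theta", "alpha", "beta")
    groups = {
        "low_gamma": low_gamma_centers,
        "medium_gamma": medium_gamma_centers,
    }
    out = {}
    pc = np.asarray(grid.phase_centers)
    ac = np.asarray(grid.amp_centers)
    for band in phase_bands:
        lo, hi = dict(scheme.bands)[band]
        rows = np.where((pc >= lo) & (pc <= hi))[0]
        for gname, centers in groups.items():
            cols = np.where(np.isin(ac, centers))[0]
            out[(band, gname)] = float(grid.mi[np.ix_(rows, cols)].mean())
    return out


BAND_PAIRS = tuple(
    (band, gamma)
    for band in ("delta", "theta", "alpha", "beta")
    for gamma in ("low_gamma", "medium_gamma")
)
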