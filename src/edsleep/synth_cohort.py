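"""Synthetic two-group wake-EEG cohort generator.

Real recordings behind this kind of sleepiness-biomarker analysis are rarely
shareable, so the generator emulates the statistical structure the analysis
assumes and exposes ground truth for every nuisance process:

* two groups defined by the Epworth Sleepiness Scale — "high" (ESS 20–24,
  n = 31 by default) and "low" (ESS 0–4, n = 41);
* six-channel (F3 F4 C3 C4 O1 O2) 200 Hz recordings built from a 1/f
  background plus one band-limited stochastic oscillator per canonical band,
  with per-group band-power profiles calibrated so that the *pipeline's own*
  relative-band-power estimator recovers the configured fractions;
* a shared band-limited source mixed into one channel pair (O2–C4 by default)
  to create group-specific inter-channel coherence in the delta and theta
  bands;
* weak phase–amplitude coupling of identical depth in both groups (the study
  condition is a PAC null);
* a 60 Hz mains line, and sporadic artifacts (transients, drifts, broadband
  bursts) at Poisson times with per-epoch, per-channel truth labels;
* covariates (age, BMI, sex) drawn per group from truncated normals /
  Bernoulli, independent of the EEG by default, with a "leakage" knob that
  makes them group-informative for confound-analysis testing.

The whole cohort is a pure function of :class:`GeneratorConfig` (including its
seed).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import edf
from .io_preprocess import (
    EEG_CHANNELS,
    ConfigurationError,
    Recording,
    highpass,
    make_epoch_grid,
    notch,
)
from .spectral_features import (
    DEFAULT_SCHEME,
    average_and_normalize,
    band_power_fractions,
    epoch_periodogram,
)

__all__ = [
    "GroupProfile",
    "CovariateParams",
    "GeneratorConfig",
    "SubjectRecord",
    "Cohort",
    "HIGH_ESS_PROFILE",
    "LOW_ESS_PROFILE",
    "sample_covariates",
    "synthesize_recording",
    "inject_artifacts",
    "generate_cohort",
    "write_cohort",
    "read_covariates",
]

LIGHTS_OUT_S = 10.0
PRE_N1_MARGIN_S = 10.0

#: group band-power profiles (relative band power recovered by the pipeline).
#: The four reported bands sum to ~0.85 in both groups; the remainder is
#: assigned to low gamma.
HIGH_ESS_BANDS = {
    "delta": 0.294,
    "theta": 0.208,
    "alpha": 0.260,
    "beta": 0.087,
    "low_gamma": 0.151,
}
LOW_ESS_BANDS = {
    "delta": 0.239,
    "theta": 0.181,
    "alpha": 0.318,
    "beta": 0.112,
    "low_gamma": 0.150,
}


@dataclass(frozen=True)
class GroupProfile:
    """Spectral structure of one ESS group."""

    band_fractions: tuple  # ((band, fraction), ...)
    coherence: tuple = ()  # ((band, target msc), ...) for the coherent pair
    pac_depth: float = 0.2

    @property
    def fractions(self) -> dict:
        return dict(self.band_fractions)

    @property
    def coherence_targets(self) -> dict:
        return dict(self.coherence)


HIGH_ESS_PROFILE = GroupProfile(
    band_fractions=tuple(HIGH_ESS_BANDS.items()),
    coherence=(("delta", 0.5), ("theta", 0.5)),
    pac_depth=0.2,
)
LOW_ESS_PROFILE = GroupProfile(
    band_fractions=tuple(LOW_ESS_BANDS.items()),
    coherence=(("delta", 0.2), ("theta", 0.2)),
    pac_depth=0.2,
)


@dataclass(frozen=True)
class CovariateParams:
    """Per-group covariate distributions (age yrs, BMI kg/m², sex).

    Defaults follow the cohort table of the emulated study; ``leakage`` in
    [0, 1] shifts the high-ESS distributions so the covariates become
    predictive of group membership (0 = the near-balanced default).
    """

    age_mean_high: float = 52.7
    age_mean_low: float = 55.7
    age_sd: float = 14.5
    bmi_mean_high: float = 39.5
    bmi_mean_low: float = 36.5
    bmi_sd_high: float = 9.9
    bmi_sd_low: float = 9.4
    female_prop_high: float = 19 / 31
    female_prop_low: float = 16 / 41
    leakage: float = 0.0

    def group_params(self, group: str) -> dict:
        lam = self.leakage
        if group == "high":
            return {
                "age_mean": self.age_mean_high - 15.0 * lam,
                "age_sd": self.age_sd,
                "bmi_mean": self.bmi_mean_high + 10.0 * lam,
                "bmi_sd": self.bmi_sd_high,
                "female_prop": min(1.0, self.female_prop_high + 0.3 * lam),
            }
        return {
            "age_mean": self.age_mean_low,
            "age_sd": self.age_sd,
            "bmi_mean": self.bmi_mean_low,
            "bmi_sd": self.bmi_sd_low,
            "female_prop": self.female_prop_low,
        }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort."""

    n_high: int = 31
    n_low: int = 41
    ess_high_range: tuple = (20, 24)
    ess_low_range: tuple = (0, 4)
    duration_s: float = 600.0
    fs: float = 200.0
    channels: tuple = EEG_CHANNELS
    profile_high: GroupProfile = HIGH_ESS_PROFILE
    profile_low: GroupProfile = LOW_ESS_PROFILE
    coherent_pair: tuple = ("C4", "O2")
    pac_phase_hz: float = 6.0
    pac_carrier_hz: float = 40.0
    line_noise_amp: float = 1.0  # relative to background SD
    artifact_rate: float = 2.0  # expected events per minute
    subject_sd: float = 0.12  # between-subject log-scale band-power jitter
    covariate_params: CovariateParams = CovariateParams()
    seed: int = 0

    def validate(self) -> None:
        if self.n_high < 2 or self.n_low < 2:
            raise ConfigurationError("each group needs at least 2 subjects")
        for lo, hi in (self.ess_high_range, self.ess_low_range):
            if lo >= hi:
                raise ConfigurationError(f"invalid ESS range [{lo}, {hi}]")
        if self.ess_high_range[0] < 20 or self.ess_low_range[1] >= 5:
            raise ConfigurationError(
                "ESS ranges must respect group definitions (high >= 20, low < 5)"
            )
        for prof in (self.profile_high, self.profile_low):
            fracs = prof.fractions
            if any(v <= 0 for v in fracs.values()):
                raise ConfigurationError("band fractions must be positive")
        if self.fs <= 2 * 60.0:
            raise ConfigurationError("fs must exceed twice the line frequency")
        if self.duration_s < LIGHTS_OUT_S + PRE_N1_MARGIN_S + 180.0:
            raise ConfigurationError(
                "duration too short to contain a 180-s wake window"
            )
        if self.artifact_rate < 0:
            raise ConfigurationError("artifact rate must be >= 0")
        for ch in self.coherent_pair:
            if ch not in self.channels:
                raise ConfigurationError(f"coherent-pair channel {ch} unknown")

    def profile(self, group: str) -> GroupProfile:
        return self.profile_high if group == "high" else self.profile_low


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # {"high", "low"}
    ess: int
    age: float
    sex: str  # {"female", "male"}
    bmi: float
    recording_path: str = ""
    artifact_truth: np.ndarray = None  # (n_epochs, n_channels) bool

    def __post_init__(self):
        high = self.group == "high"
        if high != (self.ess >= 20) or (not high) != (self.ess < 5):
            raise ConfigurationError(
                f"group/ESS mismatch: {self.group} with ESS {self.ess}"
            )


@dataclass
class Cohort:
    config: GeneratorConfig
    subjects: list  # of SubjectRecord
    recordings: dict = field(default_factory=dict)  # subject_id -> Recording


# ---------------------------------------------------------------------------
# covariates


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def sample_covariates(config: GeneratorConfig) -> list:
    """Draw per-subject covariates (no recordings yet).

    ESS uniform on the group's integer range, age/BMI truncated normals with
    the group means/SDs, sex Bernoulli with the group female proportion.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    records = []
    idx = 1
    for group, n, ess_range in (
        ("high", config.n_high, config.ess_high_range),
        ("low", config.n_low, config.ess_low_range),
    ):
        p = config.covariate_params.group_params(group)
        ess = rng.integers(ess_range[0], ess_range[1] + 1, size=n)
        age = _truncated_normal(rng, p["age_mean"], p["age_sd"], 18, 95, n)
        bmi = _truncated_normal(rng, p["bmi_mean"], p["bmi_sd"], 15, 70, n)
        female = rng.random(n) < p["female_prop"]
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"S{idx:03d}",
                    group=group,
                    ess=int(ess[i]),
                    age=float(age[i]),
                    sex="female" if female[i] else "male",
                    bmi=float(bmi[i]),
                )
            )
            idx += 1
    return records


# ---------------------------------------------------------------------------
# band-power calibration

_BACKGROUND_SD = 4.0  # µV, pink background
_OSC_TOTAL_VAR = 180.0  # µV², split across the five band oscillators
_CAL_SEED = 987654321
_CAL_DURATION_S = 900.0
_CAL_TOL = 0.002
_CAL_MAX_ITER = 10

_calibration_cache: dict = {}


def _band_edges(scheme, band):
    lo, hi = dict(scheme.bands)[band]
    return max(lo - 0.5, 0.05), hi + 0.5


def _band_noise(rng, n, fs, lo, hi):
    """Unit-variance band-limited Gaussian noise, synthesized directly in the
    frequency domain (independent complex-Gaussian coefficients inside the
    band, zero outside)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    inside = (freqs >= lo) & (freqs <= hi)
    spec = np.zeros(len(freqs), dtype=complex)
    m = int(inside.sum())
    spec[inside] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng, n, fs, sd):
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.zeros(len(freqs), dtype=complex)
    nz = freqs > 0
    m = int(nz.sum())
    spec[nz] = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / np.sqrt(
        freqs[nz]
    )
    x = np.fft.irfft(spec, n)
    return x / x.std() * sd


def _unit_band_components(
    rng, n, fs, scheme, pac_depth=0.0, phase_hz=6.0, carrier_hz=40.0
):
    """Unit-variance per-band components (plus the PAC phase series).

    Shared by calibration and synthesis so that the spectral fine structure
    (narrowband PAC carrier/phase components and their band-edge leakage) is
    identical in both.
    """
    phase_band = scheme.band_of(int(round(phase_hz)))
    carrier_band = scheme.band_of(int(round(carrier_hz)))
    pac_on = pac_depth > 0 and phase_band is not None and carrier_band is not None
    components = {}
    # bands with a 50/50 broad + narrowband(PAC) structure expose their broad
    # part separately so coherence mixing can replace only the broad half and
    # leave the coupling structure identical in both groups
    parts = {}
    phase_series = None
    for b in scheme.band_names:
        broad = _band_noise(rng, n, fs, *_band_edges(scheme, b))
        own = broad
        if pac_on and b == phase_band:
            narrow = _band_noise(rng, n, fs, phase_hz - 1.0, phase_hz + 1.0)
            own = np.sqrt(0.5) * broad + np.sqrt(0.5) * narrow
            parts[b] = (broad, narrow)
            phase_series = np.angle(scipy_hilbert(narrow))
        if pac_on and b == carrier_band:
            carrier = _band_noise(rng, n, fs, carrier_hz - 2.0, carrier_hz + 2.0)
            if phase_series is None:
                raise ConfigurationError(
                    "PAC carrier band precedes phase band in the scheme"
                )
            modulated = carrier * (1.0 + pac_depth * np.cos(phase_series))
            modulated /= np.sqrt(1.0 + pac_depth**2 / 2.0)
            own = np.sqrt(0.5) * broad + np.sqrt(0.5) * modulated
            parts[b] = (broad, modulated)
        components[b] = own
    return components, parts


def scipy_hilbert(x):
    import scipy.signal

    return scipy.signal.hilbert(x)


def _measure_fractions(signal, fs, scheme):
    rec = Recording(samples=signal[None, :], fs=fs, channel_labels=("CAL",))
    rec = notch(highpass(rec))
    grid = make_epoch_grid(rec)
    p = epoch_periodogram(grid.data, fs)
    norm = average_and_normalize(p, channel_labels=("CAL",), scheme=scheme)
    _, mean = band_power_fractions(norm, scheme)
    return mean


def calibrated_band_variances(
    profile: GroupProfile,
    fs: float,
    scheme=DEFAULT_SCHEME,
    pac_phase_hz: float = 6.0,
    pac_carrier_hz: float = 40.0,
) -> dict:
    """Oscillator variances (µV²) reproducing the profile's relative band
    powers through the package's own preprocessing + PSD estimator.

    Closed-form initialization (variance proportional to the target fraction)
    followed by at most 10 fixed-point refinements against the measured
    fractions of a long calibration realization built with the same component
    constructor as subject synthesis; stops when every band is within 0.002.
    Cached per (profile, fs, PAC frequencies).
    """
    key = (
        profile.band_fractions, profile.pac_depth, float(fs), scheme.bands,
        float(pac_phase_hz), float(pac_carrier_hz),
    )
    if key in _calibration_cache:
        return _calibration_cache[key]
    targets = profile.fractions
    bands = list(targets)
    var = {b: _OSC_TOTAL_VAR * targets[b] for b in bands}
    rng = np.random.default_rng(_CAL_SEED)
    n = int(round(_CAL_DURATION_S * fs))
    # frozen noise components: refine only the variances, not the realization
    components, _ = _unit_band_components(
        rng, n, fs, scheme, profile.pac_depth, pac_phase_hz, pac_carrier_hz
    )
    background = _pink_noise(rng, n, fs, _BACKGROUND_SD)
    line = np.sqrt(2.0) * _BACKGROUND_SD * np.sin(
        2 * np.pi * 60.0 * np.arange(n) / fs
    )
    for _ in range(_CAL_MAX_ITER):
        signal = background + line
        for b in bands:
            signal = signal + np.sqrt(var[b]) * components[b]
        measured = _measure_fractions(signal, fs, scheme)
        err = max(abs(measured[b] - targets[b]) for b in bands)
        if err < _CAL_TOL:
            break
        for b in bands:
            if measured[b] > 0:
                var[b] *= targets[b] / measured[b]
    _calibration_cache[key] = var
    return var


# ---------------------------------------------------------------------------
# recording synthesis


def synthesize_recording(
    profile: GroupProfile, config: GeneratorConfig, subject_seed: int
) -> Recording:
    """One subject's 6-channel recording (µV), deterministic given
    ``(config.seed, subject_seed)``.

    Channels are built from a pink background + calibrated band oscillators;
    the coherent-pair channels additionally share a band-limited source in the
    bands with a coherence target, mixed as ``alpha·shared +
    sqrt(1-alpha²)·own`` with ``alpha = target**(1/4)`` (for unit-variance
    components the resulting magnitude-squared coherence is ``alpha**4``).
    Weak PAC is realised by replacing half the carrier-band variance with a
    narrowband carrier whose envelope follows ``1 + depth·cos(phase)`` of a
    narrowband phase component inside the phase band.
    """
    config.validate()
    fs = config.fs
    n = int(round(config.duration_s * fs))
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 202, int(subject_seed)])
    )
    scheme = DEFAULT_SCHEME
    base_var = calibrated_band_variances(
        profile, fs, scheme, config.pac_phase_hz, config.pac_carrier_hz
    )
    # between-subject variation: mean-one lognormal jitter per band
    sd = config.subject_sd
    jitter = {
        b: float(np.exp(rng.normal(-0.5 * sd**2, sd))) for b in base_var
    }
    var = {b: v * jitter[b] for b, v in base_var.items()}

    coh_targets = profile.coherence_targets
    pair_idx = [config.channels.index(c) for c in config.coherent_pair]
    shared = {
        b: _band_noise(rng, n, fs, *_band_edges(scheme, b))
        for b in coh_targets
        if coh_targets[b] > 0
    }

    t = np.arange(n) / fs
    samples = np.empty((len(config.channels), n))
    for ci, ch in enumerate(config.channels):
        x = _pink_noise(rng, n, fs, _BACKGROUND_SD)
        x = x + config.line_noise_amp * _BACKGROUND_SD * np.sqrt(2.0) * np.sin(
            2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi)
        )
        components, parts = _unit_band_components(
            rng, n, fs, scheme, profile.pac_depth,
            config.pac_phase_hz, config.pac_carrier_hz,
        )
        for b, own in components.items():
            if b in shared and ci in pair_idx:
                alpha = coh_targets[b] ** 0.25
                if b in parts:
                    # replace only the broad half; the narrowband coupling
                    # component keeps the same weight in every group
                    broad, special = parts[b]
                    mixed = alpha * shared[b] + np.sqrt(1 - alpha**2) * broad
                    own = np.sqrt(0.5) * mixed + np.sqrt(0.5) * special
                else:
                    own = alpha * shared[b] + np.sqrt(1 - alpha**2) * own
            x = x + np.sqrt(var[b]) * own
        samples[ci] = x

    annotations = [
        (("LIGHTS_OUT"), LIGHTS_OUT_S),
        (("N1"), config.duration_s - PRE_N1_MARGIN_S),
    ]
    return Recording(
        samples=samples,
        fs=fs,
        channel_labels=config.channels,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# artifacts

_ARTIFACT_TYPES = ("transient", "drift", "burst")


def inject_artifacts(rec: Recording, config: GeneratorConfig, seed: int, return_events: bool = False):
    """Insert high-amplitude transients, slow drifts and broadband bursts at
    Poisson-distributed times; returns the corrupted recording and per-1-s-
    epoch, per-channel truth labels (full-recording epoch grid, epoch 0 at
    t = 0)."""
    if config.artifact_rate < 0:
        raise ConfigurationError("artifact rate must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303, int(seed)]))
    fs = rec.fs
    n = rec.n_samples
    n_epochs = int(n // int(round(fs)))
    truth = np.zeros((n_epochs, rec.n_channels), dtype=bool)
    if config.artifact_rate == 0:
        return (rec, truth, []) if return_events else (rec, truth)
    duration_min = rec.duration_s / 60.0
    n_events = rng.poisson(config.artifact_rate * duration_min)
    samples = rec.samples.copy()
    ch_sd = samples.std(axis=1)
    fs_i = int(round(fs))
    events = []
    for _ in range(n_events):
        kind = _ARTIFACT_TYPES[rng.integers(len(_ARTIFACT_TYPES))]
        onset = rng.uniform(0, rec.duration_s)
        if kind == "transient":
            dur, chans = 0.15, [rng.integers(rec.n_channels)]
        elif kind == "drift":
            # slow high-amplitude movement wave; fast enough (~2 Hz) to
            # survive the 1 Hz high-pass applied downstream
            dur, chans = 1.5, [rng.integers(rec.n_channels)]
        else:
            dur, chans = 1.5, list(range(rec.n_channels))
        i0 = int(onset * fs)
        i1 = min(int((onset + dur) * fs), n)
        if i1 <= i0:
            continue
        width = i1 - i0
        tt = np.arange(width) / fs
        events.append({"kind": kind, "onset_s": onset, "channels": list(map(int, chans))})
        for c in chans:
            amp = ch_sd[c]
            if kind == "transient":
                shape = 8.0 * amp * np.hanning(width)
                shape *= rng.choice([-1.0, 1.0])
            elif kind == "drift":
                shape = 6.0 * amp * np.sin(2 * np.pi * 2.0 * tt) * np.hanning(width)
            else:
                shape = 5.0 * amp * rng.standard_normal(width) * np.hanning(width)
            samples[c, i0:i1] += shape
            # label only epochs where the injected waveform reaches an
            # appreciable amplitude, not ones grazed by a tapered tail
            for e in range(int(i0 // fs_i), min(int((i1 - 1) // fs_i), n_epochs - 1) + 1):
                seg = shape[
                    max(e * fs_i - i0, 0) : max((e + 1) * fs_i - i0, 0)
                ]
                if len(seg) and np.abs(seg).max() >= 3.0 * amp:
                    truth[e, c] = True
    out = replace(rec, samples=samples), truth
    if return_events:
        return out[0], out[1], events
    return out


# ---------------------------------------------------------------------------
# cohort assembly and serialization


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Covariates + recordings + artifact truth for every subject."""
    records = sample_covariates(config)
    cohort = Cohort(config=config, subjects=records)
    for i, record in enumerate(records):
        rec = synthesize_recording(config.profile(record.group), config, i)
        rec, truth = inject_artifacts(rec, config, i)
        record.artifact_truth = truth
        cohort.recordings[record.subject_id] = rec
    return cohort


def write_cohort(directory, cohort: Cohort) -> dict:
    """Write one EDF + events sidecar + truth CSV per subject plus a cohort
    covariates CSV; returns a manifest of everything written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"edf": [], "events": [], "truth": [], "covariates": None}
    cov_path = directory / "covariates.csv"
    with open(cov_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "ess", "age", "sex", "bmi"])
        for rec in cohort.subjects:
            writer.writerow(
                [
                    rec.subject_id,
                    rec.group,
                    rec.ess,
                    f"{rec.age:.2f}",
                    rec.sex,
                    f"{rec.bmi:.2f}",
                ]
            )
    manifest["covariates"] = str(cov_path)
    for record in cohort.subjects:
        recording = cohort.recordings.get(record.subject_id)
        if recording is None:
            continue
        edf_path = directory / f"{record.subject_id}.edf"
        edf.write_edf(
            edf_path,
            recording.samples,
            recording.fs,
            recording.channel_labels,
        )
        record.recording_path = str(edf_path)
        manifest["edf"].append(str(edf_path))
        ev_path = directory / f"{record.subject_id}_events.csv"
        with open(ev_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "onset_s"])
            for label, onset in recording.annotations:
                writer.writerow([label, f"{onset:.3f}"])
        manifest["events"].append(str(ev_path))
        truth_path = directory / f"{record.subject_id}_truth.csv"
        with open(truth_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "channel", "flag"])
            truth = record.artifact_truth
            if truth is not None:
                for e, c in zip(*np.nonzero(truth)):
                    writer.writerow([int(e), recording.channel_labels[c], 1])
        manifest["truth"].append(str(truth_path))
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_covariates(path):
    """Covariates CSV back into a list of dict rows."""
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
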