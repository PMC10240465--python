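"""End-to-end orchestration: recording -> features -> statistics -> classifier.

`extract_subject_features` runs one subject through the full preprocessing and
feature chain; `build_cohort_table` assembles the subjects x features table
for a synthetic cohort (training the artifact detector on the cohort's ground
truth); `run_study` performs the whole analysis — grids, feature selection,
cross-validated kNN and the confound GLMs — in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify_confound import ConfoundReport, CvReport, confound_analysis, cross_validate
from .feature_stats import FeatureTable, SelectedFeatureSet, build_grids, select_features
from .io_preprocess import (
    ArtifactMask,
    DataError,
    Recording,
    detect_artifacts,
    drop_noisy_channels,
    highpass,
    make_epoch_grid,
    notch,
    select_wake_window,
    train_artifact_detector,
)
from .pac_features import BAND_PAIRS, bandwise_pac, clean_runs, mi_grid
from .spectral_features import (
    DEFAULT_SCHEME,
    all_pairs,
    average_and_normalize,
    band_power_fractions,
    bandwise_psd,
    bandwise_coherence,
    coherence_matrix,
    epoch_periodogram,
    pair_label,
    psd_by_hz,
)
from .synth_cohort import Cohort, GeneratorConfig, generate_cohort

__all__ = [
    "SubjectFeatures",
    "CohortFeatures",
    "StudyResult",
    "extract_subject_features",
    "build_cohort_table",
    "run_study",
]


@dataclass
class SubjectFeatures:
    features: dict  # feature name -> value (NaN = missing)
    families: dict  # feature name -> family tag
    band_power: dict  # band -> channel-mean relative band power
    window_start_s: float = 0.0
    channels_kept: tuple = ()


@dataclass
class CohortFeatures:
    table: FeatureTable
    covariates: pd.DataFrame  # age, bmi, gender (female = 1)
    band_power: pd.DataFrame  # subjects x bands, channel-mean fractions
    window_starts: pd.Series = None

    def tidy_features(self) -> pd.DataFrame:
        """Long-format view: subject_id, family, feature_name, value."""
        long = self.table.values.stack(future_stack=True).reset_index()
        long.columns = ["subject_id", "feature_name", "value"]
        long.insert(1, "family", long["feature_name"].map(self.table.families))
        return long


@dataclass
class StudyResult:
    features: CohortFeatures
    grids: list
    selection: SelectedFeatureSet
    cv_report: CvReport
    confound_report: ConfoundReport


def extract_subject_features(
    recording: Recording,
    detector=None,
    truth_mask: np.ndarray = None,
    scheme=DEFAULT_SCHEME,
    include_pac: bool = True,
    window_s: int = 180,
    prefiltered: bool = False,
) -> SubjectFeatures:
    """Full single-subject feature extraction.

    Filters (1 Hz high-pass + mains notch), epochs the lights-out-to-N1 span,
    flags artifacts with ``detector`` (or slices the full-recording
    ``truth_mask``), selects the cleanest 3-minute window, drops channels with
    > 50 % flagged epochs, and computes normalized-PSD, coherence and
    (optionally) PAC features. Dropped channels/pairs yield NaN features.
    """
    rec = recording if prefiltered else notch(highpass(recording))
    lights = rec.annotation_onset("LIGHTS_OUT")
    span = int(np.floor(rec.annotation_onset("N1") - lights))
    if detector is not None:
        grid_full = make_epoch_grid(rec, start_s=lights, n_epochs=span)
        mask = detect_artifacts(grid_full, detector)
    elif truth_mask is not None:
        offset = int(round(lights))
        mask = ArtifactMask(truth_mask[offset : offset + span])
    else:
        mask = None
    start, window, wmask = select_wake_window(rec, mask, window_s=window_s)
    keep = drop_noisy_channels(wmask)
    labels = rec.channel_labels
    kept = tuple(lab for lab, k in zip(labels, keep) if k)

    # flag every epoch of a dropped channel so no estimator consumes it
    flags = wmask.flags.copy()
    flags[:, ~keep] = True
    wmask = ArtifactMask(flags)

    periodograms = epoch_periodogram(window.data, window.fs)
    norm = average_and_normalize(
        periodograms, wmask, channel_labels=labels, scheme=scheme
    )
    per_band, _ = bandwise_psd(norm, scheme)
    frac_per_ch, frac_mean = band_power_fractions(norm, scheme)

    features: dict = {}
    families: dict = {}
    for band in scheme.band_names:
        for c, lab in enumerate(labels):
            name = f"psd_{band}_{lab}"
            features[name] = float(per_band[band][c]) if keep[c] else np.nan
            families[name] = "psd_band_channel"
    for (hz, lab), value in psd_by_hz(norm).items():
        name = f"psdhz_{hz}_{lab}"
        ok = keep[labels.index(lab)]
        features[name] = value if ok else np.nan
        families[name] = "psd_hz"

    spectra = coherence_matrix(window, wmask)
    for (plab, band), value in bandwise_coherence(spectra, scheme).items():
        name = f"coh_{plab}_{band}"
        features[name] = value
        families[name] = "coherence"

    if include_pac:
        signal = window.concatenate()
        for c, lab in enumerate(labels):
            runs = clean_runs(wmask, c, window.fs) if keep[c] else []
            if runs:
                grid = mi_grid(signal[c], runs, window.fs, channel=lab)
                pac = bandwise_pac(grid, scheme)
            else:
                pac = {bp: np.nan for bp in BAND_PAIRS}
            for (band, gamma), value in pac.items():
                name = f"pac_{band}_{gamma}_{lab}"
                features[name] = value
                families[name] = "pac"

    return SubjectFeatures(
        features=features,
        families=families,
        band_power=frac_mean,
        window_start_s=start / rec.fs,
        channels_kept=kept,
    )


def _train_cohort_detector(cohort: Cohort, max_subjects: int = 8, seed: int = 0):
    """Fit the artifact detector on the first few subjects' labelled epochs."""
    blocks, truths = [], []
    for record in cohort.subjects[:max_subjects]:
        rec = cohort.recordings[record.subject_id]
        filt = notch(highpass(rec))
        grid = make_epoch_grid(filt)
        n = min(grid.n_epochs, record.artifact_truth.shape[0])
        blocks.append(grid.data[:n])
        truths.append(record.artifact_truth[:n])
    data = np.concatenate(blocks, axis=0)
    flags = np.concatenate(truths, axis=0)
    grid_all = make_epoch_grid(
        Recording(
            samples=data.transpose(1, 0, 2).reshape(data.shape[1], -1),
            fs=cohort.config.fs,
            channel_labels=cohort.config.channels,
        )
    )
    return train_artifact_detector(grid_all, ArtifactMask(flags), seed=seed)


def build_cohort_table(
    cohort: Cohort,
    include_pac: bool = True,
    use_truth_mask: bool = False,
    detector=None,
    scheme=DEFAULT_SCHEME,
    window_s: int = 180,
) -> CohortFeatures:
    """Subjects x features table plus covariates for a synthetic cohort.

    By default an artifact detector is trained on the cohort's own ground
    truth and applied to every subject; ``use_truth_mask=True`` bypasses the
    detector and masks directly with the generator's labels.
    """
    if detector is None and not use_truth_mask:
        detector = _train_cohort_detector(cohort)
    rows, families = {}, {}
    band_rows = {}
    starts = {}
    for record in cohort.subjects:
        rec = cohort.recordings[record.subject_id]
        sf = extract_subject_features(
            rec,
            detector=detector,
            truth_mask=record.artifact_truth if use_truth_mask else None,
            scheme=scheme,
            include_pac=include_pac,
            window_s=window_s,
        )
        rows[record.subject_id] = sf.features
        families.update(sf.families)
        band_rows[record.subject_id] = sf.band_power
        starts[record.subject_id] = sf.window_start_s
    values = pd.DataFrame.from_dict(rows, orient="index")
    labels = pd.Series(
        {r.subject_id: r.group for r in cohort.subjects}, name="group"
    ).loc[values.index]
    covariates = pd.DataFrame(
        {
            r.subject_id: {
                "age": r.age,
                "bmi": r.bmi,
                "gender": 1.0 if r.sex == "female" else 0.0,
            }
            for r in cohort.subjects
        }
    ).T.loc[values.index]
    return CohortFeatures(
        table=FeatureTable(values=values, labels=labels, families=families),
        covariates=covariates,
        band_power=pd.DataFrame.from_dict(band_rows, orient="index"),
        window_starts=pd.Series(starts),
    )


def run_study(
    config: GeneratorConfig = None,
    cohort: Cohort = None,
    policy: str = "reported_set",
    include_pac: bool = True,
    cv_seed: int = 0,
    k: int = 5,
    use_truth_mask: bool = False,
) -> StudyResult:
    """Generate (or accept) a cohort and run the complete analysis."""
    if cohort is None:
        cohort = generate_cohort(config or GeneratorConfig())
    features = build_cohort_table(
        cohort, include_pac=include_pac, use_truth_mask=use_truth_mask
    )
    grids = build_grids(features.table)
    selection = select_features(grids, policy=policy)
    if not len(selection):
        raise DataError("empty feature selection; classifier stage refused")
    X = features.table.values[list(selection.names)]
    cv = cross_validate(X, features.table.labels, k=k, seed=cv_seed)
    confound = confound_analysis(cv, features.covariates)
    return StudyResult(
        features=features,
        grids=grids,
        selection=selection,
        cv_report=cv,
        confound_report=confound,
    )
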