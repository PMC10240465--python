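"""Group-difference testing, heat-map p-value grids and feature selection.

PSD and coherence features are compared between the high- and low-ESS groups
with two-sample Welch t tests; PAC features — bounded in [0, 1] and therefore
unlikely to be normal — with two-tailed Wilcoxon rank-sum tests. Significance
is declared at p < 0.05 per cell with no multiplicity adjustment: the tests
guide feature selection for the classifier rather than decide a joint null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io_preprocess import EEG_CHANNELS
from .pac_features import BAND_PAIRS
from .spectral_features import DEFAULT_SCHEME, all_pairs, pair_label

__all__ = [
    "FeatureTable",
    "PValueGrid",
    "SelectedFeatureSet",
    "REPORTED_FEATURE_SET",
    "two_sample_t",
    "ranksum",
    "build_grids",
    "select_features",
]

ALPHA = 0.05

#: the fixed three-feature set reported by the emulated study: O2–C4 coherence
#: in delta and theta, plus O2 beta-band PSD
REPORTED_FEATURE_SET = ("coh_C4-O2_delta", "coh_C4-O2_theta", "psd_beta_O2")


@dataclass
class FeatureTable:
    """Subjects x named features with missing-value support.

    ``values`` is a DataFrame indexed by subject_id; ``labels`` maps each
    subject to "high" or "low"; ``families`` maps feature name -> family tag.
    """

    values: pd.DataFrame
    labels: pd.Series
    families: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            raise ValueError("every subject needs a group label")

    def split(self, feature: str):
        col = self.values[feature]
        return (
            col[self.labels == "high"].to_numpy(dtype=float),
            col[self.labels == "low"].to_numpy(dtype=float),
        )


@dataclass
class PValueGrid:
    """Family-shaped table of test statistics and two-tailed p-values."""

    family: str
    row_labels: tuple
    col_labels: tuple
    feature_names: np.ndarray  # (rows, cols) object array
    statistic: np.ndarray
    p: np.ndarray
    alpha: float = ALPHA

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha

    def cell(self, row, col):
        i = self.row_labels.index(row)
        j = self.col_labels.index(col)
        return self.statistic[i, j], self.p[i, j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.row_labels):
            for j, c in enumerate(self.col_labels):
                rows.append(
                    {
                        "family": self.family,
                        "row": r,
                        "col": c,
                        "feature": self.feature_names[i, j],
                        "statistic": self.statistic[i, j],
                        "p": self.p[i, j],
                        "significant": bool(self.p[i, j] < self.alpha),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SelectedFeatureSet:
    names: tuple
    provenance: tuple = ()  # dicts: family, row, col, p

    def __iter__(self):
        return iter(self.names)

    def __len__(self):
        return len(self.names)


# ---------------------------------------------------------------------------
# tests


def _clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return a[~np.isnan(a)]


def two_sample_t(values_high, values_low):
    """Welch two-sample t statistic and two-tailed p (Welch–Satterthwaite
    degrees of freedom). Returns (nan, nan) with fewer than 2 values per
    group."""
    a, b = _clean(values_high), _clean(values_low)
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: identical spread; equal means give t = 0, p = 1
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def ranksum(values_high, values_low):
    """Two-tailed Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration when the combined sample is small (n <= 10) and tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a, b = _clean(values_high), _clean(values_low)
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan
    pooled = np.concatenate([a, b])
    exact = len(pooled) <= 10 and len(np.unique(pooled)) == len(pooled)
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# grids


def _grid_from_layout(table, family, row_labels, col_labels, name_fn, test_fn, alpha):
    n_r, n_c = len(row_labels), len(col_labels)
    stats = np.full((n_r, n_c), np.nan)
    pvals = np.full((n_r, n_c), np.nan)
    names = np.empty((n_r, n_c), dtype=object)
    for i, r in enumerate(row_labels):
        for j, c in enumerate(col_labels):
            name = name_fn(r, c)
            names[i, j] = name
            if name not in table.values.columns:
                continue
            hi, lo = table.split(name)
            stats[i, j], pvals[i, j] = test_fn(hi, lo)
    return PValueGrid(
        family=family,
        row_labels=tuple(row_labels),
        col_labels=tuple(col_labels),
        feature_names=names,
        statistic=stats,
        p=pvals,
        alpha=alpha,
    )


def build_grids(
    table: FeatureTable,
    scheme=DEFAULT_SCHEME,
    alpha: float = ALPHA,
    channels=EEG_CHANNELS,
    hz_range=(1, 16),
):
    """Heat-map grids for every feature family present in the table.

    t-test grids: band x channel PSD (5 x 6), by-Hz PSD (16 x 6), band x pair
    coherence (5 x 15); rank-sum grid: band-pair x channel PAC (8 x 6).
    """
    present = set(table.values.columns)
    grids = []
    bands = scheme.band_names
    if any(f"psd_{b}_{c}" in present for b in bands for c in channels):
        grids.append(
            _grid_from_layout(
                table, "psd_band_channel", bands, channels,
                lambda b, c: f"psd_{b}_{c}", two_sample_t, alpha,
            )
        )
    hzs = tuple(range(hz_range[0], hz_range[1] + 1))
    if any(f"psdhz_{h}_{c}" in present for h in hzs for c in channels):
        grids.append(
            _grid_from_layout(
                table, "psd_hz", hzs, channels,
                lambda h, c: f"psdhz_{h}_{c}", two_sample_t, alpha,
            )
        )
    pairs = tuple(pair_label(a, b) for a, b in all_pairs(channels))
    if any(f"coh_{p}_{b}" in present for p in pairs for b in bands):
        grids.append(
            _grid_from_layout(
                table, "coherence", bands, pairs,
                lambda b, p: f"coh_{p}_{b}", two_sample_t, alpha,
            )
        )
    pac_rows = tuple(f"{band}~{gamma}" for band, gamma in BAND_PAIRS)
    if any(
        f"pac_{band}_{gamma}_{c}" in present
        for band, gamma in BAND_PAIRS
        for c in channels
    ):
        grids.append(
            _grid_from_layout(
                table, "pac", pac_rows, channels,
                lambda r, c: "pac_{}_{}_{}".format(*r.split("~"), c),
                ranksum, alpha,
            )
        )
    return grids


# ---------------------------------------------------------------------------
# selection


def select_features(
    grids,
    policy: str = "significant_cells",
    alpha: float = ALPHA,
    top_k: int = None,
    source_families=("coherence", "psd_hz"),
    scheme=DEFAULT_SCHEME,
) -> SelectedFeatureSet:
    """Choose the classifier feature set from the p-value grids.

    ``significant_cells`` (default): every cell with p < alpha from the source
    grids, by-Hz PSD cells aggregated to their band-level feature (keeping the
    smallest p per band x channel), ordered by ascending p, optionally capped
    at ``top_k``. ``reported_set``: the fixed three-feature set used for
    pipeline-reproduction runs.
    """
    if policy == "reported_set":
        return SelectedFeatureSet(
            names=REPORTED_FEATURE_SET,
            provenance=tuple({"family": "reported_set", "feature": f} for f in REPORTED_FEATURE_SET),
        )
    if policy != "significant_cells":
        raise ValueError(f"unknown selection policy {policy!r}")
    chosen = {}
    for grid in grids:
        if grid.family not in source_families:
            continue
        for i, r in enumerate(grid.row_labels):
            for j, c in enumerate(grid.col_labels):
                p = grid.p[i, j]
                if np.isnan(p) or p >= alpha:
                    continue
                name = grid.feature_names[i, j]
                if grid.family == "psd_hz":
                    band = scheme.band_of(int(r))
                    if band is None:
                        continue
                    name = f"psd_{band}_{c}"
                prov = {"family": grid.family, "row": r, "col": c, "p": float(p)}
                if name not in chosen or p < chosen[name]["p"]:
                    chosen[name] = prov
    ordered = sorted(chosen.items(), key=lambda kv: kv[1]["p"])
    if top_k is not None:
        ordered = ordered[:top_k]
    return SelectedFeatureSet(
        names=tuple(name for name, _ in ordered),
        provenance=tuple(prov for _, prov in ordered),
    )
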