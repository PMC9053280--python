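"""From raw time-resolved spectra to the measurements x features nAUC matrix.

The processing chain: detect exhalation pulses in the total ion current,
(optionally) align scans on a common m/z grid, pool centroids across the
cohort and consolidate them into a feature list by kernel density, extract
per-feature intensity time-traces, drop features not correlated with the
exhalation profile, and summarise each (measurement, feature) as the mean
exhalation-time-normalised area under the curve (nAUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClinicalAnnotation",
    "RawMeasurement",
    "ExhalationWindow",
    "FeatureDefinition",
    "FeatureTable",
    "detect_exhalations",
    "align_scans",
    "build_feature_list",
    "extract_trace",
    "extract_traces",
    "breath_correlation_filter",
    "compute_nauc",
    "assemble_feature_table",
]

MZ_RANGE = (100.0, 400.0)


@dataclass(frozen=True)
class ClinicalAnnotation:
    """Per-measurement clinical state.

    Outcome classes are coded 1 (I), 2 (II), 3 (III); the binary contrasts
    used downstream are class I vs classes II+III: 'no side effects' vs
    'side effects', 'responder' vs 'non-responder', 'normal' vs 'abnormal'
    EEG.
    """

    drugs: tuple[str, ...] = ()
    total_vpa_mgL: float = 0.0
    free_vpa_mgL: float | None = None
    side_effects_class: int = 1
    response_class: int = 1
    eeg_class: int = 1

    def __post_init__(self):
        if self.total_vpa_mgL < 0:
            raise ValueError("total_vpa_mgL must be >= 0")
        if self.free_vpa_mgL is not None and self.free_vpa_mgL < 0:
            raise ValueError("free_vpa_mgL must be >= 0 or None")

    @property
    def has_side_effects(self) -> bool:
        return self.side_effects_class >= 2

    @property
    def is_non_responder(self) -> bool:
        return self.response_class >= 2

    @property
    def has_abnormal_eeg(self) -> bool:
        return self.eeg_class >= 2


@dataclass
class RawMeasurement:
    """One subject visit: centroided scans over time plus annotation."""

    measurement_id: str
    subject_id: str
    cohort: str
    polarity: str
    batch_label: str
    scan_times: np.ndarray
    scans: list[tuple[np.ndarray, np.ndarray]]  # per scan: sorted m/z, intensity
    tic: np.ndarray
    clinical: ClinicalAnnotation

    def __post_init__(self):
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        self.tic = np.asarray(self.tic, dtype=float)
        if not (len(self.tic) == len(self.scan_times) == len(self.scans)):
            raise ValueError("scan_times, scans and tic must have equal length")
        if len(self.scan_times) > 1 and np.any(np.diff(self.scan_times) <= 0):
            raise ValueError("scan_times must be strictly increasing")


@dataclass(frozen=True)
class ExhalationWindow:
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FeatureDefinition:
    feature_id: str
    mz: float
    polarity: str = "+"
    tol_ppm: float = 5.0

    def __post_init__(self):
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")

    @property
    def window(self) -> tuple[float, float]:
        half = self.mz * self.tol_ppm * 1e-6
        return self.mz - half, self.mz + half


@dataclass
class FeatureTable:
    """Measurements x features matrix of mean nAUC with row/column metadata."""

    values: pd.DataFrame          # measurements x features, mean nAUC (>= 0)
    obs: pd.DataFrame             # per-measurement metadata
    var: pd.DataFrame             # per-feature metadata (mz, polarity, tol_ppm)
    presence: pd.DataFrame        # boolean detection mask, same shape as values

    def __post_init__(self):
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("measurement and feature ids must be unique")
        if (self.values.values < 0).any():
            raise ValueError("nAUC values must be non-negative")
        if not self.values.index.equals(self.obs.index):
            raise ValueError("obs index must match values index")
        if not self.values.columns.equals(pd.Index(self.var.index)):
            raise ValueError("var index must match values columns")

    @property
    def n_measurements(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            self.values[ids].copy(),
            self.obs.copy(),
            self.var.loc[ids].copy(),
            self.presence[ids].copy(),
        )

    def subset_measurements(self, measurement_ids) -> "FeatureTable":
        ids = list(measurement_ids)
        return FeatureTable(
            self.values.loc[ids].copy(),
            self.obs.loc[ids].copy(),
            self.var.copy(),
            self.presence.loc[ids].copy(),
        )


# ---------------------------------------------------------------------------
# exhalation detection

def detect_exhalations(
    tic: np.ndarray,
    scan_times: np.ndarray,
    threshold_frac: float = 0.3,
    min_duration_s: float = 5.0,
    min_gap_s: float = 3.0,
) -> list[ExhalationWindow]:
    """Detect exhalation pulses as supra-threshold runs of the TIC.

    The baseline is the 10th percentile of the TIC; the threshold sits at
    ``baseline + threshold_frac * (max - baseline)``. Runs closer than
    ``min_gap_s`` are merged, then runs shorter than ``min_duration_s`` are
    dropped. A flat TIC yields no windows.
    """
    tic = np.asarray(tic, float)
    scan_times = np.asarray(scan_times, float)
    if len(tic) < 10:
        raise ValueError("need at least 10 scans")
    if not np.all(np.isfinite(tic)):
        raise ValueError("TIC must be finite")
    baseline = np.percentile(tic, 10)
    span = tic.max() - baseline
    if span <= 1e-12 * max(abs(tic.max()), 1.0):
        return []
    above = tic >= baseline + threshold_frac * span

    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((scan_times[i], scan_times[j]))
            i = j + 1
        else:
            i += 1
    # merge runs separated by less than min_gap_s
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < min_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [ExhalationWindow(s, e) for s, e in merged if e - s >= min_duration_s]


def exhalation_indicator(scan_times: np.ndarray, windows: list[ExhalationWindow]) -> np.ndarray:
    """0/1 vector marking scans inside any detected exhalation window."""
    ind = np.zeros(len(scan_times))
    for w in windows:
        ind[(scan_times >= w.start_s) & (scan_times <= w.end_s)] = 1.0
    return ind


# ---------------------------------------------------------------------------
# recursive FFT alignment (RAFFT-style)

def _best_lag(x: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    n = len(x)
    if n == 0 or max_shift == 0:
        return 0
    X = np.fft.rfft(ref)
    Y = np.fft.rfft(x)
    cc = np.fft.irfft(X * np.conj(Y), n=n)  # cc[l] = sum ref[i] * x[i - l]
    lags = np.concatenate([np.arange(0, min(max_shift, n - 1) + 1),
                           np.arange(-min(max_shift, n - 1), 0)])
    best = int(lags[np.argmax(cc[lags])])
    return best


def _rafft_segment(x: np.ndarray, ref: np.ndarray, max_shift: int, min_seg: int) -> np.ndarray:
    lag = _best_lag(x, ref, max_shift)
    if lag != 0:
        x = np.roll(x, lag)
    if len(x) >= 2 * min_seg and max_shift > 1:
        mid = len(x) // 2
        left = _rafft_segment(x[:mid].copy(), ref[:mid], max_shift // 2, min_seg)
        right = _rafft_segment(x[mid:].copy(), ref[mid:], max_shift // 2, min_seg)
        x = np.concatenate([left, right])
    return x


def align_scans(
    scans: np.ndarray,
    max_shift_bins: int = 10,
    min_segment_bins: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Align gridded scans by recursive FFT cross-correlation.

    ``scans`` is an (n_scans, n_bins) array of intensities on a common
    uniform m/z grid. Each scan is shifted by the integer lag maximising
    its FFT cross-correlation with the running reference (cumulative mean
    of already-aligned scans), then halved segments are re-aligned
    recursively with a halved shift budget. Circular shifts conserve the
    per-scan total intensity exactly.

    Returns (aligned scans, whole-scan shift per scan).
    """
    scans = np.asarray(scans, float)
    if scans.ndim != 2:
        raise ValueError("scans must be 2-D (n_scans, n_bins)")
    aligned = np.empty_like(scans)
    shifts = np.zeros(len(scans), dtype=int)
    ref = None
    for i, scan in enumerate(scans):
        if ref is None or scan.sum() == 0:
            aligned[i] = scan
            if ref is None:
                ref = scan.astype(float).copy()
            continue
        lag = _best_lag(scan, ref, max_shift_bins)
        shifted = np.roll(scan, lag) if lag else scan.copy()
        shifted = _rafft_segment(shifted, ref, max_shift_bins // 2, min_segment_bins)
        aligned[i] = shifted
        shifts[i] = lag
        ref = ref + (shifted - ref) / (i + 1)  # running mean reference
    return aligned, shifts


def make_mz_grid(mz_min: float = MZ_RANGE[0], mz_max: float = MZ_RANGE[1],
                 resolution: float = 140_000.0, points_per_fwhm: float = 4.0) -> np.ndarray:
    """Uniform-in-log m/z grid with step ~ FWHM/points_per_fwhm at the given
    resolving power (FWHM = m/z / resolution, so the relative step is
    constant)."""
    step = 1.0 / (resolution * points_per_fwhm)
    n = int(np.ceil(np.log(mz_max / mz_min) / step)) + 1
    return mz_min * np.exp(step * np.arange(n))


def grid_scan(mz: np.ndarray, intensity: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Deposit centroids onto the nearest grid bin (intensity-conserving)."""
    out = np.zeros(len(grid))
    if len(mz) == 0:
        return out
    idx = np.clip(np.searchsorted(grid, mz), 1, len(grid) - 1)
    left = grid[idx - 1]
    right = grid[idx]
    nearest = np.where(mz - left <= right - mz, idx - 1, idx)
    np.add.at(out, nearest, intensity)
    return out


# ---------------------------------------------------------------------------
# feature-list construction

def build_feature_list(
    measurements: list[RawMeasurement],
    kde_bandwidth_ppm: float = 5.0,
    min_presence: float = 0.10,
    tol_ppm: float = 5.0,
) -> list[FeatureDefinition]:
    """Consolidate pooled per-scan centroids into a cohort feature list.

    All centroid m/z values are pooled across scans and measurements, a
    Gaussian kernel density (bandwidth in ppm, evaluated in log-m/z where
    ppm width is constant) is estimated over the pool, and density maxima
    become candidate feature centroids. A candidate is kept iff at least
    one centroid falls within ``tol_ppm`` of it in at least ``min_presence``
    of the measurements.
    """
    if kde_bandwidth_ppm <= 0:
        raise ValueError("kde_bandwidth_ppm must be > 0")
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must lie in (0, 1]")
    if not measurements:
        return []

    pooled = []
    for m in measurements:
        for mz, _inten in m.scans:
            if len(mz):
                pooled.append(np.asarray(mz, float))
    if not pooled:
        return []
    pooled = np.concatenate(pooled)

    bw = kde_bandwidth_ppm * 1e-6
    u = np.log(pooled)
    lo, hi = u.min() - 5 * bw, u.max() + 5 * bw
    step = bw / 4.0
    edges = np.arange(lo, hi + step, step)
    hist, _ = np.histogram(u, bins=edges)
    dens = gaussian_filter1d(hist.astype(float), sigma=bw / step, mode="constant")
    centers = 0.5 * (edges[:-1] + edges[1:])

    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]) & (dens[1:-1] > 0)
    cand_u = centers[1:-1][interior]

    feats: list[FeatureDefinition] = []
    polarity = measurements[0].polarity
    n_meas = len(measurements)
    # per-measurement sorted centroid pools for fast window queries
    per_meas = []
    for m in measurements:
        all_mz = np.concatenate([s[0] for s in m.scans if len(s[0])]) if m.scans else np.array([])
        per_meas.append(np.sort(all_mz))

    kept = 0
    for cu in cand_u:
        mz_c = float(np.exp(cu))
        # refine the centroid as the mean of pooled peaks within the kernel width
        half = mz_c * 3 * bw
        sel = pooled[(pooled >= mz_c - half) & (pooled <= mz_c + half)]
        if len(sel):
            mz_c = float(sel.mean())
        half_tol = mz_c * tol_ppm * 1e-6
        n_present = sum(
            1 for arr in per_meas
            if np.searchsorted(arr, mz_c + half_tol) > np.searchsorted(arr, mz_c - half_tol)
        )
        if n_present / n_meas >= min_presence:
            kept += 1
            feats.append(FeatureDefinition(f"F{kept:05d}_{mz_c:.4f}", mz_c, polarity, tol_ppm))
    return feats


def extract_traces(measurement: RawMeasurement,
                   features: list[FeatureDefinition]) -> np.ndarray:
    """Per-scan summed centroid intensity within each feature's m/z window.

    Returns an (n_features, n_scans) array. Scans must hold m/z-sorted
    centroids (enforced by the readers and the simulator).
    """
    los = np.array([f.window[0] for f in features])
    his = np.array([f.window[1] for f in features])
    out = np.zeros((len(features), len(measurement.scans)))
    for i, (mz, inten) in enumerate(measurement.scans):
        if len(mz) == 0:
            continue
        a = np.searchsorted(mz, los)
        b = np.searchsorted(mz, his, side="right")
        counts = b - a
        one = counts == 1
        out[one, i] = inten[a[one]]
        for f in np.flatnonzero(counts > 1):  # rare: overlapping centroids
            out[f, i] = float(np.sum(inten[a[f]:b[f]]))
    return out


def extract_trace(measurement: RawMeasurement, feature: FeatureDefinition) -> np.ndarray:
    """Per-scan summed centroid intensity within the feature m/z window."""
    return extract_traces(measurement, [feature])[0]


def feature_present(trace: np.ndarray, indicator: np.ndarray, min_frac: float = 0.25) -> bool:
    """A feature is 'present' in a measurement if it is detected in at least
    ``min_frac`` of the in-window scans."""
    inw = indicator > 0
    if inw.sum() == 0:
        return False
    return (trace[inw] > 0).mean() >= min_frac


# ---------------------------------------------------------------------------
# breath-correlation filter

def _spearman_vs_indicator(traces: np.ndarray, indicator: np.ndarray,
                           n_perm: int = 10_000, seed: int = 0):
    """Spearman rho and p of each trace (row) against the 0/1 exhalation
    indicator. t-approximation for n >= 30 scans, seeded Monte-Carlo
    permutation null otherwise. Constant traces get rho = nan, p = 1."""
    n = traces.shape[1]
    r_t = stats.rankdata(traces, axis=1)
    r_i = stats.rankdata(indicator)
    sd_t = r_t.std(axis=1)
    sd_i = r_i.std()
    const = sd_t <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = ((r_t - r_t.mean(axis=1, keepdims=True)) @ (r_i - r_i.mean())) / (
            n * np.where(const, np.nan, sd_t) * sd_i
        )
    if n >= 30:
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty((n_perm, traces.shape[0]))
        zc = (r_t - r_t.mean(axis=1, keepdims=True)) / np.where(const, np.nan, sd_t)[:, None]
        zi = (r_i - r_i.mean()) / sd_i
        for b in range(n_perm):
            null[b] = zc @ zi[rng.permutation(n)] / n
        p = (1 + np.sum(np.abs(null) >= np.abs(rho)[None, :], axis=0)) / (1 + n_perm)
    p = np.where(const | ~np.isfinite(rho), 1.0, np.clip(p, 0, 1))
    rho = np.where(const, np.nan, rho)
    return rho, p


def breath_correlation_filter(
    traces_by_measurement: list[np.ndarray],
    indicators: list[np.ndarray],
    presence: np.ndarray | None = None,
    rho_min: float = 0.6,
    fdr_max: float = 0.01,
    quorum: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Keep features whose traces track the exhalation profile.

    For each measurement, Spearman rho and p are computed between every
    feature trace and the 0/1 exhalation indicator; p-values are
    Benjamini-Hochberg adjusted across features within the measurement.
    A feature passes a measurement iff rho >= rho_min and q <= fdr_max.
    It is kept iff it passes in at least ``quorum`` (default: all) of the
    measurements where it is present.

    Parameters
    ----------
    traces_by_measurement
        One (n_features, n_scans) array per measurement (same feature order).
    presence
        Optional (n_measurements, n_features) boolean mask; absent
        (feature, measurement) pairs do not count against the feature.

    Returns a boolean keep mask over features.
    """
    if len(traces_by_measurement) != len(indicators):
        raise ValueError("one indicator per measurement required")
    n_feat = traces_by_measurement[0].shape[0]
    passes = np.zeros((len(indicators), n_feat), dtype=bool)
    for i, (tr, ind) in enumerate(zip(traces_by_measurement, indicators)):
        rho, p = _spearman_vs_indicator(np.asarray(tr, float), np.asarray(ind, float),
                                        seed=seed + i)
        q = multipletests(p, method="fdr_bh")[1]
        passes[i] = (np.nan_to_num(rho, nan=-2.0) >= rho_min) & (q <= fdr_max)
    if presence is None:
        presence = np.ones_like(passes, dtype=bool)
    presence = np.asarray(presence, bool)
    n_present = presence.sum(axis=0)
    n_pass = (passes & presence).sum(axis=0)
    keep = np.zeros(n_feat, dtype=bool)
    seen = n_present > 0
    keep[seen] = n_pass[seen] >= np.ceil(quorum * n_present[seen] - 1e-9)
    return keep


# ---------------------------------------------------------------------------
# nAUC

def compute_nauc(trace: np.ndarray, scan_times: np.ndarray,
                 windows: list[ExhalationWindow]) -> float:
    """Mean exhalation-normalised area under the curve.

    Per window, the trapezoidal integral of the trace over [start, end]
    (with interpolated boundary values) divided by the window duration;
    the returned value is the arithmetic mean over windows.
    """
    if not windows:
        raise ValueError("at least one exhalation window required")
    trace = np.asarray(trace, float)
    scan_times = np.asarray(scan_times, float)
    vals = []
    for w in windows:
        inside = (scan_times > w.start_s) & (scan_times < w.end_s)
        t = np.concatenate([[w.start_s], scan_times[inside], [w.end_s]])
        y = np.concatenate([
            [np.interp(w.start_s, scan_times, trace)],
            trace[inside],
            [np.interp(w.end_s, scan_times, trace)],
        ])
        vals.append(np.trapezoid(y, t) / w.duration_s)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# table assembly

def assemble_feature_table(
    measurements: list[RawMeasurement],
    features: list[FeatureDefinition],
    threshold_frac: float = 0.3,
    min_duration_s: float = 5.0,
    min_gap_s: float = 3.0,
    presence_min_frac: float = 0.25,
    min_windows: int = 2,
) -> tuple[FeatureTable, list[tuple[str, str]]]:
    """Build the measurements x features mean-nAUC matrix.

    Measurements with fewer than ``min_windows`` detected exhalations are
    excluded and returned in the failure list as (measurement_id, reason).
    Rows and columns are sorted by id. Negative nAUC cannot occur
    (intensities are non-negative).
    """
    if not features:
        raise ValueError("empty feature list")
    ids = [m.measurement_id for m in measurements]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate measurement ids")
    features = sorted(features, key=lambda f: f.feature_id)
    measurements = sorted(measurements, key=lambda m: m.measurement_id)

    rows, obs_rows, pres_rows, failed = [], [], [], []
    kept_ids = []
    for m in measurements:
        windows = detect_exhalations(m.tic, m.scan_times, threshold_frac,
                                     min_duration_s, min_gap_s)
        if len(windows) < min_windows:
            failed.append((m.measurement_id, f"only {len(windows)} exhalations detected"))
            continue
        ind = exhalation_indicator(m.scan_times, windows)
        traces = extract_traces(m, features)
        naucs = [compute_nauc(tr, m.scan_times, windows) for tr in traces]
        pres = [feature_present(tr, ind, presence_min_frac) for tr in traces]
        rows.append(naucs)
        pres_rows.append(pres)
        kept_ids.append(m.measurement_id)
        c = m.clinical
        obs_rows.append({
            "subject_id": m.subject_id,
            "cohort": m.cohort,
            "polarity": m.polarity,
            "batch": m.batch_label,
            "drugs": ";".join(c.drugs),
            "total_vpa_mgL": c.total_vpa_mgL,
            "free_vpa_mgL": np.nan if c.free_vpa_mgL is None else c.free_vpa_mgL,
            "side_effects_class": c.side_effects_class,
            "response_class": c.response_class,
            "eeg_class": c.eeg_class,
            "side_effects": c.has_side_effects,
            "non_responder": c.is_non_responder,
            "abnormal_eeg": c.has_abnormal_eeg,
            "on_vpa": "VPA" in c.drugs,
        })
    fids = [f.feature_id for f in features]
    idx = pd.Index(kept_ids, name="measurement_id")
    values = pd.DataFrame(rows, index=idx, columns=fids)
    obs = pd.DataFrame(obs_rows, index=idx)
    var = pd.DataFrame(
        {"mz": [f.mz for f in features],
         "polarity": [f.polarity for f in features],
         "tol_ppm": [f.tol_ppm for f in features]},
        index=pd.Index(fids, name="feature_id"),
    )
    presence = pd.DataFrame(pres_rows, index=idx, columns=fids)
    return FeatureTable(values, obs, var, presence), failed
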