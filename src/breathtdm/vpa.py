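"""Serum-valproate prediction from breath features.

Drug-feature presence filtering, dual importance ranking (regression
ReliefF + bagged-tree permutation importance, combined and thresholded),
empirical-Bayes batch adjustment, exponential-kernel Gaussian-process
regression, and agreement evaluation via Lin's concordance correlation
coefficient (CCC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .traces import FeatureTable

__all__ = [
    "THERAPEUTIC_RANGE_TOTAL_MGL",
    "THERAPEUTIC_RANGE_FREE_MGL",
    "ConcordanceResult",
    "ImportanceReport",
    "EgprModel",
    "filter_drug_features",
    "rrelieff_weights",
    "forest_importance",
    "combine_and_select",
    "combat_adjust",
    "fit_egpr",
    "predict_egpr",
    "lin_ccc",
    "screen_regressors",
    "pathway_activity_ratio",
]

# Reference therapeutic ranges for valproic acid (mg/L serum).
THERAPEUTIC_RANGE_TOTAL_MGL = (50.0, 100.0)
THERAPEUTIC_RANGE_FREE_MGL = (5.0, 10.0)


# ---------------------------------------------------------------------------
# drug-feature presence filter

def filter_drug_features(table: FeatureTable, on_vpa: np.ndarray | None = None,
                         min_presence: float = 0.80) -> FeatureTable:
    """Keep features present in >= ``min_presence`` of the measurements where
    the patient was receiving the drug."""
    if on_vpa is None:
        on_vpa = table.obs["on_vpa"].values.astype(bool)
    on_vpa = np.asarray(on_vpa, bool)
    if not on_vpa.any():
        raise ValueError("no VPA measurements: cannot define drug-related features")
    frac = table.presence.values[on_vpa].mean(axis=0)
    keep = table.values.columns[frac >= min_presence]
    return table.subset_features(keep)


# ---------------------------------------------------------------------------
# importance ranking

def rrelieff_weights(X: np.ndarray, y: np.ndarray, k_neighbors: int = 10,
                     n_sampled: int | None = None, seed: int = 0,
                     rank_sigma: float = 50.0) -> np.ndarray:
    """Regression ReliefF feature weights.

    For each sampled instance, the k nearest neighbours (Manhattan distance
    on range-normalised features) update three accumulators: the probability
    of a different target, of a different feature value, and of both. The
    weight of feature f is
    ``P(diff f | diff y) - P(diff f | same y)`` estimated as
    ``N_dYdF/N_dY - (N_dF - N_dYdF)/(m - N_dY)``. Neighbour influence decays
    exponentially with rank (sigma = ``rank_sigma``). Deterministic given
    the seed.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of instances")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    rng = np.random.default_rng(seed)
    m = n if n_sampled is None else min(n_sampled, n)
    order = rng.permutation(n)[:m]

    rngX = X.max(axis=0) - X.min(axis=0)
    rngX[rngX == 0] = 1.0
    Xn = (X - X.min(axis=0)) / rngX
    ry = y.max() - y.min()
    if ry == 0:
        return np.zeros(d)
    yn = (y - y.min()) / ry

    w_rank = np.exp(-((np.arange(1, k_neighbors + 1) / rank_sigma) ** 2))
    w_rank /= w_rank.sum()

    N_dY = 0.0
    N_dF = np.zeros(d)
    N_dYdF = np.zeros(d)
    for i in order:
        dist = np.abs(Xn - Xn[i]).sum(axis=1)
        dist[i] = np.inf
        nbrs = np.argpartition(dist, k_neighbors)[:k_neighbors]
        nbrs = nbrs[np.argsort(dist[nbrs], kind="stable")]
        d_y = np.abs(yn[nbrs] - yn[i])
        d_f = np.abs(Xn[nbrs] - Xn[i])  # (k, d)
        N_dY += float(d_y @ w_rank)
        N_dF += d_f.T @ w_rank
        N_dYdF += (d_f * d_y[:, None]).T @ w_rank
    if N_dY <= 0 or m - N_dY <= 0:
        return np.zeros(d)
    return N_dYdF / N_dY - (N_dF - N_dYdF) / (m - N_dY)


def forest_importance(X: np.ndarray, y: np.ndarray, n_trees: int = 100,
                      seed: int = 0, n_repeats: int = 5) -> np.ndarray:
    """Bagged-regression-tree permutation importance (seeded)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                   bootstrap=True, n_jobs=1)
    forest.fit(X, y)
    res = permutation_importance(forest, X, y, n_repeats=n_repeats,
                                 random_state=seed, n_jobs=1)
    return res.importances_mean


@dataclass
class ImportanceReport:
    """Per-feature normalised weights from both rankers and selection flags."""

    table: pd.DataFrame  # relief_weight, forest_weight, combined_weight, selected
    cutoff: float
    strategy: str

    @property
    def selected_features(self) -> list:
        return list(self.table.index[self.table["selected"]])


def _minmax(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, float)
    span = w.max() - w.min()
    if span == 0:
        return np.full_like(w, 0.5)  # uninformative ranker contributes 0.5 uniformly
    return (w - w.min()) / span


def combine_and_select(relief_w: np.ndarray, forest_w: np.ndarray,
                       cutoff: float = 0.1, strategy: str = "mean",
                       feature_ids=None) -> ImportanceReport:
    """Combine the two importance rankings into one normalised weight.

    Each weight vector is min-max scaled to [0, 1]; the combination
    (``mean`` | ``max`` | ``rank-mean``) is renormalised so its maximum is
    1; a feature is selected iff its combined weight is strictly above the
    cutoff.
    """
    relief_w = np.asarray(relief_w, float)
    forest_w = np.asarray(forest_w, float)
    if relief_w.shape != forest_w.shape:
        raise ValueError("weight vectors must have equal length")
    if not (np.isfinite(relief_w).all() and np.isfinite(forest_w).all()):
        raise ValueError("weights must be finite")
    r, f = _minmax(relief_w), _minmax(forest_w)
    if strategy == "mean":
        comb = (r + f) / 2
    elif strategy == "max":
        comb = np.maximum(r, f)
    elif strategy == "rank-mean":
        from scipy.stats import rankdata
        comb = (rankdata(relief_w) + rankdata(forest_w)) / 2
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if comb.max() > 0:
        comb = comb / comb.max()
    sel = comb > cutoff
    if feature_ids is None:
        feature_ids = pd.RangeIndex(len(comb))
    tab = pd.DataFrame(
        {"relief_weight": r, "forest_weight": f, "combined_weight": comb, "selected": sel},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return ImportanceReport(tab, cutoff, strategy)


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment (location/scale model)

def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (2 * s2 + m**2) / s2

def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(sdat: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4, max_iter: int = 500):
    """Iterative EB posterior solution for per-batch location/scale."""
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        resid2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * resid2 + b) / (n / 2 + a - 1)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() > 0 else 0,
                     np.abs(d_new - d_old).max() / d_old.max())
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(X: pd.DataFrame | np.ndarray, batches, parametric: bool = True):
    """Remove known batch effects with the empirical-Bayes location/scale
    model (the ComBat procedure, no covariates).

    Features are standardised against the grand (batch-size-weighted) mean
    and pooled variance; per-batch location (gamma) and scale (delta^2)
    estimates are shrunk towards parametric normal / inverse-gamma priors
    and removed; the data are back-transformed so the per-feature grand
    mean and pooled variance are preserved. With ``parametric=False`` the
    raw per-batch estimates are used without shrinkage, giving an exact
    moment-matching adjustment that is idempotent to machine precision;
    the EB path, like the reference implementation, intentionally
    under-corrects by the shrinkage amount and is only asymptotically
    idempotent. A single batch returns the input unchanged.

    ``X`` is samples x features; ``batches`` a length-n label vector.
    """
    is_df = isinstance(X, pd.DataFrame)
    Xv = np.asarray(X, float).T  # features x samples, as in the original model
    batches = np.asarray(batches)
    labels, inv = np.unique(batches, return_inverse=True)
    counts = np.bincount(inv)
    for lbl, c in zip(labels, counts):
        if c < 2:
            raise ValueError(f"batch {lbl!r} has fewer than 2 measurements")
    if len(labels) == 1:
        return X.copy() if is_df else Xv.T.copy()

    G, N = Xv.shape
    batch_idx = [np.flatnonzero(inv == b) for b in range(len(labels))]
    B_hat = np.stack([Xv[:, ix].mean(axis=1) for ix in batch_idx], axis=1)  # G x nb
    grand = B_hat @ (counts / N)
    resid = Xv - B_hat[:, inv]
    var_pooled = (resid**2).mean(axis=1)
    var_pooled[var_pooled == 0] = 1e-12

    s_data = (Xv - grand[:, None]) / np.sqrt(var_pooled)[:, None]

    adj = s_data.copy()
    for b, ix in enumerate(batch_idx):
        sdat = s_data[:, ix]
        g_hat = sdat.mean(axis=1)
        # EB path follows the reference convention (n-1 denominator); the
        # exact moment-matching path uses population variance, which makes
        # the adjustment exactly idempotent
        d_hat = sdat.var(axis=1, ddof=1 if parametric else 0)
        d_hat[d_hat == 0] = 1e-12
        if parametric and G >= 2:
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            a, b_pr = _aprior(d_hat), _bprior(d_hat)
            if t2 > 0 and np.isfinite(a) and np.isfinite(b_pr) and a > 1:
                g_star, d_star = _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b_pr)
            else:
                g_star, d_star = g_hat, d_hat
        else:
            g_star, d_star = g_hat, d_hat
        adj[:, ix] = (sdat - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adj * np.sqrt(var_pooled)[:, None] + grand[:, None]
    out = out.T  # back to samples x features
    if is_df:
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


# ---------------------------------------------------------------------------
# exponential-kernel Gaussian-process regression

@dataclass
class EgprModel:
    """Fitted exponential-kernel GP: k(x, x') = sigma_f^2 exp(-||x-x'||/ell)."""

    gp: GaussianProcessRegressor
    x_mean: np.ndarray
    x_std: np.ndarray
    sigma_f2: float
    length_scale: float
    sigma_n2: float

    def __post_init__(self):
        if not (self.sigma_f2 > 0 and self.length_scale > 0 and self.sigma_n2 > 0):
            raise ValueError("kernel hyperparameters must be positive")


def fit_egpr(X: np.ndarray, y: np.ndarray, n_restarts: int = 8,
             seed: int = 0, noise_floor: float = 1e-10) -> EgprModel:
    """Fit an exponential-kernel (Matern nu=1/2) GP by marginal-likelihood
    maximisation with multi-start. Inputs are standardised by training
    statistics; predictions are posterior means clipped at 0 mg/L."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    kernel = (ConstantKernel(1.0, (1e-4, 1e4))
              * Matern(length_scale=1.0, length_scale_bounds=(1e-3, 1e4), nu=0.5)
              + WhiteKernel(noise_level=1e-2, noise_level_bounds=(noise_floor, 1e3)))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                  n_restarts_optimizer=n_restarts,
                                  random_state=seed, alpha=1e-10)
    gp.fit(Z, y)
    k = gp.kernel_
    sigma_f2 = float(k.k1.k1.constant_value)
    ell = float(k.k1.k2.length_scale)
    sigma_n2 = float(max(k.k2.noise_level, noise_floor))
    return EgprModel(gp, mu, sd, sigma_f2, ell, sigma_n2)


def predict_egpr(model: EgprModel, X: np.ndarray) -> np.ndarray:
    Z = (np.asarray(X, float) - model.x_mean) / model.x_std
    pred = model.gp.predict(Z)
    return np.clip(pred, 0.0, None)  # concentrations cannot be negative


def exponential_kernel(x: np.ndarray, x2: np.ndarray, sigma_f2: float,
                       length_scale: float) -> np.ndarray:
    """k(x, x') = sigma_f^2 exp(-||x - x'||_2 / ell)."""
    x = np.atleast_2d(x)
    x2 = np.atleast_2d(x2)
    d = np.sqrt(((x[:, None, :] - x2[None, :, :]) ** 2).sum(-1))
    return sigma_f2 * np.exp(-d / length_scale)


# ---------------------------------------------------------------------------
# Lin's concordance correlation coefficient

@dataclass(frozen=True)
class ConcordanceResult:
    ccc: float
    pearson_r: float
    location_shift: float  # mean(x) - mean(y)
    scale_ratio: float     # sd(x) / sd(y)


def lin_ccc(actual: np.ndarray, predicted: np.ndarray) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with population (1/n)
    moments:

        ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

    Conventions for degenerate input: both vectors constant and equal ->
    ccc 1; exactly one constant -> ccc 0.
    """
    x = np.asarray(actual, float)
    y = np.asarray(predicted, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-D vectors of length >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    sx2, sy2 = x.var(), y.var()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        return ConcordanceResult(1.0, 1.0, 0.0, 1.0)
    if sx2 == 0 or sy2 == 0:
        return ConcordanceResult(0.0, 0.0, mx - my,
                                 np.sqrt(sx2 / sy2) if sy2 > 0 else np.inf)
    r = sxy / np.sqrt(sx2 * sy2)
    return ConcordanceResult(float(2 * sxy / denom), float(r), float(mx - my),
                             float(np.sqrt(sx2 / sy2)))


# ---------------------------------------------------------------------------
# regressor screening

def _default_families(seed: int):
    return {
        "egpr": lambda: _EgprEstimator(seed=seed),
        "ridge": lambda: Ridge(alpha=1.0),
        "bagged_trees": lambda: RandomForestRegressor(n_estimators=100,
                                                      random_state=seed, n_jobs=1),
    }


class _EgprEstimator:
    """Thin sklearn-style adapter around fit_egpr/predict_egpr."""

    def __init__(self, seed: int = 0, n_restarts: int = 4):
        self.seed = seed
        self.n_restarts = n_restarts
        self.model: EgprModel | None = None

    def fit(self, X, y):
        self.model = fit_egpr(X, y, n_restarts=self.n_restarts, seed=self.seed)
        return self

    def predict(self, X):
        return predict_egpr(self.model, X)


def screen_regressors(X: np.ndarray, y: np.ndarray, folds: int = 5,
                      seeds=(0, 1, 2), families: dict | None = None) -> pd.DataFrame:
    """Rank regression-model families by cross-validated CCC and RMSE.

    Returns a DataFrame (one row per family, sorted by mean CCC descending)
    with mean and SD of out-of-fold CCC and RMSE over the seeded CV repeats.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if folds > len(y):
        raise ValueError("folds cannot exceed the number of samples")
    if families is None:
        families = _default_families(seed=int(seeds[0]))
    if len(families) < 1:
        raise ValueError("register at least one model family")
    rows = []
    for name, factory in families.items():
        cccs, rmses = [], []
        for s in seeds:
            kf = KFold(n_splits=folds, shuffle=True, random_state=int(s))
            pred = np.empty_like(y)
            for tr, te in kf.split(X):
                est = factory()
                est.fit(X[tr], y[tr])
                pred[te] = est.predict(X[te])
            cccs.append(lin_ccc(y, pred).ccc)
            rmses.append(float(np.sqrt(np.mean((y - pred) ** 2))))
        rows.append({"family": name, "ccc_mean": np.mean(cccs), "ccc_sd": np.std(cccs),
                     "rmse_mean": np.mean(rmses), "rmse_sd": np.std(rmses)})
    return (pd.DataFrame(rows).sort_values("ccc_mean", ascending=False)
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# metabolic-pathway activity ratio

def pathway_activity_ratio(table: FeatureTable, numerator_feature: str,
                           denominator_feature: str):
    """Per-measurement ratio of two feature nAUCs (e.g. 3-heptanone over
    4-OH-gamma-lactone, proxying beta- vs omega-1-oxidation activity),
    with a per-subject median/IQR summary across visits. Ratios with a
    zero denominator are missing and excluded from summaries."""
    for f in (numerator_feature, denominator_feature):
        if f not in table.values.columns:
            raise KeyError(f"feature {f!r} not in table")
    num = table.values[numerator_feature]
    den = table.values[denominator_feature]
    ratio = num / den.replace(0.0, np.nan)
    per_subject = (
        pd.DataFrame({"subject_id": table.obs["subject_id"], "ratio": ratio})
        .dropna()
        .groupby("subject_id")["ratio"]
        .agg(median="median",
             iqr=lambda v: float(np.subtract(*np.percentile(v, [75, 25]))),
             n_visits="count")
    )
    return ratio, per_subject
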