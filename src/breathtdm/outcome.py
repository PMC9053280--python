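"""Outcome branch: drug-modulated endogenous metabolites.

Variable-feature filtering, Welch t-tests with Benjamini-Hochberg FDR,
dual pathway enrichment (accurate-mass permutation enrichment in the
mummichog paradigm plus a weighted-KS set enrichment on the ranked t
statistics), and a first-principal-component score with a Youden-index
cutoff for classifying side-effect and drug-response status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pathways import PathwayDB, annotate_mz
from .traces import FeatureTable

__all__ = [
    "filter_endogenous",
    "differential_abundance",
    "mummichog_like_enrichment",
    "gsea_enrichment",
    "select_enriched",
    "OutcomeScoreModel",
    "fit_outcome_score",
    "score_and_classify",
    "youden_cutoff",
]


# ---------------------------------------------------------------------------
# filters and differential testing

def filter_endogenous(table: FeatureTable, min_presence: float = 0.50,
                      min_cv: float = 0.30) -> FeatureTable:
    """Keep features present in >= ``min_presence`` of all measurements and
    with a coefficient of variation (sample SD / mean of the nonzero nAUC
    values) strictly above ``min_cv``."""
    if table.n_measurements == 0:
        raise ValueError("empty table")
    pres_frac = table.presence.values.mean(axis=0)
    keep = []
    for j, fid in enumerate(table.values.columns):
        if pres_frac[j] < min_presence:
            continue
        v = table.values[fid].values
        v = v[v > 0]
        if len(v) < 2 or v.mean() == 0:
            continue
        cv = v.std(ddof=1) / v.mean()
        if cv > min_cv:
            keep.append(fid)
    return table.subset_features(keep)


def differential_abundance(X: pd.DataFrame, labels: np.ndarray,
                           eps: float | None = None) -> pd.DataFrame:
    """Per-feature Welch two-sample t-test of positive class (True: classes
    II+III) vs reference (False: class I), with Benjamini-Hochberg q-values
    and log2 fold changes of group means (pseudo-count ``eps``, default 1%
    of the median positive matrix value)."""
    labels = np.asarray(labels, bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each group needs at least 2 measurements")
    A = X.values[labels]      # positive group (II+III)
    B = X.values[~labels]     # reference group (I)
    if eps is None:
        pos = X.values[X.values > 0]
        eps = 0.01 * float(np.median(pos)) if len(pos) else 1e-9
    t, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    mean_pos = A.mean(axis=0)
    mean_ref = B.mean(axis=0)
    log2fc = np.log2((mean_pos + eps) / (mean_ref + eps))
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "q": q,
         "mean_positive": mean_pos, "mean_reference": mean_ref},
        index=X.columns.rename("feature_id"),
    )


# ---------------------------------------------------------------------------
# accurate-mass (m/z-level) permutation enrichment

def _pathway_hits(compound_sets: dict[str, set], sig_compounds: set):
    return {pid: len(cset & sig_compounds) for pid, cset in compound_sets.items()}


def mummichog_like_enrichment(
    sig_features: list,
    background_features: list,
    features_meta: pd.DataFrame,
    db: PathwayDB,
    adducts=None,
    ppm_tol: float = 2.0,
    n_perm: int = 200,
    seed: int = 0,
    randomize_ties: bool = False,
) -> pd.DataFrame:
    """Pathway enrichment directly on m/z lists (mummichog paradigm).

    Both the significant and background feature lists are putatively
    annotated to compounds via adduct arithmetic at ``ppm_tol``. Per
    pathway, the enrichment statistic is the upper hypergeometric tail of
    drawing the observed number of significant pathway compounds from the
    annotated background; the permutation null redraws ``|sig|`` features
    from the background ``n_perm`` times and the p-value is
    ``(1 + #{null >= observed}) / (1 + n_perm)`` on the -log10 tail.
    ``log2_enrichment`` is the log2 ratio of the pathway hit rate in the
    significant list to its rate in the background. Pathways with no
    background hits are excluded.

    The enrichment statistic is discrete, so the conservative +1 p-value is
    super-uniform under the null; ``randomize_ties=True`` switches to the
    randomised Monte-Carlo p-value
    ``(#{null > obs} + U*(1 + #{null == obs})) / (1 + n_perm)``,
    which is exactly uniform under the null and is what the calibration
    diagnostics use.
    """
    sig_features = list(sig_features)
    background_features = list(background_features)
    if not set(sig_features) <= set(background_features):
        raise ValueError("sig_features must be a subset of background_features")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)

    ann = annotate_mz(features_meta.loc[background_features], db, adducts, ppm_tol)
    feat2comp: dict = {}
    for fid, grp in ann.groupby("feature_id"):
        feat2comp[fid] = set(grp["compound_id"])

    def compounds_of(feats):
        out = set()
        for f in feats:
            out |= feat2comp.get(f, set())
        return out

    bg_comp = compounds_of(background_features)
    compound_sets = {pid: set(p.compound_ids) & bg_comp
                     for pid, p in db.pathways.items()}
    compound_sets = {pid: s for pid, s in compound_sets.items() if len(s) > 0}

    n_bg = len(bg_comp)

    def stat_vector(feats):
        sig_comp = compounds_of(feats)
        n_sig = len(sig_comp)
        out = {}
        for pid, cset in compound_sets.items():
            k = len(cset & sig_comp)
            K = len(cset)
            # upper tail P(X >= k) for X ~ Hypergeom(n_bg, K, n_sig)
            tail = stats.hypergeom.sf(k - 1, n_bg, K, n_sig) if n_sig else 1.0
            out[pid] = (k, K, n_sig, -np.log10(max(tail, 1e-300)))
        return out

    obs = stat_vector(sig_features)
    null_gt = {pid: 0 for pid in compound_sets}
    null_eq = {pid: 0 for pid in compound_sets}
    n_sig_feat = len(sig_features)
    bg_arr = np.array(background_features, dtype=object)
    for _ in range(n_perm):
        draw = bg_arr[rng.choice(len(bg_arr), size=n_sig_feat, replace=False)]
        null = stat_vector(list(draw))
        for pid in compound_sets:
            if null[pid][3] > obs[pid][3] + 1e-12:
                null_gt[pid] += 1
            elif abs(null[pid][3] - obs[pid][3]) <= 1e-12:
                null_eq[pid] += 1

    rows = []
    sig_comp = compounds_of(sig_features)
    n_sig_ann = max(len(sig_comp), 1)
    for pid in compound_sets:
        k, K, _, s = obs[pid]
        if randomize_ties:
            p = (null_gt[pid] + rng.random() * (1 + null_eq[pid])) / (1 + n_perm)
        else:
            p = (1 + null_gt[pid] + null_eq[pid]) / (1 + n_perm)
        rate_sig = k / n_sig_ann
        rate_bg = K / max(n_bg, 1)
        log2_enr = np.log2(rate_sig / rate_bg) if k > 0 and rate_bg > 0 else -np.inf
        rows.append({"pathway_id": pid, "name": db.pathways[pid].name,
                     "hits": k, "size_in_background": K, "p": p,
                     "log2_enrichment": log2_enr, "stat": s})
    return pd.DataFrame(rows).set_index("pathway_id")


# ---------------------------------------------------------------------------
# weighted-KS set enrichment on a ranked feature list

def _running_es(in_set: np.ndarray, scores: np.ndarray, weight: float) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    w = np.abs(scores) ** weight
    w_hit = np.where(in_set, w, 0.0)
    denom_hit = w_hit.sum()
    n_miss = (~in_set).sum()
    if denom_hit == 0 or n_miss == 0:
        return 0.0
    run = np.cumsum(w_hit / denom_hit - (~in_set) / n_miss)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def gsea_enrichment(
    ranked: pd.DataFrame,
    annotation: pd.DataFrame,
    db: PathwayDB,
    n_perm: int = 200,
    seed: int = 0,
    weight: float = 1.0,
    min_set_size: int = 2,
) -> pd.DataFrame:
    """Set-enrichment analysis on a ranked feature list.

    ``ranked`` is indexed by feature id with a signed ``score`` column
    (e.g. the t statistic); it is sorted descending internally.
    ``annotation`` maps feature_id -> compound_id (as produced by
    :func:`breathtdm.pathways.annotate_mz`). The enrichment score is the
    signed maximum of the weighted Kolmogorov-Smirnov running sum
    (hit increments proportional to |score|^weight); the null permutes the
    set-membership labels over the ranking ``n_perm`` times, and the
    two-sided p-value compares |ES| against the permuted |ES| with the +1
    correction. Pathways with fewer than ``min_set_size`` annotated
    features in the ranking are excluded. ``nes`` is ES divided by the mean
    null |ES|.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    rng = np.random.default_rng(seed)
    ranked = ranked.sort_values("score", ascending=False)
    fids = np.array(ranked.index, dtype=object)
    scores = ranked["score"].values.astype(float)
    n = len(fids)

    feat2comp: dict = {}
    for fid, grp in annotation.groupby("feature_id"):
        feat2comp[fid] = set(grp["compound_id"])

    rows = []
    for pid, pw in db.pathways.items():
        members = set(pw.compound_ids)
        in_set = np.array([bool(feat2comp.get(f, set()) & members) for f in fids])
        n_hit = int(in_set.sum())
        if n_hit < min_set_size:
            continue
        es = _running_es(in_set, scores, weight)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(n, bool)
            perm[rng.choice(n, size=n_hit, replace=False)] = True
            null[b] = _running_es(perm, scores, weight)
        p = (1 + np.sum(np.abs(null) >= abs(es))) / (1 + n_perm)
        mean_abs = np.abs(null).mean()
        nes = es / mean_abs if mean_abs > 0 else 0.0
        rows.append({"pathway_id": pid, "name": pw.name, "es": es, "nes": nes,
                     "p": p, "set_size": n_hit})
    return pd.DataFrame(rows).set_index("pathway_id") if rows else pd.DataFrame(
        columns=["name", "es", "nes", "p", "set_size"],
        index=pd.Index([], name="pathway_id"))


def select_enriched(mummichog_p: pd.Series, gsea_p: pd.Series,
                    alpha: float = 0.05) -> list:
    """Pathways significant in both algorithms (strictly p < alpha in each)."""
    common = mummichog_p.index.intersection(gsea_p.index)
    sel = [pid for pid in common
           if mummichog_p[pid] < alpha and gsea_p[pid] < alpha]
    return sel


def enrichment_table(mummichog: pd.DataFrame, gsea: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Join the two enrichment results into one per-pathway table."""
    tab = mummichog[["name", "hits", "size_in_background", "p", "log2_enrichment"]].rename(
        columns={"p": "mummichog_p"})
    tab = tab.join(gsea[["p", "es", "nes"]].rename(columns={"p": "gsea_p"}), how="inner")
    tab["selected"] = (tab["mummichog_p"] < alpha) & (tab["gsea_p"] < alpha)
    return tab


# ---------------------------------------------------------------------------
# PC1 score + Youden cutoff classifier

def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive sorted unique scores
    (positive class called when score > cutoff). Returns (cutoff, J);
    ties broken by the lowest cutoff.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        return float(uniq[0]) if len(uniq) else 0.0, 0.0
    cands = (uniq[:-1] + uniq[1:]) / 2
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_c, best_j = cands[0], -np.inf
    for c in cands:
        pred = scores > c
        sens = (pred & labels).sum() / n_pos if n_pos else 0.0
        spec = (~pred & ~labels).sum() / n_neg if n_neg else 0.0
        j = sens + spec - 1
        if j > best_j:
            best_c, best_j = c, j
    return float(best_c), float(best_j)


@dataclass
class OutcomeScoreModel:
    """First-principal-component score with a Youden threshold.

    Member features (significant + pathway-annotated), their unit-norm PC1
    loading vector, training standardisation parameters, the Youden cutoff
    on the oriented score, and the orientation (+1 if the positive class
    has the higher mean raw PC1 score, else -1).
    """

    member_ids: list
    loadings: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    cutoff: float
    orientation: int
    youden_j: float = np.nan

    def __post_init__(self):
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        nrm = np.linalg.norm(self.loadings)
        if not np.isclose(nrm, 1.0, atol=1e-8):
            raise ValueError("loading vector must have unit norm")


def fit_outcome_score(X_members: pd.DataFrame, labels: np.ndarray) -> OutcomeScoreModel:
    """Fit the PC1 score + Youden-cutoff classifier on training data.

    Columns are standardised with training mean/SD; PC1 is the leading
    eigenvector of the covariance, with its sign fixed so that the
    largest-|loading| member is positive; the oriented score puts the
    positive class (True labels) on the high side; the cutoff maximises
    Youden's J over score midpoints.
    """
    labels = np.asarray(labels, bool)
    if X_members.shape[1] < 2:
        raise ValueError("need at least 2 member features")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    X = X_members.values.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    cov = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    raw = Z @ v
    orient = 1 if raw[labels].mean() >= raw[~labels].mean() else -1
    s = orient * raw
    cutoff, j = youden_cutoff(s, labels)
    return OutcomeScoreModel(list(X_members.columns), v, mu, sd, cutoff, orient, j)


def score_and_classify(model: OutcomeScoreModel, X_new: pd.DataFrame):
    """Project new measurements on the stored PC1 and threshold them.

    X_new must contain the model's member features; standardisation uses the
    training parameters. Returns (scores, predicted positive-class flags).
    """
    missing = [f for f in model.member_ids if f not in X_new.columns]
    if missing:
        raise KeyError(f"missing member features: {missing}")
    X = X_new[model.member_ids].values.astype(float)
    Z = (X - model.mean) / model.std
    scores = model.orientation * (Z @ model.loadings)
    return scores, scores > model.cutoff
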