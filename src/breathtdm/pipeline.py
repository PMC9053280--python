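"""End-to-end pipeline: simulate/load -> feature table -> drug-concentration
regression -> outcome scoring, with a manifest of every written artifact.

The run directory contains: the feature-table CSV bundle, the selected-
predictor importance report, batch-adjusted matrices, serum-concentration
predictions with concordance metrics, differential-abundance and enrichment
tables, outcome scores/classes, the pathway DB, the synthetic truth and a
manifest (parameters, artifact SHA-256 hashes, failed measurements).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as btio
from .cohort import CohortConfig, simulate_cohort
from .outcome import (
    differential_abundance,
    enrichment_table,
    filter_endogenous,
    fit_outcome_score,
    gsea_enrichment,
    mummichog_like_enrichment,
    score_and_classify,
)
from .pathways import annotate_mz
from .traces import (
    FeatureTable,
    breath_correlation_filter,
    build_feature_list,
    detect_exhalations,
    exhalation_indicator,
    extract_traces,
    feature_present,
    assemble_feature_table,
)
from .vpa import (
    combat_adjust,
    combine_and_select,
    filter_drug_features,
    fit_egpr,
    forest_importance,
    lin_ccc,
    predict_egpr,
    rrelieff_weights,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters of the end-to-end run.

    Defaults are the documented operating points: 10% cohort presence for
    the feature list, exhalation correlation rho >= 0.6 at FDR <= 0.01,
    80% presence among drug measurements for drug-related features,
    importance cutoff 0.1, 50% presence and CV > 30% for endogenous
    features, dual-enrichment alpha 0.05.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    # feature list
    kde_bandwidth_ppm: float = 5.0
    feature_min_presence: float = 0.10
    tol_ppm: float = 5.0
    # exhalation detection
    threshold_frac: float = 0.3
    min_duration_s: float = 5.0
    min_gap_s: float = 3.0
    # breath-correlation filter
    rho_min: float = 0.6
    corr_fdr_max: float = 0.01
    corr_quorum: float = 1.0
    # VPA branch
    drug_min_presence: float = 0.80
    importance_cutoff: float = 0.1
    combat: bool = True
    train_frac: float = 0.8
    # outcome branch
    endo_min_presence: float = 0.50
    endo_min_cv: float = 0.30
    enrich_alpha: float = 0.05
    member_q_max: float = 0.25
    n_perm: int = 200
    annot_ppm: float = 2.0
    align_scans: bool = False  # synthetic cohorts carry no m/z drift

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["n_exhalations"] = list(d["cohort"]["n_exhalations"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        co = dict(d.pop("cohort", {}))
        for key in ("n_exhalations", "plateau_s", "gap_s"):
            if key in co:
                co[key] = tuple(co[key])
        return cls(cohort=CohortConfig(**co), **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _split_by_subject(table: FeatureTable, train_frac: float, seed: int):
    subjects = np.array(sorted(table.obs["subject_id"].unique()))
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n_train = max(1, int(round(train_frac * len(subjects))))
    train_subj = set(subjects[:n_train])
    is_train = table.obs["subject_id"].isin(train_subj).values
    return is_train


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full analysis on a simulated cohort and write a run directory.

    Deterministic given (config, config.seed). Returns the run directory.
    Raises RuntimeError naming the failing stage on unrecoverable errors.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    notes: dict[str, object] = {}

    # ---- stage 1: cohort -------------------------------------------------
    cfg = config.cohort
    measurements, truth, db = simulate_cohort(cfg)
    db.to_json(out / "pathway_db.json")
    truth.to_json(out / "truth.json")
    artifacts["pathway_db"] = "pathway_db.json"
    artifacts["truth"] = "truth.json"

    # ---- stage 2: feature extraction ------------------------------------
    try:
        features = build_feature_list(measurements, config.kde_bandwidth_ppm,
                                      config.feature_min_presence, config.tol_ppm)
        if not features:
            raise RuntimeError("no features found")
        ok_meas, indicators, traces_list, pres_rows = [], [], [], []
        failed = []
        for m in measurements:
            w = detect_exhalations(m.tic, m.scan_times, config.threshold_frac,
                                   config.min_duration_s, config.min_gap_s)
            if len(w) < 2:
                failed.append((m.measurement_id, f"only {len(w)} exhalations detected"))
                continue
            ind = exhalation_indicator(m.scan_times, w)
            tr = extract_traces(m, features)
            ok_meas.append(m)
            indicators.append(ind)
            traces_list.append(tr)
            pres_rows.append([feature_present(t, ind) for t in tr])
        keep = breath_correlation_filter(traces_list, indicators,
                                         presence=np.array(pres_rows),
                                         rho_min=config.rho_min,
                                         fdr_max=config.corr_fdr_max,
                                         quorum=config.corr_quorum,
                                         seed=config.seed)
        features = [f for f, k in zip(features, keep) if k]
        if not features:
            raise RuntimeError("no breath-correlated features survived")
        table, failed2 = assemble_feature_table(
            ok_meas, features, config.threshold_frac, config.min_duration_s,
            config.min_gap_s)
        failed += failed2
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage feature-extraction failed: {e}") from e
    btio.write_feature_table(table, out / "features")
    for suffix in ("values", "obs", "var", "presence"):
        artifacts[f"feature_table_{suffix}"] = f"features.{suffix}.csv"
    notes["failed_measurements"] = failed
    notes["n_features"] = table.n_features

    is_train = _split_by_subject(table, config.train_frac, config.seed + 7)
    train = table.subset_measurements(table.values.index[is_train])
    test = table.subset_measurements(table.values.index[~is_train])

    # ---- stage 3: VPA branch --------------------------------------------
    try:
        if not train.obs["on_vpa"].any():
            raise RuntimeError("no VPA measurements")
        drug = filter_drug_features(train, min_presence=config.drug_min_presence)
        X_all = table.values[drug.values.columns]
        if config.combat and table.obs["batch"].nunique() > 1:
            X_all = combat_adjust(X_all, table.obs["batch"].values)
        Xtr = X_all.loc[train.values.index]
        y_total = train.obs["total_vpa_mgL"].values
        relief = rrelieff_weights(Xtr.values, y_total, seed=config.seed)
        forest = forest_importance(Xtr.values, y_total, seed=config.seed)
        report = combine_and_select(relief, forest, cutoff=config.importance_cutoff,
                                    feature_ids=Xtr.columns)
        selected = report.selected_features
        if not selected:
            raise RuntimeError("no predictors above the importance cutoff")
        report.table.to_csv(out / "importance.csv")
        artifacts["importance"] = "importance.csv"

        test_drug = X_all.loc[test.values.index, selected]
        pred_rows = {}
        metrics = {}
        for target in ("total", "free"):
            y_tr = train.obs[f"{target}_vpa_mgL"].values
            model = fit_egpr(Xtr[selected].values, y_tr, seed=config.seed)
            y_hat = predict_egpr(model, test_drug.values)
            y_te = test.obs[f"{target}_vpa_mgL"].values
            pred_rows[f"actual_{target}"] = y_te
            pred_rows[f"predicted_{target}"] = y_hat
            metrics[f"ccc_{target}_with_zeros"] = lin_ccc(y_te, y_hat).ccc
            on = test.obs["on_vpa"].values
            if on.sum() >= 2:
                metrics[f"ccc_{target}_vpa_only"] = lin_ccc(y_te[on], y_hat[on]).ccc
        preds = pd.DataFrame(pred_rows, index=test.values.index)
        preds.to_csv(out / "vpa_predictions.csv")
        artifacts["vpa_predictions"] = "vpa_predictions.csv"
        notes["vpa_metrics"] = metrics
        notes["n_selected_predictors"] = len(selected)
    except RuntimeError as e:
        raise RuntimeError(f"stage vpa failed: {e}") from e

    # ---- stage 4: outcome branch ----------------------------------------
    try:
        endo = filter_endogenous(table, config.endo_min_presence, config.endo_min_cv)
        endo_train = endo.subset_measurements(endo.values.index[is_train])
        score_frames = []
        for outcome_col in ("side_effects", "non_responder"):
            labels_tr = endo_train.obs[outcome_col].values.astype(bool)
            diff = differential_abundance(endo_train.values, labels_tr)
            diff.to_csv(out / f"differential_{outcome_col}.csv")
            artifacts[f"differential_{outcome_col}"] = f"differential_{outcome_col}.csv"
            sig = list(diff.index[diff["q"] <= config.member_q_max])
            bg = list(diff.index)
            mum = mummichog_like_enrichment(sig, bg, endo.var, db,
                                            ppm_tol=config.annot_ppm,
                                            n_perm=config.n_perm, seed=config.seed)
            ranked = diff[["t"]].rename(columns={"t": "score"})
            ann = annotate_mz(endo.var.loc[bg], db, ppm_tol=config.annot_ppm)
            gsea = gsea_enrichment(ranked, ann, db, n_perm=config.n_perm,
                                   seed=config.seed)
            enr = enrichment_table(mum, gsea, alpha=config.enrich_alpha)
            enr.to_csv(out / f"enrichment_{outcome_col}.csv")
            artifacts[f"enrichment_{outcome_col}"] = f"enrichment_{outcome_col}.csv"
            sel_pw = list(enr.index[enr["selected"]])
            member_comp = {c for pid in sel_pw for c in db.pathways[pid].compound_ids}
            ann_sig = ann[ann["feature_id"].isin(sig)
                          & ann["compound_id"].isin(member_comp)]
            members = sorted(set(ann_sig["feature_id"]))
            if len(members) < 2:
                notes[f"outcome_{outcome_col}"] = (
                    f"skipped: only {len(members)} member features")
                continue
            model = fit_outcome_score(endo_train.values[members], labels_tr)
            scores, pred = score_and_classify(model, endo.values)
            score_frames.append(pd.DataFrame({
                "outcome": outcome_col,
                "score": scores,
                "predicted_positive": pred,
                "actual_positive": endo.obs[outcome_col].values.astype(bool),
                "is_train": is_train,
            }, index=endo.values.index))
            notes[f"outcome_{outcome_col}"] = {
                "n_members": len(members), "cutoff": model.cutoff,
                "youden_j_train": model.youden_j,
            }
        if score_frames:
            pd.concat(score_frames).to_csv(out / "outcome_scores.csv")
            artifacts["outcome_scores"] = "outcome_scores.csv"
    except RuntimeError as e:
        raise RuntimeError(f"stage outcome failed: {e}") from e

    manifest = {
        "parameters": config.to_dict(),
        "artifacts": {k: {"path": v, "sha256": _sha256(out / v)}
                      for k, v in artifacts.items()},
        "notes": notes,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
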