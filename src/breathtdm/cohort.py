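"""Seeded synthetic breath-metabolomics cohorts with recoverable ground truth.

The generator emulates a real-time breath mass-spectrometry study of
epileptic patients under antiseizure medication: each measurement is a
time-resolved series of centroided scans (m/z 100-400) in which the subject
performs 5-6 replicate exhalations. Exhalations appear as plateaued pulses
(raised-cosine edges) in the total ion current and in every breath-borne
ion trace. Three feature classes are programmed:

* drug features - 11 ions from 4 valproate-derived molecules whose
  exhalation amplitude scales with the programmed free serum valproate,
* endogenous features - breath-borne ions, a subset of which is shifted up
  in measurements labelled with side effects and down in non-responders,
* nuisance features - electronic/chemical noise uncorrelated with breathing.

Multiplicative per-(batch, feature) factors emulate acquisition-batch
effects. Everything is deterministic given the config seed, and the
:class:`SyntheticTruth` records every programmed quantity so downstream
stages can be validated against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pathways import PROTON_MASS, VPA_MOLECULES, Compound, Pathway, PathwayDB
from .traces import ClinicalAnnotation, RawMeasurement

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_feature_table_inputs",
    "truth_to_feature_table",
    "make_toy_pathway_db",
]

# Isotope spacing used to spread several features over one molecule.
_C13_SPACING = 1.003355
_NA_MINUS_H = 21.981944


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the emulated study: ~54 subjects with repeat visits,
    roughly half of the measurements under valproate (50/93 in the study),
    5-6 exhalations per measurement, 11 drug-related features from four
    molecules, and observed outcome prevalences of 23/75 (side effects),
    26/75 (non-response) and 27/75 (abnormal EEG).
    """

    n_subjects: int = 46
    visits_per_subject: int = 2
    frac_vpa: float = 50 / 93
    n_exhalations: tuple[int, int] = (5, 6)
    scan_hz: float = 2.0
    n_drug_features: int = 11
    n_endogenous_features: int = 40
    n_nuisance_features: int = 40
    effect_size_side_effects: float = math.log2(1.5)
    effect_size_nonresponse: float = -math.log2(1.5)
    noise_cv: float = 0.25
    n_batches: int = 3
    batch_scale_sd: float = 0.30
    seed: int = 0
    # secondary knobs
    prevalence_side_effects: float = 23 / 75
    prevalence_nonresponse: float = 26 / 75
    prevalence_abnormal_eeg: float = 27 / 75
    vpa_exponent: float = 1.0      # b in amplitude = a * free^b
    drug_baseline: float = 0.0     # isomeric background under drug ions
    mz_jitter_ppm: float = 1.0     # per-scan centroid mass jitter (scaled by noise_cv>0)
    plateau_s: tuple[float, float] = (10.0, 20.0)
    gap_s: tuple[float, float] = (5.0, 10.0)
    edge_s: float = 2.0
    polarity: str = "+"

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "visits_per_subject": self.visits_per_subject,
            "n_drug_features": self.n_drug_features,
            "n_endogenous_features": self.n_endogenous_features,
            "n_nuisance_features": self.n_nuisance_features,
            "n_batches": self.n_batches,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("frac_vpa", "noise_cv", "scan_hz", "batch_scale_sd",
                     "effect_size_side_effects", "effect_size_nonresponse",
                     "vpa_exponent", "drug_baseline"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.frac_vpa <= 1.0:
            raise ValueError("frac_vpa must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.scan_hz <= 0:
            raise ValueError("scan_hz must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cohort.

    measurements : per-measurement programmed clinical state (VPA levels,
        outcome classes, batch).
    features : per-feature flags (kind in {drug, endogenous, nuisance},
        molecule for drug ions, affected outcome + pathway for endogenous
        ions) and base amplitudes.
    amplitudes : measurements x features matrix of realised mean exhalation
        amplitudes (what a perfect nAUC extraction recovers, up to the
        pulse-edge window factor); for nuisance features the mean noise level.
    batch_factors : batches x features multiplicative factors.
    pulse_windows : measurement_id -> list of (plateau_start_s, plateau_end_s).
    """

    measurements: pd.DataFrame
    features: pd.DataFrame
    amplitudes: pd.DataFrame
    batch_factors: pd.DataFrame
    pulse_windows: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json

        obj = {
            "measurements": self.measurements.to_dict(orient="index"),
            "features": self.features.to_dict(orient="index"),
            "amplitudes": {
                "index": list(self.amplitudes.index),
                "columns": list(self.amplitudes.columns),
                "values": self.amplitudes.values.tolist(),
            },
            "batch_factors": {
                "index": list(self.batch_factors.index),
                "columns": list(self.batch_factors.columns),
                "values": self.batch_factors.values.tolist(),
            },
            "pulse_windows": self.pulse_windows,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def make_toy_pathway_db(
    n_pathways: int = 8,
    compounds_per_pathway: int = 6,
    seed: int = 0,
    share_prob: float = 0.15,
    min_sep_ppm: float = 10.0,
    max_retries: int = 2000,
) -> PathwayDB:
    """Generate a small pathway database with well-separated compound masses.

    Endogenous compounds get unique monoisotopic masses in [100, 380] Da
    separated pairwise by more than ``min_sep_ppm``; pathways may share
    compounds. The four valproate molecules are included, flagged as drug
    compounds and never placed in endogenous pathways.
    """
    if n_pathways < 1 or compounds_per_pathway < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    compounds: dict[str, Compound] = {}
    masses: list[float] = []
    for name, mass in VPA_MOLECULES.items():
        cid = f"DRUG_{name}"
        compounds[cid] = Compound(cid, name, mass, is_drug=True)
        masses.append(mass)

    def _new_mass() -> float:
        for _ in range(max_retries):
            m = float(rng.uniform(100.5, 380.0))
            arr = np.asarray(masses)
            if np.all(np.abs(m - arr) / arr * 1e6 > min_sep_ppm):
                masses.append(m)
                return m
        raise RuntimeError(
            f"could not place a compound mass separated by {min_sep_ppm} ppm "
            f"after {max_retries} retries"
        )

    pathways: dict[str, Pathway] = {}
    pool: list[str] = []
    n_c = 0
    for p in range(n_pathways):
        members: list[str] = []
        for _ in range(compounds_per_pathway):
            cid = None
            # share an existing compound from another pathway sometimes
            if pool and rng.random() < share_prob:
                cand = pool[int(rng.integers(len(pool)))]
                if cand not in members:
                    cid = cand
            if cid is None:
                n_c += 1
                cid = f"C{n_c:04d}"
                compounds[cid] = Compound(cid, f"compound_{n_c}", _new_mass())
                pool.append(cid)
            members.append(cid)
        pid = f"P{p + 1:03d}"
        pathways[pid] = Pathway(pid, f"pathway_{p + 1}", tuple(members))
    return PathwayDB(compounds=compounds, pathways=pathways)


def _drug_feature_mz() -> pd.DataFrame:
    """11 positive-mode ion m/z values spread over the 4 valproate molecules."""
    rows = []
    plan = {
        "valproic_acid": 3,
        "3_heptanone": 3,
        "4_OH_gamma_lactone": 3,
        "heptanedione": 2,
    }
    for mol, n in plan.items():
        m = VPA_MOLECULES[mol]
        ions = [m + PROTON_MASS, m + PROTON_MASS + _C13_SPACING, m + PROTON_MASS + _NA_MINUS_H]
        for i in range(n):
            rows.append({"molecule": mol, "mz": ions[i]})
    return pd.DataFrame(rows)


def _exhalation_schedule(rng: np.random.Generator, cfg: CohortConfig):
    """Jittered pulse schedule; returns (total_duration, plateau windows, edges)."""
    n_exh = int(rng.integers(cfg.n_exhalations[0], cfg.n_exhalations[1] + 1))
    t = float(rng.uniform(4.0, 8.0))  # lead-in
    windows = []
    for _ in range(n_exh):
        plateau = float(rng.uniform(*cfg.plateau_s))
        windows.append((t + cfg.edge_s, t + cfg.edge_s + plateau))
        t += cfg.edge_s + plateau + cfg.edge_s + float(rng.uniform(*cfg.gap_s))
    return t + 4.0, windows


def _pulse_profile(scan_times: np.ndarray, windows, edge_s: float) -> np.ndarray:
    """Raised-cosine-edged plateau profile in [0, 1] over the scan times."""
    p = np.zeros_like(scan_times)
    for start, end in windows:
        rise = (scan_times >= start - edge_s) & (scan_times < start)
        fall = (scan_times > end) & (scan_times <= end + edge_s)
        flat = (scan_times >= start) & (scan_times <= end)
        p[flat] = 1.0
        p[rise] = np.maximum(p[rise], 0.5 * (1 - np.cos(np.pi * (scan_times[rise] - start + edge_s) / edge_s)))
        p[fall] = np.maximum(p[fall], 0.5 * (1 + np.cos(np.pi * (scan_times[fall] - end) / edge_s)))
    return p


def _free_fraction(total: np.ndarray, rng: np.random.Generator, noise_cv: float) -> np.ndarray:
    """Saturable-binding-like free fraction: rises from ~7% to ~15% with total."""
    frac = 0.07 + 0.08 * total / (total + 100.0)
    free = total * frac
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1 + (0.25 * noise_cv) ** 2))
        free = free * rng.lognormal(0.0, sigma, size=free.shape)
    return np.minimum(free, total)


def _plan_cohort(cfg: CohortConfig, db: PathwayDB | None):
    """Draw everything above the scan level: clinical truth, feature roster,
    batch factors and per-measurement amplitudes. Shared by the full scan
    simulator and the fast table-level generator."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if db is None:
        db = make_toy_pathway_db(seed=cfg.seed + 101)

    n_meas = cfg.n_subjects * cfg.visits_per_subject
    meas_ids = [f"S{1 + i // cfg.visits_per_subject:03d}-V{1 + i % cfg.visits_per_subject}"
                for i in range(n_meas)]
    subj_ids = [mid.split("-")[0] for mid in meas_ids]

    # subjects on VPA stay on VPA across visits (steady-state therapy)
    n_vpa_subj = int(round(cfg.frac_vpa * cfg.n_subjects))
    vpa_subjects = set(rng.permutation(cfg.n_subjects)[:n_vpa_subj] + 1)
    on_vpa = np.array([int(s[1:]) in vpa_subjects for s in subj_ids])

    total = np.zeros(n_meas)
    total[on_vpa] = np.clip(rng.lognormal(math.log(65.0), 0.45, size=on_vpa.sum()), 5.0, 160.0)
    free = _free_fraction(total, rng, cfg.noise_cv)

    se = rng.random(n_meas) < cfg.prevalence_side_effects
    nr = rng.random(n_meas) < cfg.prevalence_nonresponse
    eeg = rng.random(n_meas) < cfg.prevalence_abnormal_eeg

    def _cls(flags):
        sub = rng.integers(2, 4, size=len(flags))  # II or III for positives
        return np.where(flags, sub, 1)

    batches = [f"B{1 + int(b)}" for b in rng.integers(cfg.n_batches, size=n_meas)]

    measurements = pd.DataFrame(
        {
            "subject_id": subj_ids,
            "batch": batches,
            "on_vpa": on_vpa,
            "total_vpa_mgL": total,
            "free_vpa_mgL": free,
            "side_effects": se,
            "non_responder": nr,
            "abnormal_eeg": eeg,
            "side_effects_class": _cls(se),
            "response_class": _cls(nr),
            "eeg_class": _cls(eeg),
        },
        index=pd.Index(meas_ids, name="measurement_id"),
    )

    # ---- feature roster -------------------------------------------------
    drug = _drug_feature_mz()
    if cfg.n_drug_features != len(drug):
        # repeat/truncate the 11-ion template if a different count is requested
        reps = int(np.ceil(cfg.n_drug_features / len(drug)))
        drug = pd.concat([drug] * reps, ignore_index=True).iloc[: cfg.n_drug_features].copy()
        extra = np.arange(len(drug)) // 11
        drug["mz"] = drug["mz"] + extra * 2 * _C13_SPACING

    endog_pws = [p for p in db.pathways.values()
                 if not any(db.compounds[c].is_drug for c in p.compound_ids)]
    if len(endog_pws) < 2:
        raise ValueError("pathway DB needs >= 2 endogenous pathways")
    se_pw, nr_pw = endog_pws[0], endog_pws[1]
    affected_comp = set(se_pw.compound_ids) | set(nr_pw.compound_ids)
    other_comp = list(dict.fromkeys(
        c for p in endog_pws[2:] for c in p.compound_ids if c not in affected_comp))

    # registry of already-used ion m/z so random features do not collide
    # (and get merged) with programmed ones during feature consolidation
    used_mz: list[float] = list(drug["mz"])

    def _draw_mz(min_sep_ppm: float = 25.0) -> float:
        for _ in range(1000):
            m = float(rng.uniform(101.0, 390.0))
            arr = np.asarray(used_mz)
            if len(arr) == 0 or np.all(np.abs(m - arr) / arr * 1e6 > min_sep_ppm):
                used_mz.append(m)
                return m
        raise RuntimeError("could not draw a collision-free m/z")

    feat_rows = []
    for i, r in drug.iterrows():
        feat_rows.append({"feature_id": f"D{i + 1:03d}", "kind": "drug", "mz": r["mz"],
                          "molecule": r["molecule"], "affected": "", "compound_id": "",
                          "pathway_id": ""})
    k = 0
    used: set[str] = set()
    for pw, label in ((se_pw, "side_effects"), (nr_pw, "response")):
        for cid in pw.compound_ids:
            if cid in used:  # a compound shared between the two programmed
                continue     # pathways keeps its first (side-effect) role
            used.add(cid)
            if k >= cfg.n_endogenous_features:
                break
            k += 1
            mz = db.compounds[cid].mass + PROTON_MASS
            used_mz.append(mz)
            feat_rows.append({"feature_id": f"E{k:03d}", "kind": "endogenous",
                              "mz": mz,
                              "molecule": "", "affected": label, "compound_id": cid,
                              "pathway_id": pw.pathway_id})
    j = 0
    while k < cfg.n_endogenous_features:
        k += 1
        if j < len(other_comp):
            cid = other_comp[j]
            j += 1
            mz = db.compounds[cid].mass + PROTON_MASS
            used_mz.append(mz)
        else:
            cid = ""
            mz = _draw_mz()
        feat_rows.append({"feature_id": f"E{k:03d}", "kind": "endogenous", "mz": mz,
                          "molecule": "", "affected": "", "compound_id": cid,
                          "pathway_id": ""})
    for i in range(cfg.n_nuisance_features):
        feat_rows.append({"feature_id": f"N{i + 1:03d}", "kind": "nuisance",
                          "mz": _draw_mz(), "molecule": "",
                          "affected": "", "compound_id": "", "pathway_id": ""})
    features = pd.DataFrame(feat_rows).set_index("feature_id")
    features["base_amp"] = 0.0
    is_drug = features["kind"] == "drug"
    is_endo = features["kind"] == "endogenous"
    is_nui = features["kind"] == "nuisance"
    # per-ion response factors a_f; endogenous base abundances; nuisance noise level
    features.loc[is_drug, "base_amp"] = rng.lognormal(math.log(50.0), 0.5, is_drug.sum())
    features.loc[is_endo, "base_amp"] = rng.lognormal(math.log(800.0), 0.7, is_endo.sum())
    features.loc[is_nui, "base_amp"] = rng.lognormal(math.log(150.0), 0.7, is_nui.sum())
    # endogenous metabolites vary heterogeneously between measurements
    # (diet, metabolism); drug ions carry only the pharmacokinetic noise
    features["noise_mult"] = 1.0
    features.loc[is_endo | is_nui, "noise_mult"] = rng.uniform(
        1.0, 1.8, int((is_endo | is_nui).sum()))

    batch_ids = [f"B{b + 1}" for b in range(cfg.n_batches)]
    bf = rng.lognormal(0.0, cfg.batch_scale_sd, size=(cfg.n_batches, len(features)))
    batch_factors = pd.DataFrame(bf, index=batch_ids, columns=features.index)

    # ---- amplitude matrix ----------------------------------------------
    if cfg.noise_cv > 0:
        cv_f = cfg.noise_cv * features["noise_mult"].values
        sigma_f = np.sqrt(np.log(1 + cv_f**2))
        z = rng.standard_normal((n_meas, len(features)))
        noise = np.exp(z * sigma_f[None, :])
    else:
        noise = np.ones((n_meas, len(features)))
    amp = np.zeros((n_meas, len(features)))
    bfac = batch_factors.loc[measurements["batch"]].values

    a_drug = features.loc[is_drug, "base_amp"].values
    amp[:, is_drug.values] = (
        cfg.drug_baseline
        + a_drug[None, :] * (free[:, None] ** cfg.vpa_exponent)
    ) * bfac[:, is_drug.values] * noise[:, is_drug.values]

    fold = np.ones((n_meas, int(is_endo.sum())))
    aff = features.loc[is_endo, "affected"].values
    fold[:, aff == "side_effects"] *= np.where(se, 2.0**cfg.effect_size_side_effects, 1.0)[:, None]
    fold[:, aff == "response"] *= np.where(nr, 2.0**cfg.effect_size_nonresponse, 1.0)[:, None]
    amp[:, is_endo.values] = (
        features.loc[is_endo, "base_amp"].values[None, :] * fold
        * bfac[:, is_endo.values] * noise[:, is_endo.values]
    )
    amp[:, is_nui.values] = features.loc[is_nui, "base_amp"].values[None, :]

    amplitudes = pd.DataFrame(amp, index=measurements.index, columns=features.index)
    truth = SyntheticTruth(measurements, features, amplitudes, batch_factors)
    return rng, db, truth


def simulate_feature_table_inputs(cfg: CohortConfig, db: PathwayDB | None = None):
    """Scan-free limit of the generator: the realised mean exhalation
    amplitude per (measurement, feature), which is exactly what nAUC
    extraction recovers on noise-free pulses. Returns (truth, db).

    Useful for cheap repeated-seed studies of the statistical stages; the
    full scan-level path is :func:`simulate_cohort`.
    """
    _, db, truth = _plan_cohort(cfg, db)
    return truth, db


def truth_to_feature_table(truth: SyntheticTruth, breath_only: bool = True):
    """Build a FeatureTable directly from the programmed amplitude matrix.

    This is the idealised output of the trace-extraction stage (mean nAUC ==
    mean plateau amplitude on noise-free pulses); nuisance features are
    excluded by default, mirroring the breath-correlation filter that
    removes them in the scan-level path.
    """
    from .traces import FeatureTable

    feats = truth.features
    if breath_only:
        feats = feats[feats["kind"] != "nuisance"]
    fids = list(feats.index)
    values = truth.amplitudes[fids].copy()
    obs = truth.measurements.copy()
    obs["on_vpa"] = obs["on_vpa"].astype(bool)
    var = pd.DataFrame({"mz": feats["mz"], "polarity": "+", "tol_ppm": 5.0},
                       index=pd.Index(fids, name="feature_id"))
    presence = values > 0
    return FeatureTable(values, obs, var, presence)


def simulate_cohort(cfg: CohortConfig, db: PathwayDB | None = None):
    """Simulate a full cohort of scan-level measurements.

    Returns (measurements, truth, db) where measurements is a list of
    :class:`RawMeasurement` with centroided scans and TIC, and truth records
    all programmed quantities. Deterministic given ``cfg.seed``.
    """
    rng, db, truth = _plan_cohort(cfg, db)
    mz0 = truth.features["mz"].values
    kinds = truth.features["kind"].values
    breathy = kinds != "nuisance"
    nui = ~breathy
    jitter_sd = cfg.mz_jitter_ppm * 1e-6 if cfg.noise_cv > 0 else 0.0

    out: list[RawMeasurement] = []
    for mi, (mid, mrow) in enumerate(truth.measurements.iterrows()):
        duration, windows = _exhalation_schedule(rng, cfg)
        truth.pulse_windows[mid] = [(float(a), float(b)) for a, b in windows]
        scan_times = np.arange(0.0, duration, 1.0 / cfg.scan_hz)
        pulse = _pulse_profile(scan_times, windows, cfg.edge_s)
        amps = truth.amplitudes.iloc[mi].values

        inten = np.zeros((len(scan_times), len(amps)))
        inten[:, breathy] = pulse[:, None] * amps[None, breathy]
        # nuisance: positive white noise around the programmed level,
        # independent of the exhalation profile
        lvl = amps[nui][None, :]
        inten[:, nui] = np.abs(rng.normal(lvl, 0.5 * lvl + 1e-9,
                                          size=(len(scan_times), int(nui.sum()))))
        if jitter_sd > 0:
            mz = mz0[None, :] * (1 + rng.normal(0, jitter_sd, size=inten.shape))
        else:
            mz = np.broadcast_to(mz0[None, :], inten.shape)

        scans = []
        for si in range(len(scan_times)):
            keep = inten[si] > 1e-9
            order = np.argsort(mz[si][keep])
            scans.append((np.ascontiguousarray(mz[si][keep][order]),
                          np.ascontiguousarray(inten[si][keep][order])))
        tic = np.array([s[1].sum() for s in scans])

        clin = ClinicalAnnotation(
            drugs=("VPA",) if mrow["on_vpa"] else ("LEV",),
            total_vpa_mgL=float(mrow["total_vpa_mgL"]),
            free_vpa_mgL=float(mrow["free_vpa_mgL"]),
            side_effects_class=int(mrow["side_effects_class"]),
            response_class=int(mrow["response_class"]),
            eeg_class=int(mrow["eeg_class"]),
        )
        out.append(
            RawMeasurement(
                measurement_id=mid,
                subject_id=mrow["subject_id"],
                cohort="paediatric",
                polarity=cfg.polarity,
                batch_label=mrow["batch"],
                scan_times=scan_times,
                scans=scans,
                tic=tic,
                clinical=clin,
            )
        )
    return out, truth, db
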