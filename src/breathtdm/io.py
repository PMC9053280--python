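"""Readers and writers for the on-disk formats.

mzXML (centroided scans; read through pyteomics, written by a minimal
conformant writer), a compact long-format trace table (TSV), clinical
annotation CSVs, and the FeatureTable CSV bundle (values / obs / var /
presence side by side).
"""

from __future__ import annotations

import base64
import struct
import xml.sax.saxutils as saxutils
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mzxml as _mzxml

from .traces import ClinicalAnnotation, FeatureTable, RawMeasurement

__all__ = [
    "write_mzxml",
    "read_mzxml",
    "write_trace_table",
    "read_trace_table",
    "write_feature_table",
    "read_feature_table",
    "clinical_to_row",
    "clinical_from_row",
]

_MZXML_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"


def _encode_peaks(mz: np.ndarray, intensity: np.ndarray) -> str:
    pairs = np.empty(2 * len(mz), dtype=">f4")
    pairs[0::2] = mz
    pairs[1::2] = intensity
    return base64.b64encode(pairs.tobytes()).decode("ascii")


def write_mzxml(measurement: RawMeasurement, path, include_tic: bool = True) -> None:
    """Write one measurement as centroided mzXML 3.2 (network-order float32
    m/z-intensity pairs, no compression)."""
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        f'<mzXML xmlns="{_MZXML_NS}">',
        f' <msRun scanCount="{len(measurement.scans)}">',
    ]
    for i, ((mz, inten), t) in enumerate(zip(measurement.scans, measurement.scan_times)):
        tic_attr = f' totIonCurrent="{measurement.tic[i]:.6f}"' if include_tic else ""
        lines.append(
            f'  <scan num="{i + 1}" msLevel="1" peaksCount="{len(mz)}" '
            f'polarity="{saxutils.escape(measurement.polarity)}" '
            f'retentionTime="PT{t:.4f}S" centroided="1"{tic_attr}>'
        )
        lines.append(
            '   <peaks compressionType="none" compressedLen="0" precision="32" '
            'byteOrder="network" contentType="m/z-int">'
            + _encode_peaks(np.asarray(mz), np.asarray(inten))
            + "</peaks>"
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    Path(path).write_text("\n".join(lines))


def read_mzxml(path, measurement_id: str | None = None,
               clinical: ClinicalAnnotation | None = None,
               subject_id: str = "", cohort: str = "paediatric",
               batch_label: str = "B1") -> RawMeasurement:
    """Read a centroided mzXML file into a RawMeasurement.

    If a scan lacks a total-ion-current attribute, the TIC is recomputed as
    the per-scan intensity sum.
    """
    scan_times, scans, tic = [], [], []
    polarity = "+"
    with _mzxml.MzXML(str(path)) as reader:
        for scan in reader:
            rt = scan["retentionTime"]
            unit = getattr(rt, "unit_info", "minute")  # mzXML convention
            t = float(rt) * 60.0 if unit == "minute" else float(rt)
            mz = np.asarray(scan.get("m/z array", []), float)
            inten = np.asarray(scan.get("intensity array", []), float)
            order = np.argsort(mz)
            mz, inten = mz[order], inten[order]
            scan_times.append(t)
            scans.append((mz, inten))
            if "totIonCurrent" in scan and scan["totIonCurrent"] is not None:
                tic.append(float(scan["totIonCurrent"]))
            else:
                tic.append(float(inten.sum()))
            polarity = scan.get("polarity", polarity) or polarity
    return RawMeasurement(
        measurement_id=measurement_id or Path(path).stem,
        subject_id=subject_id,
        cohort=cohort,
        polarity=polarity,
        batch_label=batch_label,
        scan_times=np.asarray(scan_times),
        scans=scans,
        tic=np.asarray(tic),
        clinical=clinical or ClinicalAnnotation(),
    )


# ---------------------------------------------------------------------------
# compact trace table (long TSV): one row per (feature, scan)

def write_trace_table(measurement: RawMeasurement,
                      traces: dict[str, np.ndarray],
                      feature_mz: dict[str, float], path) -> None:
    """Write per-feature intensity traces of one measurement as long TSV with
    columns measurement_id, feature_id, feature_mz, scan_time_s, intensity."""
    rows = []
    for fid, tr in traces.items():
        for t, v in zip(measurement.scan_times, tr):
            rows.append((measurement.measurement_id, fid, feature_mz[fid], t, v))
    pd.DataFrame(rows, columns=["measurement_id", "feature_id", "feature_mz",
                                "scan_time_s", "intensity"]).to_csv(
        path, sep="\t", index=False)


def read_trace_table(path, clinical: ClinicalAnnotation | None = None,
                     subject_id: str = "", cohort: str = "paediatric",
                     polarity: str = "+", batch_label: str = "B1") -> RawMeasurement:
    """Reconstruct a RawMeasurement from a long trace table.

    Each feature contributes one centroid (at its stored m/z) per scan where
    its intensity is positive; the TIC is the per-scan intensity sum.
    Non-monotone scan times are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"measurement_id", "feature_id", "feature_mz", "scan_time_s", "intensity"}
    if not need <= set(df.columns):
        raise ValueError(f"trace table missing columns {need - set(df.columns)}")
    mids = df["measurement_id"].unique()
    if len(mids) != 1:
        raise ValueError("trace table must contain exactly one measurement")
    scan_times = np.sort(df["scan_time_s"].unique())
    if len(scan_times) > 1 and np.any(np.diff(scan_times) <= 0):
        raise ValueError("scan times must be strictly increasing")
    wide = df.pivot_table(index="scan_time_s", columns="feature_id",
                          values="intensity", aggfunc="sum").reindex(scan_times).fillna(0.0)
    per_scan_counts = df.groupby(["feature_id", "scan_time_s"]).size()
    if (per_scan_counts > 1).any():
        raise ValueError("duplicate (feature, scan) rows in trace table")
    mz_of = df.drop_duplicates("feature_id").set_index("feature_id")["feature_mz"]
    fids = list(wide.columns)
    mz_vec = mz_of[fids].values.astype(float)
    order = np.argsort(mz_vec)
    mz_sorted = mz_vec[order]
    scans = []
    for _, row in wide.iterrows():
        inten = row.values.astype(float)[order]
        keep = inten > 0
        scans.append((mz_sorted[keep].copy(), inten[keep].copy()))
    tic = np.array([s[1].sum() for s in scans])
    return RawMeasurement(
        measurement_id=str(mids[0]),
        subject_id=subject_id,
        cohort=cohort,
        polarity=polarity,
        batch_label=batch_label,
        scan_times=scan_times,
        scans=scans,
        tic=tic,
        clinical=clinical or ClinicalAnnotation(),
    )


# ---------------------------------------------------------------------------
# FeatureTable bundle

def write_feature_table(table: FeatureTable, prefix) -> list[Path]:
    """Write the table as four CSVs sharing a path prefix:
    <prefix>.values.csv, .obs.csv, .var.csv, .presence.csv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (("values", table.values), ("obs", table.obs),
                     ("var", table.var), ("presence", table.presence)):
        p = prefix.with_suffix(f".{name}.csv")
        df.to_csv(p)
        paths.append(p)
    return paths


def read_feature_table(prefix) -> FeatureTable:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".values.csv"), index_col=0)
    obs = pd.read_csv(prefix.with_suffix(".obs.csv"), index_col=0)
    var = pd.read_csv(prefix.with_suffix(".var.csv"), index_col=0)
    presence = pd.read_csv(prefix.with_suffix(".presence.csv"), index_col=0)
    presence = presence.astype(bool)
    return FeatureTable(values, obs, var, presence)


# ---------------------------------------------------------------------------
# clinical annotation <-> flat row

def clinical_to_row(c: ClinicalAnnotation) -> dict:
    return {
        "drugs": ";".join(c.drugs),
        "total_vpa_mgL": c.total_vpa_mgL,
        "free_vpa_mgL": np.nan if c.free_vpa_mgL is None else c.free_vpa_mgL,
        "side_effects_class": c.side_effects_class,
        "response_class": c.response_class,
        "eeg_class": c.eeg_class,
    }


def clinical_from_row(row) -> ClinicalAnnotation:
    free = row.get("free_vpa_mgL", np.nan)
    return ClinicalAnnotation(
        drugs=tuple(d for d in str(row.get("drugs", "")).split(";") if d),
        total_vpa_mgL=float(row.get("total_vpa_mgL", 0.0)),
        free_vpa_mgL=None if pd.isna(free) else float(free),
        side_effects_class=int(row.get("side_effects_class", 1)),
        response_class=int(row.get("response_class", 1)),
        eeg_class=int(row.get("eeg_class", 1)),
    )
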