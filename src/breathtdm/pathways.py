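"""Pathway database containers and accurate-mass annotation.

A :class:`PathwayDB` maps pathways to compounds and compounds to neutral
monoisotopic masses. Features measured as m/z are putatively annotated to
compounds through adduct arithmetic within a ppm tolerance, which is the
basis of m/z-level ("mummichog-style") enrichment: no upfront compound
identification is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTON_MASS = 1.007276466

#: Default adduct mass offsets per polarity (applied to the neutral mass M).
DEFAULT_ADDUCTS = {
    "+": {"[M+H]+": PROTON_MASS},
    "-": {"[M-H]-": -PROTON_MASS},
}

# The four valproate-derived molecules detectable in breath: the parent drug,
# the beta-oxidation end product (3-heptanone), the omega-1-oxidation end
# product (4-OH-VPA gamma-lactone) and a heptanedione (C7H12O2).
VPA_MOLECULES = {
    "valproic_acid": 144.115030,      # C8H16O2
    "3_heptanone": 114.104465,        # C7H14O
    "4_OH_gamma_lactone": 142.099380,  # C8H14O2 -> [M+H]+ 143.1066
    "heptanedione": 128.083730,       # C7H12O2
}


@dataclass(frozen=True)
class Compound:
    compound_id: str
    name: str
    mass: float  # neutral monoisotopic mass, Da
    is_drug: bool = False


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    compound_ids: tuple[str, ...]


@dataclass
class PathwayDB:
    compounds: dict[str, Compound] = field(default_factory=dict)
    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pw in self.pathways.values():
            missing = [c for c in pw.compound_ids if c not in self.compounds]
            if missing:
                raise ValueError(f"pathway {pw.pathway_id} references unknown compounds {missing}")

    def compound_mass(self, compound_id: str) -> float:
        return self.compounds[compound_id].mass

    def pathways_of(self, compound_id: str) -> list[str]:
        return [p.pathway_id for p in self.pathways.values() if compound_id in p.compound_ids]

    def to_json(self, path) -> None:
        obj = {
            "compounds": [
                {"id": c.compound_id, "name": c.name, "mass": c.mass, "is_drug": c.is_drug}
                for c in self.compounds.values()
            ],
            "pathways": [
                {"id": p.pathway_id, "name": p.name, "compounds": list(p.compound_ids)}
                for p in self.pathways.values()
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PathwayDB":
        with open(path) as fh:
            obj = json.load(fh)
        compounds = {
            c["id"]: Compound(c["id"], c["name"], float(c["mass"]), bool(c.get("is_drug", False)))
            for c in obj["compounds"]
        }
        pathways = {
            p["id"]: Pathway(p["id"], p["name"], tuple(p["compounds"]))
            for p in obj["pathways"]
        }
        return cls(compounds=compounds, pathways=pathways)


def annotate_mz(
    features: pd.DataFrame,
    db: PathwayDB,
    adducts: dict[str, dict[str, float]] | None = None,
    ppm_tol: float = 2.0,
) -> pd.DataFrame:
    """Putatively annotate measured m/z features to database compounds.

    Parameters
    ----------
    features
        DataFrame indexed by feature id with columns ``mz`` and ``polarity``
        ('+' or '-').
    adducts
        Mapping polarity -> {adduct name -> mass offset added to the neutral
        mass}. Defaults to protonation/deprotonation.
    ppm_tol
        Relative tolerance; a feature matches a compound iff
        ``|mz_obs - mz_theo| / mz_theo <= ppm_tol * 1e-6``.

    Returns
    -------
    DataFrame with one row per (feature, compound, adduct) match; multiple
    candidates per feature (e.g. isomers) are all retained.
    """
    if adducts is None:
        adducts = DEFAULT_ADDUCTS
    rows = []
    comp_ids = list(db.compounds)
    masses = np.array([db.compounds[c].mass for c in comp_ids])
    for fid, row in features.iterrows():
        pol = row.get("polarity", "+")
        mz_obs = float(row["mz"])
        for adduct, offset in adducts.get(pol, {}).items():
            theo = masses + offset
            ppm = np.abs(mz_obs - theo) / theo * 1e6
            for j in np.flatnonzero(ppm <= ppm_tol):
                rows.append(
                    {
                        "feature_id": fid,
                        "compound_id": comp_ids[j],
                        "adduct": adduct,
                        "mz_observed": mz_obs,
                        "mz_theoretical": float(theo[j]),
                        "ppm_error": float(ppm[j]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "compound_id",
            "adduct",
            "mz_observed",
            "mz_theoretical",
            "ppm_error",
        ],
    )
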