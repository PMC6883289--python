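"""CSV / YAML dialects shared by the pipeline.

Pedigree CSV: columns ``id, sire, dam, sex, birth_date`` (ISO-8601);
empty cell = unknown.  Phenotype CSV: columns ``id, breed, sex,
age_months, eval_date, left_status, right_status`` with statuses {0,1}.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .liability import PhenotypeRecord, PriorSpec
from .pedigree import Pedigree, PedigreeRecord, topological_sort_pedigree

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "birth_date"]
PHENOTYPE_COLUMNS = [
    "id", "breed", "sex", "age_months", "eval_date", "left_status", "right_status",
]


def write_pedigree_csv(ped: Pedigree, path) -> None:
    rows = [
        {
            "id": r.individual_id,
            "sire": r.sire_id or "",
            "dam": r.dam_id or "",
            "sex": r.sex,
            "birth_date": r.birth_date.isoformat() if r.birth_date else "",
        }
        for r in ped.records
    ]
    pd.DataFrame(rows, columns=PEDIGREE_COLUMNS).to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    recs = []
    for row in df.itertuples(index=False):
        bd = dt.date.fromisoformat(row.birth_date) if row.birth_date else None
        recs.append(
            PedigreeRecord(
                individual_id=row.id,
                sire_id=row.sire or None,
                dam_id=row.dam or None,
                sex=row.sex or "U",
                birth_date=bd,
            )
        )
    return topological_sort_pedigree(recs)


def write_phenotypes_csv(records: list[PhenotypeRecord], path) -> None:
    rows = [
        {
            "id": r.individual_id,
            "breed": r.breed,
            "sex": r.sex,
            "age_months": r.age_months,
            "eval_date": r.eval_date.isoformat() if r.eval_date else "",
            "left_status": r.y_left,
            "right_status": r.y_right,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS).to_csv(path, index=False)


def read_phenotypes_csv(path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PhenotypeRecord(
                individual_id=row.id,
                breed=row.breed,
                sex=row.sex,
                age_months=float(row.age_months),
                eval_date=dt.date.fromisoformat(row.eval_date) if row.eval_date else None,
                y_left=int(row.left_status),
                y_right=int(row.right_status),
            )
        )
    return out


def write_relationship_matrix_csv(labels, values: np.ndarray, path) -> None:
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(path)


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def prior_from_config(cfg: dict) -> PriorSpec:
    kw = {}
    if "fixed_effect_variance" in cfg:
        kw["fixed_effect_variance"] = float(cfg["fixed_effect_variance"])
    if "iw_scale" in cfg:
        kw["iw_scale"] = np.asarray(cfg["iw_scale"], dtype=float)
    if "iw_df" in cfg:
        kw["iw_df"] = float(cfg["iw_df"])
    return PriorSpec(**kw)


def sha256_of(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
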