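"""Record eligibility filters, prevalence tables and EBV trends.

Screening-registry intake rules: dogs must be at least 24 months old at
evaluation, only the most recent submission per dog is kept, and breeds
with 380 or fewer remaining submissions are excluded (too few records for
a stable pedigree analysis).  A :class:`FilterReport` reconciles every
removal so the cleaned record count is auditable.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .mating import ElbowCategory, categorize_elbows
from .mcmc import Chain
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "filter_records",
    "prevalence_table",
    "ebv_trend",
    "population_size_category",
    "MIN_AGE_MONTHS",
    "MIN_BREED_SUBMISSIONS",
]

#: Inclusive eligibility minimum; the observed screening range starts at 24 months.
MIN_AGE_MONTHS = 24
#: Breeds need strictly more than this many submissions (post-deduplication).
MIN_BREED_SUBMISSIONS = 380


@dataclasses.dataclass
class FilterReport:
    records_in: int
    removed_invalid: int
    removed_duplicates: int
    removed_underage: int
    breeds_removed_small: int
    removed_small_breed_records: int
    records_out: int

    def reconciles(self) -> bool:
        return self.records_out == (
            self.records_in
            - self.removed_invalid
            - self.removed_duplicates
            - self.removed_underage
            - self.removed_small_breed_records
        )


def filter_records(raw: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the intake eligibility rules to raw phenotype rows.

    ``raw`` uses the phenotype CSV schema (id, breed, sex, age_months,
    eval_date, left_status, right_status).  Rules, in order: drop
    unparseable rows (logged); keep only the latest eval_date per dog;
    drop dogs younger than 24 months; drop breeds with <= 380 remaining
    submissions.  Idempotent: filtering a filtered frame changes nothing.
    """
    records_in = len(raw)
    df = raw.copy()

    def _valid(row) -> bool:
        try:
            float(row["age_months"])
            if int(row["left_status"]) not in (0, 1):
                return False
            if int(row["right_status"]) not in (0, 1):
                return False
            pd.Timestamp(row["eval_date"])
        except (ValueError, TypeError):
            return False
        return True

    valid_mask = df.apply(_valid, axis=1) if len(df) else pd.Series([], dtype=bool)
    n_invalid = int((~valid_mask).sum()) if len(df) else 0
    if n_invalid:
        for _, row in df[~valid_mask].iterrows():
            logger.warning("rejecting unparseable row for id=%s", row.get("id"))
    df = df[valid_mask].copy() if len(df) else df
    if len(df):
        df["age_months"] = df["age_months"].astype(float)
        df["eval_date"] = pd.to_datetime(df["eval_date"])
        df["left_status"] = df["left_status"].astype(int)
        df["right_status"] = df["right_status"].astype(int)

    # latest submission per dog
    if len(df):
        df = df.sort_values(["id", "eval_date"], kind="stable")
        keep = ~df.duplicated(subset="id", keep="last")
        n_dup = int((~keep).sum())
        df = df[keep]
    else:
        n_dup = 0

    underage = df["age_months"] < MIN_AGE_MONTHS if len(df) else pd.Series([], dtype=bool)
    n_under = int(underage.sum()) if len(df) else 0
    df = df[~underage] if len(df) else df

    if len(df):
        counts = df.groupby("breed").size()
        small = set(counts[counts <= MIN_BREED_SUBMISSIONS].index)
        small_mask = df["breed"].isin(small)
        n_small_records = int(small_mask.sum())
        df = df[~small_mask]
    else:
        small, n_small_records = set(), 0

    df = df.reset_index(drop=True)
    report = FilterReport(
        records_in=records_in,
        removed_invalid=n_invalid,
        removed_duplicates=n_dup,
        removed_underage=n_under,
        breeds_removed_small=len(small),
        removed_small_breed_records=n_small_records,
        records_out=len(df),
    )
    assert report.reconciles()
    return df, report


def prevalence_table(clean: pd.DataFrame) -> pd.DataFrame:
    """Per-breed prevalence of any elbow dysplasia plus mean age."""
    rows = []
    for breed, grp in clean.groupby("breed"):
        cats = [
            categorize_elbows(int(l), int(r))
            for l, r in zip(grp["left_status"], grp["right_status"])
        ]
        affected = sum(c is not ElbowCategory.N for c in cats)
        rows.append(
            {
                "breed": breed,
                "n": len(grp),
                "prevalence": affected / len(grp),
                "mean_age_months": float(grp["age_months"].mean()),
            }
        )
    return pd.DataFrame(rows)


def ebv_trend(chain: Chain, ped: Pedigree) -> pd.DataFrame:
    """Mean standardized EBV per birth year and trait.

    EBV = posterior mean of a dog's breeding value; standardized by the
    posterior-mean genetic standard deviation per trait.  Dogs without a
    birth date are excluded (counted in the ``n_missing_birth_date``
    attribute of the frame).
    """
    ebv = chain.mean_breeding_values()  # (q, 2), cols (R, L)
    sd_r = float(np.sqrt(np.mean(chain.var_r)))
    sd_l = float(np.sqrt(np.mean(chain.var_l)))
    years = []
    missing = 0
    for rec in ped.records:
        if rec.birth_date is None:
            years.append(None)
            missing += 1
        else:
            years.append(rec.birth_date.year)
    rows = []
    by_year: dict[int, list[int]] = {}
    for i, y in enumerate(years):
        if y is not None:
            by_year.setdefault(y, []).append(i)
    for year in sorted(by_year):
        idx = np.array(by_year[year])
        rows.append(
            {
                "birth_year": year,
                "mean_std_ebv_R": float(np.mean(ebv[idx, 0])) / sd_r,
                "mean_std_ebv_L": float(np.mean(ebv[idx, 1])) / sd_l,
                "n": len(idx),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_missing_birth_date"] = missing
    return out


def population_size_category(n_dogs: int) -> str:
    """Registry population-size label: small < 2000 <= medium <= 10000 < large."""
    if n_dogs < 2000:
        return "small"
    if n_dogs <= 10000:
        return "medium"
    return "large"
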