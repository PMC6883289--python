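"""Mating-type analysis of the reference synthetic study.

Tabulates the 16 sire-category x dam-category mating types, the collapsed
parent-combination prevalences (registry-table layout), the saturated
multinomial progeny-outcome model with an offspring-sex term, and the
per-birth-year mating proportions.  Everything lands in results/mating/.
"""

from pathlib import Path

import pandas as pd

from elbowgen import io
from elbowgen.mating import (
    count_mating_types,
    fit_multinomial_saturated,
    mating_proportions_by_year,
    prevalence_by_parent_combo,
)

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results" / "mating"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ped = io.read_pedigree_csv(SIM / "pedigree.csv")
    records = io.read_phenotypes_csv(SIM / "phenotypes.csv")
    table = count_mating_types(records, ped)
    table.to_dataframe().to_csv(OUT / "mating_counts.csv", index=False)
    prev = prevalence_by_parent_combo(table)
    pd.DataFrame(
        [
            {"parent_combo": k, "offspring_prevalence": "" if v is None else round(v, 4)}
            for k, v in prev.items()
        ]
    ).to_csv(OUT / "prevalence_by_combo.csv", index=False)
    fit = fit_multinomial_saturated(table, sex_effect=True)
    rows = []
    for (s, d, sex), p in sorted(fit.fitted_probs.items(), key=str):
        rows.append(
            {
                "sire_cat": s.value,
                "dam_cat": d.value,
                "offspring_sex": sex,
                **{f"p_{o.value}": round(float(p[j]), 4) for j, o in enumerate(fit.outcomes)},
            }
        )
    pd.DataFrame(rows).to_csv(OUT / "progeny_probabilities.csv", index=False)
    mating_proportions_by_year(records, ped).to_csv(
        OUT / "mating_proportions_by_year.csv", index=False
    )
    print("offspring prevalence by parent combination:")
    for k, v in prev.items():
        print(f"  {k:22s} {'-' if v is None else f'{v:.3f}'}")


if __name__ == "__main__":
    main()
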