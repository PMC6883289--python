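"""Mating-type tabulation, collapsed prevalences and the multinomial
progeny-outcome model."""

import numpy as np
import pytest

from elbowgen.liability import PhenotypeRecord
from elbowgen.mating import (
    ElbowCategory,
    categorize_elbows,
    count_mating_types,
    fit_multinomial_saturated,
    mating_proportions_by_year,
    predict_progeny_probabilities,
    prevalence_by_parent_combo,
)
from elbowgen.pedigree import PedigreeRecord, topological_sort_pedigree

N, L, R, B, U = (
    ElbowCategory.N,
    ElbowCategory.L,
    ElbowCategory.R,
    ElbowCategory.B,
    ElbowCategory.UNKNOWN,
)


def _rec(i, yl, yr, sex="M"):
    return PhenotypeRecord(i, y_left=yl, y_right=yr, sex=sex, age_months=30)


def _family(sire_status, dam_status, offspring):
    """Pedigree + phenotypes: one mating with given (yl, yr) statuses."""
    recs = [
        PedigreeRecord("S", sex="M"),
        PedigreeRecord("D", sex="F"),
    ]
    phen = []
    if sire_status is not None:
        phen.append(_rec("S", *sire_status, sex="M"))
    if dam_status is not None:
        phen.append(_rec("D", *dam_status, sex="F"))
    for k, (yl, yr, sex) in enumerate(offspring):
        recs.append(PedigreeRecord(f"O{k}", sire_id="S", dam_id="D", sex=sex))
        phen.append(_rec(f"O{k}", yl, yr, sex=sex))
    return topological_sort_pedigree(recs), phen


class TestCategorize:
    @pytest.mark.parametrize(
        "yl,yr,expected", [(0, 0, N), (1, 0, L), (0, 1, R), (1, 1, B)]
    )
    def test_known_categories(self, yl, yr, expected):
        assert categorize_elbows(yl, yr) is expected

    def test_bijection_over_status_pairs(self):
        cats = {categorize_elbows(a, b) for a in (0, 1) for b in (0, 1)}
        assert cats == {N, L, R, B}

    def test_both_missing_is_unknown(self):
        assert categorize_elbows(None, None) is U

    def test_one_sided_missing_rejected(self):
        with pytest.raises(ValueError, match="one-sided"):
            categorize_elbows(None, 1)


class TestCountMatingTypes:
    def test_counts_one_cell(self):
        ped, phen = _family(
            (0, 0), (1, 0),
            [(0, 0, "M"), (0, 0, "F"), (1, 1, "M")],
        )
        table = count_mating_types(phen, ped)
        c = table.outcome_counts[(N, L)]
        assert table.cell_total(N, L) == 3
        assert c[N] == 2 and c[B] == 1
        # parents themselves fall in the unknown x unknown cell (founders)
        assert table.cell_total(U, U) == 2

    def test_untested_parents_all_unknown(self):
        ped, phen = _family(None, None, [(0, 0, "M"), (1, 0, "F")])
        table = count_mating_types(phen, ped)
        assert table.cell_total(U, U) == 2
        assert table.grand_total == 2

    def test_empty_input(self):
        ped = topological_sort_pedigree([PedigreeRecord("X")])
        table = count_mating_types([], ped)
        assert table.grand_total == 0
        assert table.outcome_counts == {}

    def test_cell_outcomes_sum_to_cell_total(self):
        ped, phen = _family((1, 1), (0, 1), [(a, b, "M") for a in (0, 1) for b in (0, 1)])
        table = count_mating_types(phen, ped)
        for sd, c in table.outcome_counts.items():
            assert sum(c.values()) == table.cell_total(*sd)


class TestPrevalenceByCombo:
    def test_normal_normal_prevalence(self):
        ped, phen = _family(
            (0, 0), (0, 0),
            [(0, 0, "M")] * 8 + [(1, 0, "M"), (0, 1, "F")],
        )
        table = count_mating_types(phen, ped)
        prev = prevalence_by_parent_combo(table)
        assert prev["normal x normal"] == pytest.approx(0.2)

    def test_absent_combo_reported_as_none_not_zero(self):
        ped, phen = _family((0, 0), (0, 0), [(0, 0, "M")])
        prev = prevalence_by_parent_combo(count_mating_types(phen, ped))
        assert prev["affected x affected"] is None

    def test_affected_affected_pools_lateralities(self):
        # L x B and B x R matings both collapse into affected x affected
        recs, phen = [], []
        for tag, (s_stat, d_stat) in (("1", ((1, 0), (1, 1))), ("2", ((1, 1), (0, 1)))):
            recs += [
                PedigreeRecord(f"S{tag}", sex="M"),
                PedigreeRecord(f"D{tag}", sex="F"),
                PedigreeRecord(f"O{tag}", sire_id=f"S{tag}", dam_id=f"D{tag}"),
            ]
            phen += [
                _rec(f"S{tag}", *s_stat, sex="M"),
                _rec(f"D{tag}", *d_stat, sex="F"),
                _rec(f"O{tag}", 1, 1),
            ]
        ped = topological_sort_pedigree(recs)
        prev = prevalence_by_parent_combo(count_mating_types(phen, ped))
        assert prev["affected x affected"] == pytest.approx(1.0)

    def test_parent_order_invariance(self):
        ped1, phen1 = _family((0, 0), (1, 1), [(0, 0, "M")] * 3 + [(1, 1, "F")])
        ped2, phen2 = _family((1, 1), (0, 0), [(0, 0, "M")] * 3 + [(1, 1, "F")])
        p1 = prevalence_by_parent_combo(count_mating_types(phen1, ped1))
        p2 = prevalence_by_parent_combo(count_mating_types(phen2, ped2))
        assert p1["normal x affected"] == p2["normal x affected"]


class TestMultinomialFit:
    def test_single_cell_proportions(self):
        ped, phen = _family((0, 0), (0, 0), [(0, 0, "M")] * 3 + [(1, 0, "M")])
        fit = fit_multinomial_saturated(count_mating_types(phen, ped))
        p = predict_progeny_probabilities(fit, N, N)
        np.testing.assert_allclose(p, [0.75, 0.25, 0.0, 0.0], atol=1e-9)

    def test_saturated_equals_proportions_on_random_tables(self):
        rng = np.random.default_rng(42)
        from collections import Counter
        from elbowgen.mating import KNOWN_CATEGORIES, MatingTable

        for _ in range(20):
            counts = {}
            for s in KNOWN_CATEGORIES:
                for d in KNOWN_CATEGORIES:
                    if rng.random() < 0.7:
                        c = Counter(
                            {
                                k: int(v)
                                for k, v in zip(
                                    KNOWN_CATEGORIES, rng.integers(0, 30, size=4)
                                )
                                if v > 0
                            }
                        )
                        if c:
                            counts[(s, d)] = c
            if not counts:
                continue
            table = MatingTable(counts, {}, 0)
            fit = fit_multinomial_saturated(table)
            for sd, c in counts.items():
                tot = sum(c.values())
                want = np.array([c.get(k, 0) / tot for k in KNOWN_CATEGORIES])
                got = predict_progeny_probabilities(fit, *sd)
                assert np.abs(got - want).max() < 1e-6

    def test_uniform_outcomes_give_zero_log_odds(self):
        from collections import Counter
        from elbowgen.mating import MatingTable

        c = Counter({N: 5, L: 5, R: 5, B: 5})
        table = MatingTable({(N, N): c, (B, B): Counter(c)}, {}, 0)
        fit = fit_multinomial_saturated(table)
        lo = fit.coefficients[[f"log_odds_{k.value}" for k in (L, R, B)]].to_numpy()
        np.testing.assert_allclose(lo, 0.0, atol=1e-8)

    def test_matches_statsmodels_mnlogit(self):
        import pandas as pd
        import statsmodels.api as sm
        from collections import Counter
        from elbowgen.mating import MatingTable

        counts = {
            (N, N): Counter({N: 30, L: 4, R: 3, B: 2}),
            (N, B): Counter({N: 12, L: 5, R: 4, B: 6}),
            (B, B): Counter({N: 5, L: 6, R: 7, B: 9}),
        }
        table = MatingTable(counts, {}, 0)
        fit = fit_multinomial_saturated(table)
        rows = []
        for j, sd in enumerate(sorted(counts, key=lambda x: (x[0].value, x[1].value))):
            for k, cat in enumerate((N, L, R, B)):
                rows += [{"cell": j, "y": k}] * counts[sd][cat]
        df = pd.DataFrame(rows)
        X = pd.get_dummies(df["cell"], prefix="c", dtype=float)
        res = sm.MNLogit(df["y"], X).fit(method="newton", disp=False)
        probs = res.predict(X.drop_duplicates().sort_index())
        for j, sd in enumerate(sorted(counts, key=lambda x: (x[0].value, x[1].value))):
            got = predict_progeny_probabilities(fit, *sd)
            np.testing.assert_allclose(got, probs.iloc[j].to_numpy(), atol=1e-5)

    def test_sex_term_probabilities_sum_to_one(self):
        ped, phen = _family(
            (0, 0), (1, 1),
            [(0, 0, "M"), (1, 0, "M"), (0, 0, "F"), (0, 1, "F"), (1, 1, "M")],
        )
        table = count_mating_types(phen, ped)
        fit = fit_multinomial_saturated(table, sex_effect=True)
        for key in fit.fitted_probs:
            p = fit.fitted_probs[key]
            assert p.min() >= -1e-12
            assert p.sum() == pytest.approx(1.0)

    def test_unseen_cell_is_no_data_not_zero(self):
        ped, phen = _family((0, 0), (0, 0), [(0, 0, "M")])
        fit = fit_multinomial_saturated(count_mating_types(phen, ped))
        with pytest.raises(KeyError, match="no data"):
            predict_progeny_probabilities(fit, B, B)

    def test_empty_table_rejected(self):
        from elbowgen.mating import MatingTable

        with pytest.raises(ValueError):
            fit_multinomial_saturated(MatingTable({}, {}, 0))


class TestMatingProportionsByYear:
    def test_series_counts_known_matings(self):
        import datetime as dt

        recs = [
            PedigreeRecord("S", sex="M"),
            PedigreeRecord("D", sex="F"),
            PedigreeRecord("O1", sire_id="S", dam_id="D",
                           birth_date=dt.date(2005, 1, 1)),
            PedigreeRecord("O2", sire_id="S", dam_id="D",
                           birth_date=dt.date(2006, 1, 1)),
        ]
        phen = [
            _rec("S", 0, 0, "M"), _rec("D", 1, 0, "F"),
            _rec("O1", 0, 0), _rec("O2", 1, 1),
        ]
        ped = topological_sort_pedigree(recs)
        out = mating_proportions_by_year(phen, ped)
        assert list(out["birth_year"]) == [2005, 2006]
        assert (out["prop_normal_x_affected"] == 1.0).all()
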