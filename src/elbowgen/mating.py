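"""Mating-type tabulation and multinomial analysis of progeny outcomes.

Every screened dog falls into one of four mutually exclusive elbow
categories -- normal (N), left-only (L), right-only (R), bilateral (B) --
and its sire and dam, when screened, into the same four, giving 16
possible mating types (extended by UNKNOWN rows/columns for unscreened
parents).  The offspring outcome distribution per mating type is
summarised two ways:

* collapsed prevalences by unordered parent combination
  (normal x normal, normal x affected, ...), the registry-table view;
* a multinomial logistic (log-linear) model of the 4-way offspring
  outcome on mating-type indicators, optionally with an additive
  offspring-sex term.  With the cell indicators alone the model is
  saturated, so the fitted probabilities equal the within-cell outcome
  proportions -- which is the correctness oracle used in tests.

Cells with no offspring are reported as absent, never as 0%: a zero
prevalence from an empty cell is an artifact, not an estimate.
"""

from __future__ import annotations

import dataclasses
import enum
from collections import Counter

import numpy as np
import pandas as pd

from .liability import PhenotypeRecord
from .pedigree import Pedigree

__all__ = [
    "ElbowCategory",
    "MatingTable",
    "MultinomialFit",
    "categorize_elbows",
    "count_mating_types",
    "prevalence_by_parent_combo",
    "fit_multinomial_saturated",
    "predict_progeny_probabilities",
    "mating_proportions_by_year",
    "PARENT_COMBOS",
]


class ElbowCategory(str, enum.Enum):
    N = "N"  # normal both elbows
    L = "L"  # left only affected
    R = "R"  # right only affected
    B = "B"  # bilateral
    UNKNOWN = "U"

    @property
    def affected(self) -> bool:
        if self is ElbowCategory.UNKNOWN:
            raise ValueError("affection undefined for UNKNOWN")
        return self is not ElbowCategory.N


KNOWN_CATEGORIES = (ElbowCategory.N, ElbowCategory.L, ElbowCategory.R, ElbowCategory.B)
ALL_CATEGORIES = KNOWN_CATEGORIES + (ElbowCategory.UNKNOWN,)

PARENT_COMBOS = (
    "normal x normal",
    "normal x affected",
    "affected x affected",
    "normal x unknown",
    "affected x unknown",
    "unknown x unknown",
)


def categorize_elbows(y_left: int | None, y_right: int | None) -> ElbowCategory:
    """(0,0)->N, (1,0)->L, (0,1)->R, (1,1)->B; both missing -> UNKNOWN."""
    if y_left is None and y_right is None:
        return ElbowCategory.UNKNOWN
    if y_left is None or y_right is None:
        raise ValueError("one-sided missing elbow status; both sides are evaluated")
    if y_left not in (0, 1) or y_right not in (0, 1):
        raise ValueError("elbow statuses must be 0/1")
    return {
        (0, 0): ElbowCategory.N,
        (1, 0): ElbowCategory.L,
        (0, 1): ElbowCategory.R,
        (1, 1): ElbowCategory.B,
    }[(y_left, y_right)]


@dataclasses.dataclass
class MatingTable:
    """Offspring tallies per (sire category, dam category) cell.

    ``outcome_counts[(s, d)]`` maps offspring category -> count;
    ``outcome_counts_by_sex`` additionally splits by offspring sex.
    ``excluded_unknown_offspring`` counts offspring whose own category is
    UNKNOWN (they contribute to no cell).
    """

    outcome_counts: dict[tuple[ElbowCategory, ElbowCategory], Counter]
    outcome_counts_by_sex: dict[
        tuple[ElbowCategory, ElbowCategory, str], Counter
    ]
    excluded_unknown_offspring: int

    def cell_total(self, sire_cat: ElbowCategory, dam_cat: ElbowCategory) -> int:
        return sum(self.outcome_counts.get((sire_cat, dam_cat), Counter()).values())

    @property
    def grand_total(self) -> int:
        return sum(sum(c.values()) for c in self.outcome_counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in ALL_CATEGORIES:
            for d in ALL_CATEGORIES:
                c = self.outcome_counts.get((s, d), Counter())
                rows.append(
                    {
                        "sire_cat": s.value,
                        "dam_cat": d.value,
                        "n_offspring": sum(c.values()),
                        **{f"offspring_{k.value}": c.get(k, 0) for k in KNOWN_CATEGORIES},
                    }
                )
        return pd.DataFrame(rows)


def count_mating_types(
    phenotypes: list[PhenotypeRecord], ped: Pedigree
) -> MatingTable:
    """Tabulate every phenotyped offspring into one mating-type cell.

    Parent categories come from the parents' own phenotype records;
    unscreened (or unlisted) parents count as UNKNOWN.  Dogs appear both
    as offspring and, where applicable, as parents.
    """
    cat_of: dict[str, ElbowCategory] = {
        p.individual_id: categorize_elbows(p.y_left, p.y_right) for p in phenotypes
    }
    counts: dict[tuple[ElbowCategory, ElbowCategory], Counter] = {}
    by_sex: dict[tuple[ElbowCategory, ElbowCategory, str], Counter] = {}
    excluded = 0
    for p in phenotypes:
        own = cat_of[p.individual_id]
        if own is ElbowCategory.UNKNOWN:
            excluded += 1
            continue
        i = ped.index.get(p.individual_id)
        if i is None:
            raise KeyError(f"phenotyped {p.individual_id!r} not in pedigree")
        rec = ped.records[i]
        scat = cat_of.get(rec.sire_id, ElbowCategory.UNKNOWN) if rec.sire_id else ElbowCategory.UNKNOWN
        dcat = cat_of.get(rec.dam_id, ElbowCategory.UNKNOWN) if rec.dam_id else ElbowCategory.UNKNOWN
        counts.setdefault((scat, dcat), Counter())[own] += 1
        by_sex.setdefault((scat, dcat, p.sex), Counter())[own] += 1
    return MatingTable(
        outcome_counts=counts,
        outcome_counts_by_sex=by_sex,
        excluded_unknown_offspring=excluded,
    )


def _combo(scat: ElbowCategory, dcat: ElbowCategory) -> str:
    def label(c: ElbowCategory) -> str:
        if c is ElbowCategory.UNKNOWN:
            return "unknown"
        return "affected" if c.affected else "normal"

    order = {"normal": 0, "affected": 1, "unknown": 2}
    a, b = sorted((label(scat), label(dcat)), key=order.__getitem__)
    return f"{a} x {b}"


def prevalence_by_parent_combo(table: MatingTable) -> dict[str, float | None]:
    """Offspring dysplasia prevalence by collapsed parent combination.

    Unordered in the parents; combinations with no offspring are ``None``
    (absent), not 0.
    """
    totals: Counter = Counter()
    affected: Counter = Counter()
    for (s, d), c in table.outcome_counts.items():
        combo = _combo(s, d)
        n = sum(c.values())
        totals[combo] += n
        affected[combo] += sum(
            v for k, v in c.items() if k is not ElbowCategory.N
        )
    return {
        combo: (affected[combo] / totals[combo] if totals[combo] > 0 else None)
        for combo in PARENT_COMBOS
    }


@dataclasses.dataclass
class MultinomialFit:
    """Fitted multinomial logistic model of offspring outcome.

    ``fitted_probs`` maps a covariate pattern key -- ``(sire_cat,
    dam_cat)`` or ``(sire_cat, dam_cat, sex)`` -- to a probability vector
    over (N, L, R, B).  ``coefficients`` holds the log-odds parameters vs
    the N baseline; ``dropped`` lists (pattern, outcome) pairs excluded
    for separation (zero observed count in a saturated cell).
    """

    outcomes: tuple[ElbowCategory, ...]
    fitted_probs: dict
    coefficients: pd.DataFrame
    converged: bool
    n_iter: int
    grad_norm: float
    dropped: list
    sex_effect: bool


def _softmax_mle(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 200):
    """Newton-Raphson MLE of a single multinomial's softmax parameters.

    Returns (probabilities, eta vs category 0, iterations, grad norm).
    Counts must all be positive (separation handled by the caller).
    """
    n = counts.sum()
    k = counts.size
    eta = np.zeros(k - 1)  # log-odds vs category 0
    it = 0
    gnorm = np.inf
    for it in range(1, max_iter + 1):
        z = np.concatenate([[0.0], eta])
        z = z - z.max()
        p = np.exp(z)
        p /= p.sum()
        g = counts[1:] - n * p[1:]
        gnorm = float(np.max(np.abs(g)))
        if gnorm < tol * max(1.0, n):
            break
        H = n * (np.diag(p[1:]) - np.outer(p[1:], p[1:]))
        eta = eta + np.linalg.solve(H, g)
    z = np.concatenate([[0.0], eta])
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    return p, eta, it, gnorm


def fit_multinomial_saturated(
    table: MatingTable, sex_effect: bool = False
) -> MultinomialFit:
    """ML multinomial logistic fit of offspring outcome on mating type.

    Without the sex term the likelihood separates over cells (the design
    is a full set of cell indicators), so each cell is fitted by its own
    Newton iteration and the fitted probabilities equal the observed
    outcome proportions.  With ``sex_effect=True`` a shared additive
    offspring-sex coefficient links the cells and a joint Newton-Raphson
    fit is used.

    Outcomes never observed in a cell are dropped from that cell's fit
    domain (probability reported as 0) and listed in ``dropped``: a
    saturated ML fit puts no mass there and the coefficient diverges.
    """
    cells = sorted(table.outcome_counts, key=lambda sd: (sd[0].value, sd[1].value))
    if not cells:
        raise ValueError("empty mating table")
    for sd in cells:
        if sum(table.outcome_counts[sd].values()) < 1:
            raise ValueError("every included mating type needs >= 1 offspring")
    if not sex_effect:
        fitted: dict = {}
        coef_rows = []
        dropped = []
        total_iter = 0
        gmax = 0.0
        for sd in cells:
            c = table.outcome_counts[sd]
            counts = np.array([c.get(k, 0) for k in KNOWN_CATEGORIES], dtype=float)
            nz = counts > 0
            for k, keep in zip(KNOWN_CATEGORIES, nz):
                if not keep:
                    dropped.append((sd, k))
            p_full = np.zeros(4)
            if nz.sum() == 1:
                p_full[nz] = 1.0
                it, gn = 0, 0.0
            else:
                p, _, it, gn = _softmax_mle(counts[nz])
                p_full[nz] = p
            fitted[sd] = p_full
            total_iter = max(total_iter, it)
            gmax = max(gmax, gn)
            base = np.flatnonzero(nz)[0]
            with np.errstate(divide="ignore"):
                logits = np.where(p_full > 0, np.log(p_full / p_full[base]), -np.inf)
            coef_rows.append(
                {
                    "sire_cat": sd[0].value,
                    "dam_cat": sd[1].value,
                    **{
                        f"log_odds_{k.value}": logits[j]
                        for j, k in enumerate(KNOWN_CATEGORIES)
                    },
                }
            )
        return MultinomialFit(
            outcomes=KNOWN_CATEGORIES,
            fitted_probs=fitted,
            coefficients=pd.DataFrame(coef_rows),
            converged=True,
            n_iter=total_iter,
            grad_norm=gmax,
            dropped=dropped,
            sex_effect=False,
        )
    return _fit_with_sex(table, cells)


def _fit_with_sex(table: MatingTable, cells) -> MultinomialFit:
    """Joint Newton-Raphson fit with cell indicators + offspring-sex term."""
    sexes = sorted({k[2] for k in table.outcome_counts_by_sex})
    patterns = []
    Y = []
    for sd in cells:
        for sex in sexes:
            c = table.outcome_counts_by_sex.get((sd[0], sd[1], sex))
            if c:
                patterns.append((sd[0], sd[1], sex))
                Y.append([c.get(k, 0) for k in KNOWN_CATEGORIES])
    Y = np.array(Y, dtype=float)
    n_pat = len(patterns)
    n_cells = len(cells)
    cell_index = {sd: j for j, sd in enumerate(cells)}
    X = np.zeros((n_pat, n_cells + 1))
    for i, (s, d, sex) in enumerate(patterns):
        X[i, cell_index[(s, d)]] = 1.0
        X[i, n_cells] = 1.0 if sex == "M" else 0.0
    n_feat, n_out = X.shape[1], 3  # outcomes L, R, B vs baseline N
    B = np.zeros((n_feat, n_out))
    N_i = Y.sum(axis=1)
    converged = False
    gnorm = np.inf
    it = 0
    for it in range(1, 201):
        eta = X @ B
        Z = np.concatenate([np.zeros((n_pat, 1)), eta], axis=1)
        Z = Z - Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
        G = X.T @ (Y[:, 1:] - N_i[:, None] * P[:, 1:])
        gnorm = float(np.max(np.abs(G)))
        if gnorm < 1e-8 * max(1.0, N_i.sum()):
            converged = True
            break
        H = np.zeros((n_feat * n_out, n_feat * n_out))
        for k in range(n_out):
            for l in range(n_out):
                w = N_i * P[:, k + 1] * ((1.0 if k == l else 0.0) - P[:, l + 1])
                H[k * n_feat:(k + 1) * n_feat, l * n_feat:(l + 1) * n_feat] = (
                    X.T * w
                ) @ X
        try:
            step = np.linalg.solve(
                H + 1e-10 * np.eye(H.shape[0]), G.T.ravel()
            ).reshape(n_out, n_feat).T
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        step = np.clip(step, -10.0, 10.0)  # damp separation runaways
        B = B + step
    eta = X @ B
    Z = np.concatenate([np.zeros((n_pat, 1)), eta], axis=1)
    Z = Z - Z.max(axis=1, keepdims=True)
    P = np.exp(Z)
    P /= P.sum(axis=1, keepdims=True)
    fitted = {pat: P[i] for i, pat in enumerate(patterns)}
    coef = pd.DataFrame(
        B,
        index=[f"cell_{s.value}x{d.value}" for s, d in cells] + ["sex_M"],
        columns=[f"log_odds_{k.value}" for k in KNOWN_CATEGORIES[1:]],
    )
    return MultinomialFit(
        outcomes=KNOWN_CATEGORIES,
        fitted_probs=fitted,
        coefficients=coef,
        converged=converged,
        n_iter=it,
        grad_norm=gnorm,
        dropped=[],
        sex_effect=True,
    )


def predict_progeny_probabilities(
    fit: MultinomialFit,
    sire_cat: ElbowCategory,
    dam_cat: ElbowCategory,
    offspring_sex: str | None = None,
) -> np.ndarray:
    """Probability 4-vector over (N, L, R, B) for a queried mating type.

    Raises ``KeyError`` with a 'no data' message for cells the fit never
    saw -- an empty cell has no estimate, not a zero one.
    """
    key = (
        (sire_cat, dam_cat, offspring_sex)
        if fit.sex_effect
        else (sire_cat, dam_cat)
    )
    if fit.sex_effect and offspring_sex is None:
        raise ValueError("fit includes an offspring-sex term; pass offspring_sex")
    if key not in fit.fitted_probs:
        raise KeyError(f"no data for mating type {key}")
    return np.asarray(fit.fitted_probs[key])


def mating_proportions_by_year(
    phenotypes: list[PhenotypeRecord], ped: Pedigree
) -> pd.DataFrame:
    """Share of normal x normal and normal x affected matings among
    fully-screened matings, per offspring birth year."""
    cat_of = {p.individual_id: categorize_elbows(p.y_left, p.y_right) for p in phenotypes}
    rows: dict[int, Counter] = {}
    for p in phenotypes:
        i = ped.index.get(p.individual_id)
        if i is None:
            continue
        rec = ped.records[i]
        if rec.birth_date is None:
            continue
        scat = cat_of.get(rec.sire_id) if rec.sire_id else None
        dcat = cat_of.get(rec.dam_id) if rec.dam_id else None
        if scat is None or dcat is None:
            continue
        combo = _combo(scat, dcat)
        rows.setdefault(rec.birth_date.year, Counter())[combo] += 1
    out = []
    for year in sorted(rows):
        c = rows[year]
        total = sum(c.values())
        out.append(
            {
                "birth_year": year,
                "n_known_matings": total,
                "prop_normal_x_normal": c["normal x normal"] / total,
                "prop_normal_x_affected": c["normal x affected"] / total,
            }
        )
    return pd.DataFrame(out)
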