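"""Pedigrees and the additive (numerator) relationship matrix.

The additive relationship matrix ``A`` holds the expected fraction of
alleles shared identical-by-descent between every pair of individuals,
scaled so that a non-inbred individual has ``A_ii = 1`` and a
parent/offspring pair has ``A_ij = 0.5``.  It is the covariance kernel of
the animal model: breeding values are assumed to follow
``a ~ N(0, sigma_g^2 * A)``.

Three routes to ``A`` live here:

* the tabular (recursive) method, which is exact and the one used in
  analyses (:func:`build_numerator_relationship_matrix`);
* Henderson/Quaas rules for the sparse-structured inverse ``A^-1``
  accounting for inbreeding (:func:`invert_relationship_matrix`), needed
  by the Gibbs update of the genetic covariance;
* a gene-dropping Monte-Carlo estimator (:func:`gene_drop_oracle`) that
  simulates allele transmission down the pedigree and serves as an
  independent oracle for the other two.

Conventions for incomplete parentage (the data source records many dogs
with only one or no known parent): with a single known parent ``s``,
``A_ij = 0.5 * A_js`` and the diagonal stays at 1 (the unknown parent is
treated as an unrelated non-inbred founder).  Parents that are referenced
but never listed are materialised as founder records.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Iterable, Sequence

import numpy as np

__all__ = [
    "UNKNOWN",
    "PedigreeRecord",
    "Pedigree",
    "RelationshipMatrix",
    "GeneDropEstimate",
    "PedigreeError",
    "topological_sort_pedigree",
    "build_numerator_relationship_matrix",
    "inbreeding_coefficients",
    "mendelian_sampling_scale",
    "invert_relationship_matrix",
    "gene_drop_oracle",
]

#: Sentinel for an unknown parent / sex / date.
UNKNOWN = None


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclasses.dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identity, parent links, sex and birth date.

    ``sire_id``/``dam_id`` are ``None`` when unknown.  ``sex`` is one of
    ``"M"``, ``"F"`` or ``"U"``.
    """

    individual_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "U"
    birth_date: dt.date | None = None

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise PedigreeError("individual_id must be non-empty")
        if self.individual_id in (self.sire_id, self.dam_id):
            raise PedigreeError(
                f"individual {self.individual_id!r} listed as its own parent"
            )
        if self.sex not in ("M", "F", "U"):
            raise PedigreeError(f"invalid sex {self.sex!r}")


@dataclasses.dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree: every parent precedes its offspring.

    Construct via :func:`topological_sort_pedigree`; most downstream code
    relies on the parent-first ordering and on the integer parent position
    arrays (``-1`` encodes an unknown parent).
    """

    records: tuple[PedigreeRecord, ...]
    index: dict[str, int]
    materialized: frozenset[str]
    sire_pos: np.ndarray
    dam_pos: np.ndarray

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.individual_id for r in self.records]

    def position(self, individual_id: str) -> int:
        return self.index[individual_id]

    def is_founder(self, i: int) -> bool:
        return self.sire_pos[i] < 0 and self.dam_pos[i] < 0


@dataclasses.dataclass(frozen=True)
class RelationshipMatrix:
    """Dense symmetric additive relationship matrix with row labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("labels and matrix shape disagree")

    def loc(self, a: str, b: str) -> float:
        i = self.labels.index(a)
        j = self.labels.index(b)
        return float(self.values[i, j])


@dataclasses.dataclass(frozen=True)
class GeneDropEstimate:
    """Monte-Carlo estimate of A with per-entry standard errors."""

    labels: tuple[str, ...]
    values: np.ndarray
    standard_errors: np.ndarray
    n_drops: int


def topological_sort_pedigree(records: Iterable[PedigreeRecord]) -> Pedigree:
    """Order records parent-first, materialising unlisted parents as founders.

    Parameters
    ----------
    records
        Any iterable of :class:`PedigreeRecord`.  Parents referenced but not
        listed are added as founder records (sex inferred from the role they
        appear in, ``U`` if they appear as both sire and dam).

    Raises
    ------
    PedigreeError
        On duplicate identifiers or a directed cycle through parent links;
        the cycle error message contains the offending identifier chain.
    """
    recs = list(records)
    by_id: dict[str, PedigreeRecord] = {}
    for r in recs:
        if r.individual_id in by_id:
            raise PedigreeError(f"duplicate individual_id {r.individual_id!r}")
        by_id[r.individual_id] = r

    as_sire: set[str] = set()
    as_dam: set[str] = set()
    for r in recs:
        if r.sire_id is not None:
            as_sire.add(r.sire_id)
        if r.dam_id is not None:
            as_dam.add(r.dam_id)
    materialized = (as_sire | as_dam) - set(by_id)
    for pid in sorted(materialized):
        sex = "U" if (pid in as_sire and pid in as_dam) else ("M" if pid in as_sire else "F")
        by_id[pid] = PedigreeRecord(pid, sex=sex)

    # Iterative DFS with an explicit path so cycles report the chain.
    order: list[str] = []
    state: dict[str, int] = {}  # 0 = visiting, 1 = done
    for root in by_id:
        if root in state:
            continue
        stack: list[tuple[str, int]] = [(root, 0)]
        path: list[str] = []
        while stack:
            node, phase = stack.pop()
            if phase == 0:
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    cycle = path[path.index(node):] + [node]
                    raise PedigreeError("pedigree cycle: " + " -> ".join(cycle))
                state[node] = 0
                path.append(node)
                stack.append((node, 1))
                r = by_id[node]
                for parent in (r.sire_id, r.dam_id):
                    if parent is not None and state.get(parent) != 1:
                        if state.get(parent) == 0:
                            cycle = path[path.index(parent):] + [parent]
                            raise PedigreeError(
                                "pedigree cycle: " + " -> ".join(cycle)
                            )
                        stack.append((parent, 0))
            else:
                state[node] = 1
                path.pop()
                order.append(node)

    ordered = tuple(by_id[i] for i in order)
    index = {r.individual_id: k for k, r in enumerate(ordered)}
    sire_pos = np.array(
        [index[r.sire_id] if r.sire_id is not None else -1 for r in ordered],
        dtype=np.int64,
    )
    dam_pos = np.array(
        [index[r.dam_id] if r.dam_id is not None else -1 for r in ordered],
        dtype=np.int64,
    )
    return Pedigree(
        records=ordered,
        index=index,
        materialized=frozenset(materialized),
        sire_pos=sire_pos,
        dam_pos=dam_pos,
    )


def _check_sorted(ped: Pedigree) -> None:
    ar = np.arange(len(ped))
    if np.any(ped.sire_pos >= ar) or np.any(ped.dam_pos >= ar):
        raise PedigreeError("pedigree is not parent-first ordered")


def build_numerator_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method A.

    Recurrence (parent-first order, summing only known parents):
    ``A_ij = (A_j,s(i) + A_j,d(i)) / 2`` for ``j < i`` and
    ``A_ii = 1 + A_s(i),d(i) / 2`` when both parents are known, else 1.
    """
    _check_sorted(ped)
    q = len(ped)
    A = np.zeros((q, q))
    for i in range(q):
        s, d = ped.sire_pos[i], ped.dam_pos[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(labels=tuple(ped.labels), values=A)


def inbreeding_coefficients(A: RelationshipMatrix) -> np.ndarray:
    """Per-individual inbreeding coefficient ``F_i = A_ii - 1``."""
    F = np.diag(A.values) - 1.0
    if np.any(F < -1e-12) or np.any(F > 1.0 + 1e-12):
        raise ValueError("diagonal of A outside [1, 2]; not a relationship matrix")
    return np.clip(F, 0.0, 1.0)


def mendelian_sampling_scale(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Variance multipliers d_i of the Mendelian-sampling deviation.

    Quaas form: both parents known -> ``0.5 - 0.25 (F_s + F_d)``; one known
    parent ``p`` -> ``0.75 - 0.25 F_p``; founders -> 1.  These are exactly
    the scalars that make the recursive simulation of breeding values match
    the tabular A, and the weights of the Henderson A-inverse rules.
    """
    _check_sorted(ped)
    if len(F) != len(ped):
        raise ValueError("F length does not match pedigree")
    d = np.ones(len(ped))
    for i in range(len(ped)):
        s, dm = ped.sire_pos[i], ped.dam_pos[i]
        if s >= 0 and dm >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s >= 0 or dm >= 0:
            p = s if s >= 0 else dm
            d[i] = 0.75 - 0.25 * F[p]
    return d


def invert_relationship_matrix(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """A-inverse by Henderson's rules with Quaas inbreeding adjustment.

    ``A^-1 = sum_i (1/d_i) w_i w_i^T`` where ``w_i`` has 1 at ``i`` and
    -1/2 at each known parent, and ``d_i`` is the Mendelian-sampling
    variance multiplier.  Exact for any pedigree under the single-parent
    convention used by the tabular builder.
    """
    d = mendelian_sampling_scale(ped, F)  # validates sortedness / length
    if np.any(d <= 0):
        raise PedigreeError("non-positive Mendelian sampling variance; invalid F")
    q = len(ped)
    Ainv = np.zeros((q, q))
    for i in range(q):
        w = 1.0 / d[i]
        s, dm = ped.sire_pos[i], ped.dam_pos[i]
        Ainv[i, i] += w
        for p in (s, dm):
            if p >= 0:
                Ainv[p, i] -= 0.5 * w
                Ainv[i, p] -= 0.5 * w
        if s >= 0:
            Ainv[s, s] += 0.25 * w
            if dm >= 0:
                Ainv[s, dm] += 0.25 * w
                Ainv[dm, s] += 0.25 * w
        if dm >= 0:
            Ainv[dm, dm] += 0.25 * w
    return Ainv


def gene_drop_oracle(ped: Pedigree, n_drops: int, seed: int) -> GeneDropEstimate:
    """Estimate A by gene dropping.

    Every founder (and every unknown-parent slot) receives unique alleles;
    each individual inherits one allele at random from each parent,
    independently across ``n_drops`` replicates.  The additive relationship
    is twice the coancestry: the probability that alleles sampled at random
    from the two individuals are identical by descent.  Per-entry standard
    errors are the Monte-Carlo SEs of the replicate means (exactly related
    pairs, e.g. an individual with itself at the diagonal when non-inbred,
    have SE 0).
    """
    _check_sorted(ped)
    if n_drops < 1:
        raise ValueError("n_drops must be >= 1")
    rng = np.random.default_rng(seed)
    q = len(ped)
    # allele codes: founders/unknown slots get globally unique codes
    pat = np.empty((q, n_drops), dtype=np.int64)
    mat = np.empty((q, n_drops), dtype=np.int64)
    next_code = 0
    for i in range(q):
        s, d = ped.sire_pos[i], ped.dam_pos[i]
        if s >= 0:
            pick = rng.integers(0, 2, size=n_drops, dtype=np.int8)
            pat[i] = np.where(pick == 0, pat[s], mat[s])
        else:
            pat[i] = next_code  # phantom founder: unique, shared with nobody
            next_code += 1
        if d >= 0:
            pick = rng.integers(0, 2, size=n_drops, dtype=np.int8)
            mat[i] = np.where(pick == 0, pat[d], mat[d])
        else:
            mat[i] = next_code
            next_code += 1

    values = np.zeros((q, q))
    ses = np.zeros((q, q))
    inv_sqrt_n = 1.0 / np.sqrt(n_drops)
    for i in range(q):
        # diagonal: A_ii = 1 + P(paternal IBD maternal)
        k_ii = 1.0 + (pat[i] == mat[i])
        values[i, i] = k_ii.mean()
        ses[i, i] = k_ii.std(ddof=1) * inv_sqrt_n if n_drops > 1 else 0.0
        for j in range(i):
            k = 0.5 * (
                (pat[i] == pat[j]).astype(np.float64)
                + (pat[i] == mat[j])
                + (mat[i] == pat[j])
                + (mat[i] == mat[j])
            )
            values[i, j] = values[j, i] = k.mean()
            se = k.std(ddof=1) * inv_sqrt_n if n_drops > 1 else 0.0
            ses[i, j] = ses[j, i] = se
    return GeneDropEstimate(
        labels=tuple(ped.labels), values=values, standard_errors=ses, n_drops=n_drops
    )


def records_from_dataframe(df) -> list[PedigreeRecord]:
    """Build records from a pedigree table with columns id/sire/dam/sex/birth_date."""
    recs = []
    for row in df.itertuples(index=False):
        bd = getattr(row, "birth_date", None)
        if bd is not None and not isinstance(bd, dt.date):
            bd = dt.date.fromisoformat(str(bd)) if str(bd) not in ("", "nan", "NaT") else None
        recs.append(
            PedigreeRecord(
                individual_id=str(row.id),
                sire_id=_none_if_blank(getattr(row, "sire", None)),
                dam_id=_none_if_blank(getattr(row, "dam", None)),
                sex=str(getattr(row, "sex", "U") or "U"),
                birth_date=bd,
            )
        )
    return recs


def _none_if_blank(v) -> str | None:
    if v is None:
        return None
    s = str(v)
    if s == "" or s.lower() == "nan":
        return None
    return s
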