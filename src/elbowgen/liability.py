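"""Bivariate logit liability model for left/right elbow status.

Each elbow is a Bernoulli trait.  The disease probability of dog *j* for
trait *t* (R = right, L = left) is modelled through its log-odds

    theta_tj = mu_t + beta_t * (age_j - age_offset) + sex_t[sex_j]
               + a_tj + e_tj,

where ``a`` is the additive genetic (breeding) value with prior
``(a_R, a_L) ~ N(0, G (x) A)`` over the pedigree, and ``e`` is a latent
overdispersion residual with fixed unit prior variance per trait and no
cross-trait covariance.  On this scale the heritability of a trait is
``h2 = var_g / (var_g + 1)`` and the genetic correlation is
``rg = cov_gRL / sqrt(var_gR * var_gL)``.

Priors: diffuse independent normals for every fixed effect (variance
1e10 by default) and an inverse-Wishart for the 2x2 genetic covariance
``G`` with scale ``V = I`` and ``n = 3`` degrees of freedom, which makes
the implied marginal prior on ``rg`` uniform on [-1, 1].
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
from scipy.special import multigammaln

__all__ = [
    "PhenotypeRecord",
    "FixedEffects",
    "GeneticCovariance",
    "LatentState",
    "PriorSpec",
    "AGE_OFFSET",
    "linear_predictor",
    "bernoulli_loglikelihood",
    "bernoulli_loglik_array",
    "integrated_bernoulli_loglik",
    "heritability_from_variance",
    "genetic_correlation",
    "inverse_wishart_logpdf",
    "log_prior_density",
]

TRAITS = ("R", "L")

#: Age is entered as (age_months - AGE_OFFSET): offset at the 24-month
#: screening-eligibility minimum so the intercept refers to the youngest
#: eligible dog rather than an unobservable age-0 animal.
AGE_OFFSET = 24.0


@dataclasses.dataclass(frozen=True)
class PhenotypeRecord:
    """One screened dog: binary status per elbow plus covariates."""

    individual_id: str
    y_left: int
    y_right: int
    sex: str
    age_months: float
    breed: str = ""
    eval_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.y_left not in (0, 1) or self.y_right not in (0, 1):
            raise ValueError("elbow statuses must be 0 or 1")
        if self.age_months < 24:
            raise ValueError("age_months must be >= 24 (screening eligibility)")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")

    def y(self, trait: str) -> int:
        return self.y_right if trait == "R" else self.y_left


@dataclasses.dataclass
class FixedEffects:
    """Trait-specific intercept, age slope and sex contribution.

    The sex effect uses females as the reference level (sex_F = 0); the
    stored value is the male contribution.  This removes the confounding
    between an unconstrained per-sex term and the intercept without
    changing the model.
    """

    mu_r: float = 0.0
    mu_l: float = 0.0
    beta_r: float = 0.0
    beta_l: float = 0.0
    sex_m_r: float = 0.0
    sex_m_l: float = 0.0

    def mu(self, trait: str) -> float:
        return self.mu_r if trait == "R" else self.mu_l

    def beta(self, trait: str) -> float:
        return self.beta_r if trait == "R" else self.beta_l

    def sex_effect(self, trait: str, sex: str) -> float:
        if sex == "F":
            return 0.0
        return self.sex_m_r if trait == "R" else self.sex_m_l

    def as_array(self) -> np.ndarray:
        """(2, 3) array, rows (R, L), columns (mu, beta, sex_M)."""
        return np.array(
            [
                [self.mu_r, self.beta_r, self.sex_m_r],
                [self.mu_l, self.beta_l, self.sex_m_l],
            ]
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "FixedEffects":
        return cls(
            mu_r=float(arr[0, 0]), beta_r=float(arr[0, 1]), sex_m_r=float(arr[0, 2]),
            mu_l=float(arr[1, 0]), beta_l=float(arr[1, 1]), sex_m_l=float(arr[1, 2]),
        )


@dataclasses.dataclass(frozen=True)
class GeneticCovariance:
    """2x2 additive genetic covariance on the latent logit scale."""

    var_r: float
    var_l: float
    cov_rl: float

    def __post_init__(self) -> None:
        if self.var_r < 0 or self.var_l < 0:
            raise ValueError("genetic variances must be non-negative")
        if self.cov_rl**2 > self.var_r * self.var_l * (1 + 1e-12) + 1e-300:
            raise ValueError("covariance violates Cauchy-Schwarz; G not PSD")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.var_r, self.cov_rl], [self.cov_rl, self.var_l]])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "GeneticCovariance":
        m = np.asarray(m, dtype=float)
        if m.shape != (2, 2) or abs(m[0, 1] - m[1, 0]) > 1e-8 * (1 + abs(m[0, 1])):
            raise ValueError("G must be a symmetric 2x2 matrix")
        return cls(var_r=float(m[0, 0]), var_l=float(m[1, 1]),
                   cov_rl=float(0.5 * (m[0, 1] + m[1, 0])))

    @property
    def h2_r(self) -> float:
        return heritability_from_variance(self.var_r)

    @property
    def h2_l(self) -> float:
        return heritability_from_variance(self.var_l)

    @property
    def rg(self) -> float:
        return genetic_correlation(self)


@dataclasses.dataclass
class LatentState:
    """Breeding values over the pedigree and residuals over phenotyped dogs.

    ``a`` is (q, 2) over all pedigree individuals, ``e`` is (n, 2) over
    phenotyped individuals; column 0 = right, column 1 = left.  ``index``
    maps individual id -> pedigree row, ``obs_index`` maps id -> residual
    row.
    """

    a: np.ndarray
    e: np.ndarray
    index: dict[str, int]
    obs_index: dict[str, int]

    def __post_init__(self) -> None:
        if self.a.shape != (len(self.index), 2):
            raise ValueError("a must be (n_pedigree, 2)")
        if self.e.shape != (len(self.obs_index), 2):
            raise ValueError("e must be (n_phenotyped, 2)")

    @classmethod
    def zeros(cls, pedigree_ids, phenotyped_ids) -> "LatentState":
        index = {s: i for i, s in enumerate(pedigree_ids)}
        obs = {s: i for i, s in enumerate(phenotyped_ids)}
        return cls(a=np.zeros((len(index), 2)), e=np.zeros((len(obs), 2)),
                   index=index, obs_index=obs)


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters: diffuse-normal fixed effects, IW genetic covariance."""

    fixed_effect_variance: float = 1e10
    iw_scale: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(2))
    iw_df: float = 3.0

    def __post_init__(self) -> None:
        if self.fixed_effect_variance <= 0:
            raise ValueError("fixed_effect_variance must be positive")
        V = np.asarray(self.iw_scale, dtype=float)
        if V.shape != (2, 2) or np.any(np.linalg.eigvalsh(V) < -1e-12):
            raise ValueError("iw_scale must be a PSD 2x2 matrix")
        if self.iw_df <= V.shape[0] - 1:
            raise ValueError("iw_df must exceed dimension - 1")


def _trait_col(trait: str) -> int:
    if trait not in TRAITS:
        raise ValueError(f"trait must be one of {TRAITS}")
    return 0 if trait == "R" else 1


def linear_predictor(
    fx: FixedEffects,
    state: LatentState,
    rec: PhenotypeRecord,
    trait: str,
    age_offset: float = AGE_OFFSET,
) -> float:
    """Logit-scale linear predictor theta for one dog and one trait."""
    t = _trait_col(trait)
    if rec.individual_id not in state.index:
        raise KeyError(f"individual {rec.individual_id!r} not in pedigree state")
    i = state.index[rec.individual_id]
    j = state.obs_index[rec.individual_id]
    return (
        fx.mu(trait)
        + fx.beta(trait) * (rec.age_months - age_offset)
        + fx.sex_effect(trait, rec.sex)
        + state.a[i, t]
        + state.e[j, t]
    )


def bernoulli_loglik_array(theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Elementwise Bernoulli log-likelihood of logits theta for outcomes y.

    Numerically stable: log p(y|theta) = -log(1 + exp((1-2y) theta)).
    """
    sign = 1.0 - 2.0 * np.asarray(y, dtype=float)
    return -np.logaddexp(0.0, sign * np.asarray(theta, dtype=float))


def bernoulli_loglikelihood(
    fx: FixedEffects,
    state: LatentState,
    records,
    age_offset: float = AGE_OFFSET,
) -> float:
    """Total log-likelihood over all records and both traits."""
    total = 0.0
    for rec in records:
        for trait in TRAITS:
            th = linear_predictor(fx, state, rec, trait, age_offset)
            total += float(bernoulli_loglik_array(np.array(th), np.array(rec.y(trait))))
    return total


class _IntegratedLogitTable:
    """Tabulated log-likelihood of the logistic link convolved with the
    unit-variance residual.

    The model's latent residual e ~ N(0, 1) enters the linear predictor
    additively, so the likelihood of an outcome given the rest of the
    predictor, theta_bar, is the smooth monotone function

        P1(theta_bar) = E_e[ logistic(theta_bar + e) ].

    Marginalising e this way is exact (Gauss-Hermite quadrature on a dense
    grid with linear interpolation between knots) and lets samplers avoid
    carrying one residual per observation.
    """

    def __init__(self, lo: float = -60.0, hi: float = 60.0, step: float = 0.01,
                 n_nodes: int = 101) -> None:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
        logw = np.log(weights) - 0.5 * np.log(2 * np.pi)
        self.grid = np.arange(lo, hi + step, step)
        z = self.grid[:, None] + nodes[None, :]
        # log P1 and log(1 - P1) by logsumexp over quadrature nodes
        from scipy.special import logsumexp

        self.log_p1 = logsumexp(logw[None, :] - np.logaddexp(0.0, -z), axis=1)
        log_p0 = logsumexp(logw[None, :] - np.logaddexp(0.0, z), axis=1)
        # symmetry used by log_p1_at: P0(m) = P1(-m)
        assert np.allclose(log_p0, self.log_p1[::-1], atol=1e-10)

        self._lo = float(self.grid[0])
        self._inv_step = 1.0 / step
        self._nmax = self.grid.size - 2

    def log_p1_at(self, z: np.ndarray) -> np.ndarray:
        """log P1 evaluated by uniform-grid linear interpolation.

        By the symmetry of the logistic link and the residual,
        ``log P0(m) = log P1(-m)``, so this single table serves both
        outcomes: the log-likelihood of outcome y at theta_bar is
        ``log_p1_at((2 y - 1) * theta_bar)``.
        """
        u = (np.asarray(z, dtype=float) - self._lo) * self._inv_step
        u = np.clip(u, 0.0, float(self._nmax))
        i = u.astype(np.int64)
        frac = u - i
        tab = self.log_p1
        return tab[i] * (1.0 - frac) + tab[i + 1] * frac

    def loglik(self, theta_bar: np.ndarray, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return self.log_p1_at((2.0 * y - 1.0) * np.asarray(theta_bar, dtype=float))

    def prob(self, theta_bar: np.ndarray) -> np.ndarray:
        return np.exp(self.log_p1_at(np.asarray(theta_bar, dtype=float)))


_INTEGRATED_TABLE: _IntegratedLogitTable | None = None


def get_integrated_table() -> _IntegratedLogitTable:
    global _INTEGRATED_TABLE
    if _INTEGRATED_TABLE is None:
        _INTEGRATED_TABLE = _IntegratedLogitTable()
    return _INTEGRATED_TABLE


def integrated_bernoulli_loglik(theta_bar: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bernoulli log-likelihood with the unit-normal residual integrated out.

    ``theta_bar`` is the linear predictor *without* the residual term.
    """
    return get_integrated_table().loglik(theta_bar, y)


def heritability_from_variance(var_g: float) -> float:
    """Logit-scale heritability h2 = var_g / (var_g + 1).

    The residual variance is fixed at 1 on the latent scale, so this ratio
    is reported exactly as defined, without adding the logistic link
    variance pi^2/3.
    """
    if var_g < 0:
        raise ValueError("genetic variance must be non-negative")
    return var_g / (var_g + 1.0)


def genetic_correlation(G: GeneticCovariance) -> float:
    """rg = cov / sqrt(var_R * var_L); undefined when a variance is zero."""
    if G.var_r <= 0 or G.var_l <= 0:
        raise ZeroDivisionError("undefined correlation: a genetic variance is zero")
    return G.cov_rl / np.sqrt(G.var_r * G.var_l)


def inverse_wishart_logpdf(X: np.ndarray, scale: np.ndarray, df: float) -> float:
    """Log density of the inverse-Wishart IW(scale, df) at X (standard form).

    f(X) = |scale|^(df/2) / (2^(df p / 2) Gamma_p(df/2))
           * |X|^-((df+p+1)/2) * exp(-tr(scale X^-1)/2)
    """
    X = np.asarray(X, dtype=float)
    V = np.asarray(scale, dtype=float)
    p = X.shape[0]
    sign, logdet_x = np.linalg.slogdet(X)
    if sign <= 0:
        return -np.inf
    _, logdet_v = np.linalg.slogdet(V)
    tr = float(np.trace(np.linalg.solve(X, V)))
    return (
        0.5 * df * logdet_v
        - 0.5 * df * p * np.log(2.0)
        - multigammaln(0.5 * df, p)
        - 0.5 * (df + p + 1) * logdet_x
        - 0.5 * tr
    )


def log_prior_density(fx: FixedEffects, G: GeneticCovariance, prior: PriorSpec) -> float:
    """Joint log prior of the fixed effects and genetic covariance.

    Independent N(0, fixed_effect_variance) for each fixed effect plus the
    inverse-Wishart for G; -inf for non-PSD G.
    """
    v = prior.fixed_effect_variance
    vals = fx.as_array().ravel()
    normal_part = float(
        np.sum(-0.5 * np.log(2 * np.pi * v) - 0.5 * vals**2 / v)
    )
    Gm = G.matrix
    if np.any(np.linalg.eigvalsh(Gm) <= 0):
        return -np.inf
    return normal_part + inverse_wishart_logpdf(Gm, prior.iw_scale, prior.iw_df)
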