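"""Metropolis-within-Gibbs sampler for the bivariate logit animal model.

The unit-variance latent residual ``e`` is integrated out of the
likelihood analytically (a logistic link convolved with a standard
normal, tabulated once), so the sampled state is the fixed effects, the
breeding values ``a`` and the 2x2 genetic covariance ``G``.  This is the
same model -- the marginal posterior of (fixed effects, a, G) is
identical to the one with ``e`` carried explicitly -- but removes the
``a_i + e_i`` ridge along which an explicit-residual chain mixes
pathologically slowly.

Update blocks:

* adaptive single-site Gaussian random-walk Metropolis for every fixed
  effect and every breeding value (target acceptance 0.44, adaptation
  frozen at the end of warm-up so the retained chain is a fixed-kernel
  Markov chain);
* global scaling and shear moves on ``(a, G)`` jointly, constructed so
  the Gaussian ``N(0, G (x) A)`` prior is exactly invariant; these let
  the genetic variances and covariance traverse the posterior in O(1)
  steps rather than by a q-dimensional random walk;
* a conjugate Gibbs draw for ``G``: with ``W = [a_R a_L]`` (q x 2) the
  full conditional is ``IW(V + W' A^-1 W, n + q)``.

Breeding-value sites are updated one at a time mathematically, but
executed in vectorised batches over colour classes of the ``A^-1``
sparsity graph: sites in one class have ``A^-1_ij = 0``, hence
conditionally independent full conditionals, so their single-site
accept/reject decisions can be made simultaneously.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .liability import (
    AGE_OFFSET,
    PhenotypeRecord,
    PriorSpec,
    get_integrated_table,
)
from .pedigree import (
    Pedigree,
    build_numerator_relationship_matrix,
    inbreeding_coefficients,
    invert_relationship_matrix,
)

__all__ = [
    "ChainConfig",
    "Chain",
    "PosteriorSummary",
    "MetropolisWithinGibbs",
    "run_chain",
    "update_genetic_covariance",
    "thin_and_burn",
    "chain_diagnostics",
    "summarize_posterior",
    "sample_prior_genetic_correlation",
    "effective_sample_size",
    "lag1_autocorrelation",
]

#: Lag-1 autocorrelation screening bound applied to retained samples.
AUTOCORR_BOUND = 0.03
#: Genetic correlation above which the two elbows behave as repeated
#: measures of a single trait.
REPEATED_MEASURES_THRESHOLD = 0.95


@dataclasses.dataclass
class ChainConfig:
    """Chain schedule and sampler options.

    The registry-scale default (200,000 iterations, 50,000 warm-up, thin
    100) retains exactly 1,500 samples; :meth:`desk` gives a schedule
    sized for workstation reruns.
    """

    n_total: int = 200_000
    burn_in: int = 50_000
    thin: int = 100
    seed: int = 0
    target_accept: float = 0.44
    initial_scale: float = 0.3
    adapt: bool = True
    store_breeding_values: bool = False
    sample_latents: bool = True
    sample_covariance: bool = True
    recompute_stride: int = 50
    #: repetitions per iteration of the cheap global scaling/shear moves
    #: that mix the latent scale (hence the variance components)
    mix_reps: int = 20
    #: breeding-value site sweeps per iteration; extra sweeps shorten the
    #: autocorrelation time of the genetic variances
    a_sweeps: int = 4

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.burn_in >= self.n_total:
            raise ValueError("need 0 <= burn_in < n_total")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_total - self.burn_in) // self.thin

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "ChainConfig":
        kw.setdefault("n_total", 20_000)
        kw.setdefault("burn_in", 5_000)
        kw.setdefault("thin", 50)
        return cls(seed=seed, **kw)


@dataclasses.dataclass
class Chain:
    """Retained (post warm-up, thinned) samples of every scalar unknown."""

    config: ChainConfig
    pedigree_labels: tuple[str, ...]
    phenotyped_ids: tuple[str, ...]
    fx_samples: np.ndarray  # (m, 2, 3): trait (R, L) x (mu, beta, sexM)
    G_samples: np.ndarray  # (m, 2, 2)
    a_samples: np.ndarray | None  # (m, q, 2) if stored
    accept_rates: dict[str, float]

    def __len__(self) -> int:
        return self.fx_samples.shape[0]

    @property
    def var_r(self) -> np.ndarray:
        return self.G_samples[:, 0, 0]

    @property
    def var_l(self) -> np.ndarray:
        return self.G_samples[:, 1, 1]

    @property
    def cov_rl(self) -> np.ndarray:
        return self.G_samples[:, 0, 1]

    def to_dataframe(self) -> pd.DataFrame:
        m = len(self)
        df = pd.DataFrame(
            {
                "mu_R": self.fx_samples[:, 0, 0],
                "beta_R": self.fx_samples[:, 0, 1],
                "sexM_R": self.fx_samples[:, 0, 2],
                "mu_L": self.fx_samples[:, 1, 0],
                "beta_L": self.fx_samples[:, 1, 1],
                "sexM_L": self.fx_samples[:, 1, 2],
                "var_gR": self.var_r,
                "var_gL": self.var_l,
                "cov_gRL": self.cov_rl,
            },
            index=pd.RangeIndex(m, name="sample"),
        )
        df["h2_R"] = df["var_gR"] / (df["var_gR"] + 1.0)
        df["h2_L"] = df["var_gL"] / (df["var_gL"] + 1.0)
        df["rg"] = df["cov_gRL"] / np.sqrt(df["var_gR"] * df["var_gL"])
        return df

    def mean_breeding_values(self) -> np.ndarray:
        """(q, 2) posterior-mean EBVs; requires store_breeding_values."""
        if self.a_samples is None:
            raise ValueError("chain did not store breeding values")
        return self.a_samples.mean(axis=0)


class MetropolisWithinGibbs:
    """One full model fit's worth of sampler state.

    Most users call :func:`run_chain`; the class is exposed so the update
    blocks can be exercised and verified in isolation.  The linear
    predictor cache ``theta`` excludes the integrated-out residual.
    """

    def __init__(
        self,
        ped: Pedigree,
        records: list[PhenotypeRecord],
        prior: PriorSpec,
        config: ChainConfig,
    ) -> None:
        self.ped = ped
        self.prior = prior
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        q = len(ped)
        self.q = q

        A = build_numerator_relationship_matrix(ped)
        try:
            np.linalg.cholesky(A.values + 0.0)
        except np.linalg.LinAlgError as exc:
            raise ValueError("relationship matrix is not positive definite") from exc
        F = inbreeding_coefficients(A)
        self.Ainv = invert_relationship_matrix(ped, F)
        self.Ainv_diag = np.diag(self.Ainv).copy()
        self.Ainv_rowsum = self.Ainv.sum(axis=1)
        self.ones_Ainv_ones = float(self.Ainv_rowsum.sum())
        self.colour_classes = _colour_classes(self.Ainv)
        # contiguous (q, |C|) column blocks of A^-1 per colour class, so the
        # maintained product M = A^-1 W updates by one dense matmul per class
        self.Ainv_blocks = [
            np.ascontiguousarray(self.Ainv[:, C]) for C in self.colour_classes
        ]

        seen: set[str] = set()
        for r in records:
            if r.individual_id in seen:
                raise ValueError(f"duplicate phenotype for {r.individual_id!r}")
            if r.individual_id not in ped.index:
                raise ValueError(f"phenotyped {r.individual_id!r} missing from pedigree")
            seen.add(r.individual_id)
        self.records = list(records)
        n = len(records)
        self.n = n
        self.pos = np.array([ped.index[r.individual_id] for r in records], dtype=np.int64)
        self.y = np.array(
            [[r.y_right, r.y_left] for r in records], dtype=float
        ).reshape(n, 2)
        age_c = np.array([r.age_months - AGE_OFFSET for r in records])
        male = np.array([1.0 if r.sex == "M" else 0.0 for r in records])
        self.X = np.column_stack([np.ones(n), age_c, male])  # shared across traits
        # pedigree row -> phenotype row (-1 when unphenotyped)
        self.obs_row = np.full(q, -1, dtype=np.int64)
        self.obs_row[self.pos] = np.arange(n)

        # state
        self.table = get_integrated_table()
        self.ysign = 2.0 * self.y - 1.0
        self.fx = np.zeros((2, 3))
        self.a = np.zeros((q, 2))
        self.G = np.asarray(prior.iw_scale, dtype=float).copy()
        self.K = _inv2(self.G)
        self.M = self.Ainv @ self.a
        self.theta = self._full_theta()
        self.ll = self._full_ll()

        # adaptive proposal scales (log-adapted towards target_accept)
        s0 = config.initial_scale
        self.s_fx = np.full((2, 3), s0)
        self.s_a = np.full((q, 2), s0)
        self.s_tr_a = np.full(2, s0 * 0.3)
        self.s_scale = np.full(2, 0.05)
        self.s_shear = np.full(2, 0.05)

        self._acc: dict[str, list[float]] = {
            k: [0.0, 0.0] for k in ("fx", "a", "trans", "mix")
        }

    # ----- helpers -------------------------------------------------------

    def _full_theta(self) -> np.ndarray:
        th = np.empty((self.n, 2))
        for t in range(2):
            th[:, t] = self.X @ self.fx[t] + self.a[self.pos, t]
        return th

    def _full_ll(self) -> np.ndarray:
        """Cached per-observation log-likelihood at the current theta."""
        return self.table.log_p1_at(self.ysign * self.theta)

    def _count(self, family: str, acc: float, tries: float, post_burn: bool) -> None:
        if post_burn:
            rec = self._acc[family]
            rec[0] += acc
            rec[1] += tries

    # ----- update blocks -------------------------------------------------

    def _update_fixed_effects(self, adapt: bool, post_burn: bool, gamma: float) -> None:
        """Single-site adaptive random-walk Metropolis on the six fixed effects."""
        rng = self.rng
        v_fx = self.prior.fixed_effect_variance
        for t in range(2):
            for p in range(3):
                delta = self.s_fx[t, p] * rng.standard_normal()
                x = self.X[:, p]
                th_new = self.theta[:, t] + delta * x
                ll_new = self.table.log_p1_at(self.ysign[:, t] * th_new)
                dll = float(ll_new.sum() - self.ll[:, t].sum())
                old = self.fx[t, p]
                dlp = -((old + delta) ** 2 - old**2) / (2.0 * v_fx)
                acc = np.log(rng.random()) < dll + dlp
                if acc:
                    self.fx[t, p] = old + delta
                    self.theta[:, t] = th_new
                    self.ll[:, t] = ll_new
                self._count("fx", float(acc), 1.0, post_burn)
                if adapt:
                    self.s_fx[t, p] *= np.exp(
                        gamma * (float(acc) - self.config.target_accept)
                    )

    def update_location_effects(self, adapt: bool, post_burn: bool, gamma: float) -> None:
        """One sweep of all Metropolis location updates (fx, a, global moves)."""
        rng = self.rng
        self._update_fixed_effects(adapt, post_burn, gamma)

        # breeding values: single-site over colour classes, vectorised
        for _ in range(self.config.a_sweeps):
            for t in range(2):
                ktt = self.K[t, t]
                for C, Ablk in zip(self.colour_classes, self.Ainv_blocks):
                    delta = self.s_a[C, t] * rng.standard_normal(C.size)
                    mk = self.M[C] @ self.K[:, t]
                    dlp = -0.5 * (
                        2.0 * delta * mk + delta**2 * self.Ainv_diag[C] * ktt
                    )
                    dll = np.zeros(C.size)
                    rows = self.obs_row[C]
                    m = rows >= 0
                    r = rows[m]
                    if r.size:
                        zs = self.ysign[r, t]
                        ll_new = self.table.log_p1_at(
                            zs * (self.theta[r, t] + delta[m])
                        )
                        dll[m] = ll_new - self.ll[r, t]
                    acc = np.log(rng.random(C.size)) < dll + dlp
                    d_eff = np.where(acc, delta, 0.0)
                    self.a[C, t] += d_eff
                    self.M[:, t] += Ablk @ d_eff
                    if r.size:
                        acc_m = acc[m]
                        self.theta[r, t] += d_eff[m]
                        self.ll[r, t] = np.where(acc_m, ll_new, self.ll[r, t])
                    self._count("a", float(acc.sum()), float(C.size), post_burn)
                    if adapt:
                        self.s_a[C, t] *= np.exp(
                            gamma * (acc.astype(float) - self.config.target_accept)
                        )

        # intercept <-> mean breeding value translation (likelihood invariant)
        v_fx = self.prior.fixed_effect_variance
        for t in range(2):
            delta = self.s_tr_a[t] * rng.standard_normal()
            mu = self.fx[t, 0]
            msum_k = float(self.M.sum(axis=0) @ self.K[:, t])
            dlp_a = -0.5 * (
                -2.0 * delta * msum_k + delta**2 * self.ones_Ainv_ones * self.K[t, t]
            )
            dlp = dlp_a - ((mu + delta) ** 2 - mu**2) / (2.0 * v_fx)
            # theta is unchanged: every phenotyped dog carries an a term
            acc = np.log(rng.random()) < dlp
            if acc:
                self.fx[t, 0] = mu + delta
                self.a[:, t] -= delta
                self.M[:, t] -= delta * self.Ainv_rowsum
            self._count("trans", float(acc), 1.0, post_burn)
            if adapt:
                self.s_tr_a[t] *= np.exp(
                    gamma * (float(acc) - self.config.target_accept)
                )

        for _ in range(self.config.mix_reps):
            self._scale_and_shear_moves(adapt, post_burn, gamma)

    def _scale_and_shear_moves(self, adapt: bool, post_burn: bool, gamma: float) -> None:
        """Joint global moves on (a, G) with an invariant Gaussian prior.

        Scaling: ``a_t <- c a_t`` together with the congruence
        ``G <- T G T`` for ``T = diag(c, 1)``; the ``N(0, G (x) A)`` prior
        density of the transformed pair is unchanged up to the Jacobian
        ``c^(q+3)``, so acceptance is driven by the inverse-Wishart prior
        and the likelihood along the changed linear predictors.  Shear:
        ``a_t <- a_t + d a_s`` with ``G <- T G T'`` for the unit shear T,
        volume-preserving.  Both are exact Metropolis moves that let the
        genetic variances and covariance mix in O(1) rather than by a
        q-dimensional random walk.
        """
        rng = self.rng
        if not self.config.sample_covariance:
            return
        V = np.asarray(self.prior.iw_scale, dtype=float)
        nu = self.prior.iw_df

        for t in range(2):
            s = 1 - t
            # --- scaling move -------------------------------------------
            d = self.s_scale[t] * rng.standard_normal()
            c = np.exp(d)
            Gts = np.array(
                [[self.G[t, t], self.G[t, s]], [self.G[s, t], self.G[s, s]]]
            )
            G_new = np.array(
                [
                    [c * c * Gts[0, 0], c * Gts[0, 1]],
                    [c * Gts[1, 0], Gts[1, 1]],
                ]
            )
            d_iw = _iw_logratio(_relabel(G_new, t), self.G, V, nu)
            if self.n:
                apos = self.a[self.pos, t]
                th_new = self.theta[:, t] + (c - 1.0) * apos
                ll_new = self.table.log_p1_at(self.ysign[:, t] * th_new)
                dll = float(ll_new.sum() - self.ll[:, t].sum())
            else:
                th_new = self.theta[:, t]
                ll_new = self.ll[:, t]
                dll = 0.0
            # Gaussian prior of (a | G) is invariant: its density change
            # -q d cancels against the a-Jacobian except for the G part
            log_jac = (self.q + 3.0) * d
            dlp_gauss = -self.q * d  # |G'|^{-q/2} etc. net change for col scale
            if np.log(rng.random()) < d_iw + dll + log_jac + dlp_gauss:
                acc = True
                self.a[:, t] *= c
                self.M[:, t] *= c
                self.theta[:, t] = th_new
                self.ll[:, t] = ll_new
                self.G = _relabel(G_new, t)
                self.K = _inv2(self.G)
            else:
                acc = False
            self._count("mix", float(acc), 1.0, post_burn)
            if adapt:
                self.s_scale[t] *= np.exp(gamma * (float(acc) - self.config.target_accept))

            # --- shear move ---------------------------------------------
            d = self.s_shear[t] * rng.standard_normal()
            Gts = np.array(
                [[self.G[t, t], self.G[t, s]], [self.G[s, t], self.G[s, s]]]
            )
            G_new = np.array(
                [
                    [
                        Gts[0, 0] + 2.0 * d * Gts[0, 1] + d * d * Gts[1, 1],
                        Gts[0, 1] + d * Gts[1, 1],
                    ],
                    [Gts[1, 0] + d * Gts[1, 1], Gts[1, 1]],
                ]
            )
            d_iw = _iw_logratio(_relabel(G_new, t), self.G, V, nu)
            if self.n:
                th_new = self.theta[:, t] + d * self.a[self.pos, s]
                ll_new = self.table.log_p1_at(self.ysign[:, t] * th_new)
                dll = float(ll_new.sum() - self.ll[:, t].sum())
            else:
                th_new = self.theta[:, t]
                ll_new = self.ll[:, t]
                dll = 0.0
            # unit shears: Jacobians are 1 and the Gaussian prior is invariant
            if np.log(rng.random()) < d_iw + dll:
                acc = True
                self.a[:, t] += d * self.a[:, s]
                self.M[:, t] += d * self.M[:, s]
                self.theta[:, t] = th_new
                self.ll[:, t] = ll_new
                self.G = _relabel(G_new, t)
                self.K = _inv2(self.G)
            else:
                acc = False
            self._count("mix", float(acc), 1.0, post_burn)
            if adapt:
                self.s_shear[t] *= np.exp(gamma * (float(acc) - self.config.target_accept))

    def update_genetic_covariance(self) -> None:
        """Conjugate inverse-Wishart Gibbs draw of G given the breeding values."""
        self.G = update_genetic_covariance(
            self.a[:, 0], self.a[:, 1], self.Ainv, self.prior, self.rng, M=self.M
        )
        self.K = _inv2(self.G)

    # ----- driver ---------------------------------------------------------

    def run(self) -> Chain:
        cfg = self.config
        m = cfg.n_retained
        fx_s = np.empty((m, 2, 3))
        G_s = np.empty((m, 2, 2))
        a_s = np.empty((m, self.q, 2)) if cfg.store_breeding_values else None
        k = 0
        for t_iter in range(cfg.n_total):
            adapt = cfg.adapt and t_iter < cfg.burn_in
            post_burn = t_iter >= cfg.burn_in
            gamma = min(0.25, (t_iter + 1) ** -0.6)
            if cfg.sample_latents:
                self.update_location_effects(adapt, post_burn, gamma)
            else:
                self._update_fixed_effects(adapt, post_burn, gamma)
            if cfg.sample_covariance:
                self.update_genetic_covariance()
            if (t_iter + 1) % cfg.recompute_stride == 0:
                self.M = self.Ainv @ self.a
                self.theta = self._full_theta()
                self.ll = self._full_ll()
            it = t_iter + 1
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                fx_s[k] = self.fx
                G_s[k] = self.G
                if a_s is not None:
                    a_s[k] = self.a
                k += 1
        assert k == m
        rates = {
            f: (rec[0] / rec[1] if rec[1] else np.nan) for f, rec in self._acc.items()
        }
        return Chain(
            config=cfg,
            pedigree_labels=tuple(self.ped.labels),
            phenotyped_ids=tuple(r.individual_id for r in self.records),
            fx_samples=fx_s,
            G_samples=G_s,
            a_samples=a_s,
            accept_rates=rates,
        )


def _inv2(G: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a symmetric 2x2 matrix."""
    det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    return np.array([[G[1, 1], -G[0, 1]], [-G[1, 0], G[0, 0]]]) / det


def _iw_logratio(G_new: np.ndarray, G_old: np.ndarray, V: np.ndarray, nu: float) -> float:
    """log IW(G_new | V, nu) - log IW(G_old | V, nu) for 2x2 matrices.

    Normalising constants cancel; only the determinant and trace terms
    remain, evaluated in closed form.
    """
    det_new = G_new[0, 0] * G_new[1, 1] - G_new[0, 1] * G_new[1, 0]
    det_old = G_old[0, 0] * G_old[1, 1] - G_old[0, 1] * G_old[1, 0]
    if det_new <= 0 or G_new[0, 0] <= 0:
        return -np.inf

    def tr_v_ginv(G, det):
        return (
            V[0, 0] * G[1, 1]
            - (V[0, 1] + V[1, 0]) * G[0, 1]
            + V[1, 1] * G[0, 0]
        ) / det

    return float(
        -0.5 * (nu + 3.0) * (np.log(det_new) - np.log(det_old))
        - 0.5 * (tr_v_ginv(G_new, det_new) - tr_v_ginv(G_old, det_old))
    )


def _relabel(G_ts: np.ndarray, t: int) -> np.ndarray:
    """Map a matrix written in (t, s) labelling back to (R, L) order."""
    if t == 0:
        return G_ts.copy()
    return G_ts[::-1, ::-1].copy()


def _colour_classes(Ainv: np.ndarray, tol: float = 1e-10) -> list[np.ndarray]:
    """Greedy colouring of the A-inverse sparsity graph.

    Vertices in one class are mutually non-adjacent (A^-1_ij = 0), hence
    their breeding-value full conditionals are mutually independent given
    the rest and can be updated simultaneously.
    """
    q = Ainv.shape[0]
    colours = np.full(q, -1, dtype=np.int64)
    neighbours = [np.nonzero(np.abs(Ainv[i]) > tol)[0] for i in range(q)]
    for i in range(q):
        used = {colours[j] for j in neighbours[i] if j != i and colours[j] >= 0}
        c = 0
        while c in used:
            c += 1
        colours[i] = c
    return [np.nonzero(colours == c)[0] for c in range(int(colours.max()) + 1)]


def update_genetic_covariance(
    a_r: np.ndarray,
    a_l: np.ndarray,
    A_inv: np.ndarray,
    prior: PriorSpec,
    rng: np.random.Generator,
    M: np.ndarray | None = None,
) -> np.ndarray:
    """Draw G from its full conditional IW(V + W' A^-1 W, n + q).

    ``M`` may supply a precomputed ``A^-1 W`` product.
    """
    W = np.column_stack([a_r, a_l])
    q = W.shape[0]
    if A_inv.shape != (q, q):
        raise ValueError("A_inv does not match the breeding-value vectors")
    S = W.T @ (M if M is not None else A_inv @ W)
    S = 0.5 * (S + S.T)
    scale = np.asarray(prior.iw_scale, dtype=float) + S
    df = prior.iw_df + q
    return np.asarray(invwishart.rvs(df=df, scale=scale, random_state=rng))


def run_chain(
    ped: Pedigree,
    records: list[PhenotypeRecord],
    prior: PriorSpec,
    config: ChainConfig,
) -> Chain:
    """Sample the posterior and return the retained, thinned chain."""
    sampler = MetropolisWithinGibbs(ped, records, prior, config)
    return sampler.run()


def thin_and_burn(raw_chain, config: ChainConfig):
    """Keep iterations burn_in + thin, burn_in + 2*thin, ... from a raw chain.

    ``raw_chain[k]`` is iteration k+1; requires at least ``n_total`` raw
    iterations.
    """
    n = len(raw_chain)
    if config.burn_in >= n:
        raise ValueError("burn_in must be smaller than the chain length")
    return raw_chain[config.burn_in + config.thin - 1 :: config.thin][
        : config.n_retained
    ]


def lag1_autocorrelation(x: np.ndarray) -> float:
    """Pearson correlation of consecutive samples; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x[:-1]) == 0 or np.std(x[1:]) == 0:
        return np.nan
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial-positive-sequence truncation."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    xc = x - x.mean()
    if np.all(xc == 0):
        return np.nan
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    tau = 0.0
    k = 0
    while 2 * k + 1 < n:
        gamma = rho[2 * k] + (rho[2 * k + 1] if 2 * k + 1 < n else 0.0)
        if gamma <= 0:
            break
        tau += gamma
        k += 1
    tau = max(2.0 * tau - 1.0, 1e-12)
    return float(n / tau)


def chain_diagnostics(chain) -> pd.DataFrame:
    """Lag-1 autocorrelation, ESS and the <0.03 screening flag per scalar.

    Accepts a :class:`Chain` or a DataFrame of retained scalar samples.
    Constant chains get NaN autocorrelation and ``constant = True``.
    """
    df = chain.to_dataframe() if isinstance(chain, Chain) else pd.DataFrame(chain)
    if len(df) < 10:
        raise ValueError("need at least 10 retained samples for diagnostics")
    rows = []
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        constant = bool(np.all(x == x[0]))
        r1 = np.nan if constant else lag1_autocorrelation(x)
        ess = np.nan if constant else effective_sample_size(x)
        rows.append(
            {
                "quantity": col,
                "lag1_autocorr": r1,
                "ess": ess,
                "constant": constant,
                "exceeds_bound": bool(r1 > AUTOCORR_BOUND) if np.isfinite(r1) else False,
            }
        )
    return pd.DataFrame(rows).set_index("quantity")


@dataclasses.dataclass
class PosteriorSummary:
    """Mean / SD / central 95% interval per quantity, plus the
    repeated-measures flag (posterior mean rg above 0.95)."""

    table: pd.DataFrame
    repeated_measures_flag: bool


def summarize_posterior(chain) -> PosteriorSummary:
    """Summaries of the retained chain.

    Derived quantities (h2 per trait, rg) are transformed per sample
    *before* averaging.  SD is the sample standard deviation (ddof=1) of
    the retained MCMC sample; ``mcse`` divides it by sqrt(ESS).
    """
    df = chain.to_dataframe() if isinstance(chain, Chain) else pd.DataFrame(chain).copy()
    if len(df) < 2:
        raise ValueError("need at least 2 retained samples")
    if "h2_R" not in df and "var_gR" in df:
        df["h2_R"] = df["var_gR"] / (df["var_gR"] + 1.0)
    if "h2_L" not in df and "var_gL" in df:
        df["h2_L"] = df["var_gL"] / (df["var_gL"] + 1.0)
    if "rg" not in df and {"cov_gRL", "var_gR", "var_gL"} <= set(df.columns):
        df["rg"] = df["cov_gRL"] / np.sqrt(df["var_gR"] * df["var_gL"])
    rows = []
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1))
        try:
            ess = effective_sample_size(x) if x.size >= 4 else np.nan
        except ValueError:
            ess = np.nan
        rows.append(
            {
                "quantity": col,
                "mean": float(np.mean(x)),
                "sd": sd,
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
                "mcse": sd / np.sqrt(ess) if np.isfinite(ess) else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("quantity")
    flag = bool(
        "rg" in table.index and table.loc["rg", "mean"] > REPEATED_MEASURES_THRESHOLD
    )
    return PosteriorSummary(table=table, repeated_measures_flag=flag)


def sample_prior_genetic_correlation(
    prior: PriorSpec, n_draws: int, seed: int
) -> np.ndarray:
    """Draws of rg implied by the IW prior on G.

    With V = I2 and n = 3 the marginal of rg is uniform on [-1, 1].
    """
    rng = np.random.default_rng(seed)
    draws = invwishart.rvs(
        df=prior.iw_df, scale=np.asarray(prior.iw_scale, dtype=float),
        size=n_draws, random_state=rng,
    )
    draws = np.atleast_3d(draws).reshape(n_draws, 2, 2)
    return draws[:, 0, 1] / np.sqrt(draws[:, 0, 0] * draws[:, 1, 1])
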