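"""Bayesian bivariate linear mixed model for one species x season group.

Model, per record t of individual i (y is the 2-vector of z-scored
delta13C, delta15N):

    y_it = mu + beta_{campaign(it)} + b_i + e_it
    b_i  ~ N2(0, G)      (between-individual, "G-structure")
    e_it ~ N2(0, R)      (within-individual / residual, "R-structure")

with flat priors on the fixed effects and conjugate inverse-Wishart priors
on G and R (identity scale, 3 degrees of freedom by default — weakly
informative on the z-scored scale).  The sampler is a plain Gibbs cycle:

1. fixed-effect matrix B from its matrix-normal full conditional
   (flat prior => B | . ~ MN(Bhat, (X'X)^-1, R));
2. random intercepts b_i from bivariate-normal full conditionals with
   precision n_i R^-1 + G^-1;
3. G ~ IW(S_G + sum_i b_i b_i', df_G + n_individuals);
4. R ~ IW(S_R + sum_it e_it e_it', df_R + n_records).

Tissue is deliberately not a fixed effect: standardisation has removed
tissue means, and the residual tissue-to-tissue variation within an
individual is exactly the repeated-measures signal that defines the
within-individual niche component.

Convergence is assessed with the Gelman-Rubin potential scale reduction
factor over independent chains, per scalar parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import invwishart

from .errors import IdentifiabilityError, UndefinedPSRFError
from .isotope_data import StandardizedDataset

#: order of scalar parameters used for convergence diagnostics
SCALAR_PARAMS = ("mu1", "mu2", "g11", "g12", "g22", "r11", "r12", "r22")


@dataclass(frozen=True)
class MixedModelConfig:
    """MCMC settings and priors.

    Defaults follow the full-scale analysis protocol: 100,000 iterations,
    thinning 10, burn-in 5,000, five independent chains.  ``test_scale``
    returns a reduced configuration (20,000 iterations, burn-in 2,000,
    thinning 10, three chains) sized for desk-scale reruns.
    """

    n_iterations: int = 100_000
    thin: int = 10
    burn_in: int = 5_000
    n_chains: int = 5
    prior_scale_G: np.ndarray = field(default_factory=lambda: np.eye(2))
    prior_df_G: float = 3.0
    prior_scale_R: np.ndarray = field(default_factory=lambda: np.eye(2))
    prior_df_R: float = 3.0
    fixed_effects: tuple[str, ...] = ("intercept", "campaign")
    psrf_threshold: float = 1.1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_df_G <= 1 or self.prior_df_R <= 1:
            raise ValueError("inverse-Wishart df must exceed dimension - 1 = 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def test_scale(cls, **overrides) -> "MixedModelConfig":
        base = dict(n_iterations=20_000, burn_in=2_000, thin=10, n_chains=3)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter potential scale reduction factors and verdict."""

    psrf: Mapping[str, float]
    threshold: float
    converged: bool | None  # None when only one chain was run


@dataclass(frozen=True)
class GroupPosterior:
    """Retained MCMC draws for one species x season group."""

    species: str
    season: str
    campaigns: tuple[str, ...]          # reference level first
    chain: np.ndarray                   # (D,) chain index per draw
    mu: np.ndarray                      # (D, 2) intercept = reference-level mean
    beta: np.ndarray                    # (D, n_campaigns - 1, 2) offsets
    G: np.ndarray                       # (D, 2, 2)
    R: np.ndarray                       # (D, 2, 2)
    convergence: ConvergenceReport

    @property
    def n_effective_draws(self) -> int:
        return self.mu.shape[0]

    def marginal_mean(self, intercept_only: bool = False) -> np.ndarray:
        """Per-draw group centroid, (D, 2).

        Default is the campaign-averaged marginal mean: the intercept plus
        the unweighted average of all campaign effects (the reference level
        contributing zero).  ``intercept_only=True`` returns the
        reference-campaign mean instead.
        """
        if intercept_only or self.beta.shape[1] == 0:
            return self.mu.copy()
        n_camp = self.beta.shape[1] + 1
        return self.mu + self.beta.sum(axis=1) / n_camp

    def total_covariance(self) -> np.ndarray:
        """Per-draw total-niche covariance G + R, (D, 2, 2)."""
        return self.G + self.R


def _inv2(M: np.ndarray) -> np.ndarray:
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    return np.array([[M[1, 1], -M[0, 1]], [-M[1, 0], M[0, 0]]]) / det


def _run_chain(
    Y: np.ndarray,
    X: np.ndarray,
    ind_idx: np.ndarray,
    n_ind: int,
    config: MixedModelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n_rec, p = X.shape
    counts = np.bincount(ind_idx, minlength=n_ind).astype(float)
    XtX_inv = np.linalg.inv(X.T @ X)
    Lx = np.linalg.cholesky(XtX_inv)
    proj = XtX_inv @ X.T  # p x n_rec, reused every iteration

    # initial state
    G = np.eye(2)
    R = np.eye(2)
    b = np.zeros((n_ind, 2))
    B = np.zeros((p, 2))

    D = config.draws_per_chain
    out_B = np.empty((D, p, 2))
    out_G = np.empty((D, 2, 2))
    out_R = np.empty((D, 2, 2))

    unique_counts = np.unique(counts)
    keep = 0
    for it in range(1, config.n_iterations + 1):
        # 1. fixed effects | b, R  (flat prior; rows share R so GLS == OLS)
        U = Y - b[ind_idx]
        Bhat = proj @ U
        Lr = np.linalg.cholesky(R)
        B = Bhat + Lx @ rng.standard_normal((p, 2)) @ Lr.T

        # 2. random intercepts | B, G, R
        resid = Y - X @ B
        s = np.zeros((n_ind, 2))
        np.add.at(s, ind_idx, resid)
        Rinv = _inv2(R)
        Ginv = _inv2(G)
        for k in unique_counts:
            mask = counts == k
            Sigma = _inv2(k * Rinv + Ginv)
            mean = s[mask] @ (Sigma @ Rinv).T
            Ls = np.linalg.cholesky(Sigma)
            b[mask] = mean + rng.standard_normal((int(mask.sum()), 2)) @ Ls.T

        # 3. G | b
        SG = config.prior_scale_G + b.T @ b
        G = invwishart.rvs(df=config.prior_df_G + n_ind, scale=SG, random_state=rng)

        # 4. R | B, b
        E = resid - b[ind_idx]
        SR = config.prior_scale_R + E.T @ E
        R = invwishart.rvs(df=config.prior_df_R + n_rec, scale=SR, random_state=rng)

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            out_B[keep] = B
            out_G[keep] = 0.5 * (G + G.T)
            out_R[keep] = 0.5 * (R + R.T)
            keep += 1

    return out_B[:keep], out_G[:keep], out_R[:keep], np.arange(keep)


def fit_group(
    data: StandardizedDataset,
    species: str,
    season: str,
    config: MixedModelConfig | None = None,
) -> GroupPosterior:
    """Fit the bivariate mixed model to one species x season group.

    ``data`` may already be restricted to the group; otherwise it is
    restricted here.  Requires >= 3 individuals and at least one individual
    with >= 2 records (else G and R cannot be separated).  Runs
    ``config.n_chains`` independent chains from seeds spawned off
    ``config.seed`` and concatenates retained draws; the Gelman-Rubin PSRF
    is computed per scalar parameter across chains.
    """
    config = config or MixedModelConfig()
    sub = [r for r in data.records if r.species == species and r.season == season]
    if not sub:
        raise ValueError(f"no records for group {species!r} x {season!r}")

    ind_labels = sorted({r.individual_id for r in sub})
    if len(ind_labels) < 3:
        raise IdentifiabilityError("need >= 3 individuals to estimate G")
    ind_map = {lab: k for k, lab in enumerate(ind_labels)}
    ind_idx = np.array([ind_map[r.individual_id] for r in sub])
    counts = np.bincount(ind_idx, minlength=len(ind_labels))
    if counts.max() < 2:
        raise IdentifiabilityError(
            "every individual measured once: between- and within-individual "
            "variance are not separable"
        )

    Y = np.array([[r.z13C, r.z15N] for r in sub])
    campaigns = sorted({r.campaign for r in sub})
    use_campaign = "campaign" in config.fixed_effects and len(campaigns) > 1
    if use_campaign:
        camp_map = {c: k for k, c in enumerate(campaigns)}
        X = np.zeros((len(sub), len(campaigns)))
        X[:, 0] = 1.0  # intercept = reference (first) campaign
        for row, r in enumerate(sub):
            k = camp_map[r.campaign]
            if k > 0:
                X[row, k] = 1.0
    else:
        campaigns = campaigns[:1]
        X = np.ones((len(sub), 1))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    per_chain = []
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        out_B, out_G, out_R, _ = _run_chain(
            Y, X, ind_idx, len(ind_labels), config, rng
        )
        per_chain.append((out_B, out_G, out_R))

    B_all = np.concatenate([pc[0] for pc in per_chain])
    G_all = np.concatenate([pc[1] for pc in per_chain])
    R_all = np.concatenate([pc[2] for pc in per_chain])
    chain_ids = np.concatenate(
        [np.full(pc[0].shape[0], c) for c, pc in enumerate(per_chain)]
    )

    psrf: dict[str, float] = {}
    converged: bool | None = None
    if config.n_chains >= 2:
        chains_scalars = []
        for out_B, out_G, out_R in per_chain:
            chains_scalars.append(
                np.column_stack(
                    [
                        out_B[:, 0, 0], out_B[:, 0, 1],
                        out_G[:, 0, 0], out_G[:, 0, 1], out_G[:, 1, 1],
                        out_R[:, 0, 0], out_R[:, 0, 1], out_R[:, 1, 1],
                    ]
                )
            )
        for j, name in enumerate(SCALAR_PARAMS):
            psrf[name] = gelman_rubin([cs[:, j] for cs in chains_scalars])
        converged = all(v < config.psrf_threshold for v in psrf.values())

    return GroupPosterior(
        species=species,
        season=season,
        campaigns=tuple(campaigns),
        chain=chain_ids,
        mu=B_all[:, 0, :],
        beta=B_all[:, 1:, :],
        G=G_all,
        R=R_all,
        convergence=ConvergenceReport(
            psrf=psrf, threshold=config.psrf_threshold, converged=converged
        ),
    )


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor over >= 2 equal-length chains.

    PSRF = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means (sample variances,
    n-1 divisor).  Raises :class:`UndefinedPSRFError` when every chain has
    zero within-chain variance.
    """
    arrs = [np.asarray(c, dtype=float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("need >= 2 chains")
    n = arrs[0].size
    if n < 2 or any(a.size != n for a in arrs):
        raise ValueError("chains must have equal length >= 2")
    W = float(np.mean([np.var(a, ddof=1) for a in arrs]))
    if W == 0.0:
        raise UndefinedPSRFError("zero within-chain variance in all chains")
    means = np.array([a.mean() for a in arrs])
    B = n * float(np.var(means, ddof=1))
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))
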