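"""Niche components and individual-specialisation metrics from posterior draws.

Per retained MCMC draw:

    WIC = sum of eigenvalues of R   (average within-individual niche width)
    BIC = sum of eigenvalues of G   (spread among individual centroids)
    TNW = WIC + BIC                 (total niche width)
    IS  = BIC / TNW                 (individual specialisation, in [0, 1])

Metrics are computed draw-wise and then summarised (mean-of-ratios for IS,
not ratio-of-means), so the reported uncertainty is the posterior spread of
each metric.  The complementary Roughgarden orientation WIC/TNW and the
V index (1 - WIC/TNW = IS) are available as conveniences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MatrixError
from .mixed_model import GroupPosterior


def eigen_sum(M: np.ndarray, tol: float = 1e-8) -> float:
    """Sum of eigenvalues of a symmetric 2x2 matrix (equals its trace).

    Raises :class:`MatrixError` if the matrix is asymmetric beyond ``tol``.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2):
        raise MatrixError(f"expected a 2x2 matrix, got shape {M.shape}")
    scale = max(1.0, float(np.abs(M).max()))
    if float(np.abs(M - M.T).max()) > tol * scale:
        raise MatrixError("matrix is asymmetric beyond tolerance")
    return float(np.sum(np.linalg.eigvalsh(M)))


@dataclass(frozen=True)
class NicheMetricsDraws:
    """Draw-wise niche metrics for one group plus exclusion bookkeeping.

    ``is_`` has one entry per draw with TNW > 0; ``n_is_excluded`` counts
    draws where TNW = 0 made IS undefined (possible only for degenerate
    posteriors).
    """

    species: str
    season: str
    wic: np.ndarray
    bic: np.ndarray
    tnw: np.ndarray
    is_: np.ndarray
    n_is_excluded: int = 0

    @property
    def n_draws(self) -> int:
        return self.wic.size

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD and central 95% interval per metric."""
        rows = []
        for name, x in (
            ("TNW", self.tnw), ("WIC", self.wic),
            ("BIC", self.bic), ("IS", self.is_),
        ):
            if x.size == 0:
                rows.append((self.species, self.season, name,
                             np.nan, np.nan, np.nan, np.nan))
                continue
            rows.append(
                (
                    self.species, self.season, name,
                    float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                    float(np.quantile(x, 0.025)), float(np.quantile(x, 0.975)),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["species", "season", "metric", "mean", "sd", "q2.5", "q97.5"],
        )


def metrics_from_posterior(post: GroupPosterior) -> NicheMetricsDraws:
    """Draw-wise WIC/BIC/TNW/IS from a fitted group posterior."""
    if post.n_effective_draws < 1:
        raise ValueError("posterior has no draws")
    wic = np.array([eigen_sum(R) for R in post.R])
    bic = np.array([eigen_sum(G) for G in post.G])
    tnw = wic + bic
    ok = tnw > 0
    return NicheMetricsDraws(
        species=post.species,
        season=post.season,
        wic=wic,
        bic=bic,
        tnw=tnw,
        is_=bic[ok] / tnw[ok],
        n_is_excluded=int((~ok).sum()),
    )


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100 * (after - before) / before."""
    if before == 0:
        raise ValueError("percent_change undefined for before = 0")
    return 100.0 * (after - before) / before


def fold_ratio(a: float, b: float) -> float:
    """Fold ratio a / b."""
    if b == 0:
        raise ValueError("fold_ratio undefined for b = 0")
    return a / b


def roughgarden_is(draws: NicheMetricsDraws) -> np.ndarray:
    """Draw-wise WIC/TNW, the original orientation (lower = more specialised)."""
    ok = draws.tnw > 0
    return draws.wic[ok] / draws.tnw[ok]
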