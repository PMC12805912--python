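"""Ecological-opportunity indicators: prey richness and inverse Simpson diversity.

Indices are computed from counts of prey items pooled per season (one index
per season, not per pellet).  The seasonal contrast is descriptive — percent
difference of the non-breeding relative to the breeding season — with a
multinomial bootstrap interval from resampling individual prey items; no
seasonal effect is asserted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedDiversityError

SEASONS = ("breeding", "non_breeding")


def _season_counts(counts: pd.DataFrame, season: str) -> np.ndarray:
    sub = counts[counts["season"] == season]
    if sub["taxon"].duplicated().any():
        raise ConfigurationError(f"duplicate taxa within season {season!r}")
    c = sub["count"].to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    return c


def richness(counts: pd.DataFrame, season: str) -> int:
    """Number of taxa with count > 0 in the season."""
    c = _season_counts(counts, season)
    return int(np.sum(c > 0))


def inverse_simpson(counts: pd.DataFrame, season: str) -> float:
    """Reciprocal Simpson index D = 1 / sum(p_i^2) on pooled season counts.

    D ranges from 1 (single taxon) to the richness (perfectly even
    community).  Raises :class:`UndefinedDiversityError` when the season's
    total count is zero.
    """
    c = _season_counts(counts, season)
    total = c.sum()
    if total <= 0:
        raise UndefinedDiversityError(f"no prey items in season {season!r}")
    p = c / total
    return float(1.0 / np.sum(p ** 2))


def seasonal_contrast(
    counts: pd.DataFrame,
    n_bootstrap: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Percent difference (non-breeding vs breeding) in richness and diversity.

    Both indices are recomputed on ``n_bootstrap`` multinomial resamples of
    each season's prey items (totals held fixed) to give percentile
    intervals for the percent differences.  Returns a JSON-serialisable
    dict.
    """
    for season in SEASONS:
        if not (counts["season"] == season).any():
            raise ConfigurationError(f"missing season {season!r}")

    obs = {
        season: {
            "richness": richness(counts, season),
            "inverse_simpson": inverse_simpson(counts, season),
        }
        for season in SEASONS
    }

    def pct(nb: float, b: float) -> float:
        return 100.0 * (nb - b) / b

    rng = np.random.default_rng(seed)
    boot = {"richness": [], "inverse_simpson": []}
    season_probs = {}
    for season in SEASONS:
        c = _season_counts(counts, season)
        c = c[c > 0]
        season_probs[season] = (c / c.sum(), int(c.sum()))
    for _ in range(n_bootstrap):
        vals = {}
        for season in SEASONS:
            p, total = season_probs[season]
            draw = rng.multinomial(total, p)
            vals[season] = {
                "richness": float(np.sum(draw > 0)),
                "inverse_simpson": float(
                    1.0 / np.sum((draw / total) ** 2)
                ),
            }
        for key in boot:
            boot[key].append(
                pct(vals["non_breeding"][key], vals["breeding"][key])
            )

    lo, hi = (1.0 - ci) / 2.0, 1.0 - (1.0 - ci) / 2.0
    out = {"observed": obs, "n_bootstrap": n_bootstrap, "ci_level": ci}
    for key in ("richness", "inverse_simpson"):
        arr = np.array(boot[key])
        out[f"percent_change_{key}"] = {
            "estimate": pct(
                obs["non_breeding"][key], obs["breeding"][key]
            ),
            "ci_low": float(np.quantile(arr, lo)),
            "ci_high": float(np.quantile(arr, hi)),
        }
    return out
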