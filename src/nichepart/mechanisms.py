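"""Posterior tests of the four niche-based coexistence mechanisms.

Each mechanism is scored as a directional posterior probability: the
fraction of index-paired MCMC draws in which one quantity strictly exceeds
the other.

M1 (population niche segregation): interspecific niche-width overlap lower
    in breeding than non-breeding, per overlap direction.
M2 (enhanced individual specialisation): IS higher in breeding, per species.
M3 (population niche expansion): TNW higher in breeding, per species.
M4 (individual niche expansion): WIC higher in breeding, per species.

Probabilities use strict inequality; ties (measure-zero for continuous
posteriors, but possible for degenerate ones) are reported separately so
that P(left > right) + P(right > left) + P(tie) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np

from .ellipses import OverlapDraws
from .errors import ConfigurationError, PairingError
from .niche_metrics import NicheMetricsDraws, fold_ratio, percent_change

SEASONS = ("breeding", "non_breeding")

#: evidence threshold for flagging a directional difference as supported
DEFAULT_EVIDENCE_THRESHOLD = 0.67


def directional_probability(left: np.ndarray, right: np.ndarray) -> float:
    """Fraction of index-paired draws with left strictly greater than right."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.size < 1:
        raise PairingError(
            f"draw sequences must be index-paired with equal length >= 1 "
            f"(got {left.size} and {right.size})"
        )
    return float(np.mean(left > right))


def tie_fraction(left: np.ndarray, right: np.ndarray) -> float:
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise PairingError("draw sequences must be index-paired")
    return float(np.mean(left == right))


@dataclass(frozen=True)
class DirectionalTest:
    """One directional comparison with its posterior probability and effects."""

    label: str
    probability: float
    complement: float
    tie_fraction: float
    n_draws: int
    mean_left: float
    mean_right: float
    mean_difference: float
    fold_ratio: float | None
    percent_change: float | None
    supported: bool


def _compare(
    label: str,
    left: np.ndarray,
    right: np.ndarray,
    threshold: float,
) -> DirectionalTest:
    p = directional_probability(left, right)
    ties = tie_fraction(left, right)
    ml, mr = float(np.mean(left)), float(np.mean(right))
    return DirectionalTest(
        label=label,
        probability=p,
        complement=1.0 - p - ties,
        tie_fraction=ties,
        n_draws=int(np.asarray(left).size),
        mean_left=ml,
        mean_right=mr,
        mean_difference=ml - mr,
        fold_ratio=(fold_ratio(ml, mr) if mr != 0 else None),
        percent_change=(percent_change(mr, ml) if mr != 0 else None),
        supported=p > threshold,
    )


def evaluate_mechanisms(
    metrics: Mapping[tuple[str, str], NicheMetricsDraws],
    overlaps: Mapping[str, OverlapDraws],
    threshold: float = DEFAULT_EVIDENCE_THRESHOLD,
) -> dict:
    """Score M1-M4 from per-group metric draws and per-season overlap draws.

    ``metrics`` is keyed by (species, season) and must contain both seasons
    for exactly two species, all with equal retained draw counts;
    ``overlaps`` is keyed by season.  Returns a JSON-serialisable dict with
    one list of :class:`DirectionalTest` summaries per mechanism.
    """
    species = sorted({sp for sp, _ in metrics})
    for sp in species:
        for season in SEASONS:
            if (sp, season) not in metrics:
                raise ConfigurationError(f"missing group {(sp, season)}")
    for season in SEASONS:
        if season not in overlaps:
            raise ConfigurationError(f"missing overlap draws for season {season!r}")
    n_draws = {m.n_draws for m in metrics.values()}
    if len(n_draws) != 1:
        raise PairingError(f"groups have unequal retained draw counts: {n_draws}")

    report: dict[str, list[dict]] = {"M1": [], "M2": [], "M3": [], "M4": []}

    ov_b, ov_nb = overlaps["breeding"], overlaps["non_breeding"]
    for attr, lab in (
        ("a_in_b", f"{ov_b.label_a}_in_{ov_b.label_b}"),
        ("b_in_a", f"{ov_b.label_b}_in_{ov_b.label_a}"),
    ):
        report["M1"].append(
            asdict(
                _compare(
                    f"P(overlap[{lab}] breeding < non_breeding)",
                    getattr(ov_nb, attr),  # left = non-breeding
                    getattr(ov_b, attr),
                    threshold,
                )
            )
        )

    for mech, field in (("M2", "is_"), ("M3", "tnw"), ("M4", "wic")):
        for sp in species:
            b = getattr(metrics[(sp, "breeding")], field)
            nb = getattr(metrics[(sp, "non_breeding")], field)
            if b.size != nb.size:
                raise PairingError(
                    f"{sp}: {field} draws unequal across seasons "
                    f"({b.size} vs {nb.size})"
                )
            name = {"is_": "IS", "tnw": "TNW", "wic": "WIC"}[field]
            report[mech].append(
                asdict(
                    _compare(
                        f"P({name}[{sp}] breeding > non_breeding)",
                        b, nb, threshold,
                    )
                )
            )

    report["threshold"] = threshold
    return report


def interspecific_comparisons(
    metrics: Mapping[tuple[str, str], NicheMetricsDraws],
    threshold: float = DEFAULT_EVIDENCE_THRESHOLD,
) -> dict:
    """Within-season between-species comparisons of TNW, WIC, BIC and IS."""
    species = sorted({sp for sp, _ in metrics})
    if len(species) != 2:
        raise ConfigurationError("expected exactly two species")
    a, b = species
    out: dict[str, list[dict]] = {}
    for season in SEASONS:
        rows = []
        for field, name in (("tnw", "TNW"), ("wic", "WIC"),
                            ("bic", "BIC"), ("is_", "IS")):
            rows.append(
                asdict(
                    _compare(
                        f"P({name}[{a}] > {name}[{b}] | {season})",
                        getattr(metrics[(a, season)], field),
                        getattr(metrics[(b, season)], field),
                        threshold,
                    )
                )
            )
        out[season] = rows
    return out
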