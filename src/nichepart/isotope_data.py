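"""Isotope record containers, delimited-text IO, and within-tissue z-scoring.

The unit of observation is one individual x tissue measurement of the
(delta13C, delta15N) pair, labelled by species, season and sampling campaign.
Because different tissues integrate diet over different windows and carry
different discrimination offsets, raw values are standardised within tissue
(pooled across species, and by default across seasons) before any
variance-component modelling: each tissue's two isotope axes are shifted and
scaled to mean 0, SD 1, which removes systematic tissue differences while
preserving the between-species and between-individual contrasts inside each
tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTissueError,
    ParseError,
    SchemaError,
    ValidationError,
)

SEASONS = ("breeding", "non_breeding")
#: Tissues with first-class names; any other label is accepted as-is.
CORE_TISSUES = ("plasma", "red_blood_cells", "body_feather", "primary_feather")

REQUIRED_COLUMNS = (
    "individual_id",
    "species",
    "season",
    "campaign",
    "tissue",
    "d13C",
    "d15N",
)


@dataclass(frozen=True)
class IsotopeRecord:
    """One individual x tissue observation of (delta13C, delta15N) in permil."""

    individual_id: str
    species: str
    season: str
    campaign: str
    tissue: str
    d13C: float
    d15N: float


@dataclass(frozen=True)
class StandardizedRecord:
    """An isotope record on the within-tissue z-score scale."""

    individual_id: str
    species: str
    season: str
    campaign: str
    tissue: str
    z13C: float
    z15N: float


def validate_records(records: Sequence[IsotopeRecord]) -> None:
    """Check dataset invariants, raising :class:`ValidationError` on failure.

    Invariants: finite isotope values; no duplicated
    (individual_id, tissue, season) combination; valid season labels.
    """
    seen = set()
    for i, r in enumerate(records):
        if not (math.isfinite(r.d13C) and math.isfinite(r.d15N)):
            raise ValidationError(
                f"non-finite isotope value for individual {r.individual_id!r} "
                f"(record {i})"
            )
        if r.season not in SEASONS:
            raise ValidationError(
                f"unknown season {r.season!r} (record {i}); "
                f"expected one of {SEASONS}"
            )
        key = (r.individual_id, r.tissue, r.season)
        if key in seen:
            raise ValidationError(
                f"duplicate (individual, tissue, season) combination {key}"
            )
        seen.add(key)


def _detect_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_isotope_table(path: str, delimiter: str | None = None) -> list[IsotopeRecord]:
    """Read isotope records from a delimited text file (comma or tab).

    The header must contain ``individual_id, species, season, campaign,
    tissue, d13C, d15N``.  Raises :class:`SchemaError` for a missing column,
    :class:`ParseError` (citing the 1-based data row) for a non-numeric
    isotope value, and :class:`ValidationError` for duplicate keys.
    """
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    records: list[IsotopeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        vals = {}
        for col in ("d13C", "d15N"):
            raw = getattr(row, col)
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric {col} value {raw!r} on data row {i} of {path}"
                ) from None
        records.append(
            IsotopeRecord(
                individual_id=str(row.individual_id),
                species=str(row.species),
                season=str(row.season),
                campaign=str(row.campaign),
                tissue=str(row.tissue),
                d13C=vals["d13C"],
                d15N=vals["d15N"],
            )
        )
    validate_records(records)
    return records


def write_isotope_table(
    records: Iterable[IsotopeRecord], path: str, delimiter: str = ","
) -> None:
    """Write records as delimited text; floats use round-tripping repr."""
    df = records_to_frame(list(records))
    df.to_csv(path, sep=delimiter, index=False)


def records_to_frame(records: Sequence[IsotopeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=REQUIRED_COLUMNS)


def standardized_to_frame(records: Sequence[StandardizedRecord]) -> pd.DataFrame:
    cols = list(REQUIRED_COLUMNS[:5]) + ["z13C", "z15N"]
    return pd.DataFrame([r.__dict__ for r in records], columns=cols)


@dataclass(frozen=True)
class StandardizedDataset:
    """Z-scored records plus the per-tissue transform that produced them.

    ``standardization_table`` maps the grouping key (tissue, or
    (tissue, season) when standardised per season) to
    ``(mean13, sd13, mean15, sd15)``; :meth:`apply` reproduces the transform
    exactly on new raw records.
    """

    records: tuple[StandardizedRecord, ...]
    standardization_table: Mapping[tuple, tuple[float, float, float, float]]
    per_season: bool = False

    def restrict(self, species: str, season: str) -> "StandardizedDataset":
        """Subset to one species x season group, keeping the transform."""
        sub = tuple(
            r for r in self.records if r.species == species and r.season == season
        )
        return StandardizedDataset(sub, self.standardization_table, self.per_season)

    def apply(self, records: Sequence[IsotopeRecord]) -> tuple[StandardizedRecord, ...]:
        """Apply the stored transform to raw records."""
        out = []
        for r in records:
            key = (r.tissue, r.season) if self.per_season else (r.tissue,)
            m13, s13, m15, s15 = self.standardization_table[key]
            out.append(
                StandardizedRecord(
                    r.individual_id,
                    r.species,
                    r.season,
                    r.campaign,
                    r.tissue,
                    (r.d13C - m13) / s13,
                    (r.d15N - m15) / s15,
                )
            )
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        return standardized_to_frame(self.records)

    @classmethod
    def identity(cls, records: Sequence[IsotopeRecord]) -> "StandardizedDataset":
        """Wrap records already on a common scale without rescaling them.

        Useful when the inputs are simulated directly on the standardised
        scale and the per-tissue transform would be a no-op by construction.
        """
        tissues = {(r.tissue,) for r in records}
        table = {t: (0.0, 1.0, 0.0, 1.0) for t in tissues}
        std = tuple(
            StandardizedRecord(
                r.individual_id, r.species, r.season, r.campaign, r.tissue,
                r.d13C, r.d15N,
            )
            for r in records
        )
        return cls(std, table, per_season=False)


def standardize(
    records: Sequence[IsotopeRecord], per_season: bool = False
) -> StandardizedDataset:
    """Z-score delta13C and delta15N within tissue, pooled across species.

    By default a single transform per tissue is fitted, pooling seasons so
    seasonal contrasts are preserved; ``per_season=True`` fits one transform
    per (tissue, season) instead.  The sample SD (n-1 divisor) is used.

    Raises :class:`DegenerateTissueError` if any tissue group has fewer than
    two records or zero spread on either isotope axis.
    """
    validate_records(records)
    keyfn = (lambda r: (r.tissue, r.season)) if per_season else (lambda r: (r.tissue,))
    groups: dict[tuple, list[IsotopeRecord]] = {}
    for r in records:
        groups.setdefault(keyfn(r), []).append(r)

    table: dict[tuple, tuple[float, float, float, float]] = {}
    degenerate = []
    for key, grp in groups.items():
        x13 = np.array([r.d13C for r in grp])
        x15 = np.array([r.d15N for r in grp])
        if len(grp) < 2:
            degenerate.append(key)
            continue
        s13 = float(np.std(x13, ddof=1))
        s15 = float(np.std(x15, ddof=1))
        if s13 == 0.0 or s15 == 0.0:
            degenerate.append(key)
            continue
        table[key] = (float(np.mean(x13)), s13, float(np.mean(x15)), s15)
    if degenerate:
        raise DegenerateTissueError(
            "tissue groups with <2 records or zero spread: "
            + ", ".join(map(str, sorted(degenerate)))
        )

    ds = StandardizedDataset(records=(), standardization_table=table,
                             per_season=per_season)
    return replace(ds, records=ds.apply(records))
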