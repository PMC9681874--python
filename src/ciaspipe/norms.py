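"""Age-band normative tables and sign-corrected Z-scoring.

A normative table holds, for each of four contiguous age bands, a per-subtest
mean, SD and scoring direction.  ``direction`` is +1 when a larger raw score
means better performance and -1 when smaller is better (latency- and
error-count-style tasks), so that after scoring a larger Z always means
better performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, OutOfCoverageError, SchemaError

#: Canonical five-subtest battery layout.
SUBTESTS: tuple[str, ...] = (
    "identification",
    "detection",
    "groton_maze",
    "shopping_list",
    "one_back",
)

#: Default scoring directions.  Speed tasks (identification, detection) and
#: the maze error count are lower-is-better; list recall and one-back
#: accuracy are higher-is-better.  A norms file may declare any convention.
DEFAULT_DIRECTIONS: dict[str, int] = {
    "identification": -1,
    "detection": -1,
    "groton_maze": -1,
    "shopping_list": +1,
    "one_back": +1,
}

#: Canonical age bands (inclusive bounds), contiguous over 18-69.
AGE_BANDS: tuple[tuple[int, int], ...] = ((18, 34), (35, 49), (50, 59), (60, 69))


@dataclass(frozen=True)
class SubtestNorm:
    mean: float
    sd: float
    direction: int

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ConfigError(f"normative sd must be > 0, got {self.sd}")
        if self.direction not in (-1, 1):
            raise ConfigError(f"direction must be +1 or -1, got {self.direction}")


@dataclass(frozen=True)
class NormativeBand:
    """One age band of the normative table."""

    age_lo: int
    age_hi: int
    norms: Mapping[str, SubtestNorm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_lo > self.age_hi:
            raise ConfigError(f"band bounds inverted: {self.age_lo} > {self.age_hi}")

    def contains(self, age: int) -> bool:
        return self.age_lo <= age <= self.age_hi


class NormTable:
    """An ordered, disjoint, contiguous collection of normative bands."""

    def __init__(self, bands: Sequence[NormativeBand]):
        bands = sorted(bands, key=lambda b: b.age_lo)
        for prev, cur in zip(bands, bands[1:]):
            if cur.age_lo != prev.age_hi + 1:
                raise ConfigError(
                    f"bands must be contiguous and disjoint; "
                    f"{prev.age_lo}-{prev.age_hi} followed by {cur.age_lo}-{cur.age_hi}"
                )
        self.bands: tuple[NormativeBand, ...] = tuple(bands)

    @property
    def age_lo(self) -> int:
        return self.bands[0].age_lo

    @property
    def age_hi(self) -> int:
        return self.bands[-1].age_hi

    def subtests(self) -> tuple[str, ...]:
        return tuple(self.bands[0].norms)

    def lookup(self, age: int) -> NormativeBand:
        return lookup_band(age, self)

    # ---- serialisation (CSV: band_lo, band_hi, subtest, mean, sd, direction)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "band_lo": b.age_lo,
                "band_hi": b.age_hi,
                "subtest": st,
                "mean": n.mean,
                "sd": n.sd,
                "direction": n.direction,
            }
            for b in self.bands
            for st, n in b.norms.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormTable":
        required = {"band_lo", "band_hi", "subtest", "mean", "sd", "direction"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"norms table missing columns: {sorted(missing)}")
        bands = []
        for (lo, hi), grp in df.groupby(["band_lo", "band_hi"], sort=True):
            norms = {
                r.subtest: SubtestNorm(float(r.mean), float(r.sd), int(r.direction))
                for r in grp.itertuples()
            }
            bands.append(NormativeBand(int(lo), int(hi), norms))
        return cls(bands)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "NormTable":
        return cls.from_frame(pd.read_csv(path))

    def __eq__(self, other) -> bool:
        return isinstance(other, NormTable) and self.bands == other.bands


@dataclass(frozen=True)
class ZPanel:
    """Sign-corrected subtest Z-scores for one administration."""

    z: Mapping[str, float]
    composite: float | None
    visit: str | None = None

    @property
    def complete(self) -> bool:
        return self.composite is not None


def lookup_band(age: int, table: NormTable) -> NormativeBand:
    """Return the unique band whose inclusive range contains ``age``."""
    for band in table.bands:
        if band.contains(age):
            return band
    raise OutOfCoverageError(
        f"age {age} outside normative coverage "
        f"[{table.age_lo}, {table.age_hi}]"
    )


def score_subtest(raw: float, band: NormativeBand, subtest: str) -> float:
    """z = direction * (raw - mean) / sd, so larger z is always better."""
    if subtest not in band.norms:
        raise SchemaError(f"unknown subtest {subtest!r}; band holds {sorted(band.norms)}")
    n = band.norms[subtest]
    return n.direction * (raw - n.mean) / n.sd


def score_panel(
    panel: Mapping[str, float],
    band: NormativeBand,
    visit: str | None = None,
    subtests: Iterable[str] = SUBTESTS,
) -> ZPanel:
    """Score one administration; no partial composites.

    Any missing/NaN subtest leaves its z absent and suppresses the
    composite; per-subtest z values are still emitted for diagnostics.
    """
    subtests = tuple(subtests)
    z: dict[str, float] = {}
    for st in subtests:
        raw = panel.get(st)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            continue
        z[st] = score_subtest(float(raw), band, st)
    composite = (
        float(np.mean([z[st] for st in subtests])) if len(z) == len(subtests) else None
    )
    return ZPanel(z=z, composite=composite, visit=visit)


def score_dataframe(data: pd.DataFrame, table: NormTable) -> pd.DataFrame:
    """Add ``z_<subtest>`` columns and a ``composite`` column to long data.

    Rows whose age falls outside the table raise
    :class:`OutOfCoverageError` naming the offending ages.
    """
    subtests = table.subtests()
    missing_cols = [c for c in ("age", *subtests) if c not in data.columns]
    if missing_cols:
        raise SchemaError(f"data missing columns: {missing_cols}")
    out = data.copy()
    ages = out["age"].to_numpy()
    covered = np.zeros(len(out), dtype=bool)
    for st in subtests:
        out[f"z_{st}"] = np.nan
    for band in table.bands:
        mask = (ages >= band.age_lo) & (ages <= band.age_hi)
        covered |= mask
        for st in subtests:
            norm = band.norms[st]
            out.loc[mask, f"z_{st}"] = (
                norm.direction * (out.loc[mask, st] - norm.mean) / norm.sd
            )
    if not covered.all():
        bad = sorted(set(ages[~covered].tolist()))
        raise OutOfCoverageError(f"ages outside normative coverage: {bad}")
    zcols = [f"z_{st}" for st in subtests]
    zvals = out[zcols]
    out["composite"] = zvals.mean(axis=1).where(zvals.notna().all(axis=1))
    return out
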