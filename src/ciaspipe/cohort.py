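"""Analysis-population machinery.

Completer selection, the -1 SD impairment split, per-administration
intraindividual variability (IIV, the sample SD across the five subtest
Z-scores of one administration) and the Q3 + 1.5*IQR fence exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataIntegrityError,
    InsufficientSampleError,
    NotComputableError,
    SchemaError,
)
from .norms import SUBTESTS, ZPanel

IMPAIRMENT_CUTOFF = -1.0
TIMEPOINTS = ("baseline", "week5")


# ---------------------------------------------------------------------------
# completer selection


@dataclass(frozen=True)
class ExclusionLedger:
    """Ordered record of which patients each selection rule removed."""

    entries: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.entries}

    @property
    def total(self) -> int:
        return sum(len(ids) for _, ids in self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": pid, "rule": rule}
            for rule, ids in self.entries
            for pid in ids
        ]
        return pd.DataFrame(rows, columns=["patient_id", "rule"])


@dataclass(frozen=True)
class CompleterSelection:
    data: pd.DataFrame  # long rows of retained patients (all their visits)
    retained: tuple[str, ...]
    ledger: ExclusionLedger


RULE_PANSS = "missing_week5_or_panss"
RULE_CBB_BASELINE = "incomplete_cbb_baseline"
RULE_CBB_WEEK5 = "incomplete_cbb_week5"


def select_completers(scored: pd.DataFrame) -> CompleterSelection:
    """Retain patients with valid baseline and week-5 symptom totals and
    complete five-subtest panels at both analysed visits.

    Rules are applied in order, each patient counted at the first rule that
    removes them: (1) early termination / missing symptom score, (2)
    incomplete battery at baseline, (3) incomplete battery at week 5.
    """
    if "composite" not in scored.columns:
        raise SchemaError("data must be scored (composite column) before selection")
    if scored.duplicated(["patient_id", "visit"]).any():
        dups = scored.loc[
            scored.duplicated(["patient_id", "visit"]), "patient_id"
        ].tolist()
        raise DataIntegrityError(f"duplicate patient_id x visit rows: {dups}")

    def _visit(v: str) -> pd.DataFrame:
        return scored[scored["visit"] == v].set_index("patient_id")

    base, week5 = _visit("baseline"), _visit("week5")
    all_ids = sorted(scored["patient_id"].unique())

    entries: list[tuple[str, tuple[str, ...]]] = []
    removed: set[str] = set()

    def _apply(rule: str, condition) -> None:
        ids = tuple(pid for pid in all_ids if pid not in removed and condition(pid))
        if ids:
            entries.append((rule, ids))
            removed.update(ids)

    def _missing_panss(pid: str) -> bool:
        if pid not in base.index or pid not in week5.index:
            return True
        return bool(
            pd.isna(base.at[pid, "panss_total"]) or pd.isna(week5.at[pid, "panss_total"])
        )

    _apply(RULE_PANSS, _missing_panss)
    _apply(RULE_CBB_BASELINE, lambda pid: pd.isna(base.at[pid, "composite"]))
    _apply(RULE_CBB_WEEK5, lambda pid: pd.isna(week5.at[pid, "composite"]))

    retained = tuple(pid for pid in all_ids if pid not in removed)
    data = scored[scored["patient_id"].isin(retained)].reset_index(drop=True)
    return CompleterSelection(
        data=data, retained=retained, ledger=ExclusionLedger(tuple(entries))
    )


# ---------------------------------------------------------------------------
# impairment classification


def classify_impairment(baseline_composite: float) -> str:
    """``impaired`` below the -1 cutoff, ``minimally_impaired`` at or above it."""
    if baseline_composite is None or np.isnan(baseline_composite):
        raise NotComputableError("baseline composite absent: not classifiable")
    return "impaired" if baseline_composite < IMPAIRMENT_CUTOFF else "minimally_impaired"


# ---------------------------------------------------------------------------
# intraindividual variability


def compute_iiv(zpanel: ZPanel | Sequence[float], ddof: int = 1) -> float:
    """Sample SD (default denominator n-1) of the five subtest z-scores."""
    if isinstance(zpanel, ZPanel):
        if not zpanel.complete:
            raise NotComputableError("incomplete panel: IIV not computable")
        values = [zpanel.z[st] for st in SUBTESTS]
    else:
        values = list(zpanel)
    arr = np.asarray(values, dtype=float)
    if len(arr) != len(SUBTESTS) or np.isnan(arr).any():
        raise NotComputableError(
            f"IIV needs {len(SUBTESTS)} finite z-scores, got {values}"
        )
    return float(np.std(arr, ddof=ddof))


def iiv_table(
    scored: pd.DataFrame, timepoints: Iterable[str] = TIMEPOINTS, ddof: int = 1
) -> pd.DataFrame:
    """Per-administration IIV for rows with complete panels.

    Returns columns ``patient_id, timepoint, iiv``.
    """
    zcols = [f"z_{st}" for st in SUBTESTS]
    missing = [c for c in zcols if c not in scored.columns]
    if missing:
        raise SchemaError(f"scored data missing z columns: {missing}")
    rows = []
    for tp in timepoints:
        sub = scored[scored["visit"] == tp]
        z = sub[zcols].to_numpy(dtype=float)
        complete = ~np.isnan(z).any(axis=1)
        iiv = np.std(z[complete], axis=1, ddof=ddof)
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": sub.loc[complete, "patient_id"].to_numpy(),
                    "timepoint": tp,
                    "iiv": iiv,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# fences


@dataclass(frozen=True)
class Fences:
    """Upper outlier fence of one timepoint's IIV distribution."""

    q1: float
    q3: float
    n: int
    method: str = "linear"

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def fence(self) -> float:
        return self.q3 + 1.5 * self.iqr


def _quartiles_linear(values: np.ndarray) -> tuple[float, float]:
    # linear interpolation of order statistics at h = (n - 1) p + 1
    return (
        float(np.quantile(values, 0.25, method="linear")),
        float(np.quantile(values, 0.75, method="linear")),
    )


def _quartiles_hinges(values: np.ndarray) -> tuple[float, float]:
    # Tukey hinges: medians of the lower/upper halves, median shared when n odd
    v = np.sort(values)
    n = len(v)
    half = n // 2
    lower = v[: half + (n % 2)]
    upper = v[half:]
    return float(np.median(lower)), float(np.median(upper))


_QUARTILE_METHODS = {"linear": _quartiles_linear, "hinges": _quartiles_hinges}


def compute_fences(iivs: Iterable[float], method: str = "linear") -> Fences:
    """Q1/Q3 and the Q3 + 1.5*IQR fence of one timepoint's IIV values."""
    values = np.asarray(list(iivs), dtype=float)
    if len(values) < 4:
        raise InsufficientSampleError(
            f"need at least 4 IIV values for fences, got {len(values)}"
        )
    if method not in _QUARTILE_METHODS:
        raise SchemaError(f"unknown quartile method {method!r}")
    q1, q3 = _QUARTILE_METHODS[method](values)
    return Fences(q1=q1, q3=q3, n=len(values), method=method)


# ---------------------------------------------------------------------------
# flagging


@dataclass(frozen=True)
class OutlierFlags:
    records: pd.DataFrame  # patient_id, timepoint, iiv, flagged
    excluded_patients: frozenset[str]
    n_flagged_administrations: int

    @property
    def n_excluded_patients(self) -> int:
        return len(self.excluded_patients)


def flag_outlier_patients(
    iiv_records: pd.DataFrame, fences: Mapping[str, Fences]
) -> OutlierFlags:
    """Flag administrations strictly above their timepoint's fence; a patient
    flagged at one or both timepoints is excluded from all analyses."""
    unknown = set(iiv_records["timepoint"]) - set(fences)
    if unknown:
        raise SchemaError(f"IIV records reference unknown timepoints: {sorted(unknown)}")
    records = iiv_records.copy()
    thresholds = records["timepoint"].map({tp: f.fence for tp, f in fences.items()})
    records["flagged"] = records["iiv"].to_numpy() > thresholds.to_numpy()
    excluded = frozenset(records.loc[records["flagged"], "patient_id"])
    return OutlierFlags(
        records=records,
        excluded_patients=excluded,
        n_flagged_administrations=int(records["flagged"].sum()),
    )
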