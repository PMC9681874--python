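"""End-to-end orchestration: simulate/load -> score -> filter -> analyse.

Stage order is fixed: scoring, completer selection, impairment labels, IIV
fences and flags on the full evaluable sample (subgroups inherit the global
flags), then the analysis variants, baseline-comparison tables and the
symptom regression.  Every run produces a manifest that reproduces the
bundle bit-for-bit for synthetic inputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    Fences,
    OutlierFlags,
    classify_impairment,
    compute_fences,
    flag_outlier_patients,
    iiv_table,
    select_completers,
)
from .effects import (
    RegressionResult,
    baseline_comparisons,
    comparisons_to_frame,
    compute_changes,
    effects_to_frame,
    estimate_effects,
    fit_ancova,
    regress_change,
)
from .errors import (
    CiasPipeError,
    ConfigError,
    InsufficientSampleError,
    PipelineStageError,
    ZeroVarianceError,
)
from .norms import score_dataframe
from .simulate import SynthConfig, TrialDataset, generate_trial, load_dataset

EFFECT_COLUMNS = ["treatment", "n", "estimate", "se", "ci_lo", "ci_hi", "t", "p", "cohen_d"]
#: exact column heads of the written effect tables
REPORT_EFFECT_COLUMNS = [
    "Treatment",
    "Estimate (SE)",
    "CI lower",
    "CI upper",
    "p value",
    "Cohen's d",
]

STATUS_OK = "ok"
STATUS_EMPTY = "empty-analysis"


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthConfig | None = None
    data_csv: str | None = None
    norms_csv: str | None = None
    stratify: bool = True
    iiv_exclusion: bool = True
    seed: int | None = None  # overrides synth.seed when set
    fence_method: str = "linear"
    lsmeans_weighting: str = "equal"

    def resolved_synth(self) -> SynthConfig | None:
        if self.synth is None:
            return None
        if self.seed is not None:
            return dataclasses.replace(self.synth, seed=self.seed)
        return self.synth

    def validate(self) -> None:
        has_synth = self.synth is not None
        has_files = self.data_csv is not None and self.norms_csv is not None
        if has_synth == has_files:
            raise ConfigError(
                "configure exactly one input source: synthetic config or data+norms paths"
            )

    def to_dict(self) -> dict:
        synth = self.resolved_synth()
        return {
            "synth": synth.to_dict() if synth is not None else None,
            "data_csv": self.data_csv,
            "norms_csv": self.norms_csv,
            "stratify": self.stratify,
            "iiv_exclusion": self.iiv_exclusion,
            "seed": self.seed,
            "fence_method": self.fence_method,
            "lsmeans_weighting": self.lsmeans_weighting,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synth") is not None:
            d["synth"] = SynthConfig.from_dict(d["synth"])
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass
class ReportBundle:
    manifest: dict
    exclusions: pd.DataFrame  # patient_id, rule, timepoint
    baseline_tables: dict[str, pd.DataFrame]
    effect_tables: dict[str, pd.DataFrame]
    regressions: dict[str, RegressionResult | None]
    counts: dict[str, int]
    fences: dict[str, Fences]
    flags: OutlierFlags | None
    wide: pd.DataFrame
    empty: bool = False


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except CiasPipeError as exc:
                raise PipelineStageError(name, str(exc)) from exc

        return wrapped

    return deco


def _empty_effect_table() -> pd.DataFrame:
    return pd.DataFrame(columns=EFFECT_COLUMNS)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    config.validate()

    # --- input
    synth = config.resolved_synth()
    if synth is not None:
        dataset: TrialDataset = _stage("simulate")(generate_trial)(synth)
    else:
        dataset = _stage("load")(load_dataset)(config.data_csv, config.norms_csv)

    # --- scoring
    scored = _stage("scoring")(score_dataframe)(dataset.data, dataset.norms)

    # --- completer selection
    selection = _stage("completer-filter")(select_completers)(scored)
    evaluable = selection.data
    n_evaluable = len(selection.retained)

    exclusion_rows = [
        {"patient_id": pid, "rule": rule, "timepoint": ""}
        for rule, ids in selection.ledger.entries
        for pid in ids
    ]

    counts: dict[str, int] = {"n_evaluable": n_evaluable}
    for rule, ids in selection.ledger.entries:
        counts[f"n_excluded_{rule}"] = len(ids)

    if n_evaluable == 0:
        manifest = _manifest(config, counts, {}, None)
        return ReportBundle(
            manifest=manifest,
            exclusions=pd.DataFrame(exclusion_rows, columns=["patient_id", "rule", "timepoint"]),
            baseline_tables={},
            effect_tables={"all": _empty_effect_table()},
            regressions={},
            counts=counts,
            fences={},
            flags=None,
            wide=pd.DataFrame(),
            empty=True,
        )

    # --- change scores + impairment labels
    wide, routed = _stage("change-scores")(compute_changes)(evaluable)
    if routed:
        exclusion_rows += [
            {"patient_id": pid, "rule": "missing_endpoint", "timepoint": ""} for pid in routed
        ]
    wide = wide.copy()
    wide["impairment"] = [classify_impairment(v) for v in wide["baseline_composite"]]
    counts["n_impaired"] = int((wide["impairment"] == "impaired").sum())
    counts["n_minimally_impaired"] = int((wide["impairment"] == "minimally_impaired").sum())

    # --- IIV fences and flags (full evaluable sample, before any split)
    iivs = _stage("iiv")(iiv_table)(evaluable)
    fences: dict[str, Fences] = {}
    flags: OutlierFlags | None = None
    try:
        for tp in sorted(iivs["timepoint"].unique()):
            fences[tp] = compute_fences(
                iivs.loc[iivs["timepoint"] == tp, "iiv"], method=config.fence_method
            )
        flags = flag_outlier_patients(iivs, fences)
    except InsufficientSampleError:
        fences, flags = {}, None

    excluded_ids: frozenset[str] = flags.excluded_patients if flags else frozenset()
    wide["iiv_excluded"] = wide["patient_id"].isin(excluded_ids)
    counts["n_iiv_excluded"] = int(wide["iiv_excluded"].sum())
    counts["n_included"] = int(len(wide) - wide["iiv_excluded"].sum())
    counts["n_flagged_administrations"] = flags.n_flagged_administrations if flags else 0
    if flags is not None:
        exclusion_rows += [
            {"patient_id": r.patient_id, "rule": "iiv_outlier", "timepoint": r.timepoint}
            for r in flags.records.itertuples()
            if r.flagged
        ]
    if dataset.truth is not None:
        counts["n_contaminated_truth"] = int(
            dataset.truth.administrations["contaminated"].sum()
        )

    # bookkeeping invariants (cheap, checked on every run)
    assert counts["n_impaired"] + counts["n_minimally_impaired"] == len(wide)
    assert counts["n_included"] + counts["n_iiv_excluded"] == len(wide)

    # --- analysis variants
    samples = ["all"] + (["impaired", "minimal"] if config.stratify else [])
    excl_options = [False] + ([True] if config.iiv_exclusion else [])
    effect_tables: dict[str, pd.DataFrame] = {}
    for sample in samples:
        for excl in excl_options:
            key = sample + ("_iiv_excluded" if excl else "")
            sub = wide
            if sample == "impaired":
                sub = sub[sub["impairment"] == "impaired"]
            elif sample == "minimal":
                sub = sub[sub["impairment"] == "minimally_impaired"]
            if excl:
                sub = sub[~sub["iiv_excluded"]]
            try:
                fit = fit_ancova(sub)
                est = estimate_effects(fit, weighting=config.lsmeans_weighting)
                effect_tables[key] = effects_to_frame(est)
            except (InsufficientSampleError,) as exc:
                effect_tables[key] = _empty_effect_table()

    # --- baseline comparisons
    baseline_tables: dict[str, pd.DataFrame] = {}
    chars = [
        ("age", "continuous"),
        ("sex", "categorical"),
        ("baseline_panss", "continuous"),
        ("baseline_composite", "continuous"),
    ]
    for name, col in (("treatment", "arm"), ("impairment", "impairment")):
        if wide[col].nunique() >= 2:
            comps = baseline_comparisons(wide, col, chars, positive_level="male")
            baseline_tables[name] = comparisons_to_frame(comps)
    if 0 < counts["n_iiv_excluded"] < len(wide):
        wide_iiv = wide.copy()
        wide_iiv["iiv_group"] = np.where(wide_iiv["iiv_excluded"], "excluded", "included")
        comps = baseline_comparisons(wide_iiv, "iiv_group", chars, positive_level="male")
        baseline_tables["iiv"] = comparisons_to_frame(comps)

    # --- symptom regression
    regressions: dict[str, RegressionResult | None] = {}
    for key, frame in (
        ("change", wide),
        ("change_iiv_excluded", wide[~wide["iiv_excluded"]]),
    ):
        try:
            regressions[key] = regress_change(frame["d_panss"], frame["d_composite"])
        except (InsufficientSampleError, ZeroVarianceError):
            regressions[key] = None
    try:
        regressions["baseline"] = regress_change(
            wide["baseline_panss"], wide["baseline_composite"]
        )
    except (InsufficientSampleError, ZeroVarianceError):
        regressions["baseline"] = None

    manifest = _manifest(config, counts, fences, dataset.config)
    return ReportBundle(
        manifest=manifest,
        exclusions=pd.DataFrame(exclusion_rows, columns=["patient_id", "rule", "timepoint"]),
        baseline_tables=baseline_tables,
        effect_tables=effect_tables,
        regressions=regressions,
        counts=counts,
        fences=fences,
        flags=flags,
        wide=wide,
        empty=False,
    )


def _manifest(
    config: PipelineConfig,
    counts: dict,
    fences: dict[str, Fences],
    synth: SynthConfig | None,
) -> dict:
    return {
        "package": "ciaspipe",
        "version": __version__,
        "config": config.to_dict(),
        "counts": counts,
        "fences": {
            tp: {"q1": f.q1, "q3": f.q3, "iqr": f.iqr, "fence": f.fence, "n": f.n}
            for tp, f in fences.items()
        },
    }


# ---------------------------------------------------------------------------
# report writing


def format_effect_table(numeric: pd.DataFrame) -> pd.DataFrame:
    """Paper-style table: estimates to two decimals, p-values to three."""
    rows = []
    for r in numeric.itertuples():
        label = r.treatment
        if pd.notna(r.n) and r.n is not None and label != "active vs placebo":
            label = f"{r.treatment} (n={int(r.n)})"
        rows.append(
            {
                "Treatment": label,
                "Estimate (SE)": f"{r.estimate:.2f} ({r.se:.2f})",
                "CI lower": f"{r.ci_lo:.2f}",
                "CI upper": f"{r.ci_hi:.2f}",
                "p value": f"{r.p:.3f}",
                "Cohen's d": f"{r.cohen_d:.2f}",
            }
        )
    return pd.DataFrame(rows, columns=REPORT_EFFECT_COLUMNS)


def write_report(bundle: ReportBundle, outdir, fmt: str = "csv") -> tuple[dict, str]:
    """Write the report bundle atomically; returns (paths, status).

    All files are staged into a temporary directory and moved into place
    only after every write has succeeded, so an unwritable path leaves no
    partial report behind.
    """
    if fmt != "csv":
        raise ConfigError(f"unsupported report format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".report-", dir=outdir))
    try:
        staged: dict[str, Path] = {}

        def _put(name: str, writer) -> None:
            path = staging / name
            writer(path)
            staged[name] = path

        _put(
            "manifest.json",
            lambda p: p.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"),
        )
        _put("exclusions.csv", lambda p: bundle.exclusions.to_csv(p, index=False))
        for key, table in sorted(bundle.effect_tables.items()):
            _put(f"effects_{key}.csv", lambda p, t=table: format_effect_table(t).to_csv(p, index=False))
        for key, table in sorted(bundle.baseline_tables.items()):
            _put(f"baseline_{key}.csv", lambda p, t=table: t.to_csv(p, index=False, float_format="%.4f"))
        reg_rows = []
        for key in sorted(bundle.regressions):
            res = bundle.regressions[key]
            if res is None:
                continue
            reg_rows.append(
                {
                    "model": key,
                    "slope": f"{res.slope:.4f}",
                    "std_beta": f"{res.std_beta:.2f}",
                    "r2": f"{res.r2:.3f}",
                    "adj_r2": f"{res.adj_r2:.3f}",
                    "p value": f"{res.p:.3f}",
                    "n": res.n,
                }
            )
        _put(
            "regression.csv",
            lambda p: pd.DataFrame(
                reg_rows, columns=["model", "slope", "std_beta", "r2", "adj_r2", "p value", "n"]
            ).to_csv(p, index=False),
        )
        _put("summary.txt", lambda p: p.write_text(_summary_text(bundle)))

        paths = {}
        for name, src in staged.items():
            dst = outdir / name
            os.replace(src, dst)
            paths[name] = dst
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    return paths, (STATUS_EMPTY if bundle.empty else STATUS_OK)


def _summary_text(bundle: ReportBundle) -> str:
    lines = ["analysis summary", "================", ""]
    for k in sorted(bundle.counts):
        lines.append(f"{k}: {bundle.counts[k]}")
    lines.append("")
    for tp, f in sorted(bundle.fences.items()):
        lines.append(
            f"IIV fence at {tp}: q1={f.q1:.2f} q3={f.q3:.2f} iqr={f.iqr:.2f} fence={f.fence:.2f} (n={f.n})"
        )
    lines.append("")
    for key in sorted(bundle.effect_tables):
        table = bundle.effect_tables[key]
        lines.append(f"[{key}]")
        if table.empty:
            lines.append("  (no analysable patients)")
        else:
            for r in table.itertuples():
                lines.append(
                    f"  {r.treatment}: {r.estimate:.2f} ({r.se:.2f}), "
                    f"p={r.p:.3f}, d={r.cohen_d:.2f}"
                )
        lines.append("")
    return "\n".join(lines) + "\n"
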