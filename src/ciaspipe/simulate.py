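"""Synthetic randomised-trial generator with known ground truth.

Generates a two-arm trial with the statistical structure the downstream
analysis assumes: a latent cognitive ability drawn from a two-component
mixture (so the fraction with true composite below -1 is controllable
exactly), correlated subtest scores produced through band norms, a treated
week-5 shift that differs by true impairment subgroup, symptom scores
coupled to the cognitive change, and optional contamination that inflates
cross-subtest scatter without moving the panel mean in expectation.

All random draws come from one seeded generator stream in the order
documented in :func:`generate_trial`, so a dataset is a pure function of
its config.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .errors import ConfigError
from .norms import (
    AGE_BANDS,
    DEFAULT_DIRECTIONS,
    SUBTESTS,
    NormTable,
    NormativeBand,
    SubtestNorm,
    lookup_band,
)
from .panss import N_GENERAL_ITEMS, PanssScale

VISITS = ("screening", "baseline", "week5")
#: administrations that enter the analysis (and may be contaminated)
ANALYSED_VISITS = ("baseline", "week5")

DATA_COLUMNS = [
    "patient_id",
    "arm",
    "site",
    "age",
    "sex",
    "visit",
    "panss_total",
    "panss_pos",
    "panss_neg",
    *SUBTESTS,
]

# stylised per-subtest raw-score scales: (base mean, per-band drift, base sd)
_RAW_SCALES = {
    "identification": (700.0, 18.0, 80.0),
    "detection": (450.0, 12.0, 60.0),
    "groton_maze": (55.0, 3.0, 12.0),
    "shopping_list": (27.0, -0.6, 4.0),
    "one_back": (1.30, -0.02, 0.15),
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic trial."""

    n_per_arm: int = 60
    n_placebo: int | None = None  # defaults to n_per_arm (e.g. 60/65 split)
    n_sites: int = 12
    age_range: tuple[int, int] = (18, 60)
    impaired_fraction: float = 0.5
    effect_impaired: float = 0.0
    effect_minimal: float = 0.0
    subtest_sd: float = 0.5
    subtest_loading: float = 1.0
    practice_effect: float = 0.15
    change_sd: float = 0.55
    contamination_rate: float = 0.0
    contamination_scale: float = 3.0
    panss_baseline_mean: float = 96.0
    panss_baseline_sd: float = 8.0
    panss_cbb_coupling: float = 0.03
    panss_change_mean: float = -10.0
    panss_change_sd: float = 10.0
    dropout_rate: float = 0.0
    missing_subtest_rate: float = 0.0
    male_fraction: float = 0.72
    site_sd: float = 0.10
    impaired_mean: float = -2.0
    impaired_sd: float = 0.8
    minimal_mean: float = -0.4
    minimal_sd: float = 0.43
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "impaired_fraction": self.impaired_fraction,
            "contamination_rate": self.contamination_rate,
            "dropout_rate": self.dropout_rate,
            "missing_subtest_rate": self.missing_subtest_rate,
            "male_fraction": self.male_fraction,
            "panss_cbb_coupling": self.panss_cbb_coupling,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        positives = {
            "subtest_sd": self.subtest_sd,
            "change_sd": self.change_sd,
            "panss_baseline_sd": self.panss_baseline_sd,
            "panss_change_sd": self.panss_change_sd,
            "impaired_sd": self.impaired_sd,
            "minimal_sd": self.minimal_sd,
        }
        for name, v in positives.items():
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v} (degenerate mixture)")
        if self.n_per_arm < 2:
            raise ConfigError(f"n_per_arm must be >= 2, got {self.n_per_arm}")
        if self.n_placebo is not None and self.n_placebo < 2:
            raise ConfigError(f"n_placebo must be >= 2, got {self.n_placebo}")
        if self.n_sites < 1:
            raise ConfigError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.contamination_scale < 1:
            raise ConfigError(
                f"contamination_scale must be >= 1, got {self.contamination_scale}"
            )
        lo, hi = self.age_range
        if not (AGE_BANDS[0][0] <= lo <= hi <= AGE_BANDS[-1][1]):
            raise ConfigError(f"age_range {self.age_range} outside normative coverage")
        if self.site_sd < 0:
            raise ConfigError("site_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass(frozen=True)
class TrialTruth:
    """Generator-side ground truth for a synthetic dataset."""

    patients: pd.DataFrame  # patient_id, true_impaired, ability, change
    administrations: pd.DataFrame  # patient_id, visit, contaminated


@dataclass(frozen=True)
class TrialDataset:
    data: pd.DataFrame
    norms: NormTable
    config: SynthConfig | None = None
    truth: TrialTruth | None = None

    def __post_init__(self) -> None:
        if (self.config is None) != (self.truth is None):
            raise ConfigError("truth must be present iff provenance (config) is present")
        ids = self.data[["patient_id", "visit"]]
        if ids.duplicated().any():
            raise ConfigError("duplicate patient_id x visit rows")
        bad_visits = set(self.data["visit"]) - set(VISITS)
        if bad_visits:
            raise ConfigError(f"unknown visits: {sorted(bad_visits)}")


def generate_norms(n_subtests: int = 5, seed: int = 0, sd_scale: float = 1.0) -> NormTable:
    """Generate a stylised four-band normative table (18-34, 35-49, 50-59, 60-69)."""
    if n_subtests != len(SUBTESTS):
        raise ConfigError(f"battery layout requires {len(SUBTESTS)} subtests, got {n_subtests}")
    if not sd_scale > 0:
        raise ConfigError(f"sd_scale must be > 0, got {sd_scale}")
    rng = np.random.default_rng(seed)
    bands = []
    for i, (lo, hi) in enumerate(AGE_BANDS):
        norms = {}
        for st in SUBTESTS:
            base_mean, drift, base_sd = _RAW_SCALES[st]
            mean = base_mean + drift * i + rng.normal(0.0, 0.03 * base_sd)
            sd = base_sd * sd_scale * rng.uniform(0.85, 1.15)
            norms[st] = SubtestNorm(mean=mean, sd=sd, direction=DEFAULT_DIRECTIONS[st])
        bands.append(NormativeBand(lo, hi, norms))
    return NormTable(bands)


def generate_trial(config: SynthConfig) -> TrialDataset:
    """Simulate one trial.

    Draw order (single ``default_rng(config.seed)`` stream):
    arm permutation, site assignment, ages, sexes, subgroup labels, latent
    abilities (impaired then minimal candidates), site intercepts,
    change noise, subtest scatter, baseline symptom totals, subscale noise,
    screening symptom noise, coupling noise, dropout flags, missing-subtest
    flags and positions, then (if requested) the contamination sub-seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_act = config.n_per_arm
    n_pla = config.n_placebo if config.n_placebo is not None else config.n_per_arm
    n = n_act + n_pla

    # 1-4: design variables
    arms = rng.permutation(np.array(["active"] * n_act + ["placebo"] * n_pla))
    site_idx = rng.integers(0, config.n_sites, n)
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, n)
    sexes = np.where(rng.random(n) < config.male_fraction, "male", "female")

    # 5-6: latent ability from a truncated two-component mixture; truncation
    # at -1 makes the true subgroup fraction exactly impaired_fraction.
    impaired = rng.random(n) < config.impaired_fraction
    imp_draw = truncnorm.rvs(
        -np.inf,
        (-1.0 - config.impaired_mean) / config.impaired_sd,
        loc=config.impaired_mean,
        scale=config.impaired_sd,
        size=n,
        random_state=rng,
    )
    min_draw = truncnorm.rvs(
        (-1.0 - config.minimal_mean) / config.minimal_sd,
        np.inf,
        loc=config.minimal_mean,
        scale=config.minimal_sd,
        size=n,
        random_state=rng,
    )
    ability = np.where(impaired, imp_draw, min_draw)

    # 7-9: change-score components and measurement scatter
    site_eff = rng.normal(0.0, config.site_sd, config.n_sites) if config.site_sd > 0 else np.zeros(config.n_sites)
    change_noise = rng.normal(0.0, config.change_sd, n)
    scatter = rng.normal(0.0, config.subtest_sd, (n, len(VISITS), len(SUBTESTS)))

    # 10-12: symptom scores
    scale = PanssScale()
    pm, ps = config.panss_baseline_mean, config.panss_baseline_sd
    panss0 = np.rint(
        truncnorm.rvs(
            (80.0 - pm) / ps, (scale.max_total - pm) / ps, loc=pm, scale=ps, size=n, random_state=rng
        )
    )
    pos0 = np.clip(np.rint(0.27 * panss0 + rng.normal(0.0, 2.0, n)), 7, 49)
    neg0 = np.clip(np.rint(0.235 * panss0 + rng.normal(0.0, 2.5, n)), 7, 49)
    neg0 = np.minimum(neg0, panss0 - N_GENERAL_ITEMS - pos0)  # general items >= 1 each
    scr_noise = np.rint(rng.normal(0.0, 3.0, n))

    # 13: treated shift + coupling of symptom change to cognitive change
    arm_effect = np.where(
        arms == "active",
        np.where(impaired, config.effect_impaired, config.effect_minimal),
        0.0,
    )
    change = arm_effect + site_eff[site_idx] + change_noise
    eps = rng.normal(0.0, 1.0, n)
    c = config.panss_cbb_coupling
    z_change = (change - change.mean()) / change.std() if change.std() > 0 else np.zeros(n)
    d_panss = config.panss_change_mean + config.panss_change_sd * (
        -np.sqrt(c) * z_change + np.sqrt(1.0 - c) * eps
    )
    panss5 = np.clip(np.rint(panss0 + d_panss), scale.min_total, scale.max_total)
    ratio5 = panss5 / panss0
    pos5 = np.clip(np.rint(pos0 * ratio5), 7, 49)
    neg5 = np.clip(np.rint(neg0 * ratio5), 7, 49)
    neg5 = np.minimum(neg5, panss5 - N_GENERAL_ITEMS - pos5)

    # 14-15: missingness
    dropout = rng.random(n) < config.dropout_rate
    miss_draw = rng.random((n, len(VISITS))) < config.missing_subtest_rate
    miss_which = rng.integers(0, len(SUBTESTS), (n, len(VISITS)))

    norms = generate_norms(len(SUBTESTS), config.seed)

    latent = np.column_stack(
        [ability - config.practice_effect, ability, ability + change]
    )  # columns follow VISITS order
    z_true = config.subtest_loading * latent[:, :, None] + scatter  # (n, visit, subtest)

    panss_by_visit = {
        "screening": (
            np.clip(panss0 + scr_noise, scale.min_total, scale.max_total),
            pos0,
            neg0,
        ),
        "baseline": (panss0, pos0, neg0),
        "week5": (panss5, pos5, neg5),
    }

    ids = np.array([f"P{i + 1:03d}" for i in range(n)])
    sites = np.array([f"S{j + 1:02d}" for j in site_idx])
    rows = []
    for v_i, visit in enumerate(VISITS):
        tot, pos, neg = panss_by_visit[visit]
        frame = pd.DataFrame(
            {
                "patient_id": ids,
                "arm": arms,
                "site": sites,
                "age": ages,
                "sex": sexes,
                "visit": visit,
                "panss_total": tot.astype(float),
                "panss_pos": pos.astype(float),
                "panss_neg": neg.astype(float),
            }
        )
        for s_i, st in enumerate(SUBTESTS):
            raw = np.empty(n)
            for band in norms.bands:
                m = (ages >= band.age_lo) & (ages <= band.age_hi)
                norm = band.norms[st]
                raw[m] = norm.mean + norm.direction * norm.sd * z_true[m, v_i, s_i]
            raw[miss_draw[:, v_i] & (miss_which[:, v_i] == s_i)] = np.nan
            frame[st] = raw
        if visit == "week5":
            frame = frame.loc[~dropout]
        rows.append(frame)
    data = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["patient_id", "visit"], kind="stable")
        .reset_index(drop=True)[DATA_COLUMNS]
    )

    truth_patients = pd.DataFrame(
        {
            "patient_id": ids,
            "true_impaired": impaired,
            "ability": ability,
            "change": change,
        }
    )
    admin = [
        {"patient_id": pid, "visit": v, "contaminated": False}
        for pid in ids
        for v in ANALYSED_VISITS
    ]
    truth = TrialTruth(
        patients=truth_patients,
        administrations=pd.DataFrame(admin),
    )
    dataset = TrialDataset(data=data, norms=norms, config=config, truth=truth)

    if config.contamination_rate > 0:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        dataset = inject_iiv_outliers(
            dataset, config.contamination_rate, config.contamination_scale, sub_seed
        )
    return dataset


def inject_iiv_outliers(
    dataset: TrialDataset, rate: float, scale: float, seed: int
) -> TrialDataset:
    """Contaminate a Bernoulli(rate) subset of analysed administrations.

    For a contaminated administration the subtest deviations about the
    panel mean (in z space) are multiplied by ``scale`` — cross-subtest
    scatter grows by exactly that factor — and the panel mean receives a
    fresh zero-mean perturbation sized so the composite's sampling variance
    matches true scatter inflation.  The panel mean is therefore unchanged
    in expectation, while realised composites of contaminated
    administrations become noisier (the attenuation-toward-the-null
    mechanism the fence exclusion is designed to reverse).
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"rate must be in [0, 1], got {rate}")
    if scale < 1.0:
        raise ConfigError(f"scale must be >= 1, got {scale}")
    if dataset.truth is None:
        warnings.warn(
            "dataset has no truth block: contamination applied but unverifiable",
            stacklevel=2,
        )
    data = dataset.data.copy()
    rng = np.random.default_rng(seed)
    admin_rows = data.index[data["visit"].isin(ANALYSED_VISITS)]
    flags = rng.random(len(admin_rows)) < rate
    contaminated: list[tuple[str, str]] = []
    for row_idx, hit in zip(admin_rows, flags):
        if not hit:
            continue
        row = data.loc[row_idx]
        band = lookup_band(int(row["age"]), dataset.norms)
        z = {}
        for st in SUBTESTS:
            raw = row[st]
            if pd.notna(raw):
                n_st = band.norms[st]
                z[st] = n_st.direction * (raw - n_st.mean) / n_st.sd
        if len(z) < 2:
            continue  # nothing to scatter
        zv = np.array(list(z.values()))
        zbar = zv.mean()
        s_hat = zv.std(ddof=1)
        shift = rng.normal(0.0, np.sqrt(scale**2 - 1.0) * s_hat / np.sqrt(len(zv)))
        for st in z:
            n_st = band.norms[st]
            z_new = zbar + shift + scale * (z[st] - zbar)
            data.loc[row_idx, st] = n_st.mean + n_st.direction * n_st.sd * z_new
        contaminated.append((row["patient_id"], row["visit"]))

    truth = dataset.truth
    if truth is not None:
        admins = truth.administrations.copy()
        if contaminated:
            key = admins.set_index(["patient_id", "visit"]).index
            hit_mask = key.isin(contaminated)
            admins.loc[hit_mask, "contaminated"] = True
        truth = TrialTruth(patients=truth.patients.copy(), administrations=admins)
    return TrialDataset(data=data, norms=dataset.norms, config=dataset.config, truth=truth)


# ---------------------------------------------------------------------------
# serialisation


def write_dataset(dataset: TrialDataset, outdir) -> dict[str, Path]:
    """Write long-format data, norms, truth sidecars and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["data"] = outdir / "data.csv"
    dataset.data.to_csv(paths["data"], index=False)
    paths["norms"] = outdir / "norms.csv"
    dataset.norms.write_csv(paths["norms"])
    if dataset.truth is not None:
        paths["truth_patients"] = outdir / "truth_patients.csv"
        dataset.truth.patients.to_csv(paths["truth_patients"], index=False)
        paths["truth_administrations"] = outdir / "truth_administrations.csv"
        dataset.truth.administrations.to_csv(paths["truth_administrations"], index=False)
    if dataset.config is not None:
        paths["config"] = outdir / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return paths


def load_dataset(data_csv, norms_csv) -> TrialDataset:
    """Load externally supplied data (no provenance, no truth)."""
    data = pd.read_csv(data_csv)
    missing = set(DATA_COLUMNS) - set(data.columns)
    if missing:
        raise ConfigError(f"data file missing columns: {sorted(missing)}")
    return TrialDataset(data=data, norms=NormTable.read_csv(norms_csv))
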