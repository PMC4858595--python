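"""Synthetic two-arm school-cluster RCT generator with known ground truth.

Emulates the data structure of a school-randomized alcohol-prevention trial:
baseline demographic imbalance between arms, school-level clustering of the
drinking outcomes (random intercepts inducing a chosen intraclass
correlation), right-skewed zero-inflated service-use volumes over a 4-month
recall window, a small subsample that systematically fills in unrealistic
answers, cost-question nonresponse, and heavy covariate-dependent dropout at
follow-up.  Every stage draws from its own RNG stream derived from the
scenario seed by a fixed label, so adding a stage never perturbs earlier
draws, and the same seed reproduces the table bit for bit.

The drinking outcomes are generated as change scores on a latent scale:

    change = arm_effect * 1[intervention] - secular_drift + b_cluster + eps

with b_cluster ~ N(0, icc * sd^2) and eps ~ N(0, (1 - icc) * sd^2), and
T1 = clip(T0 - change, 0, upper).  The clipping keeps outcomes in their
legal range; scenarios intended for parameter-recovery checks should keep
baselines well above zero so the floor is rarely hit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .screening import PlausibilityLimits

__all__ = [
    "VolumeModel", "TrialScenario", "GroundTruth", "generate_trial",
    "inject_contamination", "apply_dropout", "write_participants",
    "read_participants", "VOLUME_CATEGORIES",
]

#: service-use and substance-use categories, with their sampling family
VOLUME_CATEGORIES = (
    "gp_contacts", "emergency_visits", "hospital_days", "ambulance_rides",
    "mental_health_contacts", "school_absence_hours",
    "attendance_officer_contacts", "work_absence_hours",
    "household_hours_missed", "other_activity_hours_missed",
    "youth_family_center_contacts", "family_care_contacts", "police_contacts",
    "youth_police_contacts", "court_proceedings", "child_protection_contacts",
    "child_health_protection_contacts", "cigarette_packs", "soft_drug_units",
    "hard_drug_units",
)

RELIGIONS = ("none", "Catholic", "Protestant", "Muslim", "other")
ETHNICITIES = ("Dutch", "Antillean", "Belgian", "German", "Surinamese",
               "Moroccan", "Turkish", "other")

# fixed per-stage RNG stream labels (spawn keys off the scenario seed)
_STREAMS = {"structure": 0, "demographics": 1, "outcomes": 2, "volumes": 3,
            "response": 4, "contamination": 5, "dropout": 6}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stage],)))


@dataclass(frozen=True)
class VolumeModel:
    """Zero-inflated right-skewed model for one volume category.

    kind 'negbin': structural zero with probability p_zero, else a negative
    binomial count with the given positive-part mean and dispersion (gamma
    shape; smaller = heavier tail).  kind 'lognormal': structural zero, else
    a log-normal with that mean and log-scale sigma = dispersion.
    """

    kind: str
    p_zero: float
    mean: float
    dispersion: float

    def __post_init__(self):
        if self.kind not in ("negbin", "lognormal"):
            raise ValueError(f"unknown volume model kind {self.kind!r}")
        if not 0 <= self.p_zero < 1:
            raise ValueError("p_zero must be in [0, 1)")
        if not np.isfinite(self.mean) or self.mean <= 0:
            raise ValueError("positive-part mean must be finite and > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        zero = rng.random(n) < self.p_zero
        if self.kind == "negbin":
            # NB as gamma-Poisson mixture: mean m, shape k
            lam = rng.gamma(self.dispersion, self.mean / self.dispersion, size=n)
            pos = rng.poisson(lam).astype(float)
        else:
            sigma = self.dispersion
            mu = np.log(self.mean) - sigma ** 2 / 2.0
            pos = rng.lognormal(mu, sigma, size=n)
        return np.where(zero, 0.0, pos)


def _default_volume_models() -> dict:
    """Study-condition defaults: sparse, right-skewed volumes whose expected
    costs under the example unit-cost table sit at the scale of a 4-month
    adolescent recall (tens of Euro per category at most)."""
    m = {
        "gp_contacts": ("negbin", 0.65, 2.2, 0.8),
        "emergency_visits": ("negbin", 0.97, 1.2, 1.0),
        "hospital_days": ("negbin", 0.985, 6.5, 0.5),
        "ambulance_rides": ("negbin", 0.985, 1.05, 1.0),
        "mental_health_contacts": ("negbin", 0.95, 3.0, 0.6),
        "school_absence_hours": ("lognormal", 0.50, 21.0, 1.0),
        "attendance_officer_contacts": ("negbin", 0.99, 2.0, 1.0),
        "work_absence_hours": ("lognormal", 0.90, 6.0, 1.0),
        "household_hours_missed": ("lognormal", 0.80, 3.7, 1.0),
        "other_activity_hours_missed": ("lognormal", 0.80, 6.8, 1.0),
        "youth_family_center_contacts": ("negbin", 0.997, 1.0, 1.0),
        "family_care_contacts": ("negbin", 0.99, 1.8, 1.0),
        "police_contacts": ("negbin", 0.992, 2.1, 0.8),
        "youth_police_contacts": ("negbin", 0.997, 1.7, 1.0),
        "court_proceedings": ("negbin", 0.997, 10.0, 0.5),
        "child_protection_contacts": ("negbin", 0.998, 2.0, 1.0),
        "child_health_protection_contacts": ("negbin", 0.996, 4.7, 1.0),
        "cigarette_packs": ("negbin", 0.75, 16.7, 0.6),
        "soft_drug_units": ("negbin", 0.93, 7.8, 0.6),
        "hard_drug_units": ("negbin", 0.995, 5.5, 0.8),
    }
    return {k: VolumeModel(kind, pz, mean, disp)
            for k, (kind, pz, mean, disp) in m.items()}


@dataclass
class TrialScenario:
    """Generating parameters of one synthetic trial.

    Defaults mirror the emulated study's conditions: 17 schools per arm of
    ~78 students (≈2650 at baseline), ICC .01 for weekly alcohol use and .06
    for binge occasions, a secular increase in drinking over the 4 months
    (control change scores -1.51 glasses/week and -0.33 occasions), arm
    effects 0.73 glasses/week and 0.49 occasions, ~3.5% systematic
    unrealistic answering, and ~70% dropout at follow-up that depends on
    covariates (missing not at random by construction).
    """

    n_clusters_per_arm: int = 17
    cluster_size_mean: int = 78
    icc_weekly: float = 0.01
    icc_binge: float = 0.06
    arm_effect_weekly: float = 0.73
    arm_effect_binge: float = 0.49
    secular_drift_weekly: float = 1.51
    secular_drift_binge: float = 0.33
    sd_change_weekly: float = 6.0
    sd_change_binge: float = 3.0
    # baseline outcome models
    weekly_t0_zero_prob: float = 0.27
    weekly_t0_mean: float = 5.3
    weekly_t0_sigma: float = 1.0
    binge_t0_zero_prob: float = 0.49
    binge_t0_mean: float = 4.3
    binge_t0_dispersion: float = 1.0
    volume_models: dict = field(default_factory=_default_volume_models)
    contamination_rate: float = 0.035
    contamination_magnitude: float = 1000.0
    dropout_rate: float = 0.70
    dropout_covariate_weights: dict = field(
        default_factory=lambda: {"age": 0.15, "education_low": 0.3,
                                 "weekly_t0": 0.02})
    baseline_imbalance: dict = field(
        default_factory=lambda: {"female": 0.07, "education_low": -0.085,
                                 "religious": 0.032, "age_tilt": -0.08})
    cost_nonresponse_t0: float = 0.026
    cost_nonresponse_t1: float = 0.053
    seed: int = 0

    def validate(self):
        fracs = ["icc_weekly", "icc_binge", "contamination_rate",
                 "dropout_rate", "weekly_t0_zero_prob", "binge_t0_zero_prob",
                 "cost_nonresponse_t0", "cost_nonresponse_t1"]
        for name in fracs:
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_clusters_per_arm < 1:
            raise ValueError("n_clusters_per_arm must be >= 1")
        if self.cluster_size_mean < 2:
            raise ValueError("cluster_size_mean must be >= 2")
        for name in ("sd_change_weekly", "sd_change_binge"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.contamination_magnitude <= 1:
            raise ValueError("contamination_magnitude must be > 1")
        for cat, model in self.volume_models.items():
            if not isinstance(model, VolumeModel):
                raise ValueError(f"volume_models[{cat!r}] is not a VolumeModel")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "TrialScenario":
        d = dict(d)
        if "volume_models" in d:
            d["volume_models"] = {
                cat: VolumeModel(**spec) if isinstance(spec, dict) else spec
                for cat, spec in d["volume_models"].items()}
        return cls(**d).validate()


@dataclass
class GroundTruth:
    """What the generator actually put in: the recovery targets."""

    true_effect_weekly: float
    true_effect_binge: float
    true_icc_weekly: float
    true_icc_binge: float
    mean_volumes: dict
    contaminated_ids: list
    seed: int

    def true_mean_costs(self, unit_costs, intervention_spec=None) -> dict:
        """Expected cost per category per arm given a unit-cost table."""
        out = {}
        for arm in ("intervention", "control"):
            per_cat = {cat: float(unit_costs.indexed_price(cat)) * mv
                       for cat, mv in self.mean_volumes.items()}
            if intervention_spec is not None and arm == "intervention":
                per_cat["intervention"] = float(intervention_spec.total())
            out[arm] = per_cat
        return out

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sample_demographics(rng, n, arm, imbalance):
    sign = 1.0 if arm == "intervention" else -1.0
    p_female = np.clip(0.48 + sign * imbalance.get("female", 0.0), 0.0, 1.0)
    p_low = np.clip(0.40 + sign * imbalance.get("education_low", 0.0), 0.0, 1.0)
    p_rel = np.clip(0.41 + sign * imbalance.get("religious", 0.0), 0.0, 1.0)
    gender = np.where(rng.random(n) < p_female, "female", "male")
    education = np.where(rng.random(n) < p_low, "low", "high")
    # ages uniform over 15-19 whole years, optionally tilted linearly by arm
    ages = np.arange(15, 20)
    tilt = imbalance.get("age_tilt", 0.0) * sign
    w = 1.0 + tilt * (ages - 17)
    w = np.clip(w, 1e-9, None)
    age = rng.choice(ages, size=n, p=w / w.sum())
    religious = rng.random(n) < p_rel
    rel_named = np.array(RELIGIONS[1:])
    rel_p = np.array([0.577, 0.169, 0.146, 0.108])
    religion = np.where(religious,
                        rng.choice(rel_named, size=n, p=rel_p), "none")
    eth_p = np.array([0.8925, 0.002, 0.004, 0.005, 0.010, 0.014, 0.019, 0.0535])
    ethnicity = rng.choice(np.array(ETHNICITIES), size=n, p=eth_p / eth_p.sum())
    return pd.DataFrame({"gender": gender, "age": age, "education": education,
                         "religion": religion, "ethnicity": ethnicity})


def _latent_changes(rng, scenario, df, outcome):
    icc = getattr(scenario, f"icc_{outcome}")
    sd = getattr(scenario, f"sd_change_{outcome}")
    effect = getattr(scenario, f"arm_effect_{outcome}")
    drift = getattr(scenario, f"secular_drift_{outcome}")
    clusters = df["cluster_id"].to_numpy()
    labels = np.unique(clusters)
    b = rng.normal(0.0, np.sqrt(icc) * sd, size=len(labels))
    b_map = dict(zip(labels, b))
    eps = rng.normal(0.0, np.sqrt(max(0.0, 1.0 - icc)) * sd, size=len(df))
    is_iv = (df["arm"] == "intervention").to_numpy()
    return (effect * is_iv - drift
            + np.array([b_map[c] for c in clusters]) + eps)


def generate_trial(scenario: TrialScenario, limits: PlausibilityLimits = None):
    """Generate a participant table and its :class:`GroundTruth`.

    Contamination and dropout are applied when the scenario's rates are
    positive; ``limits`` (needed to size contaminated answers) defaults to
    the packaged plausibility-limit table.
    """
    scenario.validate()
    seed = scenario.seed

    # --- structure: balanced clusters of fixed size
    k, m = scenario.n_clusters_per_arm, scenario.cluster_size_mean
    rows = []
    pid = 0
    for ai, arm in enumerate(("intervention", "control")):
        for c in range(k):
            cid = f"{'I' if arm == 'intervention' else 'C'}{c:03d}"
            for _ in range(m):
                rows.append((f"P{pid:06d}", cid, arm))
                pid += 1
    df = pd.DataFrame(rows, columns=["participant_id", "cluster_id", "arm"])

    # --- demographics with arm imbalance
    rng_d = _rng(seed, "demographics")
    demo = []
    for arm in ("intervention", "control"):
        n_arm = int((df["arm"] == arm).sum())
        demo.append(_sample_demographics(rng_d, n_arm, arm,
                                         scenario.baseline_imbalance))
    df = pd.concat([df.reset_index(drop=True),
                    pd.concat(demo, ignore_index=True)], axis=1)

    # --- outcomes
    rng_o = _rng(seed, "outcomes")
    n = len(df)
    zero_w = rng_o.random(n) < scenario.weekly_t0_zero_prob
    mu_w = np.log(scenario.weekly_t0_mean) - scenario.weekly_t0_sigma ** 2 / 2
    w0 = np.where(zero_w, 0.0, rng_o.lognormal(mu_w, scenario.weekly_t0_sigma, n))
    zero_b = rng_o.random(n) < scenario.binge_t0_zero_prob
    lam = rng_o.gamma(scenario.binge_t0_dispersion,
                      scenario.binge_t0_mean / scenario.binge_t0_dispersion, n)
    b0 = np.where(zero_b, 0.0, rng_o.poisson(lam).astype(float))
    b0 = np.minimum(b0, 30.0)
    chg_w = _latent_changes(rng_o, scenario, df, "weekly")
    chg_b = _latent_changes(rng_o, scenario, df, "binge")
    df["weekly_glasses_t0"] = w0
    df["weekly_glasses_t1"] = np.maximum(0.0, w0 - chg_w)
    df["binge_t0"] = b0
    df["binge_t1"] = np.clip(b0 - chg_b, 0.0, 30.0)

    # --- service-use volumes
    rng_v = _rng(seed, "volumes")
    for cat in VOLUME_CATEGORIES:
        model = scenario.volume_models.get(cat)
        df[cat] = model.sample(rng_v, n) if model is not None else 0.0

    # --- cost-question response flags
    rng_r = _rng(seed, "response")
    df["cost_answers_present_t0"] = rng_r.random(n) >= scenario.cost_nonresponse_t0
    df["cost_answers_present_t1"] = rng_r.random(n) >= scenario.cost_nonresponse_t1

    # --- contamination
    contaminated = []
    if scenario.contamination_rate > 0:
        if limits is None:
            from .config import default_limits
            limits = default_limits()
        df, contaminated = inject_contamination(
            df, scenario.contamination_rate, scenario.contamination_magnitude,
            limits, rng=_rng(seed, "contamination"))

    # --- dropout
    if scenario.dropout_rate > 0:
        df = apply_dropout(df, scenario, rng=_rng(seed, "dropout"))

    truth = GroundTruth(
        true_effect_weekly=scenario.arm_effect_weekly,
        true_effect_binge=scenario.arm_effect_binge,
        true_icc_weekly=scenario.icc_weekly,
        true_icc_binge=scenario.icc_binge,
        mean_volumes={cat: (1.0 - mod.p_zero) * mod.mean
                      for cat, mod in scenario.volume_models.items()},
        contaminated_ids=list(contaminated),
        seed=seed,
    )
    return df, truth


def inject_contamination(df: pd.DataFrame, rate: float, magnitude_factor: float,
                         limits: PlausibilityLimits, rng=None, seed: int = 0):
    """Flag a random subsample as systematic unrealistic answerers.

    Each flagged participant gets, in at least two randomly chosen volume
    fields, a value of at least ``magnitude_factor`` times that field's
    plausibility limit.  Returns (new table, flagged participant ids).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if magnitude_factor <= 1:
        raise ValueError("magnitude_factor must be > 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = df.copy()
    if rate == 0:
        return out, []
    cats = [c for c in limits.limits if c in out.columns]
    flagged_mask = rng.random(len(out)) < rate
    flagged_idx = np.flatnonzero(flagged_mask)
    for i in flagged_idx:
        # mean ~2.9 implausible fields per contaminated respondent
        n_fields = 2 + rng.poisson(0.9)
        n_fields = min(n_fields, len(cats))
        chosen = rng.choice(len(cats), size=n_fields, replace=False)
        for j in chosen:
            cat = cats[j]
            out.iloc[i, out.columns.get_loc(cat)] = (
                limits.limits[cat] * magnitude_factor * (1.0 + rng.random()))
    ids = (out.iloc[flagged_idx]["participant_id"].tolist()
           if "participant_id" in out.columns else list(flagged_idx))
    return out, ids


_DROPOUT_COVARIATES = {
    "age": lambda df: df["age"].astype(float),
    "female": lambda df: (df["gender"] == "female").astype(float),
    "education_low": lambda df: (df["education"] == "low").astype(float),
    "religious": lambda df: (df["religion"] != "none").astype(float),
    "non_dutch": lambda df: (df["ethnicity"] != "Dutch").astype(float),
    "weekly_t0": lambda df: df["weekly_glasses_t0"].astype(float),
}


def apply_dropout(df: pd.DataFrame, scenario: TrialScenario, rng=None):
    """Clear T1 fields for a covariate-dependent subsample (MNAR by design).

    P(dropout) follows a logistic model: logit(rate) plus the weighted sum
    of mean-centered covariates, so the marginal rate stays close to
    ``scenario.dropout_rate`` while selection depends on who you are.
    """
    rate = scenario.dropout_rate
    if not 0 <= rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    if rng is None:
        rng = _rng(scenario.seed, "dropout")
    out = df.copy()
    if rate == 0:
        return out
    eta = np.full(len(out), np.log(rate / (1.0 - rate)))
    for name, weight in scenario.dropout_covariate_weights.items():
        if name not in _DROPOUT_COVARIATES:
            raise ValueError(f"unknown dropout covariate {name!r}")
        x = _DROPOUT_COVARIATES[name](out).to_numpy()
        eta += weight * (x - x.mean())
    p = 1.0 / (1.0 + np.exp(-eta))
    dropped = rng.random(len(out)) < p
    out.loc[dropped, "weekly_glasses_t1"] = np.nan
    out.loc[dropped, "binge_t1"] = np.nan
    out.loc[dropped, "cost_answers_present_t1"] = False
    return out


def write_participants(df: pd.DataFrame, path):
    """Participant table as CSV; missing T1 values become empty strings."""
    df.to_csv(path, index=False, na_rep="")


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("cost_answers_present_t0", "cost_answers_present_t1"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df
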