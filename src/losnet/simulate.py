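"""Synthetic admission cohorts with planted covariate→LOS effects.

Real department-level administrative data are not redistributable, so this
module generates cohorts whose covariate prevalences match the published
department profile (per-unit age mix, cancer prevalence, sex, admission
type, time slot, weekday, internal transfers) and whose stay lengths follow
an explicit generative model:

    LOS = exp( mu_DRG + beta·x + sigma·eps ),   eps ~ N(0, 1)

a log-normal with additive covariate effects on the log mean — the simplest
strictly positive, right-skewed model consistent with the LOS literature.
The planted effect vector ``beta`` is exposed via :func:`planted_truth` so
model-recovery tests have ground truth.

The matching DRG reference table is derived from the generating model, not
from the sample: the benchmark is the exact marginal mean of the model for
each DRG (mirroring a national mean), and the outlier threshold is the
per-DRG upper quantile whose exceedance equals the configured outlier rate.
When ``sigma`` is left unset it is calibrated so the expected fraction of
stays above their benchmark hits the configured long-stay rate (default
40.06%, with 3.74% outliers — the department-level outcome mix).  Both
calibrations use the exact finite distribution of ``beta·x`` (covariate
blocks are sampled independently, so it is a small discrete convolution)
rather than Monte-Carlo.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from losnet.records import (
    AGE_CLASSES,
    ADMISSION_TYPES,
    DISCHARGE_MODES,
    DRGReference,
    HospitalizationRecord,
    TIME_SLOTS,
    UNITS,
    WEEKDAYS,
)

# ---------------------------------------------------------------------------
# Published department profile (prevalences in percent, normalized on use)

_DEPARTMENT = {
    "age": (4.72, 24.57, 21.88, 48.84),
    "cancer": 15.73,
    "sex_male": 55.55,
    "admission": (12.8, 69.0, 18.2),
    "time_slot": (33.2, 48.8, 18.1),
    "weekday": (13.9, 16.3, 16.6, 15.8, 16.3, 11.7, 10.15),
    "transfer": 0.0,  # transfers are a per-unit (micro) phenomenon
}

_UNIT_PREVALENCES = {
    "internal medicine": {
        "age": (2.30, 15.27, 18.46, 63.97), "cancer": 10.23, "sex_male": 50.26,
        "admission": (2.40, 93.60, 4.10), "time_slot": (16.5, 60.6, 22.9),
        "weekday": (13.2, 14.0, 16.1, 14.2, 15.9, 14.9, 11.7), "transfer": 0.09,
    },
    "cardiology": {
        "age": (1.46, 29.12, 32.36, 37.06), "cancer": 1.14, "sex_male": 65.69,
        "admission": (4.00, 24.70, 71.40), "time_slot": (74.1, 16.7, 9.2),
        "weekday": (14.5, 19.8, 17.3, 20.2, 17.8, 4.1, 6.3), "transfer": 0.2,
    },
    "emergency medicine": {
        "age": (4.83, 19.93, 20.64, 54.60), "cancer": 5.00, "sex_male": 55.59,
        "admission": (3.40, 96.20, 0.40), "time_slot": (12.7, 68.4, 18.9),
        "weekday": (13.8, 15.9, 14.3, 15.5, 15.1, 13.2, 12.2), "transfer": 0.16,
    },
    "geriatrics": {
        "age": (0.00, 0.23, 6.54, 93.24), "cancer": 6.20, "sex_male": 39.80,
        "admission": (1.80, 96.60, 1.60), "time_slot": (19.5, 56.8, 23.7),
        "weekday": (12.4, 13.9, 15.3, 15.9, 15.6, 15.1, 11.8), "transfer": 0.04,
    },
    "respiratory diseases": {
        "age": (1.95, 21.84, 25.59, 50.63), "cancer": 20.17, "sex_male": 61.34,
        "admission": (21.30, 62.40, 16.30), "time_slot": (31.3, 54.8, 13.9),
        "weekday": (12.2, 18.2, 16.1, 15.3, 17.5, 11.8, 8.8), "transfer": 0.06,
    },
    "neurology": {
        "age": (6.33, 25.18, 19.42, 49.06), "cancer": 8.35, "sex_male": 54.24,
        "admission": (12.40, 86.00, 1.60), "time_slot": (34.2, 43.7, 22.0),
        "weekday": (12.5, 14.2, 17.0, 16.4, 14.2, 13.5, 12.1), "transfer": 0.09,
    },
    "oncology": {
        "age": (1.61, 42.97, 31.53, 23.90), "cancer": 94.98, "sex_male": 56.43,
        "admission": (18.50, 42.00, 39.60), "time_slot": (57.2, 33.5, 9.2),
        "weekday": (17.1, 17.7, 16.1, 16.7, 16.7, 8.8, 7.0), "transfer": 0.08,
    },
}

# Unit shares: the seven modelled units in their observed relative sizes
# (largest: internal medicine, cardiology, emergency medicine), the six
# small units sharing the remainder equally.
_UNIT_MIX = {
    "internal medicine": 0.1593, "cardiology": 0.1458, "emergency medicine": 0.1323,
    "geriatrics": 0.1050, "respiratory diseases": 0.0851, "neurology": 0.0823,
    "oncology": 0.0589,
    "hematology": 0.03855, "infectious diseases": 0.03855, "nephrology": 0.03855,
    "coronary care": 0.03855, "gastroenterology": 0.03855, "rheumatology": 0.03855,
}

# Diagnosis-group case mix; the top 10 cover 85% of admissions.  Each group
# maps to one DRG with a realistic national-mean stay (days) and tariff.
_DIAGNOSES = {
    # group: (probability, ICD-9-CM-style codes, DRG, benchmark days, tariff EUR)
    "heart failure": (0.14, ("4280", "4281", "4289"), "127", 8.94, 3608.0),
    "pneumonia": (0.12, ("4829", "485", "486"), "089", 10.81, 3945.0),
    "sepsis": (0.10, ("0380", "0389", "03811"), "416", 13.96, 4512.0),
    "stroke": (0.09, ("434", "436"), "014", 9.30, 3674.0),
    "copd": (0.08, ("4910", "4960"), "088", 9.70, 3746.0),
    "urinary tract infection": (0.07, ("5990",), "320", 7.50, 3350.0),
    "gastrointestinal bleeding": (0.07, ("5789",), "174", 6.80, 3224.0),
    "renal failure": (0.06, ("5849",), "316", 8.20, 3476.0),
    "arrhythmia": (0.06, ("4271",), "138", 5.76, 3037.0),
    "neoplasm": (0.06, ("1629", "1748"), "082", 10.72, 3930.0),
    "anemia": (0.05, ("2859",), "395", 6.20, 3116.0),
    "cellulitis": (0.04, ("6826",), "277", 7.90, 3422.0),
    "syncope": (0.03, ("7802",), "142", 4.80, 2864.0),
    "cirrhosis": (0.03, ("5712",), "202", 9.10, 3638.0),
}

#: Default planted effects (log-scale shifts of the mean stay).
DEFAULT_EFFECTS = {
    "age_>75": 0.15,
    "cancer": 0.20,
    "adm_planned": 0.10,
    "slot_night": -0.10,
    "day_Sat": 0.08,
    "day_Sun": 0.08,
}

_DISCHARGE_PROBS = (0.80, 0.08, 0.07, 0.05)


def _normalize(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    s = v.sum()
    if s <= 0:
        raise ValueError("probability vector must have positive mass")
    return v / s


@dataclass
class CohortConfig:
    """Full specification of one synthetic cohort.

    ``effects`` maps design-matrix column names (``cancer``, ``age_>75``,
    ``slot_night``, ``diag_sepsis``, ``transfer``, ...) to additive log-scale
    LOS effects.  ``sigma`` is the log-normal noise sd; ``None`` calibrates
    it so the expected long-stay fraction equals ``target_long``.
    """

    n_records: int = 10_000
    seed: int = 0
    year: int = 2018
    unit_mix: dict = field(default_factory=lambda: dict(_UNIT_MIX))
    prevalences: dict = field(default_factory=lambda: {
        "__default__": dict(_DEPARTMENT), **{u: dict(p) for u, p in _UNIT_PREVALENCES.items()}
    })
    diagnosis_probs: dict = field(
        default_factory=lambda: {g: v[0] for g, v in _DIAGNOSES.items()})
    diagnosis_codes: dict = field(
        default_factory=lambda: {g: v[1] for g, v in _DIAGNOSES.items()})
    drg_of_group: dict = field(
        default_factory=lambda: {g: v[2] for g, v in _DIAGNOSES.items()})
    benchmark_days: dict = field(
        default_factory=lambda: {v[2]: v[3] for v in _DIAGNOSES.values()})
    reimbursement: dict = field(
        default_factory=lambda: {v[2]: v[4] for v in _DIAGNOSES.values()})
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    sigma: float | None = None
    target_long: float = 0.4006
    target_outlier: float = 0.0374

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        for name, vec in (("unit_mix", list(self.unit_mix.values())),
                          ("diagnosis_probs", list(self.diagnosis_probs.values()))):
            if abs(_normalize(vec).sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} does not normalize")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("noise sd must be positive")
        unknown = set(self.unit_mix) - set(UNITS)
        if unknown:
            raise ValueError(f"unknown units in unit_mix: {sorted(unknown)}")

    def replace(self, **changes) -> "CohortConfig":
        return dataclasses.replace(self, **changes)

    @property
    def n_drg(self) -> int:
        return len(set(self.drg_of_group.values()))

    def unit_prevalences(self, unit: str) -> dict:
        return self.prevalences.get(unit, self.prevalences["__default__"])


def default_department_config(n_records: int = 10_000, seed: int = 0) -> CohortConfig:
    """The default department-calibrated cohort configuration.

    Department-level prevalences (male 55.55%, age>75 48.84%, cancer 15.73%,
    admissions 12.8/69.0/18.2%, afternoon 48.8%, ...) with per-unit profiles
    for the seven modelled units, and outcome rates calibrated to 40.06%
    long stays / 3.74% outliers.
    """
    return CohortConfig(n_records=n_records, seed=seed)


# ---------------------------------------------------------------------------
# Exact finite distribution of the planted linear predictor

def _block_dist(levels_probs: list[tuple[str | None, float]], effects: dict) -> dict:
    """Distribution of one covariate block's effect contribution."""
    out: dict[float, float] = {}
    for col, p in levels_probs:
        v = effects.get(col, 0.0) if col is not None else 0.0
        out[v] = out.get(v, 0.0) + p
    return out


def _convolve(a: dict, b: dict) -> dict:
    out: dict[float, float] = {}
    for va, pa in a.items():
        for vb, pb in b.items():
            k = round(va + vb, 12)
            out[k] = out.get(k, 0.0) + pa * pb
    return out


def _unit_blocks(prev: dict, effects: dict) -> dict:
    """Effect distribution of all non-diagnosis covariates for one unit."""
    age = _normalize(prev["age"])
    adm = _normalize(prev["admission"])
    slot = _normalize(prev["time_slot"])
    day = _normalize(prev["weekday"])
    p_cancer = prev["cancer"] / 100.0
    p_male = prev["sex_male"] / 100.0
    p_tr = prev.get("transfer", 0.0) / 100.0
    blocks = [
        [("sex_male", p_male), (None, 1 - p_male)],
        [(f"age_{a}", p) for a, p in zip(AGE_CLASSES, age)],
        [("cancer", p_cancer), (None, 1 - p_cancer)],
        [(f"adm_{t}", p) for t, p in zip(ADMISSION_TYPES, adm)],
        [(f"slot_{t}", p) for t, p in zip(TIME_SLOTS, slot)],
        [(f"day_{d}", p) for d, p in zip(WEEKDAYS, day)],
        [("transfer", p_tr), (None, 1 - p_tr)],
    ]
    dist = {0.0: 1.0}
    for block in blocks:
        dist = _convolve(dist, _block_dist(block, effects))
    return dist


def _covariate_effect_distribution(config: CohortConfig) -> dict:
    """Mixture over units of the per-unit effect distributions."""
    mix = _normalize(list(config.unit_mix.values()))
    out: dict[float, float] = {}
    for (unit, _), w in zip(config.unit_mix.items(), mix):
        for v, p in _unit_blocks(config.unit_prevalences(unit), config.effects).items():
            out[v] = out.get(v, 0.0) + w * p
    return out


def _drg_effect_distributions(config: CohortConfig) -> dict[str, dict]:
    """Per-DRG distribution of beta·x (diagnosis effect + covariate mixture)."""
    base = _covariate_effect_distribution(config)
    groups_of_drg: dict[str, list[str]] = {}
    for g, d in config.drg_of_group.items():
        groups_of_drg.setdefault(d, []).append(g)
    out = {}
    for drg, groups in groups_of_drg.items():
        probs = _normalize([config.diagnosis_probs[g] for g in groups])
        diag = {}
        for g, p in zip(groups, probs):
            v = config.effects.get(f"diag_{g}", 0.0)
            diag[v] = diag.get(v, 0.0) + p
        out[drg] = _convolve(diag, base)
    return out


def _drg_weights(config: CohortConfig) -> dict[str, float]:
    probs = _normalize(list(config.diagnosis_probs.values()))
    out: dict[str, float] = {}
    for (g, _), p in zip(config.diagnosis_probs.items(), probs):
        d = config.drg_of_group[g]
        out[d] = out.get(d, 0.0) + p
    return out


def _long_fraction(sigma: float, dists: dict[str, dict], weights: dict[str, float]) -> float:
    """Expected P(LOS > model-mean benchmark) under noise sd ``sigma``.

    With the benchmark equal to the model marginal mean, the per-DRG long
    fraction is P(v + sigma·eps > log E[e^v] + sigma^2/2), independent of the
    DRG baseline.
    """
    total = 0.0
    for drg, dist in dists.items():
        v = np.array(list(dist.keys()))
        p = np.array(list(dist.values()))
        log_m = np.log(np.sum(p * np.exp(v)))
        frac = np.sum(p * norm.sf((log_m + sigma**2 / 2 - v) / sigma))
        total += weights[drg] * frac
    return total


def _calibrate_sigma(config: CohortConfig, dists, weights) -> float:
    if config.sigma is not None:
        return config.sigma
    f = lambda s: _long_fraction(s, dists, weights) - config.target_long
    lo, hi = 1e-3, 4.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(
            "cannot calibrate noise sd to the requested long-stay rate; "
            "set sigma explicitly"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


def model_reference_table(config: CohortConfig) -> dict[str, DRGReference]:
    """The DRG reference implied by the generating model.

    Benchmark = exact marginal mean LOS of the model per DRG; threshold = the
    per-DRG quantile exceeded with probability ``target_outlier``.
    """
    dists = _drg_effect_distributions(config)
    weights = _drg_weights(config)
    sigma = _calibrate_sigma(config, dists, weights)
    q = 1.0 - config.target_outlier
    table: dict[str, DRGReference] = {}
    for drg, dist in dists.items():
        v = np.array(list(dist.keys()))
        p = np.array(list(dist.values()))
        log_m = float(np.log(np.sum(p * np.exp(v))))
        bench = config.benchmark_days[drg]
        mu = np.log(bench) - log_m - sigma**2 / 2  # baseline log-mean of this DRG
        # threshold: F(T) = q for the lognormal mixture
        cdf = lambda t: float(np.sum(p * norm.cdf((t - mu - v) / sigma))) - q
        lo = mu + v.min() - 10 * sigma
        hi = mu + v.max() + 10 * sigma
        log_t = brentq(cdf, lo, hi, xtol=1e-12)
        table[drg] = DRGReference(
            drg_code=drg,
            benchmark_los=bench,
            threshold_los=float(np.exp(log_t)),
            mean_reimbursement=config.reimbursement[drg],
        )
    return table


def baseline_log_means(config: CohortConfig) -> dict[str, float]:
    """Per-DRG baseline log-mean mu implied by the benchmark targets."""
    dists = _drg_effect_distributions(config)
    weights = _drg_weights(config)
    sigma = _calibrate_sigma(config, dists, weights)
    out = {}
    for drg, dist in dists.items():
        v = np.array(list(dist.keys()))
        p = np.array(list(dist.values()))
        log_m = float(np.log(np.sum(p * np.exp(v))))
        out[drg] = float(np.log(config.benchmark_days[drg]) - log_m - sigma**2 / 2)
    return out


def calibrated_sigma(config: CohortConfig) -> float:
    dists = _drg_effect_distributions(config)
    return _calibrate_sigma(config, dists, _drg_weights(config))


def planted_truth(config: CohortConfig) -> dict[str, float]:
    """The exact effect vector used by the generator, one entry per column.

    Ordered as the macro design-matrix columns plus the diagnosis groups and
    the transfer flag; covariates the config gives no effect carry 0.
    """
    cols = (
        ["sex_male"] + [f"age_{a}" for a in AGE_CLASSES] + ["cancer"]
        + [f"adm_{t}" for t in ADMISSION_TYPES] + [f"slot_{t}" for t in TIME_SLOTS]
        + [f"day_{d}" for d in WEEKDAYS]
        + [f"diag_{g}" for g in config.diagnosis_probs]
        + ["transfer"]
    )
    return {c: float(config.effects.get(c, 0.0)) for c in cols}


# ---------------------------------------------------------------------------
# Cohort generation

def _draw_level(rng, levels, probs, n):
    return rng.choice(len(levels), size=n, p=_normalize(probs))


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[HospitalizationRecord], dict[str, DRGReference]]:
    """Draw a cohort and its model-derived DRG reference table.

    Deterministic given ``config.seed``.  Covariates are sampled per unit
    from the configured prevalences; LOS is log-normal around the DRG
    baseline shifted by the planted effects.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    mus = baseline_log_means(config)
    sigma = calibrated_sigma(config)
    drg_ref = model_reference_table(config)

    units = list(config.unit_mix.keys())
    unit_idx = _draw_level(rng, units, list(config.unit_mix.values()), n)
    groups = list(config.diagnosis_probs.keys())
    group_idx = _draw_level(rng, groups, list(config.diagnosis_probs.values()), n)

    # per-unit covariate draws
    sex = np.zeros(n, dtype=int)
    cancer = np.zeros(n, dtype=int)
    transfer = np.zeros(n, dtype=int)
    age_i = np.zeros(n, dtype=int)
    adm_i = np.zeros(n, dtype=int)
    slot_i = np.zeros(n, dtype=int)
    day_i = np.zeros(n, dtype=int)
    for u, unit in enumerate(units):
        mask = unit_idx == u
        m = int(mask.sum())
        if m == 0:
            continue
        prev = config.unit_prevalences(unit)
        sex[mask] = rng.random(m) < prev["sex_male"] / 100.0
        cancer[mask] = rng.random(m) < prev["cancer"] / 100.0
        transfer[mask] = rng.random(m) < prev.get("transfer", 0.0) / 100.0
        age_i[mask] = _draw_level(rng, AGE_CLASSES, prev["age"], m)
        adm_i[mask] = _draw_level(rng, ADMISSION_TYPES, prev["admission"], m)
        slot_i[mask] = _draw_level(rng, TIME_SLOTS, prev["time_slot"], m)
        day_i[mask] = _draw_level(rng, WEEKDAYS, prev["weekday"], m)

    eff = config.effects
    lin = np.zeros(n)
    lin += sex * eff.get("sex_male", 0.0)
    lin += np.array([eff.get(f"age_{AGE_CLASSES[i]}", 0.0) for i in range(4)])[age_i]
    lin += cancer * eff.get("cancer", 0.0)
    lin += np.array([eff.get(f"adm_{t}", 0.0) for t in ADMISSION_TYPES])[adm_i]
    lin += np.array([eff.get(f"slot_{t}", 0.0) for t in TIME_SLOTS])[slot_i]
    lin += np.array([eff.get(f"day_{d}", 0.0) for d in WEEKDAYS])[day_i]
    lin += transfer * eff.get("transfer", 0.0)
    lin += np.array([eff.get(f"diag_{g}", 0.0) for g in groups])[group_idx]

    mu_vec = np.array([mus[config.drg_of_group[g]] for g in groups])[group_idx]
    los = np.exp(mu_vec + lin + sigma * rng.standard_normal(n))

    discharge_i = _draw_level(rng, DISCHARGE_MODES, _DISCHARGE_PROBS, n)
    records = []
    for i in range(n):
        g = groups[group_idx[i]]
        codes = config.diagnosis_codes[g]
        records.append(HospitalizationRecord(
            record_id=f"H{config.year}-{i:06d}",
            unit=units[unit_idx[i]],
            sex=int(sex[i]),
            age_class=AGE_CLASSES[age_i[i]],
            cancer=int(cancer[i]),
            admission_type=ADMISSION_TYPES[adm_i[i]],
            time_slot=TIME_SLOTS[slot_i[i]],
            weekday=WEEKDAYS[day_i[i]],
            diagnosis_code=codes[int(rng.integers(len(codes)))],
            diagnosis_group=g,
            drg_code=config.drg_of_group[g],
            los_days=float(los[i]),
            discharge_mode=DISCHARGE_MODES[discharge_i[i]],
            transfer=int(transfer[i]),
            year=config.year,
        ))
    return records, drg_ref
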