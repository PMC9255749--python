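"""Synthetic ICU cohort generation for ordinal GOSE prognosis studies.

Real multicentre TBI datasets are access-controlled, so every downstream
stage of the pipeline is exercised on seeded synthetic cohorts that emulate
the statistical structure the analysis assumes:

* a seven-category ordinal outcome (GOSE 1, 2/3, 4, 5, 6, 7, 8) with the
  marginal distribution of a reference ICU cohort (n = 1,550);
* the ten-predictor concise baseline set (the validated IMPACT predictors:
  age, motor GCS, pupillary reactivity, hypoxia, hypotension, Marshall CT
  class, traumatic subarachnoid haemorrhage, extradural haematoma, glucose,
  haemoglobin), with marginals matched to the reference cohort's printed
  medians/IQRs and category frequencies;
* realistic multivariate missingness patterns (54.77% complete cases;
  14.71% with only glucose and haemoglobin missing);
* a proportional-odds latent generative link, so that ordinal-regression
  recovery tests are well-posed; and
* wide heterogeneous per-patient records (categorical, continuous,
  free-text and missing fields) at a scale of ~532 unique tokens per
  patient, for token-embedding models.

Only marginal summaries of the reference cohort are public; joint predictor
correlations are therefore configurable rather than calibrated, and the
generator draws predictors independently by default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .probability import N_CATEGORIES


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


# Marginal outcome counts of the reference ICU cohort (n = 1,550), in
# category order GOSE 1, 2/3, 4, 5, 6, 7, 8.
GOSE_MARGINAL_COUNTS: tuple[int, ...] = (318, 262, 120, 227, 200, 206, 217)
DEFAULT_CATEGORY_PROBS: tuple[float, ...] = tuple(
    c / sum(GOSE_MARGINAL_COUNTS) for c in GOSE_MARGINAL_COUNTS
)
# Cutpoints on the latent scale chosen so that a null linear predictor
# reproduces the marginal outcome distribution exactly.
DEFAULT_CUTPOINTS: tuple[float, ...] = tuple(
    float(logit(np.cumsum(DEFAULT_CATEGORY_PROBS)[:-1][k])) for k in range(6)
)

CONCISE_PREDICTORS: tuple[str, ...] = (
    "age",
    "GCSm",
    "pupils",
    "hypoxia",
    "hypotension",
    "marshall",
    "tsah",
    "edh",
    "glucose",
    "hb",
)

EXTENDED_PREDICTORS: tuple[str, ...] = CONCISE_PREDICTORS + (
    "retired",
    "education",
    "nfl",
    "gfap",
    "ttau",
    "s100b",
    "ais_head",
    "amnesia",
)


@dataclass(frozen=True)
class PredictorSpec:
    """Marginal specification of one baseline predictor.

    ``kind`` is one of ``continuous``, ``binary`` or ``categorical``;
    ``center``/``scale`` standardise the predictor's contribution to the
    latent linear predictor so coefficients are per-SD effects.
    """

    name: str
    kind: str
    levels: tuple = ()
    probs: tuple = ()
    dist: dict = field(default_factory=dict)
    center: float = 0.0
    scale: float = 1.0


def concise_schema() -> list[PredictorSpec]:
    """The ten concise (IMPACT) predictors, marginals matched to the reference cohort."""
    return [
        # age: median 51, IQR 31-66 -> truncated normal on [16, 95]
        PredictorSpec("age", "continuous",
                      dist={"family": "truncnorm", "mean": 50.0, "sd": 24.0,
                            "low": 16.0, "high": 95.0},
                      center=50.0, scale=20.0),
        # motor GCS: 6 levels, frequencies from the reference cohort
        PredictorSpec("GCSm", "categorical", levels=(1, 2, 3, 4, 5, 6),
                      probs=(0.321, 0.036, 0.042, 0.076, 0.202, 0.323)),
        # unreactive pupils: 0, 1 or 2
        PredictorSpec("pupils", "categorical", levels=(0, 1, 2),
                      probs=(0.810, 0.076, 0.114)),
        PredictorSpec("hypoxia", "binary", levels=(0, 1), probs=(0.866, 0.134)),
        PredictorSpec("hypotension", "binary", levels=(0, 1), probs=(0.865, 0.135)),
        # Marshall CT class I-VI (mass lesions V and VI split evenly)
        PredictorSpec("marshall", "categorical", levels=(1, 2, 3, 4, 5, 6),
                      probs=(0.094, 0.472, 0.086, 0.013, 0.167, 0.168)),
        PredictorSpec("tsah", "binary", levels=(0, 1), probs=(0.237, 0.763)),
        PredictorSpec("edh", "binary", levels=(0, 1), probs=(0.806, 0.194)),
        # glucose mmol/L: median 7.7, IQR 6.6-9.4 -> log-normal
        PredictorSpec("glucose", "continuous",
                      dist={"family": "lognormal", "log_mean": 2.041, "log_sd": 0.262},
                      center=7.9, scale=2.2),
        # haemoglobin g/dL: median 13, IQR 12-14
        PredictorSpec("hb", "continuous",
                      dist={"family": "normal", "mean": 13.0, "sd": 1.48},
                      center=13.0, scale=1.48),
    ]


def extended_schema() -> list[PredictorSpec]:
    """Concise predictors plus the eight high-impact additions.

    The additions mirror the extended concise set: retirement status, formal
    education, four protein biomarkers (NFL, GFAP, total tau, S100B; drawn
    log-normal as biomarker concentrations are right-skewed), the worst
    head/neck AIS severity score and post-traumatic amnesia.
    """
    extra = [
        PredictorSpec("retired", "binary", levels=(0, 1), probs=(0.75, 0.25)),
        PredictorSpec("education", "continuous",
                      dist={"family": "truncnorm", "mean": 12.0, "sd": 4.0,
                            "low": 0.0, "high": 22.0},
                      center=12.0, scale=3.7),
        PredictorSpec("nfl", "continuous",
                      dist={"family": "lognormal", "log_mean": 3.0, "log_sd": 1.0},
                      center=33.0, scale=45.0),
        PredictorSpec("gfap", "continuous",
                      dist={"family": "lognormal", "log_mean": 8.0, "log_sd": 1.2},
                      center=6100.0, scale=11000.0),
        PredictorSpec("ttau", "continuous",
                      dist={"family": "lognormal", "log_mean": 2.0, "log_sd": 0.9},
                      center=11.0, scale=12.0),
        PredictorSpec("s100b", "continuous",
                      dist={"family": "lognormal", "log_mean": -1.0, "log_sd": 0.8},
                      center=0.5, scale=0.5),
        PredictorSpec("ais_head", "categorical", levels=(1, 2, 3, 4, 5, 6),
                      probs=(0.05, 0.10, 0.25, 0.30, 0.25, 0.05)),
        PredictorSpec("amnesia", "binary", levels=(0, 1), probs=(0.6, 0.4)),
    ]
    return concise_schema() + extra


def default_coefficients(schema_name: str = "concise") -> dict:
    """Per-SD (continuous) and per-level (categorical) latent effects.

    Positive values shift patients towards better outcomes under the
    proportional-odds convention P(Y <= k) = sigmoid(theta_k - eta).
    Magnitudes are plausible for TBI prognosis (age, pupils and Marshall
    class dominate) but are a design choice: the reference study prints no
    generative coefficients.
    """
    beta = {
        "age": -0.55,
        "GCSm": {1: -0.55, 2: -0.45, 3: -0.30, 4: -0.10, 5: 0.25, 6: 0.60},
        "pupils": {0: 0.25, 1: -0.45, 2: -1.05},
        "hypoxia": -0.35,
        "hypotension": -0.45,
        "marshall": {1: 0.45, 2: 0.30, 3: -0.30, 4: -0.45, 5: -0.55, 6: -0.60},
        "tsah": -0.30,
        "edh": 0.20,
        "glucose": -0.30,
        "hb": 0.18,
    }
    if schema_name == "extended":
        beta.update({
            "retired": -0.30,
            "education": 0.20,
            "nfl": -0.40,
            "gfap": -0.35,
            "ttau": -0.30,
            "s100b": -0.35,
            "ais_head": {1: 0.3, 2: 0.2, 3: 0.0, 4: -0.15, 5: -0.35, 6: -0.5},
            "amnesia": -0.15,
        })
    return beta


def default_missingness() -> list[tuple[tuple[str, ...], float]]:
    """Default per-patient missingness patterns (missing-completely-at-random).

    Calibrated so that 54.77% of patients have no missing concise predictors
    and 14.71% have only glucose and haemoglobin missing; the remaining mass
    is spread over plausible co-missingness of the CT variables, pupils and
    motor GCS.
    """
    return [
        (("glucose", "hb"), 0.1471),
        (("marshall", "tsah", "edh"), 0.0900),
        (("marshall", "tsah", "edh", "glucose", "hb"), 0.0850),
        (("glucose",), 0.0400),
        (("hb",), 0.0300),
        (("pupils",), 0.0250),
        (("pupils", "GCSm"), 0.0150),
        (("GCSm",), 0.0102),
        (("glucose", "hb", "pupils"), 0.0100),
    ]


@dataclass(frozen=True)
class HeterogeneousRecordSpec:
    """Scale and signal content of the wide heterogeneous records.

    Defaults target a median of ~532 unique non-missing tokens per patient
    (IQR roughly 486-580), the scale of an all-predictor ICU baseline
    extraction. ``informative_*`` variables are correlated with the latent
    linear predictor; the rest are pure noise. ``tokens_spread`` is the SD
    of the per-patient recorded-field count (IQR = 1.349 x SD).
    """

    n_continuous: int = 400
    n_categorical: int = 380
    n_text: int = 56
    informative_continuous: int = 8
    informative_categorical: int = 8
    informative_text: int = 8
    tokens_center: float = 532.0
    tokens_spread: float = 69.7
    missing_rate: float = 0.02
    n_levels: int = 6
    signal: float = 1.0

    def scaled(self, factor: float) -> "HeterogeneousRecordSpec":
        """A proportionally smaller spec for fast tests (e.g. factor=0.1)."""
        return dataclasses.replace(
            self,
            n_continuous=max(self.informative_continuous, int(self.n_continuous * factor)),
            n_categorical=max(self.informative_categorical, int(self.n_categorical * factor)),
            n_text=max(self.informative_text, int(self.n_text * factor)),
            tokens_center=self.tokens_center * factor,
            tokens_spread=self.tokens_spread * factor,
        )

    def variable_names(self) -> dict[str, list[str]]:
        cont = [f"ContVar{i:04d}" for i in range(self.n_continuous)]
        cat = [f"CatVar{i:04d}" for i in range(self.n_categorical)]
        text = [f"TextVar{i:04d}" for i in range(self.n_text)]
        return {"continuous": cont, "categorical": cat, "text": text}

    def kind_map(self) -> dict[str, str]:
        names = self.variable_names()
        m = {v: k for k, vs in names.items() for v in vs}
        m.update({
            "GCSTotalScore": "categorical",
            "SystolicBloodPressure": "continuous",
            "InjuryDescription": "text",
            "PriorMedications": "text",
        })
        return m

    def informative_names(self) -> list[str]:
        names = self.variable_names()
        return (
            names["continuous"][: self.informative_continuous]
            + names["categorical"][: self.informative_categorical]
            + names["text"][: self.informative_text]
            + ["GCSTotalScore", "InjuryDescription"]
        )


# Fixed free-text pool; only the strip-and-lowercase normalisation matters
# downstream, so short injury-description phrases suffice.
TEXT_PHRASES: tuple[str, ...] = (
    "Skull fracture!", "Diffuse axonal injury", "Subdural haematoma",
    "Epidural bleed", "Cerebral contusion", "Midline shift",
    "Basal cistern effacement", "Intraventricular haemorrhage",
    "Frontal contusion", "Temporal contusion", "Cerebral oedema",
    "Petechial haemorrhages", "Fall from height", "Road traffic accident",
    "Assault", "Sports injury", "Penetrating injury", "Crush injury",
    "Scalp laceration", "Facial fractures", "No acute findings",
    "Polytrauma", "Isolated head injury", "Bicycle accident",
)
_TEXT_SEVERITY = {
    "worse": ("Diffuse axonal injury", "Midline shift", "Basal cistern effacement",
              "Cerebral oedema", "Penetrating injury", "Polytrauma"),
    "mid": ("Subdural haematoma", "Cerebral contusion", "Frontal contusion",
            "Temporal contusion", "Road traffic accident", "Fall from height"),
    "better": ("No acute findings", "Scalp laceration", "Sports injury",
               "Isolated head injury", "Bicycle accident", "Skull fracture!"),
}


@dataclass
class GeneratorConfig:
    """Complete specification of one synthetic cohort draw."""

    n_patients: int
    category_probs: tuple = DEFAULT_CATEGORY_PROBS
    cutpoints: tuple = DEFAULT_CUTPOINTS
    coefficients: dict = field(default_factory=dict)
    schema: list = field(default_factory=concise_schema)
    missingness: list = field(default_factory=default_missingness)
    record_spec: HeterogeneousRecordSpec | None = None
    outcome_mode: str = "latent"  # 'marginal' (mode A) or 'latent' (mode B)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.shape != (N_CATEGORIES,) or np.any(probs < 0):
            raise ConfigurationError("category_probs must be 7 non-negative reals")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigurationError("category_probs must sum to 1 (tol 1e-12)")
        cuts = np.asarray(self.cutpoints, dtype=float)
        if cuts.shape != (6,) or np.any(np.diff(cuts) <= 0):
            raise ConfigurationError("cutpoints must be 6 strictly increasing reals")
        names = {s.name for s in self.schema}
        for pred in self.coefficients:
            if pred not in names:
                raise ConfigurationError(
                    f"coefficient references predictor {pred!r} absent from schema")
        total = sum(p for _, p in self.missingness)
        if total > 1 + 1e-12:
            raise ConfigurationError("missingness pattern probabilities sum above 1")
        for subset, _ in self.missingness:
            for v in subset:
                if v not in names:
                    raise ConfigurationError(
                        f"missingness pattern references unknown predictor {v!r}")
        if self.outcome_mode not in ("marginal", "latent"):
            raise ConfigurationError("outcome_mode must be 'marginal' or 'latent'")


def default_config(n_patients: int = 1550, outcome_mode: str = "latent",
                   schema_name: str = "concise", seed: int = 0,
                   with_missingness: bool = True) -> GeneratorConfig:
    """A ready-to-run configuration reproducing the study conditions."""
    schema = concise_schema() if schema_name == "concise" else extended_schema()
    return GeneratorConfig(
        n_patients=n_patients,
        coefficients=default_coefficients(schema_name),
        schema=schema,
        missingness=default_missingness() if with_missingness else [],
        outcome_mode=outcome_mode,
        seed=seed,
    )


@dataclass
class SyntheticCohort:
    """A generated cohort: observed table, complete truth, and config echo.

    ``table`` has one row per patient (patient_id, predictors, outcome);
    masked cells are NaN, with the pre-masking values retained in ``truth``
    alongside the latent linear predictor ``eta``. ``missing_mask`` is True
    where a cell has been masked.
    """

    table: pd.DataFrame
    truth: pd.DataFrame
    missing_mask: pd.DataFrame
    config: GeneratorConfig

    @property
    def predictor_names(self) -> list[str]:
        return [s.name for s in self.config.schema]

    def write(self, table_path, truth_path) -> None:
        """Write the cohort as delimited text plus a JSON truth sidecar."""
        self.table.to_csv(table_path, index=False)
        payload = {
            "eta": self.truth["eta"].tolist(),
            "complete": {c: self.truth[c].tolist() for c in self.truth.columns},
            "patient_id": self.table["patient_id"].tolist(),
            "seed": self.config.seed,
        }
        with open(truth_path, "w") as fh:
            json.dump(payload, fh)


def _draw_predictor(spec: PredictorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind in ("categorical", "binary"):
        probs = np.asarray(spec.probs, dtype=float)
        probs = probs / probs.sum()
        return rng.choice(np.asarray(spec.levels, dtype=float), size=n, p=probs)
    family = spec.dist.get("family")
    if family == "normal":
        return rng.normal(spec.dist["mean"], spec.dist["sd"], size=n)
    if family == "lognormal":
        return rng.lognormal(spec.dist["log_mean"], spec.dist["log_sd"], size=n)
    if family == "truncnorm":
        lo, hi = spec.dist["low"], spec.dist["high"]
        mu, sd = spec.dist["mean"], spec.dist["sd"]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    raise ConfigurationError(f"unknown continuous family {family!r} for {spec.name}")


def linear_predictor(table: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Latent linear predictor eta = x'beta under the generator's coefficients."""
    eta = np.zeros(len(table))
    specs = {s.name: s for s in config.schema}
    for name, beta in config.coefficients.items():
        spec = specs[name]
        x = table[name].to_numpy(dtype=float)
        if isinstance(beta, dict):
            contrib = np.zeros_like(eta)
            for level, b in beta.items():
                contrib[x == float(level)] = b
            eta += contrib
        elif spec.kind == "binary":
            eta += beta * x
        else:
            eta += beta * (x - spec.center) / spec.scale
    return eta


def generate_concise_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a complete cohort (no missingness applied yet).

    Outcomes are drawn either directly from the marginal category
    probabilities (``outcome_mode='marginal'``) or from the
    proportional-odds link ``P(Y <= k | x) = sigmoid(theta_k - eta)``
    (``outcome_mode='latent'``). Deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    n = config.n_patients
    data = {"patient_id": [f"P{i:05d}" for i in range(n)]}
    for spec in config.schema:
        data[spec.name] = _draw_predictor(spec, n, rng)
    table = pd.DataFrame(data)
    eta = linear_predictor(table, config)
    if config.outcome_mode == "marginal":
        outcome = rng.choice(np.arange(1, 8), size=n, p=np.asarray(config.category_probs))
    else:
        cuts = np.asarray(config.cutpoints)
        cum = expit(cuts[None, :] - eta[:, None])          # (n, 6) = P(Y <= k)
        u = rng.uniform(size=n)
        outcome = 1 + (u[:, None] > cum).sum(axis=1)       # category codes 1..7
    table["outcome"] = outcome.astype(int)
    truth = table.drop(columns=["patient_id"]).copy()
    truth.insert(0, "eta", eta)
    mask = pd.DataFrame(False, index=table.index,
                        columns=[s.name for s in config.schema])
    return SyntheticCohort(table=table, truth=truth, missing_mask=mask, config=config)


def apply_missingness(cohort: SyntheticCohort,
                      patterns: list[tuple[tuple[str, ...], float]] | None = None,
                      ) -> SyntheticCohort:
    """Mask predictor cells according to per-patient missingness patterns.

    Each patient is assigned one pattern (or none, with the leftover
    probability mass = complete cases); the outcome and the truth sidecar
    are never altered.
    """
    if patterns is None:
        patterns = cohort.config.missingness
    names = {s.name for s in cohort.config.schema}
    for subset, _ in patterns:
        for v in subset:
            if v not in names:
                raise ConfigurationError(f"pattern references unknown predictor {v!r}")
    probs = np.asarray([p for _, p in patterns], dtype=float)
    if probs.sum() > 1 + 1e-12:
        raise ConfigurationError("missingness pattern probabilities sum above 1")
    if not patterns:
        return cohort
    rng = np.random.default_rng([2, cohort.config.seed])
    full = np.append(probs, 1.0 - probs.sum())             # last index = complete
    assignment = rng.choice(len(full), size=len(cohort.table), p=full)
    table = cohort.table.copy()
    mask = cohort.missing_mask.copy()
    for k, (subset, _) in enumerate(patterns):
        rows = assignment == k
        for v in subset:
            table.loc[rows, v] = np.nan
            mask.loc[rows, v] = True
    return SyntheticCohort(table=table, truth=cohort.truth, missing_mask=mask,
                           config=cohort.config)


def generate_heterogeneous_records(config: GeneratorConfig, cohort: SyntheticCohort,
                                   spec: HeterogeneousRecordSpec | None = None,
                                   ) -> list[dict]:
    """Generate wide raw records (categorical/continuous/text/missing fields).

    Informative variables are correlated with the patient's latent linear
    predictor; the remainder are noise. Each record is a dict
    ``{"patient_id": ..., "fields": {name: value-or-None}}``, the format the
    tokenizer consumes; the per-variable kind map comes from
    ``spec.kind_map()``.
    """
    spec = spec or config.record_spec or HeterogeneousRecordSpec()
    rng = np.random.default_rng([3, config.seed])
    names = spec.variable_names()
    informative = set(spec.informative_names())
    all_vars = (names["continuous"] + names["categorical"] + names["text"]
                + ["GCSTotalScore", "SystolicBloodPressure",
                   "InjuryDescription", "PriorMedications"])
    kind = spec.kind_map()
    eta = cohort.truth["eta"].to_numpy()
    eta_sd = eta.std() if eta.std() > 0 else 1.0
    eta_z = (eta - eta.mean()) / eta_sd
    always = [v for v in all_vars if v in informative or v == "PriorMedications"]
    optional = np.array([v for v in all_vars if v not in always])
    records = []
    for i, pid in enumerate(cohort.table["patient_id"]):
        m = int(np.clip(rng.normal(spec.tokens_center, spec.tokens_spread),
                        len(always), len(all_vars)))
        n_opt = max(0, m - len(always))
        chosen = list(always) + list(rng.choice(optional, size=min(n_opt, len(optional)),
                                                replace=False))
        fields: dict = {}
        for v in chosen:
            is_inf = v in informative
            latent = spec.signal * eta_z[i] + rng.normal() if is_inf else rng.normal()
            k = kind[v]
            if v == "GCSTotalScore":
                fields[v] = int(np.clip(round(9 + 3 * latent), 3, 15))
            elif v == "PriorMedications":
                # frequently absent on purpose: exercises the NA token path
                fields[v] = None if rng.uniform() < 0.5 else "none reported"
            elif k == "continuous":
                fields[v] = float(latent) if is_inf else float(rng.normal())
            elif k == "categorical":
                lvl = int(np.clip(np.floor((latent + 3.0) / 6.0 * spec.n_levels),
                                  0, spec.n_levels - 1))
                fields[v] = lvl if is_inf else int(rng.integers(spec.n_levels))
            else:  # text
                if is_inf:
                    pool = (_TEXT_SEVERITY["worse"] if latent < -0.43
                            else _TEXT_SEVERITY["mid"] if latent < 0.43
                            else _TEXT_SEVERITY["better"])
                    fields[v] = str(rng.choice(pool))
                else:
                    fields[v] = str(rng.choice(TEXT_PHRASES))
        # a sprinkling of explicitly-missing extra fields -> NA tokens
        n_missing = rng.binomial(len(optional), spec.missing_rate)
        for v in rng.choice(optional, size=min(n_missing, len(optional)), replace=False):
            fields.setdefault(v, None)
        records.append({"patient_id": pid, "fields": fields})
    return records


def write_records_jsonl(records: list[dict], path) -> None:
    """Write heterogeneous records as JSON-lines, one record object per patient."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_records_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
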